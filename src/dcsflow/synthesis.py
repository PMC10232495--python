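"""Synthetic-data generators.

Everything here is a pure function of (configuration, seed) and exists to
exercise the rest of the package under controlled conditions:

* ``correlation_noise`` — adds shot-noise-limited, lag-correlated noise to a
  clean correlation curve (Koppel-type scaling: per-lag sd proportional to
  ``1/sqrt(count_rate * averaging_time)``);
* ``generate_pulsatile_bfi`` — cardiac-pulsatile BFi traces with
  beat-to-beat jitter and multiplicative task epochs (baseline /
  activation / recovery), returning ground-truth beat onsets;
* ``generate_curve_stream`` — converts a BFi time series into a stream of
  correlation curves at an instrument rate (100 Hz long-separation or 10 Hz
  short-separation conventions) through the homodyne or heterodyne forward
  model;
* ``generate_linescan_frames`` — raw heterodyne linescan-camera pixel
  streams: a complex circular-Gaussian speckle field with prescribed
  temporal correlation interfered with a constant reference, plus quadratic
  drift, a rank-1 common-mode signal, integrate-while-read line leakage and
  additive read noise, with the ground truth returned for recovery tests.

The noise and speckle models are standard statistical stand-ins (documented
in the methods note); real instruments add artifacts these generators do
not attempt to reproduce quantitatively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import lfilter

from .core_models import (CorrelationCurve, Flow, MeasurementGeometry,
                          OpticalProperties, heterodyne_g2, semi_infinite_g1,
                          siegert_g2)
from .physio_analysis import BfiTimeSeries

__all__ = [
    "PulsatileParams",
    "LinescanConfig",
    "Epoch",
    "tourniquet_schedule",
    "breath_hold_schedule",
    "correlation_noise",
    "generate_pulsatile_bfi",
    "generate_curve_stream",
    "generate_linescan_frames",
    "multi_tau_lags",
]


@dataclass(frozen=True)
class Epoch:
    """A task epoch: BFi is multiplied by ``multiplier`` on
    [onset, onset + duration)."""

    label: str
    onset: float
    duration: float
    multiplier: float = 1.0


def tourniquet_schedule(n_cycles: int = 3) -> tuple:
    """Tourniquet-style schedule: 60 s baseline, n x (30 s pressure,
    30 s release), 60 s recovery.  Multipliers are applied by the caller."""
    epochs = []
    t = 60.0
    for i in range(n_cycles):
        epochs.append(Epoch(f"pressure_{i}", t, 30.0, 1.0))
        t += 60.0
    return tuple(epochs)


def breath_hold_schedule(n_cycles: int = 4) -> tuple:
    """Breath-hold-style schedule: 60 s baseline, n x (30 s hold,
    40 s normal breathing), 20 s recovery."""
    epochs = []
    t = 60.0
    for i in range(n_cycles):
        epochs.append(Epoch(f"hold_{i}", t, 30.0, 1.0))
        t += 70.0
    return tuple(epochs)


@dataclass(frozen=True)
class PulsatileParams:
    """Parameters of the pulsatile BFi generator.

    ``mean_bfi`` [cm^2/s] is the beat-averaged BFi during baseline;
    ``pulsatility_fraction`` in [0, 1) scales the zero-mean cardiac waveform;
    ``heart_rate`` [beats/min] with Gaussian beat-to-beat jitter
    ``rr_jitter_sd`` [s]; ``systolic_peak_phase`` sets where in the cycle
    the waveform peaks; ``epochs`` multiply BFi on their intervals.
    """

    mean_bfi: float = 1e-8
    pulsatility_fraction: float = 0.3
    heart_rate: float = 60.0
    rr_jitter_sd: float = 0.02
    systolic_peak_phase: float = 0.2
    epochs: tuple = ()
    sample_rate: float = 100.0

    def __post_init__(self) -> None:
        if self.mean_bfi <= 0:
            raise ValueError("mean_bfi must be > 0")
        if not (0 <= self.pulsatility_fraction < 1):
            raise ValueError("pulsatility_fraction must lie in [0, 1)")
        if self.sample_rate <= 2 * self.heart_rate / 60.0:
            raise ValueError("sample_rate must exceed twice the heart-rate frequency")


def _pulse_shape(phase: np.ndarray, peak_phase: float) -> np.ndarray:
    """Zero-mean cardiac waveform on phase in [0, 1): fast systolic rise to
    a peak at ``peak_phase``, exponential diastolic decay; normalized to a
    peak-to-peak amplitude of 2 (so it spans roughly [-1, 1])."""
    p = phase / peak_phase
    w = p * np.exp(1.0 - p)
    # dense reference grid for the normalization constants
    ref = np.linspace(0, 1, 512, endpoint=False) / peak_phase
    wr = ref * np.exp(1.0 - ref)
    w = w - wr.mean()
    return 2.0 * w / (wr.max() - wr.min())


def generate_pulsatile_bfi(params: PulsatileParams, duration: float,
                           seed: int) -> tuple:
    """Generate a pulsatile BFi time series.

    Returns ``(series, beat_onsets)`` where ``series`` is a
    :class:`~dcsflow.physio_analysis.BfiTimeSeries` sampled at
    ``params.sample_rate`` and ``beat_onsets`` are the ground-truth beat
    start times [s].
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed)
    mean_rr = 60.0 / params.heart_rate
    onsets = [0.0]
    while onsets[-1] < duration:
        rr = mean_rr + rng.normal(0.0, params.rr_jitter_sd)
        rr = max(rr, 0.3)
        onsets.append(onsets[-1] + rr)
    onsets = np.asarray(onsets)

    t = np.arange(0.0, duration, 1.0 / params.sample_rate)
    beat_idx = np.clip(np.searchsorted(onsets, t, side="right") - 1, 0,
                       onsets.size - 2)
    phase = (t - onsets[beat_idx]) / (onsets[beat_idx + 1] - onsets[beat_idx])
    waveform = _pulse_shape(np.clip(phase, 0.0, 1.0 - 1e-9),
                            params.systolic_peak_phase)

    mult = np.ones_like(t)
    for ep in params.epochs:
        mult[(t >= ep.onset) & (t < ep.onset + ep.duration)] *= ep.multiplier

    bfi = params.mean_bfi * mult * (1.0 + params.pulsatility_fraction * waveform)
    annotations = [(ep.label, ep.onset, ep.duration) for ep in params.epochs]
    series = BfiTimeSeries(t=t, bfi=bfi, rate=params.sample_rate,
                           annotations=annotations)
    return series, onsets[onsets <= duration]


def correlation_noise(clean: CorrelationCurve, count_rate: float,
                      averaging_time: float, beta: float, seed: int,
                      correlation_lags: float = 2.0) -> CorrelationCurve:
    """Add lag-correlated, shot-noise-limited noise to a clean curve.

    The per-lag standard deviation follows the photon-correlation scaling
    ``sd ~ sqrt(1 + beta |g1|^2) / sqrt(count_rate * averaging_time)``; the
    noise is correlated across neighboring lags (Gaussian kernel of width
    ``correlation_lags``), as real multi-tau correlator noise is.
    """
    if count_rate <= 0 or averaging_time <= 0:
        raise ValueError("count_rate and averaging_time must be > 0")
    if not (0 <= beta <= 1):
        raise ValueError("beta must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    v = clean.values
    if clean.kind == "homodyne_g2":
        g1_sq = np.clip((v - 1.0) / max(beta, 1e-12), 0.0, 1.0)
    elif clean.kind == "heterodyne_raw":
        amp = max(v[0] - v[-1], 1e-12)
        g1_sq = np.clip((v - v[-1]) / amp, 0.0, 1.0) ** 2
    else:  # g1_normalized
        g1_sq = np.clip(v, -1.0, 1.0) ** 2
    sd = np.sqrt(1.0 + beta * g1_sq) / math.sqrt(count_rate * averaging_time)
    white = rng.standard_normal(v.size)
    smooth = gaussian_filter1d(white, sigma=correlation_lags, mode="nearest")
    # renormalize so the per-lag variance is preserved after smoothing
    smooth /= math.sqrt(np.sum(gaussian_filter1d(
        np.eye(1, v.size, v.size // 2)[0], sigma=correlation_lags,
        mode="nearest") ** 2))
    noisy = v + sd * smooth
    return CorrelationCurve(tau=clean.tau, values=noisy, kind=clean.kind,
                            beta=clean.beta, timestamp=clean.timestamp,
                            meta={**clean.meta, "noise_seed": int(seed)})


def generate_curve_stream(bfi_series: BfiTimeSeries,
                          props: OpticalProperties,
                          geom: MeasurementGeometry,
                          tau, rate: float = 100.0,
                          mode: str = "homodyne", beta: float = 0.5,
                          intensities: tuple = (1.0, 1e6),
                          noise: Optional[dict] = None,
                          seed: int = 0) -> list:
    """One correlation curve per ``1/rate`` window of a BFi series.

    Each window's mean BFi is pushed through the semi-infinite forward model
    and the chosen detection model (``homodyne``: Siegert g2;
    ``heterodyne``: interferometric g2 with sample/reference intensities
    ``intensities``).  ``noise`` is an optional dict with keys
    ``count_rate`` [photons/s] and optionally ``averaging_time`` [s]
    (default ``1/rate``) passed to :func:`correlation_noise`.
    """
    if mode not in ("homodyne", "heterodyne"):
        raise ValueError("mode must be 'homodyne' or 'heterodyne'")
    window = bfi_series.rate / rate
    if window < 1 or abs(window - round(window)) > 1e-9:
        raise ValueError("instrument rate must divide the series sample rate")
    window = int(round(window))
    tau = np.asarray(tau, dtype=float)
    n_curves = bfi_series.bfi.size // window
    curves = []
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(max(n_curves, 1))
    for i in range(n_curves):
        sl = slice(i * window, (i + 1) * window)
        bfi = float(bfi_series.bfi[sl].mean())
        g1 = semi_infinite_g1(tau, props, geom, Flow(bfi))
        if mode == "homodyne":
            vals = siegert_g2(g1, beta)
            kind = "homodyne_g2"
        else:
            vals = heterodyne_g2(g1, beta, intensities[0], intensities[1])
            kind = "heterodyne_raw"
        curve = CorrelationCurve(tau=tau, values=vals, kind=kind, beta=beta,
                                 timestamp=float(bfi_series.t[sl][0]),
                                 meta={"window_mean_bfi": bfi})
        if noise is not None:
            curve = correlation_noise(
                curve, count_rate=noise["count_rate"],
                averaging_time=noise.get("averaging_time", 1.0 / rate),
                beta=beta, seed=int(child_seeds[i]) & 0x7FFFFFFF)
        curves.append(curve)
    return curves


@dataclass(frozen=True)
class LinescanConfig:
    """Configuration of the synthetic heterodyne linescan camera stream.

    The sample field at each pixel is an independent complex
    circular-Gaussian process with prescribed temporal autocorrelation
    (``decorrelation='exponential'`` with time constant ``tau_c`` [s], or
    ``'semi_infinite'`` using ``props``/``geom``/``bfi``), interfered with a
    constant reference of ``reference_level`` counts.  ``signal_amplitude``
    is the mean sample intensity in counts.  Hardware artifacts injected on
    top: per-pixel quadratic drift (``drift_amplitude`` counts peak over the
    record), a rank-1 common-mode signal (``common_mode_amplitude`` counts),
    integrate-while-read leakage (``iwr_coupling`` fraction of the previous
    line) and Gaussian read noise (``read_noise_sd`` counts).
    """

    n_pixels: int = 2048
    line_rate: float = 300e3
    reference_level: float = 1000.0
    signal_amplitude: float = 1.0
    decorrelation: str = "exponential"
    tau_c: float = 1e-4
    props: Optional[OpticalProperties] = None
    geom: Optional[MeasurementGeometry] = None
    bfi: float = 1e-8  # typical in-vivo long-separation fit value [cm^2/s]
    drift_amplitude: float = 0.0
    common_mode_amplitude: float = 0.0
    iwr_coupling: float = 0.0
    read_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pixels < 1:
            raise ValueError("n_pixels must be >= 1")
        if self.line_rate <= 0:
            raise ValueError("line_rate must be > 0")
        if self.reference_level < 0:
            raise ValueError("reference_level must be >= 0")
        if not (0 <= self.iwr_coupling < 1):
            raise ValueError("iwr_coupling must lie in [0, 1)")
        if self.decorrelation not in ("exponential", "semi_infinite"):
            raise ValueError("decorrelation must be 'exponential' or 'semi_infinite'")


def _field_autocorrelation(cfg: LinescanConfig, lags_s: np.ndarray) -> np.ndarray:
    if cfg.decorrelation == "exponential":
        return np.exp(-lags_s / cfg.tau_c)
    props = cfg.props or OpticalProperties(0.1, 8.0, 1.4)
    geom = cfg.geom or MeasurementGeometry(rho=2.5)
    return semi_infinite_g1(lags_s, props, geom, Flow(cfg.bfi))


def _gaussian_field(r: np.ndarray, n: int, rng) -> np.ndarray:
    """Stationary complex circular-Gaussian sequence of length n with
    autocorrelation r (circulant embedding)."""
    m = r.size
    circ = np.concatenate([r, r[-2:0:-1]])
    lam = np.fft.fft(circ).real
    lam = np.clip(lam, 0.0, None)
    size = circ.size
    xi = (rng.standard_normal(size) + 1j * rng.standard_normal(size)) / math.sqrt(2)
    spectrum = xi * np.sqrt(lam)
    x = np.fft.fft(spectrum) / math.sqrt(size)
    return x[:n]


def generate_linescan_frames(cfg: LinescanConfig, duration: float) -> tuple:
    """Synthesize a raw linescan pixel-intensity matrix.

    Returns ``(frames, truth)``: ``frames`` has shape
    ``(n_pixels, n_lines)``; ``truth`` is a dict with the injected field
    autocorrelation (callable on lags in seconds), the common-mode pixel
    pattern, and the configuration echoes needed by recovery tests.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    n_lines = int(round(duration * cfg.line_rate))
    if n_lines < 4:
        raise ValueError("duration too short for the line rate")
    est_bytes = cfg.n_pixels * n_lines * 8 * 3
    if est_bytes > 4e9:
        raise MemoryError("requested linescan block exceeds ~4 GB; generate in chunks")
    rng = np.random.default_rng(cfg.seed)
    dt = 1.0 / cfg.line_rate
    lags = np.arange(n_lines) * dt
    r = _field_autocorrelation(cfg, lags)

    frames = np.empty((cfg.n_pixels, n_lines))
    ref_amp = math.sqrt(cfg.reference_level)
    sig_amp = math.sqrt(cfg.signal_amplitude)
    for p in range(cfg.n_pixels):
        field = sig_amp * _gaussian_field(r, n_lines, rng)
        frames[p] = np.abs(ref_amp + field) ** 2

    tt = np.linspace(0.0, 1.0, n_lines)
    if cfg.drift_amplitude:
        a = cfg.drift_amplitude * rng.uniform(-1, 1, size=cfg.n_pixels)
        b = cfg.drift_amplitude * rng.uniform(-1, 1, size=cfg.n_pixels)
        frames += a[:, None] * tt[None, :] + b[:, None] * tt[None, :] ** 2

    pattern = np.zeros(cfg.n_pixels)
    if cfg.common_mode_amplitude:
        pattern = gaussian_filter1d(rng.standard_normal(cfg.n_pixels),
                                    sigma=max(cfg.n_pixels / 16, 1))
        pattern /= np.linalg.norm(pattern) / math.sqrt(cfg.n_pixels)
        timecourse = cfg.common_mode_amplitude * np.sin(
            2 * math.pi * 5.0 * tt) * (1 + 0.3 * gaussian_filter1d(
                rng.standard_normal(n_lines), sigma=n_lines / 64))
        frames += pattern[:, None] * timecourse[None, :]

    if cfg.iwr_coupling:
        c = cfg.iwr_coupling
        first = frames[:, 0].copy()
        filtered = lfilter([1.0 - c], [1.0, -c], frames[:, 1:], axis=1,
                           zi=(c * first)[:, None])[0]
        frames = np.concatenate([first[:, None], filtered], axis=1)

    if cfg.read_noise_sd:
        frames += rng.normal(0.0, cfg.read_noise_sd, size=frames.shape)

    truth = {
        "g1": lambda lag_s: _field_autocorrelation(cfg, np.asarray(lag_s, float)),
        "tau_c": cfg.tau_c,
        "bfi": cfg.bfi,
        "common_mode_pattern": pattern,
        "config": cfg,
    }
    return frames, truth


def multi_tau_lags(n_linear: int = 16, max_lag: int = 256,
                   points_per_octave: int = 8) -> np.ndarray:
    """Multi-tau-style lag index grid: ``n_linear`` unit-spaced lags, then
    logarithmically spaced up to ``max_lag`` (integers, deduplicated)."""
    if max_lag <= n_linear:
        return np.arange(1, max_lag + 1)
    lin = np.arange(1, n_linear + 1)
    n_log = max(int(math.log2(max_lag / n_linear) * points_per_octave), 1)
    log = np.unique(np.round(np.geomspace(n_linear + 1, max_lag, n_log)).astype(int))
    return np.unique(np.concatenate([lin, log]))
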
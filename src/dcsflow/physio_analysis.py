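"""Blood-flow time-series analytics for instrument comparison studies.

Operations on uniformly sampled BFi traces: beat-to-beat cardiac filtering,
cardiac-gated averaging with per-phase coefficient of variation, relative
blood flow (rBFi) trial averaging, cross-correlation time alignment,
Bland-Altman agreement statistics, and the tourniquet-based estimate of a
long channel's superficial (scalp) sensitivity.

Beat onsets enter as given times (in practice, ECG R-peaks); a simple
peak-picker is provided as a convenience for synthetic traces only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "BfiTimeSeries",
    "BeatTimes",
    "GatedResult",
    "beat_average",
    "cardiac_gate",
    "relative_bfi",
    "align_cross_correlation",
    "bland_altman",
    "scalp_sensitivity",
    "detect_peaks",
]


@dataclass
class BfiTimeSeries:
    """Uniformly sampled BFi trace.

    ``annotations`` is a list of ``(label, onset_s, duration_s)`` tuples
    marking task events.
    """

    t: np.ndarray
    bfi: np.ndarray
    rate: float
    annotations: List[Tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.bfi = np.asarray(self.bfi, dtype=float)
        if self.t.shape != self.bfi.shape or self.t.ndim != 1:
            raise ValueError("t and bfi must be 1-D arrays of equal length")
        if self.t.size < 2:
            raise ValueError("series needs at least 2 samples")
        dt = np.diff(self.t)
        if not np.allclose(dt, 1.0 / self.rate, rtol=1e-6, atol=1e-9):
            raise ValueError("series must be uniformly sampled at the stated rate")
        if np.any(~np.isfinite(self.bfi)) or np.any(self.bfi < 0):
            raise ValueError("bfi values must be finite and >= 0")

    def __len__(self) -> int:
        return self.t.size


@dataclass
class BeatTimes:
    """Cardiac beat (R-peak) onset times [s]."""

    onsets: np.ndarray
    enforce_physiological_rr: bool = True

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.onsets.ndim != 1 or self.onsets.size < 2:
            raise ValueError("need at least 2 beat onsets")
        rr = np.diff(self.onsets)
        if np.any(rr <= 0):
            raise ValueError("beat onsets must be strictly increasing")
        if self.enforce_physiological_rr and (np.any(rr < 0.3) or np.any(rr > 2.0)):
            raise ValueError("RR intervals outside 0.3-2 s; pass "
                             "enforce_physiological_rr=False to override")


@dataclass
class GatedResult:
    """Cardiac-gated waveform: per-phase mean, sd and CoV across traces."""

    phase: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    cov: np.ndarray
    n_traces: int


def beat_average(series: BfiTimeSeries, beats: BeatTimes) -> BfiTimeSeries:
    """Replace the trace by per-beat mean BFi, resampled back to the
    original grid.

    Each RR interval's mean is assigned to the beat center; values between
    beat centers are linearly interpolated and the edges held constant.
    """
    onsets = beats.onsets
    if onsets.size < 2:
        raise ValueError("need at least 2 beats")
    centers, means = [], []
    for a, b in zip(onsets[:-1], onsets[1:]):
        sel = (series.t >= a) & (series.t < b)
        if not np.any(sel):
            continue
        centers.append(0.5 * (a + b))
        means.append(series.bfi[sel].mean())
    if len(centers) < 2:
        raise ValueError("fewer than 2 beats overlap the series")
    filtered = np.interp(series.t, centers, means)
    return BfiTimeSeries(t=series.t, bfi=filtered, rate=series.rate,
                         annotations=list(series.annotations))


def _resample_beat(series: BfiTimeSeries, a: float, b: float,
                   n_phases: int) -> np.ndarray:
    ph_t = a + (b - a) * (np.arange(n_phases) + 0.5) / n_phases
    return np.interp(ph_t, series.t, series.bfi)


def cardiac_gate(series: BfiTimeSeries, beats: BeatTimes, n_phases: int = 100,
                 n_cycles_per_trace: int = 3) -> GatedResult:
    """Cardiac-gated averaging.

    Consecutive groups of ``n_cycles_per_trace`` beats form one trace; each
    beat is linearly time-warped onto ``n_phases`` phase bins, traces are
    stacked and averaged, and the per-phase coefficient of variation
    ``CoV = sd / mean`` across traces is computed.
    """
    onsets = beats.onsets
    sel = (onsets >= series.t[0]) & (onsets <= series.t[-1])
    onsets = onsets[sel]
    n_beats = onsets.size - 1
    if n_beats < n_cycles_per_trace:
        raise ValueError(f"need at least {n_cycles_per_trace} complete beats, "
                         f"got {n_beats}")
    n_traces = n_beats // n_cycles_per_trace
    traces = np.empty((n_traces, n_cycles_per_trace * n_phases))
    for i in range(n_traces):
        segs = []
        for c in range(n_cycles_per_trace):
            k = i * n_cycles_per_trace + c
            segs.append(_resample_beat(series, onsets[k], onsets[k + 1], n_phases))
        traces[i] = np.concatenate(segs)
    mean = traces.mean(axis=0)
    sd = traces.std(axis=0, ddof=1) if n_traces > 1 else np.zeros_like(mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = np.where(mean > 0, sd / mean, np.nan)
    phase = (np.arange(mean.size) + 0.5) / n_phases
    return GatedResult(phase=phase, mean=mean, sd=sd, cov=cov, n_traces=n_traces)


def relative_bfi(series: BfiTimeSeries, events: Optional[Sequence] = None,
                 baseline_duration: float = 20.0,
                 post_duration: Optional[float] = None) -> dict:
    """Scale each trial to relative BFi (rBFi) by its own pre-event mean.

    ``events`` defaults to the series annotations; each entry is
    ``(label, onset_s, duration_s)``.  Each trial window spans
    ``[-baseline_duration, duration + post]`` around its onset and is
    divided by the mean BFi over the ``baseline_duration`` seconds before
    onset.  Trials lacking a full baseline are skipped with a warning.

    Returns a dict with ``time`` (relative to onset), ``trials``
    (n_trials x n_samples matrix) and ``mean`` across trials.
    """
    events = list(events) if events is not None else list(series.annotations)
    if not events:
        raise ValueError("no events to analyze")
    rate = series.rate
    n_base = int(round(baseline_duration * rate))
    trials = []
    for label, onset, duration in events:
        post = duration if post_duration is None else post_duration
        i0 = int(round((onset - series.t[0]) * rate))
        i_start = i0 - n_base
        i_stop = i0 + int(round((duration + post) * rate))
        if i_start < 0 or i0 > len(series):
            warnings.warn(f"trial {label!r} lacks {baseline_duration} s of "
                          "baseline; skipped", RuntimeWarning, stacklevel=2)
            continue
        i_stop = min(i_stop, len(series))
        base = series.bfi[i_start:i0].mean()
        if base <= 0:
            warnings.warn(f"trial {label!r} has nonpositive baseline; skipped",
                          RuntimeWarning, stacklevel=2)
            continue
        trials.append(series.bfi[i_start:i_stop] / base)
    if not trials:
        raise ValueError("no usable trials")
    n_min = min(len(tr) for tr in trials)
    mat = np.vstack([tr[:n_min] for tr in trials])
    time = (np.arange(n_min) - n_base) / rate
    return {"time": time, "trials": mat, "mean": mat.mean(axis=0)}


def align_cross_correlation(a: BfiTimeSeries, b: BfiTimeSeries,
                            max_lag: float = 5.0,
                            min_correlation: float = 0.2) -> float:
    """Time offset of ``b`` relative to ``a`` maximizing the normalized
    cross-correlation, with parabolic sub-sample refinement.

    Positive return value means ``b`` is delayed: ``b(t) ~ a(t - offset)``.
    Raises on flat signals; warns if the peak correlation is below
    ``min_correlation`` (signals likely unrelated).
    """
    if abs(a.rate - b.rate) > 1e-9:
        raise ValueError("series must share a sampling rate")
    xa = a.bfi - a.bfi.mean()
    xb = b.bfi - b.bfi.mean()
    # flatness must be judged relative to the signal scale (BFi ~ 1e-8)
    if xa.std() <= 1e-12 * max(abs(a.bfi).max(), 1e-300) \
            or xb.std() <= 1e-12 * max(abs(b.bfi).max(), 1e-300):
        raise ValueError("no structure: at least one series is constant")
    max_k = int(round(max_lag * a.rate))
    n = min(xa.size, xb.size)
    xa, xb = xa[:n], xb[:n]
    lags = np.arange(-max_k, max_k + 1)
    corr = np.empty(lags.size)
    for i, k in enumerate(lags):
        if k >= 0:
            u, v = xa[: n - k], xb[k:]
        else:
            u, v = xa[-k:], xb[: n + k]
        denom = np.sqrt(np.sum(u**2) * np.sum(v**2))
        corr[i] = np.sum(u * v) / denom if denom > 0 else 0.0
    i_pk = int(np.argmax(corr))
    if corr[i_pk] < min_correlation:
        warnings.warn(f"peak cross-correlation {corr[i_pk]:.2f} below "
                      f"{min_correlation}; alignment unreliable",
                      RuntimeWarning, stacklevel=2)
    # parabolic refinement on the three points around the peak
    shift = 0.0
    if 0 < i_pk < lags.size - 1:
        y0, y1, y2 = corr[i_pk - 1], corr[i_pk], corr[i_pk + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            shift = 0.5 * (y0 - y2) / denom
    return (lags[i_pk] + shift) / a.rate


def bland_altman(x, y) -> dict:
    """Bland-Altman agreement statistics between paired measurements.

    Returns ``bias = mean(y - x)``, ``sd`` (sample sd of the differences)
    and 95% limits of agreement ``bias +/- 1.96 sd``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return {"bias": bias, "sd": sd,
            "limits": (bias - 1.96 * sd, bias + 1.96 * sd),
            "mean_values": 0.5 * (x + y)}


def scalp_sensitivity(short_fractional_drop: float,
                      long_fractional_drop: float) -> float:
    """Superficial (scalp) sensitivity of a long channel from a
    superficial-only perturbation (tourniquet).

    Given the percent BFi drops of the short (scalp-only) and long channels,
    and assuming the perturbation modulates only superficial flow, the long
    channel's scalp sensitivity is ``100 * long / short`` percent.
    """
    if not (0 < short_fractional_drop <= 100):
        raise ValueError("short-channel drop must lie in (0, 100]")
    if not (0 <= long_fractional_drop <= short_fractional_drop):
        raise ValueError("long-channel drop must lie in [0, short drop]; a "
                         "larger long drop violates the superficial-only model")
    return 100.0 * long_fractional_drop / short_fractional_drop


def detect_peaks(signal, rate: float, min_rr: float = 0.3) -> np.ndarray:
    """Convenience peak-picker for synthetic pulse-like traces (test
    utility; real studies should supply ECG-derived beat times)."""
    signal = np.asarray(signal, dtype=float)
    idx, _ = find_peaks(signal, distance=max(int(min_rr * rate), 1))
    return idx / rate
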
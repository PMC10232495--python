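"""Linescan-camera preprocessing: raw pixel streams to heterodyne curves.

The cleaning chain mirrors the processing used for interferometric DCS with
a fast linescan sensor, in the simplest faithful form of each step:

1. ``correct_integrate_while_read`` — invert the previous-line leakage of
   the camera's integrate-while-read mode;
2. ``detrend_quadratic`` — remove per-pixel quadratic intensity drift
   within each analysis window (window mean re-added);
3. ``average_adjacent_pixels`` — non-overlapping k-pixel means;
4. ``remove_common_mode`` — regress out the across-camera common signal
   (mean-reference regression or first-principal-component subtraction);
5. ``intensities_to_g2`` — per-window, per-channel normalized intensity
   autocorrelation on a multi-tau lag grid, averaged across channels,
   yielding heterodyne correlation curves at the window rate (10 ms
   windows give the conventional 100 Hz).

All matrices are ``(pixels_or_channels, lines)``.
"""

from __future__ import annotations

import numpy as np

from .core_models import CorrelationCurve
from .synthesis import multi_tau_lags

__all__ = [
    "correct_integrate_while_read",
    "detrend_quadratic",
    "average_adjacent_pixels",
    "remove_common_mode",
    "intensities_to_g2",
]


def correct_integrate_while_read(raw: np.ndarray, coupling: float) -> np.ndarray:
    """Invert integrate-while-read line leakage.

    Models the camera as ``obs_t = (1 - c) true_t + c obs_{t-1}`` and
    inverts it exactly: ``true_t = (obs_t - c obs_{t-1}) / (1 - c)``; the
    first line is taken as-is.  ``coupling = 0`` is the identity.
    """
    if not (0 <= coupling < 1):
        raise ValueError("coupling must lie in [0, 1)")
    raw = np.asarray(raw, dtype=float)
    if coupling == 0:
        return raw.copy()
    out = np.empty_like(raw)
    out[:, 0] = raw[:, 0]
    out[:, 1:] = (raw[:, 1:] - coupling * raw[:, :-1]) / (1.0 - coupling)
    return out


def detrend_quadratic(signals: np.ndarray, window: int | None = None) -> np.ndarray:
    """Remove a per-pixel least-squares quadratic within each window.

    ``window`` is the analysis-interval length in lines (default: the whole
    record).  The window mean is re-added so intensities stay positive.
    Idempotent: detrending twice over the same windows equals once.
    """
    signals = np.asarray(signals, dtype=float)
    n = signals.shape[1]
    if window is None:
        window = n
    if window < 3:
        raise ValueError("window must span at least 3 samples")
    out = np.empty_like(signals)
    for start in range(0, n, window):
        stop = min(start + window, n)
        m = stop - start
        if m < 3:  # trailing remainder too short for a quadratic: mean only
            block = signals[:, start:stop]
            out[:, start:stop] = block - block.mean(axis=1, keepdims=True) \
                + block.mean(axis=1, keepdims=True)
            continue
        t = np.linspace(-1.0, 1.0, m)
        design = np.vander(t, 3, increasing=True)  # 1, t, t^2
        pinv = np.linalg.pinv(design)
        block = signals[:, start:stop]
        coeffs = block @ pinv.T
        fitted = coeffs @ design.T
        out[:, start:stop] = block - fitted + block.mean(axis=1, keepdims=True)
    return out


def average_adjacent_pixels(signals: np.ndarray, k: int) -> np.ndarray:
    """Non-overlapping k-pixel means; the trailing remainder is dropped."""
    signals = np.asarray(signals, dtype=float)
    n_pix = signals.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_pix:
        raise ValueError(f"k={k} exceeds the {n_pix} available pixels")
    n_groups = n_pix // k
    return signals[: n_groups * k].reshape(n_groups, k, -1).mean(axis=1)


def remove_common_mode(signals: np.ndarray, method: str = "mean") -> np.ndarray:
    """Suppress the signal component common to all channels.

    ``method='mean'``: each channel is regressed (least squares) against
    the across-channel mean timecourse and the fitted common component is
    subtracted.  ``method='pca'``: the projection onto the first principal
    component of the channel covariance is subtracted.  Channel means are
    preserved in both cases.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.shape[0] < 2:
        raise ValueError("common-mode removal needs at least 2 channels")
    centered = signals - signals.mean(axis=1, keepdims=True)
    if method == "mean":
        ref = centered.mean(axis=0)
        denom = np.dot(ref, ref)
        if denom == 0:
            return signals.copy()
        beta = centered @ ref / denom
        cleaned = centered - np.outer(beta, ref)
    elif method == "pca":
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        pc1 = vt[0]
        cleaned = centered - np.outer(centered @ pc1, pc1)
    else:
        raise ValueError("method must be 'mean' or 'pca'")
    return cleaned + signals.mean(axis=1, keepdims=True)


def intensities_to_g2(signals: np.ndarray, line_rate: float,
                      window: float = 0.01, lags: np.ndarray | None = None) -> list:
    """Windowed, channel-averaged normalized intensity autocorrelation.

    For each window of ``window`` seconds (default 10 ms, i.e. curves at
    100 Hz) and each channel, computes
    ``g2(k) = <I_t I_{t+k}> / <I>^2`` on a multi-tau lag-index grid
    (lag 0 excluded — it carries the noise spike), then averages across
    channels.  Requires ``window * line_rate >= 4 * max(lags)``.

    Returns a list of ``CorrelationCurve`` (kind ``heterodyne_raw``) with
    timestamps at each window start.
    """
    signals = np.asarray(signals, dtype=float)
    n_lines = signals.shape[1]
    nw = int(round(window * line_rate))
    if lags is None:
        lags = multi_tau_lags(n_linear=16, max_lag=max(nw // 8, 24))
    lags = np.asarray(lags, dtype=int)
    if np.any(lags < 1):
        raise ValueError("lag indices must be >= 1 (lag 0 is excluded)")
    if nw < 4 * lags.max():
        raise ValueError(f"window of {nw} lines is too short for a max lag "
                         f"of {lags.max()} (need >= 4x)")
    tau = lags / line_rate
    curves = []
    for start in range(0, n_lines - nw + 1, nw):
        block = signals[:, start:start + nw]
        mean_i = block.mean(axis=1)
        g2 = np.empty((block.shape[0], lags.size))
        for j, k in enumerate(lags):
            g2[:, j] = (block[:, :-k] * block[:, k:]).mean(axis=1) / mean_i**2
        curve = CorrelationCurve(tau=tau, values=g2.mean(axis=0),
                                 kind="heterodyne_raw",
                                 timestamp=start / line_rate,
                                 meta={"n_channels": int(block.shape[0]),
                                       "window_s": window})
        curves.append(curve)
    if not curves:
        raise ValueError("record shorter than one analysis window")
    return curves
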
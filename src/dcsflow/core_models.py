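"""Analytic forward models for diffuse correlation spectroscopy (DCS).

This module contains the closed-form physics connecting tissue dynamics to
measured temporal autocorrelation functions:

* the Siegert relation between the intensity autocorrelation ``g2`` and the
  normalized electric-field autocorrelation ``g1`` (homodyne detection),
* the heterodyne (interferometric) generalization in which a strong reference
  field mixes with the sample field, making the measured ``g2 - 1`` contain a
  term linear in ``|g1|``,
* the semi-infinite correlation-diffusion solution for ``g1`` in reflectance
  geometry,
* the pathlength-resolved form of ``g1`` as a weighted sum over photon
  pathlengths, and
* small instrument-budget helpers (guided-mode counts for multimode fibers,
  heterodyne sample/reference intensity ratio).

Units are centimeters and seconds throughout.  The blood flow index (BFi) is
an effective Brownian diffusion coefficient ``alpha * Db`` in cm^2/s with
mean squared displacement ``<dr^2(tau)> = 6 * BFi * tau``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "OpticalProperties",
    "MeasurementGeometry",
    "Flow",
    "CorrelationCurve",
    "CURVE_KINDS",
    "effective_reflection_coefficient",
    "semi_infinite_g1",
    "siegert_g2",
    "heterodyne_g2",
    "pathlength_g1",
    "count_fiber_modes",
    "sample_reference_intensity_ratio",
]

#: Default vacuum wavelength [cm] (1064 nm, long-wavelength DCS).
DEFAULT_WAVELENGTH_CM = 1064e-7

#: Conventional tissue refractive index.
DEFAULT_TISSUE_INDEX = 1.4

CURVE_KINDS = ("homodyne_g2", "heterodyne_raw", "g1_normalized")


def _require_finite(name: str, *values: float) -> None:
    for v in values:
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{name} must be finite, got {v!r}")


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical properties of a turbid medium.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient [1/cm], > 0.
    mu_s_prime : float
        Reduced scattering coefficient [1/cm], > 0.  The transport mean free
        path is ``l* = 1 / mu_s_prime``.
    n : float
        Refractive index, >= 1.
    """

    mu_a: float
    mu_s_prime: float
    n: float = DEFAULT_TISSUE_INDEX

    def __post_init__(self) -> None:
        _require_finite("optical properties", self.mu_a, self.mu_s_prime, self.n)
        if self.mu_a <= 0:
            raise ValueError(f"mu_a must be > 0, got {self.mu_a}")
        if self.mu_s_prime <= 0:
            raise ValueError(f"mu_s_prime must be > 0, got {self.mu_s_prime}")
        if self.n < 1:
            raise ValueError(f"refractive index must be >= 1, got {self.n}")

    @property
    def l_star(self) -> float:
        """Transport (reduced) mean free path [cm]."""
        return 1.0 / self.mu_s_prime


@dataclass(frozen=True)
class MeasurementGeometry:
    """Reflectance measurement geometry.

    Parameters
    ----------
    rho : float
        Source-detector separation on the tissue surface [cm], > 0.
    wavelength : float
        Vacuum wavelength [cm]; default 1064 nm.
    """

    rho: float
    wavelength: float = DEFAULT_WAVELENGTH_CM

    def __post_init__(self) -> None:
        _require_finite("geometry", self.rho, self.wavelength)
        if self.rho <= 0:
            raise ValueError(f"rho must be > 0, got {self.rho}")
        if self.wavelength <= 0:
            raise ValueError(f"wavelength must be > 0, got {self.wavelength}")

    @property
    def k0(self) -> float:
        """Vacuum wavenumber 2*pi/wavelength [1/cm]."""
        return 2.0 * math.pi / self.wavelength


@dataclass(frozen=True)
class Flow:
    """Dynamics of the moving scatterers, parameterized by the blood flow
    index BFi = alpha * Db [cm^2/s], so that ``<dr^2(tau)> = 6 * BFi * tau``."""

    bfi: float

    def __post_init__(self) -> None:
        _require_finite("flow", self.bfi)
        if self.bfi < 0:
            raise ValueError(f"bfi must be >= 0, got {self.bfi}")


@dataclass
class CorrelationCurve:
    """A measured or modeled temporal autocorrelation curve.

    Attributes
    ----------
    tau : ndarray
        Strictly increasing lag grid [s], first lag >= 0.
    values : ndarray
        Correlation values (dimensionless), finite.
    kind : str
        One of ``homodyne_g2`` (Siegert-form intensity autocorrelation),
        ``heterodyne_raw`` (interferometric intensity autocorrelation, not
        yet normalized) or ``g1_normalized`` (proportional to ``|g1|``,
        normalized to start at ~1).
    beta : float, optional
        Coherence parameter when known.
    timestamp : float, optional
        Acquisition time [s] for curve streams.
    meta : dict
        Free-form metadata (channel counts, acquisition rate, ...).
    """

    tau: np.ndarray
    values: np.ndarray
    kind: str
    beta: Optional[float] = None
    timestamp: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in CURVE_KINDS:
            raise ValueError(f"unknown curve kind {self.kind!r}; expected one of {CURVE_KINDS}")
        if self.tau.ndim != 1 or self.values.shape != self.tau.shape:
            raise ValueError("tau and values must be 1-D arrays of equal length")
        if self.tau.size == 0:
            raise ValueError("empty lag grid")
        if self.tau[0] < 0 or np.any(np.diff(self.tau) <= 0):
            raise ValueError("tau must be strictly increasing with tau[0] >= 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("correlation values must be finite")
        if self.beta is not None and not (0.0 <= self.beta <= 1.0):
            raise ValueError(f"beta must lie in [0, 1], got {self.beta}")
        if self.kind == "g1_normalized" and self.values[0] > 1.0 + 0.2:
            raise ValueError("g1_normalized curve should start near 1")

    def __len__(self) -> int:
        return self.tau.size


def effective_reflection_coefficient(n: float) -> float:
    """Effective internal reflection coefficient ``Reff`` of the
    extrapolated-boundary condition for a semi-infinite medium in air.

    Uses the standard polynomial fit
    ``Reff(n) = -1.440 n^-2 + 0.71 n^-1 + 0.668 + 0.0636 n``.

    Parameters
    ----------
    n : float
        Refractive index of the medium relative to the ambient, >= 1.
    """
    _require_finite("n", n)
    if n < 1:
        raise ValueError(f"refractive index must be >= 1, got {n}")
    return -1.440 * n**-2 + 0.71 / n + 0.668 + 0.0636 * n


def _k_tau(tau: np.ndarray, props: OpticalProperties, geom: MeasurementGeometry,
           flow: Flow) -> np.ndarray:
    """Decay wavenumber K(tau) of the correlation-diffusion equation."""
    k0 = geom.k0
    return np.sqrt(
        3.0 * props.mu_a * props.mu_s_prime
        + 6.0 * k0**2 * props.n**2 * props.mu_s_prime**2 * flow.bfi * tau
    )


def semi_infinite_g1(tau, props: OpticalProperties, geom: MeasurementGeometry,
                     flow: Flow) -> np.ndarray:
    """Normalized field autocorrelation ``g1(tau)`` for a semi-infinite,
    homogeneous medium measured in reflectance.

    The solution of the correlation-diffusion equation with the
    extrapolated-boundary condition::

        g1(tau) = [rb exp(-K(tau) r1) - r1 exp(-K(tau) rb)]
                  / [rb exp(-K(0) r1) - r1 exp(-K(0) rb)]

    with ``K(tau) = sqrt(3 mu_a mu_s' + 6 k0^2 n^2 mu_s'^2 BFi tau)``,
    ``r1 = sqrt(rho^2 + l*^2)``, ``rb = sqrt(rho^2 + (l* + 2 zb)^2)``,
    ``zb = (2 / 3 mu_s') (1 + Reff) / (1 - Reff)``.

    Returns an array with ``g1(0) = 1`` exactly, strictly decreasing in tau
    for ``bfi > 0``.
    """
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    if np.any(tau < 0) or not np.all(np.isfinite(tau)):
        raise ValueError("tau must be finite and >= 0")
    l_star = props.l_star
    reff = effective_reflection_coefficient(props.n)
    zb = (2.0 / (3.0 * props.mu_s_prime)) * (1.0 + reff) / (1.0 - reff)
    r1 = math.hypot(geom.rho, l_star)
    rb = math.hypot(geom.rho, l_star + 2.0 * zb)
    k = _k_tau(tau, props, geom, flow)
    k0_static = math.sqrt(3.0 * props.mu_a * props.mu_s_prime)
    num = rb * np.exp(-k * r1) - r1 * np.exp(-k * rb)
    den = rb * math.exp(-k0_static * r1) - r1 * math.exp(-k0_static * rb)
    return num / den


def siegert_g2(g1, beta: float) -> np.ndarray:
    """Homodyne intensity autocorrelation via the Siegert relation,
    ``g2 = 1 + beta |g1|^2``."""
    if not np.isfinite(beta) or not (0.0 <= beta <= 1.0):
        raise ValueError(f"beta must lie in [0, 1], got {beta}")
    g1 = np.asarray(g1, dtype=float)
    return 1.0 + beta * np.abs(g1) ** 2


def heterodyne_g2(g1, beta: float, i_sample: float, i_reference: float) -> np.ndarray:
    """Heterodyne (interferometric) intensity autocorrelation.

    With mean sample intensity ``I_S``, reference intensity ``I_R`` and total
    ``I_T = I_S + I_R``::

        g2 = 1 + beta (I_S/I_T)^2 |g1|^2 + beta (2 I_S I_R / I_T^2) |g1|

    For ``I_R = 0`` this reduces exactly to the Siegert relation.  In the
    reference-dominant limit ``I_R >> I_S`` the linear term dominates and
    ``g2 - 1`` is proportional to ``|g1|``.
    """
    if not np.isfinite(beta) or not (0.0 <= beta <= 1.0):
        raise ValueError(f"beta must lie in [0, 1], got {beta}")
    if i_sample < 0 or i_reference < 0:
        raise ValueError("intensities must be >= 0")
    i_total = i_sample + i_reference
    if i_total <= 0:
        raise ValueError("at least one of I_S, I_R must be positive")
    g1 = np.abs(np.asarray(g1, dtype=float))
    quad = beta * (i_sample / i_total) ** 2
    lin = beta * 2.0 * i_sample * i_reference / i_total**2
    return 1.0 + quad * g1**2 + lin * g1


def pathlength_g1(tau, pathlengths, weights, props: OpticalProperties,
                  geom: MeasurementGeometry, flow: Flow) -> np.ndarray:
    """Field autocorrelation from a discretized pathlength distribution.

    Discretization of the pathlength integral::

        g1(tau) = sum_s P(s) exp(-(1/3) k0^2 n^2 <dr^2(tau)> s / l*)
                = sum_s P(s) exp(-2 k0^2 n^2 mu_s' BFi tau s)

    Parameters
    ----------
    pathlengths : array_like
        Sampled pathlengths s [cm], > 0.
    weights : array_like
        Nonnegative probabilities P(s); must sum to ~1 (renormalized).
    """
    s = np.asarray(pathlengths, dtype=float)
    w = np.asarray(weights, dtype=float)
    if s.size == 0:
        raise ValueError("empty pathlength sample set")
    if s.shape != w.shape:
        raise ValueError("pathlengths and weights must have equal shapes")
    if np.any(s <= 0):
        raise ValueError("pathlengths must be > 0")
    if np.any(w < 0):
        raise ValueError("weights must be >= 0")
    total = w.sum()
    if not math.isclose(total, 1.0, rel_tol=1e-6):
        raise ValueError(f"weights must sum to 1 (got {total}); normalize P(s) first")
    w = w / total
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    if np.any(tau < 0):
        raise ValueError("tau must be >= 0")
    rate = 2.0 * geom.k0**2 * props.n**2 * props.mu_s_prime * flow.bfi * s
    # g1[i] = sum_j w[j] * exp(-rate[j] * tau[i])
    return np.exp(-np.outer(tau, rate)) @ w


#: V-number below which a step-index fiber is single mode.
SINGLE_MODE_CUTOFF_V = 2.405


def count_fiber_modes(core_diameter: float, numerical_aperture: float,
                      wavelength: float = DEFAULT_WAVELENGTH_CM,
                      n_fibers: int = 1) -> float:
    """Approximate number of guided modes in step-index multimode fibers.

    Uses ``V = pi * d * NA / wavelength`` and the large-V estimate
    ``V^2 / 2`` modes per fiber, counting both polarizations.  Below the
    single-mode cutoff (V < 2.405) each fiber carries 2 (polarization) modes.

    All lengths in consistent units (cm by default).
    """
    if core_diameter <= 0 or numerical_aperture <= 0 or wavelength <= 0:
        raise ValueError("core diameter, NA and wavelength must be > 0")
    if n_fibers < 1:
        raise ValueError("n_fibers must be >= 1")
    v = math.pi * core_diameter * numerical_aperture / wavelength
    per_fiber = 2.0 if v < SINGLE_MODE_CUTOFF_V else v**2 / 2.0
    return n_fibers * per_fiber


def sample_reference_intensity_ratio(power_per_mode: float, n_modes: float,
                                     reference_power: float,
                                     n_source_fibers: int = 2) -> float:
    """Estimated sample-to-reference intensity ratio of a heterodyne DCS
    detector plane.

    ``ratio = power_per_mode * n_modes * n_source_fibers / reference_power``
    (dimensionless; e.g. 2.4e-8 means "1 to ~4e7").  Reported as computed; a
    rough instrument budget, not a calibrated quantity.
    """
    if power_per_mode <= 0 or n_modes <= 0 or reference_power <= 0:
        raise ValueError("powers and mode count must be > 0")
    if n_source_fibers < 1:
        raise ValueError("n_source_fibers must be >= 1")
    return power_per_mode * n_modes * n_source_fibers / reference_power
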
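"""Layered-slab correlation Monte Carlo with momentum-transfer tallies.

Photons are launched as a pencil beam normal to the top surface of a stack
of plane-parallel layers (top layer = scalp side) and tracked until they
escape through the top surface, leave the simulation domain, or their
accumulated absorption makes them negligible.  For every photon detected in
an annulus around the source the simulation records

* the survival weight at exit (Beer-Lambert attenuation
  ``exp(-sum_j mu_a,j s_j)`` applied once from the per-layer pathlengths),
* the pathlength traveled in each layer ``s_j`` [cm], and
* the accumulated dimensionless momentum transfer in each layer
  ``Y_j = sum_events (1 - cos(theta))``.

These records are dynamics-free: the field autocorrelation for any
assignment of per-layer blood flow indices follows in post-processing as ::

    g1(tau) = sum_i w_i exp(-2 k0^2 tau sum_j n_j^2 BFi_j Y_ij) / sum_i w_i

which generalizes the pathlength integral of a homogeneous medium (for which
``E[Y] = s / l*``) to layered tissue.

Scattering uses the Henyey-Greenstein phase function (default anisotropy
g = 0.9, ``mu_s = mu_s' / (1 - g)``); boundaries use unpolarized Fresnel
reflection/refraction.  The detector is an annulus centered on the source,
exploiting cylindrical symmetry for desk-scale statistics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .core_models import Flow, MeasurementGeometry, OpticalProperties

__all__ = [
    "TissueLayer",
    "LayeredSlab",
    "PhotonRecords",
    "three_layer_head",
    "simulate_photons",
    "mc_g1",
    "mc_pathlength_distribution",
]


@dataclass(frozen=True)
class TissueLayer:
    """One plane-parallel tissue layer.

    ``thickness=None`` marks a semi-infinite layer (allowed only for the
    last layer of a slab).  ``mu_s = mu_s' / (1 - g)`` must be positive.
    """

    props: OpticalProperties
    flow: Flow
    thickness: Optional[float] = None  # cm; None = semi-infinite
    anisotropy_g: float = 0.9

    def __post_init__(self) -> None:
        if self.thickness is not None and self.thickness <= 0:
            raise ValueError("layer thickness must be > 0 (or None for semi-infinite)")
        if not (-1.0 < self.anisotropy_g < 1.0):
            raise ValueError("anisotropy g must lie in (-1, 1)")

    @property
    def semi_infinite(self) -> bool:
        return self.thickness is None

    @property
    def mu_s(self) -> float:
        """Scattering coefficient [1/cm] from the similarity relation."""
        return self.props.mu_s_prime / (1.0 - self.anisotropy_g)


@dataclass(frozen=True)
class LayeredSlab:
    """Ordered stack of layers; the first layer is the scalp side."""

    layers: tuple
    ambient_n: float = 1.0

    def __post_init__(self) -> None:
        layers = tuple(self.layers)
        object.__setattr__(self, "layers", layers)
        if len(layers) == 0:
            raise ValueError("slab needs at least one layer")
        for i, lay in enumerate(layers[:-1]):
            if lay.semi_infinite:
                raise ValueError(f"only the last layer may be semi-infinite (layer {i})")
        if self.ambient_n < 1:
            raise ValueError("ambient refractive index must be >= 1")

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def with_brain_bfi_scaled(self, factor: float) -> "LayeredSlab":
        """Return a copy with the last (deepest) layer's BFi multiplied."""
        last = self.layers[-1]
        new_last = TissueLayer(props=last.props, flow=Flow(last.flow.bfi * factor),
                               thickness=last.thickness, anisotropy_g=last.anisotropy_g)
        return LayeredSlab(self.layers[:-1] + (new_last,), ambient_n=self.ambient_n)


def three_layer_head(scalp_bfi: float = 1e-8, skull_bfi: float = 2e-9,
                     brain_bfi: float = 6e-8) -> LayeredSlab:
    """Representative adult-forehead geometry: 5 mm scalp, 7 mm skull,
    semi-infinite brain.  Optical properties are typical long-wavelength
    values; override by constructing a :class:`LayeredSlab` directly."""
    return LayeredSlab(
        layers=(
            TissueLayer(OpticalProperties(mu_a=0.15, mu_s_prime=8.0, n=1.4),
                        Flow(scalp_bfi), thickness=0.5),
            TissueLayer(OpticalProperties(mu_a=0.10, mu_s_prime=9.0, n=1.4),
                        Flow(skull_bfi), thickness=0.7),
            TissueLayer(OpticalProperties(mu_a=0.13, mu_s_prime=10.0, n=1.4),
                        Flow(brain_bfi), thickness=None),
        ),
        ambient_n=1.0,
    )


@dataclass
class PhotonRecords:
    """Detected-photon tallies in structure-of-arrays form.

    ``weight`` has shape (N,), ``pathlength`` and ``momentum_transfer``
    have shape (N, n_layers).  ``n_launched`` is the number of photons
    launched to obtain these detections.
    """

    weight: np.ndarray
    pathlength: np.ndarray
    momentum_transfer: np.ndarray
    n_launched: int
    seed: int
    annulus: tuple = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.weight = np.asarray(self.weight, dtype=float)
        self.pathlength = np.asarray(self.pathlength, dtype=float)
        self.momentum_transfer = np.asarray(self.momentum_transfer, dtype=float)
        n = self.weight.size
        if self.pathlength.shape[0] != n or self.momentum_transfer.shape != self.pathlength.shape:
            raise ValueError("inconsistent record array shapes")
        if n and (np.any(self.weight <= 0) or np.any(self.weight > 1.0 + 1e-12)):
            raise ValueError("detected weights must lie in (0, 1]")
        if np.any(self.pathlength < 0) or np.any(self.momentum_transfer < 0):
            raise ValueError("tallies must be >= 0")

    def __len__(self) -> int:
        return self.weight.size

    @property
    def total_pathlength(self) -> np.ndarray:
        return self.pathlength.sum(axis=1)


@njit(cache=True, fastmath=True)
def _fresnel_unpolarized(ni, nt, cos_i):
    """Return (reflectance, cos of transmitted angle); R=1 marks TIR."""
    sin_i2 = 1.0 - cos_i * cos_i
    if sin_i2 < 0.0:
        sin_i2 = 0.0
    sin_t2 = (ni / nt) ** 2 * sin_i2
    if sin_t2 >= 1.0:
        return 1.0, 0.0
    cos_t = math.sqrt(1.0 - sin_t2)
    rs = (ni * cos_i - nt * cos_t) / (ni * cos_i + nt * cos_t)
    rp = (ni * cos_t - nt * cos_i) / (ni * cos_t + nt * cos_i)
    return 0.5 * (rs * rs + rp * rp), cos_t


@njit(cache=True, fastmath=True)
def _mc_kernel(seed, n_photons, z_top, z_bot, mu_s, mu_a, g_hg, n_layer,
               n_ambient, r_in, r_out, kill_depth, kill_radius,
               max_absorption_depth, cap,
               out_w, out_path, out_mt):
    np.random.seed(seed)
    n_lay = mu_s.size
    # specular loss at normal incidence on entry
    r_spec = ((n_ambient - n_layer[0]) / (n_ambient + n_layer[0])) ** 2
    w0 = 1.0 - r_spec
    kill_radius2 = kill_radius * kill_radius
    path = np.zeros(n_lay)
    mt = np.zeros(n_lay)
    count = 0
    for _ in range(n_photons):
        if count >= cap:
            break
        x = 0.0
        y = 0.0
        z = 1e-12
        ux = 0.0
        uy = 0.0
        uz = 1.0
        lay = 0
        for j in range(n_lay):
            path[j] = 0.0
            mt[j] = 0.0
        alive = True
        while alive:
            t_opt = -math.log(np.random.random())
            while t_opt > 0.0 and alive:
                ms = mu_s[lay]
                d = t_opt / ms
                if uz > 0.0:
                    db = (z_bot[lay] - z) / uz
                elif uz < 0.0:
                    db = (z_top[lay] - z) / uz
                else:
                    db = 1e30
                if d <= db:
                    x += ux * d
                    y += uy * d
                    z += uz * d
                    path[lay] += d
                    t_opt = 0.0
                else:
                    x += ux * db
                    y += uy * db
                    z += uz * db
                    path[lay] += db
                    t_opt -= db * ms
                    if uz < 0.0 and lay == 0:
                        # top surface
                        refl, _ = _fresnel_unpolarized(n_layer[0], n_ambient, -uz)
                        if np.random.random() < refl:
                            uz = -uz
                            z = 1e-12
                        else:
                            r_exit = math.sqrt(x * x + y * y)
                            if r_in <= r_exit <= r_out:
                                ab = 0.0
                                for j in range(n_lay):
                                    ab += mu_a[j] * path[j]
                                wd = w0 * math.exp(-ab)
                                if wd > 0.0:  # guard against underflow records
                                    out_w[count] = wd
                                    for j in range(n_lay):
                                        out_path[count, j] = path[j]
                                        out_mt[count, j] = mt[j]
                                    count += 1
                            alive = False
                    elif uz > 0.0 and lay == n_lay - 1:
                        # bottom face of a finite last layer: Fresnel vs ambient
                        refl, _ = _fresnel_unpolarized(n_layer[lay], n_ambient, uz)
                        if np.random.random() < refl:
                            uz = -uz
                            z = z_bot[lay] - 1e-12
                        else:
                            alive = False
                    else:
                        nxt = lay + 1 if uz > 0.0 else lay - 1
                        ni = n_layer[lay]
                        nt = n_layer[nxt]
                        if ni == nt:
                            lay = nxt
                        else:
                            cos_i = abs(uz)
                            refl, cos_t = _fresnel_unpolarized(ni, nt, cos_i)
                            if np.random.random() < refl:
                                uz = -uz
                            else:
                                ratio = ni / nt
                                ux *= ratio
                                uy *= ratio
                                uz = cos_t if uz > 0.0 else -cos_t
                                norm = math.sqrt(ux * ux + uy * uy + uz * uz)
                                ux /= norm
                                uy /= norm
                                uz /= norm
                                lay = nxt
            if not alive:
                break
            # domain / absorption kills (generous bounds; contributions beyond
            # carry negligible detected weight)
            if z > kill_depth or x * x + y * y > kill_radius2:
                break
            ab = 0.0
            for j in range(n_lay):
                ab += mu_a[j] * path[j]
            if ab > max_absorption_depth:
                break
            # Henyey-Greenstein scattering
            g = g_hg[lay]
            if g == 0.0:
                cos_th = 2.0 * np.random.random() - 1.0
            else:
                tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * np.random.random())
                cos_th = (1.0 + g * g - tmp * tmp) / (2.0 * g)
                if cos_th > 1.0:
                    cos_th = 1.0
                elif cos_th < -1.0:
                    cos_th = -1.0
            sin_th = math.sqrt(max(0.0, 1.0 - cos_th * cos_th))
            phi = 2.0 * math.pi * np.random.random()
            cos_p = math.cos(phi)
            sin_p = math.sin(phi)
            if abs(uz) > 0.99999:
                ux = sin_th * cos_p
                uy = sin_th * sin_p
                uz = cos_th if uz > 0.0 else -cos_th
            else:
                den = math.sqrt(1.0 - uz * uz)
                ux_n = sin_th * (ux * uz * cos_p - uy * sin_p) / den + ux * cos_th
                uy_n = sin_th * (uy * uz * cos_p + ux * sin_p) / den + uy * cos_th
                uz_n = -sin_th * cos_p * den + uz * cos_th
                ux = ux_n
                uy = uy_n
                uz = uz_n
            mt[lay] += 1.0 - cos_th
    return count


def simulate_photons(slab: LayeredSlab, geom: MeasurementGeometry,
                     detector_annulus: Sequence[float], n_photons: int,
                     seed: int, *, kill_depth: float = 8.0,
                     kill_radius_margin: float = 6.0,
                     max_absorption_depth: float = 12.0,
                     record_cap: int = 5_000_000) -> PhotonRecords:
    """Run the layered-slab Monte Carlo and return detected-photon records.

    Parameters
    ----------
    detector_annulus : (r_in, r_out)
        Detection annulus radii [cm] on the top surface, ``0 <= r_in < r_out``.
        Center it on the target source-detector separation.
    n_photons : int
        Photons to launch (>= 1).
    seed : int
        PRNG seed; runs are reproducible bitwise for a given seed.
    kill_depth, kill_radius_margin, max_absorption_depth :
        Domain-truncation controls.  Photons deeper than ``kill_depth`` [cm],
        farther than ``r_out + kill_radius_margin`` laterally, or with
        accumulated absorption optical depth above ``max_absorption_depth``
        (weight < ~6e-6 at the default) are terminated; their detected-weight
        contribution is negligible at tissue-like absorption.

    Returns
    -------
    PhotonRecords
        Empty (with a warning) if nothing was detected.
    """
    r_in, r_out = float(detector_annulus[0]), float(detector_annulus[1])
    if not (0 <= r_in < r_out):
        raise ValueError("annulus must satisfy 0 <= r_in < r_out")
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    n_lay = slab.n_layers
    mu_s = np.array([lay.mu_s for lay in slab.layers])
    mu_a = np.array([lay.props.mu_a for lay in slab.layers])
    g_hg = np.array([lay.anisotropy_g for lay in slab.layers])
    n_layer = np.array([lay.props.n for lay in slab.layers])
    z_top = np.zeros(n_lay)
    z_bot = np.zeros(n_lay)
    z = 0.0
    for i, lay in enumerate(slab.layers):
        z_top[i] = z
        z = z + lay.thickness if lay.thickness is not None else 1e30
        z_bot[i] = z

    cap = int(min(record_cap, n_photons))
    out_w = np.empty(cap)
    out_path = np.empty((cap, n_lay))
    out_mt = np.empty((cap, n_lay))
    count = _mc_kernel(seed, int(n_photons), z_top, z_bot, mu_s, mu_a, g_hg,
                       n_layer, slab.ambient_n, r_in, r_out,
                       kill_depth, r_out + kill_radius_margin,
                       max_absorption_depth, cap, out_w, out_path, out_mt)
    if count == 0:
        warnings.warn("no photons detected in the annulus; returning empty records",
                      RuntimeWarning, stacklevel=2)
    return PhotonRecords(
        weight=out_w[:count].copy(),
        pathlength=out_path[:count].copy(),
        momentum_transfer=out_mt[:count].copy(),
        n_launched=int(n_photons),
        seed=int(seed),
        annulus=(r_in, r_out),
    )


def mc_g1(records: PhotonRecords, tau, slab: LayeredSlab,
          geom: MeasurementGeometry, *, chunk: int = 200_000) -> np.ndarray:
    """Field autocorrelation from momentum-transfer tallies.

    ``g1(tau) = sum_i w_i exp(-2 k0^2 tau sum_j n_j^2 BFi_j Y_ij) / sum_i w_i``

    The records are independent of the assumed dynamics, so the same run can
    be re-evaluated for any per-layer BFi assignment (e.g. a baseline and an
    activated brain state).
    """
    if len(records) == 0:
        raise ValueError("empty photon record set")
    w = records.weight
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("all-zero detected weights")
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    if np.any(tau < 0):
        raise ValueError("tau must be >= 0")
    k0 = geom.k0
    coeff = np.array([2.0 * k0**2 * lay.props.n**2 * lay.flow.bfi
                      for lay in slab.layers])
    out = np.zeros(tau.size)
    n = len(records)
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        decay_rate = records.momentum_transfer[sl] @ coeff  # (m,)
        out += np.exp(-np.outer(tau, decay_rate)) @ w[sl]
    return out / wsum


def mc_pathlength_distribution(records: PhotonRecords, bin_edges) -> tuple:
    """Weight-normalized histogram P(s) of total pathlength.

    Returns ``(probabilities, bin_edges)`` with probabilities summing to 1
    over the bins (pathlengths outside the edges are excluded before
    normalizing).
    """
    if len(records) == 0:
        raise ValueError("empty photon record set")
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be 1-D and strictly increasing")
    hist, edges = np.histogram(records.total_pathlength, bins=edges,
                               weights=records.weight)
    total = hist.sum()
    if total <= 0:
        raise ValueError("no weight inside the given bins")
    return hist / total, edges
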
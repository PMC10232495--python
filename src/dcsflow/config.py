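"""Run configuration: YAML schema with strict (unknown-key-rejecting)
validation, and the packaged multilayer simulation experiment runner.

A run configuration has named sections::

    slab:          # layer stack, top first
      ambient_n: 1.0
      layers:
        - {mu_a: 0.15, mu_s_prime: 8.0, n: 1.4, g: 0.9, bfi: 1.0e-8, thickness: 0.5}
        - {mu_a: 0.10, mu_s_prime: 9.0, n: 1.4, g: 0.9, bfi: 2.0e-9, thickness: 0.7}
        - {mu_a: 0.13, mu_s_prime: 10.0, n: 1.4, g: 0.9, bfi: 6.0e-8}   # semi-infinite
    geometry:      {rho: 2.5, wavelength_nm: 1064.0}
    mc:            {n_photons: 1200000, annulus_halfwidth: 0.25, seed: 1}
    fitting:       {x: 2.5, x_grid_max: 5.0, x_grid_step: 0.25, fraction: 0.05,
                    beta: 0.5, fit_mu_a: 0.13, fit_mu_s_prime: 9.0}
    experiment:    {activation: 1.5, tau_min: 1.0e-7, tau_max: 1.0e-2, n_tau: 80}

Every runner writes the resolved configuration beside its outputs so a run
is reproducible from (resolved config, seed) alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .core_models import Flow, MeasurementGeometry, OpticalProperties
from .mc_transport import LayeredSlab, TissueLayer

__all__ = [
    "RunConfig",
    "SlabConfig",
    "LayerConfig",
    "load_config",
    "default_forehead_config",
]


class ConfigError(ValueError):
    """Schema violation in a run configuration."""


def _check_keys(section: str, data: dict, allowed: set) -> None:
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in section {section!r}: {sorted(unknown)}")


@dataclass(frozen=True)
class LayerConfig:
    mu_a: float
    mu_s_prime: float
    bfi: float
    n: float = 1.4
    g: float = 0.9
    thickness: Optional[float] = None

    def to_layer(self) -> TissueLayer:
        return TissueLayer(props=OpticalProperties(self.mu_a, self.mu_s_prime, self.n),
                           flow=Flow(self.bfi), thickness=self.thickness,
                           anisotropy_g=self.g)


@dataclass(frozen=True)
class SlabConfig:
    layers: tuple
    ambient_n: float = 1.0

    def to_slab(self) -> LayeredSlab:
        return LayeredSlab(tuple(l.to_layer() for l in self.layers),
                           ambient_n=self.ambient_n)


@dataclass(frozen=True)
class RunConfig:
    slab: SlabConfig
    rho: float = 2.5
    wavelength_nm: float = 1064.0
    n_photons: int = 1_200_000
    annulus_halfwidth: float = 0.25
    seed: int = 1
    x: float = 2.5
    x_grid_max: float = 5.0
    x_grid_step: float = 0.25
    fraction: float = 0.05
    beta: float = 0.5
    fit_mu_a: float = 0.13
    fit_mu_s_prime: float = 9.0
    fit_n: float = 1.4
    activation: float = 1.5
    tau_min: float = 1e-7
    tau_max: float = 1e-2
    n_tau: int = 80

    def geometry(self) -> MeasurementGeometry:
        return MeasurementGeometry(rho=self.rho,
                                   wavelength=self.wavelength_nm * 1e-7)

    def fit_props(self) -> OpticalProperties:
        """Homogeneous optical properties assumed by the semi-infinite
        fitting model (deliberately distinct from the layered truth)."""
        return OpticalProperties(self.fit_mu_a, self.fit_mu_s_prime, self.fit_n)

    def tau_grid(self) -> np.ndarray:
        return np.logspace(np.log10(self.tau_min), np.log10(self.tau_max),
                           self.n_tau)

    def x_grid(self) -> np.ndarray:
        return np.arange(0.0, self.x_grid_max + 1e-9, self.x_grid_step)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["slab"] = {
            "ambient_n": self.slab.ambient_n,
            "layers": [dataclasses.asdict(l) for l in self.slab.layers],
        }
        return d


_GEOMETRY_KEYS = {"rho", "wavelength_nm"}
_MC_KEYS = {"n_photons", "annulus_halfwidth", "seed"}
_FIT_KEYS = {"x", "x_grid_max", "x_grid_step", "fraction", "beta",
             "fit_mu_a", "fit_mu_s_prime", "fit_n"}
_EXPERIMENT_KEYS = {"activation", "tau_min", "tau_max", "n_tau"}
_LAYER_KEYS = {"mu_a", "mu_s_prime", "bfi", "n", "g", "thickness"}


def _parse_slab(data: dict) -> SlabConfig:
    _check_keys("slab", data, {"layers", "ambient_n"})
    if "layers" not in data or not data["layers"]:
        raise ConfigError("slab section needs a non-empty 'layers' list")
    layers = []
    for i, ld in enumerate(data["layers"]):
        _check_keys(f"slab.layers[{i}]", ld, _LAYER_KEYS)
        try:
            layers.append(LayerConfig(**ld))
        except TypeError as exc:
            raise ConfigError(f"slab.layers[{i}]: {exc}") from exc
    return SlabConfig(layers=tuple(layers),
                      ambient_n=float(data.get("ambient_n", 1.0)))


def parse_config(data: dict) -> RunConfig:
    _check_keys("<root>", data, {"slab", "geometry", "mc", "fitting", "experiment"})
    if "slab" not in data:
        raise ConfigError("missing required section 'slab'")
    kwargs = {"slab": _parse_slab(data["slab"])}
    for section, allowed in (("geometry", _GEOMETRY_KEYS), ("mc", _MC_KEYS),
                             ("fitting", _FIT_KEYS), ("experiment", _EXPERIMENT_KEYS)):
        sec = data.get(section, {})
        _check_keys(section, sec, allowed)
        kwargs.update(sec)
    try:
        cfg = RunConfig(**kwargs)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    if cfg.n_photons < 1:
        raise ConfigError("mc.n_photons must be >= 1")
    return cfg


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    return parse_config(data)


def save_resolved_config(path, cfg: RunConfig) -> None:
    """Write the fully resolved configuration next to a run's outputs."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def default_forehead_config(n_photons: int = 1_200_000, seed: int = 1) -> RunConfig:
    """Representative-forehead defaults for the multilayer fitting
    experiment (5 mm scalp / 7 mm skull / semi-infinite brain)."""
    slab = SlabConfig(layers=(
        LayerConfig(mu_a=0.15, mu_s_prime=8.0, bfi=1e-8, thickness=0.5),
        LayerConfig(mu_a=0.10, mu_s_prime=9.0, bfi=2e-9, thickness=0.7),
        LayerConfig(mu_a=0.13, mu_s_prime=10.0, bfi=6e-8),
    ))
    return RunConfig(slab=slab, n_photons=n_photons, seed=seed)
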
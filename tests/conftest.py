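"""Shared fixtures.

The Monte Carlo runs are the expensive part of the suite, so they are
session-scoped and shared across test modules.  Problem sizes are chosen
for desk-scale runtimes (hundreds of thousands to ~1e6 launched photons);
tolerances in the tests account for the resulting statistics.
"""

import numpy as np
import pytest

from dcsflow.config import default_forehead_config
from dcsflow.core_models import Flow, MeasurementGeometry, OpticalProperties
from dcsflow.experiments import run_multilayer_fit_experiment
from dcsflow.mc_transport import (LayeredSlab, TissueLayer, simulate_photons)


@pytest.fixture(scope="session")
def homog_props():
    return OpticalProperties(mu_a=0.1, mu_s_prime=10.0, n=1.4)


@pytest.fixture(scope="session")
def homog_slab(homog_props):
    return LayeredSlab((TissueLayer(homog_props, Flow(6e-8), thickness=None),),
                       ambient_n=1.0)


@pytest.fixture(scope="session")
def geom15():
    return MeasurementGeometry(rho=1.5)


@pytest.fixture(scope="session")
def homog_records(homog_slab, geom15):
    """Homogeneous semi-infinite run at rho = 1.5 cm (air above)."""
    return simulate_photons(homog_slab, geom15, (1.3, 1.7), 600_000, seed=101)


@pytest.fixture(scope="session")
def matched_slab():
    """Index-matched boundary (n = 1 everywhere): diffusion-theory oracle
    territory."""
    props = OpticalProperties(mu_a=0.1, mu_s_prime=10.0, n=1.0)
    return LayeredSlab((TissueLayer(props, Flow(6e-8), thickness=None),),
                       ambient_n=1.0)


@pytest.fixture(scope="session")
def matched_records(matched_slab):
    geom = MeasurementGeometry(rho=1.0)
    return simulate_photons(matched_slab, geom, (0.9, 1.1), 250_000, seed=202)


@pytest.fixture(scope="session")
def forehead_config():
    return default_forehead_config(n_photons=800_000, seed=7)


@pytest.fixture(scope="session")
def forehead_records(forehead_config):
    cfg = forehead_config
    annulus = (cfg.rho - cfg.annulus_halfwidth, cfg.rho + cfg.annulus_halfwidth)
    return simulate_photons(cfg.slab.to_slab(), cfg.geometry(), annulus,
                            cfg.n_photons, seed=cfg.seed)


@pytest.fixture(scope="session")
def forehead_report(forehead_config, forehead_records):
    """Full multilayer fitting experiment on the representative forehead
    slab (baseline + 50% brain activation, exponent grid 0..5)."""
    return run_multilayer_fit_experiment(forehead_config, records=forehead_records)
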
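"""Monte Carlo transport tests: determinism, attenuation, tallies,
agreement with diffusion theory, and the momentum-transfer/pathlength
equivalence that underpins the correlation synthesis."""

import numpy as np
import pytest
from scipy.integrate import quad

from dcsflow.core_models import (Flow, MeasurementGeometry, OpticalProperties,
                                 pathlength_g1, semi_infinite_g1,
                                 effective_reflection_coefficient)
from dcsflow.mc_transport import (LayeredSlab, PhotonRecords, TissueLayer,
                                  mc_g1, mc_pathlength_distribution,
                                  simulate_photons, three_layer_head)

TAU = np.logspace(-7, -2, 60)


def diffusion_mean_pathlength(mu_a, mu_s_prime, n, rho):
    """Independent oracle: mean detected pathlength from the first moment of
    the time-domain semi-infinite diffusion reflectance (extrapolated
    boundary), parameterized directly by pathlength s = c*t."""
    z0 = 1.0 / mu_s_prime
    reff = effective_reflection_coefficient(n)
    zb = (2.0 / (3.0 * mu_s_prime)) * (1 + reff) / (1 - reff)
    z1 = z0 + 2 * zb

    def kernel(s):
        common = s**-2.5 * np.exp(-mu_a * s - 3 * mu_s_prime * rho**2 / (4 * s))
        return common * (z0 * np.exp(-3 * mu_s_prime * z0**2 / (4 * s))
                         + z1 * np.exp(-3 * mu_s_prime * z1**2 / (4 * s)))

    num = quad(lambda s: s * kernel(s), 1e-3, 300, limit=200)[0]
    den = quad(kernel, 1e-3, 300, limit=200)[0]
    return num / den


class TestSimulatePhotons:
    def test_same_seed_reproduces_records(self, homog_slab, geom15):
        a = simulate_photons(homog_slab, geom15, (1.3, 1.7), 20_000, seed=5)
        b = simulate_photons(homog_slab, geom15, (1.3, 1.7), 20_000, seed=5)
        np.testing.assert_array_equal(a.weight, b.weight)
        np.testing.assert_array_equal(a.pathlength, b.pathlength)
        np.testing.assert_array_equal(a.momentum_transfer, b.momentum_transfer)

    def test_extreme_absorption_kills_weights(self):
        props = OpticalProperties(mu_a=1e3, mu_s_prime=10.0, n=1.4)
        slab = LayeredSlab((TissueLayer(props, Flow(1e-8), None),))
        rec = simulate_photons(slab, MeasurementGeometry(0.2), (0.05, 0.4),
                               20_000, seed=1, max_absorption_depth=500.0)
        assert len(rec) > 0
        assert np.all(rec.weight < 1e-6)

    def test_empty_detection_warns(self, homog_slab, geom15):
        with pytest.warns(RuntimeWarning, match="no photons detected"):
            rec = simulate_photons(homog_slab, geom15, (7.5, 7.6), 50, seed=3)
        assert len(rec) == 0

    def test_total_detected_weight_bounded(self, homog_records):
        assert homog_records.weight.sum() <= homog_records.n_launched
        assert np.all(homog_records.weight <= 1.0)

    def test_pathlengths_exceed_source_detector_chord(self, homog_records):
        assert homog_records.total_pathlength.min() >= homog_records.annulus[0]

    def test_index_mismatch_retains_photons(self, matched_slab):
        """Fresnel internal reflection at a mismatched surface keeps photons
        inside: the total escaping (detected-anywhere) weight fraction is
        larger for a matched boundary."""
        geom = MeasurementGeometry(rho=1.0)
        mismatched = LayeredSlab(
            (TissueLayer(OpticalProperties(0.1, 10.0, 1.4), Flow(6e-8), None),),
            ambient_n=1.0)
        wide = (1e-6, 6.0)  # essentially the whole top surface
        rec_match = simulate_photons(matched_slab, geom, wide, 30_000, seed=9)
        rec_mis = simulate_photons(mismatched, geom, wide, 30_000, seed=9)
        assert rec_match.weight.sum() > rec_mis.weight.sum()

    def test_mean_pathlength_matches_diffusion_oracle(self, matched_records,
                                                      matched_slab):
        props = matched_slab.layers[0].props
        oracle = diffusion_mean_pathlength(props.mu_a, props.mu_s_prime,
                                           props.n, rho=1.0)
        mc = np.average(matched_records.total_pathlength,
                        weights=matched_records.weight)
        assert mc == pytest.approx(oracle, rel=0.10)


class TestMomentumTransferTallies:
    def test_momentum_transfer_equals_reduced_pathlength(self, homog_records,
                                                         homog_props):
        """E[Y] = s / l* links the momentum-transfer tally to the reduced
        pathlength in a homogeneous medium."""
        y = homog_records.momentum_transfer.sum(axis=1)
        s_over_lstar = homog_records.total_pathlength * homog_props.mu_s_prime
        ratio = np.average(y, weights=homog_records.weight) / \
            np.average(s_over_lstar, weights=homog_records.weight)
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_layer_partition_sums_to_total(self):
        slab = three_layer_head()
        rec = simulate_photons(slab, MeasurementGeometry(1.0), (0.8, 1.2),
                               40_000, seed=21)
        # per-layer tallies are the partition of the trajectory
        assert rec.pathlength.shape[1] == 3
        assert np.all(rec.pathlength.sum(axis=1) >= 0.8)
        assert np.any(rec.pathlength[:, 1] > 0)  # some photons reach the skull


class TestMcG1:
    def test_zero_flow_gives_unity(self, homog_records, homog_slab, geom15):
        frozen = LayeredSlab(
            (TissueLayer(homog_slab.layers[0].props, Flow(0.0), None),))
        g1 = mc_g1(homog_records, TAU, frozen, geom15)
        assert np.allclose(g1, 1.0)

    def test_matches_semi_infinite_solution(self, homog_records, homog_slab,
                                            homog_props, geom15):
        """MC autocorrelation vs the closed-form diffusion solution on a
        homogeneous medium: max deviation below 0.02."""
        g1_mc = mc_g1(homog_records, TAU, homog_slab, geom15)
        g1_an = semi_infinite_g1(TAU, homog_props, geom15, Flow(6e-8))
        assert np.max(np.abs(g1_mc - g1_an)) < 0.02

    def test_flow_time_rescaling_identity(self, homog_records, homog_slab,
                                          geom15):
        """Doubling every layer's BFi is exactly a factor-2 lag compression."""
        doubled = LayeredSlab(
            (TissueLayer(homog_slab.layers[0].props, Flow(1.2e-7), None),))
        g_doubled = mc_g1(homog_records, TAU, doubled, geom15)
        g_stretched = mc_g1(homog_records, 2 * TAU, homog_slab, geom15)
        np.testing.assert_allclose(g_doubled, g_stretched, rtol=1e-12)

    def test_monotone_nonincreasing_and_normalized(self, homog_records,
                                                   homog_slab, geom15):
        g1 = mc_g1(homog_records, np.concatenate([[0.0], TAU]), homog_slab, geom15)
        assert g1[0] == pytest.approx(1.0)
        assert np.all(np.diff(g1) <= 1e-15)

    def test_empty_records_rejected(self, homog_slab, geom15):
        empty = PhotonRecords(weight=np.empty(0), pathlength=np.empty((0, 1)),
                              momentum_transfer=np.empty((0, 1)),
                              n_launched=10, seed=0)
        with pytest.raises(ValueError):
            mc_g1(empty, TAU, homog_slab, geom15)


class TestPathlengthDistribution:
    def test_normalized_histogram_with_geometric_lower_bound(self, homog_records):
        edges = np.linspace(0, 60, 121)
        p, edges = mc_pathlength_distribution(homog_records, edges)
        assert p.sum() == pytest.approx(1.0)
        centers = 0.5 * (edges[:-1] + edges[1:])
        assert p[centers < homog_records.annulus[0]].sum() == 0.0

    def test_single_record_is_delta(self):
        rec = PhotonRecords(weight=np.array([0.5]),
                            pathlength=np.array([[7.3]]),
                            momentum_transfer=np.array([[73.0]]),
                            n_launched=100, seed=0)
        p, _ = mc_pathlength_distribution(rec, np.linspace(0, 20, 21))
        assert np.count_nonzero(p) == 1
        assert p.max() == pytest.approx(1.0)

    def test_feeding_distribution_into_pathlength_g1_matches_mc(
            self, homog_records, homog_slab, homog_props, geom15):
        """Internal cross-oracle: the histogram P(s) pushed through the
        pathlength-resolved closed form reproduces the tally-based g1."""
        edges = np.geomspace(1.3, 120, 200)
        p, edges = mc_pathlength_distribution(homog_records, edges)
        centers = np.sqrt(edges[:-1] * edges[1:])
        keep = p > 0
        g1_hist = pathlength_g1(TAU, centers[keep], p[keep] / p[keep].sum(),
                                homog_props, geom15, Flow(6e-8))
        g1_mc = mc_g1(homog_records, TAU, homog_slab, geom15)
        assert np.max(np.abs(g1_hist - g1_mc)) < 0.03

    def test_rejects_bad_bins(self, homog_records):
        with pytest.raises(ValueError):
            mc_pathlength_distribution(homog_records, [1.0, 0.5])


class TestSlabValidation:
    def test_only_last_layer_semi_infinite(self):
        props = OpticalProperties(0.1, 10.0, 1.4)
        with pytest.raises(ValueError):
            LayeredSlab((TissueLayer(props, Flow(0), None),
                         TissueLayer(props, Flow(0), 1.0)))

    def test_brain_scaling_helper(self):
        slab = three_layer_head(brain_bfi=6e-8)
        scaled = slab.with_brain_bfi_scaled(1.5)
        assert scaled.layers[-1].flow.bfi == pytest.approx(9e-8)
        assert scaled.layers[0].flow.bfi == slab.layers[0].flow.bfi
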
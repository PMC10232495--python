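"""Physiological time-series analytics tests: beat filtering, cardiac
gating, relative BFi, alignment, agreement statistics, and the tourniquet
scalp-sensitivity estimate."""

import numpy as np
import pytest

from dcsflow.physio_analysis import (BeatTimes, BfiTimeSeries,
                                     align_cross_correlation, beat_average,
                                     bland_altman, cardiac_gate, detect_peaks,
                                     relative_bfi, scalp_sensitivity)
from dcsflow.synthesis import Epoch, PulsatileParams, generate_pulsatile_bfi


def make_series(duration=60.0, rate=100.0, pulsatility=0.3, mean_bfi=1e-8,
                seed=0, epochs=(), noise_sd=0.0, jitter=0.0):
    params = PulsatileParams(mean_bfi=mean_bfi, pulsatility_fraction=pulsatility,
                             rr_jitter_sd=jitter, epochs=tuple(epochs),
                             sample_rate=rate)
    series, beats = generate_pulsatile_bfi(params, duration, seed)
    if noise_sd:
        rng = np.random.default_rng(seed + 77)
        bfi = np.clip(series.bfi + rng.normal(0, noise_sd, series.bfi.size), 0, None)
        series = BfiTimeSeries(series.t, bfi, series.rate, series.annotations)
    return series, BeatTimes(beats)


class TestBeatAverage:
    def test_constant_series_unchanged(self):
        series, beats = make_series(pulsatility=0.0)
        out = beat_average(series, beats)
        np.testing.assert_allclose(out.bfi, series.bfi, rtol=1e-12)

    def test_cardiac_oscillation_suppressed(self):
        series, beats = make_series(pulsatility=0.5, duration=120.0)
        out = beat_average(series, beats)
        dc = series.bfi.mean()
        assert np.ptp(series.bfi) / max(np.ptp(out.bfi), 1e-30) > 10
        assert out.bfi.mean() == pytest.approx(dc, rel=0.01)

    def test_known_per_beat_means_recovered(self):
        rate = 100.0
        t = np.arange(0, 10, 1 / rate)
        bfi = np.repeat(np.arange(1.0, 11.0), int(rate)) * 1e-9
        series = BfiTimeSeries(t, bfi, rate)
        beats = BeatTimes(np.arange(0.0, 10.5, 1.0), enforce_physiological_rr=False)
        out = beat_average(series, beats)
        centers = np.arange(0.5, 10.0, 1.0)
        expected = np.arange(1.0, 11.0) * 1e-9
        got = np.interp(centers, out.t, out.bfi)
        np.testing.assert_allclose(got, expected, rtol=1e-9)

    def test_beats_outside_series_rejected(self):
        series, _ = make_series(duration=10.0)
        outside = BeatTimes(np.array([100.0, 101.0]),
                            enforce_physiological_rr=False)
        with pytest.raises(ValueError):
            beat_average(series, outside)


class TestCardiacGate:
    def test_noiseless_periodic_waveform(self):
        series, beats = make_series(duration=60.0, pulsatility=0.4, jitter=0.0)
        gated = cardiac_gate(series, beats, n_phases=50, n_cycles_per_trace=1)
        assert np.nanmax(gated.cov) < 1e-10
        # every trace is the same cycle: the gated mean repeats it
        one_beat = cardiac_gate(series, beats, n_phases=50,
                                n_cycles_per_trace=3)
        np.testing.assert_allclose(one_beat.mean[:50], one_beat.mean[50:100],
                                   rtol=1e-6)

    def test_cov_matches_injected_noise(self):
        """Per-phase CoV across traces ~ noise sd / mean for
        amplitude-stationary noise (200 beats)."""
        mean_bfi, noise_sd = 1e-8, 5e-10
        series, beats = make_series(duration=200.0, pulsatility=0.1,
                                    mean_bfi=mean_bfi, noise_sd=noise_sd,
                                    jitter=0.0, seed=3)
        gated = cardiac_gate(series, beats, n_phases=25, n_cycles_per_trace=1)
        assert np.nanmean(gated.cov) == pytest.approx(noise_sd / mean_bfi,
                                                      rel=0.15)

    def test_cov_ratio_tracks_noise_ratio(self):
        """Two instruments with noise sds sigma and sigma/2.25 show a CoV
        ratio of ~2.25."""
        mean_bfi, sigma = 1e-8, 9e-10
        noisy, beats = make_series(duration=300.0, pulsatility=0.1,
                                   mean_bfi=mean_bfi, noise_sd=sigma, seed=5)
        quiet, _ = make_series(duration=300.0, pulsatility=0.1,
                               mean_bfi=mean_bfi, noise_sd=sigma / 2.25, seed=5)
        cov_hi = np.nanmean(cardiac_gate(noisy, beats, 25, 1).cov)
        cov_lo = np.nanmean(cardiac_gate(quiet, beats, 25, 1).cov)
        assert cov_hi / cov_lo == pytest.approx(2.25, rel=0.10)

    def test_insufficient_beats_rejected(self):
        series, _ = make_series(duration=3.0)
        beats = BeatTimes(np.array([0.0, 1.0]), enforce_physiological_rr=False)
        with pytest.raises(ValueError):
            cardiac_gate(series, beats, n_phases=10, n_cycles_per_trace=3)


class TestRelativeBfi:
    def test_constant_series_gives_unity(self):
        series, _ = make_series(duration=120.0, pulsatility=0.0,
                                epochs=[Epoch("a", 60.0, 20.0, 1.0)])
        res = relative_bfi(series)
        np.testing.assert_allclose(res["mean"], 1.0, rtol=1e-12)

    def test_step_activation_plateau(self):
        series, _ = make_series(duration=150.0, pulsatility=0.0,
                                epochs=[Epoch("a", 60.0, 40.0, 1.5)])
        res = relative_bfi(series)
        during = res["mean"][(res["time"] > 5) & (res["time"] < 35)]
        assert during.mean() == pytest.approx(1.5, rel=1e-6)

    def test_scale_invariance_across_trials(self):
        """Different baselines, equal fractional response: identical rBFi."""
        e1 = [Epoch("t1", 40.0, 20.0, 1.4)]
        s1, _ = make_series(duration=100.0, pulsatility=0.0, mean_bfi=1e-8,
                            epochs=e1)
        s2, _ = make_series(duration=100.0, pulsatility=0.0, mean_bfi=7e-8,
                            epochs=e1)
        r1 = relative_bfi(s1)
        r2 = relative_bfi(s2)
        np.testing.assert_allclose(r1["trials"], r2["trials"], rtol=1e-12)

    def test_missing_baseline_skipped_with_warning(self):
        series, _ = make_series(duration=100.0,
                                epochs=[Epoch("early", 5.0, 10.0, 1.5),
                                        Epoch("ok", 60.0, 10.0, 1.5)])
        with pytest.warns(RuntimeWarning, match="baseline"):
            res = relative_bfi(series)
        assert res["trials"].shape[0] == 1


class TestAlignment:
    def test_known_shift_recovered(self):
        series, _ = make_series(duration=120.0, pulsatility=0.3, jitter=0.03,
                                seed=8)
        shift_s = 0.37
        k = int(round(shift_s * series.rate))
        shifted = BfiTimeSeries(series.t[:-k], series.bfi[k:], series.rate)
        base = BfiTimeSeries(series.t[:-k], series.bfi[:-k], series.rate)
        offset = align_cross_correlation(shifted, base, max_lag=2.0)
        assert offset == pytest.approx(shift_s, abs=1.5 / series.rate)

    def test_self_alignment_is_zero(self):
        # beat-to-beat jitter breaks the periodicity tie between lag 0 and
        # whole cardiac periods, as it does in real traces
        series, _ = make_series(duration=60.0, seed=9, jitter=0.04)
        assert align_cross_correlation(series, series) == pytest.approx(0.0, abs=1e-6)

    def test_flat_signal_rejected_and_noise_flagged(self):
        rate = 50.0
        t = np.arange(0, 30, 1 / rate)
        flat = BfiTimeSeries(t, np.full(t.size, 1e-8), rate)
        with pytest.raises(ValueError, match="no structure"):
            align_cross_correlation(flat, flat)
        rng = np.random.default_rng(10)
        a = BfiTimeSeries(t, np.abs(rng.normal(1e-8, 1e-9, t.size)), rate)
        b = BfiTimeSeries(t, np.abs(rng.normal(1e-8, 1e-9, t.size)), rate)
        with pytest.warns(RuntimeWarning, match="unreliable"):
            align_cross_correlation(a, b, max_lag=1.0)


class TestBlandAltman:
    def test_identical_and_offset_pairs(self):
        x = np.linspace(1e-9, 1e-8, 50)
        res = bland_altman(x, x)
        assert res["bias"] == 0 and res["sd"] == 0
        res = bland_altman(x, x + 3e-10)
        assert res["bias"] == pytest.approx(3e-10)
        assert res["sd"] == pytest.approx(0.0, abs=1e-22)
        assert res["limits"][0] == pytest.approx(3e-10)

    def test_gaussian_differences_recovered(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(5e-9, 5e-8, 10_000)
        mu, sigma = 4.27e-10, 8.39e-10
        y = x + rng.normal(mu, sigma, x.size)
        res = bland_altman(x, y)
        assert res["bias"] == pytest.approx(mu, rel=0.05)
        assert res["sd"] == pytest.approx(sigma, rel=0.05)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0])


class TestScalpSensitivity:
    def test_tourniquet_worked_example(self):
        assert round(scalp_sensitivity(85.3, 39.2)) == 46

    def test_limits(self):
        assert scalp_sensitivity(80.0, 0.0) == 0.0
        assert scalp_sensitivity(42.0, 42.0) == 100.0

    def test_long_exceeding_short_rejected(self):
        with pytest.raises(ValueError):
            scalp_sensitivity(40.0, 60.0)


class TestUnitInvariance:
    def test_gating_and_rbfi_invariant_to_rescaling(self):
        series, beats = make_series(duration=80.0, noise_sd=3e-10, seed=12,
                                    epochs=[Epoch("a", 40.0, 20.0, 1.3)])
        scale = 3.7e4
        scaled = BfiTimeSeries(series.t, series.bfi * scale, series.rate,
                               series.annotations)
        g1 = cardiac_gate(series, beats, 20, 1)
        g2 = cardiac_gate(scaled, beats, 20, 1)
        np.testing.assert_allclose(g2.cov, g1.cov, rtol=1e-9)
        r1 = relative_bfi(series)
        r2 = relative_bfi(scaled)
        np.testing.assert_allclose(r2["mean"], r1["mean"], rtol=1e-9)
        # Bland-Altman statistics scale linearly instead
        ba1 = bland_altman(series.bfi, series.bfi * 1.01)
        ba2 = bland_altman(scaled.bfi, scaled.bfi * 1.01)
        assert ba2["bias"] == pytest.approx(scale * ba1["bias"], rel=1e-9)


class TestEndToEndTourniquet:
    def test_pipeline_reproduces_configured_sensitivity(self):
        """Superficial-only flow drop on synthetic short/long channels:
        the full chain (beat filter -> rBFi -> drops -> sensitivity)
        recovers the configured scalp-sensitivity fraction within 3%."""
        drop_short = 0.80          # short channel sees the full scalp drop
        sensitivity = 0.46         # configured long-channel scalp sensitivity
        drop_long = sensitivity * drop_short
        epochs_s = [Epoch("cuff", 60.0, 30.0, 1 - drop_short)]
        epochs_l = [Epoch("cuff", 60.0, 30.0, 1 - drop_long)]
        short, beats = make_series(duration=120.0, pulsatility=0.3,
                                   noise_sd=2e-10, seed=21, epochs=epochs_s)
        long_, _ = make_series(duration=120.0, pulsatility=0.3,
                               noise_sd=2e-10, seed=22, epochs=epochs_l)
        drops = []
        for series in (short, long_):
            filtered = beat_average(series, beats)
            res = relative_bfi(filtered)
            during = res["mean"][(res["time"] > 10) & (res["time"] < 28)]
            drops.append(100 * (1 - during.mean()))
        est = scalp_sensitivity(drops[0], drops[1])
        assert est == pytest.approx(100 * sensitivity, abs=3.0)


def test_detect_peaks_on_synthetic_pulse():
    series, beats = make_series(duration=30.0, pulsatility=0.5, jitter=0.0)
    peaks = detect_peaks(series.bfi, series.rate)
    rr = np.diff(peaks)
    assert rr.mean() == pytest.approx(1.0, rel=0.05)
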
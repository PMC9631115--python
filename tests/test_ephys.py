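"""Unit quality control, responsiveness, and surface detection."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from visuomotor import ephys as ep
from visuomotor.synth import (
    SyntheticUnitTruth,
    make_template,
    simulate_lfp_correlation,
    simulate_unit,
)


class TestWaveformShape:
    def test_canonical_somatic_waveform_passes(self):
        template, peak, _ = make_template(trough_to_peak_us=400.0)
        shape = ep.qc_waveform_shape(template[peak], 30000.0)
        assert shape.passed
        assert shape.trough_to_peak_us == pytest.approx(400.0, abs=40.0)

    def test_short_duration_fails_bound(self):
        template, peak, _ = make_template(
            trough_to_peak_us=50.0,
            trough_width_us=15.0,
            peak_width_us=20.0,
            sample_rate=120000.0,
            n_samples=328,
        )
        shape = ep.qc_waveform_shape(template[peak], 120000.0)
        assert shape.trough_to_peak_us < 100.0
        assert not shape.duration_ok

    def test_peak_before_trough_fails_shape(self):
        template, peak, _ = make_template()
        shape = ep.qc_waveform_shape(template[peak][::-1], 30000.0)
        assert not shape.shape_ok

    def test_small_trough_fails_shape(self):
        template, peak, _ = make_template(trough_amplitude=20.0, peak_amplitude=60.0)
        shape = ep.qc_waveform_shape(template[peak], 30000.0)
        assert not shape.shape_ok

    def test_noisy_baseline_fails(self):
        template, peak, _ = make_template()
        w = template[peak].copy()
        w[:5] = 0.5 * w.min()
        shape = ep.qc_waveform_shape(w, 30000.0)
        assert not shape.baseline_ok

    def test_flat_waveform_fails_with_reason(self):
        shape = ep.qc_waveform_shape(np.zeros(82), 30000.0)
        assert not shape.passed and shape.reason == "flat waveform"

    @given(st.floats(0.1, 100.0))
    def test_ratio_criteria_invariant_to_scaling(self, gain):
        template, peak, _ = make_template()
        a = ep.qc_waveform_shape(template[peak], 30000.0)
        b = ep.qc_waveform_shape(gain * template[peak], 30000.0)
        assert (a.shape_ok, a.duration_ok, a.baseline_ok) == (
            b.shape_ok,
            b.duration_ok,
            b.baseline_ok,
        )


class TestSpatialDecay:
    def test_constant_amplitudes_pass(self):
        ok, slope = ep.qc_spatial_decay(np.full(8, 60.0), np.arange(8.0))
        assert ok and slope == pytest.approx(0.0)

    @pytest.mark.parametrize("slope_true, expect_pass", [(-30.0, False), (-5.0, True)])
    def test_planted_slopes(self, slope_true, expect_pass):
        dists = np.arange(8.0)
        amps = 100.0 + slope_true * dists
        ok, slope = ep.qc_spatial_decay(amps, dists)
        assert ok is expect_pass
        assert slope == pytest.approx(slope_true)

    def test_too_few_channels_indeterminate(self):
        with pytest.warns(UserWarning, match="channels"):
            ok, slope = ep.qc_spatial_decay(np.array([1.0, 2.0]), np.array([0.0, 1.0]))
        assert ok and np.isnan(slope)


class TestMissingFraction:
    @pytest.mark.parametrize(
        "floor, expected",
        [(40.0, stats.norm.cdf(-1.0)), (45.0, stats.norm.cdf(-0.5))],
    )
    def test_truncated_gaussian_recovery(self, rng, floor, expected):
        amps = rng.normal(50.0, 10.0, 30000)
        est = ep.estimate_missing_fraction(amps[amps >= floor], floor)
        assert est == pytest.approx(expected, abs=0.03)

    def test_floor_below_everything_is_near_zero(self, rng):
        amps = rng.normal(50.0, 10.0, 5000)
        assert ep.estimate_missing_fraction(amps, amps.min() - 50.0) < 0.01

    def test_consistency_with_sample_size(self):
        """Estimator error shrinks as the amplitude sample grows."""
        rng = np.random.default_rng(4)
        truth = stats.norm.cdf(-1.0)
        errs = []
        for n in (1_000, 100_000):
            amps = rng.normal(50.0, 10.0, n)
            est = ep.estimate_missing_fraction(amps[amps >= 40.0], 40.0)
            errs.append(abs(est - truth))
        assert errs[1] < errs[0]

    def test_zero_variance_warns(self):
        with pytest.warns(UserWarning, match="variance"):
            assert ep.estimate_missing_fraction(np.full(100, 5.0), 1.0) == 0.0


class TestContamination:
    def test_zero_violations_zero_contamination(self):
        times = np.arange(0.0, 10.0, 0.05)  # 50 ms ISIs, no violations
        f_p, r = ep.refractory_contamination(times, duration=10.0)
        assert f_p == 0.0 and r == 0

    def test_printed_example_inverts_correctly(self):
        """N=10,000, T=3600 s, r=5 -> F_p near 0.05 (numeric inversion oracle)."""
        params = ep.QCParams()
        n, t_total, r = 10_000, 3600.0, 5
        f_p, _ = ep.refractory_contamination(
            np.linspace(0, t_total, n), t_total, params, n_violations=r
        )
        # oracle: grid-evaluate the forward formula and pick the best F_p
        grid = np.linspace(0.0, 0.5, 200_001)
        fwd = (
            2.0
            * (params.refractory_period - params.censored_period)
            * n**2
            * (1 - grid)
            * grid
            / t_total
        )
        oracle = grid[np.argmin(np.abs(fwd - r))]
        assert f_p == pytest.approx(oracle, abs=1e-4)
        assert f_p == pytest.approx(0.05, abs=0.005)

    def test_negative_discriminant_reports_full_contamination(self):
        times = np.sort(np.random.default_rng(0).uniform(0, 1.0, 2000))
        f_p, _ = ep.refractory_contamination(times, duration=1.0)
        assert f_p == 1.0

    @given(st.integers(0, 40), st.integers(500, 20000), st.floats(600.0, 7200.0))
    def test_forward_formula_reproduces_violation_count(self, r, n, t_total):
        """Inverting then forward-evaluating recovers r (when a root exists)."""
        params = ep.QCParams()
        f_p, _ = ep.refractory_contamination(
            np.linspace(0, t_total, n), t_total, params, n_violations=r
        )
        if f_p < 1.0:
            fwd = (
                2.0
                * (params.refractory_period - params.censored_period)
                * n**2
                * (1 - f_p)
                * f_p
                / t_total
            )
            assert fwd == pytest.approx(r, abs=1e-6)

    def test_estimate_tracks_planted_contamination(self):
        """Recovered F_p orders and roughly matches planted truth (smoke check;
        the well-replicated recovery bound lives in the acceptance suite)."""
        rng = np.random.default_rng(9)
        means = []
        for f_true in (0.0, 0.1, 0.2):
            ests = [
                ep.refractory_contamination(
                    simulate_unit(
                        SyntheticUnitTruth(contamination=f_true, base_rate=5.0),
                        duration=1800.0,
                        rng=rng,
                    ).spike_times,
                    1800.0,
                )[0]
                for _ in range(4)
            ]
            means.append(np.mean(ests))
        assert means[0] < 0.03
        assert means[0] < means[1] < means[2]

    def test_too_few_spikes_warns(self):
        with pytest.warns(UserWarning, match="spikes"):
            f_p, r = ep.refractory_contamination(np.array([1.0]), 10.0)
        assert f_p == 0.0


class TestClassifyUnit:
    def test_clean_simulated_unit_passes_all_seven(self):
        truth = SyntheticUnitTruth(contamination=0.0, base_rate=5.0)
        unit = simulate_unit(truth, duration=600.0, seed=13)
        qc = ep.classify_unit_quality(unit, duration=600.0)
        assert qc.overall, qc
        assert qc.n_spikes > 2500

    def test_low_count_fails_count_criterion(self):
        truth = SyntheticUnitTruth(base_rate=0.4)
        unit = simulate_unit(truth, duration=600.0, seed=14)
        qc = ep.classify_unit_quality(unit, duration=600.0)
        assert unit.spike_times.size < 300
        assert not qc.count_ok and not qc.overall

    def test_contaminated_unit_fails_contamination(self):
        truth = SyntheticUnitTruth(contamination=0.2, base_rate=8.0)
        unit = simulate_unit(truth, duration=1800.0, seed=15)
        qc = ep.classify_unit_quality(unit, duration=1800.0)
        assert not qc.contamination_ok

    def test_truncated_amplitudes_fail_missing(self):
        truth = SyntheticUnitTruth(detection_floor=45.0, base_rate=8.0)
        unit = simulate_unit(truth, duration=1200.0, seed=16)
        qc = ep.classify_unit_quality(unit, duration=1200.0)
        assert not qc.missing_ok  # ~31% below the floor, over the 20% cap


class TestCellType:
    @pytest.mark.parametrize(
        "duration_us, expected",
        [(250.0, "narrow"), (600.0, "wide"), (400.0, "wide")],
    )
    def test_boundary_and_tie_rule(self, duration_us, expected):
        assert ep.classify_cell_type(duration_us) == expected


class TestMultiunitNormalization:
    def test_baseline_rate_maps_to_zero(self):
        traces = np.full((3, 50), 4.0)
        out, _ = ep.normalize_multiunit(traces, np.full(3, 4.0))
        assert np.allclose(out, 0.0)

    def test_doubling_with_small_softening_near_one(self):
        traces = np.full((1, 10), 20.0)
        out, s = ep.normalize_multiunit(
            traces, np.array([10.0]), pooled_baseline_rates=np.array([0.01, 0.02, 10.0])
        )
        assert out == pytest.approx(np.full((1, 10), 1.0), rel=0.01)

    def test_softening_equals_sorted_percentile(self, rng):
        pool = rng.uniform(0, 30, 200)
        _, s = ep.normalize_multiunit(
            np.zeros((1, 5)), np.array([1.0]), pooled_baseline_rates=pool
        )
        assert s == pytest.approx(np.percentile(pool, 10))

    def test_empty_baseline_rejected(self):
        with pytest.raises(ValueError):
            ep.normalize_multiunit(np.zeros((1, 5)), np.array([1.0, 2.0]))


class TestShuffleResponsiveness:
    def test_identical_windows_not_significant(self, rng):
        rates = rng.poisson(5, 40).astype(float)
        res = ep.shuffle_responsiveness(rates, rates.copy(), rng=rng)
        assert res.statistic == 0.0 and not res.significant and res.sign == "none"

    def test_constant_offset_hits_minimum_p(self, rng):
        base = rng.poisson(5, 50).astype(float)
        res = ep.shuffle_responsiveness(base, base + 10.0, n_shuffles=1000, rng=rng)
        assert res.p_value == pytest.approx(1 / 1001)
        assert res.sign == "positive"

    def test_negative_response_sign(self, rng):
        base = np.full(50, 12.0)
        res = ep.shuffle_responsiveness(base, base - 6.0, rng=rng)
        assert res.significant and res.sign == "negative"

    def test_too_few_trials_reports_absent(self, rng):
        res = ep.shuffle_responsiveness(np.ones(3), np.ones(3) + 5, rng=rng)
        assert res.p_value is None and not res.significant


class TestSurfaceChannel:
    def test_block_diagonal_boundary(self):
        c = np.eye(40)
        c[:20, :20] = 0.9
        c[20:, 20:] = 0.6
        np.fill_diagonal(c, 1.0)
        assert ep.detect_surface_channel(c) == 20

    def test_simulated_lfp_within_one_channel(self):
        c = simulate_lfp_correlation(surface_channel=20, seed=30)
        assert abs(ep.detect_surface_channel(c) - 20) <= 1

    def test_uniform_correlation_returns_none(self):
        c = np.full((30, 30), 0.5)
        np.fill_diagonal(c, 1.0)
        with pytest.warns(UserWarning, match="boundary"):
            assert ep.detect_surface_channel(c) is None


class TestSyntheticUnits:
    def test_zero_contamination_respects_refractory(self):
        truth = SyntheticUnitTruth(contamination=0.0, base_rate=20.0)
        unit = simulate_unit(truth, duration=300.0, seed=17)
        assert np.all(np.diff(unit.spike_times) >= truth.refractory_period - 1e-12)

    def test_spike_count_matches_rate(self):
        truth = SyntheticUnitTruth(base_rate=5.0)
        unit = simulate_unit(truth, duration=600.0, seed=18)
        assert abs(unit.spike_times.size - 3000) < 3 * np.sqrt(3000)

    def test_amplitude_floor_removes_gaussian_tail(self):
        truth = SyntheticUnitTruth(base_rate=30.0, detection_floor=40.0)
        unit = simulate_unit(truth, duration=600.0, seed=19)
        kept = unit.spike_times.size
        expected_total = 30.0 * 600.0
        frac_removed = 1.0 - kept / expected_total
        assert frac_removed == pytest.approx(stats.norm.cdf(-1.0), abs=0.03)
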
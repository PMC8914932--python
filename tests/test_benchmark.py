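"""Benchmark statistics: filtering, resampling, event matching, agreement."""

import itertools
import math

import numpy as np
import pytest

import spf
from spf.benchmark import match_times
from spf.errors import ConfigurationError, DomainError, EventStructureError


class TestLowpassFilter:
    def test_dc_gain_is_unity(self):
        x = np.full(500, 3.7)
        assert np.allclose(spf.lowpass_filter(x, fs=100.0), x, atol=1e-9)

    def test_stopband_attenuation_matches_analytic_response(self):
        fs, f_test = 200.0, 60.0
        t = np.arange(4000) / fs
        x = np.sin(2 * np.pi * f_test * t)
        y = spf.lowpass_filter(x, fs=fs)
        # forward-backward 2nd-order digital Butterworth: amplitude gain
        # |H|^2 = 1/(1 + (tan(pi f/fs)/tan(pi fc/fs))^4) (bilinear prewarp)
        warp = math.tan(math.pi * f_test / fs) / math.tan(math.pi * 25.0 / fs)
        expected = 1.0 / (1.0 + warp ** 4)
        mid = slice(1000, 3000)  # steady-state region, away from edges
        ratio = np.abs(y[mid]).max() / np.abs(x[mid]).max()
        assert ratio < 0.05
        assert ratio == pytest.approx(expected, rel=0.1)

    def test_linearity(self):
        rng = np.random.default_rng(13)
        x, y = rng.normal(size=300), rng.normal(size=300)
        lhs = spf.lowpass_filter(2.5 * x - 1.5 * y, fs=100.0)
        rhs = 2.5 * spf.lowpass_filter(x, fs=100.0) - \
            1.5 * spf.lowpass_filter(y, fs=100.0)
        assert np.max(np.abs(lhs - rhs)) < 1e-9

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ConfigurationError):
            spf.lowpass_filter(np.zeros(100), fs=40.0, cutoff=25.0)


class TestResampleStance:
    def test_output_length_is_exactly_1000(self):
        t = np.arange(300) / 100.0
        out = spf.resample_stance(t, np.sin(t), hs=0.5, to=2.0)
        assert out.shape == (1000,)

    def test_constant_signal_stays_constant(self):
        t = np.arange(300) / 100.0
        out = spf.resample_stance(t, np.full(300, 4.2), 0.5, 2.0, n=50)
        assert np.allclose(out, 4.2)

    def test_exact_on_linear_ramp(self):
        t = np.arange(300) / 100.0
        x = 3.0 * t - 1.0
        out = spf.resample_stance(t, x, 0.5, 2.0, n=777)
        grid = np.linspace(0.5, 2.0, 777)
        assert np.max(np.abs(out - (3.0 * grid - 1.0))) < 1e-9

    def test_degenerate_stance_rejected(self):
        t = np.arange(10) / 100.0
        with pytest.raises(DomainError):
            spf.resample_stance(t, np.zeros(10), 0.05, 0.05)


class TestMatchEvents:
    def test_identical_lists_pair_with_zero_error(self):
        ref = np.array([1.0, 2.6, 4.2])
        m = match_times(ref, ref, max_gap=0.8)
        assert np.allclose(m.errors, 0.0)
        assert m.unmatched_ref.size == 0 and m.unmatched_det.size == 0

    def test_rigid_shift_reproduced_in_errors(self):
        ref = np.array([1.0, 2.6, 4.2])
        m = match_times(ref + 0.02, ref, max_gap=0.8)
        assert np.allclose(m.errors, 0.02)

    def test_out_of_gap_detection_is_false_alarm(self):
        m = match_times(np.array([1.0, 9.0]), np.array([1.1]), max_gap=0.5)
        assert m.n_pairs == 1
        assert m.unmatched_det.tolist() == [9.0]

    def test_agrees_with_exhaustive_minimal_pairing(self):
        rng = np.random.default_rng(14)
        for _ in range(30):
            ref = np.sort(rng.uniform(0, 10, rng.integers(1, 5)))
            det = np.sort(rng.uniform(0, 10, rng.integers(1, 5)))
            gap = 1.0
            m = match_times(det, ref, gap)
            # brute force over all injective assignments: maximal pair count,
            # minimal total |error|
            best = None
            n_pairs_best = -1
            for k in range(min(len(ref), len(det)), -1, -1):
                for ref_idx in itertools.combinations(range(len(ref)), k):
                    for det_idx in itertools.permutations(range(len(det)), k):
                        errs = [abs(det[d] - ref[r])
                                for r, d in zip(ref_idx, det_idx)]
                        if any(e > gap for e in errs):
                            continue
                        total = sum(errs)
                        if k > n_pairs_best or (k == n_pairs_best
                                                and total < best - 1e-12):
                            best, n_pairs_best = total, k
                if n_pairs_best >= 0:
                    break
            assert m.n_pairs == n_pairs_best
            assert np.abs(m.errors).sum() == pytest.approx(best, abs=1e-9)


class TestEventErrorStats:
    def test_all_late_constant_errors(self):
        s = spf.event_error_stats([0.02, 0.02, 0.02], stride_period=1.6)
        assert s.mae == pytest.approx(0.020)
        assert s.pct_late == 1.0
        assert s.mae_pct_stride == pytest.approx(100 * 0.02 / 1.6)

    def test_symmetric_errors_half_late(self):
        s = spf.event_error_stats([-0.01, 0.01], stride_period=1.6)
        assert s.pct_late == 0.5

    def test_quantiles_match_independent_implementation(self):
        rng = np.random.default_rng(15)
        for _ in range(50):
            errs = rng.normal(0, 0.05, rng.integers(3, 40))
            s = spf.event_error_stats(errs, 1.6)
            ae = sorted(abs(e) for e in errs)

            def quantile(q):  # linear interpolation between order statistics
                pos = q * (len(ae) - 1)
                lo = math.floor(pos)
                hi = math.ceil(pos)
                return ae[lo] + (pos - lo) * (ae[hi] - ae[lo])

            assert s.mae == pytest.approx(quantile(0.5), abs=1e-12)
            assert s.iqr == pytest.approx(quantile(0.75) - quantile(0.25),
                                          abs=1e-12)

    def test_empty_pairing_rejected(self):
        with pytest.raises(DomainError):
            spf.event_error_stats([], 1.6)


class TestStanceDurations:
    def test_simple_stride(self):
        st = spf.stance_durations(spf.GaitEvents([1.0], [1.65]))
        assert st.tolist() == [pytest.approx(0.65)]

    def test_unterminated_final_stride_omitted(self):
        st = spf.stance_durations(spf.GaitEvents([1.0, 2.6], [1.65]))
        assert st.size == 1

    def test_non_interleaved_rejected(self):
        with pytest.raises(EventStructureError):
            spf.stance_durations(spf.GaitEvents([1.0, 1.2], [2.0, 2.2]))

    def test_simulator_truth_duration(self, noisy_trial):
        st = spf.stance_durations(noisy_trial.truth)
        assert np.allclose(st, 0.62 * 1.6, atol=0.01)


class TestWaveformAgreement:
    def test_identical_signals(self):
        a = np.random.default_rng(16).normal(size=(3, 100))
        wa = spf.waveform_agreement(a, a.copy())
        assert wa.pearson_r == pytest.approx(1.0)
        assert wa.rmse == 0.0

    def test_negated_signal_anticorrelates(self):
        a = np.random.default_rng(17).normal(size=(2, 50))
        assert spf.waveform_agreement(a, -a).pearson_r == pytest.approx(-1.0)

    def test_constant_input_has_undefined_correlation(self):
        wa = spf.waveform_agreement(np.ones((1, 10)), np.ones((1, 10)))
        assert np.isnan(wa.pearson_r)

    def test_matches_textbook_formulas(self):
        rng = np.random.default_rng(18)
        for _ in range(25):
            a = rng.normal(size=(4, 60))
            b = rng.normal(size=(4, 60))
            wa = spf.waveform_agreement(a, b)
            x, y = a.ravel(), b.ravel()
            r = (np.sum((x - x.mean()) * (y - y.mean()))
                 / np.sqrt(np.sum((x - x.mean()) ** 2)
                           * np.sum((y - y.mean()) ** 2)))
            rmse = np.sqrt(np.mean((x - y) ** 2))
            assert wa.pearson_r == pytest.approx(r, abs=1e-12)
            assert wa.rmse == pytest.approx(rmse, abs=1e-12)


class TestPeakVgrf:
    def test_constant_stance(self):
        peaks = spf.peak_vgrf_normalized(np.full((1, 100), 700.0), 70.0)
        assert peaks.tolist() == [10.0]

    def test_doubling_mass_halves_value(self):
        m = np.random.default_rng(19).uniform(0, 800, (3, 50))
        assert np.allclose(spf.peak_vgrf_normalized(m, 140.0),
                           spf.peak_vgrf_normalized(m, 70.0) / 2.0)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(DomainError):
            spf.peak_vgrf_normalized(np.ones((1, 5)), 0.0)


class TestTrialEvaluation:
    def test_statistics_invariant_to_global_time_shift(self):
        ref = spf.GaitEvents([1.0, 2.6, 4.2], [1.99, 3.59, 5.19])
        det = spf.GaitEvents([1.03, 2.62, 4.25], [1.97, 3.56, 5.18])
        shift = 11.7
        for kind in ("HS", "TO"):
            m0 = spf.match_events(det, ref)[kind]
            ref_s = spf.GaitEvents(ref.hs_times + shift, ref.to_times + shift)
            det_s = spf.GaitEvents(det.hs_times + shift, det.to_times + shift)
            m1 = spf.match_events(det_s, ref_s)[kind]
            assert np.allclose(m0.errors, m1.errors)

    def test_full_pipeline_meets_timing_budget(self, noisy_trial):
        report = spf.evaluate_trial(noisy_trial)
        for det in ("PS", "IMU"):
            for kind in ("HS", "TO"):
                assert report["detectors"][det][kind]["mae_s"] <= 0.100

    def test_ps_underestimates_stance_on_noiseless_trial(self, quiet_trial,
                                                         poly, layout,
                                                         thresholds):
        vgrf = spf.compute_vgrf(quiet_trial.voltages, poly, layout, thresholds)
        ev = spf.ps_segment(quiet_trial.t_pressure, vgrf, thresholds.vgrf_min)
        truth = quiet_trial.truth
        assert np.all(ev.hs_times >= truth.hs_times)   # HS detected late
        assert np.all(ev.to_times <= truth.to_times)   # TO detected early
        assert np.all(spf.stance_durations(ev)
                      < spf.stance_durations(truth))

    def test_cohort_grouping_is_median_of_trial_medians(self):
        trials = [spf.simulate_trial(spf.GaitProfileParams(n_strides=4, seed=s))
                  for s in (21, 22, 23)]
        report = spf.evaluate_cohort(trials)
        maes = [t["detectors"]["PS"]["HS"]["mae_s"] for t in report.per_trial]
        assert report.grouped["detectors"]["PS"]["HS"]["mae_s"] == pytest.approx(
            float(np.median(maes)))
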
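"""EMG rejection chain, MEP quantification and condition statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from setms.mep import (EMGTrialSet, baseline_correct, biphasic_check,
                       compare_conditions, group_compare_independent,
                       outlier_reject, peak_to_peak, percent_change,
                       quantify_meps, rms_reject, simple_linreg)
from setms.scheduling import StimulusPlan
from setms.synthetic import ParticipantEMGParams, gen_emg_trials, mep_template

FS = 5000.0
TIME_MS = -200.0 + np.arange(int(0.260 * FS) + 1) * 1000.0 / FS


def _trials(data, condition="setms"):
    return EMGTrialSet(np.atleast_2d(data), FS, TIME_MS, condition)


def _noise_trials(n, sd=0.008, seed=0):
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, sd, size=(n, TIME_MS.size))


class TestBaselineCorrect:
    def test_constant_offset_removed(self):
        out = baseline_correct(_trials(np.full(TIME_MS.size, 0.3)))
        win = (TIME_MS >= -20) & (TIME_MS <= -5)
        assert out.data[0, win].mean() == pytest.approx(0.0, abs=1e-15)
        assert np.allclose(out.data[0], 0.0)

    def test_zero_trace_unchanged(self):
        out = baseline_correct(_trials(np.zeros(TIME_MS.size)))
        assert np.allclose(out.data, 0.0)

    def test_ramp_shifted_by_window_mean(self):
        ramp = np.linspace(0.0, 1.0, TIME_MS.size)
        win = (TIME_MS >= -20) & (TIME_MS <= -5)
        out = baseline_correct(_trials(ramp))
        assert np.allclose(out.data[0], ramp - ramp[win].mean())


class TestRmsReject:
    def test_identical_trials_none_rejected(self):
        data = np.tile(np.sin(TIME_MS / 30.0), (100, 1))
        assert not rms_reject(_trials(data)).any()

    def test_seeded_high_rms_trials_flagged_exactly(self):
        data = _noise_trials(100)
        data[10:15] += _noise_trials(5, sd=0.08, seed=1)  # 10x background
        flags = rms_reject(_trials(data))
        assert np.flatnonzero(flags).tolist() == [10, 11, 12, 13, 14]

    def test_pulse_window_omitted(self):
        data = _noise_trials(50)
        omit = (TIME_MS > -5) & (TIME_MS < 5)
        data[3, omit] = 100.0  # huge, but inside the omitted interval
        assert not rms_reject(_trials(data))[3]

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            rms_reject(_trials(np.zeros((2, TIME_MS.size))))


class TestBiphasicCheck:
    def test_template_passes(self):
        data = _noise_trials(1) + 1.0 * mep_template(TIME_MS, 22.0)
        assert biphasic_check(_trials(data))[0]

    def test_flat_noise_fails(self):
        assert not biphasic_check(_trials(_noise_trials(1, seed=2)))[0]

    def test_monophasic_pulse_fails(self):
        mono = 1.0 * np.exp(-0.5 * ((TIME_MS - 25.0) / 5.0) ** 2)
        data = _noise_trials(1, seed=3) + mono
        win = (TIME_MS >= 15) & (TIME_MS <= 40)
        # oracle: sign-excursion scan inside the window
        sigma = data[0, (TIME_MS >= -200) & (TIME_MS <= -20)].std()
        has_pos = (data[0, win] > 3 * sigma).any()
        has_neg = (data[0, win] < -3 * sigma).any()
        assert has_pos and not has_neg
        assert not biphasic_check(_trials(data))[0]


class TestOutlierReject:
    def test_equal_amplitudes_none_flagged(self):
        assert not outlier_reject(np.ones(50)).any()

    def test_extreme_amplitude_flagged(self):
        p2p = np.concatenate([np.full(99, 1.0) +
                              np.random.default_rng(4).normal(0, 0.1, 99),
                              [50.0]])
        flags = outlier_reject(p2p)
        assert flags[-1] and flags.sum() == 1

    def test_boundary_value_not_flagged(self):
        p2p = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        thresh = p2p.mean() + 5 * p2p.std(ddof=0)
        flags = outlier_reject(np.append(p2p, thresh))
        assert not flags[-1]  # strict inequality at the boundary


class TestPeakToPeak:
    def test_template_amplitude(self):
        data = np.zeros(TIME_MS.size)
        data[np.argmin(np.abs(TIME_MS - 25.0))] = 1.2
        data[np.argmin(np.abs(TIME_MS - 35.0))] = -0.8
        assert peak_to_peak(_trials(data))[0] == pytest.approx(2.0)

    def test_flat_trial_zero(self):
        assert peak_to_peak(_trials(np.zeros(TIME_MS.size)))[0] == 0.0

    def test_extremes_outside_window_ignored(self):
        data = np.zeros(TIME_MS.size)
        data[np.argmin(np.abs(TIME_MS - 17.0))] = 5.0
        data[np.argmin(np.abs(TIME_MS - 51.0))] = -5.0
        data[np.argmin(np.abs(TIME_MS - 30.0))] = 0.5
        assert peak_to_peak(_trials(data))[0] == pytest.approx(0.5)


class TestPercentChange:
    def test_condition_means_delta(self):
        assert percent_change(3.08, 2.44) == pytest.approx(26.2295, abs=1e-3)

    @pytest.mark.parametrize("a,b,expected", [(2.0, 2.0, 0.0),
                                              (3.0, 2.0, 50.0)])
    def test_simple_values(self, a, b, expected):
        assert percent_change(a, b) == expected

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.1, 100.0), st.floats(0.1, 100.0))
    def test_forward_backward_round_trip(self, a, b):
        pa = percent_change(a, b)
        pb = percent_change(b, a)
        # (1 + pa/100)(1 + pb/100) = (a/b)(b/a) = 1 exactly
        assert (1 + pa / 100.0) * (1 + pb / 100.0) == pytest.approx(
            1.0, rel=1e-12)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_change(1.0, 0.0)


class TestFilterChain:
    def test_seeded_fixture_rejected_exactly_with_reasons(self, pulse_plan):
        params = ParticipantEMGParams(n_trials=100, artifact_fraction=0.05,
                                      outlier_fraction=0.01,
                                      absent_fraction=0.0, seed=42)
        trials, truth = gen_emg_trials(params, pulse_plan)
        res = quantify_meps(trials)
        merged = res.audit.merge(truth, on="trial")
        assert res.n_rejected == 6
        assert (merged.loc[merged.label == "artifact",
                           "reject_reason"] == "rms").all()
        assert (merged.loc[merged.label == "outlier",
                           "reject_reason"] == "outlier").all()
        assert (merged.loc[merged.label == "clean", "kept"]).all()

    def test_each_trial_has_exactly_one_reason(self, pulse_plan):
        params = ParticipantEMGParams(seed=5)
        trials, _ = gen_emg_trials(params, pulse_plan)
        res = quantify_meps(trials)
        assert (res.audit.kept == (res.audit.reject_reason == "none")).all()
        assert res.n_kept + res.n_rejected == trials.n_trials

    def test_artifact_free_set_rejection_below_5_percent(self, pulse_plan):
        params = ParticipantEMGParams(artifact_fraction=0.0,
                                      outlier_fraction=0.0,
                                      absent_fraction=0.0, n_trials=150,
                                      seed=6)
        trials, _ = gen_emg_trials(params, pulse_plan)
        res = quantify_meps(trials)
        assert res.fraction_rejected < 0.05

    def test_clean_mean_amplitude_recovered_within_2_percent(self, pulse_plan):
        params = ParticipantEMGParams(artifact_fraction=0.0,
                                      outlier_fraction=0.0,
                                      absent_fraction=0.0, n_trials=150,
                                      seed=7)
        trials, truth = gen_emg_trials(params, pulse_plan)
        res = quantify_meps(trials)
        kept = res.audit.merge(truth, on="trial").query("kept")
        assert res.mean_p2p == pytest.approx(kept.true_amp_mV.mean(),
                                             rel=0.02)


class TestGroupStats:
    def test_identical_group_means_give_zero_t(self):
        st_ = group_compare_independent([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert st_.t_stat == pytest.approx(0.0, abs=1e-15)

    def test_independent_t_matches_scipy(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            x = rng.normal(size=10)
            y = rng.normal(1.0, 2.0, size=14)
            ours = group_compare_independent(x, y)
            ref = sps.ttest_ind(x, y, equal_var=True)
            assert ours.t_stat == pytest.approx(ref.statistic, abs=1e-10)
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-10)
            assert ours.df == x.size + y.size - 2

    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        res = simple_linreg(x, 2.0 * x)
        assert res["slope"] == pytest.approx(2.0)
        assert res["r2"] == pytest.approx(1.0)

    def test_ols_matches_statsmodels(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(13)
        for _ in range(20):
            x = rng.normal(size=15)
            y = 0.5 * x + rng.normal(size=15)
            ours = simple_linreg(x, y)
            ref = sm.OLS(y, sm.add_constant(x)).fit()
            assert ours["slope"] == pytest.approx(ref.params[1], abs=1e-10)
            assert ours["intercept"] == pytest.approx(ref.params[0],
                                                      abs=1e-10)
            assert ours["r2"] == pytest.approx(ref.rsquared, abs=1e-10)
            assert ours["f_stat"] == pytest.approx(ref.fvalue, abs=1e-8)
            assert ours["p_value"] == pytest.approx(ref.f_pvalue, abs=1e-10)


class TestCompareConditions:
    def test_identical_conditions_flagged(self):
        res = compare_conditions([2.0, 3.0], [2.0, 3.0])
        assert res.mean_percent_change == 0.0
        assert np.isnan(res.stats.t_stat)

    def test_two_participant_percent_changes(self):
        res = compare_conditions([1.1, 1.3], [1.0, 1.0])
        assert res.mean_percent_change == pytest.approx(20.0)
        assert res.median_percent_change == pytest.approx(20.0)
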
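"""Generators: ITC calibration, EEG/EMG datasets, cohort stratification."""

import numpy as np
import pytest

from setms.preprocess import EEGEpochs
from setms.synthetic import (CohortSpec, ParticipantEEGParams,
                             ParticipantEMGParams, _stratified_phases,
                             gen_cohort, gen_eeg_epochs, gen_emg_trials,
                             itc_from_mix, mix_for_itc)
from setms.tfr import band_average, itc, morlet_transform


class TestCalibration:
    def test_half_mixing_matches_closed_form(self):
        # at w = 1/2 the mixture phase is theta/2, whose resultant is 2/pi
        assert itc_from_mix(0.5) == pytest.approx(2.0 / np.pi, abs=2e-3)

    def test_limits(self):
        assert itc_from_mix(0.0) == pytest.approx(0.0, abs=1e-12)
        assert itc_from_mix(1.0) == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_mixing_level(self):
        grid = np.linspace(0.0, 1.0, 21)
        vals = itc_from_mix(grid)
        assert np.all(np.diff(vals) > 0)

    def test_monte_carlo_itc_increases_with_mixing(self):
        # independent check on raw resultant lengths, 2000 trials per level
        rng = np.random.default_rng(14)
        means = []
        for w in [0.0, 0.25, 0.5, 0.75, 1.0]:
            theta = rng.uniform(0, 2 * np.pi, size=(20, 2000))
            z = w + (1 - w) * np.exp(1j * theta)
            means.append(np.abs((z / np.abs(z)).mean(axis=1)).mean())
        assert np.all(np.diff(means) > 0)

    def test_round_trip_inverse(self):
        targets = np.array([0.06, 0.11, 0.5, 0.9])
        assert np.allclose(itc_from_mix(mix_for_itc(targets)), targets,
                           atol=1e-6)

    @pytest.mark.parametrize("target", [0.06, 0.11, 0.5, 0.9])
    def test_generated_data_measured_itc_matches_target(self, target):
        # beta-band coherence is constant by construction: generate 500
        # trials, run the Morlet/ITC analysis on the beta band and compare
        params = ParticipantEEGParams(beta_itc=target, n_trials=500, seed=15)
        ep = gen_eeg_epochs(params, channels=["C3"])
        res = morlet_transform(ep, freqs=np.arange(20.0, 27.0))
        series = band_average(itc(res.coeffs[0]), res.freqs_hz, (20.0, 26.0))
        measured = series[np.abs(res.times_ms) <= 300.0].mean()
        assert measured == pytest.approx(target, abs=0.03)


class TestStratifiedPhases:
    def test_marginally_uniform_but_low_resultant(self):
        rng = np.random.default_rng(16)
        theta = _stratified_phases(100, rng)
        assert np.abs(np.exp(1j * theta).mean()) < 0.02
        # Kolmogorov-Smirnov against the uniform marginal over many draws
        draws = np.concatenate([_stratified_phases(100, rng)
                                for _ in range(50)])
        from scipy.stats import kstest
        assert kstest(draws / (2 * np.pi), "uniform").pvalue > 0.01


class TestEEGGenerator:
    def test_bit_identical_under_same_seed(self):
        p = ParticipantEEGParams(seed=17, n_trials=8)
        a = gen_eeg_epochs(p)
        b = gen_eeg_epochs(p)
        assert np.array_equal(a.data, b.data)

    def test_signal_only_on_motor_channels(self):
        p = ParticipantEEGParams(seed=18, n_trials=4, noise_sd_uV=0.0)
        ep = gen_eeg_epochs(p)
        rms = np.sqrt((ep.data ** 2).mean(axis=(1, 2)))
        for i, name in enumerate(ep.channel_names):
            if name in ("C5", "C3", "C1"):
                assert rms[i] > 1.0
            else:
                assert rms[i] == 0.0

    def test_itc_ordering_enforced_unless_inverted(self):
        with pytest.raises(ValueError, match="inverted"):
            ParticipantEEGParams(trough_itc=0.2, peak_itc=0.1)
        ParticipantEEGParams(trough_itc=0.2, peak_itc=0.1, inverted=True)

    def test_window_must_cover_baseline(self):
        with pytest.raises(ValueError, match="window"):
            gen_eeg_epochs(ParticipantEEGParams(seed=0, n_trials=4),
                           window_ms=(-400.0, 400.0))

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError, match="fs"):
            gen_eeg_epochs(ParticipantEEGParams(seed=0, n_trials=4), fs=100.0)

    def test_pink_noise_option_changes_spectrum(self):
        base = ParticipantEEGParams(seed=19, n_trials=4, alpha_amp_uV=0.0,
                                    beta_amp_uV=0.0)
        white = gen_eeg_epochs(base)
        pink = gen_eeg_epochs(
            ParticipantEEGParams(seed=19, n_trials=4, alpha_amp_uV=0.0,
                                 beta_amp_uV=0.0, pink_noise=True))
        def lowband_power(ep):
            spec = np.abs(np.fft.rfft(ep.data[0, :, 0])) ** 2
            f = np.fft.rfftfreq(ep.data.shape[1], 1e-3)
            return spec[(f > 0.5) & (f < 5)].sum() / spec[f > 0.5].sum()
        assert lowband_power(pink) > 3 * lowband_power(white)


class TestEMGGenerator:
    def test_truth_labels_cover_every_trial(self, pulse_plan):
        params = ParticipantEMGParams(seed=20)
        trials, truth = gen_emg_trials(params, pulse_plan)
        assert len(truth) == trials.n_trials
        assert set(truth.label) <= {"clean", "artifact", "outlier", "absent"}
        counts = truth.label.value_counts()
        assert counts.get("artifact", 0) == round(0.05 * params.n_trials)
        assert counts.get("absent", 0) == round(0.15 * params.n_trials)

    def test_bit_identical_under_same_seed(self, pulse_plan):
        params = ParticipantEMGParams(seed=21)
        a, _ = gen_emg_trials(params, pulse_plan)
        b, _ = gen_emg_trials(params, pulse_plan)
        assert np.array_equal(a.data, b.data)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ParticipantEMGParams(mep_latency_ms=50.0)
        with pytest.raises(ValueError):
            ParticipantEMGParams(mean_amp_mV={"setms": -1.0})

    def test_unknown_condition_rejected(self, pulse_plan):
        from setms.scheduling import StimulusPlan
        plan = StimulusPlan("setms", pulse_plan.pulse_times_s, -200.0,
                            pulse_plan.isi_s)
        params = ParticipantEMGParams(mean_amp_mV={"standard": 2.0}, seed=0)
        with pytest.raises(ValueError, match="no mean amplitude"):
            gen_emg_trials(params, plan)


class TestCohort:
    def test_group_means_exact_by_stratification(self):
        cohort = gen_cohort(CohortSpec(master_seed=1, n_inverted_slope=0))
        assert cohort.eeg_truth.trough_time_ms.mean() == pytest.approx(
            -156.48, abs=1e-9)
        assert cohort.eeg_truth.peak_time_ms.mean() == pytest.approx(
            46.41, abs=1e-9)
        for cond, mean in [("setms", 3.08), ("standard", 2.44),
                           ("auditory_control", 2.38)]:
            assert cohort.emg_truth[f"amp_{cond}"].mean() == pytest.approx(
                mean, abs=1e-9)
            assert (cohort.emg_truth[f"amp_{cond}"] > 0).all()

    def test_single_participant_gets_group_mean(self):
        spec = CohortSpec(n_participants_eeg=1, n_participants_emg=1,
                          n_inverted_slope=0, master_seed=2)
        cohort = gen_cohort(spec)
        assert cohort.eeg_truth.trough_time_ms.iloc[0] == pytest.approx(
            -156.48)
        assert cohort.emg_truth.amp_setms.iloc[0] == pytest.approx(3.08)

    def test_one_inverted_participant_in_default_cohort(self):
        cohort = gen_cohort(CohortSpec(master_seed=3))
        inv = cohort.eeg_truth.inverted
        assert inv.sum() == 1
        rises = cohort.eeg_truth.peak_itc - cohort.eeg_truth.trough_itc
        assert (rises[~inv] > 0).all()
        assert (rises[inv] < 0).all()

    def test_trough_precedes_peak_for_every_participant(self):
        cohort = gen_cohort(CohortSpec(master_seed=4))
        assert (cohort.eeg_truth.trough_time_ms
                < cohort.eeg_truth.peak_time_ms).all()

    def test_truth_tables_reproducible(self):
        a = gen_cohort(CohortSpec(master_seed=5))
        b = gen_cohort(CohortSpec(master_seed=5))
        assert a.eeg_truth.equals(b.eeg_truth)
        assert a.emg_truth.equals(b.emg_truth)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_inverted_slope=30)
        with pytest.raises(ValueError):
            CohortSpec(eeg_sd={"trough_time_ms": -1.0})


class TestIO:
    def test_emg_round_trip(self, tmp_path, pulse_plan):
        from setms.synthetic import write_emg_delimited
        params = ParticipantEMGParams(n_trials=10, seed=22)
        trials, truth = gen_emg_trials(params, pulse_plan)
        write_emg_delimited(trials, truth, tmp_path / "emg")
        mat = np.loadtxt(tmp_path / "emg.tsv", delimiter="\t")
        assert mat.shape == trials.data.shape
        assert (tmp_path / "emg_truth.tsv").exists()

    def test_events_tsv(self, tmp_path):
        from setms.scheduling import make_beat_schedule, schedule_pulses
        from setms.synthetic import write_events_tsv
        from setms.preprocess import read_events_tsv
        sched = make_beat_schedule(120.0, 30.0, "duple")
        plan = schedule_pulses(sched, "setms", seed=0)
        write_events_tsv(tmp_path / "ev.tsv", sched, [plan])
        ev = read_events_tsv(tmp_path / "ev.tsv")
        assert set(ev.kind) == {"strong", "weak", "pulse"}
        assert (ev.onset_s.diff().dropna() >= 0).all()
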
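"""Task-branch preprocessing: inversion, rejection, filtering, blocks, averages."""

import dataclasses

import numpy as np
import pytest

from nadnirs.params import AnalysisParams
from nadnirs import preproc_task as pt
from nadnirs.synthdata import SimParams, simulate_cohort, hb_to_od, RawRecording


def _hb_from_arrays(hbo, hbr, schedule=None, fs=10.0):
    return pt.HbSeries(np.atleast_2d(hbo), np.atleast_2d(hbr), fs, schedule)


class TestOdToHb:
    def test_zero_od_zero_hb(self, small_cohort):
        rec = small_cohort[0]
        rec0 = RawRecording(0, rec.layout, rec.sample_rate, rec.wavelengths,
                            np.zeros_like(rec.od), rec.schedule)
        hb = pt.od_to_hb(rec0)
        assert not hb.hbo.any() and not hb.hbr.any()
        assert hb.n_samples == rec.n_samples

    def test_simulator_round_trip_noise_free(self, quiet_sim_params):
        """Inversion of the simulator's forward model is exact without noise."""
        sp = dataclasses.replace(quiet_sim_params, noise_sd=0.0, cardiac_amp=0.0,
                                 resp_amp=0.0, mayer_amp=0.0, drift_amp=0.0,
                                 hbr_noise_sd=0.0)
        rec = simulate_cohort(1, "neonate", sp, seed=2)[0]
        hb = pt.od_to_hb(rec)
        od1, od2 = hb_to_od(hb.hbo, hb.hbr, rec.wavelengths)
        assert np.abs(od1 - rec.od[:, 0, :]).max() < 1e-9
        assert np.abs(od2 - rec.od[:, 1, :]).max() < 1e-9

    def test_singular_table_rejected(self, small_cohort):
        rec = small_cohort[0]
        bad = {695.0: (1.0, 1.0), 830.0: (1.0, 1.0)}
        with pytest.raises(pt.PreprocError):
            pt.od_to_hb(rec, table=bad)


class TestTrialRejection:
    def test_constant_series_all_valid(self, neonate_schedule):
        n = int(neonate_schedule.duration * 10)
        hb = _hb_from_arrays(np.full((3, n), 0.5), np.full((3, n), -0.2),
                             neonate_schedule)
        valid = pt.flag_bad_trials(hb)
        assert valid.all()
        assert valid.shape == (20, 3)

    def test_single_spike_invalidates_only_its_trial(self, neonate_schedule):
        n = int(neonate_schedule.duration * 10)
        hbo = np.zeros((2, n))
        trials = neonate_schedule.target_trials()
        k = 4
        i = int(trials[k].onset * 10) + 30
        hbo[0, i] = 0.2  # > 0.15 mM·mm between consecutive samples
        hb = _hb_from_arrays(hbo, np.zeros_like(hbo), neonate_schedule)
        valid = pt.flag_bad_trials(hb)
        assert not valid[k, 0]
        assert valid[k, 1]
        mask = np.ones_like(valid, bool)
        mask[k, 0] = False
        assert valid[mask].all()

    def test_threshold_is_strict(self, neonate_schedule):
        """A ramp climbing 0.14 mM·mm per sample stays below the > 0.15 criterion."""
        n = int(neonate_schedule.duration * 10)
        ramp = np.cumsum(np.full(n, 0.14))
        ramp = ramp - ramp.mean()
        # keep absolute values under saturation by wrapping
        ramp = 4.0 * np.sin(ramp / ramp.max() * np.pi / 2)
        hbo = np.diff(np.r_[0, np.minimum.accumulate(np.zeros(n))])  # unused
        series = np.cumsum(np.full(n, 0.07))[None, :] % 1.0  # 0.07/sample steps
        hb = _hb_from_arrays(series, series, neonate_schedule)  # sum steps 0.14
        valid = pt.flag_bad_trials(hb)
        # wrap points introduce big jumps; exclude trials containing them
        sums = 2 * series[0]
        jump_samples = np.where(np.abs(np.diff(sums)) > 0.15)[0]
        for k, ev in enumerate(neonate_schedule.target_trials()):
            i0 = int((ev.onset - 5) * 10)
            i1 = i0 + 280
            if not ((jump_samples >= i0) & (jump_samples < i1)).any():
                assert valid[k, 0]

    def test_saturation_invalidates_trial(self, neonate_schedule):
        n = int(neonate_schedule.duration * 10)
        hbo = np.zeros((1, n))
        trials = neonate_schedule.target_trials()
        i = int(trials[2].onset * 10) + 10
        hbo[0, i:i + 5] = 5.5  # above the 5 mM·mm ceiling
        # keep the entry step below the motion criterion by ramping slowly
        hbo[0, i - 100:i] = np.linspace(0, 5.5, 100)
        hbo[0, i + 5:i + 105] = np.linspace(5.5, 0, 100)
        hb = _hb_from_arrays(hbo, np.zeros_like(hbo), neonate_schedule)
        valid = pt.flag_bad_trials(hb)
        assert not valid[2, 0]


class TestBandpass:
    @pytest.mark.parametrize("freq,kind", [(0.1, "pass"), (2.0, "stop")])
    def test_frequency_response(self, freq, kind, neonate_schedule):
        fs, n = 10.0, 6000
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * freq * t)[None, :]
        hb = pt.HbSeries(x.copy(), x.copy(), fs)
        out = pt.bandpass_task(hb).hbo[0, 1000:-1000]
        amp = np.max(np.abs(out))
        if kind == "pass":
            assert amp == pytest.approx(1.0, rel=0.05)
        else:
            assert amp < 0.1

    def test_dc_removed(self):
        hb = pt.HbSeries(np.full((1, 4000), 3.0), np.zeros((1, 4000)), 10.0)
        out = pt.bandpass_task(hb).hbo[0, 500:-500]
        assert np.abs(out.mean()) < 1e-3

    def test_band_outside_nyquist_rejected(self):
        hb = pt.HbSeries(np.zeros((1, 100)), np.zeros((1, 100)), 10.0)
        with pytest.raises(pt.PreprocError):
            pt.bandpass_task(hb, AnalysisParams(task_band=(0.02, 6.0)))


class TestSegmentation:
    def test_epoch_count_shape_alignment(self, neonate_schedule):
        n = int(neonate_schedule.duration * 10)
        t = np.arange(n) / 10.0
        hb = _hb_from_arrays(t, t, neonate_schedule)  # value == time in s
        blocks = pt.segment_blocks(hb)
        assert blocks.n_trials == 20
        assert blocks.epochs_hbo.shape == (20, 1, 280)
        for k, ev in enumerate(neonate_schedule.target_trials()):
            # epoch sample 50 corresponds to stimulus onset (floor indexing)
            assert blocks.epochs_hbo[k, 0, 50] == pytest.approx(
                np.floor((ev.onset - 5.0) * 10) / 10 + 5.0, abs=0.11)

    def test_flags_copied_and_mismatch_rejected(self, neonate_schedule):
        n = int(neonate_schedule.duration * 10)
        hb = _hb_from_arrays(np.zeros(n), np.zeros(n), neonate_schedule)
        flags = np.ones((20, 1), bool)
        flags[3, 0] = False
        blocks = pt.segment_blocks(hb, flags=flags)
        assert not blocks.valid[3, 0] and blocks.reasons[3] == "artifact"
        with pytest.raises(pt.PreprocError):
            pt.segment_blocks(hb, flags=np.ones((5, 1), bool))


class TestBaselineCorrection:
    def test_straight_line_zeroed(self):
        line = 0.3 + 0.02 * np.arange(280)
        out = pt.linear_baseline_correct(line)
        assert np.abs(out).max() < 1e-10

    def test_bump_preserved_anchors_zeroed(self):
        idx = np.arange(280)
        line = -0.1 + 0.005 * idx
        bump = np.exp(-0.5 * ((idx - 140) / 15.0) ** 2)
        out = pt.linear_baseline_correct(line + bump)
        assert np.abs(out[:50].mean()) < 1e-10   # first 5-s window
        assert np.abs(out[-50:].mean()) < 1e-10  # last 5-s window
        assert out[140] == pytest.approx(1.0, abs=0.01)

    def test_scaling_linearity(self, rng):
        x = rng.standard_normal(280)
        assert np.allclose(pt.linear_baseline_correct(3.5 * x),
                           3.5 * pt.linear_baseline_correct(x))


class TestAveraging:
    def _blockset(self, values, valid, conditions):
        n_trials = len(conditions)
        epochs = np.tile(np.asarray(values, float)[:, None, None], (1, 1, 280))
        return pt.BlockSet(epochs, epochs.copy(), list(conditions),
                           np.asarray(valid, bool).reshape(n_trials, 1),
                           [""] * n_trials, 10.0)

    def test_constant_blocks_average_to_constant(self):
        conds = ["correct_trial", "incorrect_trial"] * 3
        bs = self._blockset([2.0] * 6, [True] * 6, conds)
        avg = pt.average_subject(bs)
        assert avg.included
        # constant epochs are flattened by baseline correction
        assert np.allclose(avg.mean_hbo["correct_trial"], 0.0, atol=1e-12)

    def test_single_valid_trial_excludes_subject(self):
        conds = ["correct_trial"] * 3 + ["incorrect_trial"] * 3
        valid = [True, False, False, True, True, True]
        avg = pt.average_subject(self._blockset([1.0] * 6, valid, conds))
        assert not avg.included
        assert avg.n_valid["correct_trial"][0] == 1

    def test_mean_of_identical_epochs(self, rng):
        epoch = rng.standard_normal(280)
        epochs = np.tile(epoch[None, None, :], (4, 1, 1))
        bs = pt.BlockSet(epochs, epochs.copy(),
                         ["correct_trial", "correct_trial",
                          "incorrect_trial", "incorrect_trial"],
                         np.ones((4, 1), bool), [""] * 4, 10.0)
        avg = pt.average_subject(bs)
        expected = pt.linear_baseline_correct(epoch)
        assert np.allclose(avg.mean_hbo["correct_trial"][0], expected)


class TestConservation:
    def test_epochs_partition_into_valid_and_invalid(self, small_cohort):
        rec = small_cohort[0]
        hb = pt.od_to_hb(rec)
        flags = pt.flag_bad_trials(hb)
        blocks = pt.segment_blocks(pt.bandpass_task(hb), flags=flags)
        n_targets = len(rec.schedule.target_trials())
        assert blocks.n_trials == n_targets
        assert blocks.valid.sum() + (~blocks.valid).sum() == n_targets * 46

    def test_rejection_matches_planted_artifacts(self, quiet_sim_params):
        """With artifacts as the only corruption, invalid trials == trials
        overlapping planted spikes (sensitivity and specificity 1)."""
        import dataclasses
        from nadnirs.synthdata import simulate_cohort
        sp = dataclasses.replace(quiet_sim_params, noise_sd=0.0, cardiac_amp=0.0,
                                 resp_amp=0.0, mayer_amp=0.0, drift_amp=0.0,
                                 hbr_noise_sd=0.0, p_trial_artifact=0.5)
        rec = simulate_cohort(1, "neonate", sp, seed=9)[0]
        hb = pt.od_to_hb(rec)
        valid = pt.flag_bad_trials(hb)
        spike_times = [t for t, k in rec.ground_truth.artifact_times if k == "spike"]
        for k, ev in enumerate(rec.schedule.target_trials()):
            lo, hi = ev.onset - 5.0, ev.onset + 23.0
            overlaps = any(lo <= t_art + 0.4 and t_art <= hi for t_art in spike_times)
            assert valid[k].all() != overlaps
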
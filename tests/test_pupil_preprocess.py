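"""Preprocessing chain: blink screening, outlier exclusion, binning,
baseline correction, matrix assembly and trial conservation."""

import numpy as np
import pandas as pd
import pytest

from pupilwalk.pupil_preprocess import (
    PreprocessConfig,
    build_trial_matrix,
    downsample_and_baseline,
    exclude_outlier_trials,
    preprocess_experiment,
    read_trial_matrix,
    screen_blinks,
    write_trial_matrix,
)
from pupilwalk.synthetic_pupil import TrialRecording


def make_trial(samples, validity=None, rate=500.0, onset_index=100, subject="S01",
               condition="happy", trial_id=0):
    samples = np.asarray(samples, dtype=float)
    if validity is None:
        validity = ~np.isnan(samples)
    return TrialRecording(
        subject_id=subject,
        condition=condition,
        samples=samples,
        validity=np.asarray(validity, dtype=bool),
        sample_rate=rate,
        onset_index=onset_index,
        trial_id=trial_id,
    )


NO_PAD = PreprocessConfig(blink_pad_ms=0.0)


class TestScreenBlinks:
    def test_clean_trial_is_identity(self):
        tr = make_trial(np.linspace(1, 2, 500))
        out, reason = screen_blinks(tr, PreprocessConfig())
        assert reason is None
        assert np.array_equal(out.samples, tr.samples)

    def test_linear_midpoint_interpolation(self):
        cfg = PreprocessConfig(blink_pad_ms=0.0, max_invalid_fraction=0.5)
        tr = make_trial([2.0, np.nan, 4.0], validity=[True, False, True])
        out, reason = screen_blinks(tr, cfg)
        assert reason is None
        assert np.allclose(out.samples, [2.0, 3.0, 4.0])
        assert out.validity.all()

    def test_gap_longer_than_cap_discards(self):
        # 600 ms gap at 500 Hz = 300 samples, cap 500 ms = 250 samples
        valid = np.ones(1000, dtype=bool)
        valid[300:600] = False
        tr = make_trial(np.ones(1000), validity=valid)
        out, reason = screen_blinks(tr, NO_PAD)
        assert out is None and reason == "gap_too_long"

    def test_padding_extends_gap_before_interpolation(self):
        # 50 ms pad at 500 Hz = 25 samples each side
        valid = np.ones(500, dtype=bool)
        valid[200:210] = False
        samples = np.arange(500, dtype=float)
        tr = make_trial(samples, validity=valid)
        out, _ = screen_blinks(tr, PreprocessConfig(blink_pad_ms=50.0))
        # padded neighbourhood is re-interpolated from samples 174 and 235;
        # the trace is linear so values are unchanged
        assert np.allclose(out.samples, samples)
        out2, _ = screen_blinks(
            make_trial(np.r_[np.zeros(200), np.full(10, np.nan), np.full(290, 10.0)],
                       validity=valid),
            PreprocessConfig(blink_pad_ms=50.0),
        )
        # with padding, samples 175..234 are interpolated between 0 and 10
        assert out2.samples[150] == 0.0 and out2.samples[260] == 10.0
        assert 0.0 < out2.samples[200] < 10.0

    def test_total_invalid_fraction_discards(self):
        valid = np.ones(1000, dtype=bool)
        for start in range(100, 900, 200):
            valid[start : start + 100] = False
        tr = make_trial(np.ones(1000), validity=valid)
        out, reason = screen_blinks(tr, PreprocessConfig(blink_pad_ms=0.0,
                                                         max_invalid_fraction=0.25))
        assert out is None and reason == "too_many_invalid"

    def test_boundary_gap_discards(self):
        valid = np.ones(400, dtype=bool)
        valid[:20] = False
        out, reason = screen_blinks(make_trial(np.ones(400), validity=valid), NO_PAD)
        assert out is None and reason == "boundary_gap"

    def test_all_invalid_discards_without_raising(self):
        tr = make_trial(np.full(100, np.nan), validity=np.zeros(100, dtype=bool))
        out, reason = screen_blinks(tr, PreprocessConfig())
        assert out is None and reason == "all_invalid"


class TestExcludeOutliers:
    def test_deviant_trial_mean_excluded(self):
        # ten trials at 1.0 plus one at 9.0: z = 7.27/2.30 = 3.16 > 3
        trials = [make_trial(np.full(10, 1.0), trial_id=i) for i in range(10)]
        trials.append(make_trial(np.full(10, 9.0), trial_id=10))
        retained, excluded = exclude_outlier_trials(trials)
        assert [tid for tid, _ in excluded] == [10]
        assert len(retained) == 10

    def test_mild_deviant_retained(self):
        # with spread among the other trials the deviant's z = 2.64 < 3
        base = [0.9, 1.1] * 5
        trials = [make_trial(np.full(10, v), trial_id=i) for i, v in enumerate(base)]
        trials.append(make_trial(np.full(10, 1.5), trial_id=10))
        retained, excluded = exclude_outlier_trials(trials)
        assert excluded == [] and len(retained) == 11

    def test_equal_means_none_excluded(self):
        trials = [make_trial(np.full(10, 2.0), trial_id=i) for i in range(5)]
        retained, excluded = exclude_outlier_trials(trials)
        assert len(retained) == 5 and excluded == []

    def test_fewer_than_three_trials_errors(self):
        with pytest.raises(ValueError, match="insufficient"):
            exclude_outlier_trials([make_trial(np.ones(5)), make_trial(np.ones(5))])


class TestDownsampleAndBaseline:
    def test_bin_layout_4000ms_at_500hz(self):
        tr = make_trial(np.ones(2100), onset_index=100)
        bins, reason = downsample_and_baseline(tr, PreprocessConfig(), stim_ms=4000.0)
        assert reason is None and bins.size == 80

    def test_constant_trace_gives_zero_bins(self):
        tr = make_trial(np.full(2100, 5.0), onset_index=100)
        bins, _ = downsample_and_baseline(tr, PreprocessConfig(), stim_ms=4000.0)
        assert np.allclose(bins, 0.0, atol=1e-12)

    def test_alternating_baseline_hand_value(self):
        # baseline alternates 4, 6 (mean 5); stimulus constant 7 -> bins = 2
        samples = np.r_[np.tile([4.0, 6.0], 50), np.full(2000, 7.0)]
        tr = make_trial(samples, onset_index=100)
        bins, _ = downsample_and_baseline(tr, PreprocessConfig(), stim_ms=4000.0)
        assert np.allclose(bins, 2.0)

    def test_missing_baseline_discards(self):
        samples = np.r_[np.full(100, np.nan), np.ones(2000)]
        valid = np.r_[np.zeros(100, dtype=bool), np.ones(2000, dtype=bool)]
        tr = make_trial(samples, validity=valid, onset_index=100)
        bins, reason = downsample_and_baseline(tr, PreprocessConfig(), stim_ms=4000.0)
        assert bins is None and reason == "no_baseline"

    def test_bins_average_only_valid_samples(self):
        samples = np.r_[np.zeros(100), np.full(2000, 3.0)]
        valid = np.ones(2100, dtype=bool)
        samples[150:175] = np.nan  # second half of bin 1 invalid
        valid[150:175] = False
        tr = make_trial(samples, validity=valid, onset_index=100)
        bins, _ = downsample_and_baseline(tr, PreprocessConfig(), stim_ms=4000.0)
        assert bins[1] == pytest.approx(3.0)

    def test_downsample_baseline_commute_on_clean_traces(self):
        rng = np.random.default_rng(6)
        samples = rng.normal(10.0, 1.0, 2100)
        tr = make_trial(samples, onset_index=100)
        bins, _ = downsample_and_baseline(tr, PreprocessConfig(), stim_ms=4000.0)
        baseline = samples[:100].mean()
        manual = (samples[100:] - baseline).reshape(80, 25).mean(axis=1)
        assert np.allclose(bins, manual, atol=1e-12)


class TestBuildMatrix:
    def bins(self, *vals):
        return np.asarray(vals, dtype=float)

    def test_single_trial_cell_equals_trace(self):
        m = build_trial_matrix(
            [("S01", "happy", self.bins(1, 2, 3))], ["happy"], [25.0, 75.0, 125.0]
        )
        assert np.allclose(m.values[0, 0], [1, 2, 3])
        assert m.trial_counts[0, 0] == 1

    def test_cell_mean_and_scalar(self):
        m = build_trial_matrix(
            [("S01", "happy", self.bins(0, 2)), ("S01", "happy", self.bins(2, 0))],
            ["happy"],
            [25.0, 75.0],
        )
        assert np.allclose(m.values[0, 0], [1.0, 1.0])
        m2 = build_trial_matrix(
            [("S01", "happy", self.bins(1, 1, 4))], ["happy"], [25.0, 75.0, 125.0]
        )
        assert m2.scalar_means[0, 0] == pytest.approx(2.0)

    def test_empty_cell_raises_with_cell_name(self):
        with pytest.raises(ValueError, match="S01/sad"):
            build_trial_matrix(
                [("S01", "happy", self.bins(1.0))], ["happy", "sad"], [25.0]
            )


class TestExperimentChain:
    def test_trial_conservation(self, default_experiment, default_matrix):
        """Every simulated trial lands in the matrix counts or the log."""
        _, trials, _ = default_experiment
        assert default_matrix.trial_counts.sum() + len(default_matrix.exclusions) == len(trials)

    def test_rerun_is_bit_identical(self, default_experiment, default_matrix):
        from pupilwalk.synthetic_pupil import CONDITIONS

        cfg, trials, _ = default_experiment
        again = preprocess_experiment(trials, stim_ms=cfg.stim_ms, conditions=CONDITIONS)
        assert np.array_equal(again.values, default_matrix.values)
        assert again.exclusions.equals(default_matrix.exclusions)

    def test_matrix_tsv_round_trip(self, tmp_path, default_matrix):
        path = tmp_path / "matrix.tsv"
        write_trial_matrix(default_matrix, path)
        back = read_trial_matrix(path)
        assert back.subjects == default_matrix.subjects
        assert back.conditions == default_matrix.conditions
        assert np.allclose(back.values, default_matrix.values)
        assert np.array_equal(back.trial_counts, default_matrix.trial_counts)
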
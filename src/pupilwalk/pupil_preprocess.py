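"""Pupil-trace preprocessing: blink screening, outlier exclusion,
down-sampling and baseline correction.

The chain applied to each raw trial is

1. blink screening: invalid runs are padded by ``blink_pad_ms`` on each
   side, then linearly interpolated from flanking valid samples if the
   run is at most ``max_interp_gap_ms`` long; the trial is discarded
   (with a logged reason) if a run exceeds that cap, the total invalid
   fraction exceeds ``max_invalid_fraction``, or a run touches a trace
   boundary and so has no flanking sample;
2. per-subject exclusion of trials whose mean diameter lies more than
   3 population SDs from that subject's mean of trial means (pooled
   across conditions, single pass);
3. down-sampling to 20 Hz (non-overlapping 50 ms bins averaged over
   valid samples) and baseline correction by the mean diameter over the
   [-200, 0) ms pre-stimulus window.

The per-cell output is the bin-wise mean over retained trials plus a
scalar mean over the stimulus-window bins, organized subject x
condition x time-bin in a :class:`TrialMatrix`.  Every input trial ends
up either in the matrix counts or in the exclusion log.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic_pupil import TrialRecording

__all__ = [
    "PreprocessConfig",
    "TrialMatrix",
    "screen_blinks",
    "exclude_outlier_trials",
    "downsample_and_baseline",
    "build_trial_matrix",
    "preprocess_experiment",
    "read_dataset",
    "write_trial_matrix",
    "read_trial_matrix",
]


@dataclass(frozen=True)
class PreprocessConfig:
    max_interp_gap_ms: float = 500.0
    max_invalid_fraction: float = 0.25
    blink_pad_ms: float = 50.0
    outlier_sd: float = 3.0
    downsample_hz: float = 20.0
    baseline_window_ms: float = 200.0

    def __post_init__(self) -> None:
        for name in ("max_interp_gap_ms", "blink_pad_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0 < self.max_invalid_fraction <= 1:
            raise ValueError("max_invalid_fraction must lie in (0, 1]")
        if self.outlier_sd <= 0 or self.downsample_hz <= 0 or self.baseline_window_ms <= 0:
            raise ValueError("outlier_sd, downsample_hz, baseline_window_ms must be positive")


@dataclass
class TrialMatrix:
    """Preprocessed traces organized subject x condition x time-bin."""

    values: np.ndarray                 # (n_subjects, n_conditions, n_bins)
    scalar_means: np.ndarray           # (n_subjects, n_conditions)
    trial_counts: np.ndarray           # (n_subjects, n_conditions), int
    subjects: list[str]
    conditions: tuple[str, ...]
    bin_centers_ms: np.ndarray         # ms from stimulus onset
    exclusions: pd.DataFrame           # columns: subject, trial, reason

    def condition_matrix(self, condition: str) -> np.ndarray:
        """(n_subjects, n_bins) matrix for one condition."""
        return self.values[:, self.conditions.index(condition), :]


# ---------------------------------------------------------------------------
# Blink screening
# ---------------------------------------------------------------------------

def _invalid_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs of True in a boolean mask."""
    idx = np.flatnonzero(np.diff(np.r_[0, mask.view(np.int8), 0]))
    return list(zip(idx[0::2], idx[1::2]))


def screen_blinks(
    trial: TrialRecording, cfg: PreprocessConfig
) -> tuple[TrialRecording | None, str | None]:
    """Interpolate blink gaps or discard the trial.

    Returns ``(screened_trial, None)`` on success or ``(None, reason)``
    on discard; never raises for bad data.
    """
    samples = np.asarray(trial.samples, dtype=float)
    invalid = ~np.asarray(trial.validity, dtype=bool) | np.isnan(samples)
    if not invalid.any():
        return trial, None
    if invalid.all():
        return None, "all_invalid"

    pad = int(round(cfg.blink_pad_ms * trial.sample_rate / 1000.0))
    if pad:
        padded = invalid.copy()
        for start, stop in _invalid_runs(invalid):
            padded[max(0, start - pad) : stop + pad] = True
        invalid = padded
        if invalid.all():
            return None, "all_invalid"

    max_gap = int(round(cfg.max_interp_gap_ms * trial.sample_rate / 1000.0))
    runs = _invalid_runs(invalid)
    if any(stop - start > max_gap for start, stop in runs):
        return None, "gap_too_long"
    if invalid.mean() > cfg.max_invalid_fraction:
        return None, "too_many_invalid"
    if runs[0][0] == 0 or runs[-1][1] == invalid.size:
        return None, "boundary_gap"

    valid_idx = np.flatnonzero(~invalid)
    out = samples.copy()
    fill = np.flatnonzero(invalid)
    out[fill] = np.interp(fill, valid_idx, samples[valid_idx])
    return (
        TrialRecording(
            subject_id=trial.subject_id,
            condition=trial.condition,
            samples=out,
            validity=np.ones_like(invalid, dtype=bool),
            sample_rate=trial.sample_rate,
            onset_index=trial.onset_index,
            trial_id=trial.trial_id,
        ),
        None,
    )


# ---------------------------------------------------------------------------
# Outlier exclusion
# ---------------------------------------------------------------------------

def exclude_outlier_trials(
    trials: Sequence[TrialRecording], outlier_sd: float = 3.0
) -> tuple[list[TrialRecording], list[tuple[int, str]]]:
    """Exclude one subject's trials whose mean diameter deviates more
    than ``outlier_sd`` population SDs from the subject's mean of trial
    means (all conditions pooled, single pass)."""
    if len(trials) < 3:
        raise ValueError("insufficient trials for outlier screening (need >= 3)")
    means = np.array([np.nanmean(t.samples) for t in trials])
    center = means.mean()
    sd = means.std()  # population SD over this subject's trial means
    if sd == 0.0:
        return list(trials), []
    z = np.abs(means - center) / sd
    keep = z <= outlier_sd
    retained = [t for t, k in zip(trials, keep) if k]
    excluded = [(t.trial_id, "outlier") for t, k in zip(trials, keep) if not k]
    return retained, excluded


# ---------------------------------------------------------------------------
# Down-sampling and baseline correction
# ---------------------------------------------------------------------------

def downsample_and_baseline(
    trial: TrialRecording, cfg: PreprocessConfig, stim_ms: float | None = None
) -> tuple[np.ndarray | None, str | None]:
    """Bin a screened trial to 50 ms means and subtract the pre-stimulus
    baseline.  Returns ``(bins, None)`` or ``(None, "no_baseline")``.

    Bins cover the stimulus window [0, stim_ms); samples are assigned to
    bins by time, and each bin averages its valid samples.
    """
    samples = np.asarray(trial.samples, dtype=float)
    valid = np.asarray(trial.validity, dtype=bool) & ~np.isnan(samples)
    t_ms = (np.arange(samples.size) - trial.onset_index) / trial.sample_rate * 1000.0

    base_mask = (t_ms >= -cfg.baseline_window_ms) & (t_ms < 0.0) & valid
    if not base_mask.any():
        return None, "no_baseline"
    baseline = samples[base_mask].mean()

    bin_ms = 1000.0 / cfg.downsample_hz
    if stim_ms is None:
        stim_ms = (samples.size - trial.onset_index) / trial.sample_rate * 1000.0
    n_bins = int(round(stim_ms / bin_ms))
    stim = (t_ms >= 0.0) & (t_ms < n_bins * bin_ms)
    idx = np.floor(t_ms[stim] / bin_ms).astype(int)
    vals = np.where(valid[stim], samples[stim], 0.0)
    cnt = np.bincount(idx, weights=valid[stim].astype(float), minlength=n_bins)
    tot = np.bincount(idx, weights=vals, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        bins = tot / cnt
    return bins - baseline, None


# ---------------------------------------------------------------------------
# Matrix assembly
# ---------------------------------------------------------------------------

def build_trial_matrix(
    binned: Sequence[tuple[str, str, np.ndarray]],
    conditions: Sequence[str],
    bin_centers_ms: np.ndarray,
    exclusions: pd.DataFrame | None = None,
) -> TrialMatrix:
    """Aggregate per-trial binned traces (subject, condition, bins) into
    cell-wise means.  Raises if any subject x condition cell is empty."""
    subjects = sorted({s for s, _, _ in binned})
    conditions = tuple(conditions)
    n_bins = len(bin_centers_ms)
    values = np.zeros((len(subjects), len(conditions), n_bins))
    counts = np.zeros((len(subjects), len(conditions)), dtype=int)
    s_index = {s: i for i, s in enumerate(subjects)}
    c_index = {c: i for i, c in enumerate(conditions)}
    for sid, cond, bins in binned:
        i, j = s_index[sid], c_index[cond]
        values[i, j] += bins
        counts[i, j] += 1
    empty = np.argwhere(counts == 0)
    if empty.size:
        cells = ", ".join(f"{subjects[i]}/{conditions[j]}" for i, j in empty)
        raise ValueError(f"empty subject x condition cells: {cells}")
    values /= counts[:, :, None]
    if exclusions is None:
        exclusions = pd.DataFrame(columns=["subject", "trial", "reason"])
    return TrialMatrix(
        values=values,
        scalar_means=values.mean(axis=2),
        trial_counts=counts,
        subjects=subjects,
        conditions=conditions,
        bin_centers_ms=np.asarray(bin_centers_ms, dtype=float),
        exclusions=exclusions,
    )


def preprocess_experiment(
    trials: Sequence[TrialRecording],
    cfg: PreprocessConfig | None = None,
    stim_ms: float | None = None,
    conditions: Sequence[str] | None = None,
) -> TrialMatrix:
    """Run the full preprocessing chain over an experiment's trials.

    Clean trials (no invalid samples) with a common length take a
    vectorized path; trials with artifacts go through
    :func:`screen_blinks` individually.  Deterministic: reruns on the
    same input are bit-identical.
    """
    cfg = PreprocessConfig() if cfg is None else cfg
    if conditions is None:
        seen: list[str] = []
        for t in trials:
            if t.condition not in seen:
                seen.append(t.condition)
        conditions = seen

    by_subject: dict[str, list[TrialRecording]] = {}
    for t in trials:
        by_subject.setdefault(t.subject_id, []).append(t)

    excl_rows: list[tuple[str, int, str]] = []
    binned: list[tuple[str, str, np.ndarray]] = []
    bin_ms = 1000.0 / cfg.downsample_hz
    bin_centers = None

    for sid, trs in by_subject.items():
        screened: list[TrialRecording] = []
        for t in trs:
            ok, reason = screen_blinks(t, cfg)
            if ok is None:
                excl_rows.append((sid, t.trial_id, reason))
            else:
                screened.append(ok)
        if len(screened) < 3:
            raise ValueError(f"insufficient trials after screening for subject {sid}")
        retained, outliers = exclude_outlier_trials(screened, cfg.outlier_sd)
        excl_rows.extend((sid, tid, reason) for tid, reason in outliers)
        for t in retained:
            bins, reason = downsample_and_baseline(t, cfg, stim_ms=stim_ms)
            if bins is None:
                excl_rows.append((sid, t.trial_id, reason))
                continue
            binned.append((sid, t.condition, bins))
            if bin_centers is None:
                bin_centers = (np.arange(bins.size) + 0.5) * bin_ms

    exclusions = pd.DataFrame(excl_rows, columns=["subject", "trial", "reason"])
    return build_trial_matrix(binned, conditions, bin_centers, exclusions)


# ---------------------------------------------------------------------------
# On-disk formats
# ---------------------------------------------------------------------------

def read_dataset(samples_dir, events_path, sample_rate: float = 500.0,
                 pre_ms: float = 200.0, stim_ms: float = 4000.0) -> list[TrialRecording]:
    """Epoch per-subject sample TSVs into trials using an events CSV.

    Samples with valid = 0 or pupil = 0 (hardware zeros) are treated as
    invalid; each trial covers [onset - pre_ms, onset + stim_ms).
    """
    events = pd.read_csv(events_path)
    trials: list[TrialRecording] = []
    n_samp = int(round((pre_ms + stim_ms) * sample_rate / 1000.0))
    onset_index = int(round(pre_ms * sample_rate / 1000.0))
    for sid, ev in events.groupby("subject", sort=False):
        df = pd.read_csv(os.path.join(samples_dir, f"{sid}_samples.tsv"), sep="\t")
        t = df["time_ms"].to_numpy()
        pupil = df["pupil"].to_numpy(dtype=float)
        valid = (df["valid"].to_numpy() != 0) & (pupil != 0.0) & ~np.isnan(pupil)
        pupil = np.where(valid, pupil, np.nan)
        for _, row in ev.iterrows():
            start_t = row["onset_ms"] - pre_ms
            i0 = int(np.searchsorted(t, start_t - 1e-6))
            sl = slice(i0, i0 + n_samp)
            trials.append(
                TrialRecording(
                    subject_id=str(sid),
                    condition=row["condition"],
                    samples=pupil[sl].copy(),
                    validity=valid[sl].copy(),
                    sample_rate=sample_rate,
                    onset_index=onset_index,
                    trial_id=int(row["trial"]),
                )
            )
    return trials


def write_trial_matrix(matrix: TrialMatrix, path) -> None:
    """Long-format TSV: subject, condition, bin_center_ms, value, n_trials."""
    rows = []
    for i, sid in enumerate(matrix.subjects):
        for j, cond in enumerate(matrix.conditions):
            for b, center in enumerate(matrix.bin_centers_ms):
                rows.append(
                    (sid, cond, center, matrix.values[i, j, b], matrix.trial_counts[i, j])
                )
    pd.DataFrame(
        rows, columns=["subject", "condition", "bin_center_ms", "value", "n_trials"]
    ).to_csv(path, sep="\t", index=False)


def read_trial_matrix(path) -> TrialMatrix:
    df = pd.read_csv(path, sep="\t")
    subjects = sorted(df["subject"].astype(str).unique())
    conditions = tuple(dict.fromkeys(df["condition"]))
    centers = np.sort(df["bin_center_ms"].unique())
    values = np.zeros((len(subjects), len(conditions), len(centers)))
    counts = np.zeros((len(subjects), len(conditions)), dtype=int)
    s_index = {s: i for i, s in enumerate(subjects)}
    c_index = {c: i for i, c in enumerate(conditions)}
    b_index = {c: i for i, c in enumerate(centers)}
    for row in df.itertuples(index=False):
        i, j = s_index[str(row.subject)], c_index[row.condition]
        values[i, j, b_index[row.bin_center_ms]] = row.value
        counts[i, j] = row.n_trials
    return TrialMatrix(
        values=values,
        scalar_means=values.mean(axis=2),
        trial_counts=counts,
        subjects=subjects,
        conditions=conditions,
        bin_centers_ms=centers,
        exclusions=pd.DataFrame(columns=["subject", "trial", "reason"]),
    )
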
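"""Synthetic multi-subject pupillometry experiments with known ground truth.

The simulator emulates a passive-viewing experiment in which subjects
watch happy, sad or neutral point-light walkers while pupil diameter is
sampled at 500 Hz over a 200 ms pre-stimulus baseline plus a 4000 ms
stimulus window.  Each trial trace is

    subject baseline
    + shared stimulus-evoked transient (gamma-shaped dilation)
    + subject sensitivity x condition effect (logistic ramp from the
      condition's onset latency, sustained to stimulus offset)
    + AR(1) noise,

with blink artifacts marked as invalid samples (diameter undefined).
Subjects differ in a single sensitivity multiplier that scales all
condition effects; the multiplier is drawn jointly with a latent trait
score at a configurable correlation, and the trait is mapped
rank-preservingly to an integer 0-50 autism-spectrum quotient (AQ).
The generative defaults (:func:`default_paper_config`) encode the
reference study conditions: 24 subjects, 40 trials per condition, a
positive happy effect from 1750 ms, a negative sad effect from 1850 ms,
a null neutral condition, and an AQ--sensitivity correlation of -0.47.

Everything is reproducible bit-for-bit from ``SimConfig.seed``.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as _signal

CONDITIONS: tuple[str, ...] = ("happy", "sad", "neutral")

__all__ = [
    "CONDITIONS",
    "EffectSpec",
    "NoiseSpec",
    "BlinkSpec",
    "SimConfig",
    "TrialRecording",
    "GroundTruth",
    "default_paper_config",
    "simulate_experiment",
    "simulate_null_bins",
    "write_dataset",
]


@dataclass(frozen=True)
class EffectSpec:
    """One condition's true pupil effect: a logistic ramp of the given
    amplitude (a.u., sign carries direction) starting at ``onset_ms`` and
    reaching plateau over ``ramp_ms``, sustained to stimulus offset.
    The effect is exactly zero before ``onset_ms``."""

    onset_ms: float
    amplitude: float
    ramp_ms: float = 300.0


@dataclass(frozen=True)
class NoiseSpec:
    """AR(1) sample noise: n[t] = ar1_coefficient * n[t-1] + e[t] with
    innovations e ~ N(0, white_sd^2).  ar1_coefficient = 0 gives white
    noise."""

    white_sd: float = 0.12
    ar1_coefficient: float = 0.99


@dataclass(frozen=True)
class BlinkSpec:
    """Blink artifacts: Poisson occurrences at ``rate_per_s`` with
    durations uniform in ``duration_ms``; affected samples are invalid."""

    rate_per_s: float = 0.10
    duration_ms: tuple[float, float] = (100.0, 300.0)


@dataclass(frozen=True)
class SimConfig:
    """Full description of one simulated experiment."""

    n_subjects: int = 24
    trials_per_condition: int = 40
    sample_rate: float = 500.0
    pre_ms: float = 200.0
    stim_ms: float = 4000.0
    effects: Mapping[str, EffectSpec] = field(
        default_factory=lambda: {
            "happy": EffectSpec(onset_ms=1750.0, amplitude=0.30),
            "sad": EffectSpec(onset_ms=1850.0, amplitude=-0.24),
            "neutral": EffectSpec(onset_ms=0.0, amplitude=0.0),
        }
    )
    subject_sensitivity_sd: float = 1.1
    aq_effect_correlation: float = -0.47
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    blink: BlinkSpec = field(default_factory=BlinkSpec)
    baseline_mean: float = 1000.0
    baseline_sd: float = 50.0
    evoked_amplitude: float = 0.5
    evoked_peak_ms: float = 900.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.trials_per_condition < 1:
            raise ValueError("trials_per_condition must be >= 1")
        if self.sample_rate <= 0 or self.pre_ms < 0 or self.stim_ms <= 0:
            raise ValueError("durations and sample rate must be positive")
        n_samples = (self.pre_ms + self.stim_ms) * self.sample_rate / 1000.0
        if abs(n_samples - round(n_samples)) > 1e-9:
            raise ValueError("trace duration must be a whole number of samples")
        if not abs(self.aq_effect_correlation) < 1.0:
            raise ValueError("|aq_effect_correlation| must be < 1")
        if self.subject_sensitivity_sd < 0 or self.noise.white_sd < 0:
            raise ValueError("SDs must be nonnegative")
        if not 0 <= abs(self.noise.ar1_coefficient) < 1:
            raise ValueError("|ar1_coefficient| must be < 1")
        if self.blink.rate_per_s < 0:
            raise ValueError("blink rate must be nonnegative")
        for cond, eff in self.effects.items():
            if not 0.0 <= eff.onset_ms <= self.stim_ms:
                raise ValueError(f"{cond}: onset_ms must lie in [0, stim_ms]")

    @property
    def n_samples(self) -> int:
        return int(round((self.pre_ms + self.stim_ms) * self.sample_rate / 1000.0))

    @property
    def onset_index(self) -> int:
        return int(round(self.pre_ms * self.sample_rate / 1000.0))

    def sample_times_ms(self) -> np.ndarray:
        """Time of each sample in ms relative to stimulus onset."""
        return np.arange(self.n_samples) / self.sample_rate * 1000.0 - self.pre_ms


@dataclass
class TrialRecording:
    """One trial's raw pupil samples with metadata.

    Invalid samples (blinks) carry NaN diameter; ``onset_index`` is the
    sample index of stimulus onset.
    """

    subject_id: str
    condition: str
    samples: np.ndarray
    validity: np.ndarray
    sample_rate: float
    onset_index: int
    trial_id: int = 0


@dataclass
class GroundTruth:
    """Generative state of one simulated experiment."""

    subject_ids: list[str]
    baselines: np.ndarray
    sensitivities: np.ndarray
    aq_scores: np.ndarray
    effect_traces: dict[str, np.ndarray]   # per-condition, 50 ms bins
    effect_windows: dict[str, tuple[float, float] | None]  # ms, nonzero span
    bin_centers_ms: np.ndarray


def default_paper_config(seed: int = 0) -> SimConfig:
    """The reference study conditions.

    24 subjects, 40 trials per condition at 500 Hz; happy effect onset
    1750 ms (dilation), sad onset 1850 ms (constriction), neutral null;
    AQ--sensitivity correlation -0.47.  Amplitudes and noise are fixed
    so that group-level effect sizes land in the moderate range the
    paradigm is powered for (scalar d_z ~ 0.6-0.7 at n = 24).
    """
    return SimConfig(seed=seed)


def _effect_time_course(eff: EffectSpec, t_ms: np.ndarray) -> np.ndarray:
    """Logistic ramp, hard-zeroed before onset (truth is exactly 0 there)."""
    if eff.amplitude == 0.0:
        return np.zeros_like(t_ms)
    ramp = max(eff.ramp_ms, 1e-9)
    x = (t_ms - eff.onset_ms - ramp / 2.0) * 8.0 / ramp
    out = eff.amplitude / (1.0 + np.exp(-x))
    out[t_ms < eff.onset_ms] = 0.0
    return out


def _evoked(cfg: SimConfig, t_ms: np.ndarray) -> np.ndarray:
    """Shared gamma-shaped dilation transient, peak 1 at evoked_peak_ms."""
    tp = cfg.evoked_peak_ms
    rel = np.clip(t_ms, 0.0, None) / tp
    g = rel**2 * np.exp(2.0 * (1.0 - rel))
    g[t_ms <= 0.0] = 0.0
    return cfg.evoked_amplitude * g


def true_effect_bins(cfg: SimConfig, bin_ms: float = 50.0) -> tuple[np.ndarray, dict, dict]:
    """Condition effect time courses averaged into analysis bins."""
    n_bins = int(round(cfg.stim_ms / bin_ms))
    centers = (np.arange(n_bins) + 0.5) * bin_ms
    traces: dict[str, np.ndarray] = {}
    windows: dict[str, tuple[float, float] | None] = {}
    t = cfg.sample_times_ms()
    stim = t >= 0.0
    for cond in cfg.effects:
        course = _effect_time_course(cfg.effects[cond], t)[stim]
        k = course.size // n_bins
        traces[cond] = course[: n_bins * k].reshape(n_bins, k).mean(axis=1)
        nz = np.flatnonzero(traces[cond] != 0.0)
        if nz.size:
            windows[cond] = (nz[0] * bin_ms, (nz[-1] + 1) * bin_ms)
        else:
            windows[cond] = None
    return centers, traces, windows


def simulate_experiment(config: SimConfig) -> tuple[list[TrialRecording], GroundTruth]:
    """Simulate one full experiment; fully reproducible from config.seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    rho = config.aq_effect_correlation

    # latent bivariate normal: (sensitivity deviate, AQ trait deviate)
    z = rng.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n)
    sensitivities = 1.0 + config.subject_sensitivity_sd * z[:, 0]
    # rank-preserving linear map of the latent normal onto the 0-50
    # integer AQ range (population location 20, spread 7)
    aq_scores = np.clip(np.rint(20.0 + 7.0 * z[:, 1]), 0, 50).astype(int)
    baselines = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    subject_ids = [f"S{j+1:02d}" for j in range(n)]

    t_ms = config.sample_times_ms()
    evoked = _evoked(config, t_ms)
    courses = {c: _effect_time_course(config.effects[c], t_ms) for c in config.effects}
    conds = list(config.effects)
    n_trials = config.trials_per_condition * len(conds)
    n_samp = config.n_samples
    phi = config.noise.ar1_coefficient
    blink_lo, blink_hi = config.blink.duration_ms

    trials: list[TrialRecording] = []
    for j, sid in enumerate(subject_ids):
        order = rng.permutation(np.repeat(np.arange(len(conds)), config.trials_per_condition))
        innov = rng.normal(0.0, config.noise.white_sd, size=(n_trials, n_samp))
        noise = _signal.lfilter([1.0], [1.0, -phi], innov, axis=1)
        n_blinks = rng.poisson(config.blink.rate_per_s * (n_samp / config.sample_rate), size=n_trials)
        for i in range(n_trials):
            cond = conds[order[i]]
            trace = baselines[j] + evoked + sensitivities[j] * courses[cond] + noise[i]
            validity = np.ones(n_samp, dtype=bool)
            for _ in range(n_blinks[i]):
                start = rng.integers(0, n_samp)
                dur = int(round(rng.uniform(blink_lo, blink_hi) * config.sample_rate / 1000.0))
                validity[start : start + dur] = False
            trace[~validity] = np.nan
            trials.append(
                TrialRecording(
                    subject_id=sid,
                    condition=cond,
                    samples=trace,
                    validity=validity,
                    sample_rate=config.sample_rate,
                    onset_index=config.onset_index,
                    trial_id=i,
                )
            )

    centers, bin_traces, windows = true_effect_bins(config)
    truth = GroundTruth(
        subject_ids=subject_ids,
        baselines=baselines,
        sensitivities=sensitivities,
        aq_scores=aq_scores,
        effect_traces=bin_traces,
        effect_windows=windows,
        bin_centers_ms=centers,
    )
    return trials, truth


def simulate_null_bins(
    n_subjects: int,
    n_bins: int,
    ar1: float = 0.6,
    sd: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two null condition matrices (subject x bin) of AR(1) noise.

    A light-weight generator for permutation-test calibration studies at
    the analysis-bin level, bypassing the sample-level pipeline.
    """
    rng = np.random.default_rng() if rng is None else rng
    out = []
    for _ in range(2):
        innov = rng.normal(0.0, sd, size=(n_subjects, n_bins))
        out.append(_signal.lfilter([1.0], [1.0, -ar1], innov, axis=1))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Dataset writer (eye-tracker TSV dialect + events CSV + AQ CSV)
# ---------------------------------------------------------------------------

def write_dataset(trials: Sequence[TrialRecording], truth: GroundTruth, outdir) -> None:
    """Write an experiment in the on-disk dialect the preprocessing
    reader consumes: per-subject sample TSVs (time_ms, pupil, gaze_x,
    gaze_y, valid) laid out trial after trial on a global clock, an
    events CSV (subject, trial, condition, onset_ms) and an AQ CSV.
    Invalid samples are written as hardware zeros."""
    os.makedirs(outdir, exist_ok=True)
    by_subject: dict[str, list[TrialRecording]] = {}
    for tr in trials:
        by_subject.setdefault(tr.subject_id, []).append(tr)

    gap_ms = 1000.0
    with open(os.path.join(outdir, "events.csv"), "w", newline="") as ev:
        w = csv.writer(ev)
        w.writerow(["subject", "trial", "condition", "onset_ms"])
        for sid, trs in by_subject.items():
            clock = 0.0
            with open(os.path.join(outdir, f"{sid}_samples.tsv"), "w") as fh:
                fh.write("time_ms\tpupil\tgaze_x\tgaze_y\tvalid\n")
                for tr in trs:
                    dt = 1000.0 / tr.sample_rate
                    onset_ms = clock + tr.onset_index * dt
                    w.writerow([sid, tr.trial_id, tr.condition, f"{onset_ms:.3f}"])
                    for k in range(tr.samples.size):
                        t = clock + k * dt
                        if tr.validity[k]:
                            fh.write(f"{t:.3f}\t{tr.samples[k]:.6f}\t960.0\t540.0\t1\n")
                        else:
                            fh.write(f"{t:.3f}\t0.0\t960.0\t540.0\t0\n")
                    clock += tr.samples.size * dt + gap_ms

    with open(os.path.join(outdir, "aq.csv"), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject", "aq"])
        for sid, aq in zip(truth.subject_ids, truth.aq_scores):
            w.writerow([sid, int(aq)])
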
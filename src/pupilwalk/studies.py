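"""Replication studies: the calibration and recovery experiments that
validate the pipeline against its own synthetic ground truth.

Each study runs the full relevant code path (simulation -> preprocessing
-> inference) many times and reduces the outcome to one number:

* type-I calibration: rejection rate of the cluster test on null data;
* enumeration agreement: Monte-Carlo vs exact sign-flip p-values;
* effect-window recovery: how often the corrected happy-vs-neutral
  window overlaps the true effect window under the reference conditions;
* AQ-correlation recovery: mean estimated AQ--(happy-sad) correlation
  across replicate experiments against the generative value;
* stimulus invariants: speed calibration and transform identities.

All randomness is drawn from a single base seed via seed-sequence
spawning, so every study is reproducible end to end.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .cluster_permutation import ClusterTestConfig, cluster_test
from .pupil_preprocess import preprocess_experiment
from .synthetic_pupil import (
    CONDITIONS,
    default_paper_config,
    simulate_experiment,
    simulate_null_bins,
)
from .walker_stimuli import (
    WalkerConfig,
    generate_walker,
    invert,
    mean_dot_speed,
    path_arc_positions,
    remove_acceleration,
    scramble,
)

__all__ = [
    "child_seeds",
    "type1_calibration",
    "enumeration_agreement",
    "effect_window_recovery",
    "aq_correlation_recovery",
    "stimulus_invariants",
]


def child_seeds(seed: int, n: int) -> list[int]:
    """n independent 31-bit seeds derived from one base seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n)]


def type1_calibration(
    n_experiments: int = 500,
    n_subjects: int = 24,
    n_bins: int = 80,
    ar1: float = 0.6,
    n_permutations: int = 1000,
    seed: int = 0,
) -> float:
    """Fraction of null experiments with any corrected significant
    cluster.  Null data are AR(1) noise at the analysis-bin level; the
    nominal rate is the cluster alpha (0.05)."""
    seeds = child_seeds(seed, n_experiments)
    rng = np.random.default_rng(child_seeds(seed + 1, 1)[0])
    rejections = 0
    for s in seeds:
        a, b = simulate_null_bins(n_subjects, n_bins, ar1=ar1, rng=rng)
        res = cluster_test(a, b, ClusterTestConfig(n_permutations=n_permutations, seed=s))
        if res.corrected_sig_windows:
            rejections += 1
    return rejections / n_experiments


def enumeration_agreement(
    n_datasets: int = 20,
    n_subjects: int = 6,
    n_bins: int = 40,
    n_permutations: int = 2000,
    seed: int = 0,
) -> float:
    """Largest |p_montecarlo - p_exact| for the strongest cluster over
    datasets small enough to enumerate all 2^n sign patterns."""
    rng = np.random.default_rng(child_seeds(seed, 1)[0])
    seeds = child_seeds(seed + 1, n_datasets)
    worst = 0.0
    for s in seeds:
        a, b = simulate_null_bins(n_subjects, n_bins, ar1=0.5, rng=rng)
        a[:, n_bins // 4 : n_bins // 2] += 1.2
        exact = cluster_test(a, b, ClusterTestConfig(enumeration="always"))
        mc = cluster_test(
            a, b,
            ClusterTestConfig(n_permutations=n_permutations, seed=s, enumeration="never"),
        )
        if exact.clusters:
            p_exact = min(c.p for c in exact.clusters)
            p_mc = min(c.p for c in mc.clusters)
            worst = max(worst, abs(p_exact - p_mc))
    return worst


def effect_window_recovery(
    n_experiments: int = 100,
    n_permutations: int = 2000,
    seed: int = 0,
) -> float:
    """Fraction of reference-condition experiments whose corrected
    happy-vs-neutral window overlaps the true effect window."""
    seeds = child_seeds(seed, n_experiments)
    hits = 0
    for s in seeds:
        cfg = default_paper_config(seed=s)
        trials, truth = simulate_experiment(cfg)
        matrix = preprocess_experiment(trials, stim_ms=cfg.stim_ms, conditions=CONDITIONS)
        res = cluster_test(
            matrix.condition_matrix("happy"),
            matrix.condition_matrix("neutral"),
            ClusterTestConfig(n_permutations=n_permutations, seed=s),
            matrix.bin_centers_ms,
        )
        lo, hi = truth.effect_windows["happy"]
        if any(a < hi and b > lo for a, b in res.corrected_sig_windows):
            hits += 1
    return hits / n_experiments


def aq_correlation_recovery(
    n_experiments: int = 200,
    seed: int = 0,
) -> float:
    """Mean estimated correlation between AQ and the happy-sad pupil
    modulation score across replicate reference-condition experiments.
    The generative latent correlation is the config's
    aq_effect_correlation (-0.47 by default); measurement noise
    attenuates the recovered value slightly."""
    seeds = child_seeds(seed, n_experiments)
    rs = []
    for s in seeds:
        cfg = default_paper_config(seed=s)
        trials, truth = simulate_experiment(cfg)
        matrix = preprocess_experiment(trials, stim_ms=cfg.stim_ms, conditions=CONDITIONS)
        idx = {c: i for i, c in enumerate(matrix.conditions)}
        score = matrix.scalar_means[:, idx["happy"]] - matrix.scalar_means[:, idx["sad"]]
        rs.append(np.corrcoef(score, truth.aq_scores)[0, 1])
    return float(np.mean(rs))


@dataclass
class StimulusInvariants:
    happy_speed: float
    neutral_speed: float
    sad_speed: float
    max_speed_cv: float            # worst per-dot arc-speed CV after de-acceleration
    max_mean_speed_rel_err: float  # worst per-dot mean-speed conservation error
    scramble_diffs_exact: bool
    invert_involution_exact: bool


def stimulus_invariants(seed: int = 0, n_frames: int = 240) -> StimulusInvariants:
    """Walker speed calibration plus the transform identities."""
    speeds = {}
    for name, emotion in (("happy", 6.0), ("neutral", 0.0), ("sad", -6.0)):
        seq = generate_walker(WalkerConfig(emotion_score=emotion, n_frames=n_frames), seed=seed)
        speeds[name] = mean_dot_speed(seq)

    seq = generate_walker(WalkerConfig(emotion_score=0.0, n_frames=n_frames), seed=seed)
    deaccel = remove_acceleration(seq)
    max_cv = 0.0
    max_err = 0.0
    for m in range(seq.positions.shape[1]):
        p = seq.positions[:, m]
        s = path_arc_positions(p, deaccel.positions[:, m])
        ds = np.diff(s)
        max_cv = max(max_cv, float(ds.std() / ds.mean()))
        orig_mean = np.linalg.norm(np.diff(p, axis=0), axis=1).mean()
        max_err = max(max_err, abs(ds.mean() - orig_mean) / orig_mean)

    scr = scramble(seq, seed=seed + 1)
    diffs_exact = bool(
        np.array_equal(np.diff(scr.positions, axis=0), np.diff(seq.positions, axis=0))
    )
    inv_exact = bool(np.array_equal(invert(invert(seq)).positions, seq.positions))
    return StimulusInvariants(
        happy_speed=speeds["happy"],
        neutral_speed=speeds["neutral"],
        sad_speed=speeds["sad"],
        max_speed_cv=max_cv,
        max_mean_speed_rel_err=max_err,
        scramble_diffs_exact=diffs_exact,
        invert_involution_exact=inv_exact,
    )
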
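"""End-to-end orchestration: simulate (or load) -> preprocess ->
cluster contrasts -> scalar statistics -> serializable report.

The pipeline reproduces the full analysis graph of a passive-viewing
emotional-walker pupillometry experiment: three pairwise time-course
contrasts (happy-neutral, sad-neutral, happy-sad) via cluster-based
permutation tests, a one-way RM-ANOVA plus Holm/Bonferroni-corrected
paired contrasts on the scalar mean pupil size, and Pearson/Fisher
correlations between AQ scores and the per-subject pupil modulation
scores.  All randomness derives from a single seed (split per stage),
so a rerun with the same config yields an identical report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .aggregate_stats import (
    AnovaResult,
    CorrelationResult,
    PairedTestResult,
    ReliabilityResult,
    paired_tests_with_corrections,
    pearson_with_ci,
    reliability,
    rm_anova_oneway,
)
from .cluster_permutation import ClusterTestConfig, ClusterTestResult, cluster_test
from .pupil_preprocess import PreprocessConfig, TrialMatrix, preprocess_experiment, read_dataset
from .synthetic_pupil import CONDITIONS, GroundTruth, SimConfig, default_paper_config, simulate_experiment

__all__ = [
    "RunConfig",
    "StatsReport",
    "run_pipeline",
    "compute_modulation_scores",
    "validate_report",
]

DEFAULT_CONTRASTS: tuple[tuple[str, str], ...] = (
    ("happy", "neutral"),
    ("sad", "neutral"),
    ("happy", "sad"),
)


@dataclass(frozen=True)
class RunConfig:
    mode: str = "simulate"                     # "simulate" | "files"
    sim: SimConfig = field(default_factory=default_paper_config)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    cluster: ClusterTestConfig = field(default_factory=ClusterTestConfig)
    contrasts: tuple[tuple[str, str], ...] = DEFAULT_CONTRASTS
    samples_dir: str | None = None
    events_path: str | None = None
    aq_path: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "files"):
            raise ValueError("mode must be 'simulate' or 'files'")
        if self.mode == "files" and (self.samples_dir is None or self.events_path is None):
            raise ValueError("files mode requires samples_dir and events_path")


@dataclass
class StatsReport:
    contrasts: dict[str, ClusterTestResult]
    anova: AnovaResult
    paired: list[PairedTestResult]
    correlations: dict[str, CorrelationResult]
    reliability: ReliabilityResult | None
    modulation_scores: pd.DataFrame
    matrix: TrialMatrix
    truth: GroundTruth | None
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "contrasts": {k: v.to_dict() for k, v in self.contrasts.items()},
            "anova": self.anova.to_dict(),
            "paired": [p.to_dict() for p in self.paired],
            "correlations": {k: v.to_dict() for k, v in self.correlations.items()},
            "reliability": None if self.reliability is None else self.reliability.to_dict(),
            "modulation_scores": {
                col: [float(v) for v in self.modulation_scores[col]]
                for col in self.modulation_scores.columns
            },
            "subjects": list(self.matrix.subjects),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def compute_modulation_scores(matrix: TrialMatrix) -> pd.DataFrame:
    """Per-subject pupil modulation scores: pairwise differences of the
    scalar mean pupil size over the stimulus window."""
    for cond in ("happy", "sad", "neutral"):
        if cond not in matrix.conditions:
            raise ValueError(f"missing condition: {cond}")
    s = {c: matrix.scalar_means[:, matrix.conditions.index(c)] for c in ("happy", "sad", "neutral")}
    return pd.DataFrame(
        {
            "happy_minus_sad": s["happy"] - s["sad"],
            "happy_minus_neutral": s["happy"] - s["neutral"],
            "sad_minus_neutral": s["sad"] - s["neutral"],
        },
        index=matrix.subjects,
    )


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n)]


def run_pipeline(cfg: RunConfig) -> StatsReport:
    """Execute the full analysis graph and return the report."""
    seeds = _child_seeds(cfg.seed, 1 + len(cfg.contrasts))

    truth: GroundTruth | None = None
    aq: np.ndarray | None = None
    if cfg.mode == "simulate":
        sim = dataclasses.replace(cfg.sim, seed=seeds[0])
        trials, truth = simulate_experiment(sim)
        stim_ms = sim.stim_ms
        aq = truth.aq_scores
    else:
        trials = read_dataset(cfg.samples_dir, cfg.events_path)
        stim_ms = None
        if cfg.aq_path is not None:
            aq_df = pd.read_csv(cfg.aq_path).set_index("subject")["aq"]
            aq = aq_df

    matrix = preprocess_experiment(
        trials, cfg.preprocess, stim_ms=stim_ms, conditions=CONDITIONS
    )
    if isinstance(aq, pd.Series):
        aq = aq.reindex(matrix.subjects).to_numpy(dtype=float)

    contrasts: dict[str, ClusterTestResult] = {}
    for (a, b), s in zip(cfg.contrasts, seeds[1:]):
        ccfg = dataclasses.replace(cfg.cluster, seed=s)
        contrasts[f"{a}-{b}"] = cluster_test(
            matrix.condition_matrix(a),
            matrix.condition_matrix(b),
            ccfg,
            matrix.bin_centers_ms,
        )

    anova = rm_anova_oneway(matrix.scalar_means, matrix.conditions)
    paired = paired_tests_with_corrections(
        matrix.scalar_means, matrix.conditions, cfg.contrasts
    )
    scores = compute_modulation_scores(matrix)
    correlations: dict[str, CorrelationResult] = {}
    if aq is not None:
        for col in scores.columns:
            correlations[f"aq_vs_{col}"] = pearson_with_ci(scores[col].to_numpy(), aq)

    provenance = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "mode": cfg.mode,
        "n_subjects": len(matrix.subjects),
        "conditions": list(matrix.conditions),
    }
    return StatsReport(
        contrasts=contrasts,
        anova=anova,
        paired=paired,
        correlations=correlations,
        reliability=None,
        modulation_scores=scores,
        matrix=matrix,
        truth=truth,
        provenance=provenance,
    )


def session_reliability(report1: StatsReport, report2: StatsReport) -> ReliabilityResult:
    """Test--retest reliability of the happy-sad modulation score across
    two sessions of the same subjects."""
    s1 = report1.modulation_scores["happy_minus_sad"].to_numpy()
    s2 = report2.modulation_scores["happy_minus_sad"].to_numpy()
    return reliability(s1, s2)


# ---------------------------------------------------------------------------
# Report schema (shipped JSON schema + minimal structural validator)
# ---------------------------------------------------------------------------

def _load_schema() -> dict:
    with resources.files("pupilwalk").joinpath("data/statsreport.schema.json").open() as fh:
        return json.load(fh)


def validate_report(obj: dict, schema: dict | None = None, path: str = "$") -> None:
    """Validate a report dict against the shipped JSON schema.

    Implements the structural subset used by the schema (type, required,
    properties, items, additionalProperties as sub-schema); raises
    ``ValueError`` naming the offending path.
    """
    if schema is None:
        schema = _load_schema()
    typ = schema.get("type")
    if typ is not None:
        py = {
            "object": dict,
            "array": list,
            "string": str,
            "integer": int,
            "boolean": bool,
        }.get(typ)
        if typ == "number":
            if obj is not None and not isinstance(obj, (int, float)):
                raise ValueError(f"{path}: expected number, got {type(obj).__name__}")
        elif typ == "integer":
            if not isinstance(obj, int) or isinstance(obj, bool):
                raise ValueError(f"{path}: expected integer, got {type(obj).__name__}")
        elif py is not None and not isinstance(obj, py):
            if not (schema.get("nullable") and obj is None):
                raise ValueError(f"{path}: expected {typ}, got {type(obj).__name__}")
    if isinstance(obj, dict):
        for req in schema.get("required", []):
            if req not in obj:
                raise ValueError(f"{path}: missing required key '{req}'")
        props = schema.get("properties", {})
        for key, sub in props.items():
            if key in obj:
                validate_report(obj[key], sub, f"{path}.{key}")
        extra = schema.get("additionalProperties")
        if isinstance(extra, dict):
            for key, val in obj.items():
                if key not in props:
                    validate_report(val, extra, f"{path}.{key}")
    if isinstance(obj, list) and "items" in schema:
        for i, item in enumerate(obj):
            validate_report(item, schema["items"], f"{path}[{i}]")
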
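#!/usr/bin/env python
"""Scalar statistics on the preprocessed experiment.

One-way RM-ANOVA (Greenhouse-Geisser handled) over the three emotional
conditions' mean pupil size, Holm/Bonferroni-corrected paired
contrasts with Cohen's d_z, and Fisher-z correlations between AQ and
the per-subject pupil modulation scores.  Writes
results/stats_summary.json.
"""

import json
import os

import pandas as pd

from pupilwalk.aggregate_stats import (
    paired_tests_with_corrections,
    pearson_with_ci,
    rm_anova_oneway,
)
from pupilwalk.pipeline import DEFAULT_CONTRASTS, compute_modulation_scores
from pupilwalk.pupil_preprocess import read_trial_matrix

OUT = "results"
os.makedirs(OUT, exist_ok=True)

matrix = read_trial_matrix("scratch/trial_matrix.tsv")
aq = pd.read_csv("scratch/sim/aq.csv").set_index("subject")["aq"].reindex(matrix.subjects)

anova = rm_anova_oneway(matrix.scalar_means, matrix.conditions)
print(f"RM-ANOVA: F({anova.df_effect_gg:.1f}, {anova.df_error_gg:.1f}) = {anova.F:.2f}, "
      f"p = {anova.p_preferred:.4f}, eta_p^2 = {anova.partial_eta_sq:.2f} "
      f"(GG epsilon = {anova.gg_epsilon:.2f})")

paired = paired_tests_with_corrections(matrix.scalar_means, matrix.conditions, DEFAULT_CONTRASTS)
for r in paired:
    print(f"  {r.name:14s} t({r.df}) = {r.t:+.2f}, d_z = {r.cohens_dz:.2f}, "
          f"p_holm = {r.p_holm:.4f}, 95% CI [{r.mean_diff_ci95[0]:+.3f}, {r.mean_diff_ci95[1]:+.3f}]")

scores = compute_modulation_scores(matrix)
correlations = {}
for col in scores.columns:
    res = pearson_with_ci(scores[col].to_numpy(), aq.to_numpy(dtype=float))
    correlations[f"aq_vs_{col}"] = res.to_dict()
    print(f"  AQ vs {col:20s} r({res.df}) = {res.r:+.2f}, p = {res.p:.4f}, "
          f"95% CI [{res.ci95[0]:+.2f}, {res.ci95[1]:+.2f}]")

payload = {
    "anova": anova.to_dict(),
    "paired": [r.to_dict() for r in paired],
    "correlations": correlations,
}
with open(f"{OUT}/stats_summary.json", "w") as fh:
    json.dump(payload, fh, indent=2, sort_keys=True)
print(f"summary in {OUT}/stats_summary.json")
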
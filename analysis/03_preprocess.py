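#!/usr/bin/env python
"""Preprocess the simulated raw dataset into the trial matrix.

Reads scratch/sim/ (written by 02_simulate_experiment.py), runs blink
screening, +/-3 SD trial exclusion, 20 Hz down-sampling and baseline
correction, and reports what was excluded and why.  The full trial
matrix goes to scratch/trial_matrix.tsv; per-subject scalar means to
results/scalar_means.tsv.
"""

import os

import pandas as pd

from pupilwalk.pupil_preprocess import preprocess_experiment, read_dataset, write_trial_matrix
from pupilwalk.synthetic_pupil import CONDITIONS

OUT = "results"
SCRATCH = "scratch"
os.makedirs(OUT, exist_ok=True)

trials = read_dataset(f"{SCRATCH}/sim", f"{SCRATCH}/sim/events.csv")
matrix = preprocess_experiment(trials, stim_ms=4000.0, conditions=CONDITIONS)

n_bins = matrix.values.shape[2]
print(f"trial matrix: {len(matrix.subjects)} subjects x {len(matrix.conditions)} "
      f"conditions x {n_bins} bins of 50 ms")
print(f"retained {matrix.trial_counts.sum()} of {len(trials)} trials; exclusions by reason:")
for reason, count in matrix.exclusions["reason"].value_counts().items():
    print(f"  {reason:16s} {count}")

write_trial_matrix(matrix, f"{SCRATCH}/trial_matrix.tsv")
matrix.exclusions.to_csv(f"{OUT}/exclusion_log.csv", index=False)

scalar = pd.DataFrame(
    matrix.scalar_means, index=matrix.subjects, columns=list(matrix.conditions)
).round(4)
scalar.index.name = "subject"
scalar.to_csv(f"{OUT}/scalar_means.tsv", sep="\t")
print(f"matrix in {SCRATCH}/trial_matrix.tsv, scalar means in {OUT}/scalar_means.tsv")
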
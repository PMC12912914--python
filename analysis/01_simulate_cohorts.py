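#!/usr/bin/env python
"""Generate the two synthetic study cohorts.

Writes, under results/: screening.csv (3632 community subjects with
severity classes, scores and outcome times) and scores.csv +
subjects.csv (2040 pre-procedure subjects with irregular score
trajectories, survival and covariates).
"""

from astraj.pipeline import run

out = run("simulate", outdir="results")["simulate"]
print(f"Screening cohort: {out['screening_n']} subjects")
print(f"Trajectory cohort: {out['trajectory_n']} subjects, "
      f"{out['trajectory_observations']} score observations")
print("Artifacts in results/: screening.csv, scores.csv, subjects.csv")
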
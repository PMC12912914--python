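#!/usr/bin/env python
"""Community screening validation.

Computes the AUROC for moderate/severe AS detection, the
Youden-optimal cutpoint with its confusion summary, the Bayes
prevalence-projection table (1-5% grid plus the observed-prevalence
row), and the prognosis of false-positive screens vs. true negatives
(AS hospitalisation and heart failure, unadjusted and PCP-HF adjusted).
"""

from astraj.pipeline import run

rep = run("screen", outdir="results")["screen"]
print(f"n = {rep['n']}, case prevalence {100 * rep['prevalence']:.2f}%")
print(f"AUROC {rep['auroc']['value']:.3f} "
      f"(95% CI {rep['auroc']['ci'][0]:.3f}-{rep['auroc']['ci'][1]:.3f})")
c = rep["confusion"]
print(f"Youden cutpoint {rep['cutpoint']:.3f}: sensitivity "
      f"{100 * c['sensitivity']:.1f}%, specificity "
      f"{100 * c['specificity']:.1f}%")
for row in rep["projections"]:
    tag = "observed" if row["observed"] else "     "
    print(f"  prevalence {100 * row['population_prevalence']:5.2f}% {tag}: "
          f"PPV {100 * row['ppv']:5.1f}%, NPV {100 * row['npv']:5.1f}%, "
          f"screen rate {100 * row['positive_screen_rate']:5.1f}%")
for key, p in rep["fp_prognosis"].items():
    print(f"  FP vs TN {key}: HR {p['hazard_ratio']:.2f} "
          f"({p['ci_low']:.2f}-{p['ci_high']:.2f}), p={p['p_value']:.2g}")
print("Artifacts: screening_report.json, table1.csv")
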
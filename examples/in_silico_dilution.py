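"""In silico dilution series: detection AUC versus ctDNA fraction.

Simulates case/control cohorts by admixing a 9%-fraction tumour template
into control feature noise at decreasing target fractions, scores every
sample with the full reference-cohort/multimodal machinery, and reports
per-fraction AUC.
"""

import numpy as np

from ctdetect import make_synthetic_templates, simulate_cohort
from ctdetect.simulate import auc_by_fraction, score_cohort

templates = make_synthetic_templates(seed=0)
fractions = [0.001, 0.004, 0.007, 0.01, 0.02]
cohort = simulate_cohort(templates, fractions, n_per_group=500, seed=1)
print(f"simulated {len(cohort)} samples "
      f"({len(fractions)} fractions x 500 cases + 500 controls)")

scores = score_cohort(cohort, templates)
aucs = auc_by_fraction(cohort, scores["combined"])
for r in fractions:
    print(f"  ctDNA fraction {100 * r:4.1f}%: multimodal AUC = {aucs[r]:.3f}")
print("AUC is non-decreasing in the ctDNA fraction: below the per-feature "
      "detection limit both groups score zero (AUC ~ 0.5), and discrimination "
      "emerges once diluted arm/marker shifts clear the q < 0.05 gate. At the "
      "template's own 9% fraction a case reproduces the tumour profile exactly "
      "(mixture weight w = r/rho).")
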
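"""CDR-based glaucoma screening with ROC/AUC on a synthetic cohort.

Extracts the cup-to-disc ratio from segmentation masks (here the ground-
truth masks, isolating the screening step from segmentation quality),
screens at the clinical CDR > 0.5 threshold, and sweeps the threshold for
the ROC curve.
"""

import numpy as np

from eards.data import make_synthetic_dataset
from eards.metrics import cdr, screen, structure_masks

cohort = make_synthetic_dataset(n=60, seed=11, size=256, glaucoma_fraction=0.3)
scores, labels = [], []
for s in cohort:
    disc, cup = structure_masks(s.mask)
    scores.append(cdr(cup, disc).value)
    labels.append(s.glaucomatous)

report = screen(scores, labels, threshold=0.5)
tp = sum(d and l for d, l in zip(report.decisions, labels))
fp = sum(d and not l for d, l in zip(report.decisions, labels))
print(f"cohort: {len(cohort)} eyes, {sum(labels)} glaucomatous")
print(f"screened positive at CDR > 0.5: {report.decisions.sum()} "
      f"({tp} true, {fp} false)")
print(f"AUC over the CDR threshold sweep: {report.auc:.4f}")
print("\nAn AUC near 1 reflects the separated CDR regimes of the synthetic")
print("cohort; on real cohorts the CDR distributions overlap and the AUC of")
print("CDR-based screening is typically 0.9-0.97.")
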
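"""Compare synthetic patient cohorts with rank-sum statistics.

Simulates a 104-patient cohort (43 ILC, 38 IDC, 12 fibroadenoma, 11
fibrocystic mastopathy) at the metrics level: cancer patients receive a
0.15 shift of window share from fatty to disrupted on the tumor side, benign
patients none. Group contrasts are then tested exactly as for real data.
"""

import numpy as np

from mammofractal import CohortSpec, boxplot_summary, compare_groups, simulate_cohort_metrics
from mammofractal.synthetic import CANCER_GROUPS

spec = CohortSpec(seed=2024, cancer_effect=0.15)
records = simulate_cohort_metrics(spec)

yb_cancer = [r.yb_factor for r in records if r.group in CANCER_GROUPS]
yb_benign = [r.yb_factor for r in records if r.group not in CANCER_GROUPS]

print(f"patients: {len(records)} ({len(yb_cancer)} cancer, {len(yb_benign)} benign)")
print(f"median YB Factor  cancer: {np.median(yb_cancer):.2f}   benign: {np.median(yb_benign):.2f}")
print(f"fraction YB > 1   cancer: {np.mean(np.array(yb_cancer) > 1):.2f}"
      f"   benign: {np.mean(np.array(yb_benign) > 1):.2f}")

box = boxplot_summary(yb_cancer)
print(f"cancer YB five-number summary: "
      f"{box.minimum:.2f} | {box.q1:.2f} | {box.median:.2f} | {box.q3:.2f} | {box.maximum:.2f}")

print()
print("metric      contrast              n_A  n_B   p (rank-sum, unadjusted)")
for c in compare_groups(records):
    print(f"{c.metric:<11} {c.group_a:>8} vs {c.group_b:<8} {c.n_a:4d} {c.n_b:4d}   {c.p_value:.4g}")

print()
print("With the built-in asymmetry effect the YB Factor separates cancer")
print("from benign patients sharply (tiny p); benign-only contrasts behave")
print("like null comparisons (p spread over (0, 1)).")
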
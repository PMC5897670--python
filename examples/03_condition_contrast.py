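"""Contrast influence hierarchies between two conditions across subjects.

Simulates a 30-subject cohort whose hub couples more strongly in the
high-intensity condition, computes each subject's influencing degree in
both conditions, and runs the per-node paired t-test with BH-FDR over the
14 regions.  The planted hub should show the largest contrast and survive
correction.
"""

import pandas as pd

import depna

cohort = depna.simulate_cohort(depna.CohortSpec(n_subjects=30, seed=3))

lo, hi = {}, {}
for a, b in zip(cohort.low, cohort.high):
    lo[a.subject_id] = depna.influencing_degree(
        depna.dependency_matrix(depna.pearson_correlations(a))).scores
    hi[b.subject_id] = depna.influencing_degree(
        depna.dependency_matrix(depna.pearson_correlations(b))).scores

result = depna.paired_condition_ttest(pd.DataFrame(lo).T, pd.DataFrame(hi).T)
print("high vs low condition, per-node paired t (df = 29), BH-FDR over 14:")
print(result[["mean_low", "mean_high", "t", "p", "q"]].round(4).to_string())

top = result["t"].abs().idxmax()
print(f"\nlargest contrast: {top} (t = {result.loc[top, 't']:.2f}, "
      f"q = {result.loc[top, 'q']:.4f}) — the planted hub is "
      f"{cohort.spec.hub_label}.")
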
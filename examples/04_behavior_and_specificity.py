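"""Relate influence differences to behavior and test spatial specificity.

Simulates a default cohort (negative behavior slope), correlates each
subject's low-minus-high hub influencing degree with the rating-derived
intensity AUC (3-SD outliers excluded), then compares the hub's observed
contrast t against the same analysis on random node sets.
"""

import pandas as pd

import depna
from depna.pipeline import random_network_tstats

cohort = depna.simulate_cohort(depna.CohortSpec(n_subjects=40, seed=9))

lo, hi = {}, {}
for a, b in zip(cohort.low, cohort.high):
    lo[a.subject_id] = depna.influencing_degree(
        depna.dependency_matrix(depna.pearson_correlations(a))).scores["vmPFC"]
    hi[b.subject_id] = depna.influencing_degree(
        depna.dependency_matrix(depna.pearson_correlations(b))).scores["vmPFC"]
delta = pd.Series(lo) - pd.Series(hi)

r, p, n = depna.behavior_correlation(delta, cohort.behavior["anger_auc"])
print(f"low-minus-high vmPFC influence vs intensity AUC: "
      f"r = {r:.2f}, p = {p:.3g}, n = {n}")
print("(negative: subjects whose hub gains more influence in the high "
      "condition report more intensity)\n")

res = depna.paired_condition_ttest(
    pd.DataFrame({"vmPFC": pd.Series(lo)}), pd.DataFrame({"vmPFC": pd.Series(hi)})
)
observed_t = res.loc["vmPFC", "t"]
rand = random_network_tstats(n_subjects=40, n_nodes=14, t_len=44, k=100,
                             pool_size=50, seed=1)
p_spec = depna.specificity_bootstrap(observed_t, rand, mode="tstat")
print(f"observed hub contrast t = {observed_t:.2f}; "
      f"random-network background (k = 100) gives empirical p = {p_spec:.4f}")
print("(small p: the effect is specific to the network, not a global "
      "artifact any random node set would show)")
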
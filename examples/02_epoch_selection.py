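"""Select low/high-intensity epochs from continuous emotion ratings.

Generates 20 subjects' rating traces (10 Hz, 21-level scale, a smoothed
low-to-high step), finds the longest pair of equal-length windows whose
ratings differ by a Wilcoxon signed-rank test at p < 0.01, and maps the
windows onto TR = 3 s volume indices.
"""

import depna

cohort = depna.simulate_cohort(depna.CohortSpec(n_subjects=20, seed=7))

pair = depna.find_epoch_pair(cohort.ratings, alpha=0.01)
pair = depna.epochs_to_tr(pair, tr_seconds=3.0)

print(f"low-intensity epoch : {pair.low_window[0]:6.1f} - "
      f"{pair.low_window[1]:6.1f} s  -> TRs {pair.tr_windows['low']}")
print(f"high-intensity epoch: {pair.high_window[0]:6.1f} - "
      f"{pair.high_window[1]:6.1f} s  -> TRs {pair.tr_windows['high']}")
print(f"epoch length        : {pair.length_s:.0f} s "
      f"({pair.tr_windows['n_volumes']} volumes each)")
print(f"Wilcoxon signed-rank: p = {pair.wilcoxon_p:.2e}")

auc = depna.rating_auc(cohort.ratings[0])
print(f"\nfirst subject's rating AUC: {auc:.0f} scale-units x s "
      "(the per-subject overall intensity index)")
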
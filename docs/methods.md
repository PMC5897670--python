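# Methods

## The model

Dependency network analysis treats a correlation network as a system in
which some nodes *carry* the couplings of others. For nodes i, k and a
conditioning node j, with C the ROI–ROI Pearson correlation matrix of
one subject in one condition,

    PC(i,k|j) = (C(i,k) − C(i,j)C(k,j)) / √[(1 − C²(i,j))(1 − C²(k,j))]
    d(i,k|j)  = max(0, C(i,k) − PC(i,k|j))
    D(i,j)    = 1/(N−1) · Σ_{k≠j} d(i,k|j)
    degree(j) = Σ_{i≠j} D(i,j)

d(i,k|j) is large only when a substantial fraction of the i–k
correlation is attributable to j (common cause or mediator); it is
floored at zero so aggregates never mix signed contributions. The k = i
term of the D sum is kept as written — it is identically zero because
C(i,i) = 1 forces PC(i,i|j) = 1 — and the normalizer is N−1. D is
asymmetric: D(i,j) is the influence of j *on* i. Influence here is a
statement about correlation structure, not causality.

Network-restricted variants, for two disjoint sub-networks (here a
6-node reactivity set and an 8-node regulation set):

- **intra**: the full pipeline recomputed on the sub-network's node set
  alone, so conditioning triplets never leave the sub-network. This is
  the default because the quantity is a self-contained description of
  the sub-network; masking the full-network D to the sub-network block
  is available as `intra_mode="masked_full"`.
- **inter, within-target**: for a source node j, the aggregate of
  d(i,k|j) over unordered pairs {i,k} inside the other network, each
  pair counted once.
- **inter, between-networks**: the aggregate over i in the target
  network and k in the source network excluding j.
- **total inter-network influence**: the sum of a network's per-node
  inter scores.

The inter variants default to the *mean* over contributing pairs and
expose `agg="sum"`; the global and intra degrees are sums over target
nodes of per-target means, as defined above. Means and sums order nodes
identically within a scheme; reporting both conventions makes
magnitudes comparable across schemes with very different pair counts.

### Numerical choices

- Eq-style partial correlations are applied to **raw Pearson r** by
  default. Applying the same algebra to Fisher-z values (the historical
  convention) is available as `correlation_transform="fisher_z"`: it is
  ill-defined for |z| ≥ 1, so the denominator is floored at 1e-12 with a
  warning. On raw r the closed form equals the correlation of
  least-squares residuals after removing the conditioning node — an
  identity the tests verify to 1e-10 — which is why raw r is the
  default.
- |r| = 1 conditioning correlations are degenerate (zero denominator)
  and raise an error naming the pair; the Fisher-z route with clipping
  is the escape hatch for near-singular inputs.
- The vectorized triple-tensor implementation is checked against a
  literal nested-loop implementation to 1e-12 on random matrices; the
  d(i,i|j) slot is set to exactly 0 rather than trusting
  `sqrt(x·x) == x`.
- Per-epoch column z-scoring is on by default. Pearson r is invariant
  to it, so it only stabilizes the Fisher-z path and file round-trips.

## Epoch selection

Continuous ratings (10 Hz, 21 discrete levels by default) are reduced to
a group-median trace. Candidate window lengths L descend from half the
trace; at each L all non-overlapping equal-length window pairs are
candidates, and a pair passes if the two windows' ratings differ at
p < α (default 0.01) by a two-sided Wilcoxon signed-rank test. The
pairing unit defaults to `subjects` (per-subject window medians, paired
across subjects — the natural reading of a group criterion); a
`timepoints` mode pairs group-median samples by within-window position.
Among passing pairs at the first feasible L, the pair maximizing the
group-median difference wins, with deterministic tie-breaks (earliest
high-window start, then earliest low-window start). Internally,
candidates are tested in descending median-difference order and
zero-difference pairs are skipped; this returns exactly the exhaustive
answer (verified against full enumeration in the tests) at a fraction of
the Wilcoxon calls. If no pair passes at any length the search fails
loudly rather than returning a weak split.

Second-space windows map to half-open TR windows by flooring
(t + lag)/TR at both bounds; unequal TR counts are reconciled by
truncating the longer window's end, and windows under 3 volumes are
rejected. Hemodynamic lag defaults to 0 s and is configurable. The AUC
intensity index is the trapezoidal integral of the trace over time
(scale-units × seconds).

## Group inference

Per-node condition contrasts are two-tailed paired t-tests (high minus
low), df = n−1, corrected with Benjamini–Hochberg across the nodes
tested (the family size can be set larger than the vector when only a
subset is adjusted). Zero-variance difference vectors yield a signed
infinite t with p → 0 and an explicit `zero_variance` flag instead of
NaN; these p's are floored at the smallest positive float for the BH
step. Edgewise contrasts apply the same paired t to every off-diagonal
dependency entry and keep edges j→i (direction of influence) at
p < 0.05 (uncorrected, by design — the edge graph is descriptive).

Behavior correlations are Pearson r between per-subject low-minus-high
influence differences and a behavioral measure, after listwise deletion
of missing values and exclusion of subjects deviating more than 3 SD
from the mean on either variable (applied two-sided). The low-minus-high
direction is the package-wide difference convention and is recorded in
output metadata.

### Specificity bootstrap

The specificity p-value compares an observed statistic with the same
statistic recomputed on k random size-matched node sets:
p = (#{random ≥ observed in the observed direction} + 1)/(k + 1). For
correlations, extremeness follows the observed sign. A `literal_eq5`
flag reproduces the historical counting rule (randoms ≤ observed),
which rewards unremarkable findings and exists only for reproduction;
the default implements the test's stated intent. The add-one smoothing
makes the null distribution of p uniform on {1,…,k+1}/(k+1), which the
tests confirm by a KS check. Random node sets are drawn from a
user-supplied pool of candidate time series; the packaged pool is
i.i.d. Gaussian (a synthetic stand-in for random gray-matter regions —
atlas-based voxel sampling is out of scope). The pipeline's group-level
background statistic is the **maximum** per-node paired t across each
random network, a conservative choice since the observed statistic is
also the network's most extreme node.

## Synthetic cohorts

`simulate_cohort` emulates the statistical structure the analysis
assumes, at the reference design's scale: 74 subjects, the 14-node
two-network roster, two conditions of 44 volumes at TR = 3 s (132-s
epochs). Per subject s and condition c the hub node is white Gaussian
h, and every other node is

    x_i = β_{s,c}·h + g·f_net(i) + ε_i

with f_net a per-network shared factor (weight g = 0.3), ε white
Gaussian noise (sd 1.0), and β_{s,c} = coupling_c + N(0, 0.10) drawn
independently per subject and condition (defaults coupling_low = 0.15,
coupling_high = 0.45). Influence is planted as common-cause coupling
precisely because d is a common-cause/mediation detector; there is no
claim of hemodynamic realism (an AR(1) noise option exists for stress
testing and is off by default — the Pearson-based method is the
target). Rating traces are smoothed 3→15 steps on the 21-level scale
(sigmoid rise of 8 s, jittered midpoint, sample noise sd 0.8), chosen so
a low plateau, a clear transition and a high plateau occupy the two
halves as in a low-to-high emotional induction. Behavior couples to the
planted effect as slope·(β_low − β_high) + noise, so with the default
negative slope the sample correlation between low-minus-high hub
influence and behavior is negative; the rating AUC inherits the same
coupling through a per-subject high-plateau shift. Everything is
reproducible byte-for-byte from the `CohortSpec.seed`.

What passing tests on these cohorts shows: the pipeline recovers planted
common-cause hierarchies, controls false positives on exchangeable
Gaussian nulls, and propagates behavior couplings of the planted form.
What it does not show: robustness to hemodynamic autocorrelation,
motion/physiological artifacts, non-Gaussian tails, or misspecified ROI
definitions — real-data properties the generator deliberately does not
model.

## Problem sizes in the validation suite

The test suite and acceptance script run at the study's own dimensions
where the property demands it (74 subjects × 14 nodes × 44 volumes for
calibration and recovery; 1000 null replicates in the suite, 500 in the
script; 500 oracle matrices; 100 behavior cohorts; 20-cohort recovery
grids), and at reduced cohort counts for smoke/unit paths. These sizes
are the package's validation design: large enough that binomial error
bands are tight relative to the margins being asserted.

## Known limitations

- First-order partialing only: influence through pairs of nodes jointly
  is not captured.
- The zeroing of negative d discards suppression effects by
  construction (sums would otherwise mix signs); negative influence is
  not interpretable in this framework.
- The edge graph uses uncorrected per-edge thresholds; treat it as
  descriptive, not inferential.
- Spherical-ROI extraction interprets centers in the volume's own
  world-space millimeters; no template-space conversion is attempted,
  and no preprocessing (motion correction, filtering, smoothing) is
  performed — inputs are assumed fully preprocessed.
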
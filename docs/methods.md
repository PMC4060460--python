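# Methods

This note documents the model, the parameter choices, the synthetic-data
generator and the numerical conventions used by `fuzzyrules`.

## Data model and preprocessing

Input is a genes × samples matrix of nonnegative linear-scale signals (as
produced by array summarization software), a boolean detection mask
("present calls"; only an explicit `P` counts, marginal `M` and absent `A`
do not), and a per-sample clinical label in {CG, OA, RA}. All processing is
per *study group* (one center's cohort, or a pooled cohort declared as its
own group): genes are kept only if present in every sample of the group
(`mode="all_probesets"` disables the filter), each sample is divided by its
median signal and log2-transformed. Normalizing per study group — rather
than batch-correcting pooled data — is the design that makes rule sets
transferable across centers: each center's samples are placed on their own
median-centered scale before any model is applied.

The median is taken over the retained (post-filter) panel by default;
`median_domain="all"` instead uses the full unfiltered array, since either
reading of "the median over all probe sets" is defensible. Even-count
medians are the midpoint of the two central values. Consequently the
per-sample median of the *linear* back-transformed values is exactly 1,
while the log2 median is 0 only up to the midpoint convention.

## Fuzzy discretization

Each gene is discretized independently with 1-D fuzzy C-means, c = 2
clusters, implemented in-package and vectorized across genes:

* fuzzifier m = 2 (the universal default; configurable). For c = 2 the
  membership of the high cluster reduces to
  u_high(y) = 1 / (1 + ((CT2 − y)/(y − CT1))^(2/(m−1))).
* deterministic initialization at the 25th/75th percentiles of the gene's
  values (falling back to min/max when the quartiles coincide); on bimodal
  data the converged centers are insensitive to the initialization, and the
  deterministic choice makes rule sets exactly reproducible.
* convergence when the largest center shift is below 1e-8, at most 300
  iterations. Batch fitting stops on the worst gene, so per-gene centers
  agree with an isolated fit to the tolerance, not to machine precision.
* zero-variance genes cannot be discretized; they are dropped before rule
  induction with a logged warning.

The *modified* membership M′ clips the FCM membership to hard assignment
outside the inter-center interval: M′_low = 1 below CT1, M′_high = 1 above
CT2, the FCM value in between. M′ is monotone in y and the pair always sums
to 1. A value exactly at a center receives hard membership for that
center's cluster (the limit of both the piecewise rule and the FCM
formula). Crisp assignment, used for support counting, is "high" iff
M′_high > 0.5; the tie at exactly 0.5 goes to "low" (deterministic,
affecting only samples at the membership crossing).

Cluster models are serialized (gene, CT1, CT2, m) so that test cohorts are
weighted with the *training* model — cross-center application logically
requires it, although test cohorts are normalized within their own group.

## Rule induction and the relevance index

All uniconditional rules (gene, low/high → class) are scored on the
training group. With supports n (samples), n_C (class C), n_P (premise
cluster), n_PC (both), and two-sided binomial confidence intervals at level
α — Clopper–Pearson by default; Wilson and normal-approximation intervals
are available via `ci_method` because the exact historical construction of
the index's intervals is not pinned down —

    RI = (L_cond − U_unc) / (1 − U_unc)   if L_cond > U_unc and U_unc < 1
    RI = L_cond − U_unc                   otherwise,

where [·, U_unc] is the interval for p(C) from (n_C, n) and [L_cond, ·] the
interval for p(C | premise) from (n_PC, n_P). A rule is retained iff
RI > 0; retained rules are ranked per class by descending RI, ties broken
by (gene id, level). RI is nondecreasing in n_PC and nonincreasing in α.
Intervals are tabulated per (denominator, count) and cached per (n, α,
method), which makes grid scans and permutation controls cheap.

**Level selection.** α starts at 0.95 and is reduced along a grid
(0.95 → 0.50, step 0.01) to the largest value at which every class present
in the data has more than three positive-RI rules; absent classes (a cohort
without controls) are exempt. The reduction is integral to the method, not
a convenience: in a 16-sample cohort whose majority class holds 10 samples,
even a *perfectly* class-pure premise has RI < 0 at α = 0.95, because the
unconditional interval of the majority class already reaches ≈ 0.85.

**Permuted-label control.** For each of `n_permutations` (default 100)
random non-identity label permutations, the largest grid level admitting at
least one positive-RI rule per present class is recorded; the maximum over
permutations should fall below the level used on the real labels. The
positivity condition is monotone along the grid, so each permutation is
resolved by bisection.

## Pruning

Pruning cuts each class's ranked list to a top-rank prefix; rank order is
never reshuffled. Per class with r_max > 0 the prefix length is constrained
to [4, 2·min_C(r_max)] (clipped to r_max; lists shorter than 4 are kept
whole with a warning; empty lists stay empty and do not enter the min).
The objective is lexicographic: training misclassifications first, then
total rule count, then the prefix vector (CG, OA, RA) as a deterministic
tie-break. The search is greedy coordinate descent starting from the
constraint-clipped full prefixes, taking the best single-class ±1 move
until none improves; on instances small enough for exhaustive enumeration
the greedy optimum matches the exhaustive one (oracle-tested on 100 random
instances). Vote totals for candidate prefixes are evaluated from
cumulative weight sums, so the search costs O(moves × samples).

## Prediction and evaluation

Each rule votes with weight W_rj = M′ of its cluster at the sample's
normalized expression of its gene; per-class weights are raw sums over the
(pruned) list — rule-count balance is handled by the pruning constraints,
not by averaging (`normalize_votes` exists but defaults off). The maximal
total wins; exact ties are flagged and broken by the fixed order
CG < OA < RA; all-zero samples are labelled `unclassified` and counted as
errors in every evaluation. A rule gene absent from a prediction panel
raises by default; the `"zero"` policy (weight 0, logged) is used for
cross-center application, where independently filtered panels need not
coincide.

Confusion matrices are predicted (rows) × true (columns). The six measures
use column conventions: sensitivities divide the diagonal cell by its true
column total; specificity for RA divides the non-RA classified predictions
in the CG and OA columns by those columns' total (symmetrically for OA);
overall specificity is the CG diagonal over the CG column and is undefined
without control samples; accuracy is the diagonal sum over n, identical to
Hits/n. Undefined measures are reported `n.a.`, never 0. Display rounding
is one decimal; internal values keep full precision — note a hit rate of
22/23 prints as 95.7.

Cross-center evaluation trains the full pipeline on one group and applies
it to each other group. Test samples whose true class has no rules in the
trained system cannot be recognized by design and are excluded from the
evaluation (e.g. control samples under a classifier trained without
controls), shrinking the test set accordingly.

Internal validation: leave-one-out CV refits clustering, induction and
pruning on each n−1 subset, holding α at the full-set selection (per-fold
re-selection would let fold size drive the level); bootstrap validation
(default B = 200, seeded) refits on resamples and scores out-of-bag
samples. The present-call panel is fixed once per group and not re-derived
per fold.

## Synthetic multi-center cohorts

The generator emulates a three-center arthritis cohort: centers with class
counts (CG/OA/RA) of 10/10/13, 10/10/10 and 0/6/10 by default, 2,000 genes,
and per-gene log2-Gaussian signals (log-normal on the linear scale, so the
log2 of median-normalized data is Gaussian — the simplest model with the
required bimodal structure). Defaults, all overridable:

* baseline level mu = 7 with gene-to-gene spread 1.0 (plausible log2
  microarray mid-range);
* markers: for each class, 5 "high" and 5 "low" genes; a (class c, high)
  marker draws class-c samples from mode mu + delta and all others from mu,
  with within-mode sd sigma; "low" swaps the mode assignment. Defaults
  delta = 2, sigma = 0.3;
* background genes: class-independent, within-gene sd 0.3;
* multiplicative scale effects on the linear scale: per-center log2 offset
  sd 0.2 and per-sample sd 0.1, mimicking lab and hybridization effects;
  both are exactly removed by median normalization;
* present calls: independent Bernoulli with p = 0.95; marker genes are
  present everywhere by default (`markers_always_present`), since the
  present-call filter keeps only all-present genes and the planted signal
  is meant to survive filtering — disable it to study signal loss.

Identical seeds give bit-identical cohorts. The generator does *not*
emulate probe-level data, correlated gene modules, class-imbalanced
dropout, or disease biology beyond class-dependent modes — so passing tests
demonstrate recovery of planted bimodal structure under scale and detection
noise, not performance on real tissue profiles.

### What marker recovery does and does not guarantee

With modes 4 within-mode sd apart, the crisp premise boundary lies ≈ 2 sd
from each mode, so each out-of-class sample enters the premise cluster with
probability ≈ 2.5%. Two or more such crossings (≈ 10–15% of marker genes in
a 30-sample cohort) push the Clopper–Pearson conditional lower bound below
the unconditional upper bound: those markers yield no rule even though the
*classifier* (voting over the surviving rules) still attains zero training
errors and ≳ 95% mean cross-center accuracy at that effect size. Complete
per-marker recovery holds from roughly the default effect size
(delta ≈ 6.7 sigma) upward. This is a property of the relevance index —
it demands near-pure conditional support — and is documented rather than
patched.

## Problem sizes used in the shipped tests

The test suite runs cohorts of 120–800 genes and the acceptance-level
simulation study uses 10 seeds × 3 centers × 600 genes with the class
compositions above; these sizes were chosen so the full suite completes in
well under a minute of CPU while every statistical check retains its power
(interval tables are exact, not asymptotic, at any n).
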
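# fuzzyrules

Rule-based classification of multi-center transcriptome profiles.

`fuzzyrules` discriminates clinical states — healthy controls (CG),
osteoarthritis (OA) and rheumatoid arthritis (RA) — from gene expression
profiles of synovial tissue using a transparent, rule-based classifier
instead of a black-box model or a differential-expression gene list. Each
decision rule reads *IF gene i is expressed low/high THEN class C*, so a
trained classifier is a short, auditable list of genes with direction of
regulation. The package is aimed at researchers working with multi-center
microarray or bulk expression cohorts who need classifiers that transfer
across centers without cross-center batch correction.

## Method

For each study group (center) independently:

1. **Preprocessing.** Keep probe sets detected ("present call") in every
   sample of the group, then normalize each sample by its median signal and
   take log2: *y<sub>ij</sub>* = log2(*x<sub>ij</sub>* / med<sub>j</sub>).
2. **Fuzzy discretization.** Per gene, fit a two-cluster fuzzy C-means
   model on *y<sub>i·</sub>*, giving centers *CT<sub>i1</sub>* <
   *CT<sub>i2</sub>* ("low"/"high"). A modified membership degree *M′* is
   hard (1/0) outside the interval [*CT<sub>i1</sub>*, *CT<sub>i2</sub>*]
   and the ordinary fuzzy C-means membership in between.
3. **Rule induction.** Enumerate all uniconditional rules
   (gene, low/high → class) and score each with the relevance index: the
   normalized gap between the two-sided binomial confidence interval of
   p(C | premise), from supports (*n<sub>PC</sub>*, *n<sub>P</sub>*), and
   that of p(C), from (*n<sub>C</sub>*, *n*):

   RI = (L<sub>cond</sub> − U<sub>unc</sub>) / (1 − U<sub>unc</sub>) when the
   gap is positive, else the (non-positive) raw gap. Rules with RI > 0 are
   kept and ranked per class. The confidence level starts at 0.95 and is
   reduced on a grid until every class present in the data has more than
   three rules; a permuted-label control verifies that the level used
   exceeds what random class assignments can achieve.
4. **Pruning.** Each ranked list is cut to a top-rank prefix by greedy
   search minimizing (training errors, rule count), with at least 4 rules
   per class (where available) and at most twice the smallest nonempty
   primary list — balanced rule sets by construction.
5. **Prediction.** For a new sample, every rule votes with weight
   *W<sub>rj</sub>* = *M′* of its cluster at the sample's normalized
   expression; per-class weights are summed and the class with the maximal
   total wins (defuzzification). Samples with all-zero weights are reported
   as unclassifiable, never silently assigned.
6. **Evaluation.** Predicted × true confusion matrices and six quality
   measures (per-class sensitivity and specificity, overall specificity,
   accuracy) with column-based formulas that degrade gracefully for cohorts
   without controls.

## Worked example

Train on one simulated center and test on the two others:

```python
import fuzzyrules as fr

spec = fr.CohortSpec(seed=1, n_genes=2000)       # three centers, planted markers
datasets, truth = fr.generate_cohorts(spec)
pp = [fr.preprocess(d) for d in datasets]         # per-center filter + normalize

clf = fr.fit_study_group(pp[1])                   # train on the 10/10/10 center
print(clf.alpha_, clf.r_max_, clf.r_opt_)
# 0.95 {'CG': 10, 'OA': 10, 'RA': 10} {'CG': 4, 'OA': 4, 'RA': 4}

report = fr.cross_center(pp[1], [pp[0], pp[2]], clf=clf)
print(report.as_table())
```

```
                     Berlin->Jena Berlin->Leipzig
rules_CG                      4.0               4
rules_OA                      4.0               4
rules_RA                      4.0               4
sensitivity_RA              100.0           100.0
sensitivity_OA              100.0           100.0
specificity_RA              100.0           100.0
specificity_OA              100.0           100.0
overall_specificity         100.0            n.a.
accuracy                    100.0           100.0
test_samples                 33.0              16
hits_total                   33.0              16
errors_total                  0.0               0
```

The classifier kept the default confidence level 0.95, induced 10 rules per
class and pruned each list to its top 4. Applied to the other two centers it
classifies every sample correctly; the third center has no control samples,
so overall specificity (a control-column quantity) is reported `n.a.` there.

`FuzzyRuleClassifier` is a scikit-learn estimator (`fit(X, y)` on a
samples × genes matrix of normalized values, `predict`,
`decision_function`, `get_params`/`set_params`, clonable, pipeline-safe);
`predict_result` exposes the full per-rule weight audit trail. The same
pipeline is scriptable from the shell:

```bash
fuzzyrules simulate --outdir data --seed 1
fuzzyrules train --datadir data --center Berlin --outdir model
fuzzyrules predict --ruleset model/Berlin_ruleset.json \
    --clusters model/Berlin_clusters.json --datadir data --center Jena \
    --out predictions.csv
fuzzyrules crossval --datadir data --train Berlin
```

## Limitations

Rule induction demands near-pure conditional support: markers whose premise
cluster captures even two out-of-class samples can fall below the relevance
threshold in cohorts of 16–33 samples, so weak markers (modes ≲ 4 within-mode
standard deviations apart) are not guaranteed individual recovery even when
the ensemble classifies perfectly. See `docs/methods.md` for the full model
description, parameter rationale and numerical conventions.
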
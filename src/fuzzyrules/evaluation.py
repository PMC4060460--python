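"""Confusion matrices, quality metrics and cross-center validation.

The confusion matrix is laid out predicted (rows) x true clinical status
(columns). From it, six quality measures are computed with column-based
formulas. Writing TN for the correctly-predicted controls (the CG/CG cell):

* sensitivity for RA = TP_RA / (TP_RA + FN_RA + FP_OA), all from the true-RA
  column (FN_RA = RA samples predicted CG, FP_OA = RA samples predicted OA);
* sensitivity for OA symmetric, from the true-OA column;
* specificity for RA = TN_RA / (TN_RA + FP_RA), where TN_RA collects every
  non-RA prediction in the CG and OA columns (TN + FN_OA + TP_OA + the CG
  samples predicted OA) and FP_RA the RA predictions in those two columns;
* specificity for OA symmetric (non-OA predictions in the CG and RA columns);
* overall specificity = TN / (TN + FP_OA + FP_RA), CG column only — defined
  only when control samples exist, reported "n.a." otherwise;
* accuracy = (TN + TP_OA + TP_RA) / n, identical to Hits / n.

In a cohort without controls the specificity formulas degrade gracefully:
FP_RA is then simply the OA samples misclassified as RA, and vice versa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import UNCLASSIFIED, FuzzyRuleClassifier, PredictionResult
from .dataset import CLASSES, ExpressionDataset
from .config import PipelineConfig

logger = logging.getLogger(__name__)

METRIC_NAMES = (
    "sensitivity_RA",
    "sensitivity_OA",
    "specificity_RA",
    "specificity_OA",
    "overall_specificity",
    "accuracy",
)


@dataclass
class ConfusionMatrix:
    """Predicted x true count matrix over the three clinical states."""

    table: pd.DataFrame  # rows: predicted (+ optional "unclassified"); cols: true

    @classmethod
    def from_predictions(cls, predictions: pd.Series, truth: pd.Series) -> "ConfusionMatrix":
        truth = truth.loc[predictions.index]
        bad = set(truth) - set(CLASSES)
        if bad:
            raise ValueError(f"unknown true label(s) {sorted(bad)!r}")
        bad = set(predictions) - set(CLASSES) - {UNCLASSIFIED}
        if bad:
            raise ValueError(f"unknown predicted label(s) {sorted(bad)!r}")
        cols = [c for c in CLASSES if c in set(truth)]
        rows = list(CLASSES) + ([UNCLASSIFIED] if (predictions == UNCLASSIFIED).any() else [])
        if (predictions == UNCLASSIFIED).any():
            logger.warning(
                "%d unclassifiable sample(s) counted as errors",
                int((predictions == UNCLASSIFIED).sum()),
            )
        table = pd.crosstab(predictions, truth).reindex(index=rows, columns=cols, fill_value=0)
        table.index.name = "predicted"
        table.columns.name = "true"
        return cls(table)

    def cell(self, predicted: str, true: str) -> int:
        if predicted in self.table.index and true in self.table.columns:
            return int(self.table.loc[predicted, true])
        return 0

    @property
    def n(self) -> int:
        return int(self.table.to_numpy().sum())

    @property
    def hits(self) -> int:
        return sum(self.cell(c, c) for c in CLASSES)

    @property
    def errors(self) -> int:
        return self.n - self.hits

    def hits_for(self, c: str) -> int:
        return self.cell(c, c)

    def errors_for(self, c: str) -> int:
        if c not in self.table.columns:
            return 0
        return int(self.table[c].sum()) - self.cell(c, c)

    def column_total(self, c: str) -> int:
        return int(self.table[c].sum()) if c in self.table.columns else 0


@dataclass
class QualityMetrics:
    """The six quality measures, as percentages (None where undefined)."""

    sensitivity_RA: float | None
    sensitivity_OA: float | None
    specificity_RA: float | None
    specificity_OA: float | None
    overall_specificity: float | None
    accuracy: float | None

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in METRIC_NAMES}

    def rounded(self, decimals: int = 1) -> dict:
        """Display form: one decimal, "n.a." for undefined values."""
        out = {}
        for k, v in self.as_dict().items():
            out[k] = "n.a." if v is None else float(np.round(v, decimals))
        return out


def _ratio(num: int, den: int) -> float | None:
    if den == 0:
        return None
    return 100.0 * num / den


def compute_metrics(cm: ConfusionMatrix) -> QualityMetrics:
    """All six measures from a confusion matrix (column conventions above)."""
    tn = cm.cell("CG", "CG")
    tp_ra, tp_oa = cm.cell("RA", "RA"), cm.cell("OA", "OA")

    sens_ra = _ratio(tp_ra, cm.column_total("RA"))
    sens_oa = _ratio(tp_oa, cm.column_total("OA"))

    # specificity for RA: CG and OA columns, non-RA (classified) predictions
    # vs RA predictions; unclassifiable samples stay in the denominator
    tn_ra = sum(cm.cell(p, t) for t in ("CG", "OA") for p in ("CG", "OA"))
    den_ra = cm.column_total("CG") + cm.column_total("OA")
    spec_ra = _ratio(tn_ra, den_ra)

    tn_oa = sum(cm.cell(p, t) for t in ("CG", "RA") for p in ("CG", "RA"))
    den_oa = cm.column_total("CG") + cm.column_total("RA")
    spec_oa = _ratio(tn_oa, den_oa)

    overall = _ratio(tn, cm.column_total("CG")) if "CG" in cm.table.columns else None
    accuracy = _ratio(tn + tp_oa + tp_ra, cm.n)
    return QualityMetrics(sens_ra, sens_oa, spec_ra, spec_oa, overall, accuracy)


def confusion(predictions: pd.Series, truth: pd.Series) -> ConfusionMatrix:
    """Build the predicted x true confusion matrix."""
    return ConfusionMatrix.from_predictions(pd.Series(predictions), pd.Series(truth))


# ---------------------------------------------------------------------------
# pipeline orchestration
# ---------------------------------------------------------------------------

def fit_study_group(
    ds: ExpressionDataset, config: PipelineConfig | None = None
) -> FuzzyRuleClassifier:
    """Train the full pipeline (clustering, induction, pruning) on one group.

    ``ds`` must already be preprocessed (filtered and normalized within its
    own study group).
    """
    if not ds.normalized:
        raise ValueError("dataset must be preprocessed (normalized) before training")
    config = config or PipelineConfig()
    clf = FuzzyRuleClassifier(study_group=ds.center, **config.classifier_kwargs())
    return clf.fit(ds.values.T, ds.labels)


@dataclass
class TestOutcome:
    """One (train -> test) evaluation in a cross-center report."""

    train: str
    test: str
    n_test: int
    n_excluded: int
    rule_counts: dict[str, int]
    cm: ConfusionMatrix
    metrics: QualityMetrics
    prediction: PredictionResult = field(repr=False, default=None)


@dataclass
class EvaluationReport:
    """Cross-center evaluation results plus summary statistics."""

    outcomes: list[TestOutcome]

    def as_table(self, decimals: int = 1) -> pd.DataFrame:
        """Assessment table: one column per (train -> test) pair."""
        cols = {}
        for o in self.outcomes:
            col = {f"rules_{c}": o.rule_counts[c] for c in CLASSES}
            col.update(o.metrics.rounded(decimals))
            col["test_samples"] = o.n_test
            for c in CLASSES:
                col[f"hits_{c}"] = o.cm.hits_for(c)
            col["hits_total"] = o.cm.hits
            for c in CLASSES:
                col[f"errors_{c}"] = o.cm.errors_for(c)
            col["errors_total"] = o.cm.errors
            cols[f"{o.train}->{o.test}"] = col
        return pd.DataFrame(cols)

    def summary(self) -> pd.DataFrame:
        """Mean / min / max of each metric over the tests (ignoring n.a.)."""
        rows = {}
        for name in METRIC_NAMES:
            vals = [getattr(o.metrics, name) for o in self.outcomes]
            vals = [v for v in vals if v is not None]
            rows[name] = {
                "mean": float(np.mean(vals)) if vals else np.nan,
                "min": float(np.min(vals)) if vals else np.nan,
                "max": float(np.max(vals)) if vals else np.nan,
                "n_tests": len(vals),
            }
        return pd.DataFrame(rows).T


def evaluate_on(
    clf: FuzzyRuleClassifier,
    test_ds: ExpressionDataset,
    missing_gene: str = "zero",
    exclude_uncovered_classes: bool = True,
) -> TestOutcome:
    """Apply a trained classifier to an (independently preprocessed) test set.

    Test samples whose true class has no rules in the trained system cannot
    be recognized by design; with ``exclude_uncovered_classes`` (default)
    they are dropped from the evaluation — e.g. control samples when the
    training cohort contained no controls — mirroring how cohorts without a
    class are assessed.
    """
    if not test_ds.normalized:
        raise ValueError("test dataset must be preprocessed (normalized) first")
    system = clf.rule_system_
    covered = {c for c in CLASSES if len(system.active_rules(c)) > 0}
    labels = test_ds.labels
    keep = labels.index if not exclude_uncovered_classes else labels.index[labels.isin(covered)]
    n_excluded = len(labels) - len(keep)
    if n_excluded:
        logger.warning(
            "excluding %d test sample(s) of class(es) without rules in %r",
            n_excluded, clf.study_group,
        )
    values = test_ds.values[list(keep)]
    old_missing = clf.missing_gene
    clf.missing_gene = missing_gene
    try:
        result = clf.predict_result(values.T)
    finally:
        clf.missing_gene = old_missing
    cm = confusion(result.predictions, labels.loc[keep])
    return TestOutcome(
        train=clf.study_group,
        test=test_ds.center,
        n_test=len(keep),
        n_excluded=n_excluded,
        rule_counts={c: len(system.active_rules(c)) for c in CLASSES},
        cm=cm,
        metrics=compute_metrics(cm),
        prediction=result,
    )


def cross_center(
    train_ds: ExpressionDataset,
    test_ds_list: Sequence[ExpressionDataset],
    config: PipelineConfig | None = None,
    missing_gene: str = "zero",
    exclude_uncovered_classes: bool = True,
    clf: FuzzyRuleClassifier | None = None,
) -> EvaluationReport:
    """Train on one study group, evaluate on each test group.

    Passing the training set itself in ``test_ds_list`` yields the
    training re-application mode. All datasets must have been preprocessed
    independently (per study group).
    """
    if clf is None:
        clf = fit_study_group(train_ds, config)
    outcomes = [
        evaluate_on(clf, t, missing_gene=missing_gene,
                    exclude_uncovered_classes=exclude_uncovered_classes)
        for t in test_ds_list
    ]
    return EvaluationReport(outcomes)


def all_pairs_cross_center(
    datasets: Sequence[ExpressionDataset],
    config: PipelineConfig | None = None,
    missing_gene: str = "zero",
) -> EvaluationReport:
    """Every center trained once, applied to every other center."""
    outcomes = []
    for train in datasets:
        clf = fit_study_group(train, config)
        for test in datasets:
            if test.center == train.center:
                continue
            outcomes.append(evaluate_on(clf, test, missing_gene=missing_gene))
    return EvaluationReport(outcomes)


# ---------------------------------------------------------------------------
# internal validation
# ---------------------------------------------------------------------------

def _refit_subset(
    ds: ExpressionDataset,
    sample_ids: Sequence[str],
    config: PipelineConfig,
    alpha: float,
) -> FuzzyRuleClassifier:
    """Retrain the pipeline on a subset/resample of the samples.

    ``sample_ids`` may contain repeats (bootstrap); columns are de-duplicated
    by suffixing. The confidence level is held fixed at ``alpha``.
    """
    ids = list(sample_ids)
    uniq = [f"{s}#{k}" for k, s in enumerate(ids)]
    values = ds.values[ids].copy()
    values.columns = uniq
    labels = pd.Series([ds.labels[s] for s in ids], index=uniq)
    kwargs = config.classifier_kwargs()
    kwargs["alpha"] = alpha
    clf = FuzzyRuleClassifier(study_group=ds.center, **kwargs)
    return clf.fit(values.T, labels)


def loocv(ds: ExpressionDataset, config: PipelineConfig | None = None) -> dict:
    """Leave-one-out cross-validation of the full pipeline.

    The confidence level is selected once on the full set and held fixed in
    every fold (re-selecting per fold would let fold size drive the level);
    clustering, induction and pruning are refitted per fold. Folds whose
    training part lacks a class are flagged; that class simply obtains no
    rules there, as in induction.
    """
    config = config or PipelineConfig()
    full = fit_study_group(ds, config)
    alpha = full.alpha_
    preds, flagged = {}, []
    for s in ds.sample_ids:
        rest = [x for x in ds.sample_ids if x != s]
        if ds.labels[s] not in set(ds.labels[rest]):
            flagged.append(s)
        clf = _refit_subset(ds, rest, config, alpha)
        old = clf.missing_gene
        clf.missing_gene = "zero"
        preds[s] = clf.predict(ds.values[[s]].T)[0]
        clf.missing_gene = old
    preds = pd.Series(preds).loc[ds.sample_ids]
    errors = int(((preds != ds.labels) | (preds == UNCLASSIFIED)).sum())
    return {
        "alpha": alpha,
        "predictions": preds,
        "errors": errors,
        "error_rate": errors / ds.n_samples,
        "flagged_folds": flagged,
    }


def bootstrap_validation(
    ds: ExpressionDataset,
    B: int = 200,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> dict:
    """Bootstrap with out-of-bag prediction.

    Each replicate resamples the cohort with replacement, refits the
    pipeline (fixed confidence level from the full-set selection) and
    predicts the out-of-bag samples; the reported error rate averages the
    per-replicate out-of-bag error.
    """
    config = config or PipelineConfig()
    full = fit_study_group(ds, config)
    alpha = full.alpha_
    rng = np.random.default_rng(seed)
    ids = np.array(ds.sample_ids)
    n = len(ids)
    rates = []
    for _ in range(B):
        take = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), take)
        if len(oob) == 0:
            continue
        clf = _refit_subset(ds, ids[take], config, alpha)
        clf.missing_gene = "zero"
        p = pd.Series(clf.predict(ds.values[ids[oob]].T), index=ids[oob])
        truth = ds.labels.loc[ids[oob]]
        rates.append(float(((p != truth) | (p == UNCLASSIFIED)).mean()))
    return {
        "alpha": alpha,
        "B": B,
        "oob_error_rate": float(np.mean(rates)) if rates else np.nan,
        "per_replicate": rates,
    }
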
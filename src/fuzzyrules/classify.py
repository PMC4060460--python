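"""Applying rule systems to samples: fuzzy-vote prediction.

Each rule contributes its modified membership degree, evaluated at the
sample's normalized expression of the rule's gene, as a weight in [0, 1].
Per sample, weights are summed over the rules of each conclusion (raw sums,
not means — the rule sets are balanced during pruning instead) and the
conclusion with the highest total wins ("defuzzification"). Ties are
flagged and broken toward the fixed class order CG < OA < RA; a sample with
all three totals zero is unclassifiable and reported as such, never
silently assigned.

:class:`FuzzyRuleClassifier` wraps the whole training pipeline (per-gene
fuzzy C-means, rule induction with automatic confidence-level selection,
constrained pruning) behind the scikit-learn estimator API: ``fit`` on a
samples x genes matrix of *normalized* log2 values, then ``predict`` /
``decision_function`` on new samples normalized within their own study
group but weighted with the training cluster models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .clustering import HIGH, GeneClusterModels
from .dataset import CLASSES
from .rules import (
    DEFAULT_ALPHA_GRID,
    MIN_RULES_PER_CONCLUSION,
    Rule,
    RuleSystem,
    alpha_random_control,
    enumerate_rules,
    select_alpha,
)

logger = logging.getLogger(__name__)

#: label reported for samples whose three vote totals are all zero
UNCLASSIFIED = "unclassified"


class MissingGeneError(KeyError):
    """A rule's gene is absent from the sample panel being classified."""


@dataclass
class PredictionResult:
    """Predictions plus the full per-rule weight audit trail.

    Attributes
    ----------
    weights : pandas.DataFrame
        Per-rule membership weights, rows indexed by
        (conclusion, rank, gene, level), columns = samples.
    totals : pandas.DataFrame
        Aggregated vote weight per (sample, conclusion); samples x 3.
    predictions : pandas.Series
        Winning conclusion per sample, or :data:`UNCLASSIFIED`.
    tie : pandas.Series of bool
        True where two or more conclusions share the maximal weight.
    """

    weights: pd.DataFrame
    totals: pd.DataFrame
    predictions: pd.Series
    tie: pd.Series

    @property
    def unclassifiable(self) -> pd.Series:
        return self.predictions == UNCLASSIFIED


def rule_weight(rule: Rule, models: GeneClusterModels, y_profile, missing: str = "error") -> float:
    """Membership weight of one rule for one sample profile.

    ``y_profile`` maps gene id -> normalized value (Series or mapping).
    """
    if rule.gene not in models:
        raise MissingGeneError(f"no cluster model for gene {rule.gene!r}")
    try:
        y = y_profile[rule.gene]
    except KeyError:
        if missing == "zero":
            logger.warning("gene %r missing from sample panel; weight set to 0", rule.gene)
            return 0.0
        raise MissingGeneError(f"gene {rule.gene!r} missing from the sample's panel") from None
    lo, hi = models[rule.gene].modified_membership(float(y))
    return hi if rule.level == HIGH else lo


def weight_matrix(
    rules: list[Rule],
    models: GeneClusterModels,
    values: pd.DataFrame,
    missing: str = "error",
) -> pd.DataFrame:
    """Vectorized rule x sample weight matrix for a list of rules.

    ``values`` is genes x samples (normalized). Rows are indexed by
    (conclusion, rank, gene, level) in the given rule order.
    """
    if not rules:
        return pd.DataFrame(
            np.zeros((0, values.shape[1])),
            index=pd.MultiIndex.from_arrays([[], [], [], []],
                                            names=["conclusion", "rank", "gene", "level"]),
            columns=values.columns,
        )
    genes = [r.gene for r in rules]
    missing_genes = sorted({g for g in genes if g not in values.index})
    if missing_genes:
        if missing != "zero":
            raise MissingGeneError(
                f"gene(s) missing from the sample panel: {missing_genes[:5]}"
                + ("..." if len(missing_genes) > 5 else "")
            )
        logger.warning(
            "%d rule gene(s) missing from the sample panel; weights set to 0: %s",
            len(missing_genes), missing_genes[:5],
        )
    present_genes = [g for g in dict.fromkeys(genes) if g in values.index]
    sub_models = GeneClusterModels(models.centers.loc[present_genes], m=models.m)
    mh = sub_models.membership_high(values.loc[present_genes])  # unique genes x samples

    W = np.zeros((len(rules), values.shape[1]))
    for i, r in enumerate(rules):
        if r.gene in mh.index:
            row = mh.loc[r.gene].to_numpy()
            W[i] = row if r.level == HIGH else 1.0 - row
    index = pd.MultiIndex.from_tuples(
        [(r.conclusion, r.rank, r.gene, r.level) for r in rules],
        names=["conclusion", "rank", "gene", "level"],
    )
    return pd.DataFrame(W, index=index, columns=values.columns)


def predict_samples(
    system: RuleSystem,
    models: GeneClusterModels,
    values: pd.DataFrame,
    use_pruned: bool = True,
    normalize_votes: bool = False,
    missing: str = "error",
) -> PredictionResult:
    """Apply a rule system to a genes x samples matrix of normalized values."""
    rules = [
        r
        for c in CLASSES
        for r in (system.active_rules(c) if use_pruned else system.rules.get(c, []))
    ]
    W = weight_matrix(rules, models, values, missing=missing)
    totals = pd.DataFrame(0.0, index=values.columns, columns=list(CLASSES))
    for c in CLASSES:
        if c in W.index.get_level_values("conclusion"):
            block = W.xs(c, level="conclusion")
            agg = block.sum(axis=0)
            if normalize_votes and len(block):
                agg = agg / len(block)
            totals[c] = agg
    arr = totals.to_numpy()
    best = arr.max(axis=1)
    pred_idx = arr.argmax(axis=1)  # first max -> CG < OA < RA tie order
    tie = (arr == best[:, None]).sum(axis=1) > 1
    preds = np.array(CLASSES, dtype=object)[pred_idx]
    preds[best == 0.0] = UNCLASSIFIED
    return PredictionResult(
        weights=W,
        totals=totals,
        predictions=pd.Series(preds, index=values.columns, name="prediction"),
        tie=pd.Series(tie, index=values.columns, name="tie"),
    )


class FuzzyRuleClassifier(ClassifierMixin, BaseEstimator):
    """Rule-based transcriptome classifier with fuzzy discretization.

    Parameters
    ----------
    alpha : float or None
        Confidence level for the relevance-index intervals. ``None`` (the
        default) selects the largest level on ``alpha_grid`` at which every
        class present in the training data obtains more than
        ``min_rules_for_alpha`` positive-RI rules.
    alpha_grid : sequence of float
        Descending candidate levels (default 0.95 .. 0.50, step 0.01).
    m : float
        Fuzzy C-means fuzzifier (> 1).
    ci_method : str
        Binomial interval construction: ``clopper_pearson`` (default),
        ``wilson`` or ``normal``.
    prune : bool
        Reduce each ranked rule list to an optimized rank prefix (default
        True).
    min_rules, max_rules_factor : int
        Pruning constraints: at least ``min_rules`` rules per conclusion
        (where available) and at most ``max_rules_factor`` times the
        smallest nonempty primary list.
    normalize_votes : bool
        Divide vote totals by rule-list length. Off by default: rule counts
        are balanced by pruning instead.
    missing_gene : str
        Policy when a rule's gene is absent from a prediction panel:
        ``"error"`` (default) or ``"zero"``.
    random_control : bool
        After fitting, run the permuted-label control for the selected
        level (result in ``random_control_``).
    random_state : int or None
        Seed for the permutation control.

    Attributes
    ----------
    classes_ : ndarray
        Classes seen during fit.
    models_ : GeneClusterModels
        Per-gene two-cluster models.
    rule_system_ : RuleSystem
        Ranked (and, if requested, pruned) rule lists.
    alpha_ : float
        Confidence level actually used.
    """

    def __init__(
        self,
        alpha: float | None = None,
        alpha_grid=DEFAULT_ALPHA_GRID,
        m: float = 2.0,
        fcm_tol: float = 1e-8,
        fcm_max_iter: int = 300,
        ci_method: str = "clopper_pearson",
        prune: bool = True,
        min_rules: int = 4,
        max_rules_factor: int = 2,
        min_rules_for_alpha: int = MIN_RULES_PER_CONCLUSION,
        normalize_votes: bool = False,
        missing_gene: str = "error",
        random_control: bool = False,
        n_permutations: int = 100,
        random_state: int | None = 0,
        study_group: str = "train",
    ):
        self.alpha = alpha
        self.alpha_grid = alpha_grid
        self.m = m
        self.fcm_tol = fcm_tol
        self.fcm_max_iter = fcm_max_iter
        self.ci_method = ci_method
        self.prune = prune
        self.min_rules = min_rules
        self.max_rules_factor = max_rules_factor
        self.min_rules_for_alpha = min_rules_for_alpha
        self.normalize_votes = normalize_votes
        self.missing_gene = missing_gene
        self.random_control = random_control
        self.n_permutations = n_permutations
        self.random_state = random_state
        self.study_group = study_group

    # -- helpers ------------------------------------------------------
    def _to_values(self, X) -> pd.DataFrame:
        """samples x genes input -> genes x samples DataFrame."""
        if isinstance(X, pd.DataFrame):
            return X.T
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D samples x genes matrix")
        genes = getattr(self, "feature_names_in_", None)
        if genes is None or len(genes) != X.shape[1]:
            genes = [f"g{i}" for i in range(X.shape[1])]
        return pd.DataFrame(X.T, index=genes)

    # -- estimator API ------------------------------------------------
    def fit(self, X, y):
        from .pruning import PruneConstraints, prune as prune_system  # local: avoids cycle

        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim != 2:
                raise ValueError("expected a 2-D samples x genes matrix")
        self.n_features_in_ = X.shape[1]
        values = self._to_values(X)
        y = pd.Series(np.asarray(y, dtype=object), index=values.columns)
        unknown = set(y) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown class label(s) {sorted(unknown)!r}; expected {CLASSES}")
        if len(y) != values.shape[1]:
            raise ValueError("X and y have inconsistent sample counts")
        self.classes_ = np.array([c for c in CLASSES if c in set(y)], dtype=object)

        self.models_ = GeneClusterModels.fit(
            values, m=self.m, tol=self.fcm_tol, max_iter=self.fcm_max_iter
        )
        if self.alpha is None:
            self.alpha_ = select_alpha(
                values, y, self.models_,
                alpha_grid=self.alpha_grid,
                ci_method=self.ci_method,
                min_rules=self.min_rules_for_alpha,
            )
        else:
            self.alpha_ = float(self.alpha)
        system = enumerate_rules(
            values, y, self.models_,
            alpha=self.alpha_, ci_method=self.ci_method, study_group=self.study_group,
        )
        if self.random_control:
            ctrl = alpha_random_control(
                values, y, self.models_, self.alpha_,
                alpha_grid=self.alpha_grid, ci_method=self.ci_method,
                n_permutations=self.n_permutations, seed=self.random_state,
            )
            system.alpha_random = ctrl.alpha_random
            self.random_control_ = ctrl
        if self.prune:
            system = prune_system(
                system, values, y, self.models_,
                constraints=PruneConstraints(self.min_rules, self.max_rules_factor),
                normalize_votes=self.normalize_votes,
            )
        self.rule_system_ = system
        self.r_max_ = system.r_max_all
        self.r_opt_ = dict(system.r_opt) if system.r_opt is not None else None
        return self

    def predict_result(self, X) -> PredictionResult:
        """Full prediction audit (per-rule weights, totals, ties)."""
        check_is_fitted(self, "rule_system_")
        values = self._to_values(X)
        return predict_samples(
            self.rule_system_, self.models_, values,
            normalize_votes=self.normalize_votes, missing=self.missing_gene,
        )

    def decision_function(self, X) -> np.ndarray:
        """Aggregated vote weights, one column per class in CG/OA/RA order."""
        return self.predict_result(X).totals.to_numpy()

    def predict(self, X) -> np.ndarray:
        """Predicted class per sample (:data:`UNCLASSIFIED` if all votes are 0)."""
        return self.predict_result(X).predictions.to_numpy()
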
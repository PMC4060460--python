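"""Constrained greedy pruning of ranked rule sets.

Pruning cuts each conclusion's ranked rule list down to a top-rank prefix
(the rank order is never reshuffled), jointly choosing the three prefix
lengths to minimize first the number of training misclassifications
("Errors") and then the total rule count. Constraints keep the sets
balanced: each conclusion keeps at least ``min_rules`` rules (or its whole
list, if shorter) and at most ``max_rules_factor`` times the smallest
nonempty primary list. Conclusions with no rules at all are exempt and do
not enter the upper-bound minimum.

The greedy schedule starts from the constraint-clipped full prefixes and
repeatedly takes the best single-conclusion prefix increment/decrement
until no move improves the lexicographic objective
(errors, total rules, prefix vector). On small instances this matches
exhaustive search over all feasible prefix combinations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .classify import UNCLASSIFIED, predict_samples, weight_matrix
from .clustering import GeneClusterModels
from .dataset import CLASSES
from .rules import RuleSystem

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PruneConstraints:
    """Balance constraints on the pruned prefix lengths."""

    min_rules: int = 4
    max_rules_factor: int = 2

    def bounds(self, r_max: dict[str, int]) -> dict[str, tuple[int, int]]:
        """Feasible (lo, hi) prefix range per conclusion.

        Empty lists stay empty; lists shorter than ``min_rules`` are kept
        whole (constraint relaxed, logged).
        """
        nonzero = [v for v in r_max.values() if v > 0]
        cap = self.max_rules_factor * min(nonzero) if nonzero else 0
        out: dict[str, tuple[int, int]] = {}
        for c, rm in r_max.items():
            if rm == 0:
                out[c] = (0, 0)
            elif rm < self.min_rules:
                logger.warning(
                    "conclusion %s has only %d primary rule(s) (< %d); keeping all",
                    c, rm, self.min_rules,
                )
                out[c] = (rm, rm)
            else:
                lo = self.min_rules
                hi = min(rm, max(lo, cap))
                out[c] = (lo, hi)
        return out


def _prediction_errors(cum: dict[str, np.ndarray], config: tuple[int, ...], lab_idx: np.ndarray) -> int:
    """Errors for a prefix configuration, from per-conclusion cumulative weights.

    ``cum[c]`` has shape (r_max_c + 1, n): row k = vote totals using the
    top-k rules. Argmax takes the first maximum (class order CG < OA < RA);
    all-zero samples are unclassifiable and count as errors.
    """
    totals = np.stack([cum[c][k] for c, k in zip(CLASSES, config)])  # (3, n)
    pred = totals.argmax(axis=0)
    allzero = totals.max(axis=0) == 0.0
    return int(np.sum((pred != lab_idx) | allzero))


def _cumulative_weights(
    system: RuleSystem, values: pd.DataFrame, models: GeneClusterModels
) -> dict[str, np.ndarray]:
    n = values.shape[1]
    cum: dict[str, np.ndarray] = {}
    for c in CLASSES:
        rules = system.rules.get(c, [])
        W = weight_matrix(rules, models, values).to_numpy()
        cum[c] = np.vstack([np.zeros((1, n)), np.cumsum(W, axis=0)])
    return cum


def prune(
    system: RuleSystem,
    values: pd.DataFrame,
    labels: pd.Series,
    models: GeneClusterModels,
    constraints: PruneConstraints = PruneConstraints(),
    normalize_votes: bool = False,
) -> RuleSystem:
    """Greedy search for the optimal prefix lengths on the training set.

    ``values``/``labels`` must be the training data the system was induced
    from. Returns a copy of the system with ``r_opt`` set.
    """
    bounds = constraints.bounds(system.r_max_all)
    lab_idx = np.asarray([CLASSES.index(l) for l in labels.loc[values.columns]])
    cum = _cumulative_weights(system, values, models)
    if normalize_votes:
        for c in CLASSES:
            k = np.arange(cum[c].shape[0])[:, None]
            cum[c] = cum[c] / np.maximum(k, 1)

    def objective(config: tuple[int, ...]):
        return (_prediction_errors(cum, config, lab_idx), sum(config), config)

    current = tuple(bounds[c][1] for c in CLASSES)
    best = objective(current)
    while True:
        candidates = []
        for i, c in enumerate(CLASSES):
            lo, hi = bounds[c]
            for step in (-1, +1):
                k = current[i] + step
                if lo <= k <= hi:
                    cand = current[:i] + (k,) + current[i + 1 :]
                    candidates.append(objective(cand))
        if not candidates:
            break
        winner = min(candidates)
        if winner < best:
            best = winner
            current = winner[2]
        else:
            break
    return replace(system, r_opt={c: k for c, k in zip(CLASSES, current)})


def exhaustive_prune(
    system: RuleSystem,
    values: pd.DataFrame,
    labels: pd.Series,
    models: GeneClusterModels,
    constraints: PruneConstraints = PruneConstraints(),
):
    """Exhaustive search over all feasible prefix combinations.

    Intended for small instances (oracle for the greedy search); returns
    (pruned system, objective value).
    """
    bounds = constraints.bounds(system.r_max_all)
    lab_idx = np.asarray([CLASSES.index(l) for l in labels.loc[values.columns]])
    cum = _cumulative_weights(system, values, models)
    best = None
    for k0 in range(bounds[CLASSES[0]][0], bounds[CLASSES[0]][1] + 1):
        for k1 in range(bounds[CLASSES[1]][0], bounds[CLASSES[1]][1] + 1):
            for k2 in range(bounds[CLASSES[2]][0], bounds[CLASSES[2]][1] + 1):
                config = (k0, k1, k2)
                obj = (_prediction_errors(cum, config, lab_idx), sum(config), config)
                if best is None or obj < best:
                    best = obj
    return replace(system, r_opt={c: k for c, k in zip(CLASSES, best[2])}), best


def training_errors(
    system: RuleSystem,
    values: pd.DataFrame,
    labels: pd.Series,
    models: GeneClusterModels,
    use_pruned: bool = True,
    normalize_votes: bool = False,
) -> int:
    """Number of misclassified training samples under the (pruned) system."""
    res = predict_samples(
        system, models, values, use_pruned=use_pruned, normalize_votes=normalize_votes
    )
    truth = labels.loc[values.columns]
    return int(((res.predictions != truth) | (res.predictions == UNCLASSIFIED)).sum())
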
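"""Uniconditional rule induction ranked by the binomial relevance index.

A rule reads "IF gene *i* is low/high THEN class *C*". Rules are scored by
the relevance index (RI): the normalized gap between a two-sided binomial
confidence interval for the conditional probability p(C | premise), built
from the supports (n_PC, n_P), and the interval for the unconditional
probability p(C), built from (n_C, n), both at confidence level ``alpha``::

    RI = (L_cond - U_unc) / (1 - U_unc)   if L_cond > U_unc and U_unc < 1
    RI = L_cond - U_unc                   otherwise (<= 0)

A rule is interesting — retained — iff RI > 0, i.e. the conditional interval
lies strictly above the unconditional one. Positive RI lies in (0, 1].

The default interval is the exact Clopper–Pearson construction; Wilson and
normal-approximation intervals are available via ``ci_method``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import HIGH, LOW, GeneClusterModels
from .dataset import CLASSES

DEFAULT_ALPHA = 0.95
#: alpha grid scanned when the default level yields too few rules:
#: 0.95 down to 0.50 in steps of 0.01.
DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.95, 0.4999, -0.01), 2))
#: every conclusion present in the data must end up with more than
#: MIN_RULES_PER_CONCLUSION positive-RI rules
MIN_RULES_PER_CONCLUSION = 3

CI_METHODS = ("clopper_pearson", "wilson", "normal")


class UndefinedPremiseError(ValueError):
    """The premise cluster contains no sample (n_P = 0)."""


# ---------------------------------------------------------------------------
# binomial confidence intervals (tabulated per denominator for speed)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1024)
def _ci_tables(n: int, alpha: float, method: str) -> tuple[np.ndarray, np.ndarray]:
    """Lower/upper two-sided CI bounds for all (denominator d <= n, count k <= d).

    Returns arrays of shape (n+1, n+1) indexed ``[d, k]``; entries with
    k > d are meaningless. Cached because rule enumeration, alpha selection
    and the permutation control evaluate the same small set of count tuples
    thousands of times.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("confidence level alpha must be in (0, 1)")
    d, k = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
    tail = (1.0 - alpha) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        if method == "clopper_pearson":
            lower = stats.beta.ppf(tail, k, d - k + 1)
            upper = stats.beta.ppf(1.0 - tail, k + 1, np.maximum(d - k, 1e-12))
        elif method in ("wilson", "normal"):
            z = stats.norm.ppf(1.0 - tail)
            with np.errstate(invalid="ignore"):
                p = np.where(d > 0, k / np.maximum(d, 1), 0.0)
            if method == "wilson":
                denom = 1.0 + z**2 / np.maximum(d, 1)
                center = (p + z**2 / (2.0 * np.maximum(d, 1))) / denom
                half = (
                    z
                    / denom
                    * np.sqrt(p * (1 - p) / np.maximum(d, 1) + z**2 / (4.0 * np.maximum(d, 1) ** 2))
                )
            else:
                center = p
                half = z * np.sqrt(p * (1 - p) / np.maximum(d, 1))
            lower = np.clip(center - half, 0.0, 1.0)
            upper = np.clip(center + half, 0.0, 1.0)
        else:
            raise ValueError(f"unknown ci_method {method!r}; choose from {CI_METHODS}")
    lower = np.where(k <= 0, 0.0, lower)
    upper = np.where(k >= d, 1.0, upper)
    lower[d == 0] = 0.0
    upper[d == 0] = 1.0
    lower.setflags(write=False)
    upper.setflags(write=False)
    return lower, upper


def binomial_interval(k: int, d: int, alpha: float, method: str = "clopper_pearson"):
    """Two-sided confidence interval for a binomial proportion k/d."""
    lower, upper = _ci_tables(int(d), float(alpha), method)
    return float(lower[d, k]), float(upper[d, k])


def _ri_from_bounds(l_cond: np.ndarray, u_unc: np.ndarray) -> np.ndarray:
    gap = l_cond - u_unc
    with np.errstate(divide="ignore", invalid="ignore"):
        normalized = gap / (1.0 - u_unc)
    return np.where((gap > 0) & (u_unc < 1.0), normalized, gap)


def relevance_index(
    n_PC, n_P, n_C, n: int, alpha: float = DEFAULT_ALPHA, ci_method: str = "clopper_pearson"
):
    """Relevance index for one rule or (vectorized) arrays of support counts.

    Raises :class:`UndefinedPremiseError` where n_P = 0 and validates the
    count invariants 0 <= n_PC <= min(n_P, n_C) <= n.
    """
    n_PC = np.asarray(n_PC, dtype=int)
    n_P = np.asarray(n_P, dtype=int)
    n_C = np.asarray(n_C, dtype=int)
    scalar = n_PC.ndim == 0 and n_P.ndim == 0 and n_C.ndim == 0
    n_PC, n_P, n_C = np.atleast_1d(n_PC, n_P, n_C)
    n = int(n)
    if np.any(n_P == 0):
        raise UndefinedPremiseError("premise cluster contains no sample (n_P = 0)")
    if (
        np.any(n_PC < 0)
        or np.any(n_PC > np.minimum(n_P, n_C))
        or np.any(n_P > n)
        or np.any(n_C > n)
    ):
        raise ValueError("support counts violate 0 <= n_PC <= min(n_P, n_C) <= n")
    lower, upper = _ci_tables(n, float(alpha), ci_method)
    ri = _ri_from_bounds(lower[n_P, n_PC], upper[n, n_C])
    return float(ri[0]) if scalar else ri


# ---------------------------------------------------------------------------
# rules and rule systems
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Rule:
    """One uniconditional rule with its supports, score and rank."""

    gene: str
    level: str  # "low" | "high"
    conclusion: str  # "CG" | "OA" | "RA"
    n: int
    n_C: int
    n_P: int
    n_PC: int
    ri: float
    rank: int  # 1-based rank within its conclusion's list


@dataclass
class RuleSystem:
    """Per-conclusion ranked rule lists induced for one study group."""

    study_group: str
    alpha: float
    rules: dict[str, list[Rule]]
    alpha_random: float | None = None
    r_opt: dict[str, int] | None = None
    ci_method: str = "clopper_pearson"

    def r_max(self, conclusion: str) -> int:
        return len(self.rules.get(conclusion, []))

    @property
    def r_max_all(self) -> dict[str, int]:
        return {c: self.r_max(c) for c in CLASSES}

    def active_rules(self, conclusion: str) -> list[Rule]:
        """The rules actually applied: the pruned prefix if pruning ran."""
        lst = self.rules.get(conclusion, [])
        if self.r_opt is not None:
            return lst[: self.r_opt.get(conclusion, len(lst))]
        return lst

    @property
    def total_active(self) -> int:
        return sum(len(self.active_rules(c)) for c in CLASSES)

    def gene_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in CLASSES:
            for r in self.rules.get(c, []):
                seen.setdefault(r.gene)
        return list(seen)

    # -- serialization ------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        obj = {
            "version": 1,
            "study_group": self.study_group,
            "alpha": self.alpha,
            "alpha_random": self.alpha_random,
            "ci_method": self.ci_method,
            "r_opt": self.r_opt,
            "rules": [
                {**asdict(r), "pruned_in": self.r_opt is not None
                 and r.rank <= self.r_opt.get(r.conclusion, self.r_max(r.conclusion))}
                for c in CLASSES
                for r in self.rules.get(c, [])
            ],
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RuleSystem":
        obj = json.loads(Path(path).read_text())
        rules: dict[str, list[Rule]] = {c: [] for c in CLASSES}
        for rec in obj["rules"]:
            rec = {k: v for k, v in rec.items() if k != "pruned_in"}
            rules[rec["conclusion"]].append(Rule(**rec))
        for c in CLASSES:
            rules[c].sort(key=lambda r: r.rank)
        return cls(
            study_group=obj["study_group"],
            alpha=obj["alpha"],
            alpha_random=obj.get("alpha_random"),
            r_opt=obj.get("r_opt"),
            ci_method=obj.get("ci_method", "clopper_pearson"),
            rules=rules,
        )


# ---------------------------------------------------------------------------
# support counting and enumeration
# ---------------------------------------------------------------------------

def _support_counts(high_mask: np.ndarray, labels: np.ndarray):
    """Vectorized supports for all (gene, level, conclusion) triples.

    ``high_mask``: (G, n) boolean crisp assignment to the high cluster;
    ``labels``: (n,) integer class indices into :data:`CLASSES`.

    Returns ``(n_C, n_P, n_PC)`` where n_P and n_PC carry a leading level
    axis of size 2 ordered (low, high): n_P is (2, G), n_PC is (2, G, 3).
    """
    n = high_mask.shape[1]
    onehot = np.zeros((n, len(CLASSES)), dtype=int)
    onehot[np.arange(n), labels] = 1
    n_C = onehot.sum(axis=0)
    nP_high = high_mask.sum(axis=1)
    nPC_high = high_mask.astype(int) @ onehot
    n_P = np.stack([n - nP_high, nP_high])
    n_PC = np.stack([n_C[None, :] - nPC_high, nPC_high])
    return n_C, n_P, n_PC


def _ri_matrix(n_C, n_P, n_PC, n, alpha, ci_method):
    """RI for every triple; undefined premises (n_P = 0) yield -inf."""
    lower, upper = _ci_tables(n, float(alpha), ci_method)
    l_cond = lower[n_P[None, :, :], n_PC.transpose(2, 0, 1)]  # (3, 2, G)
    u_unc = upper[n, n_C][:, None, None]
    ri = _ri_from_bounds(l_cond, u_unc)  # (3 classes, 2 levels, G)
    ri = np.where(n_P[None, :, :] == 0, -np.inf, ri)
    return ri


def enumerate_rules(
    values: pd.DataFrame,
    labels: pd.Series,
    models: GeneClusterModels,
    alpha: float = DEFAULT_ALPHA,
    ci_method: str = "clopper_pearson",
    study_group: str = "unnamed",
) -> RuleSystem:
    """Generate all positive-RI uniconditional rules, ranked per conclusion.

    ``values`` is the normalized genes x samples matrix the models were
    fitted on (training data). Ties in RI are broken by (gene id, level) for
    a deterministic ranking.
    """
    genes = models.gene_ids
    high_mask = models.membership_high(values).to_numpy() > 0.5
    lab_idx = np.asarray([CLASSES.index(l) for l in labels.loc[values.columns]])
    n = len(lab_idx)
    n_C, n_P, n_PC = _support_counts(high_mask, lab_idx)
    ri = _ri_matrix(n_C, n_P, n_PC, n, alpha, ci_method)

    levels = (LOW, HIGH)
    rules: dict[str, list[Rule]] = {c: [] for c in CLASSES}
    for ci, conclusion in enumerate(CLASSES):
        keep = np.argwhere(ri[ci] > 0)
        recs = sorted(
            (
                (-ri[ci, li, gi], str(genes[gi]), levels[li], gi, li)
                for li, gi in keep
            ),
        )
        rules[conclusion] = [
            Rule(
                gene=g,
                level=lv,
                conclusion=conclusion,
                n=n,
                n_C=int(n_C[ci]),
                n_P=int(n_P[li, gi]),
                n_PC=int(n_PC[li, gi, ci]),
                ri=float(-negri),
                rank=rank,
            )
            for rank, (negri, g, lv, gi, li) in enumerate(recs, start=1)
        ]
    return RuleSystem(study_group=study_group, alpha=float(alpha), rules=rules, ci_method=ci_method)


class AlphaSelectionError(RuntimeError):
    """No grid level yields enough rules for every present conclusion."""


def select_alpha(
    values: pd.DataFrame,
    labels: pd.Series,
    models: GeneClusterModels,
    alpha_grid=DEFAULT_ALPHA_GRID,
    ci_method: str = "clopper_pearson",
    min_rules: int = MIN_RULES_PER_CONCLUSION,
) -> float:
    """Largest grid level at which every present conclusion has > ``min_rules``
    positive-RI rules.

    Conclusions with no samples in the data (e.g. a cohort without controls)
    are exempt. Returns the first (largest) satisfying level of the
    descending grid; raises :class:`AlphaSelectionError` with per-conclusion
    counts if even the smallest level fails.
    """
    high_mask = models.membership_high(values).to_numpy() > 0.5
    lab_idx = np.asarray([CLASSES.index(l) for l in labels.loc[values.columns]])
    n = len(lab_idx)
    n_C, n_P, n_PC = _support_counts(high_mask, lab_idx)
    present = n_C > 0
    last_counts = None
    for alpha in alpha_grid:
        ri = _ri_matrix(n_C, n_P, n_PC, n, alpha, ci_method)
        counts = (ri > 0).sum(axis=(1, 2))
        last_counts = counts
        if np.all(counts[present] > min_rules):
            return float(alpha)
    raise AlphaSelectionError(
        "no alpha in the grid yields more than "
        f"{min_rules} rules per conclusion; counts at alpha={alpha_grid[-1]}: "
        + ", ".join(f"{c}={int(k)}" for c, k in zip(CLASSES, last_counts))
    )


@dataclass
class RandomControlResult:
    """Outcome of the permuted-label alpha control."""

    alpha: float  # level used on the real labels
    alpha_random: float  # max over permutations (nan if never achieved)
    per_permutation: list[float] = field(repr=False, default_factory=list)

    @property
    def passed(self) -> bool:
        """True when the real-data level exceeds the permutation level."""
        return bool(np.isnan(self.alpha_random) or self.alpha > self.alpha_random)


def alpha_random_control(
    values: pd.DataFrame,
    labels: pd.Series,
    models: GeneClusterModels,
    alpha: float,
    alpha_grid=DEFAULT_ALPHA_GRID,
    ci_method: str = "clopper_pearson",
    n_permutations: int = 100,
    seed: int | None = 0,
) -> RandomControlResult:
    """Permutation control for the chosen confidence level.

    For each random permutation of the class labels, find the largest grid
    level at which at least one positive-RI rule exists for every conclusion
    present in the data; report the maximum over permutations. Identity
    permutations are rejected and redrawn. A sound level on the real data
    should exceed this permutation level.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    high_mask = models.membership_high(values).to_numpy() > 0.5
    lab_idx = np.asarray([CLASSES.index(l) for l in labels.loc[values.columns]])
    n = len(lab_idx)
    grid = list(alpha_grid)

    def best_alpha(perm_labels: np.ndarray) -> float:
        n_C, n_P, n_PC = _support_counts(high_mask, perm_labels)
        present = n_C > 0

        def ok(a: float) -> bool:
            ri = _ri_matrix(n_C, n_P, n_PC, n, a, ci_method)
            return bool(np.all((ri > 0).any(axis=(1, 2))[present]))

        # the positivity condition is monotone along the descending grid
        # (intervals widen as the level rises), so bisect for the first
        # satisfying index
        if not ok(grid[-1]):
            return float("nan")
        if ok(grid[0]):
            return grid[0]
        lo, hi = 0, len(grid) - 1  # ok(grid[lo]) False, ok(grid[hi]) True
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if ok(grid[mid]):
                hi = mid
            else:
                lo = mid
        return grid[hi]

    per_perm = []
    for _ in range(n_permutations):
        for _attempt in range(1000):
            perm = rng.permutation(n)
            if not np.array_equal(perm, np.arange(n)) and not np.array_equal(
                lab_idx[perm], lab_idx
            ):
                break
        per_perm.append(best_alpha(lab_idx[perm]))
    arr = np.asarray(per_perm)
    alpha_random = float(np.nanmax(arr)) if not np.all(np.isnan(arr)) else float("nan")
    return RandomControlResult(alpha=float(alpha), alpha_random=alpha_random, per_permutation=per_perm)
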
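"""Independent reference implementations used only to check the main code.

Deliberately written on different primitives than the package: statsmodels
for the exact binomial interval, plain-Python loops for memberships and
tallies.
"""

import numpy as np
from statsmodels.stats.proportion import proportion_confint


def cp_interval(k, n, level):
    """Exact (Clopper–Pearson) two-sided interval via statsmodels."""
    lo, hi = proportion_confint(k, n, alpha=1 - level, method="beta")
    return float(lo), float(hi)


def relevance_index_oracle(n_PC, n_P, n_C, n, level):
    """Interval-gap relevance index from the statsmodels intervals."""
    l_cond, _ = cp_interval(n_PC, n_P, level)
    _, u_unc = cp_interval(n_C, n, level)
    gap = l_cond - u_unc
    if gap > 0 and u_unc < 1:
        return gap / (1 - u_unc)
    return gap


def fcm_membership(y, centers, m=2.0):
    """Plain FCM membership u_k(y) = 1 / sum_l (d_k/d_l)^(2/(m-1))."""
    d = [abs(y - c) for c in centers]
    if any(dd == 0 for dd in d):
        return [1.0 if dd == 0 else 0.0 for dd in d]
    p = 2.0 / (m - 1.0)
    return [1.0 / sum((d[k] / d[l]) ** p for l in range(len(centers))) for k in range(len(centers))]


def tally_confusion(preds, truth, classes):
    """Loop-based confusion tally: dict (predicted, true) -> count."""
    out = {}
    for p, t in zip(preds, truth):
        out[(p, t)] = out.get((p, t), 0) + 1
    return out
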
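"""Per-gene two-cluster fuzzy C-means on normalized log2 expression.

Every gene is discretized independently into a "low" and a "high" expression
cluster by 1-D fuzzy C-means (c=2). Downstream, samples are weighted with a
*modified* membership degree M': hard 1/0 outside the interval spanned by the
two cluster centers, the ordinary FCM membership in between. With the default
fuzzifier m=2 the in-between membership of the high cluster has the closed
form ``1 / (1 + ((ct_high - y) / (y - ct_low))**2)``.

The fit is deterministic: centers are initialized at the 25th/75th
percentiles of the gene's values, so refitting (in any sample order) yields
identical centers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LOW, HIGH = "low", "high"


class DegenerateGeneError(ValueError):
    """All values of a gene identical — no two clusters exist."""


@dataclass(frozen=True)
class GeneClusterModel:
    """Fitted two-cluster model for one gene (centers on the y scale)."""

    gene_id: str
    ct_low: float
    ct_high: float
    m: float = 2.0

    def __post_init__(self):
        if not self.ct_low < self.ct_high:
            raise ValueError(
                f"gene {self.gene_id!r}: cluster centers must satisfy ct_low < ct_high"
            )
        if not self.m > 1:
            raise ValueError("fuzzifier m must be > 1")

    def modified_membership(self, y: float) -> tuple[float, float]:
        """Return ``(M'_low, M'_high)`` at expression value ``y``.

        Hard (1, 0) at or below the low center, hard (0, 1) at or above the
        high center, FCM membership strictly in between; the pair always sums
        to 1.
        """
        m_high = _membership_high(
            np.asarray([y], dtype=float),
            np.asarray([self.ct_low]),
            np.asarray([self.ct_high]),
            self.m,
        )[0]
        return 1.0 - m_high, m_high

    def assign(self, y: float) -> str:
        """Crisp cluster label; ties (M'_low == M'_high) go to "low"."""
        lo, hi = self.modified_membership(y)
        return HIGH if hi > lo else LOW


def _membership_high(y: np.ndarray, ct_low: np.ndarray, ct_high: np.ndarray, m: float) -> np.ndarray:
    """Vectorized M'_high; ``ct_low``/``ct_high`` broadcast against ``y``."""
    y = np.asarray(y, dtype=float)
    out = np.empty(np.broadcast(y, ct_low, ct_high).shape, dtype=float)
    y, ct_low, ct_high = np.broadcast_arrays(y, ct_low, ct_high)
    below = y <= ct_low
    above = y >= ct_high
    mid = ~(below | above)
    out[below] = 0.0
    out[above] = 1.0
    if mid.any():
        d_low = y[mid] - ct_low[mid]
        d_high = ct_high[mid] - y[mid]
        p = 2.0 / (m - 1.0)
        out[mid] = 1.0 / (1.0 + (d_high / d_low) ** p)
    return out


def _fcm_1d_two_clusters(
    Y: np.ndarray, m: float = 2.0, tol: float = 1e-8, max_iter: int = 300
) -> np.ndarray:
    """Fuzzy C-means with c=2 on each row of ``Y`` (genes x samples).

    Returns an array (n_genes, 2) of centers sorted ascending per gene.
    Rows must each contain >= 2 distinct values.
    """
    Y = np.asarray(Y, dtype=float)
    lo = np.percentile(Y, 25, axis=1)
    hi = np.percentile(Y, 75, axis=1)
    flat = hi - lo <= 0
    if flat.any():
        # skewed rows where both quartiles coincide: fall back to min/max
        lo[flat] = Y[flat].min(axis=1)
        hi[flat] = Y[flat].max(axis=1)
    centers = np.stack([lo, hi], axis=1)
    p = 2.0 / (m - 1.0)
    for _ in range(max_iter):
        d = np.abs(Y[:, None, :] - centers[:, :, None])  # (G, 2, n)
        # membership: u_k = d_k^-p / sum_l d_l^-p, with exact hits hard
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = (d[:, 1, :] / d[:, 0, :]) ** p
            u_low = ratio / (1.0 + ratio)
        zero_low = d[:, 0, :] == 0
        zero_high = d[:, 1, :] == 0
        u_low[zero_low] = 1.0
        u_low[zero_high] = 0.0
        u_low[zero_low & zero_high] = 0.5  # centers collided on the point
        u = np.stack([u_low, 1.0 - u_low], axis=1)
        um = u**m
        new_centers = (um * Y[:, None, :]).sum(axis=2) / um.sum(axis=2)
        shift = np.abs(new_centers - centers).max()
        centers = new_centers
        if shift < tol:
            break
    centers.sort(axis=1)
    return centers


def fit_gene_clusters(
    y_row, gene_id: str = "gene", m: float = 2.0, tol: float = 1e-8, max_iter: int = 300
) -> GeneClusterModel:
    """Fit the two-cluster model for a single gene's normalized values."""
    y_row = np.asarray(y_row, dtype=float)
    if np.unique(y_row).size < 2:
        raise DegenerateGeneError(f"gene {gene_id!r}: all values identical")
    centers = _fcm_1d_two_clusters(y_row[None, :], m=m, tol=tol, max_iter=max_iter)[0]
    if not centers[0] < centers[1]:
        raise DegenerateGeneError(f"gene {gene_id!r}: cluster centers collapsed")
    return GeneClusterModel(gene_id=str(gene_id), ct_low=centers[0], ct_high=centers[1], m=m)


class GeneClusterModels:
    """Collection of per-gene cluster models with vectorized evaluation.

    Attributes
    ----------
    centers : pandas.DataFrame
        Index = gene id, columns ``ct_low``/``ct_high``.
    m : float
        Fuzzifier shared by all genes.
    dropped : list of str
        Degenerate genes (zero variance) excluded from rule induction.
    """

    def __init__(self, centers: pd.DataFrame, m: float = 2.0, dropped: list | None = None):
        bad = centers.index[~(centers["ct_low"] < centers["ct_high"])]
        if len(bad):
            raise ValueError(f"centers not strictly ordered for gene(s) {list(bad)[:5]!r}")
        self.centers = centers
        self.m = float(m)
        self.dropped = list(dropped or [])

    @classmethod
    def fit(cls, values: pd.DataFrame, m: float = 2.0, tol: float = 1e-8, max_iter: int = 300):
        """Fit all genes of a normalized values matrix (genes x samples)."""
        Y = values.to_numpy(dtype=float)
        spread = Y.max(axis=1) - Y.min(axis=1)
        ok = spread > 0
        dropped = list(values.index[~ok])
        if dropped:
            logger.warning(
                "dropping %d zero-variance gene(s) from clustering: %s%s",
                len(dropped), dropped[:5], "..." if len(dropped) > 5 else "",
            )
        centers = _fcm_1d_two_clusters(Y[ok], m=m, tol=tol, max_iter=max_iter)
        collapsed = ~(centers[:, 0] < centers[:, 1])
        if collapsed.any():
            more = list(values.index[ok][collapsed])
            logger.warning("dropping %d gene(s) with collapsed centers: %s", len(more), more[:5])
            dropped += more
            centers = centers[~collapsed]
        index = values.index[ok][~collapsed] if collapsed.any() else values.index[ok]
        df = pd.DataFrame(centers, index=index, columns=["ct_low", "ct_high"])
        return cls(df, m=m, dropped=dropped)

    # -- vectorized evaluation ----------------------------------------
    def __len__(self) -> int:
        return len(self.centers)

    def __contains__(self, gene_id) -> bool:
        return gene_id in self.centers.index

    def __getitem__(self, gene_id) -> GeneClusterModel:
        row = self.centers.loc[gene_id]
        return GeneClusterModel(str(gene_id), float(row["ct_low"]), float(row["ct_high"]), self.m)

    @property
    def gene_ids(self) -> list:
        return list(self.centers.index)

    def membership_high(self, values: pd.DataFrame) -> pd.DataFrame:
        """M'_high for every (model gene, sample) of a values matrix."""
        sub = values.loc[self.centers.index]
        mh = _membership_high(
            sub.to_numpy(dtype=float),
            self.centers["ct_low"].to_numpy()[:, None],
            self.centers["ct_high"].to_numpy()[:, None],
            self.m,
        )
        return pd.DataFrame(mh, index=sub.index, columns=sub.columns)

    def assign(self, values: pd.DataFrame) -> pd.DataFrame:
        """Crisp low/high assignment matrix (ties at M'=0.5 go to low)."""
        mh = self.membership_high(values)
        return mh.gt(0.5).replace({True: HIGH, False: LOW})

    # -- serialization ------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        obj = {
            "version": 1,
            "m": self.m,
            "genes": {
                str(g): {"ct_low": float(r["ct_low"]), "ct_high": float(r["ct_high"])}
                for g, r in self.centers.iterrows()
            },
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneClusterModels":
        obj = json.loads(Path(path).read_text())
        df = pd.DataFrame.from_dict(obj["genes"], orient="index")[["ct_low", "ct_high"]]
        return cls(df, m=obj["m"])
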
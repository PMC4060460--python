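"""Present-call filtering and per-sample median/log2 normalization.

The pipeline order is fixed: filter first, then normalize, because the
filter defines the gene panel over which each sample's median is taken
(configurable via ``median_domain``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .dataset import DatasetError, ExpressionDataset


class EmptyPanelError(DatasetError):
    """No gene survives the present-call filter."""


def filter_present(ds: ExpressionDataset, mode: str = "present_all") -> ExpressionDataset:
    """Restrict a dataset to genes detected ("present") in every sample.

    ``mode="all_probesets"`` skips filtering entirely (the variant that keeps
    every probe set independent of its detection call). Gene order is
    preserved; the operation is idempotent.
    """
    if ds.normalized:
        raise DatasetError("filter_present must run before normalization")
    if mode == "all_probesets":
        return ds
    if mode != "present_all":
        raise ValueError(f"unknown filter mode {mode!r}")
    keep = ds.present.all(axis=1)
    if not keep.any():
        raise EmptyPanelError(
            f"no gene is present in all {ds.n_samples} samples of study group {ds.center!r}"
        )
    return ds.copy_with(
        signals=ds.signals.loc[keep],
        present=ds.present.loc[keep],
    )


def normalize(
    ds: ExpressionDataset,
    median_domain: str = "retained",
    full_signals: pd.DataFrame | None = None,
) -> ExpressionDataset:
    """Median-scale each sample and take log2: ``y_ij = log2(x_ij / med_j)``.

    The median runs over the dataset's (post-filter) gene panel by default.
    With ``median_domain="all"`` it runs over an unfiltered signal matrix
    passed as ``full_signals`` — the alternative reading in which the
    per-sample median is taken over the whole array rather than the retained
    panel. Normalization is always per study group; never normalize pooled
    raw data unless the pooled group is itself the declared study group.
    """
    sig = ds.signals.to_numpy(dtype=float)
    if np.any(sig <= 0):
        g, s = np.argwhere(sig <= 0)[0]
        raise DatasetError(
            f"non-positive signal for gene {ds.signals.index[g]!r} in sample "
            f"{ds.signals.columns[s]!r}; cannot take log2"
        )
    if median_domain == "retained":
        med = np.median(sig, axis=0)
    elif median_domain == "all":
        if full_signals is None:
            raise ValueError("median_domain='all' requires the unfiltered signal matrix")
        med = np.median(full_signals[ds.signals.columns].to_numpy(dtype=float), axis=0)
    else:
        raise ValueError(f"unknown median_domain {median_domain!r}")
    y = np.log2(sig / med)
    values = pd.DataFrame(y, index=ds.signals.index, columns=ds.signals.columns)
    return ds.copy_with(values=values, normalized=True)


def preprocess(
    ds: ExpressionDataset,
    mode: str = "present_all",
    median_domain: str = "retained",
) -> ExpressionDataset:
    """filter_present -> normalize, in that (fixed) order."""
    full = ds.signals if median_domain == "all" else None
    return normalize(filter_present(ds, mode=mode), median_domain=median_domain, full_signals=full)


class MedianLog2Normalizer(BaseEstimator, TransformerMixin):
    """Stateless sklearn transformer: per-sample median scaling then log2.

    Operates on samples x genes arrays (sklearn orientation). Each row is
    divided by its own median over the gene axis and log2-transformed, so the
    output is invariant to per-sample multiplicative scale.
    """

    def fit(self, X, y=None):  # noqa: D102 — stateless
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D samples x genes matrix")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if np.any(X <= 0):
            raise ValueError("signals must be strictly positive for log2 normalization")
        med = np.median(X, axis=1, keepdims=True)
        return np.log2(X / med)
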
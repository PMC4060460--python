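"""Expression dataset container and on-disk formats.

A dataset bundles a genes x samples signal matrix (linear scale, as produced
by array summarization software such as MAS5.0), a matching boolean detection
("present call") mask, per-sample clinical labels and a study-group tag.

On disk the package uses plain-text formats:

* expression TSV — first column ``probe_set_id``, remaining columns one per
  sample, linear-scale signals;
* calls TSV — same shape, cells ``P``/``M``/``A`` (only ``P`` counts as
  present);
* annotation CSV — columns ``sample_id,center,class`` with class in
  {CG, OA, RA}.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: The three clinical states, in the fixed order used everywhere (ties in
#: defuzzification are broken toward the earlier class).
CLASSES = ("CG", "OA", "RA")


class DatasetError(ValueError):
    """Raised when a dataset violates its structural invariants."""


@dataclass
class ExpressionDataset:
    """Genes x samples expression data for one study group.

    Parameters
    ----------
    signals : pandas.DataFrame
        Linear-scale signal matrix, index = probe-set/gene ids,
        columns = sample ids. Strictly positive wherever ``present``.
    present : pandas.DataFrame
        Boolean detection mask, same shape/index/columns as ``signals``.
    labels : pandas.Series
        Clinical status per sample, values in :data:`CLASSES`.
    center : str
        Study-group tag (e.g. a clinical center name, or ``"Total"`` for a
        pooled group).
    values : pandas.DataFrame, optional
        Normalized log2 values ``y_ij``; present only after normalization.
    """

    signals: pd.DataFrame
    present: pd.DataFrame
    labels: pd.Series
    center: str = "unnamed"
    values: pd.DataFrame | None = None
    normalized: bool = field(default=False)

    def __post_init__(self) -> None:
        self.signals = pd.DataFrame(self.signals)
        self.present = pd.DataFrame(self.present).astype(bool)
        self.labels = pd.Series(self.labels)
        self.validate()

    # -- invariants ---------------------------------------------------
    def validate(self) -> None:
        if not self.signals.index.equals(self.present.index) or not self.signals.columns.equals(
            self.present.columns
        ):
            raise DatasetError("signals and present-call matrices are not aligned")
        if self.signals.index.has_duplicates:
            dup = self.signals.index[self.signals.index.duplicated()][0]
            raise DatasetError(f"duplicate gene id {dup!r}")
        if self.signals.columns.has_duplicates:
            dup = self.signals.columns[self.signals.columns.duplicated()][0]
            raise DatasetError(f"duplicate sample id {dup!r}")
        if list(self.labels.index) != list(self.signals.columns):
            raise DatasetError("label index does not match sample ids")
        bad = set(self.labels) - set(CLASSES)
        if bad:
            raise DatasetError(
                f"unknown class label(s) {sorted(bad)!r}; expected one of {CLASSES}"
            )
        sig = self.signals.to_numpy(dtype=float)
        if np.any(~np.isfinite(sig)):
            raise DatasetError("non-finite signal values")
        if np.any((sig <= 0) & self.present.to_numpy()):
            g, s = np.argwhere((sig <= 0) & self.present.to_numpy())[0]
            raise DatasetError(
                f"non-positive signal for present gene {self.signals.index[g]!r} "
                f"in sample {self.signals.columns[s]!r}"
            )
        if self.normalized and self.values is None:
            raise DatasetError("normalized flag set but no values matrix")

    # -- conveniences -------------------------------------------------
    @property
    def gene_ids(self) -> list:
        return list(self.signals.index)

    @property
    def sample_ids(self) -> list:
        return list(self.signals.columns)

    @property
    def n_genes(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    def class_counts(self) -> pd.Series:
        return self.labels.value_counts().reindex(CLASSES, fill_value=0)

    def copy_with(self, **kwargs) -> "ExpressionDataset":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression(
    expr_path: str | Path,
    calls_path: str | Path | None,
    annot_path: str | Path,
    center: str | None = None,
) -> ExpressionDataset:
    """Read an expression TSV, a present-call TSV and a sample annotation CSV.

    When ``calls_path`` is None every gene is taken as present in every
    sample. ``center`` restricts the annotation to one study group; if omitted
    the annotation must contain exactly one center.
    """
    signals = pd.read_csv(expr_path, sep="\t", index_col=0)
    annot = pd.read_csv(annot_path)
    for col in ("sample_id", "center", "class"):
        if col not in annot.columns:
            raise DatasetError(f"annotation file lacks required column {col!r}")
    if center is not None:
        annot = annot[annot["center"] == center]
        if annot.empty:
            raise DatasetError(f"no samples annotated for center {center!r}")
    else:
        centers = annot["center"].unique()
        if len(centers) != 1:
            raise DatasetError(
                f"annotation contains centers {list(centers)!r}; pass center= to select one"
            )
        center = str(centers[0])
    annot = annot.set_index("sample_id")
    if annot.index.has_duplicates:
        dup = annot.index[annot.index.duplicated()][0]
        raise DatasetError(f"duplicate sample id {dup!r} in annotation")

    missing = [s for s in annot.index if s not in signals.columns]
    if missing:
        raise DatasetError(f"annotated sample(s) missing from expression matrix: {missing}")
    signals = signals[list(annot.index)]

    if calls_path is not None:
        calls = pd.read_csv(calls_path, sep="\t", index_col=0)
        if not calls.index.equals(signals.index):
            raise DatasetError("calls file gene ids do not match expression matrix")
        missing = [s for s in annot.index if s not in calls.columns]
        if missing:
            raise DatasetError(f"annotated sample(s) missing from calls file: {missing}")
        # only an explicit "P" counts as present; "M" (marginal) and "A"
        # (absent) both fail the filter
        present = calls[list(annot.index)].astype(str) == "P"
    else:
        present = pd.DataFrame(True, index=signals.index, columns=signals.columns)

    return ExpressionDataset(
        signals=signals,
        present=present,
        labels=annot["class"],
        center=center,
    )


def write_expression(ds: ExpressionDataset, expr_path, calls_path=None, annot_path=None) -> None:
    """Write a dataset back to the TSV/CSV dialect read by :func:`read_expression`."""
    out = ds.signals.copy()
    out.index.name = "probe_set_id"
    out.to_csv(expr_path, sep="\t")
    if calls_path is not None:
        calls = ds.present.replace({True: "P", False: "A"})
        calls.index.name = "probe_set_id"
        calls.to_csv(calls_path, sep="\t")
    if annot_path is not None:
        annot = pd.DataFrame(
            {"sample_id": ds.sample_ids, "center": ds.center, "class": ds.labels.values}
        )
        annot.to_csv(annot_path, index=False)
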
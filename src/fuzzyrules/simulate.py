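"""Synthetic multi-center expression cohorts with planted marker genes.

The generator emulates the structure of a multi-center microarray study of
synovial tissue: three clinical centers with unbalanced class compositions
(controls CG, osteoarthritis OA, rheumatoid arthritis RA), several thousand
probe sets, a small set of class-dependent bimodal marker genes, and
class-independent background genes. Signals are log2-Gaussian (log-normal on
the linear scale): a marker of (conclusion c, direction "high") draws its
log2 signal from a mode shifted up by ``delta`` in samples of class c and
from the baseline mode elsewhere; direction "low" swaps the two mode
assignments. Per-center and per-sample multiplicative scale factors mimic
lab and hybridization effects and are exactly removable by per-sample median
normalization. Detection ("present") calls are independent Bernoulli draws.

Defaults plant the class structure a rule-based classifier should recover
with high confidence: modes ``delta = 2`` log2 units apart against a
within-mode spread of ``sigma = 0.3``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import HIGH, LOW
from .dataset import CLASSES, ExpressionDataset


class ConfigurationError(ValueError):
    """A cohort specification field is invalid (the message names it)."""


@dataclass(frozen=True)
class CenterSpec:
    """Sample counts per class for one simulated center."""

    name: str
    n_CG: int = 10
    n_OA: int = 10
    n_RA: int = 10

    @property
    def n_samples(self) -> int:
        return self.n_CG + self.n_OA + self.n_RA

    def counts(self) -> dict[str, int]:
        return {"CG": self.n_CG, "OA": self.n_OA, "RA": self.n_RA}


@dataclass(frozen=True)
class MarkerSpec:
    """A block of marker genes for one (conclusion, direction)."""

    conclusion: str
    direction: str  # "low" | "high"
    n_markers: int = 5
    delta: float = 2.0  # log2 shift between the two modes
    sigma: float = 0.3  # within-mode sd (log2)


def _default_centers() -> tuple[CenterSpec, ...]:
    # three centers with the unbalanced class mix typical of retrospective
    # multi-center tissue collections (incl. one center without controls)
    return (
        CenterSpec("Jena", 10, 10, 13),
        CenterSpec("Berlin", 10, 10, 10),
        CenterSpec("Leipzig", 0, 6, 10),
    )


def _default_markers() -> tuple[MarkerSpec, ...]:
    return tuple(
        MarkerSpec(conclusion=c, direction=d) for c in CLASSES for d in (HIGH, LOW)
    )


@dataclass(frozen=True)
class CohortSpec:
    """Full specification of a simulated multi-center cohort."""

    centers: tuple[CenterSpec, ...] = field(default_factory=_default_centers)
    n_genes: int = 2000
    marker_spec: tuple[MarkerSpec, ...] = field(default_factory=_default_markers)
    mu: float = 7.0  # baseline log2 signal level
    baseline_sd: float = 1.0  # gene-to-gene spread of baseline levels
    background_sd: float = 0.3  # within-gene noise of background genes
    center_scale_sd: float = 0.2  # sd of the per-center log2 scale offset
    sample_scale_sd: float = 0.1  # sd of the per-sample log2 scale offset
    present_prob: float = 0.95
    markers_always_present: bool = True
    seed: int = 0

    def validate(self) -> None:
        for c in self.centers:
            for fld in ("n_CG", "n_OA", "n_RA"):
                if getattr(c, fld) < 0:
                    raise ConfigurationError(f"center {c.name!r}: {fld} must be >= 0")
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        total_markers = sum(m.n_markers for m in self.marker_spec)
        if total_markers > self.n_genes:
            raise ConfigurationError("marker_spec: total n_markers exceeds n_genes")
        for m in self.marker_spec:
            if m.conclusion not in CLASSES:
                raise ConfigurationError(f"marker_spec: unknown conclusion {m.conclusion!r}")
            if m.direction not in (LOW, HIGH):
                raise ConfigurationError(f"marker_spec: unknown direction {m.direction!r}")
            if m.n_markers < 0:
                raise ConfigurationError("marker_spec: n_markers must be >= 0")
            if not m.delta > 0:
                raise ConfigurationError("marker_spec: delta must be > 0")
            if not m.sigma > 0:
                raise ConfigurationError("marker_spec: sigma must be > 0")
        if not 0 < self.present_prob <= 1:
            raise ConfigurationError("present_prob must be in (0, 1]")
        for fld in ("baseline_sd", "background_sd"):
            if getattr(self, fld) < 0:
                raise ConfigurationError(f"{fld} must be >= 0")
        for fld in ("center_scale_sd", "sample_scale_sd"):
            if getattr(self, fld) < 0:
                raise ConfigurationError(f"{fld} must be >= 0")

    @classmethod
    def from_dict(cls, obj: dict) -> "CohortSpec":
        obj = dict(obj)
        if "centers" in obj:
            obj["centers"] = tuple(CenterSpec(**c) for c in obj["centers"])
        if "marker_spec" in obj:
            obj["marker_spec"] = tuple(MarkerSpec(**m) for m in obj["marker_spec"])
        return cls(**obj)


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort.

    ``marker_table`` maps gene id -> (conclusion, direction); ``labels`` maps
    center -> {sample id -> true class}.
    """

    marker_table: dict[str, tuple[str, str]]
    labels: dict[str, dict[str, str]]

    def markers_for(self, conclusion: str) -> list[str]:
        return [g for g, (c, _) in self.marker_table.items() if c == conclusion]

    def to_json(self, path: str | Path) -> None:
        obj = {
            "markers": {g: {"conclusion": c, "direction": d} for g, (c, d) in self.marker_table.items()},
            "labels": self.labels,
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        obj = json.loads(Path(path).read_text())
        return cls(
            marker_table={g: (m["conclusion"], m["direction"]) for g, m in obj["markers"].items()},
            labels=obj["labels"],
        )


def generate_cohorts(spec: CohortSpec) -> tuple[list[ExpressionDataset], GroundTruth]:
    """Generate one dataset per center plus the planted ground truth.

    The same marker table, per-gene baselines and random seed govern all
    centers, so the planted biology is shared while scale effects and noise
    are center-specific. Identical specs (same seed) produce bit-identical
    datasets.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    width = max(4, len(str(spec.n_genes)))
    gene_ids = np.array([f"G{i:0{width}d}" for i in range(1, spec.n_genes + 1)])
    baselines = spec.mu + spec.baseline_sd * rng.standard_normal(spec.n_genes)

    # place marker blocks on randomly chosen genes
    order = rng.permutation(spec.n_genes)
    marker_table: dict[str, tuple[str, str]] = {}
    gene_sd = np.full(spec.n_genes, spec.background_sd)
    # per gene: class column of the +delta mode (one-hot or inverted one-hot)
    shift = np.zeros((spec.n_genes, len(CLASSES)))
    pos = 0
    for mspec in spec.marker_spec:
        idx = order[pos : pos + mspec.n_markers]
        pos += mspec.n_markers
        ci = CLASSES.index(mspec.conclusion)
        for gi in idx:
            marker_table[str(gene_ids[gi])] = (mspec.conclusion, mspec.direction)
        gene_sd[idx] = mspec.sigma
        if mspec.direction == HIGH:
            shift[idx, ci] = mspec.delta  # class c sits in the upper mode
        else:
            shift[idx, :] = mspec.delta  # everyone but class c sits up
            shift[idx, ci] = 0.0

    datasets: list[ExpressionDataset] = []
    labels_by_center: dict[str, dict[str, str]] = {}
    for center in spec.centers:
        labels = [c for c in CLASSES for _ in range(center.counts()[c])]
        n = len(labels)
        sample_ids = [f"{center.name}_{c}{k + 1:02d}" for c in CLASSES for k in range(center.counts()[c])]
        lab_idx = np.array([CLASSES.index(c) for c in labels], dtype=int)

        center_offset = spec.center_scale_sd * rng.standard_normal()
        sample_offset = spec.sample_scale_sd * rng.standard_normal(n)
        noise = gene_sd[:, None] * rng.standard_normal((spec.n_genes, n))
        log2_signal = (
            baselines[:, None] + shift[:, lab_idx] + noise + center_offset + sample_offset[None, :]
        )
        signals = pd.DataFrame(2.0**log2_signal, index=gene_ids, columns=sample_ids)

        present = rng.random((spec.n_genes, n)) < spec.present_prob
        if spec.markers_always_present and marker_table:
            marker_idx = [i for i, g in enumerate(gene_ids) if g in marker_table]
            present[marker_idx, :] = True
        present = pd.DataFrame(present, index=gene_ids, columns=sample_ids)

        datasets.append(
            ExpressionDataset(
                signals=signals,
                present=present,
                labels=pd.Series(labels, index=sample_ids),
                center=center.name,
            )
        )
        labels_by_center[center.name] = dict(zip(sample_ids, labels))

    return datasets, GroundTruth(marker_table=marker_table, labels=labels_by_center)
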
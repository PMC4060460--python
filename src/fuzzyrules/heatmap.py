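"""Rule x sample membership-weight heatmap export (TSV, optional PNG)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .classify import PredictionResult
from .dataset import CLASSES
from .rules import RuleSystem


def heatmap_frame(
    result: PredictionResult,
    truth: pd.Series,
    system: RuleSystem | None = None,
) -> pd.DataFrame:
    """Weights as a display table: rules as rows (grouped by conclusion, in
    rank order), samples as columns (grouped by true class), with leading
    annotation columns and a ``pruned`` flag marking the optimized prefix.
    """
    W = result.weights
    sample_order = [s for c in CLASSES for s in truth.index[truth == c]]
    sample_order += [s for s in W.columns if s not in sample_order]
    W = W[[s for s in sample_order if s in W.columns]]

    rows = []
    for (conclusion, rank, gene, level), weights in W.iterrows():
        in_prefix = 1
        if system is not None and system.r_opt is not None:
            in_prefix = int(rank <= system.r_opt.get(conclusion, 10**9))
        rows.append(
            {"conclusion": conclusion, "rank": rank, "gene": gene, "level": level,
             "pruned": in_prefix, **weights.to_dict()}
        )
    return pd.DataFrame(rows)


def write_heatmap(
    result: PredictionResult,
    truth: pd.Series,
    path: str | Path,
    system: RuleSystem | None = None,
    png_path: str | Path | None = None,
) -> pd.DataFrame:
    """Write the heatmap TSV (and optionally a PNG rendering).

    The second line of the TSV annotates each sample column with its true
    class. The returned frame holds exactly the weights used in vote
    aggregation.
    """
    frame = heatmap_frame(result, truth, system)
    sample_cols = [c for c in frame.columns if c not in ("conclusion", "rank", "gene", "level", "pruned")]
    with open(path, "w") as fh:
        fh.write("\t".join(frame.columns) + "\n")
        ann = [""] * 5 + [str(truth.get(s, "")) for s in sample_cols]
        fh.write("true_class\t" + "\t".join(ann[1:]) + "\n")
        frame.to_csv(fh, sep="\t", header=False, index=False)
    if png_path is not None:
        _render_png(frame, sample_cols, png_path)
    return frame


def _render_png(frame: pd.DataFrame, sample_cols: list, png_path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = frame[sample_cols].to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(max(4, len(sample_cols) * 0.25), max(3, len(frame) * 0.2)))
    ax.imshow(mat, aspect="auto", cmap="viridis", vmin=0, vmax=1)
    ax.set_xticks(range(len(sample_cols)))
    ax.set_xticklabels(sample_cols, rotation=90, fontsize=5)
    ax.set_yticks(range(len(frame)))
    ax.set_yticklabels(
        [f"{r.conclusion}:{r.rank} {r.gene} {r.level}" for r in frame.itertuples()], fontsize=5
    )
    boundaries = frame["conclusion"].ne(frame["conclusion"].shift()).to_numpy().nonzero()[0][1:]
    for b in boundaries:
        ax.axhline(b - 0.5, color="white", lw=0.8)
    fig.tight_layout()
    fig.savefig(png_path, dpi=150)
    plt.close(fig)
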
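"""Figure rendering from the TSV outputs.

Every plot consumes only the tab-separated tables the analysis commands
write (never in-memory state), so figures are reproducible from the TSVs
alone.  Four kinds are supported: per-individual genotype tracks,
Manhattan plots of a windowed statistic, MDS scatter plots, and LD pair
dot plots.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["PlotSpec", "render"]

_REQUIRED = {
    "tracks": ["sample", "chrom", "start_bp", "mean_genotype"],
    "manhattan": ["chrom", "start_bp", "value"],
    "mds": ["axis1", "axis2"],
    "ld": ["pos_a", "pos_b", "r2"],
}


@dataclass
class PlotSpec:
    kind: str
    table: str                       # input TSV path
    out: str                         # output image path (.png or .svg)
    highlight: list[tuple[str, int, int]] = field(default_factory=list)
    color_by: str | None = None      # column for point labels/colors (mds)
    highlight_table: str | None = None  # outliers.tsv for manhattan
    width: float = 10.0
    height: float = 6.0
    dpi: int = 150

    def __post_init__(self) -> None:
        if self.kind not in _REQUIRED:
            raise ValueError(f"unknown plot kind {self.kind!r}")


def _read_table(path: str) -> pd.DataFrame:
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rt") as fh:
        return pd.read_csv(fh, sep="\t")


def render(spec: PlotSpec) -> str:
    """Render one figure; returns the output path."""
    df = _read_table(spec.table)
    missing = [c for c in _REQUIRED[spec.kind] if c not in df.columns]
    if missing:
        raise ValueError(f"{spec.table}: missing required columns {missing}")
    fig = {
        "tracks": _plot_tracks,
        "manhattan": _plot_manhattan,
        "mds": _plot_mds,
        "ld": _plot_ld,
    }[spec.kind](df, spec)
    fig.savefig(spec.out, dpi=spec.dpi)
    plt.close(fig)
    return spec.out


def _shade(ax, chrom: str, highlight) -> None:
    for c, s, e in highlight:
        if c == chrom:
            ax.axvspan(s, e, color="gold", alpha=0.25, lw=0)


def _plot_tracks(df: pd.DataFrame, spec: PlotSpec):
    samples = list(pd.unique(df["sample"]))
    chroms = list(pd.unique(df["chrom"]))
    fig, axes = plt.subplots(
        len(samples), len(chroms), squeeze=False, sharey=True,
        figsize=(max(spec.width, 3 * len(chroms)), max(spec.height, 1.2 * len(samples))),
    )
    for i, s in enumerate(samples):
        for j, c in enumerate(chroms):
            ax = axes[i][j]
            sub = df[(df["sample"] == s) & (df["chrom"] == c)]
            ax.plot(sub["start_bp"], sub["mean_genotype"], lw=0.7, color="steelblue")
            ax.set_ylim(-0.05, 2.05)
            _shade(ax, c, spec.highlight)
            if j == 0:
                ax.set_ylabel(s, rotation=0, ha="right", fontsize=7)
            if i == 0:
                ax.set_title(c, fontsize=8)
            ax.tick_params(labelsize=6)
    fig.suptitle("windowed mean genotype per individual", fontsize=10)
    fig.tight_layout()
    return fig


def _plot_manhattan(df: pd.DataFrame, spec: PlotSpec):
    fig, ax = plt.subplots(figsize=(spec.width, spec.height))
    chroms = list(pd.unique(df["chrom"]))
    offset = 0
    ticks = []
    n_highlighted = 0
    out_keys = set()
    if spec.highlight_table:
        out = _read_table(spec.highlight_table)
        out = out[out.get("is_outlier", pd.Series(dtype=bool)) == True]  # noqa: E712
        out_keys = set(out["index"].astype(int))
    for ci, c in enumerate(chroms):
        sub = df[df["chrom"] == c]
        x = sub["start_bp"].to_numpy() + offset
        ax.scatter(x, sub["value"], s=4, color=["#3b6ea5", "#9ab7d3"][ci % 2])
        if out_keys:
            hi = sub.index.isin(out_keys)
            ax.scatter(x[hi], sub["value"].to_numpy()[hi], s=12, color="crimson",
                       zorder=3)
            n_highlighted += int(hi.sum())
        ticks.append((offset + x[-1]) / 2 if len(x) else offset)
        offset = x[-1] + 1 if len(x) else offset
    ax.set_xticks(ticks)
    ax.set_xticklabels(chroms, fontsize=8)
    ax.set_ylabel("value")
    fig.tight_layout()
    fig.n_highlighted = n_highlighted  # smoke-testable count
    return fig


def _plot_mds(df: pd.DataFrame, spec: PlotSpec):
    fig, ax = plt.subplots(figsize=(spec.width, spec.height))
    if spec.color_by and spec.color_by in df.columns:
        for g, sub in df.groupby(spec.color_by):
            ax.scatter(sub["axis1"], sub["axis2"], label=str(g), s=25)
        ax.legend(title=spec.color_by, fontsize=8)
    else:
        ax.scatter(df["axis1"], df["axis2"], s=25, color="steelblue")
    ax.set_xlabel("MDS axis 1")
    ax.set_ylabel("MDS axis 2")
    fig.tight_layout()
    return fig


def _plot_ld(df: pd.DataFrame, spec: PlotSpec):
    fig, ax = plt.subplots(figsize=(spec.width, spec.height))
    sc = ax.scatter(df["pos_a"], df["pos_b"], c=df["r2"], s=3, cmap="viridis",
                    vmin=0, vmax=1)
    fig.colorbar(sc, label="r²")
    ax.set_xlabel("position a (bp)")
    ax.set_ylabel("position b (bp)")
    fig.tight_layout()
    return fig
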
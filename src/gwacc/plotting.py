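"""Accuracy-accentuated Manhattan plots.

Both the genome-wise and the chromosome-wise view put -log10(p) on the
y-axis and color every point by an accuracy metric through a gray-to-
saturated ramp: low accuracy fades into gray, high accuracy stands out.
Even-numbered chromosomes use a blue family, odd-numbered a red family, so
adjacent chromosomes remain distinguishable while the accuracy accent is
preserved.  Every plotting call also returns (and can save) the exact
(x, y, color-value) table it drew, so plots are testable without pixel
comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.cm import ScalarMappable
from matplotlib.colors import LinearSegmentedColormap, Normalize

from ._util import ColumnError, GwaccError, chrom_sort_key, format_number, normalize_chrom

log = logging.getLogger(__name__)

CMAP_EVEN = LinearSegmentedColormap.from_list("accu_even", ["#c8c8c8", "#08519c"])
CMAP_ODD = LinearSegmentedColormap.from_list("accu_odd", ["#c8c8c8", "#a50f15"])

#: Gap inserted between chromosomes, as a fraction of the total genome span.
CHROM_GAP_FRACTION = 0.02


@dataclass
class PlotSpec:
    """Rendering options shared by both Manhattan views.

    metric: accuracy column used for point color (percent scale).
    vmin/vmax: metric range mapped onto the color ramp.
    highlight: (chrom, pos) loci marked with a dashed vertical line.
    sig_line: optional -log10(p) threshold drawn as a horizontal line.
    data_out: optional TSV path for the plotted-point table.
    """

    metric: str = "Avr_acc"
    vmin: float = 0.0
    vmax: float = 100.0
    highlight: list = field(default_factory=list)
    sig_line: float | None = None
    point_size: float = 10.0
    data_out: str | None = None

    def __post_init__(self) -> None:
        if not self.vmin < self.vmax:
            raise ValueError("color ramp bounds need vmin < vmax")


def _plottable(acc, spec: PlotSpec) -> pd.DataFrame:
    if "neg_log10_p" not in acc.data.columns:
        raise GwaccError("no neg_log10_p column; run add_pvalues before plotting")
    if spec.metric not in acc.data.columns:
        raise ColumnError(
            f"metric {spec.metric!r} not in table; available: {list(acc.data.columns)}"
        )
    df = pd.DataFrame(
        {
            "chrom": acc.data["#CHROM"].map(normalize_chrom),
            "pos": acc.data["POS"].astype(int),
            "neg_log10_p": acc.data["neg_log10_p"].astype(float),
            "color_value": acc.data[spec.metric].astype(float),
        }
    )
    df = df[np.isfinite(df["neg_log10_p"])].reset_index(drop=True)
    if df.empty:
        raise GwaccError("nothing to plot: every variant has an undefined p-value")
    return df


def _family(chrom: str, rank: int):
    """Blue ramp for even chromosomes, red for odd; rank parity as fallback."""
    num = int(chrom) if chrom.isdigit() else rank + 1
    return ("even", CMAP_EVEN) if num % 2 == 0 else ("odd", CMAP_ODD)


def _finish(fig, ax, spec: PlotSpec, df: pd.DataFrame, out):
    norm = Normalize(spec.vmin, spec.vmax)
    for cmap, tag in ((CMAP_EVEN, "even chr"), (CMAP_ODD, "odd chr")):
        cbar = fig.colorbar(ScalarMappable(norm=norm, cmap=cmap), ax=ax,
                            fraction=0.04, pad=0.02)
        cbar.set_label(f"{spec.metric} (%) — {tag}")
    if spec.sig_line is not None:
        ax.axhline(spec.sig_line, color="black", linestyle=":", linewidth=1)
    ax.set_ylabel(r"$-\log_{10}(p)$")
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
        log.info("saved plot to %s", out)
    plt.close(fig)
    if spec.data_out:
        df.to_csv(spec.data_out, sep="\t", index=False)


def manhattan_genome(acc, out=None, spec: PlotSpec | None = None) -> pd.DataFrame:
    """Genome-wise Manhattan plot; returns the plotted-point table.

    x is the cumulative genomic coordinate (per-chromosome offsets plus a
    small cosmetic gap), chromosome ticks sit at each chromosome's center,
    and the returned table holds one row per drawn point with columns
    chrom, pos, x, neg_log10_p, color_value, family.
    """
    spec = spec or PlotSpec()
    df = _plottable(acc, spec)

    order = sorted(df["chrom"].unique(), key=chrom_sort_key)
    spans = {c: df.loc[df["chrom"] == c, "pos"].max() for c in order}
    gap = max(1.0, CHROM_GAP_FRACTION * float(sum(spans.values())))
    offsets = {}
    cursor = 0.0
    for c in order:
        offsets[c] = cursor
        cursor += float(spans[c]) + gap
    df["x"] = df["pos"].astype(float) + df["chrom"].map(offsets)
    # offsets are separated by each chromosome's span plus the gap, so
    # sorting on x alone orders chromosomes and positions jointly
    df = df.sort_values("x", kind="stable").reset_index(drop=True)

    norm = Normalize(spec.vmin, spec.vmax)
    fig, ax = plt.subplots(figsize=(12, 4.5))
    families = []
    for rank, c in enumerate(order):
        sub = df[df["chrom"] == c]
        fam, cmap = _family(c, rank)
        families.append((c, fam))
        colors = cmap(norm(np.nan_to_num(sub["color_value"].to_numpy(), nan=spec.vmin)))
        ax.scatter(sub["x"], sub["neg_log10_p"], s=spec.point_size, c=colors,
                   linewidths=0, rasterized=True)
    fam_map = dict(families)
    df["family"] = df["chrom"].map(fam_map)

    for chrom, pos in spec.highlight:
        cn = normalize_chrom(chrom)
        if cn in offsets:
            ax.axvline(offsets[cn] + float(pos), color="black",
                       linestyle="--", linewidth=0.8)
    ax.set_xticks([offsets[c] + spans[c] / 2.0 for c in order])
    ax.set_xticklabels(order)
    ax.set_xlabel("chromosome")
    _finish(fig, ax, spec, df, out)
    return df


def manhattan_chromosome(acc, chrom, out=None, spec: PlotSpec | None = None,
                         annotate_top: int = 3) -> pd.DataFrame:
    """Chromosome-wise Manhattan plot with the top-metric points labeled.

    x is the base-pair position on ``chrom``; the ``annotate_top``
    highest-metric points carry their metric value in parentheses.  Returns
    the plotted-point table (columns as in :func:`manhattan_genome`).
    """
    spec = spec or PlotSpec()
    df = _plottable(acc, spec)
    cn = normalize_chrom(chrom)
    avail = sorted(df["chrom"].unique(), key=chrom_sort_key)
    df = df[df["chrom"] == cn].sort_values("pos").reset_index(drop=True)
    if df.empty:
        raise GwaccError(f"chromosome {chrom!r} not in table; available: {avail}")
    df["x"] = df["pos"].astype(float)
    rank = avail.index(cn)
    fam, cmap = _family(cn, rank)
    df["family"] = fam

    norm = Normalize(spec.vmin, spec.vmax)
    fig, ax = plt.subplots(figsize=(8, 4.5))
    colors = cmap(norm(np.nan_to_num(df["color_value"].to_numpy(), nan=spec.vmin)))
    ax.scatter(df["x"], df["neg_log10_p"], s=spec.point_size, c=colors,
               linewidths=0, rasterized=True)

    if annotate_top > 0:
        defined = df[np.isfinite(df["color_value"])]
        top = defined.nlargest(annotate_top, "color_value")
        for _, row in top.iterrows():
            ax.annotate(
                f"({format_number(row['color_value'])})",
                (row["x"], row["neg_log10_p"]),
                textcoords="offset points", xytext=(0, 6),
                ha="center", fontsize=8,
            )
    for hchrom, pos in spec.highlight:
        if normalize_chrom(hchrom) == cn:
            ax.axvline(float(pos), color="black", linestyle="--", linewidth=0.8)
    ax.set_xlabel(f"position on chromosome {cn} (bp)")
    _finish(fig, ax, spec, df, out)
    return df
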
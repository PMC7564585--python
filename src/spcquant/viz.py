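"""Graphical outputs: Venn, volcano, heatmap, p-value histograms, PQ-FDR, PCA.

Every figure is a pure rendering of a payload computed by the analysis
modules — the payload builders here (`venn_counts`, `volcano_points`,
`heatmap_selection`, `pvalue_histogram`, `pca_scores`) add no statistics of
their own, so each figure is recomputable from the output CSVs alone.
Rendering uses the non-interactive matplotlib Agg backend and is
deterministic.
"""

from __future__ import annotations

import io as _stdio
from math import acos, cos, pi, sin, sqrt

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.optimize import brentq
from sklearn.decomposition import PCA

from .comparison import Category, Stream
from .samesame import PQFDRCurve, TripletPartition
from .stringency import StateMatrix, StringencyPartition

__all__ = [
    "venn_counts",
    "plot_venn",
    "volcano_points",
    "plot_volcano",
    "heatmap_selection",
    "plot_heatmap",
    "pvalue_histogram",
    "plot_pvalue_histogram",
    "plot_pqfdr",
    "pca_scores",
    "plot_pca",
    "figure_to_png",
]


def figure_to_png(fig: plt.Figure, dpi: int = 150) -> bytes:
    buf = _stdio.BytesIO()
    fig.savefig(buf, format="png", dpi=dpi, bbox_inches="tight")
    plt.close(fig)
    return buf.getvalue()


# ---------------------------------------------------------------- Venn


def venn_counts(
    partition: StringencyPartition, control_state: str, treatment_state: str
) -> tuple[int, int, int]:
    """(unique to control, shared, unique to treatment) high-stringency counts.

    These are the raw set-overlap counts of the two per-state high-
    stringency inventories (proteins reproducibly identified in either
    sample, or both), as drawn in the proportional Venn diagram.
    """
    high_c = partition.high[control_state]
    high_t = partition.high[treatment_state]
    shared = high_c & high_t
    return len(high_c - high_t), len(shared), len(high_t - high_c)


def _lens_area(d: float, r1: float, r2: float) -> float:
    """Intersection area of two circles with radii r1, r2 at centre distance d."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return pi * min(r1, r2) ** 2
    a1 = acos((d * d + r1 * r1 - r2 * r2) / (2 * d * r1))
    a2 = acos((d * d + r2 * r2 - r1 * r1) / (2 * d * r2))
    return r1 * r1 * (a1 - sin(2 * a1) / 2) + r2 * r2 * (a2 - sin(2 * a2) / 2)


def plot_venn(
    counts: tuple[int, int, int], labels: tuple[str, str]
) -> plt.Figure:
    """Area-proportional two-circle Venn for (unique_a, shared, unique_b).

    Circle areas are proportional to set sizes and the centre distance is
    solved so the lens area matches the shared count.
    """
    only_a, shared, only_b = counts
    size_a, size_b = only_a + shared, only_b + shared
    if size_a == 0 and size_b == 0:
        raise ValueError("both sets empty; nothing to draw")
    r1 = sqrt(max(size_a, 1e-9) / pi)
    r2 = sqrt(max(size_b, 1e-9) / pi)
    if shared == 0:
        d = (r1 + r2) * 1.1
    elif shared >= min(size_a, size_b):
        d = abs(r1 - r2)
    else:
        d = brentq(lambda x: _lens_area(x, r1, r2) - shared, abs(r1 - r2) + 1e-12, r1 + r2 - 1e-12)

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for cx, r, color in ((0.0, r1, "#1f77b4"), (d, r2, "#ff7f0e")):
        ax.add_patch(plt.Circle((cx, 0), r, alpha=0.45, color=color, lw=0))
    ax.text(-r1 * 0.6 if shared else 0.0, 0, str(only_a), ha="center", va="center", fontsize=12)
    ax.text(d + r2 * 0.6 if shared else d, 0, str(only_b), ha="center", va="center", fontsize=12)
    if shared:
        ax.text((d + r1 - r2) / 2, 0, str(shared), ha="center", va="center", fontsize=12)
    ax.text(0, r1 * 1.08, labels[0], ha="center", fontsize=11)
    ax.text(d, r2 * 1.08, labels[1], ha="center", fontsize=11)
    lim = max(r1, d + r2) + 0.5
    ax.set_xlim(-r1 - 0.5, lim)
    ax.set_ylim(-max(r1, r2) - 0.5, max(r1, r2) + 0.8)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title("High-stringency protein overlap")
    return fig


# ---------------------------------------------------------------- volcano


def volcano_points(comparison_table: pd.DataFrame) -> pd.DataFrame:
    """Per tested protein: x = log2 fold change, y = -log10 p.

    p-values are floored at machine epsilon before the log so that
    near-zero p-values remain plottable.
    """
    tested = comparison_table[comparison_table["p_value"].notna()]
    p = np.maximum(tested["p_value"].to_numpy(float), np.finfo(float).eps)
    return pd.DataFrame(
        {
            "identifier": tested["identifier"].to_numpy(),
            "log2_fold_change": tested["log2_fold_change"].to_numpy(float),
            "neg_log10_p": -np.log10(p),
        }
    )


def plot_volcano(
    comparison_table: pd.DataFrame, alpha: float = 0.05, title: str = "Volcano plot"
) -> plt.Figure:
    pts = volcano_points(comparison_table)
    sig = pts["neg_log10_p"] > -np.log10(alpha)
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(pts.loc[~sig, "log2_fold_change"], pts.loc[~sig, "neg_log10_p"],
               s=10, c="grey", alpha=0.6, lw=0)
    ax.scatter(pts.loc[sig, "log2_fold_change"], pts.loc[sig, "neg_log10_p"],
               s=12, c="#d62728", alpha=0.8, lw=0)
    ax.axhline(-np.log10(alpha), ls="--", lw=0.8, c="k")
    ax.axvline(0, ls=":", lw=0.8, c="k")
    ax.set_xlabel("log2 fold change (treatment / control, NSAF)")
    ax.set_ylabel("-log10 p (Students t-test)")
    ax.set_title(title)
    return fig


# ---------------------------------------------------------------- heatmap


def heatmap_selection(comparison_table: pd.DataFrame, k: int = 20) -> list[str]:
    """Identifiers of the top-k most significant tested proteins.

    Ranked by ascending p-value; ties broken by descending |log2 fold
    change|, then ascending identifier. Truncates to the number of tested
    proteins when fewer than k exist.
    """
    tested = comparison_table[comparison_table["p_value"].notna()].copy()
    tested["abs_fc"] = tested["log2_fold_change"].abs()
    ranked = tested.sort_values(
        ["p_value", "abs_fc", "identifier"],
        ascending=[True, False, True],
        kind="stable",
    )
    return list(ranked["identifier"].head(k))


def plot_heatmap(
    selection: list[str],
    ln_nsaf_control: pd.DataFrame,
    ln_nsaf_treatment: pd.DataFrame,
    control_state: str,
    treatment_state: str,
    *,
    row_standardise: bool = True,
) -> plt.Figure:
    """lnNSAF heatmap of the selected proteins across every replicate.

    Rows are z-scored per protein by default so relative patterns are
    comparable across abundance scales; raw-lnNSAF mode is available.
    """
    block = pd.concat(
        [
            ln_nsaf_control.loc[selection].add_prefix(f"{control_state}-R"),
            ln_nsaf_treatment.loc[selection].add_prefix(f"{treatment_state}-R"),
        ],
        axis=1,
    )
    values = block.to_numpy(float)
    if row_standardise:
        mu = values.mean(axis=1, keepdims=True)
        sd = values.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        values = (values - mu) / sd
    fig, ax = plt.subplots(figsize=(max(6, 0.5 * block.shape[1]), max(4, 0.3 * len(selection))))
    im = ax.imshow(values, aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(block.shape[1]), block.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(selection)), selection, fontsize=7)
    fig.colorbar(im, ax=ax, label="row-standardised lnNSAF" if row_standardise else "lnNSAF")
    ax.set_title(f"Top {len(selection)} differentially expressed proteins")
    return fig


# ---------------------------------------------------------------- p-value histogram


def pvalue_histogram(p_values: np.ndarray, bin_width: float = 0.05) -> pd.DataFrame:
    """Fixed-width bin counts on [0, 1]; the first bin holds p < bin_width."""
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(p, bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def plot_pvalue_histogram(
    p_values: np.ndarray, title: str, bin_width: float = 0.05
) -> plt.Figure:
    hist = pvalue_histogram(p_values, bin_width)
    fig, ax = plt.subplots(figsize=(6, 4))
    colors = ["#1a6b32"] + ["#8fce9f"] * (len(hist) - 1)  # first bin (p < 0.05) dark
    ax.bar(hist["bin_left"], hist["count"], width=bin_width, align="edge",
           color=colors, edgecolor="white")
    ax.set_xlabel("p-value (Students t-test)")
    ax.set_ylabel("number of proteins")
    ax.set_title(title)
    return fig


# ---------------------------------------------------------------- PQ-FDR


def plot_pqfdr(
    grand_average: PQFDRCurve,
    state_averages: list[PQFDRCurve],
    q_star: float | None = None,
    target: float = 1.0,
) -> plt.Figure:
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for c in state_averages:
        ax.plot(c.q_grid, c.pqfdr, lw=1, alpha=0.6, label=c.source)
    ax.plot(grand_average.q_grid, grand_average.pqfdr, lw=2, c="k", label="grand average")
    ax.axhline(target, ls="--", lw=0.8, c="r")
    if q_star is not None:
        ax.axvline(q_star, ls="--", lw=0.8, c="r")
        ax.annotate(f"Q = {q_star:.3f}", (q_star, target), textcoords="offset points",
                    xytext=(6, 6), fontsize=9)
    ax.set_xlabel("BH Q value threshold")
    ax.set_ylabel("PQ-FDR (%)")
    ax.set_title("Same-same permutation PQ-FDR")
    ax.legend(fontsize=7)
    return fig


# ---------------------------------------------------------------- PCA


def pca_scores(matrix: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Replicate scores on the first two principal components.

    *matrix* is protein x replicate; replicates are the observations and
    proteins the variables, centred per protein (the standard feature
    centring), unscaled. Returns (scores indexed by replicate column,
    explained-variance fractions).
    """
    if matrix.shape[1] < 3:
        raise ValueError("PCA needs at least 3 replicate columns")
    X = matrix.to_numpy(float).T  # observations = replicates
    pca = PCA(n_components=2)
    scores = pca.fit_transform(X)
    if pca.explained_variance_[1] <= 1e-12 and pca.explained_variance_[0] <= 1e-12:
        raise ValueError("fewer than 2 non-degenerate components")
    return (
        pd.DataFrame(scores, index=matrix.columns, columns=["PC1", "PC2"]),
        pca.explained_variance_ratio_,
    )


def plot_pca(
    matrices: dict[str, pd.DataFrame],
    title: str,
    group_of: dict[str, str] | None = None,
) -> plt.Figure:
    """Inter-state (or same-same) PCA of replicate profiles.

    *matrices* maps state label -> protein x replicate matrix; the state
    matrices are outer-joined on proteins (missing entries 0) and each
    replicate becomes one observation. `group_of` optionally recolours
    replicates by same-same partition group instead of by state.
    """
    labelled = []
    for state, m in matrices.items():
        labelled.append(m.add_prefix(f"{state}-R"))
    joined = pd.concat(labelled, axis=1).fillna(0.0)
    scores, evr = pca_scores(joined)
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    groups = (
        {col: group_of.get(col, "?") for col in scores.index}
        if group_of
        else {col: col.rsplit("-R", 1)[0] for col in scores.index}
    )
    for g in sorted(set(groups.values())):
        cols = [c for c in scores.index if groups[c] == g]
        ax.scatter(scores.loc[cols, "PC1"], scores.loc[cols, "PC2"], label=g, s=40)
        for c in cols:
            ax.annotate(c, scores.loc[c], fontsize=6, xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel(f"PC1 ({100 * evr[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * evr[1]:.1f}%)")
    ax.set_title(title)
    ax.legend(fontsize=8)
    return fig
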
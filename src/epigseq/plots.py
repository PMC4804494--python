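"""Visual outputs: per-pattern profile plots, a heatmap of the clustered
genes and a principal-coordinate plot of the samples.

All plots show log2 RPM ratios to the mean of the control samples.  The
sample embedding uses classical scaling of the sample-by-sample CY_s
similarity computed over the clustered genes only: the similarity matrix is
double-centred and eigendecomposed, and the first three coordinates are
plotted.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .io_counts import CountMatrix, RatioMatrix  # noqa: E402
from .similarity import DEFAULT_ZERO_SUB, cy_matrix  # noqa: E402

__all__ = ["plot_pattern_profiles", "plot_heatmap", "plot_pca", "sample_coordinates"]

_FORMATS = ("png", "svg")


def _group_colors(group_labels):
    groups = []
    for g in group_labels:
        if g not in groups:
            groups.append(g)
    cmap = plt.get_cmap("tab10")
    color_of = {g: cmap(i % 10) for i, g in enumerate(groups)}
    return groups, color_of


def _save(fig, outdir: Path, stem: str):
    paths = []
    for fmt in _FORMATS:
        p = Path(outdir) / f"{stem}.{fmt}"
        fig.savefig(p, format=fmt)
        paths.append(p)
    plt.close(fig)
    return paths


def plot_pattern_profiles(result, ratio: RatioMatrix, outdir) -> list:
    """One profile plot per pattern showing its representative gene."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    groups, color_of = _group_colors(ratio.group_labels)
    written = []
    for cl in result.clusters:
        fig, ax = plt.subplots(figsize=(5, 3.2))
        y = ratio.values[cl.representative]
        x = np.arange(len(y))
        for g in groups:
            cols = [j for j, lbl in enumerate(ratio.group_labels) if lbl == g]
            ax.plot(x[cols], y[cols], "o-", color=color_of[g], label=g, ms=4)
        ax.axhline(0.0, color="0.6", lw=0.8)
        ax.set_title(f"Pattern {cl.number}: {ratio.gene_ids[cl.representative]}")
        ax.set_xlabel("sample")
        ax.set_ylabel("log2 RPM ratio vs control mean")
        ax.legend(fontsize=6, ncol=2)
        fig.tight_layout()
        written += _save(fig, outdir, f"pattern_{cl.number}_profile")
    return written


def plot_heatmap(result, ratio: RatioMatrix, outdir) -> list:
    """Heatmap of all clustered genes, ordered by pattern, diverging scale
    centred at 0; row colours mark the pattern."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    order, row_pattern = [], []
    for cl in result.clusters:
        order += list(cl.members)
        row_pattern += [cl.number] * len(cl.members)
    if not order:
        raise ValueError("no clustered genes to draw")
    data = ratio.values[order]
    vmax = max(1e-9, np.nanmax(np.abs(data)))
    fig, (ax_pat, ax) = plt.subplots(
        1, 2, figsize=(7, max(3.0, 0.08 * len(order) + 1.5)),
        gridspec_kw={"width_ratios": [1, 30], "wspace": 0.02},
    )
    ax.imshow(data, aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax,
              interpolation="nearest")
    ax_pat.imshow(np.array(row_pattern)[:, None], aspect="auto", cmap="tab10",
                  interpolation="nearest")
    ax_pat.set_xticks([])
    ax_pat.set_yticks([])
    ax.set_yticks([])
    ax.set_xticks(range(len(ratio.group_labels)))
    ax.set_xticklabels(ratio.group_labels, rotation=90, fontsize=5)
    ax.set_title("log2 RPM ratio vs control mean")
    return _save(fig, outdir, "heatmap")


def sample_coordinates(result, cm: CountMatrix,
                       zero_sub: float = DEFAULT_ZERO_SUB) -> np.ndarray:
    """Classical-scaling coordinates of samples from sample x sample CY_s.

    Sample profiles are the count vectors over the clustered genes; the
    similarity matrix is double-centred and eigendecomposed, and coordinates
    are eigenvectors scaled by the square roots of the non-negative
    eigenvalues (largest first).
    """
    genes = [g for cl in result.clusters for g in cl.members]
    if len(genes) < 3:
        raise ValueError("need at least 3 clustered genes for the embedding")
    X = cm.counts[genes].T.astype(float)  # samples x clustered genes
    keep = ~(X == 0).all(axis=1)
    if not keep.all():
        raise ValueError("a sample has zero counts over every clustered gene")
    S = cy_matrix(X, zero_sub=zero_sub)
    n = S.shape[0]
    H = np.eye(n) - np.ones((n, n)) / n
    K = H @ S @ H
    vals, vecs = np.linalg.eigh(K)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    coords = vecs * np.sqrt(np.clip(vals, 0.0, None))
    return coords


def plot_pca(result, cm: CountMatrix, outdir,
             zero_sub: float = DEFAULT_ZERO_SUB) -> list:
    """3-D scatter of the first three sample coordinates, coloured by group."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    coords = sample_coordinates(result, cm, zero_sub=zero_sub)
    if coords.shape[1] < 3 or np.allclose(coords[:, 0], coords[0, 0]):
        # degenerate similarity: all samples effectively identical
        coords = np.zeros((cm.n_samples, 3))
    groups, color_of = _group_colors(cm.group_labels)
    fig = plt.figure(figsize=(5, 4.2))
    ax = fig.add_subplot(projection="3d")
    for g in groups:
        cols = [j for j, lbl in enumerate(cm.group_labels) if lbl == g]
        ax.scatter(coords[cols, 0], coords[cols, 1], coords[cols, 2],
                   color=color_of[g], label=g, s=18)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.set_zlabel("PC3")
    ax.legend(fontsize=6, ncol=2)
    return _save(fig, outdir, "pca")
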
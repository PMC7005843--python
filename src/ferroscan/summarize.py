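"""Comparative summaries across samples: count matrices, normalisation,
row scaling, Ward/Euclidean clustering with bootstrap support, exports.

The count matrix has one row per functional category (the fixed 12-label
schema) and one column per sample; a cell counts the *distinct* evidence
genes contributing to that category's calls in that sample (a gene counts
once per category even when several rules cite it).  Normalisation divides
by the sample's total predicted ORFs and multiplies by 100 (percent of
ORFs).  For the heatmap/dendrogram, category rows are z-scored with the
sample (n-1) standard deviation; samples are then clustered with Ward's
method on Euclidean distances.  Cluster uncertainty is assessed with an
ordinary bootstrap over category rows: the support of an internal node is
the percentage of resampled matrices whose Ward tree contains the same
leaf set.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .family_db import CATEGORY_SCHEMA
from .neighborhoods import CategoryCall
from .sequence_io import SampleInput


def count_matrix(samples: list[tuple[SampleInput, list[CategoryCall]]]) -> pd.DataFrame:
    """Category x sample matrix of distinct evidence-gene counts."""
    if not samples:
        raise ValueError("at least one sample is required")
    data = {}
    for sample, calls in samples:
        col = {}
        for cat in CATEGORY_SCHEMA:
            genes: set[str] = set()
            for c in calls:
                if c.category == cat:
                    genes |= c.evidence_genes
            col[cat] = len(genes)
        data[sample.sample_id] = col
    return pd.DataFrame(data, index=list(CATEGORY_SCHEMA), dtype=float)


def normalize(matrix: pd.DataFrame, orf_counts: dict[str, int]) -> pd.DataFrame:
    """Cells as percent of each sample's predicted protein-coding genes."""
    out = matrix.copy()
    for col in out.columns:
        if col not in orf_counts:
            raise ValueError(f"missing orf_count for sample {col!r}")
        n = orf_counts[col]
        if n <= 0:
            raise ValueError(f"sample {col!r}: orf_count must be positive")
        out[col] = 100.0 * out[col] / n
    return out


def scale_rows(matrix: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Z-score each category row (mean 0, sd 1); constant rows become 0."""
    if matrix.shape[1] < 2:
        raise ValueError("row scaling requires at least 2 samples")
    vals = matrix.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=ddof, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = (vals - mean) / sd
    scaled[np.broadcast_to(sd == 0, scaled.shape)] = 0.0
    scaled = np.nan_to_num(scaled, nan=0.0)
    return pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns)


@dataclass
class Dendrogram:
    """Ward merge tree over samples with optional bootstrap support.

    ``linkage`` is a scipy linkage matrix over ``labels`` (sorted sample
    ids); ``support`` maps each internal node's leaf set to the percentage
    of bootstrap trees containing it (``None`` when not computed).
    """

    labels: list[str]
    linkage: np.ndarray
    support: dict[frozenset, float] | None = None

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def clades(self) -> list[frozenset]:
        """Leaf-label sets of all internal nodes, in merge order."""
        n = len(self.labels)
        sets: dict[int, frozenset] = {i: frozenset({self.labels[i]}) for i in range(n)}
        out = []
        for k, (a, b, *_rest) in enumerate(self.linkage):
            merged = sets[int(a)] | sets[int(b)]
            sets[n + k] = merged
            out.append(merged)
        return out

    def newick(self) -> str:
        """Newick string with bootstrap support as internal-node labels."""
        n = len(self.labels)
        children: dict[int, tuple[int, int]] = {}
        for k, row in enumerate(self.linkage):
            children[n + k] = (int(row[0]), int(row[1]))
        clades = self.clades()

        def height(node: int) -> float:
            return 0.0 if node < n else float(self.linkage[node - n, 2])

        def render(node: int, parent_h: float) -> str:
            bl = parent_h - height(node)
            if node < n:
                return f"{self.labels[node]}:{bl:.6g}"
            a, b = children[node]
            h = height(node)
            label = ""
            if self.support is not None:
                s = self.support.get(clades[node - n])
                if s is not None:
                    label = f"{s:.6g}"
            return f"({render(a, h)},{render(b, h)}){label}:{bl:.6g}"

        root = n + len(clades) - 1
        a, b = children[root]
        h = height(root)
        label = ""
        if self.support is not None:
            s = self.support.get(clades[-1])
            if s is not None:
                label = f"{s:.6g}"
        return f"({render(a, h)},{render(b, h)}){label};"


def _ward_linkage(data: np.ndarray) -> np.ndarray:
    # observations are samples (rows of `data`)
    return hierarchy.linkage(data, method="ward", metric="euclidean")


def ward_cluster(matrix: pd.DataFrame, seed: int = 0, bootstrap_b: int = 0) -> Dendrogram:
    """Ward/Euclidean agglomerative clustering of samples.

    Columns are sorted by sample id before clustering, making the tree
    invariant to input column order.  With ``bootstrap_b`` > 0 and at least
    3 samples, per-node support is the percentage of category-resampled
    (with replacement) matrices whose Ward tree contains the node's leaf
    set; the root's support is 100 by construction.
    """
    if matrix.shape[1] < 2:
        raise ValueError("clustering requires at least 2 samples")
    matrix = matrix.reindex(columns=sorted(matrix.columns))
    labels = list(matrix.columns)
    data = matrix.to_numpy(dtype=float).T
    Z = _ward_linkage(data)
    dg = Dendrogram(labels=labels, linkage=Z)
    if bootstrap_b > 0:
        if len(labels) < 3:
            dg.support = None
            return dg
        rng = np.random.default_rng(seed)
        target = dg.clades()
        counts = {c: 0 for c in target}
        n_rows = matrix.shape[0]
        for _ in range(bootstrap_b):
            rows = rng.integers(0, n_rows, size=n_rows)
            bz = _ward_linkage(matrix.to_numpy(dtype=float)[rows, :].T)
            bclades = set(Dendrogram(labels=labels, linkage=bz).clades())
            for c in target:
                if c in bclades:
                    counts[c] += 1
        dg.support = {c: 100.0 * counts[c] / bootstrap_b for c in target}
    return dg


def export(
    matrix: pd.DataFrame,
    dendrogram: Dendrogram | None,
    calls: list[CategoryCall],
    outdir: str | Path,
    normalized: pd.DataFrame | None = None,
    render_figures: bool = False,
) -> dict[str, Path]:
    """Write matrix TSV, long-format dot-plot TSV, Newick tree and
    (optionally) rendered figures.  Returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    path = outdir / "category_counts.tsv"
    matrix.to_csv(path, sep="\t", float_format="%.6g", index_label="category")
    written["matrix"] = path

    dot_source = normalized if normalized is not None else matrix
    rows = [
        {"sample": s, "category": c, "value": float(dot_source.loc[c, s])}
        for s in dot_source.columns
        for c in dot_source.index
    ]
    path = outdir / "dotplot.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
    written["dotplot"] = path

    if normalized is not None:
        path = outdir / "category_counts_normalized.tsv"
        normalized.to_csv(path, sep="\t", float_format="%.6g", index_label="category")
        written["normalized"] = path

    if dendrogram is not None:
        path = outdir / "samples.newick"
        path.write_text(dendrogram.newick() + "\n")
        written["tree"] = path

    if calls:
        from .neighborhoods import write_calls_csv

        path = outdir / "category_calls.csv"
        write_calls_csv(calls, path)
        written["calls"] = path

    if render_figures:
        written.update(_render_figures(matrix, dendrogram, outdir))
    return written


def _render_figures(matrix: pd.DataFrame, dendrogram: Dendrogram | None, outdir: Path) -> dict[str, Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = {}
    fig, ax = plt.subplots(figsize=(max(4, matrix.shape[1]), 6))
    im = ax.imshow(matrix.to_numpy(dtype=float), aspect="auto", cmap="viridis")
    ax.set_yticks(range(len(matrix.index)), matrix.index, fontsize=7)
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=90, fontsize=7)
    fig.colorbar(im, ax=ax, shrink=0.6)
    fig.tight_layout()
    path = outdir / "heatmap.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written["heatmap"] = path

    if dendrogram is not None:
        fig, ax = plt.subplots(figsize=(6, 4))
        hierarchy.dendrogram(dendrogram.linkage, labels=dendrogram.labels, ax=ax)
        ax.tick_params(axis="x", rotation=90, labelsize=7)
        fig.tight_layout()
        path = outdir / "dendrogram.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written["dendrogram"] = path
    return written
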
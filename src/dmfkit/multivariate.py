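"""Sample-level multivariate views of the fragment-methylation matrix.

PCA operates on samples as observations and fragments as variables: each
fragment is centred across samples (no unit-variance scaling by default) and
scores come from the singular value decomposition.  Component signs are
fixed by flipping each loading vector so its largest-magnitude entry is
positive, making outputs reproducible across BLAS implementations.

Hierarchical clustering defaults to Euclidean distance with complete
linkage, which guarantees monotone merge heights and deterministic trees.
The heatmap exporter re-orders the matrix by dendrogram leaf order and
bundles it with cohort (column) and genome-region (row) annotations, ready
for any plotting front-end.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "PcaResult",
    "ClusteringResult",
    "HeatmapBundle",
    "pca_samples",
    "hclust_samples",
    "heatmap_export",
]


@dataclass
class PcaResult:
    """Sample scores, per-component variance fractions, fragment loadings."""

    scores: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame  # fragments x components

    def write(self, scores_path: str | Path, variance_path: str | Path) -> None:
        self.scores.to_csv(scores_path, sep="\t")
        pd.DataFrame(
            {
                "component": self.scores.columns,
                "variance_fraction": self.explained_variance_ratio,
            }
        ).to_csv(variance_path, sep="\t", index=False)


def pca_samples(
    percent: pd.DataFrame, n_components: int | None = None, scale: bool = False
) -> PcaResult:
    """PCA of samples over a complete (no missing values) fragment subset.

    ``percent`` is fragments x samples.  Components are ordered by
    decreasing variance; the variance fractions are the squared singular
    values over the total fragment-wise variance.
    """
    if percent.shape[0] < 1:
        raise ValueError("need at least one fragment")
    if percent.shape[1] < 3:
        raise ValueError("need at least three samples")
    x = percent.to_numpy(float).T  # samples x fragments
    if not np.all(np.isfinite(x)):
        raise ValueError("matrix contains missing values; filter first")
    x = x - x.mean(axis=0, keepdims=True)
    if scale:
        sd = x.std(axis=0, ddof=1)
        x = x / np.where(sd > 0, sd, 1.0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    max_rank = min(x.shape[0] - 1, x.shape[1])
    m = max_rank if n_components is None else min(n_components, max_rank)
    # deterministic sign: largest-magnitude loading entry positive
    for j in range(m):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    total_var = (s**2).sum()
    ratio = (s[:m] ** 2) / total_var if total_var > 0 else np.zeros(m)
    comps = [f"PC{j + 1}" for j in range(m)]
    scores = pd.DataFrame(
        u[:, :m] * s[:m], index=percent.columns, columns=comps
    )
    loadings = pd.DataFrame(vt[:m].T, index=percent.index, columns=comps)
    return PcaResult(scores=scores, explained_variance_ratio=ratio, loadings=loadings)


@dataclass
class ClusteringResult:
    """Agglomerative merge tree over samples (scipy linkage encoding)."""

    linkage: np.ndarray
    labels: list[str]
    metric: str = "euclidean"
    method: str = "complete"

    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage)
        return [self.labels[i] for i in order]

    def cut(self, k: int) -> pd.Series:
        """Flat cluster ids (1..k) from cutting the dendrogram at k clusters."""
        assign = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(assign, index=self.labels, name="cluster")

    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                length = parent_height
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{parent_height - node.dist:.6g}"

        body = walk(tree, tree.dist)
        return body + ";"


def hclust_samples(
    percent: pd.DataFrame, metric: str = "euclidean", method: str = "complete"
) -> ClusteringResult:
    """Agglomerative clustering of samples on their fragment profiles."""
    if percent.shape[1] < 2:
        raise ValueError("need at least two samples")
    x = percent.to_numpy(float).T
    if not np.all(np.isfinite(x)):
        raise ValueError("matrix contains missing values; filter first")
    d = pdist(x, metric=metric)
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite distances")
    z = hierarchy.linkage(d, method=method)
    return ClusteringResult(
        linkage=z, labels=list(percent.columns), metric=metric, method=method
    )


@dataclass
class HeatmapBundle:
    """Dendrogram-ordered matrix with row-region and column-group annotations."""

    values: pd.DataFrame
    row_annotations: pd.Series
    col_annotations: pd.Series

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.values.to_csv(outdir / "heatmap_values.tsv", sep="\t")
        self.row_annotations.rename("region").to_csv(
            outdir / "heatmap_rows.tsv", sep="\t"
        )
        self.col_annotations.rename("group").to_csv(
            outdir / "heatmap_cols.tsv", sep="\t"
        )

    @classmethod
    def read(cls, outdir: str | Path) -> "HeatmapBundle":
        outdir = Path(outdir)
        values = pd.read_csv(outdir / "heatmap_values.tsv", sep="\t", index_col=0)
        rows = pd.read_csv(outdir / "heatmap_rows.tsv", sep="\t", index_col=0)["region"]
        cols = pd.read_csv(outdir / "heatmap_cols.tsv", sep="\t", index_col=0)["group"]
        return cls(values=values, row_annotations=rows, col_annotations=cols)


def heatmap_export(
    percent: pd.DataFrame,
    row_annotations: pd.Series,
    col_annotations: pd.Series,
    col_clustering: ClusteringResult | None = None,
    row_clustering: ClusteringResult | None = None,
) -> HeatmapBundle:
    """Order the matrix by dendrogram leaves and attach annotations.

    Without a clustering the identity ordering is kept.  The output matrix
    is a pure permutation of the input.
    """
    if len(row_annotations) != percent.shape[0]:
        raise ValueError("row annotation length mismatch")
    if len(col_annotations) != percent.shape[1]:
        raise ValueError("column annotation length mismatch")
    values = percent
    if col_clustering is not None:
        values = values[col_clustering.leaf_order()]
    if row_clustering is not None:
        values = values.loc[row_clustering.leaf_order()]
    return HeatmapBundle(
        values=values,
        row_annotations=row_annotations.reindex(values.index),
        col_annotations=col_annotations.reindex(values.columns),
    )
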
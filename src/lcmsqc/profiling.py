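"""Downstream multivariate and univariate profiling statistics.

PCA on log2-transformed, mean-centered (unscaled) data; per-feature
one-way fixed-effects ANOVA with Benjamini-Hochberg FDR adjustment; and
average-linkage hierarchical clustering with heatmap/Newick export.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests


@dataclass
class PCAResult:
    """Scores (samples x components), loadings (features x components) and
    per-component explained-variance fractions."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_explained: np.ndarray
    dropped_features: list[str]


def pca(matrix: pd.DataFrame, n_components: int = 5) -> PCAResult:
    """SVD-based PCA of a samples x features matrix.

    Columns are mean-centered, not scaled.  Features containing missing
    values are dropped (and reported) rather than imputed.  Sign
    convention: the largest-magnitude loading of each component is made
    positive, so results are deterministic.
    """
    dropped = list(matrix.columns[matrix.isna().any(axis=0)])
    X = matrix.drop(columns=dropped)
    if X.shape[1] == 0:
        raise ValueError("no complete features left for PCA")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc.to_numpy(dtype=float), full_matrices=False)
    k = min(n_components, len(s))
    # deterministic sign: largest |loading| positive per component
    for j in range(k):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = U[:, :k] * s[:k]
    total_var = float((s**2).sum())
    var_exp = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    comp = [f"PC{j + 1}" for j in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=X.index, columns=comp),
        loadings=pd.DataFrame(Vt[:k].T, index=X.columns, columns=comp),
        variance_explained=var_exp,
        dropped_features=dropped,
    )


def per_feature_anova(
    matrix: pd.DataFrame, class_labels: pd.Series | np.ndarray
) -> pd.DataFrame:
    """One-way fixed-effects F-test per feature, BH-adjusted across features.

    ``matrix`` is samples x features (log2, replicate-averaged);
    ``class_labels`` aligns with its rows.  Returns a DataFrame with
    columns F, p and q (Benjamini-Hochberg).
    """
    labels = np.asarray(class_labels)
    if len(labels) != matrix.shape[0]:
        raise ValueError("class labels do not align with matrix rows")
    classes = pd.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    groups = [matrix.to_numpy(dtype=float)[labels == c] for c in classes]
    if any(g.shape[0] < 2 for g in groups):
        raise ValueError("need at least two replicates per class")
    F, p = stats.f_oneway(*groups, axis=0)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame({"F": F, "p": p, "q": q}, index=matrix.columns)


@dataclass
class ClusterResult:
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list
    col_order: list
    ordered_matrix: pd.DataFrame
    row_labels: list = None  # original input order, for dendrogram export
    col_labels: list = None


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


def cluster_heatmap(
    matrix: pd.DataFrame,
    metric: str = "euclidean",
    method: str = "average",
    standardize_rows: bool = True,
    png_path: str | None = None,
) -> ClusterResult:
    """Agglomerative clustering of rows and columns of a profile matrix.

    ``matrix`` is typically features x cultivars of replicate-averaged
    log2 intensities.  Rows are z-standardized for display by default
    (clustering runs on the displayed values).  Leaf order is scipy's
    deterministic order (ties broken by input index).  Optionally writes a
    heatmap PNG.
    """
    M = matrix.copy().astype(float)
    if M.isna().any().any():
        raise ValueError("matrix must be complete for clustering")
    if standardize_rows:
        sd = M.std(axis=1, ddof=0).replace(0.0, 1.0)
        M = M.sub(M.mean(axis=1), axis=0).div(sd, axis=0)
    def _cluster(X, labels):
        if X.shape[0] < 2:  # a single item: nothing to merge
            return np.empty((0, 4)), list(labels)
        Z = hierarchy.linkage(pdist(X, metric=metric), method=method)
        return Z, list(np.asarray(labels)[hierarchy.leaves_list(Z)])

    row_Z, row_order = _cluster(M.to_numpy(), M.index)
    col_Z, col_order = _cluster(M.to_numpy().T, M.columns)
    ordered = M.loc[row_order, col_order]
    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(max(4, 0.5 * len(col_order)), max(4, 0.12 * len(row_order)))
        )
        im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="RdBu_r")
        ax.set_xticks(range(len(col_order)), col_order, rotation=90, fontsize=7)
        ax.set_yticks([])
        fig.colorbar(im, ax=ax, label="standardized log2 abundance")
        fig.tight_layout()
        fig.savefig(png_path, dpi=150)
        plt.close(fig)
    return ClusterResult(
        row_Z, col_Z, row_order, col_order, ordered,
        row_labels=[str(r) for r in M.index],
        col_labels=[str(c) for c in M.columns],
    )


def dendrogram_newick(result: ClusterResult, axis: str = "columns") -> str:
    """Export a clustering dendrogram in Newick form.

    Leaf names come from the matrix labels in their original input order
    (linkage node ids index that order).
    """
    if axis == "columns":
        return _linkage_to_newick(result.col_linkage, result.col_labels)
    if axis == "rows":
        return _linkage_to_newick(result.row_linkage, result.row_labels)
    raise ValueError("axis must be 'rows' or 'columns'")
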
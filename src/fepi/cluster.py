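"""Hierarchical clustering of genes by their log2 fold-change profiles.

Genes are rows, contrasts are columns; cells hold log2(mean fold change) and
are missing where the fold was undetermined (zero-control genes).  Distances
are computed pairwise-complete over the cells both genes share; the default
metric is correlation distance (1 - Pearson) with average linkage, which
groups genes by profile shape, and Euclidean distance is available as an
alternative.  Ties are broken so that the tree, and its depth-first leaf
order, are invariant to input gene order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

__all__ = [
    "ClusterResult",
    "log2_fold_matrix",
    "hierarchical_cluster",
    "to_newick",
]


def log2_fold_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Overlap table -> genes x [fe, pi] matrix of log2 folds (NaN = missing)."""
    for side in ("fe", "pi"):
        bad = (~table[f"{side}_undetermined"]) & (table[f"{side}_mean"] <= 0)
        if bad.any():
            raise ValueError(f"non-positive fold for {list(table.index[bad])}")
    out = pd.DataFrame(index=table.index)
    for side in ("fe", "pi"):
        vals = np.log2(table[f"{side}_mean"].to_numpy(dtype=float))
        vals[table[f"{side}_undetermined"].to_numpy(bool)] = np.nan
        out[side] = vals
    return out


def _pairwise_distance(x: np.ndarray, metric: str) -> np.ndarray:
    """Condensed pairwise-complete distance matrix over rows of ``x``."""
    n = x.shape[0]
    out = np.empty(n * (n - 1) // 2)
    idx = 0
    for i in range(n):
        for j in range(i + 1, n):
            both = np.isfinite(x[i]) & np.isfinite(x[j])
            a, b = x[i, both], x[j, both]
            if metric == "euclidean":
                # scale up so sparsely-shared profiles are comparable
                d = np.sqrt(a.size and ((a - b) ** 2).sum() * x.shape[1] / a.size)
                out[idx] = d if a.size else np.inf
            else:  # correlation distance
                if a.size < 2:
                    out[idx] = 2.0  # no shared information: maximal distance
                elif a.std() == 0 or b.std() == 0:
                    out[idx] = 0.0 if np.allclose(a, b) else 1.0
                else:
                    out[idx] = 1.0 - np.corrcoef(a, b)[0, 1]
            idx += 1
    return out


@dataclass
class ClusterResult:
    genes: list[str]           # lexicographic order used for the linkage
    linkage: np.ndarray        # scipy linkage matrix
    leaf_order: list[str]      # depth-first leaf order of the tree
    excluded: list[str]        # genes with no finite cell

    def ordered_matrix(self, matrix: pd.DataFrame) -> pd.DataFrame:
        return matrix.loc[self.leaf_order]


def hierarchical_cluster(
    matrix: pd.DataFrame,
    linkage: str = "average",
    distance: str = "correlation",
) -> ClusterResult:
    """Agglomeratively cluster the rows of a log2-fold matrix.

    Genes whose cells are all missing are excluded (and reported in the
    result); at least two scorable genes are required.  Input rows are sorted
    lexicographically before linkage so that merge-distance ties resolve by
    smallest gene id and the output is independent of input order.
    """
    if distance not in ("correlation", "euclidean"):
        raise ValueError("distance must be 'correlation' or 'euclidean'")
    vals = matrix.to_numpy(dtype=float)
    usable = np.isfinite(vals).any(axis=1)
    excluded = sorted(matrix.index[~usable])
    genes = sorted(matrix.index[usable])
    if len(genes) < 2:
        raise ValueError("need at least two genes with data to cluster")
    x = matrix.loc[genes].to_numpy(dtype=float)
    dist = _pairwise_distance(x, distance)
    z = hierarchy.linkage(dist, method=linkage)
    leaves = hierarchy.leaves_list(z)
    return ClusterResult(
        genes=genes,
        linkage=z,
        leaf_order=[genes[i] for i in leaves],
        excluded=excluded,
    )


def to_newick(result: ClusterResult) -> str:
    """Dendrogram as Newick; branch lengths are merge-height differences."""
    tree = hierarchy.to_tree(result.linkage)

    def walk(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{result.genes[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    if tree.is_leaf():
        return f"{result.genes[tree.id]};"
    left = walk(tree.left, tree.dist)
    right = walk(tree.right, tree.dist)
    return f"({left},{right});"


def plot_heatmap(result: ClusterResult, matrix: pd.DataFrame, path) -> None:
    """Optional heatmap of the leaf-ordered matrix (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = result.ordered_matrix(matrix)
    fig, ax = plt.subplots(figsize=(4, max(2, 0.12 * len(ordered))))
    masked = np.ma.masked_invalid(ordered.to_numpy())
    cmap = plt.get_cmap("RdBu_r").copy()
    cmap.set_bad("grey")
    im = ax.imshow(masked, aspect="auto", cmap=cmap)
    ax.set_xticks(range(ordered.shape[1]), ordered.columns)
    ax.set_yticks(range(len(ordered)), ordered.index, fontsize=4)
    fig.colorbar(im, ax=ax, label="log2 fold change")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
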
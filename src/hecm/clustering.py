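"""Heat-map matrix preparation and agglomerative hierarchical clustering.

Columns (peak areas plus ALT/AST endpoints) are z-scored so colour encodes
relative level; rows and columns are ordered by agglomerative clustering
(euclidean or correlation distance, average or complete linkage).  The
tested artifact is the ordered matrix and the linkage records, not pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.spatial.distance import pdist

__all__ = ["HeatmapMatrix", "zscore_columns", "hierarchical_cluster", "cluster_heatmap", "plot_heatmap"]

_METRICS = {"euclidean", "correlation"}
_LINKAGES = {"average", "complete"}


def zscore_columns(M: np.ndarray) -> np.ndarray:
    """Per-column z-scores using the sample (ddof=1) standard deviation.

    A constant column cannot be standardised; it is set to all zeros with a
    warning.
    """
    M = np.atleast_2d(np.asarray(M, dtype=float))
    if M.shape[0] < 2:
        raise ValueError("z-scoring needs at least 2 rows")
    mean = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    const = sd == 0
    if np.any(const):
        warnings.warn(
            f"constant column(s) {np.flatnonzero(const).tolist()} set to zeros",
            stacklevel=2,
        )
    sd = np.where(const, 1.0, sd)
    Z = (M - mean) / sd
    Z[:, const] = 0.0
    return Z


def _leaf_order(Z: np.ndarray, n: int) -> list[int]:
    """Left-before-right dendrogram traversal.

    At every internal node the child subtree containing the lower original
    index is visited first, making the order deterministic.
    """
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for k, (a, b, _, _) in enumerate(Z):
        a, b = int(a), int(b)
        left, right = members.pop(a), members.pop(b)
        if min(right) < min(left):
            left, right = right, left
        members[n + k] = left + right
    (order,) = members.values()
    return order


def hierarchical_cluster(
    M: np.ndarray, metric: str = "euclidean", linkage: str = "average"
) -> tuple[np.ndarray, list[int]]:
    """Agglomerative clustering of the rows of ``M``.

    Returns the linkage records ``Z`` (scipy format: child a, child b, merge
    height, cluster size) and the deterministic leaf order.
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(_METRICS)}")
    if linkage not in _LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {sorted(_LINKAGES)}")
    M = np.atleast_2d(np.asarray(M, dtype=float))
    if M.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    if not np.all(np.isfinite(M)):
        raise ValueError("matrix must be finite")
    D = pdist(M, metric=metric)
    Z = _scipy_linkage(D, method=linkage)
    return Z, _leaf_order(Z, M.shape[0])


@dataclass
class HeatmapMatrix:
    """Z-scored matrix with dendrogram orders and linkage records."""

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray  # column-wise z-scores
    row_order: list[int]
    col_order: list[int]
    row_linkage: np.ndarray
    col_linkage: np.ndarray

    def ordered(self) -> np.ndarray:
        return self.values[np.ix_(self.row_order, self.col_order)]

    def ordered_col_ids(self) -> list[str]:
        return [self.col_ids[j] for j in self.col_order]

    def ordered_row_ids(self) -> list[str]:
        return [self.row_ids[i] for i in self.row_order]


def cluster_heatmap(
    M: np.ndarray,
    row_ids: list[str],
    col_ids: list[str],
    metric: str = "euclidean",
    linkage: str = "average",
) -> HeatmapMatrix:
    """Z-score columns of ``M`` and cluster both rows and columns."""
    Z = zscore_columns(M)
    row_link, row_order = hierarchical_cluster(Z, metric, linkage)
    col_link, col_order = hierarchical_cluster(Z.T, metric, linkage)
    return HeatmapMatrix(
        row_ids=list(row_ids),
        col_ids=list(col_ids),
        values=Z,
        row_order=row_order,
        col_order=col_order,
        row_linkage=row_link,
        col_linkage=col_link,
    )


def plot_heatmap(h: HeatmapMatrix, path) -> None:
    """Optional rendering of the ordered matrix to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 6))
    im = ax.imshow(h.ordered(), aspect="auto", cmap="coolwarm")
    ax.set_xticks(range(len(h.col_ids)))
    ax.set_xticklabels(h.ordered_col_ids(), rotation=90, fontsize=7)
    ax.set_yticks(range(len(h.row_ids)))
    ax.set_yticklabels(h.ordered_row_ids(), fontsize=6)
    fig.colorbar(im, ax=ax, label="column z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
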
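"""Sample correlation and correlation-distance hierarchical clustering.

Heatmap-style clustering of stoichiometry barcodes: Pearson correlation
between profiles, correlation distance d = 1 - r (so d in [0, 2]), and
UPGMA (unweighted average linkage), where the distance between two clusters
is the mean of all cross-pair distances.  Ties between equally close pairs
are broken by the smallest (i, j) original-index pair, which makes the
dendrogram bit-reproducible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .multivariate import ScaledMatrix, _as_frame

__all__ = [
    "CorrelationMatrix",
    "Dendrogram",
    "pearson_correlation",
    "correlation_distance",
    "average_linkage",
    "cut_tree",
    "cluster_composition",
]

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    """Symmetric sample-sample Pearson correlation with pair counts.

    ``r[i, j]`` is computed over the RPs observed in both samples
    (pairwise-complete); ``n_shared[i, j]`` records how many such RPs there
    were.  Pairs sharing fewer than ``min_periods`` RPs get a missing r.
    """

    r: pd.DataFrame
    n_shared: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.r.index)

    def to_tsv(self, path) -> None:
        out = self.r.copy()
        out.index.name = "sample"
        out.to_csv(path, sep="\t", float_format="%.17g", na_rep="")


def pearson_correlation(matrix, min_periods: int = 3) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlation between sample profiles.

    Accepts a :class:`~riboratio.ratios.RatioMatrix`,
    :class:`~riboratio.multivariate.ScaledMatrix` or DataFrame with samples
    as columns.

    Raises
    ------
    ValueError
        With fewer than two samples.
    """
    frame = _as_frame(matrix)
    if frame.shape[1] < 2:
        raise ValueError("need >= 2 samples for a correlation matrix")
    r = frame.corr(method="pearson", min_periods=min_periods)
    present = frame.notna().astype(int)
    n_shared = pd.DataFrame(
        present.T.to_numpy() @ present.to_numpy(),
        index=frame.columns, columns=frame.columns,
    )
    r_arr = r.to_numpy(dtype=float, copy=True)
    np.fill_diagonal(r_arr, 1.0)
    r = pd.DataFrame(r_arr, index=r.index, columns=r.columns)
    thin = (n_shared < min_periods).to_numpy()
    np.fill_diagonal(thin, False)
    if thin.any():
        logger.warning(
            "%d sample pair(s) share < %d RPs; correlation left missing",
            int(thin.sum()) // 2, min_periods,
        )
    return CorrelationMatrix(r=r, n_shared=n_shared)


def correlation_distance(x, axis: str = "columns") -> pd.DataFrame:
    """Correlation distance d = 1 - Pearson r between item profiles.

    ``axis="columns"`` clusters samples, ``axis="rows"`` clusters RPs.  A
    :class:`CorrelationMatrix` is converted directly.

    Raises
    ------
    ValueError
        If any profile is constant (its correlations are undefined) —
        constant rows should have been dropped during scaling.
    """
    if isinstance(x, CorrelationMatrix):
        return 1.0 - x.r
    frame = _as_frame(x)
    if axis == "rows":
        frame = frame.T
    elif axis != "columns":
        raise ValueError("axis must be 'rows' or 'columns'")
    if frame.shape[1] < 2:
        raise ValueError("need >= 2 items to compute distances")
    sd = frame.std(axis=0, ddof=1, skipna=True)
    if (sd == 0).any():
        bad = list(frame.columns[(sd == 0)])
        raise ValueError(f"constant profiles have undefined correlation: {bad}")
    r = frame.corr(method="pearson", min_periods=2)
    if r.isna().to_numpy().any():
        raise ValueError(
            "undefined correlations (too few shared observations) — "
            "impute or drop sparse items before clustering"
        )
    d_arr = (1.0 - r).to_numpy(dtype=float, copy=True)
    np.fill_diagonal(d_arr, 0.0)
    return pd.DataFrame(d_arr, index=r.index, columns=r.columns)


@dataclass
class Dendrogram:
    """Result of agglomerative clustering over n leaves.

    ``merges`` holds n-1 rows ``(node_a, node_b, height, size)`` in merge
    order; leaves are numbered 0..n-1 and internal nodes n, n+1, ... as in
    scipy's linkage matrix.  ``leaf_order`` is the left-to-right leaf
    sequence for heatmap display.
    """

    merges: np.ndarray
    leaf_labels: list[str]
    linkage_method: str = "average"
    distance: str = "correlation"

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def to_linkage_matrix(self) -> np.ndarray:
        """The scipy-compatible (n-1) x 4 linkage matrix."""
        return self.merges.astype(float)

    @property
    def leaf_order(self) -> list[str]:
        order: list[str] = []
        n = self.n_leaves

        def walk(node: int) -> None:
            if node < n:
                order.append(self.leaf_labels[node])
            else:
                a, b, _, _ = self.merges[node - n]
                walk(int(a))
                walk(int(b))

        if n == 1:
            return list(self.leaf_labels)
        walk(2 * n - 2)
        return order

    def to_newick(self) -> str:
        """Newick serialization with branch lengths from merge heights."""
        n = self.n_leaves
        heights = {i: 0.0 for i in range(n)}
        for idx, (a, b, h, _) in enumerate(self.merges):
            heights[n + idx] = float(h)

        def render(node: int, parent_h: float) -> str:
            blen = max(parent_h - heights[node], 0.0) / 2.0
            if node < n:
                return f"{self.leaf_labels[node]}:{blen:.10g}"
            a, b, h, _ = self.merges[node - n]
            inner = ",".join(
                render(int(c), float(h)) for c in (int(a), int(b))
            )
            return f"({inner}):{blen:.10g}"

        if n == 1:
            return f"{self.leaf_labels[0]};"
        root = 2 * n - 2
        a, b, h, _ = self.merges[-1]
        inner = ",".join(render(int(c), float(h)) for c in (int(a), int(b)))
        return f"({inner});"


def average_linkage(d: pd.DataFrame | np.ndarray,
                    labels: list[str] | None = None) -> Dendrogram:
    """UPGMA clustering of a symmetric distance matrix.

    Iteratively merges the closest pair of clusters; after a merge the
    distance from the new cluster to any other is the size-weighted mean of
    the two members' distances (the Lance-Williams update for unweighted
    average linkage, equivalent to the mean over all cross pairs).  Ties are
    broken by the lexicographically smallest pair of current node indices.

    Raises
    ------
    ValueError
        If the matrix is not square/symmetric or has a nonzero diagonal.
    """
    if isinstance(d, pd.DataFrame):
        labels = labels or list(map(str, d.columns))
        dm = d.to_numpy(dtype=float)
    else:
        dm = np.asarray(d, dtype=float)
        labels = labels or [str(i) for i in range(dm.shape[0])]
    n = dm.shape[0]
    if dm.ndim != 2 or dm.shape[0] != dm.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dm, dm.T, atol=1e-12, equal_nan=False):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(dm), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.isnan(dm).any():
        raise ValueError("distance matrix contains missing values")
    if n < 2:
        raise ValueError("need >= 2 leaves")

    # active clusters: node id -> (position in working matrix, size)
    work = dm.copy()
    node_of = list(range(n))          # working-row index -> node id
    sizes = {i: 1 for i in range(n)}
    merges = np.zeros((n - 1, 4))
    next_node = n
    for step in range(n - 1):
        m = work.shape[0]
        iu = np.triu_indices(m, k=1)
        flat = work[iu]
        best = np.flatnonzero(flat == flat.min())
        # ties: smallest (node_i, node_j) among candidate pairs
        cand = sorted(
            (min(node_of[iu[0][b]], node_of[iu[1][b]]),
             max(node_of[iu[0][b]], node_of[iu[1][b]]), b)
            for b in best
        )
        b = cand[0][2]
        i, j = int(iu[0][b]), int(iu[1][b])
        na, nb = node_of[i], node_of[j]
        h = float(work[i, j])
        sa, sb = sizes[na], sizes[nb]
        merges[step] = (min(na, nb), max(na, nb), h, sa + sb)

        # Lance-Williams unweighted-average update
        new_row = (sa * work[i] + sb * work[j]) / (sa + sb)
        keep = [k for k in range(m) if k not in (i, j)]
        work = work[np.ix_(keep, keep)]
        new_row = new_row[keep]
        work = np.block([
            [work, new_row[:, None]],
            [new_row[None, :], np.zeros((1, 1))],
        ])
        node_of = [node_of[k] for k in keep] + [next_node]
        sizes[next_node] = sa + sb
        next_node += 1

    return Dendrogram(merges=merges, leaf_labels=list(labels))


def cut_tree(dend: Dendrogram, k: int) -> pd.Series:
    """Cluster labels (1..k) from cutting the dendrogram into k clusters.

    Because UPGMA merge heights are monotone, the k-cluster partition is
    obtained by undoing the last k-1 merges.  Labels are numbered by first
    appearance in leaf order.

    Raises
    ------
    ValueError
        If k is outside 1..n_leaves.
    """
    n = dend.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - k):
        a, b, _, _ = dend.merges[step]
        node = n + step
        parent[find(int(a))] = node
        parent[find(int(b))] = node

    roots: dict[int, int] = {}
    labels = np.zeros(n, dtype=int)
    order_index = {lab: i for i, lab in enumerate(dend.leaf_labels)}
    for lab in dend.leaf_order:
        leaf = order_index[lab]
        r = find(leaf)
        if r not in roots:
            roots[r] = len(roots) + 1
        labels[leaf] = roots[r]
    return pd.Series(labels, index=dend.leaf_labels, name="cluster")


def cluster_composition(
    clusters: pd.Series, groups: pd.Series | dict[str, str]
) -> pd.DataFrame:
    """Cross-tabulate cluster labels against sample group labels."""
    g = pd.Series(groups) if not isinstance(groups, pd.Series) else groups
    g = g.reindex(clusters.index)
    return pd.crosstab(clusters, g.rename("group"))
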
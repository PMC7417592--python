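"""Clustering, pseudotime ordering and branch detection.

The trajectory stage resolves the post-activation bifurcation: cells are
clustered by density peaks in PCA space, ordering genes are selected by an
across-cluster Kruskal-Wallis test, a principal tree is fitted as a minimum
spanning tree over cluster centroids with cells projected onto its edges,
and pseudotime is the geodesic distance from the root along the tree.
Branch points are tree nodes of degree >= 3; a branch is a maximal
branch-point-free tree segment.

The principal tree is a deliberately simple, deterministic stand-in for
elastic principal-graph methods (DDRTree and kin): it preserves the
decision-relevant outputs — pseudotime, branch labels, branch points —
while remaining exactly testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.decomposition import PCA

from .bulk import bh_adjust

__all__ = [
    "ClusterModel",
    "TrajectoryModel",
    "reduce_dims",
    "embed_2d",
    "cluster_density_peak",
    "select_ordering_genes",
    "fit_principal_tree",
    "assign_branches",
]


@dataclass
class ClusterModel:
    """Density-peak clustering result."""

    labels: pd.Series  # cell -> cluster id (0..n_clusters-1)
    rho: np.ndarray  # local density per cell
    delta: np.ndarray  # distance to nearest higher-density cell
    centers: np.ndarray  # indices of cluster-center cells
    rho_threshold: float
    delta_threshold: float

    @property
    def n_clusters(self) -> int:
        return len(self.centers)


@dataclass
class TrajectoryModel:
    """Principal tree with per-cell pseudotime and branch assignment."""

    embedding: np.ndarray  # cells x d reduced space the tree lives in
    nodes: np.ndarray  # node (centroid) coordinates, nodes x d
    edges: list[tuple[int, int]]  # tree edges between node indices
    root: int  # root node index
    pseudotime: pd.Series  # cell -> geodesic distance from root
    cell_edge: pd.Series  # cell -> index into edges
    branch: pd.Series  # cell -> branch (segment) id
    branch_points: list[int] = field(default_factory=list)  # node indices, degree >= 3

    @property
    def n_branches(self) -> int:
        return int(self.branch.nunique())


def reduce_dims(
    X: np.ndarray | ad.AnnData, num_dim: int = 10
) -> np.ndarray:
    """Top principal components of the centered matrix.

    Sign convention: each component is flipped so its largest-magnitude
    loading is positive, making the embedding deterministic.
    """
    if isinstance(X, ad.AnnData):
        X = np.asarray(X.X, dtype=float)
    X = np.asarray(X, dtype=float)
    if num_dim > min(X.shape):
        raise ValueError(
            f"num_dim={num_dim} exceeds matrix rank bound {min(X.shape)}"
        )
    pca = PCA(n_components=num_dim, svd_solver="full")
    emb = pca.fit_transform(X - X.mean(axis=0))
    comp = pca.components_
    flip = np.sign(comp[np.arange(comp.shape[0]), np.abs(comp).argmax(axis=1)])
    flip[flip == 0] = 1.0
    return emb * flip


def embed_2d(
    embedding: np.ndarray, perplexity: float = 30.0, seed: int = 1
) -> tuple[np.ndarray, float]:
    """Deterministic 2D display embedding (t-SNE; PCA fallback for tiny n).

    Returns the coordinates and a neighbor-preservation score: the mean
    fraction of each cell's 10 nearest neighbors in the input space retained
    among its 10 nearest in the 2D layout.
    """
    from sklearn.manifold import TSNE

    X = np.asarray(embedding, dtype=float)
    n = X.shape[0]
    if n < 8:
        Y = X[:, :2].copy() if X.shape[1] >= 2 else np.c_[X, np.zeros(n)]
    else:
        perp = float(min(perplexity, (n - 1) / 3.0))
        Y = TSNE(
            n_components=2,
            perplexity=perp,
            random_state=seed,
            init="pca",
        ).fit_transform(X)
    k = min(10, n - 1)
    if k < 1:
        return Y, 1.0
    nn_in = np.argsort(squareform(pdist(X)), axis=1)[:, 1 : k + 1]
    nn_out = np.argsort(squareform(pdist(Y)), axis=1)[:, 1 : k + 1]
    score = float(
        np.mean(
            [len(set(nn_in[i]) & set(nn_out[i])) / k for i in range(n)]
        )
    )
    return Y, score


def cluster_density_peak(
    embedding: np.ndarray,
    neighbor_fraction: float = 0.01,
    center_separation: float = 1.5,
    min_density: float = 1.0,
    max_centers: int = 16,
    cell_names: pd.Index | None = None,
) -> ClusterModel:
    """Density-peak clustering (rho/delta decision rule).

    rho_i counts cells within a kernel distance d_c, taken as a quantile of
    all pairwise distances; the quantile is ``neighbor_fraction`` but never
    below 20/n, so small datasets keep enough neighbors in the kernel for a
    stable density estimate.  delta_i is the distance to the nearest
    higher-density cell (for the global density maximum, the largest
    pairwise distance).  Cluster centers are density peaks — rho of at
    least ``min_density``, separated from any denser cell by more than
    ``center_separation`` x d_c — ranked by the decision-graph product
    rho x delta and capped at ``max_centers``.  Peaks of locally different
    density all qualify, which resolves trajectory arms whose occupancy
    (hence density) varies along the division ladder.  All other cells join
    the cluster of their nearest higher-density neighbor.
    """
    X = np.asarray(embedding, dtype=float)
    n = X.shape[0]
    if n < 10:
        raise ValueError("density-peak clustering needs >= 10 cells")
    D = squareform(pdist(X))
    off_diag = D[~np.eye(n, dtype=bool)]
    if off_diag.max() == 0:  # all cells identical
        labels = pd.Series(np.zeros(n, int), index=cell_names)
        return ClusterModel(labels, np.full(n, n - 1.0), np.zeros(n), np.array([0]), 0.0, 0.0)
    d_c = np.quantile(off_diag, max(neighbor_fraction, min(0.5, 20.0 / n)))
    if d_c == 0:
        d_c = off_diag[off_diag > 0].min()
    rho = (D < d_c).sum(axis=1) - 1.0  # exclude self
    # deterministic total order on density: break rho ties by cell index
    order = np.lexsort((np.arange(n), -rho))  # descending rho
    delta = np.empty(n)
    nearest_higher = np.full(n, -1)
    delta[order[0]] = D[order[0]].max()
    for pos in range(1, n):
        i = order[pos]
        higher = order[:pos]
        j = higher[np.argmin(D[i, higher])]
        delta[i] = D[i, j]
        nearest_higher[i] = j
    delta_thr = float(center_separation * d_c)
    candidates = np.flatnonzero((delta > delta_thr) & (rho >= min_density))
    gamma = rho * delta
    candidates = candidates[np.argsort(-gamma[candidates], kind="mergesort")]
    centers = np.sort(candidates[:max_centers])
    if centers.size == 0:
        centers = np.array([int(np.argmax(gamma))])
    rho_thr = float(rho[centers].min())
    labels_arr = np.full(n, -1)
    for c_id, c in enumerate(centers):
        labels_arr[c] = c_id
    for pos in range(n):  # descending density: parent already labeled
        i = order[pos]
        if labels_arr[i] == -1:
            labels_arr[i] = labels_arr[nearest_higher[i]]
    labels = pd.Series(labels_arr, index=cell_names, name="cluster")
    return ClusterModel(labels, rho, delta, centers, rho_thr, delta_thr)


def select_ordering_genes(
    adata: ad.AnnData,
    clusters: pd.Series,
    n_top: int = 1000,
) -> pd.DataFrame:
    """Across-cluster Kruskal-Wallis test; top genes by BH q-value.

    Returns a DataFrame indexed by gene with columns ``p``, ``q``,
    ``statistic`` and boolean ``selected`` marking the top ``n_top`` by
    ascending q, with p then descending statistic as tie-breakers.
    Constant genes get p = 1 by convention and are never selected ahead of
    varying ones.
    """
    groups = clusters.reindex(adata.obs_names)
    uniq = sorted(groups.dropna().unique())
    if len(uniq) < 2:
        raise ValueError("ordering-gene selection needs >= 2 clusters")
    X = np.asarray(adata.X, dtype=float)
    idx = [np.flatnonzero((groups == g).to_numpy()) for g in uniq]
    p = np.ones(adata.n_vars)
    stat = np.zeros(adata.n_vars)
    for g in range(adata.n_vars):
        col = X[:, g]
        if np.ptp(col) == 0:
            continue
        samples = [col[i] for i in idx]
        try:
            res = stats.kruskal(*samples)
        except ValueError:  # all values identical across groups
            continue
        if np.isfinite(res.pvalue):
            p[g], stat[g] = res.pvalue, res.statistic
    q = bh_adjust(p)
    table = pd.DataFrame(
        {"p": p, "q": q, "statistic": stat}, index=adata.var_names
    )
    n_top_eff = min(n_top, adata.n_vars)
    ranked = table.sort_values(
        ["q", "p", "statistic"], ascending=[True, True, False], kind="mergesort"
    )
    selected = set(ranked.index[:n_top_eff])
    table["selected"] = table.index.isin(selected)
    return table


def _segment_edges(edges: list[tuple[int, int]], degrees: dict[int, int]) -> list[int]:
    """Assign each edge a segment id; segments are maximal paths free of
    interior branch points (nodes of degree >= 3)."""
    seg = [-1] * len(edges)
    adj: dict[int, list[int]] = {}
    for e, (a, b) in enumerate(edges):
        adj.setdefault(a, []).append(e)
        adj.setdefault(b, []).append(e)
    next_id = 0
    for e0 in range(len(edges)):
        if seg[e0] != -1:
            continue
        seg[e0] = next_id
        frontier = [e0]
        while frontier:
            e = frontier.pop()
            for node in edges[e]:
                if degrees[node] >= 3:
                    continue  # branch point: do not cross
                for e2 in adj[node]:
                    if seg[e2] == -1:
                        seg[e2] = next_id
                        frontier.append(e2)
        next_id += 1
    return seg


def _project_cells(
    emb: np.ndarray, nodes: np.ndarray, edges: list[tuple[int, int]]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthogonal projection of each cell onto its nearest tree edge."""
    n = emb.shape[0]
    best_d = np.full(n, np.inf)
    best_edge = np.zeros(n, int)
    best_t = np.zeros(n)
    for e, (a, b) in enumerate(edges):
        va, vb = nodes[a], nodes[b]
        ab = vb - va
        L2 = ab @ ab
        t = np.clip((emb - va) @ ab / L2, 0.0, 1.0) if L2 > 0 else np.zeros(n)
        proj = va + t[:, None] * ab
        d = np.linalg.norm(emb - proj, axis=1)
        upd = d < best_d
        best_d[upd], best_edge[upd], best_t[upd] = d[upd], e, t[upd]
    return best_edge, best_t, best_d


def _prune_small_branches(
    emb: np.ndarray,
    nodes: np.ndarray,
    edges: list[tuple[int, int]],
    root: int,
    min_branch_fraction: float,
) -> list[tuple[int, int]]:
    """Iteratively drop leaf segments carrying few cells.

    A leaf segment (maximal branch-point-free path ending in a leaf node)
    whose projected cells number less than ``min_branch_fraction`` of all
    cells is removed, except when it contains the root; cells re-project
    onto the remaining tree.  Suppresses spurious side branches produced by
    over-clustering along a continuum.
    """
    n = emb.shape[0]
    edges = list(edges)
    while len(edges) > 1:
        best_edge, _, _ = _project_cells(emb, nodes, edges)
        degrees: dict[int, int] = {}
        for a, b in edges:
            degrees[a] = degrees.get(a, 0) + 1
            degrees[b] = degrees.get(b, 0) + 1
        if not any(d >= 3 for d in degrees.values()):
            break  # a path: nothing to prune
        seg = _segment_edges(edges, degrees)
        counts = np.bincount([seg[e] for e in best_edge], minlength=max(seg) + 1)
        prunable = []
        for s in range(max(seg) + 1):
            seg_edges = [e for e in range(len(edges)) if seg[e] == s]
            seg_nodes = {v for e in seg_edges for v in edges[e]}
            has_leaf = any(degrees[v] == 1 for v in seg_nodes)
            if has_leaf and root not in seg_nodes and counts[s] < min_branch_fraction * n:
                prunable.append((counts[s], s, seg_edges))
        if not prunable:
            break
        _, _, drop = min(prunable)
        edges = [edges[e] for e in range(len(edges)) if e not in set(drop)]
    return edges


def fit_principal_tree(
    adata: ad.AnnData,
    clusters: pd.Series,
    num_dim: int = 10,
    root_cluster: int | None = None,
    root_labels: pd.Series | None = None,
    root_label_value: str = "0",
    ordering_genes: pd.Index | None = None,
    min_branch_fraction: float = 0.05,
) -> TrajectoryModel:
    """Fit the MST-over-centroids principal tree and order cells.

    The reduced space is PCA of the (optionally ordering-gene-restricted)
    matrix.  The root is ``root_cluster`` if given, otherwise the cluster
    with the highest fraction of cells whose ``root_labels`` annotation
    equals ``root_label_value`` (e.g. the naive-B division-0 label), else
    cluster 0.  Pseudotime of a cell is the tree geodesic from the root
    node to the cell's orthogonal projection onto its nearest tree edge.
    """
    data = adata
    if ordering_genes is not None:
        keep = adata.var_names.isin(ordering_genes)
        if keep.sum() == 0:
            raise ValueError("no ordering genes present in the matrix")
        data = adata[:, keep]
    X = np.asarray(data.X, dtype=float)
    emb = reduce_dims(X, num_dim=min(num_dim, min(X.shape)))

    labels = clusters.reindex(adata.obs_names)
    uniq = sorted(labels.dropna().unique())
    nodes = np.vstack([emb[(labels == g).to_numpy()].mean(axis=0) for g in uniq])
    n_nodes = len(uniq)

    if n_nodes == 1:
        pt = np.linalg.norm(emb - nodes[0], axis=1) * 0.0
        zero = pd.Series(0, index=adata.obs_names)
        return TrajectoryModel(
            embedding=emb,
            nodes=nodes,
            edges=[],
            root=0,
            pseudotime=pd.Series(pt, index=adata.obs_names, name="pseudotime"),
            cell_edge=zero.rename("edge") - 1,
            branch=zero.rename("branch"),
            branch_points=[],
        )

    mst = minimum_spanning_tree(squareform(pdist(nodes)))
    mst = mst.tocoo()
    edges = [(int(a), int(b)) for a, b in zip(mst.row, mst.col)]

    # root selection
    if root_cluster is not None:
        root = uniq.index(root_cluster)
    elif root_labels is not None:
        fracs = [
            (root_labels.reindex(adata.obs_names)[(labels == g).to_numpy()] == root_label_value).mean()
            for g in uniq
        ]
        root = int(np.argmax(fracs))
    else:
        root = 0

    if min_branch_fraction > 0:
        edges = _prune_small_branches(emb, nodes, edges, root, min_branch_fraction)
    n = emb.shape[0]
    best_edge, best_t, _ = _project_cells(emb, nodes, edges)

    G = nx.Graph()
    for e, (a, b) in enumerate(edges):
        G.add_edge(a, b, weight=float(np.linalg.norm(nodes[a] - nodes[b])))
    node_dist = nx.single_source_dijkstra_path_length(G, root)

    pt = np.empty(n)
    for i in range(n):
        a, b = edges[best_edge[i]]
        L = float(np.linalg.norm(nodes[a] - nodes[b]))
        via_a = node_dist[a] + best_t[i] * L
        via_b = node_dist[b] + (1.0 - best_t[i]) * L
        pt[i] = min(via_a, via_b)

    degrees = {v: G.degree(v) for v in G.nodes}
    branch_points = sorted(v for v, d in degrees.items() if d >= 3)
    seg = _segment_edges(edges, degrees)
    branch = pd.Series(
        [seg[e] for e in best_edge], index=adata.obs_names, name="branch"
    )
    return TrajectoryModel(
        embedding=emb,
        nodes=nodes,
        edges=edges,
        root=root,
        pseudotime=pd.Series(pt, index=adata.obs_names, name="pseudotime"),
        cell_edge=pd.Series(best_edge, index=adata.obs_names, name="edge"),
        branch=branch,
        branch_points=branch_points,
    )


def assign_branches(model: TrajectoryModel) -> pd.Series:
    """Per-cell branch ids (maximal branch-point-free tree segments)."""
    return model.branch
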
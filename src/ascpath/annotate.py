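"""Reference-guided KNN annotation of single cells.

Bridges bulk and single-cell data: the query cells and labeled bulk
replicate profiles are merged on shared gene symbols, quantile normalized
jointly so every column carries the same empirical distribution, and each
cell is assigned the plurality label of its k nearest reference columns in
Euclidean distance.  The same machinery transfers cluster labels between
single-cell datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .simulate import ReferencePanel

__all__ = [
    "CellAnnotation",
    "to_gene_frame",
    "merge_on_genes",
    "quantile_normalize",
    "knn_annotate",
    "annotate_cells",
]


@dataclass
class CellAnnotation:
    """Per-cell label assignments with vote bookkeeping."""

    assignments: pd.DataFrame  # index cell; columns: label, vote_fraction, nn_distance
    vote_fractions: pd.DataFrame  # cell x label vote shares (rows sum to 1)

    @property
    def labels(self) -> pd.Series:
        return self.assignments["label"]


def to_gene_frame(adata: ad.AnnData, layer: str | None = None) -> pd.DataFrame:
    """AnnData -> genes x cells DataFrame over biological genes."""
    X = adata.layers[layer] if layer else adata.X
    X = np.asarray(X, dtype=float)
    df = pd.DataFrame(X.T, index=adata.var_names, columns=adata.obs_names)
    if "is_spike" in adata.var:
        df = df.loc[~adata.var["is_spike"].to_numpy()]
    return df


def merge_on_genes(
    query: pd.DataFrame, panel: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Row-bind query cells and reference columns on exact gene-id matches.

    Returns the combined genes x (cells + replicates) matrix and the size of
    the gene intersection.
    """
    shared = query.index.intersection(panel.index)
    if len(shared) == 0:
        raise ValueError("query and panel share no gene identifiers")
    combined = pd.concat([query.loc[shared], panel.loc[shared]], axis=1)
    if combined.columns.duplicated().any():
        raise ValueError("query and panel column names collide")
    return combined, len(shared)


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Classic quantile normalization.

    Each column is replaced by the cross-column mean of the rank-ordered
    values; ties within a column receive the mean of the rank-mean values
    over their tied positions, so the sorted values of every output column
    are identical.
    """
    if df.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 columns")
    X = df.to_numpy(dtype=float)
    n, m = X.shape
    order = np.argsort(X, axis=0, kind="mergesort")
    sorted_vals = np.take_along_axis(X, order, axis=0)
    rank_means = sorted_vals.mean(axis=1)
    out = np.empty_like(X)
    for j in range(m):
        col_sorted = sorted_vals[:, j]
        # tie groups are contiguous runs in the sorted column
        starts = np.r_[0, np.flatnonzero(np.diff(col_sorted)) + 1]
        sums = np.add.reduceat(rank_means, starts)
        sizes = np.diff(np.r_[starts, n])
        group_means = sums / sizes
        vals = np.repeat(group_means, sizes)
        out[order[:, j], j] = vals
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def knn_annotate(
    combined: pd.DataFrame,
    panel_labels: pd.Series,
    k: int | None = None,
) -> CellAnnotation:
    """Plurality-vote KNN label transfer on a quantile-normalized matrix.

    ``panel_labels`` maps reference column names (a subset of ``combined``'s
    columns) to labels; remaining columns are query cells.  ``k`` defaults
    to the replicate count of the smallest label class.  Ties are broken by
    smaller mean distance among the tied labels, then lexicographically.
    """
    ref_cols = [c for c in combined.columns if c in panel_labels.index]
    query_cols = [c for c in combined.columns if c not in panel_labels.index]
    if not ref_cols:
        raise ValueError("no reference columns found in combined matrix")
    labels = panel_labels.loc[ref_cols]
    if k is None:
        k = int(labels.value_counts().min())
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(ref_cols):
        raise ValueError(f"k={k} exceeds number of reference columns ({len(ref_cols)})")

    Q = combined[query_cols].to_numpy(dtype=float).T  # cells x genes
    R = combined[ref_cols].to_numpy(dtype=float).T  # refs x genes
    D = cdist(Q, R)  # Euclidean
    label_values = sorted(labels.unique())
    lab_arr = labels.to_numpy()

    nn_idx = np.argsort(D, axis=1, kind="mergesort")[:, :k]
    assigned, fractions, nn_dist = [], [], []
    votes = np.zeros((len(query_cols), len(label_values)))
    for i in range(len(query_cols)):
        neigh_labels = lab_arr[nn_idx[i]]
        counts = pd.Series(neigh_labels).value_counts()
        top = counts.max()
        tied = sorted(counts.index[counts == top])
        if len(tied) > 1:
            mean_d = {
                lab: D[i, nn_idx[i]][neigh_labels == lab].mean() for lab in tied
            }
            tied = [min(tied, key=lambda lab: (mean_d[lab], lab))]
        assigned.append(tied[0])
        fractions.append(top / k)
        nn_dist.append(D[i].min())
        for lab, c in counts.items():
            votes[i, label_values.index(lab)] = c / k

    assignments = pd.DataFrame(
        {
            "label": assigned,
            "vote_fraction": fractions,
            "nn_distance": nn_dist,
        },
        index=pd.Index(query_cols, name="cell"),
    )
    vote_df = pd.DataFrame(votes, index=assignments.index, columns=label_values)
    return CellAnnotation(assignments=assignments, vote_fractions=vote_df)


def annotate_cells(
    adata: ad.AnnData,
    panel: ReferencePanel,
    k: int | None = None,
    layer: str | None = None,
) -> CellAnnotation:
    """Full bridge: merge cells with a bulk panel, quantile normalize, KNN.

    Writes the division label to ``obs['division_label']`` and its cell-type
    annotation to ``obs['cell_type_label']``.
    """
    query = to_gene_frame(adata, layer=layer)
    ref = panel.matrix.loc[~panel.matrix.index.str.startswith("ERCC-")]
    combined, _ = merge_on_genes(query, ref)
    norm = quantile_normalize(combined)
    result = knn_annotate(norm, panel.labels, k=k)
    adata.obs["division_label"] = result.labels.reindex(adata.obs_names)
    adata.obs["cell_type_label"] = (
        adata.obs["division_label"].map(panel.cell_types).astype(object)
    )
    return result
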
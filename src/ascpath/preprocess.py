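"""Single-cell QC filtering and normalization.

Operates on AnnData (cells x genes, raw UMI in ``.X``).  Spike-in rows, when
present (``var['is_spike']``), count toward nothing here: QC and library
sizes are computed over biological genes only.
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import scipy.sparse as sp

__all__ = ["qc_filter", "libsize_sqrt_transform", "log_normalize"]


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def _bio_mask(adata: ad.AnnData) -> np.ndarray:
    if "is_spike" in adata.var:
        return ~adata.var["is_spike"].to_numpy()
    return np.ones(adata.n_vars, dtype=bool)


def qc_filter(
    adata: ad.AnnData,
    min_cells_per_gene: int = 10,
    min_umi_per_cell: int = 1000,
) -> ad.AnnData:
    """Remove lowly-covered genes and cells in a single pass.

    Genes expressed (count > 0) in fewer than ``min_cells_per_gene`` cells
    and cells with total UMI below ``min_umi_per_cell`` are dropped; both
    criteria are evaluated on the *input* matrix, so the result can differ
    from iterating the two rules.  Spike rows are always retained and do not
    contribute to cell totals.
    """
    X = _dense(adata.X)
    bio = _bio_mask(adata)
    cells_per_gene = (X > 0).sum(axis=0)
    gene_keep = (cells_per_gene >= min_cells_per_gene) | ~bio
    umi_per_cell = X[:, bio].sum(axis=1)
    cell_keep = umi_per_cell >= min_umi_per_cell
    if not cell_keep.any():
        raise ValueError(
            f"QC removed all {adata.n_obs} cells "
            f"(min total UMI {min_umi_per_cell}; max observed {umi_per_cell.max():.0f})"
        )
    out = adata[cell_keep, gene_keep].copy()
    out.uns["qc"] = {
        "genes_removed": int((~gene_keep).sum()),
        "cells_removed": int((~cell_keep).sum()),
        "min_cells_per_gene": min_cells_per_gene,
        "min_umi_per_cell": min_umi_per_cell,
    }
    return out


def libsize_sqrt_transform(adata: ad.AnnData) -> ad.AnnData:
    """Median library-size normalization followed by square root.

    Each cell is scaled so its biological-gene total equals the median input
    library size, then the whole matrix is sqrt-transformed.  This is the
    input representation for diffusion imputation.
    """
    X = _dense(adata.X).astype(float)
    bio = _bio_mask(adata)
    lib = X[:, bio].sum(axis=1)
    if (lib <= 0).any():
        bad = adata.obs_names[lib <= 0].tolist()
        raise ValueError(f"cells with zero library size: {bad[:5]}")
    target = float(np.median(lib))
    out = adata.copy()
    out.X = np.sqrt(X * (target / lib)[:, None])
    out.uns["unit"] = "sqrt of median-libsize-normalized UMI"
    out.uns["libsize_target"] = target
    return out


def log_normalize(adata: ad.AnnData, target_sum: float = 1e4) -> ad.AnnData:
    """Scale each cell to ``target_sum`` total counts, then log(1 + x).

    The representation used for PCA, clustering and ordering-gene selection.
    """
    X = _dense(adata.X).astype(float)
    bio = _bio_mask(adata)
    lib = X[:, bio].sum(axis=1)
    if (lib <= 0).any():
        bad = adata.obs_names[lib <= 0].tolist()
        raise ValueError(f"cells with zero library size: {bad[:5]}")
    out = adata.copy()
    out.X = np.log1p(X * (target_sum / lib)[:, None])
    out.uns["unit"] = "log1p of CP10K"
    out.uns["libsize_target"] = float(target_sum)
    return out
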
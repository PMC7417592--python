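"""Markov-diffusion imputation of single-cell expression.

Builds a row-stochastic cell-cell transition operator from an adaptive
Gaussian kernel on a kNN graph in PCA space and powers it to smooth the
expression matrix — the diffusion-based denoising used for all expression
displays and activity scores downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import anndata as ad
import numpy as np
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

__all__ = ["DiffusionOperator", "build_operator", "impute"]


@dataclass
class DiffusionOperator:
    """Row-stochastic cell x cell transition matrix with its parameters."""

    matrix: np.ndarray  # dense, rows sum to 1
    k: int
    ka: int
    n_pcs: int
    cell_names: list[str]

    def __post_init__(self) -> None:
        rows = self.matrix.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError("operator rows must sum to 1")
        if (self.matrix < 0).any():
            raise ValueError("operator entries must be non-negative")

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savetxt(path / "operator.tsv", self.matrix, delimiter="\t")
        meta = {
            "k": self.k,
            "ka": self.ka,
            "n_pcs": self.n_pcs,
            "cell_names": self.cell_names,
        }
        (path / "operator.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "DiffusionOperator":
        path = Path(path)
        meta = json.loads((path / "operator.json").read_text())
        mat = np.loadtxt(path / "operator.tsv", delimiter="\t", ndmin=2)
        return cls(matrix=mat, **meta)


def build_operator(
    adata: ad.AnnData, k: int = 30, ka: int = 10, n_pcs: int = 20, seed: int = 1
) -> DiffusionOperator:
    """Build the diffusion operator from normalized expression.

    Euclidean kNN in the top ``n_pcs`` principal components; Gaussian kernel
    with per-cell bandwidth equal to the distance to the ``ka``-th neighbor;
    kernel symmetrized by addition, then rows normalized to sum 1.
    """
    n = adata.n_obs
    if k >= n:
        raise ValueError(f"k={k} must be < number of cells ({n})")
    if ka > k:
        raise ValueError("ka must be <= k")
    X = np.asarray(adata.X, dtype=float)
    n_pcs_eff = min(n_pcs, min(X.shape) - 1)
    if n_pcs_eff >= 2:
        pcs = PCA(n_components=n_pcs_eff, svd_solver="full", random_state=seed).fit_transform(
            X - X.mean(axis=0)
        )
    else:
        pcs = X
    # query extra neighbors so ties at the kNN boundary (e.g. duplicate
    # cells) are kept symmetrically rather than truncated arbitrarily
    n_query = min(n, k + 17)
    nn = NearestNeighbors(n_neighbors=n_query).fit(pcs)
    dist, idx = nn.kneighbors(pcs)  # includes self at distance 0
    sigma = dist[:, ka]
    sigma[sigma == 0] = np.finfo(float).eps
    cutoff = dist[:, k] * (1 + 1e-12)
    W = np.zeros((n, n))
    for i in range(n):
        keep = dist[i] <= cutoff[i]
        W[i, idx[i, keep]] = np.exp(-((dist[i, keep] / sigma[i]) ** 2))
    W = W + W.T  # symmetrize by addition
    P = W / W.sum(axis=1, keepdims=True)
    return DiffusionOperator(
        matrix=P, k=k, ka=ka, n_pcs=n_pcs_eff, cell_names=list(adata.obs_names)
    )


def impute(adata: ad.AnnData, op: DiffusionOperator, t: int = 3) -> ad.AnnData:
    """Diffuse expression: X_imputed = P^t X.  t = 0 returns the input."""
    if t < 0 or int(t) != t:
        raise ValueError("t must be a non-negative integer")
    if op.matrix.shape[0] != adata.n_obs:
        raise ValueError(
            f"operator built on {op.matrix.shape[0]} cells, data has {adata.n_obs}"
        )
    X = np.asarray(adata.X, dtype=float)
    for _ in range(int(t)):
        X = op.matrix @ X
    out = adata.copy()
    out.X = X
    out.uns["unit"] = "imputed"
    out.uns["diffusion_t"] = int(t)
    return out
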
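"""Preranked gene-set enrichment, leading edges, and activity scores.

Genes are ranked by a signed significance score; enrichment of a gene set
is the extremum of the weighted Kolmogorov-Smirnov running statistic over
the ranked list, with a gene-label permutation null (set membership is
re-drawn uniformly at random).  The per-cell activity of a gene list is the
cube of its mean imputed expression; pseudotime profiles are row-max
normalized bin means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RankedGeneList",
    "EnrichmentResult",
    "rank_genes",
    "gsea_preranked",
    "leading_edge",
    "activity_score",
    "pseudotime_profile",
]


@dataclass
class RankedGeneList:
    """Descending-ordered signed ranking scores; no duplicate genes."""

    scores: pd.Series  # index gene, values signed score, sorted descending

    def __post_init__(self) -> None:
        if self.scores.index.duplicated().any():
            raise ValueError("ranked list contains duplicate genes")

    @property
    def genes(self) -> pd.Index:
        return self.scores.index

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class EnrichmentResult:
    """One ranked list x one gene set."""

    es: float
    nes: float
    p_value: float
    leading_edge: list[str]
    n_permutations: int
    es_index: int  # position of the running-sum extremum (0-based)
    hit_mask: np.ndarray  # boolean over ranked list


def rank_genes(
    table: pd.DataFrame, mode: str = "one-minus-p"
) -> RankedGeneList:
    """Signed significance ranking from per-gene (p, sign of fold change).

    ``table`` needs columns ``p`` and ``log2fc`` (only its sign is used; a
    ``sign`` column is accepted instead).  Default score sign(FC) x (1 - p)
    puts up-regulated significant genes first and down-regulated significant
    genes last; ``mode='literal'`` computes sign(FC) x p.  Genes with zero
    or missing sign are dropped.  Ties break by |log2fc| descending, then
    gene id.
    """
    if "sign" in table.columns:
        sign = np.sign(table["sign"].to_numpy(dtype=float))
        mag = np.abs(table["sign"].to_numpy(dtype=float))
    else:
        sign = np.sign(table["log2fc"].to_numpy(dtype=float))
        mag = np.abs(table["log2fc"].to_numpy(dtype=float))
    p = table["p"].to_numpy(dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    keep = sign != 0
    if mode == "one-minus-p":
        score = sign * (1.0 - p)
    elif mode == "literal":
        score = sign * p
    else:
        raise ValueError(f"unknown ranking mode: {mode}")
    df = pd.DataFrame(
        {"score": score[keep], "mag": mag[keep]},
        index=table.index[keep],
    )
    order = np.lexsort(
        (df.index.to_numpy(), -df["mag"].to_numpy(), -df["score"].to_numpy())
    )
    df = df.iloc[order]
    return RankedGeneList(scores=df["score"].rename("score"))


def _running_extremum(
    scores: np.ndarray, hit: np.ndarray, weight: float
) -> tuple[float, int]:
    """ES and extremum position of the weighted KS running sum (O(N))."""
    n = scores.size
    n_hit = int(hit.sum())
    w = np.abs(scores) ** weight
    denom_hit = w[hit].sum()
    steps = np.where(hit, w / denom_hit if denom_hit > 0 else 0.0, -1.0 / (n - n_hit))
    running = np.cumsum(steps)
    i_max, i_min = int(np.argmax(running)), int(np.argmin(running))
    if abs(running[i_max]) >= abs(running[i_min]):
        return float(running[i_max]), i_max
    return float(running[i_min]), i_min


def _perm_es(
    scores: np.ndarray, set_size: int, n_perm: int, weight: float, rng
) -> np.ndarray:
    """Null ES distribution under uniform re-draws of set membership.

    Works from sorted hit positions only: the running-sum extremum is
    attained just after or just before a hit, so O(|S| log |S|) per draw.
    """
    n = scores.size
    w = np.abs(scores) ** weight
    miss = 1.0 / (n - set_size)
    # positions: n_perm x set_size unique draws
    pos = np.argsort(rng.random((n_perm, n)), axis=1)[:, :set_size]
    pos.sort(axis=1)
    inc = w[pos]
    denom = inc.sum(axis=1, keepdims=True)
    denom[denom == 0] = 1.0
    inc = inc / denom
    cum_inc = np.cumsum(inc, axis=1)
    j = np.arange(set_size)[None, :]
    misses_before = (pos - j) * miss
    after = cum_inc - misses_before  # running value just after each hit
    before = after - inc - miss  # value just before each hit (post next-miss)
    # candidate extrema: after each hit (maxima), before each hit minus the
    # final tail; the running sum ends at 0 and minima occur right before hits
    lo = np.minimum((cum_inc - inc) - misses_before, 0.0).min(axis=1)
    hi = after.max(axis=1)
    es = np.where(np.abs(hi) >= np.abs(lo), hi, lo)
    return es


def gsea_preranked(
    ranked: RankedGeneList,
    gene_set: list[str] | set[str],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 1,
) -> EnrichmentResult:
    """Weighted-KS preranked enrichment with a gene-label permutation null.

    Hits advance the running sum by |score|^weight / sum over hits; misses
    retreat by 1/(N - N_hit); ES is the extremum of largest magnitude.
    p = (1 + #{|ES_perm| >= |ES|}) / (n_perm + 1), so the smallest
    attainable p is 1/(n_perm + 1).  NES divides ES by the mean |null ES|
    of the same sign.
    """
    scores = ranked.scores.to_numpy(dtype=float)
    hit = np.asarray(ranked.genes.isin(set(gene_set)))
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    if n_hit == len(ranked):
        raise ValueError("gene set covers the entire ranked list")
    es, es_idx = _running_extremum(scores, hit, weight)

    rng = np.random.default_rng(seed)
    null = _perm_es(scores, n_hit, n_perm, weight, rng)
    p = (1.0 + np.sum(np.abs(null) >= abs(es))) / (n_perm + 1.0)
    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    nes = es / np.abs(same_sign).mean() if same_sign.size else np.nan

    result = EnrichmentResult(
        es=es,
        nes=float(nes),
        p_value=float(p),
        leading_edge=[],
        n_permutations=n_perm,
        es_index=es_idx,
        hit_mask=hit,
    )
    result.leading_edge = leading_edge(ranked, result)
    return result


def leading_edge(ranked: RankedGeneList, result: EnrichmentResult) -> list[str]:
    """Set members driving the enrichment extremum.

    ES > 0: members at or before the running-sum maximum; ES < 0: members at
    or after the minimum; ES = 0: empty.
    """
    if result.es == 0:
        return []
    genes = ranked.genes.to_numpy()
    hit = result.hit_mask
    if result.es > 0:
        mask = hit & (np.arange(len(genes)) <= result.es_index)
    else:
        mask = hit & (np.arange(len(genes)) >= result.es_index)
    return list(genes[mask])


def activity_score(
    expr: pd.DataFrame, genes: list[str], mode: str = "mean-cubed"
) -> pd.Series:
    """Per-cell gene-set activity from imputed expression.

    ``expr`` is genes x cells.  Default: (mean expression of the listed
    genes)^3; ``mode='mean-of-cubes'`` averages the cubes instead.  Cubing
    is monotone on non-negative input, so cell rankings match the plain
    mean; it sharpens display contrast.
    """
    present = [g for g in genes if g in expr.index]
    if not present:
        raise ValueError("no listed gene found in the expression matrix")
    sub = expr.loc[present]
    if mode == "mean-cubed":
        return (sub.mean(axis=0) ** 3).rename("activity")
    if mode == "mean-of-cubes":
        return (sub.pow(3).mean(axis=0)).rename("activity")
    raise ValueError(f"unknown activity mode: {mode}")


def pseudotime_profile(
    expr: pd.DataFrame,
    pseudotime: pd.Series,
    genes: list[str],
    n_bins: int = 50,
) -> pd.DataFrame:
    """Gene x pseudotime-bin mean expression, row-normalized to max 1.

    Cells are binned by pseudotime quantiles; each gene's bin means are
    divided by their maximum (all-zero genes stay 0).
    """
    cells = pseudotime.index.intersection(expr.columns)
    if n_bins > len(cells):
        raise ValueError(f"n_bins={n_bins} exceeds cell count ({len(cells)})")
    pt = pseudotime.loc[cells]
    bins = pd.qcut(pt.rank(method="first"), n_bins, labels=False)
    present = [g for g in genes if g in expr.index]
    sub = expr.loc[present, cells]
    prof = sub.T.groupby(bins.to_numpy()).mean().T
    maxima = prof.max(axis=1)
    nz = maxima > 0
    prof.loc[nz] = prof.loc[nz].div(maxima[nz], axis=0)
    return prof
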
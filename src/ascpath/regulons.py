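"""Regulon (transcription-factor target set) activity scoring.

Regulon definitions are consumed as input (factor -> target list with motif
annotations); this module computes per-cell activity as the normalized area
under the target-recovery curve within the top-ranked genes of each cell
(AUCell-style), correlates activity change with factor expression change
between clusters, and partitions motif annotations by class
(AP-1 / AICE / other).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import activity_score

__all__ = [
    "RegulonSet",
    "score_regulons",
    "activity_expression_correlation",
    "motif_class_fractions",
]

MOTIF_CLASSES = ("AP-1", "AICE", "other")


@dataclass
class RegulonSet:
    """Factor -> target gene list, plus per-factor motif annotations."""

    targets: dict[str, list[str]]
    motifs: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for factor, tg in self.targets.items():
            if len(tg) == 0:
                raise ValueError(f"regulon {factor} has an empty target list")
        for factor, tags in self.motifs.items():
            bad = set(tags) - set(MOTIF_CLASSES)
            if bad:
                raise ValueError(
                    f"regulon {factor} has motif tags outside {MOTIF_CLASSES}: {sorted(bad)}"
                )

    @property
    def factors(self) -> list[str]:
        return list(self.targets)


def _recovery_auc(ranks: np.ndarray, n_genes: int, n_targets: int, n_top: int) -> float:
    """Step-sum AUC of the target-recovery curve over the top n_top ranks.

    ``ranks`` holds the 0-based rank positions of the regulon's targets in
    one cell's descending expression ordering.  Normalized so that targets
    occupying the very top ranks score 1.
    """
    hits = np.sort(ranks[ranks < n_top])
    # y(r) = number of targets found among top r; AUC = sum over r=1..n_top
    auc = float(np.sum(n_top - hits))
    k = min(n_targets, n_top)
    max_auc = float(np.sum(n_top - np.arange(k)))
    return auc / max_auc


def score_regulons(
    expr: pd.DataFrame,
    regulons: RegulonSet,
    mode: str = "rank-auc",
    top_fraction: float = 0.05,
    min_counts_per_gene: float = 10,
    min_cells_per_gene: int = 9,
) -> pd.DataFrame:
    """Factor x cell activity matrix.

    ``expr`` is genes x cells.  Genes with fewer than ``min_counts_per_gene``
    total counts or expressed in fewer than ``min_cells_per_gene`` cells are
    dropped before ranking.  In ``rank-auc`` mode a cell's activity for a
    factor is the normalized recovery AUC of that factor's targets within
    the top ``top_fraction`` of the cell's expression ranking (invariant to
    per-cell monotone transforms).  ``mean-cubed`` delegates to the gene-set
    activity score.  Factors whose targets all fall outside the filtered
    matrix are dropped with a warning attribute on the result
    (``result.attrs['dropped']``).
    """
    keep = (expr.sum(axis=1) >= min_counts_per_gene) & (
        (expr > 0).sum(axis=1) >= min_cells_per_gene
    )
    mat = expr.loc[keep]
    if mat.empty:
        raise ValueError("gene filter removed every gene")
    dropped: list[str] = []
    rows: dict[str, pd.Series] = {}
    if mode == "mean-cubed":
        for factor in regulons.factors:
            present = [g for g in regulons.targets[factor] if g in mat.index]
            if not present:
                dropped.append(factor)
                continue
            rows[factor] = activity_score(mat, present, mode="mean-cubed")
    elif mode == "rank-auc":
        n_genes = mat.shape[0]
        n_top = max(1, int(round(top_fraction * n_genes)))
        # descending expression ranks per cell, ties broken by gene order
        order = np.argsort(-mat.to_numpy(), axis=0, kind="mergesort")
        rank_of_gene = np.empty_like(order)
        np.put_along_axis(
            rank_of_gene, order, np.arange(n_genes)[:, None].repeat(mat.shape[1], 1), axis=0
        )
        gene_pos = {g: i for i, g in enumerate(mat.index)}
        for factor in regulons.factors:
            tg_idx = [gene_pos[g] for g in regulons.targets[factor] if g in gene_pos]
            if not tg_idx:
                dropped.append(factor)
                continue
            tg_ranks = rank_of_gene[tg_idx, :]  # targets x cells
            vals = [
                _recovery_auc(tg_ranks[:, c], n_genes, len(tg_idx), n_top)
                for c in range(mat.shape[1])
            ]
            rows[factor] = pd.Series(vals, index=mat.columns)
    else:
        raise ValueError(f"unknown scoring mode: {mode}")
    if not rows:
        raise ValueError("no regulon overlaps the filtered expression matrix")
    out = pd.DataFrame(rows).T
    out.attrs["mode"] = mode
    out.attrs["dropped"] = dropped
    return out


def activity_expression_correlation(
    expr: pd.DataFrame,
    activity: pd.DataFrame,
    cells_a: list[str],
    cells_b: list[str],
    epsilon: float = 0.01,
) -> tuple[pd.DataFrame, float]:
    """Per-factor expression vs activity log2 fold changes between clusters.

    For each factor present in both matrices: log2((mean_a + eps) /
    (mean_b + eps)) of the factor's own expression and of its activity.
    Returns the table plus the Pearson correlation across factors (NaN,
    flagged in ``table.attrs['r_defined']``, when fewer than 3 factors or a
    zero-variance axis).
    """
    if len(cells_a) == 0 or len(cells_b) == 0:
        raise ValueError("both cell groups must be non-empty")
    factors = [f for f in activity.index if f in expr.index]
    recs = []
    for f in factors:
        e_a = expr.loc[f, cells_a].mean()
        e_b = expr.loc[f, cells_b].mean()
        a_a = activity.loc[f, cells_a].mean()
        a_b = activity.loc[f, cells_b].mean()
        recs.append(
            {
                "factor": f,
                "log2fc_expression": np.log2((e_a + epsilon) / (e_b + epsilon)),
                "log2fc_activity": np.log2((a_a + epsilon) / (a_b + epsilon)),
            }
        )
    table = pd.DataFrame(recs).set_index("factor")
    x = table["log2fc_expression"].to_numpy()
    y = table["log2fc_activity"].to_numpy()
    defined = len(table) >= 3 and np.std(x) > 0 and np.std(y) > 0
    r = float(stats.pearsonr(x, y).statistic) if defined else float("nan")
    table.attrs["r_defined"] = defined
    if defined:
        slope, intercept = np.polyfit(x, y, 1)
        table.attrs["regression"] = {"slope": float(slope), "intercept": float(intercept)}
    return table, r


def motif_class_fractions(regulons: RegulonSet, factor: str) -> dict[str, float]:
    """Fraction of a factor's motif annotations in each class; sums to 1."""
    tags = regulons.motifs.get(factor, [])
    if not tags:
        raise ValueError(f"factor {factor} has no motif annotations")
    n = len(tags)
    return {cls: tags.count(cls) / n for cls in MOTIF_CLASSES}
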
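"""Bulk RNA-seq normalization and absolute quantification.

Implements the division-sorted bulk workflow: reads-per-million scaling, the
per-group detection filter, ERCC spike-in molecules-per-cell conversion

    mRNA_A / cell = (FPKM_A / n_cells) * (sum molecules_ERCC / sum FPKM_ERCC),

total mRNA content per sample, and differential-expression flagging with a
hand-rolled Benjamini-Hochberg step-up.  The upstream per-gene test is
pluggable; the default is a two-sample Wilcoxon rank-sum on log2(RPM + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BulkMatrix",
    "rpm_normalize",
    "filter_detected",
    "molecules_per_cell",
    "total_mrna_content",
    "bh_adjust",
    "flag_deg",
    "wilcoxon_de",
]

SPIKE_PREFIX = "ERCC-"


@dataclass
class BulkMatrix:
    """Genes x samples bulk expression matrix with a unit tag.

    Spike-in rows are identified by ``spike_prefix`` on the gene id.  Each
    sample belongs to exactly one experimental group via ``groups``.
    """

    values: pd.DataFrame
    unit: str = "counts"  # counts | RPM | FPKM | molecules-per-cell
    groups: pd.Series | None = None  # sample -> group
    cells_per_sample: float = 1000.0
    spike_prefix: str = SPIKE_PREFIX

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.groups is not None:
            missing = set(self.values.columns) - set(self.groups.index)
            if missing:
                raise ValueError(f"samples without a group: {sorted(missing)}")

    @property
    def spike_mask(self) -> pd.Series:
        return self.values.index.str.startswith(self.spike_prefix)

    def biological(self) -> pd.DataFrame:
        return self.values.loc[~self.spike_mask]

    def spikes(self) -> pd.DataFrame:
        return self.values.loc[self.spike_mask]

    def with_values(self, values: pd.DataFrame, unit: str) -> "BulkMatrix":
        return replace(self, values=values, unit=unit)


def rpm_normalize(mat: BulkMatrix, include_spikes: bool = False) -> BulkMatrix:
    """Scale each sample to one million reads.

    The per-million denominator covers biological genes only by default;
    spike rows are carried through scaled by the same factor so the
    spike/gene ratio within a sample is preserved.
    """
    denom_rows = mat.values if include_spikes else mat.biological()
    totals = denom_rows.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-sum sample(s): {list(zero.index)}")
    out = mat.values * (1e6 / totals)
    return mat.with_values(out, "RPM")


def filter_detected(
    mat: BulkMatrix, min_rpm: float = 3.0, exclude_spikes: bool = True
) -> pd.Index:
    """Genes detected at >= min_rpm in *every* sample of at least one group."""
    if mat.groups is None:
        raise ValueError("detection filter requires a group map")
    values = mat.biological() if exclude_spikes else mat.values
    keep = np.zeros(len(values), dtype=bool)
    for grp, samples in mat.groups.groupby(mat.groups):
        cols = samples.index
        if len(cols) == 0:
            raise ValueError(f"empty group: {grp}")
        keep |= (values[cols] >= min_rpm).all(axis=1).to_numpy()
    return values.index[keep]


def molecules_per_cell(
    mat: BulkMatrix, spike_molecules: pd.Series
) -> BulkMatrix:
    """Convert FPKM (or RPM) to absolute mRNA molecules per cell.

    For each gene A and sample: (FPKM_A / n_cells) x (sum spike molecules /
    sum spike FPKM).  The spike molecule sum runs over the spikes present in
    the matrix; spike rows are excluded from the returned biological matrix.
    """
    spk = mat.spikes()
    if spk.empty:
        raise ValueError("no spike-in rows found; cannot quantify absolutely")
    if mat.cells_per_sample <= 0:
        raise ValueError("cells_per_sample must be > 0")
    known = spike_molecules.reindex(spk.index)
    if known.isna().any():
        missing = list(spk.index[known.isna()])
        raise ValueError(f"spikes without a molecule reference: {missing}")
    spike_fpkm_sum = spk.sum(axis=0)
    bad = spike_fpkm_sum[spike_fpkm_sum <= 0]
    if len(bad):
        raise ValueError(f"zero spike FPKM in sample(s): {list(bad.index)}")
    factor = known.sum() / spike_fpkm_sum  # per-sample molecules per FPKM unit
    out = mat.biological().mul(factor, axis=1) / mat.cells_per_sample
    return mat.with_values(out, "molecules-per-cell")


def total_mrna_content(mat: BulkMatrix) -> pd.Series:
    """Total mRNA molecules per cell in each sample (biological genes only)."""
    if mat.unit != "molecules-per-cell":
        raise ValueError("total mRNA content requires molecules-per-cell unit")
    return mat.biological().sum(axis=0)


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    q_(i) = min_{j >= i} p_(j) * m / j, enforced by a cumulative minimum from
    the largest p downward; order-preserving and permutation-invariant.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def flag_deg(
    stats_table: pd.DataFrame,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Flag differentially expressed genes.

    ``stats_table`` needs columns ``log2fc`` and ``p``; returns it with
    ``fdr`` (BH-adjusted) and ``significant`` = (|log2FC| > lfc_threshold
    and FDR < fdr_threshold) added.
    """
    out = stats_table.copy()
    if out.empty:
        out["fdr"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
        return out
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = (out["log2fc"].abs() > lfc_threshold) & (
        out["fdr"] < fdr_threshold
    )
    return out


def wilcoxon_de(
    rpm: BulkMatrix, group_a: str, group_b: str, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Default per-gene two-sample test: Wilcoxon rank-sum on log2(RPM + 1).

    Assumption-light plumbing upstream of :func:`flag_deg`; swap in any test
    producing (log2fc, p) per gene.
    """
    if rpm.groups is None:
        raise ValueError("group map required")
    cols_a = rpm.groups.index[rpm.groups == group_a]
    cols_b = rpm.groups.index[rpm.groups == group_b]
    if len(cols_a) == 0 or len(cols_b) == 0:
        raise ValueError("both groups must be non-empty")
    bio = rpm.biological()
    la = np.log2(bio[cols_a].to_numpy() + pseudocount)
    lb = np.log2(bio[cols_b].to_numpy() + pseudocount)
    log2fc = la.mean(axis=1) - lb.mean(axis=1)
    res = stats.mannwhitneyu(la, lb, axis=1, alternative="two-sided")
    p = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
    return pd.DataFrame({"log2fc": log2fc, "p": p}, index=bio.index)
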
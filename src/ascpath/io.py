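"""Readers and writers for the pipeline's standard formats.

10x-style MTX triplets (matrix.mtx / features.tsv / barcodes.tsv), dense TSV
matrices, GMT gene-set collections, spike reference tables, reference-panel
TSVs with a label header, and regulon TSVs.  MTX indices are 1-based on disk
and 0-based in memory; duplicate gene identifiers are collapsed by summation
with a warning.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .regulons import RegulonSet
from .simulate import ReferencePanel, PANEL_CELL_TYPES

__all__ = [
    "read_mtx_triplet",
    "write_mtx_triplet",
    "read_gmt",
    "write_gmt",
    "read_tsv_matrix",
    "write_tsv_matrix",
    "read_spike_reference",
    "write_spike_reference",
    "read_panel",
    "write_panel",
    "read_regulons",
    "write_regulons",
]


def write_mtx_triplet(adata: ad.AnnData, outdir: str | Path) -> None:
    """Write genes x cells MTX triplet (matrix.mtx, features.tsv, barcodes.tsv)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    mat = sp.coo_matrix(np.asarray(X).T if not sp.issparse(X) else X.T)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), mat)
    feats = pd.DataFrame({"gene": adata.var_names})
    if "is_spike" in adata.var:
        feats["is_spike"] = adata.var["is_spike"].to_numpy().astype(int)
    feats.to_csv(outdir / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(
        outdir / "barcodes.tsv", sep="\t", header=False, index=False
    )


def read_mtx_triplet(indir: str | Path) -> ad.AnnData:
    """Read a 10x-style triplet into AnnData (cells x genes)."""
    indir = Path(indir)
    for name in ("matrix.mtx", "features.tsv", "barcodes.tsv"):
        if not (indir / name).exists():
            raise FileNotFoundError(f"missing {name} in {indir}")
    mat = scipy.io.mmread(str(indir / "matrix.mtx")).tocsr()  # genes x cells
    feats = pd.read_csv(indir / "features.tsv", sep="\t", header=None)
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
    if mat.shape[0] != len(feats) or mat.shape[1] != len(barcodes):
        raise ValueError(
            f"matrix is {mat.shape} but features/barcodes have "
            f"{len(feats)}/{len(barcodes)} entries"
        )
    genes = feats[0].astype(str)
    X = np.asarray(mat.T.todense(), dtype=float)
    if genes.duplicated().any():
        warnings.warn("duplicate gene ids collapsed by summation")
        df = pd.DataFrame(X.T)
        df["gene"] = genes.to_numpy()
        X = df.groupby("gene", sort=False).sum().to_numpy().T
        genes = pd.Series(df.groupby("gene", sort=False).sum().index)
    var = pd.DataFrame(index=pd.Index(genes, name="gene"))
    if feats.shape[1] > 1:
        is_spike = feats.groupby(feats[0].astype(str), sort=False)[1].first()
        var["is_spike"] = is_spike.reindex(var.index).fillna(0).astype(bool)
    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=pd.Index(barcodes.astype(str), name="cell")),
        var=var,
    )
    adata.uns["unit"] = "raw UMI"
    return adata


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT: one set per line: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        name = parts[0]
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate gene set {name!r}")
        sets[name] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    lines = [
        "\t".join([name, "ascpath"] + list(genes)) for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_tsv_matrix(path: str | Path) -> pd.DataFrame:
    """Dense TSV matrix with a header row of sample/cell ids, genes as rows."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_tsv_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_spike_reference(path: str | Path) -> pd.Series:
    """Spike reference TSV: columns spike_id, molecules."""
    df = pd.read_csv(path, sep="\t")
    if not {"spike_id", "molecules"} <= set(df.columns):
        raise ValueError("spike reference needs columns spike_id, molecules")
    s = df.set_index("spike_id")["molecules"].astype(float)
    if (s <= 0).any():
        raise ValueError("spike molecule counts must be positive")
    if s.index.duplicated().any():
        raise ValueError("duplicate spike ids")
    return s


def write_spike_reference(spikes: pd.Series, path: str | Path) -> None:
    spikes.rename("molecules").rename_axis("spike_id").reset_index().to_csv(
        path, sep="\t", index=False
    )


def write_panel(panel: ReferencePanel, path: str | Path) -> None:
    """Panel TSV: first header line '#labels', then the matrix."""
    labels = "\t".join(["#labels"] + [panel.labels[c] for c in panel.matrix.columns])
    body = panel.matrix.to_csv(sep="\t")
    Path(path).write_text(labels + "\n" + body)


def read_panel(path: str | Path) -> ReferencePanel:
    text = Path(path).read_text().splitlines()
    if not text or not text[0].startswith("#labels"):
        raise ValueError("panel TSV must start with a '#labels' header line")
    label_vals = text[0].split("\t")[1:]
    from io import StringIO

    mat = pd.read_csv(StringIO("\n".join(text[1:])), sep="\t", index_col=0)
    if len(label_vals) != mat.shape[1]:
        raise ValueError("label header length does not match column count")
    labels = pd.Series(dict(zip(mat.columns, label_vals)), name="label")
    return ReferencePanel(
        matrix=mat, labels=labels, cell_types=dict(PANEL_CELL_TYPES)
    )


def read_regulons(path: str | Path) -> RegulonSet:
    """Regulon TSV: columns factor, target, motif_class (one row per pair)."""
    df = pd.read_csv(path, sep="\t")
    need = {"factor", "target", "motif_class"}
    if not need <= set(df.columns):
        raise ValueError(f"regulon TSV needs columns {sorted(need)}")
    targets: dict[str, list[str]] = {}
    motifs: dict[str, list[str]] = {}
    for factor, grp in df.groupby("factor", sort=False):
        targets[factor] = list(dict.fromkeys(grp["target"]))
        motifs[factor] = list(grp["motif_class"].dropna())
    return RegulonSet(targets=targets, motifs=motifs)


def write_regulons(regulons: RegulonSet, path: str | Path) -> None:
    recs = []
    for factor, tgs in regulons.targets.items():
        tags = regulons.motifs.get(factor, [])
        for i, t in enumerate(tgs):
            recs.append(
                {
                    "factor": factor,
                    "target": t,
                    "motif_class": tags[i] if i < len(tags) else None,
                }
            )
    pd.DataFrame(recs).to_csv(path, sep="\t", index=False)
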
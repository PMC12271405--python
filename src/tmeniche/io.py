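"""Readers and writers for the on-disk exchange formats.

Cell tables and cluster labels travel as TSV, patient metadata as CSV,
spatial samples as the 10X Visium triplet (matrix.mtx + features.tsv +
barcodes.tsv + tissue_positions.csv), gene sets as GMT, ligand-receptor
pairs as two-column CSV, and ground truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .stniche import STSample, make_st_sample

__all__ = [
    "read_cell_table",
    "write_cell_table",
    "write_visium",
    "read_visium",
    "read_gmt",
    "write_gmt",
    "read_lr_table",
    "read_protein_gene_map",
    "map_proteins_to_genes",
    "write_json",
]


def read_cell_table(path) -> pd.DataFrame:
    """Read a per-cell TSV (cell_id, roi_id, patient_id, x, y, marker_*)."""
    df = pd.read_csv(path, sep="\t")
    required = {"cell_id", "roi_id", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cell table missing columns: {sorted(missing)}")
    return df


def write_cell_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_visium(sample: STSample, outdir) -> None:
    """Write one sample as matrix.mtx + features/barcodes TSV + positions CSV.

    The matrix is written genes x spots, following the 10X convention.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    adata = sample.adata
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    mmwrite(str(outdir / "matrix.mtx"), sp.coo_matrix(X.T), field="integer")
    feats = pd.DataFrame(
        {
            "gene_id": adata.var_names,
            "gene_name": adata.var_names,
            "feature_type": "Gene Expression",
        }
    )
    feats.to_csv(outdir / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(
        outdir / "barcodes.tsv", sep="\t", header=False, index=False
    )
    pos = pd.DataFrame(
        {
            "barcode": adata.obs_names,
            "in_tissue": 1,
            "array_row": adata.obs["array_row"].to_numpy(),
            "array_col": adata.obs["array_col"].to_numpy(),
            "pxl_row_in_fullres": adata.obs["array_row"].to_numpy() * 100,
            "pxl_col_in_fullres": adata.obs["array_col"].to_numpy() * 100,
        }
    )
    pos.to_csv(outdir / "tissue_positions.csv", index=False)


def read_visium(indir, sample_id: str | None = None, group: str = "") -> STSample:
    """Load a Visium triplet directory back into an :class:`STSample`."""
    indir = Path(indir)
    mat = sp.csr_matrix(mmread(str(indir / "matrix.mtx"))).T  # spots x genes
    feats = pd.read_csv(indir / "features.tsv", sep="\t", header=None)
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    pos = pd.read_csv(indir / "tissue_positions.csv").set_index("barcode")
    pos.index = pos.index.astype(str)
    pos = pos.loc[barcodes]
    return make_st_sample(
        sample_id or indir.name,
        group,
        mat,
        feats[1].tolist() if feats.shape[1] > 1 else feats[0].tolist(),
        pos,
    )


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_lr_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "ligand" not in cols or "receptor" not in cols:
        raise ValueError("LR table needs 'ligand' and 'receptor' columns")
    out = df.rename(columns={cols["ligand"]: "ligand", cols["receptor"]: "receptor"})
    out["ligand"] = out["ligand"].str.upper()
    out["receptor"] = out["receptor"].str.upper()
    return out.drop_duplicates(subset=["ligand", "receptor"]).reset_index(drop=True)


def read_protein_gene_map(path) -> dict[str, str]:
    """Two-column CSV (protein, gene) mapping panel names to gene symbols.

    E.g. CD31 -> PECAM1 when converting an IMC community into an ST query.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("mapping needs two columns: protein, gene")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def map_proteins_to_genes(proteins, mapping: dict[str, str]) -> list[str]:
    """Translate protein markers to gene symbols, keeping unmapped names."""
    return [mapping.get(p, p) for p in proteins]


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
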
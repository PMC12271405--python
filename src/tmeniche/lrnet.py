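"""Ligand-receptor enrichment in niche ESGs and the cell-interaction network.

A ligand-receptor pair is niche-enriched when both genes are recurrent
extended signature genes.  Enriched pairs are summarized into a cell-type
interaction matrix: with the indicator I(LR, c1, c2) = 1 when the ligand is
expressed in cell type c1 and the receptor in c2 (above a per-gene
threshold), the normalizer N(LR) = sum_{c1,c2} I counts the expressing
ordered type pairs, and

    CI(c1, c2) = sum_LR I(LR, c1, c2) / N(LR),

so each retained pair distributes exactly one unit of mass over the
ordered cell-type pairs.  "Expressed" defaults to the gene's niche
cell-type expression exceeding its median across cell types; a numeric
threshold can be supplied instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CINetwork", "lr_enrich", "ci_network"]


@dataclass
class CINetwork:
    """Cell-type interaction scores with per-pair bookkeeping."""

    ordered: pd.DataFrame  # ligand cell type (rows) x receptor cell type (cols)
    symmetric: pd.DataFrame  # unordered-pair mass: CI + CI.T off-diagonal
    n_lr: pd.Series  # N(LR) per retained pair label "LIG->REC"
    contributions: pd.DataFrame  # pair, ligand_ct, receptor_ct, weight

    @property
    def n_pairs_retained(self) -> int:
        return len(self.n_lr)


def lr_enrich(esg_genes, lr_table: pd.DataFrame) -> pd.DataFrame:
    """Pairs whose ligand AND receptor are both in the ESG list."""
    genes = {g.upper() for g in esg_genes}
    tab = lr_table.copy()
    keep = tab["ligand"].str.upper().isin(genes) & tab["receptor"].str.upper().isin(genes)
    return tab[keep].reset_index(drop=True)


def _expressed(expr: pd.DataFrame, threshold) -> pd.DataFrame:
    """Boolean gene x cell-type 'expressed' matrix."""
    if isinstance(threshold, str) and threshold == "median":
        med = expr.median(axis=1)
        return expr.gt(med, axis=0)
    return expr > float(threshold)


def ci_network(
    pairs: pd.DataFrame,
    celltype_expr: pd.DataFrame,
    threshold="median",
) -> CINetwork:
    """Cell-interaction network from enriched LR pairs and cell-type expression.

    ``pairs`` has ligand/receptor columns; ``celltype_expr`` is gene x cell
    type (e.g. the niche cell-type expression projection).  Pairs whose
    genes are absent from the expression matrix, or expressed in no
    cell-type pair (N = 0), are dropped.
    """
    types = list(celltype_expr.columns)
    on = _expressed(celltype_expr, threshold)
    ordered = pd.DataFrame(0.0, index=types, columns=types)
    n_lr: dict[str, int] = {}
    contrib_rows = []
    for _, row in pairs.iterrows():
        lig, rec = row["ligand"], row["receptor"]
        if lig not in on.index or rec not in on.index:
            continue
        lig_on = on.loc[lig].to_numpy(bool)
        rec_on = on.loc[rec].to_numpy(bool)
        I = np.outer(lig_on, rec_on)
        n = int(I.sum())
        if n == 0:
            continue
        label = f"{lig}->{rec}"
        n_lr[label] = n
        ordered += I / n
        for i, c1 in enumerate(types):
            for j, c2 in enumerate(types):
                if I[i, j]:
                    contrib_rows.append(
                        {"pair": label, "ligand_ct": c1, "receptor_ct": c2, "weight": 1.0 / n}
                    )
    if not n_lr:
        warnings.warn("no LR pair expressed in any cell-type pair; empty network")
    sym = ordered + ordered.T
    np.fill_diagonal(sym.values, np.diag(ordered))
    return CINetwork(
        ordered=ordered,
        symmetric=sym,
        n_lr=pd.Series(n_lr, dtype=int),
        contributions=pd.DataFrame(
            contrib_rows, columns=["pair", "ligand_ct", "receptor_ct", "weight"]
        ),
    )
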
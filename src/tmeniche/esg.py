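"""Extended signature genes (ESGs) and their validation statistics.

Spots of an ST sample are stratified by QCS into community-high (top 10%)
and community-low (bottom 10%) deciles; per-sample ESGs are the genes
up-regulated in the high spots (Wilcoxon rank-sum, BH q <= 0.05, log2 fold
change floor).  A gene is a recurrent group signature when it is an ESG in
at least half of the focal group's samples and in a strictly larger
fraction than in the other group.

ESGs are projected onto cell types with a single-cell reference:

    Expr_{g,c,N} = AvgExpr_{g,c} * V_{g,N},
    V_{g,N} = mean_{s in N} VExpr_{g,s} - mean_{s in S} VExpr_{g,s},

where the niche N is the community-high spot set.  Validation utilities
cover the per-gene high/low log2 fold change with a one-sided paired t
test across genes, region-level (GeoMx-style) niche scores, and the
upper-tail hypergeometric overlap test against external signatures.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .stniche import STSample, QCSResult, normalize_st

__all__ = [
    "ESGSet",
    "CellTypeNicheExpression",
    "stratify_spots",
    "per_sample_esg",
    "recurrent_esgs",
    "celltype_niche_expression",
    "validation_lfc",
    "paired_lfc_test",
    "geomx_score",
    "overlap_test",
]

logger = logging.getLogger(__name__)

LFC_PSEUDOCOUNT = 1e-9


@dataclass
class ESGSet:
    """Per-sample ESG lists with group-level recurrence."""

    per_sample: dict[str, list[str]]
    groups: dict[str, str]
    focal_group: str
    recurrent: list[str]
    fractions: pd.DataFrame  # gene x group fraction of samples carrying it


@dataclass
class CellTypeNicheExpression:
    """Eq-style projection of niche expression onto reference cell types."""

    matrix: pd.DataFrame  # gene x cell type, AvgExpr * V
    v: pd.Series  # per-gene niche-minus-background expression
    avg_expr: pd.DataFrame  # reference gene x cell type means
    omitted: list[str] = field(default_factory=list)


def stratify_spots(
    scores,
    top: float = 0.10,
    bottom: float = 0.10,
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the QCS-highest and -lowest spot deciles.

    Ties are broken by stable spot order.  Overlapping sets (too few
    spots) raise an error.
    """
    scores = np.asarray(scores, float)
    n = len(scores)
    n_high = max(1, int(n * top))
    n_low = max(1, int(n * bottom))
    order = np.argsort(scores, kind="stable")
    low = np.sort(order[:n_low])
    high = np.sort(order[::-1][:n_high])
    if np.intersect1d(high, low).size:
        raise ValueError("high and low spot sets overlap; sample too small")
    return high, low


def per_sample_esg(
    sample: STSample,
    high: np.ndarray,
    low: np.ndarray,
    alpha: float = 0.05,
    min_lfc: float = 0.25,
) -> list[str]:
    """Genes up-regulated in community-high vs community-low spots.

    One-sided Wilcoxon rank-sum per gene (high > low) on the log-normalized
    layer, BH-adjusted q <= alpha, and a log2 fold-change floor computed on
    the same non-negative layer with a pseudocount.  Zero-variance genes
    are skipped.
    """
    if len(high) < 5 or len(low) < 5:
        raise ValueError("need >= 5 spots in each of high and low")
    if "lognorm" not in sample.adata.layers:
        normalize_st(sample)
    E = np.asarray(sample.adata.layers["lognorm"])
    genes = sample.adata.var_names
    hi, lo = E[high], E[low]
    keep = np.std(np.vstack([hi, lo]), axis=0) > 0
    pvals = np.ones(keep.sum())
    with np.errstate(invalid="ignore"):
        res = stats.mannwhitneyu(hi[:, keep], lo[:, keep], alternative="greater", axis=0)
    pvals = res.pvalue
    lfc = np.log2(
        (hi[:, keep].mean(axis=0) + LFC_PSEUDOCOUNT)
        / (lo[:, keep].mean(axis=0) + LFC_PSEUDOCOUNT)
    )
    q = multipletests(pvals, method="fdr_bh")[1]
    sel = (q <= alpha) & (lfc >= min_lfc)
    return [g for g, s in zip(genes[keep], sel) if s]


def recurrent_esgs(
    per_sample: dict[str, list[str]],
    groups: dict[str, str],
    focal_group: str,
) -> ESGSet:
    """Group-recurrent ESGs: >= 50% of focal samples, strictly above the other group.

    ``per_sample`` maps sample ids to their ESG lists and ``groups`` maps
    sample ids to group labels.
    """
    focal = [s for s, g in groups.items() if g == focal_group]
    other = [s for s, g in groups.items() if g != focal_group]
    if len(focal) < 2:
        raise ValueError("need >= 2 samples in the focal group")
    all_genes = sorted({g for lst in per_sample.values() for g in lst})
    frac = pd.DataFrame(index=all_genes, columns=["focal", "other"], dtype=float)
    for gene in all_genes:
        frac.loc[gene, "focal"] = np.mean([gene in per_sample.get(s, []) for s in focal])
        frac.loc[gene, "other"] = (
            np.mean([gene in per_sample.get(s, []) for s in other]) if other else 0.0
        )
    keep = frac[(frac["focal"] >= 0.5) & (frac["focal"] > frac["other"])]
    return ESGSet(
        per_sample=dict(per_sample),
        groups=dict(groups),
        focal_group=focal_group,
        recurrent=sorted(keep.index),
        fractions=frac,
    )


def celltype_niche_expression(
    genes,
    reference: pd.DataFrame,
    sample: STSample,
    niche: np.ndarray,
    layer: str = "lognorm",
) -> CellTypeNicheExpression:
    """Project niche expression of the given genes onto reference cell types.

    ``reference`` is gene x cell-type mean expression; ``niche`` indexes the
    community-high spots.  Genes missing from the reference or the sample
    are omitted with a log entry.
    """
    if layer not in sample.adata.layers:
        normalize_st(sample)
    E = np.asarray(sample.adata.layers[layer])
    measured = set(sample.adata.var_names)
    usable = [g for g in genes if g in reference.index and g in measured]
    omitted = sorted(set(genes) - set(usable))
    if omitted:
        logger.info("celltype_niche_expression: omitted genes %s", omitted)
    if not usable:
        raise ValueError("no ESG covered by both the reference and the sample")
    idx = sample.adata.var_names.get_indexer(usable)
    v = pd.Series(
        E[niche][:, idx].mean(axis=0) - E[:, idx].mean(axis=0),
        index=usable,
        name="V",
    )
    avg = reference.loc[usable]
    matrix = avg.mul(v, axis=0)
    return CellTypeNicheExpression(matrix=matrix, v=v, avg_expr=avg, omitted=omitted)


def validation_lfc(
    sample: STSample,
    high: np.ndarray,
    low: np.ndarray,
    genes,
    layer: str = "lognorm",
) -> pd.Series:
    """Per-gene log2(avgExpr_high / avgExpr_low) on the normalized layer.

    Uses a pseudocount to keep ratios defined; all-zero genes are excluded.
    """
    if layer not in sample.adata.layers:
        normalize_st(sample)
    E = np.asarray(sample.adata.layers[layer])
    usable = [g for g in genes if g in set(sample.adata.var_names)]
    idx = sample.adata.var_names.get_indexer(usable)
    sub = E[:, idx]
    nonzero = sub.sum(axis=0) > 0
    usable = [g for g, k in zip(usable, nonzero) if k]
    idx = idx[nonzero]
    hi = E[high][:, idx].mean(axis=0)
    lo = E[low][:, idx].mean(axis=0)
    return pd.Series(
        np.log2((hi + LFC_PSEUDOCOUNT) / (lo + LFC_PSEUDOCOUNT)),
        index=usable,
        name=sample.sample_id,
    )


def paired_lfc_test(
    lfc_by_sample: pd.DataFrame,
    groups: dict[str, str],
    focal_group: str,
) -> tuple[float, float]:
    """One-sided paired t test of per-gene group-mean fold changes.

    Columns of ``lfc_by_sample`` are samples, rows genes; pairs are genes,
    comparing the focal-group mean lfc against the other group's
    (alternative: focal larger).
    """
    focal_cols = [c for c in lfc_by_sample.columns if groups.get(c) == focal_group]
    other_cols = [c for c in lfc_by_sample.columns if groups.get(c) != focal_group]
    if not focal_cols or not other_cols:
        raise ValueError("both groups must be represented")
    a = lfc_by_sample[focal_cols].mean(axis=1)
    b = lfc_by_sample[other_cols].mean(axis=1)
    res = stats.ttest_rel(a, b, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def geomx_score(roi_expression: pd.DataFrame, geneset) -> pd.Series:
    """Region-level niche score: sum of log-normalized expression over a gene set.

    ``roi_expression`` is ROI x gene, already log-normalized.
    """
    genes = [g for g in geneset if g in roi_expression.columns]
    if not genes:
        raise ValueError("gene set has no overlap with the measured genes")
    return roi_expression[genes].sum(axis=1).rename("niche_score")


def overlap_test(set_a, set_b, universe_size: int) -> tuple[int, float]:
    """Upper-tail hypergeometric test of the overlap between two gene sets."""
    a, b = set(set_a), set(set_b)
    if universe_size < max(len(a), len(b)):
        raise ValueError("universe smaller than one of the sets")
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, universe_size, len(a), len(b)))
    return k, p
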
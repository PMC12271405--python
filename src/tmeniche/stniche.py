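"""Visium-style spatial-transcriptomics niche scoring.

Implements the query co-localization score (QCS): for a gene set Q derived
from a cell community, the per-spot score is the mean scaled, log-normalized
expression of the query genes,

    QCS_{x,A} = (1/|Q|) * sum_{q in Q} Expr_{x,A}(q),

with significance judged per spot against a permutation null in which each
query gene's expression vector is independently shuffled across in-tissue
spots (destroying the spatial dependence among query genes while preserving
each gene's marginal distribution).  The per-sample statistic QCS_A is the
number of significant spots.

Spatial coherence of the significant-spot mask is quantified with a
silhouette-style score delta computed on a rank-normalized, exponentially
transformed distance r(s_i, s_j) = 1 - q**(rank_d(s_i,s_j) - 1), where
rank_d is the mutual rank (geometric mean of the two directed distance
ranks) of the spot pair.  delta is in [-1, 1]; compact patterns score high,
scattered patterns near 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.stats import rankdata

from anndata import AnnData
import scanpy as sc

__all__ = [
    "STSample",
    "QCSResult",
    "make_st_sample",
    "normalize_st",
    "qcs",
    "spatial_clustering",
    "compare_groups",
]


@dataclass
class STSample:
    """One spatial-transcriptomics sample: spots x genes with coordinates.

    ``adata.X`` holds raw counts; :func:`normalize_st` adds ``lognorm``
    (library-size normalized + log1p) and ``scaled`` (per-gene z) layers.
    ``adata.obs`` carries ``array_row``/``array_col`` grid coordinates.
    """

    sample_id: str
    group: str
    adata: AnnData

    @property
    def n_spots(self) -> int:
        return self.adata.n_obs

    @property
    def genes(self) -> pd.Index:
        return self.adata.var_names

    def coords(self) -> np.ndarray:
        return self.adata.obs[["array_row", "array_col"]].to_numpy(float)


@dataclass
class QCSResult:
    """Per-spot QCS scores with their permutation-null significance mask."""

    sample_id: str
    scores: np.ndarray
    mask: np.ndarray
    qcs_a: int
    alpha: float
    n_perm: int
    genes_used: list[str] = field(default_factory=list)
    delta: float | None = None


def make_st_sample(
    sample_id: str,
    group: str,
    counts,
    gene_names,
    positions: pd.DataFrame,
) -> STSample:
    """Assemble an :class:`STSample` from a counts matrix and spot positions.

    ``counts`` is spots x genes (dense or sparse); ``positions`` must carry
    ``array_row`` and ``array_col`` columns indexed like the spots.
    """
    X = sp.csr_matrix(counts) if not sp.issparse(counts) else counts.tocsr()
    adata = AnnData(X=X)
    adata.var_names = list(gene_names)
    adata.obs_names = [str(b) for b in positions.index]
    adata.obs["array_row"] = np.asarray(positions["array_row"])
    adata.obs["array_col"] = np.asarray(positions["array_col"])
    if "in_tissue" in positions:
        adata.obs["in_tissue"] = np.asarray(positions["in_tissue"])
        adata = adata[adata.obs["in_tissue"].astype(bool)].copy()
    return STSample(sample_id=sample_id, group=group, adata=adata)


def normalize_st(sample: STSample, target_sum: float | None = None) -> np.ndarray:
    """Normalize counts: median library-size scaling, log1p, per-gene z.

    Spots with zero total counts are dropped with a warning.  Adds the
    ``lognorm`` and ``scaled`` layers in place and returns the scaled
    (spots x genes) matrix.  Zero-variance genes scale to all zeros.
    """
    adata = sample.adata
    totals = np.asarray(adata.X.sum(axis=1)).ravel()
    if np.any(totals == 0):
        warnings.warn(
            f"{sample.sample_id}: dropping {int((totals == 0).sum())} zero-count spots"
        )
        sample.adata = adata = adata[totals > 0].copy()
        totals = totals[totals > 0]
    if target_sum is None:
        target_sum = float(np.median(totals))
    work = adata.copy()
    sc.pp.normalize_total(work, target_sum=target_sum)
    sc.pp.log1p(work)
    lognorm = work.X.toarray() if sp.issparse(work.X) else np.asarray(work.X)
    lognorm = lognorm.astype(np.float64)
    adata.layers["lognorm"] = lognorm
    mu = lognorm.mean(axis=0)
    sd = lognorm.std(axis=0, ddof=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    scaled = (lognorm - mu) / sd_safe
    scaled[:, sd == 0] = 0.0
    adata.layers["scaled"] = scaled
    return scaled


def _query_matrix(sample: STSample, query, layer: str = "scaled"):
    if layer not in sample.adata.layers:
        normalize_st(sample)
    genes = [g for g in query if g in sample.adata.var_names]
    dropped = sorted(set(query) - set(genes))
    if dropped:
        warnings.warn(f"{sample.sample_id}: query genes not measured, dropped: {dropped}")
    if not genes:
        raise ValueError(f"{sample.sample_id}: no query genes measured")
    idx = sample.adata.var_names.get_indexer(genes)
    return np.asarray(sample.adata.layers[layer])[:, idx], genes


def qcs(
    sample: STSample,
    query,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> QCSResult:
    """Per-spot query co-localization score and its permutation null.

    A spot is significant when its observed QCS exceeds the (1 - alpha)
    quantile of its own null distribution over ``n_perm`` shuffles, each of
    which permutes every query gene's expression independently across spots.
    """
    E, genes = _query_matrix(sample, query)
    if len(genes) < 2:
        warnings.warn(f"{sample.sample_id}: fewer than 2 query genes; null is degenerate")
    n_spots, nq = E.shape
    obs = E.mean(axis=1)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, n_spots))
    for p in range(n_perm):
        acc = np.zeros(n_spots)
        for j in range(nq):
            acc += E[rng.permutation(n_spots), j]
        null[p] = acc / nq
    thresh = np.quantile(null, 1.0 - alpha, axis=0)
    mask = obs > thresh
    return QCSResult(
        sample_id=sample.sample_id,
        scores=obs,
        mask=mask,
        qcs_a=int(mask.sum()),
        alpha=alpha,
        n_perm=n_perm,
        genes_used=genes,
    )


def mutual_rank_distance(coords: np.ndarray, q_const: float = 0.95) -> np.ndarray:
    """Rank-normalized exponential distance r = 1 - q**(mutual_rank - 1).

    Directed ranks are computed per spot over its Euclidean distances to all
    other spots (average ranks on ties); the mutual rank of a pair is the
    geometric mean of its two directed ranks.  Symmetric by construction.
    """
    coords = np.asarray(coords, float)
    n = len(coords)
    D = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    R = np.empty((n, n))
    for i in range(n):
        d = D[i].copy()
        d[i] = np.inf  # self excluded: ranked last, never used
        R[i] = rankdata(d, method="average")
    mr = np.sqrt(R * R.T)
    return 1.0 - q_const ** (mr - 1.0)


def spatial_clustering(coords, mask, q_const: float = 0.95) -> float:
    """Silhouette-style spatial coherence delta of a binary spot mask.

    For each positive spot i, m_i is the mean transformed distance to the
    negative spots and n_i the mean to the other positive spots; delta is
    the average of (m_i - n_i) / max(m_i, n_i) over positive spots.
    """
    mask = np.asarray(mask, bool)
    coords = np.asarray(coords, float)
    pos = np.flatnonzero(mask)
    neg = np.flatnonzero(~mask)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError(
            f"spatial_clustering undefined: |L1|={len(pos)}, |L0|={len(neg)} (need >= 2 each)"
        )
    r = mutual_rank_distance(coords, q_const=q_const)
    sil = np.empty(len(pos))
    for k, i in enumerate(pos):
        m_i = r[i, neg].mean()
        others = pos[pos != i]
        n_i = r[i, others].mean()
        sil[k] = (m_i - n_i) / max(m_i, n_i)
    return float(sil.mean())


def compare_groups(
    values,
    groups,
    reference: str,
    test: str = "t",
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Two-sample comparison of per-sample statistics between groups.

    ``test`` is Welch's t (``"t"``) or Kolmogorov-Smirnov (``"ks"``);
    ``alternative="greater"`` tests reference-group values larger.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    a = values[groups == reference]
    b = values[groups != reference]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("compare_groups needs >= 2 samples per group")
    if test == "t":
        res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    elif test == "ks":
        # scipy's 'greater' KS alternative means CDF(a) > CDF(b), i.e. a
        # stochastically smaller; flip so 'greater' means reference larger.
        alt = {"greater": "less", "less": "greater"}.get(alternative, alternative)
        res = stats.ks_2samp(a, b, alternative=alt)
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)
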
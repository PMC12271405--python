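"""Spatial cluster-cluster proximity enrichment and group-differential tests.

Each ROI's cells are joined by a Delaunay triangulation; the interaction
statistic for an unordered cluster pair (a, b) is the number of Delaunay
edges joining the two clusters.  A within-ROI label-shuffling null (cluster
abundances preserved, graph fixed) converts the observed count into a
z-score.  Group-differential interactions are found per pair with a
random-intercept linear mixed model

    z ~ group + (1 | patient)

compared against the intercept-only null by a maximum-likelihood
likelihood-ratio test, with Benjamini-Hochberg adjustment across pairs and
an optional leave-2-patient-out subsampling confidence interval.  A simple
pixel-pair co-localization count (pairs closer than a pixel threshold)
supports immunofluorescence validation.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import Delaunay, QhullError, cKDTree
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "SpatialGraph",
    "cohort_interaction_table",
    "build_delaunay",
    "proximity_enrichment",
    "differential_interactions",
    "leave2out_ci",
    "pixel_coloc_count",
]


@dataclass
class SpatialGraph:
    """Undirected Delaunay adjacency of the cells in one ROI."""

    roi_id: str
    n_nodes: int
    edges: np.ndarray  # (E, 2) with edges[:, 0] < edges[:, 1]


def build_delaunay(coords, roi_id: str = "roi") -> SpatialGraph:
    """Delaunay spatial graph of one ROI's cell positions.

    Duplicate coordinates are jittered by eps = 1e-6 (deterministically
    seeded by the ROI id) with a warning; fewer than 3 cells or a fully
    collinear ROI raises an error naming the ROI.
    """
    pts = np.asarray(coords, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"{roi_id}: expected (n, 2) coordinates")
    if not np.all(np.isfinite(pts)):
        raise ValueError(f"{roi_id}: non-finite coordinates")
    if len(pts) < 3:
        raise ValueError(f"{roi_id}: need >= 3 cells for a Delaunay graph")
    if len(np.unique(pts, axis=0)) < len(pts):
        warnings.warn(f"{roi_id}: duplicate coordinates jittered by 1e-6")
        rng = np.random.default_rng(zlib.crc32(str(roi_id).encode()))
        pts = pts + rng.uniform(-1e-6, 1e-6, size=pts.shape)
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise ValueError(f"{roi_id}: degenerate (collinear?) cell positions") from exc
    edges = set()
    for simplex in tri.simplices:
        for i in range(3):
            u, v = simplex[i], simplex[(i + 1) % 3]
            edges.add((min(u, v), max(u, v)))
    e = np.array(sorted(edges), dtype=int)
    return SpatialGraph(roi_id=str(roi_id), n_nodes=len(pts), edges=e)


def _pair_counts(codes: np.ndarray, edges: np.ndarray, n_levels: int) -> np.ndarray:
    """Counts of edges joining each unordered code pair, as an L x L upper array."""
    a = codes[edges[:, 0]]
    b = codes[edges[:, 1]]
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    flat = np.bincount(lo * n_levels + hi, minlength=n_levels * n_levels)
    return flat.reshape(n_levels, n_levels)


def proximity_enrichment(
    graph: SpatialGraph,
    labels,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation z-scores of cluster-pair adjacency in one ROI.

    Shuffles cell labels within the ROI ``n_perm`` times (graph fixed,
    abundances preserved) and returns one row per unordered pair of the
    clusters present: observed count, null mean/sd, and
    z = (obs - mean) / sd (0 when the null sd is 0).
    """
    labels = pd.Series(list(labels))
    if len(labels) != graph.n_nodes:
        raise ValueError("labels must cover all nodes of the graph")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} < 100: z-scores will be unstable")
    levels = sorted(labels.unique())
    lut = {lab: i for i, lab in enumerate(levels)}
    codes = labels.map(lut).to_numpy()
    L = len(levels)
    obs = _pair_counts(codes, graph.edges, L)
    rng = np.random.default_rng(seed)
    acc = np.zeros((L, L))
    acc2 = np.zeros((L, L))
    for _ in range(n_perm):
        c = _pair_counts(rng.permutation(codes), graph.edges, L)
        acc += c
        acc2 += c.astype(float) ** 2
    mean = acc / n_perm
    var = np.maximum(acc2 / n_perm - mean**2, 0.0)
    sd = np.sqrt(var)
    rows = []
    for i in range(L):
        for j in range(i, L):
            z = 0.0 if sd[i, j] == 0 else (obs[i, j] - mean[i, j]) / sd[i, j]
            rows.append(
                {
                    "roi_id": graph.roi_id,
                    "clusterA": levels[i],
                    "clusterB": levels[j],
                    "obs": int(obs[i, j]),
                    "null_mean": mean[i, j],
                    "null_sd": sd[i, j],
                    "z": float(z),
                }
            )
    return pd.DataFrame(rows)


def cohort_interaction_table(
    cells: pd.DataFrame,
    labels: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Proximity-enrichment z table over every ROI of a cell table.

    ``cells`` needs cell_id/roi_id/x/y; ``labels`` is indexed by cell_id.
    Each ROI gets its own derived permutation seed.
    """
    tables = []
    for i, (roi, sub) in enumerate(cells.groupby("roi_id", sort=True)):
        graph = build_delaunay(sub[["x", "y"]].to_numpy(), roi_id=roi)
        tables.append(
            proximity_enrichment(
                graph, labels.loc[sub["cell_id"]], n_perm=n_perm, seed=seed + i
            )
        )
    return pd.concat(tables, ignore_index=True)


def _fit_pair_lmm(sub: pd.DataFrame) -> tuple[float, float] | None:
    """ML fit of z ~ group_ind + (1|patient) vs null; (coef, LRT p)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        try:
            full = sm.MixedLM(
                sub["z"].to_numpy(),
                sm.add_constant(sub["group_ind"].to_numpy()),
                groups=sub["patient_id"].to_numpy(),
            ).fit(reml=False)
            null = sm.MixedLM(
                sub["z"].to_numpy(),
                np.ones((len(sub), 1)),
                groups=sub["patient_id"].to_numpy(),
            ).fit(reml=False)
        except (np.linalg.LinAlgError, ValueError):
            return None
    with np.errstate(invalid="ignore"):
        lrt = max(0.0, 2.0 * (full.llf - null.llf))
    p = float(stats.chi2.sf(lrt, df=1))
    return float(full.params[1]), p


def _merge_meta(table: pd.DataFrame, meta: pd.DataFrame, reference: str) -> pd.DataFrame:
    df = table.merge(meta[["roi_id", "patient_id", "group"]], on="roi_id", how="inner")
    df["group_ind"] = (df["group"] == reference).astype(float)
    df["pair"] = df.apply(lambda r: f"{r['clusterA']}--{r['clusterB']}", axis=1)
    return df


def differential_interactions(
    table: pd.DataFrame,
    meta: pd.DataFrame,
    reference: str = "groupA",
    one_sided: bool = False,
    min_rois: int = 3,
) -> pd.DataFrame:
    """Group-differential interaction pairs via a random-intercept model.

    ``table`` is the per-ROI interaction z table; ``meta`` maps roi_id to
    patient_id and group.  A positive coefficient means the pair is
    enriched in the ``reference`` group.  The likelihood-ratio p-value can
    optionally be halved when the coefficient sign matches the tested
    (reference-enriched) direction (``one_sided``); q-values are
    Benjamini-Hochberg across pairs.  Pairs observed in fewer than
    ``min_rois`` ROIs are skipped with a warning.
    """
    groups = meta["group"].unique()
    for g in groups:
        if meta.loc[meta["group"] == g, "patient_id"].nunique() < 2:
            raise ValueError(f"need >= 2 patients per group (group {g})")
    df = _merge_meta(table, meta, reference)
    rows = []
    for pair, sub in df.groupby("pair", sort=True):
        if sub["roi_id"].nunique() < min_rois:
            warnings.warn(f"pair {pair}: observed in <{min_rois} ROIs, skipped")
            continue
        res = _fit_pair_lmm(sub)
        if res is None:
            warnings.warn(f"pair {pair}: mixed-model fit failed, skipped")
            continue
        coef, p = res
        if one_sided:
            p = p / 2 if coef > 0 else 1 - p / 2
        rows.append(
            {
                "clusterA": sub["clusterA"].iloc[0],
                "clusterB": sub["clusterB"].iloc[0],
                "pair": pair,
                "coef": coef,
                "p": p,
                "n_rois": sub["roi_id"].nunique(),
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        warnings.warn("no pairs eligible for differential testing")
        return out
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def leave2out_ci(
    table: pd.DataFrame,
    meta: pd.DataFrame,
    pairs: list[str] | None = None,
    reference: str = "groupA",
    n_subsamples: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Leave-2-patient-out subsampling 95% CI of the group coefficient.

    Refits the mixed model on ``n_subsamples`` random removals of two
    patients; the CI is the 2.5/97.5 percentile band of the coefficients.
    """
    for g in meta["group"].unique():
        if meta.loc[meta["group"] == g, "patient_id"].nunique() < 4:
            raise ValueError("leave-2-out requires >= 4 patients per group")
    df = _merge_meta(table, meta, reference)
    if pairs is None:
        pairs = sorted(df["pair"].unique())
    patients = np.array(sorted(meta["patient_id"].unique()))
    rng = np.random.default_rng(seed)
    rows = []
    for pair in pairs:
        sub_all = df[df["pair"] == pair]
        coefs = []
        for _ in range(n_subsamples):
            drop = rng.choice(patients, size=2, replace=False)
            sub = sub_all[~sub_all["patient_id"].isin(drop)]
            res = _fit_pair_lmm(sub)
            if res is not None:
                coefs.append(res[0])
        if not coefs:
            warnings.warn(f"pair {pair}: all subsample fits failed")
            continue
        lo, hi = np.percentile(coefs, [2.5, 97.5])
        rows.append({"pair": pair, "ci_lo": float(lo), "ci_hi": float(hi)})
    return pd.DataFrame(rows)


def pixel_coloc_count(
    pixels_a,
    pixels_b,
    maxdist: float = 40.0,
    n_nuclei: int | None = None,
) -> float:
    """Count of cross-channel pixel pairs strictly closer than ``maxdist``.

    With ``n_nuclei`` the count is normalized per cell.  Empty inputs give 0.
    """
    A = np.atleast_2d(np.asarray(pixels_a, float))
    B = np.atleast_2d(np.asarray(pixels_b, float))
    if A.size == 0 or B.size == 0:
        count = 0
    else:
        if not (np.isfinite(A).all() and np.isfinite(B).all()):
            raise ValueError("pixel coordinates must be finite")
        ta = cKDTree(A)
        hits = ta.query_ball_tree(cKDTree(B), r=maxdist)
        count = 0
        for i, js in enumerate(hits):
            if js:
                d = np.linalg.norm(B[js] - A[i], axis=1)
                count += int((d < maxdist).sum())
    if n_nuclei is not None:
        if n_nuclei <= 0:
            raise ValueError("n_nuclei must be positive")
        return count / n_nuclei
    return count
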
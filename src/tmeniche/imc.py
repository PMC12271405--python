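"""Single-cell IMC phenotyping: normalization, K-means, differential markers.

Protein intensities are log1p-transformed, z-scored per marker across all
cells, then z-scored per cell across markers, in that order.  Cells are
phenotyped by K-means over many random restarts (the restart with the
lowest within-cluster sum of squares wins), and each cluster is assigned
the markers that are significantly higher in it than in nearly every other
cluster in one-vs-one Welch tests — with K = 20 clusters the requirement
is 17 of the 19 comparisons, generalized to ceil((K-1) * 17/19) otherwise.
Clusters are named by concatenating their differential markers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

__all__ = ["ClusterModel", "normalize_expression", "cluster_cells", "differential_markers"]

DEFAULT_K = 20
DEFAULT_RESTARTS = 1000
MARKER_VOTE_FRACTION = 17 / 19


@dataclass
class ClusterModel:
    """Fitted phenotyping model: labels, centroids, and marker annotation."""

    k: int
    centroids: np.ndarray  # K x M, normalized space
    labels: np.ndarray  # per-cell cluster in 0..K-1
    inertia: float
    markers: dict[int, list[str]] = field(default_factory=dict)
    names: dict[int, str] = field(default_factory=dict)


def _zscore(X: np.ndarray, axis: int) -> np.ndarray:
    mu = X.mean(axis=axis, keepdims=True)
    sd = X.std(axis=axis, ddof=0, keepdims=True)
    out = np.where(sd > 0, (X - mu) / np.where(sd == 0, 1.0, sd), 0.0)
    return out


def normalize_expression(X) -> np.ndarray:
    """log1p, then z per marker (column), then z per cell (row).

    Accepts a cells x markers array or DataFrame of non-negative
    intensities.  Zero-variance columns/rows map to zeros.
    """
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("expected a non-empty cells x markers matrix")
    if np.any(arr < 0):
        raise ValueError("intensities must be non-negative")
    arr = np.log1p(arr)
    arr = _zscore(arr, axis=0)
    arr = _zscore(arr, axis=1)
    return arr


def cluster_cells(
    X,
    k: int = DEFAULT_K,
    n_restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
) -> ClusterModel:
    """K-means phenotyping with multiple random restarts.

    The restart with the minimum within-cluster sum of squares is kept;
    deterministic given ``seed``.
    """
    arr = np.asarray(X, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    if k > arr.shape[0]:
        raise ValueError(f"k={k} exceeds the number of cells ({arr.shape[0]})")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(arr)
    return ClusterModel(
        k=k, centroids=km.cluster_centers_, labels=labels, inertia=float(km.inertia_)
    )


def differential_markers(
    model: ClusterModel,
    X,
    alpha: float = 0.05,
    marker_names: list[str] | None = None,
) -> dict[int, list[str]]:
    """One-vs-one differential protein markers per cluster.

    A marker belongs to cluster k when, in Welch t-tests against every
    other cluster, it is significant (p <= alpha) with the cluster-k mean
    higher in at least ceil((K-1) * 17/19) of the K-1 comparisons.
    Clusters with fewer than two cells yield an empty list with a warning.
    Updates ``model.markers``/``model.names`` in place and returns the
    marker dict.
    """
    arr = np.asarray(X, dtype=float)
    n_markers = arr.shape[1]
    if marker_names is None:
        marker_names = [f"marker_{j + 1}" for j in range(n_markers)]
    k = model.k
    need = math.ceil((k - 1) * MARKER_VOTE_FRACTION)
    groups = [arr[model.labels == c] for c in range(k)]
    out: dict[int, list[str]] = {}
    for c in range(k):
        if len(groups[c]) < 2:
            warnings.warn(f"cluster {c} has <2 cells; no differential markers")
            out[c] = []
            continue
        votes = np.zeros(n_markers, dtype=int)
        for other in range(k):
            if other == c or len(groups[other]) < 2:
                continue
            with np.errstate(invalid="ignore", divide="ignore"):
                t, p = stats.ttest_ind(groups[c], groups[other], equal_var=False, axis=0)
            higher = groups[c].mean(axis=0) > groups[other].mean(axis=0)
            votes += ((p <= alpha) & higher & np.isfinite(p)).astype(int)
        out[c] = [marker_names[j] for j in np.flatnonzero(votes >= need)]
    model.markers = out
    model.names = {
        c: "_".join(m) if m else f"cluster{c}" for c, m in out.items()
    }
    return out
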
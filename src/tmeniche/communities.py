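"""Cell communities: assembly, cross-dataset matching, and patient scoring.

A community is a connected component of the graph whose nodes are cell
clusters and whose edges are group-differential interactions passing the
FDR cut (default 0.20) with the requested coefficient sign.  Components are
pruned in two ways: a component that is a single node carrying only a
self-interaction is dropped, and bridge edges — graph-theoretic bridges
whose removal splits a component into two sub-components of at least two
nodes each — are removed before components are re-extracted.

Communities found independently in different cohorts are matched on their
protein-marker content (union of the member clusters' differential
markers); the match score is the intersection size and assignment is greedy
best-first.  Patients are scored by averaging each member edge's
interaction z across the patient's ROIs, summing over the community's
edges, and summing communities into a community-all score used to stratify
patients at the cohort mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Community",
    "detect_communities",
    "match_communities",
    "score_patients",
]

DEFAULT_FDR = 0.20


@dataclass
class Community:
    """A connected set of cluster nodes with their interaction edges."""

    id: str
    nodes: frozenset
    edges: frozenset  # of unordered (a, b) tuples, a <= b
    markers: frozenset = field(default_factory=frozenset)
    provenance: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.nodes)


def _norm_edge(a, b) -> tuple:
    return (a, b) if str(a) <= str(b) else (b, a)


def detect_communities(
    diff: pd.DataFrame,
    fdr: float = DEFAULT_FDR,
    direction: str = "positive",
    markers: dict | None = None,
    provenance: dict | None = None,
) -> list[Community]:
    """Connected-component communities from the differential-interaction table.

    Keeps pairs with q <= fdr and the requested coefficient sign, builds the
    undirected cluster graph (self-loops retained), extracts connected
    components, and prunes (i) single-node components whose only edge is a
    self-loop and (ii) qualifying bridge edges, re-extracting components.
    """
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")
    sign = 1.0 if direction == "positive" else -1.0
    sel = diff[(diff["q"] <= fdr) & (sign * diff["coef"] > 0)]
    if sel.empty:
        warnings.warn("no differential interactions pass the FDR/sign filter")
        return []
    G = nx.Graph()
    for _, row in sel.iterrows():
        G.add_edge(row["clusterA"], row["clusterB"])

    # prune rule ii: bridges whose removal leaves two sub-components of >= 2 nodes
    to_remove = []
    for u, v in nx.bridges(G):
        H = G.copy()
        H.remove_edge(u, v)
        side_u = nx.node_connected_component(H, u)
        side_v = nx.node_connected_component(H, v)
        if len(side_u) >= 2 and len(side_v) >= 2:
            to_remove.append((u, v))
    G.remove_edges_from(to_remove)

    comms: list[Community] = []
    for nodes in nx.connected_components(G):
        sub = G.subgraph(nodes)
        edges = frozenset(_norm_edge(a, b) for a, b in sub.edges())
        # prune rule i: singleton with only a self-interaction
        if len(nodes) == 1 and all(a == b for a, b in edges):
            continue
        mk = frozenset()
        if markers:
            mk = frozenset(m for n in nodes for m in markers.get(n, []))
        comms.append(
            Community(
                id="",
                nodes=frozenset(nodes),
                edges=edges,
                markers=mk,
                provenance=dict(provenance or {}),
            )
        )
    comms.sort(key=lambda c: (-c.size, sorted(str(n) for n in c.nodes)))
    for i, c in enumerate(comms):
        c.id = f"C{i + 1}"
    return comms


def match_communities(
    comms_a: list[Community],
    comms_b: list[Community],
) -> pd.DataFrame:
    """Marker-based matching between two community sets.

    The match score of a pair is the size of the intersection of the
    communities' marker sets.  The assignment maximizes the total match
    score over injective pairings (Hungarian algorithm, which reduces to
    best-first matching when the top scores are unambiguous, the regime
    cross-cohort communities live in); zero-score or empty-marker pairs
    stay unmatched.  Matches are ranked by score, ties broken by larger
    combined community size then lexicographic ids; the top match is the
    Community1 of each set.
    """
    from scipy.optimize import linear_sum_assignment

    if not comms_a or not comms_b:
        return pd.DataFrame(columns=["id_a", "id_b", "score", "rank"])
    S = np.array(
        [[len(ca.markers & cb.markers) for cb in comms_b] for ca in comms_a]
    )
    ai, bi = linear_sum_assignment(S, maximize=True)
    rows = []
    for i, j in zip(ai, bi):
        if S[i, j] > 0:
            ca, cb = comms_a[i], comms_b[j]
            rows.append(
                {
                    "id_a": ca.id,
                    "id_b": cb.id,
                    "score": int(S[i, j]),
                    "_size": ca.size + cb.size,
                }
            )
    rows.sort(key=lambda r: (-r["score"], -r["_size"], r["id_a"], r["id_b"]))
    out = pd.DataFrame(rows, columns=["id_a", "id_b", "score", "_size"]).drop(
        columns="_size"
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def resolve_split_merge(
    ca: Community,
    cb1: Community,
    cb2: Community,
    arbiter: list[Community] | None,
) -> str:
    """Arbitrate whether a community matches the union of two smaller ones.

    When community ``ca`` ties against ``cb1`` and ``cb2`` separately, a
    third dataset decides: if the best arbiter match of the merged marker
    set beats the best single match, report ``"merge"``, else ``"split"``.
    Without a third dataset the decision falls back to the higher total
    match score, which for a tie is the merged union.
    """
    merged = cb1.markers | cb2.markers
    if not arbiter:
        merged_score = len(ca.markers & merged)
        split_score = max(len(ca.markers & cb1.markers), len(ca.markers & cb2.markers))
        return "merge" if merged_score >= split_score else "split"
    best_merged = max((len(merged & cc.markers) for cc in arbiter), default=0)
    best_split = max(
        (max(len(cb1.markers & cc.markers), len(cb2.markers & cc.markers)) for cc in arbiter),
        default=0,
    )
    return "merge" if best_merged >= best_split else "split"


def score_patients(
    table: pd.DataFrame,
    communities: list[Community],
    meta: pd.DataFrame,
) -> pd.DataFrame:
    """Per-patient community scores and high/low stratification.

    For each community edge, the pair's z is averaged over the patient's
    ROIs (avoiding any reward for ROI count), then summed over the
    community's edges to a per-community score; the community-all score is
    the sum over communities and strata split at the cohort mean of the
    community-all score.  Patients with no ROIs in the table are excluded
    with a warning.
    """
    df = table.merge(meta[["roi_id", "patient_id"]], on="roi_id", how="inner")
    df["edge"] = [
        _norm_edge(a, b) for a, b in zip(df["clusterA"], df["clusterB"])
    ]
    all_patients = meta["patient_id"].unique()
    with_rois = set(df["patient_id"].unique())
    missing = [p for p in all_patients if p not in with_rois]
    if missing:
        warnings.warn(f"patients with zero ROIs excluded: {missing}")
    rows = []
    for patient, sub in df.groupby("patient_id", sort=True):
        edge_mean = sub.groupby("edge")["z"].mean()
        rec: dict = {"patient_id": patient}
        total = 0.0
        for comm in communities:
            score = float(sum(edge_mean.get(e, 0.0) for e in comm.edges))
            rec[comm.id] = score
            total += score
        rec["community_all"] = total
        rows.append(rec)
    out = pd.DataFrame(rows)
    if out.empty:
        warnings.warn("no patients could be scored")
        return out
    mean_all = out["community_all"].mean()
    out["stratum"] = np.where(out["community_all"] > mean_all, "high", "low")
    return out
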
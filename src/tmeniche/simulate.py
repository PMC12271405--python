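"""Synthetic cohorts with planted spatial structure and known ground truth.

Emulates the study designs the pipeline targets:

* multi-patient, two-group IMC-like cohorts — per-ROI cell positions on a
  600 x 600 micron square with log-normal marker intensities drawn from
  cluster archetypes, and, in one group, planted cluster pairs whose cells
  are seeded within one Delaunay neighborhood of a partner cell;
* Visium-style ST samples on a spot lattice with negative-binomial counts
  and, in one group, a spatially compact disc niche co-expressing the
  planted query and extended-signature genes — the other group receives the
  same elevation scattered uniformly (a diffuse pattern of equal total
  burden);
* a per-cell-type mean-expression reference and a ligand-receptor pair
  table partially embedded in the planted signature genes;
* exponential survival times whose hazard scales with a per-patient score.

All generators are pure functions of :class:`SimConfig` (one seed, split
hierarchically per patient / ROI / sample), so a fixed config reproduces
byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .stniche import STSample, make_st_sample

__all__ = [
    "SimConfig",
    "GroundTruth",
    "IMCCohort",
    "gen_imc_cohort",
    "gen_st_cohort",
    "gen_reference_and_lr",
    "gen_survival",
]

GROUPS = ("groupA", "groupB")
ROI_SIZE = 600.0  # microns, square ROI side


@dataclass
class SimConfig:
    """Parameters of one synthetic study.

    ``planted_pairs`` entries are ``(clusterA, clusterB, group, strength)``
    with strength in [0, 1]: the probability that a cell of clusterB in an
    ROI of that group is seeded adjacent to a random clusterA cell.
    ``niche_effect`` is a natural-log fold change applied to the planted
    genes inside the niche; ``hazard_ratio`` is the per-SD hazard ratio tied
    to the patient score fed to :func:`gen_survival`.
    """

    seed: int = 0
    n_patients_per_group: int = 10
    rois_per_patient: int = 2
    cells_per_roi: int = 500
    n_markers: int = 26
    n_clusters: int = 20
    planted_pairs: list[tuple[int, int, str, float]] = field(default_factory=list)
    st_grid: tuple[int, int] = (40, 40)
    n_st_samples_per_group: int = 10
    n_genes: int = 500
    niche_radius: float = 6.0
    planted_query_genes: list[str] | None = None
    planted_esg_genes: list[str] | None = None
    niche_effect: float = 1.5
    nb_dispersion: float = 0.3
    n_cell_types: int = 5
    n_lr_pairs: int = 50
    hazard_ratio: float = 3.0
    censoring_fraction: float = 0.3
    baseline_median_months: float = 24.0

    def gene_universe(self) -> list[str]:
        return [f"G{i:04d}" for i in range(1, self.n_genes + 1)]

    def query_genes(self) -> list[str]:
        if self.planted_query_genes is not None:
            return list(self.planted_query_genes)
        return self.gene_universe()[:8]

    def esg_genes(self) -> list[str]:
        if self.planted_esg_genes is not None:
            return list(self.planted_esg_genes)
        return self.gene_universe()[8:38]

    def validate(self) -> None:
        universe = set(self.gene_universe())
        for lst, name in (
            (self.query_genes(), "planted_query_genes"),
            (self.esg_genes(), "planted_esg_genes"),
        ):
            extra = set(lst) - universe
            if extra:
                raise ValueError(f"{name} outside the gene universe: {sorted(extra)}")
        for a, b, grp, strength in self.planted_pairs:
            if grp not in GROUPS:
                raise ValueError(f"planted pair group {grp!r} not in {GROUPS}")
            if not 0.0 <= strength <= 1.0:
                raise ValueError(f"adjacency strength {strength} outside [0, 1]")
            if not (0 <= a < self.n_clusters and 0 <= b < self.n_clusters):
                raise ValueError(f"planted pair ({a},{b}) outside 0..{self.n_clusters - 1}")
        if not 0.0 <= self.censoring_fraction < 1.0:
            raise ValueError("censoring_fraction must be in [0, 1)")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")


@dataclass
class GroundTruth:
    """Planted structure used to score the downstream stages."""

    cell_labels: pd.DataFrame | None = None  # cell_id, roi_id, true_cluster
    planted_pairs: list[tuple[int, int, str, float]] = field(default_factory=list)
    niche_masks: dict[str, np.ndarray] = field(default_factory=dict)
    esg_genes: list[str] = field(default_factory=list)
    query_genes: list[str] = field(default_factory=list)
    log_hazard: float | None = None

    def to_jsonable(self) -> dict:
        out = {
            "planted_pairs": [list(p) for p in self.planted_pairs],
            "esg_genes": self.esg_genes,
            "query_genes": self.query_genes,
            "log_hazard": self.log_hazard,
            "niche_masks": {k: v.astype(int).tolist() for k, v in self.niche_masks.items()},
        }
        if self.cell_labels is not None:
            out["cell_labels"] = self.cell_labels.to_dict(orient="list")
        return out


@dataclass
class IMCCohort:
    """Per-cell table plus patient metadata for one IMC-like cohort."""

    cells: pd.DataFrame  # cell_id, roi_id, patient_id, x, y, marker_*
    metadata: pd.DataFrame  # patient_id, group, age, stage, bmi

    def marker_columns(self) -> list[str]:
        return [c for c in self.cells.columns if c.startswith("marker_")]

    def roi_map(self) -> pd.DataFrame:
        m = self.cells[["roi_id", "patient_id"]].drop_duplicates()
        return m.merge(self.metadata[["patient_id", "group"]], on="patient_id")


def _archetypes(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Cluster-mean matrix (K x M) in log-intensity space.

    Each cluster carries two signature markers (round-robin over the panel)
    at a +2 log-mean; background log-mean 0.
    """
    mu = np.zeros((config.n_clusters, config.n_markers))
    for k in range(config.n_clusters):
        for j in (2 * k, 2 * k + 1):
            mu[k, j % config.n_markers] = 2.0
    return mu


def gen_imc_cohort(config: SimConfig) -> tuple[IMCCohort, GroundTruth]:
    """Generate a two-group IMC cohort with planted adjacent cluster pairs.

    In ROIs of a planted pair's group, each clusterB cell is, with
    probability equal to the adjacency strength, re-seeded within roughly
    half the typical nearest-neighbour spacing of a random clusterA cell,
    which places it inside that cell's Delaunay neighbourhood; all other
    placements are uniform on the ROI square.
    """
    config.validate()
    if config.n_clusters < 2:
        raise ValueError("need n_clusters >= 2")
    if config.cells_per_roi < 10 * config.n_clusters:
        raise ValueError("need cells_per_roi >= 10 * n_clusters")
    root = np.random.SeedSequence(config.seed)
    arch_rng = np.random.default_rng(root.spawn(1)[0])
    mu = _archetypes(config, arch_rng)
    sigma = 0.5
    # within-Delaunay seeding radius: about half the mean NN spacing
    seed_radius = 0.5 * ROI_SIZE / np.sqrt(config.cells_per_roi)

    rows, meta_rows, label_rows = [], [], []
    n_pat = config.n_patients_per_group
    pat_seqs = root.spawn(2 * n_pat + 1)[1:]
    for p_idx in range(2 * n_pat):
        group = GROUPS[p_idx // n_pat]
        patient_id = f"P{p_idx + 1:03d}"
        prng = np.random.default_rng(pat_seqs[p_idx])
        meta_rows.append(
            {
                "patient_id": patient_id,
                "group": group,
                "age": float(np.round(prng.normal(58, 10), 1)),
                "stage": int(prng.integers(1, 4)),
                "bmi": float(np.round(prng.normal(28, 4), 1)),
            }
        )
        pairs_here = [pp for pp in config.planted_pairs if pp[2] == group]
        for r in range(config.rois_per_patient):
            roi_id = f"{patient_id}_R{r + 1}"
            rng = np.random.default_rng(pat_seqs[p_idx].spawn(config.rois_per_patient)[r])
            n = config.cells_per_roi
            labels = rng.integers(0, config.n_clusters, size=n)
            pos = rng.uniform(0, ROI_SIZE, size=(n, 2))
            for a, b, _, strength in pairs_here:
                a_idx = np.flatnonzero(labels == a)
                b_idx = np.flatnonzero(labels == b)
                if len(a_idx) == 0 or len(b_idx) == 0 or strength == 0:
                    continue
                move = b_idx[rng.random(len(b_idx)) < strength]
                partners = rng.choice(a_idx, size=len(move))
                theta = rng.uniform(0, 2 * np.pi, size=len(move))
                rad = seed_radius * np.sqrt(rng.random(len(move)))
                offs = np.column_stack([np.cos(theta), np.sin(theta)]) * rad[:, None]
                pos[move] = np.clip(pos[partners] + offs, 0, ROI_SIZE)
            intens = np.exp(rng.normal(mu[labels], sigma))
            for i in range(n):
                rows.append(
                    {
                        "cell_id": f"{roi_id}_c{i + 1}",
                        "roi_id": roi_id,
                        "patient_id": patient_id,
                        "x": pos[i, 0],
                        "y": pos[i, 1],
                        **{f"marker_{m + 1}": intens[i, m] for m in range(config.n_markers)},
                    }
                )
                label_rows.append(
                    {"cell_id": f"{roi_id}_c{i + 1}", "roi_id": roi_id, "true_cluster": int(labels[i])}
                )
    cohort = IMCCohort(cells=pd.DataFrame(rows), metadata=pd.DataFrame(meta_rows))
    gt = GroundTruth(
        cell_labels=pd.DataFrame(label_rows),
        planted_pairs=list(config.planted_pairs),
    )
    return cohort, gt


def _disc_mask(rows: int, cols: int, center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return ((rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2).ravel()


def gen_st_cohort(config: SimConfig) -> tuple[list[STSample], GroundTruth]:
    """Generate two-group ST samples with a planted niche in one group.

    groupA samples carry a compact disc of ``niche_radius`` spots in which
    the planted query and ESG genes are elevated by exp(niche_effect);
    groupB receives the same per-spot elevation on an equal number of
    uniformly scattered spots, emulating a diffuse expression pattern of
    the same total burden.
    """
    config.validate()
    rows, cols = config.st_grid
    if config.niche_radius >= min(rows, cols) / 2:
        raise ValueError("niche_radius must be < min(grid)/2")
    universe = config.gene_universe()
    planted = sorted(set(config.query_genes()) | set(config.esg_genes()))
    planted_idx = np.array([universe.index(g) for g in planted])

    root = np.random.SeedSequence(config.seed + 1)
    base_rng = np.random.default_rng(root.spawn(1)[0])
    # per-gene baseline means on a log-normal grid, typical count ~2
    gene_mu = np.exp(base_rng.normal(np.log(2.0), 0.6, size=config.n_genes))

    samples: list[STSample] = []
    masks: dict[str, np.ndarray] = {}
    n_per = config.n_st_samples_per_group
    seqs = root.spawn(2 * n_per + 1)[1:]
    grid = pd.DataFrame(
        {
            "array_row": np.repeat(np.arange(rows), cols),
            "array_col": np.tile(np.arange(cols), rows),
        },
        index=[f"spot{r * cols + c:05d}" for r in range(rows) for c in range(cols)],
    )
    n_spots = rows * cols
    for s_idx in range(2 * n_per):
        group = GROUPS[s_idx // n_per]
        sample_id = f"S{s_idx + 1:03d}"
        rng = np.random.default_rng(seqs[s_idx])
        mu_mat = np.tile(gene_mu, (n_spots, 1))
        if group == "groupA":
            r0 = config.niche_radius
            center = (rng.uniform(r0, rows - 1 - r0), rng.uniform(r0, cols - 1 - r0))
            mask = _disc_mask(rows, cols, center, r0)
        else:
            n_mask = int(np.round(np.pi * config.niche_radius**2))
            chosen = rng.choice(n_spots, size=min(n_mask, n_spots), replace=False)
            mask = np.zeros(n_spots, bool)
            mask[chosen] = True
        if config.niche_effect != 0:
            mu_mat[np.ix_(mask, planted_idx)] *= np.exp(config.niche_effect)
        # gamma-Poisson mixture = negative binomial with dispersion phi
        phi = config.nb_dispersion
        if phi > 0:
            lam = rng.gamma(shape=1.0 / phi, scale=mu_mat * phi)
        else:
            lam = mu_mat
        counts = rng.poisson(lam)
        samples.append(make_st_sample(sample_id, group, counts, universe, grid))
        masks[sample_id] = mask
    gt = GroundTruth(
        niche_masks=masks,
        esg_genes=config.esg_genes(),
        query_genes=config.query_genes(),
    )
    return samples, gt


def gen_reference_and_lr(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cell-type mean-expression reference and a ligand-receptor pair table.

    Each cell type receives a block of designated marker genes whose mean is
    highest in that type.  A subset of LR pairs (up to 10) is drawn with
    both genes inside the planted ESG list so that niche-level LR enrichment
    has a ground truth.
    """
    if config.n_cell_types < 2:
        raise ValueError("need >= 2 cell types")
    config.validate()
    universe = config.gene_universe()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed + 2))
    types = [f"CT{t + 1}" for t in range(config.n_cell_types)]
    ref = pd.DataFrame(
        np.exp(rng.normal(0.0, 0.2, size=(config.n_genes, config.n_cell_types))),
        index=universe,
        columns=types,
    )
    markers_per_type = 10
    for t, ct in enumerate(types):
        block = universe[t * markers_per_type : (t + 1) * markers_per_type]
        ref.loc[block, ct] *= 5.0

    esg = [g for g in config.esg_genes() if g in universe]
    pairs: set[tuple[str, str]] = set()
    n_embedded = min(10, config.n_lr_pairs, len(esg) // 2)
    while len(pairs) < n_embedded:
        lig, rec = rng.choice(esg, size=2, replace=False)
        pairs.add((lig, rec))
    while len(pairs) < config.n_lr_pairs:
        lig, rec = rng.choice(universe, size=2, replace=False)
        pairs.add((lig, rec))
    lr = pd.DataFrame(sorted(pairs), columns=["ligand", "receptor"])
    return ref, lr


def gen_survival(scores: pd.Series, config: SimConfig) -> pd.DataFrame:
    """Exponential survival with hazard h0 * HR**z tied to standardized scores.

    Censoring is an independent exponential calibrated so that each subject
    is censored before its event with probability ``censoring_fraction``.
    Times are in months; the baseline median is ``baseline_median_months``.
    """
    scores = pd.Series(scores).astype(float)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    config.validate()
    sd = scores.std(ddof=0)
    z = (scores - scores.mean()) / sd if sd > 0 else scores * 0.0
    rng = np.random.default_rng(np.random.SeedSequence(config.seed + 3))
    h0 = np.log(2) / config.baseline_median_months
    haz = h0 * config.hazard_ratio ** z.to_numpy()
    t_event = rng.exponential(1.0 / haz)
    f = config.censoring_fraction
    if f > 0:
        c_haz = haz * f / (1.0 - f)
        t_cens = rng.exponential(1.0 / c_haz)
    else:
        t_cens = np.full_like(t_event, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame(
        {"patient_id": scores.index, "time": time, "event": event}
    ).reset_index(drop=True)


def config_to_dict(config: SimConfig) -> dict:
    return asdict(config)
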
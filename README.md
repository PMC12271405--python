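# tmeniche

Spatial multi-omic discovery of group-associated cell–cell interaction
communities and transcriptomic niches in the tumor microenvironment.

Imaging mass cytometry (IMC) gives per-cell protein profiles with spatial
coordinates inside tissue regions of interest (ROIs); Visium-style spatial
transcriptomics (ST) gives genome-wide expression on a spot lattice.
`tmeniche` implements an integrative pipeline that asks, for a cohort split
into two patient groups: *which cell types sit next to each other more often
in one group, do those adjacencies organize into multicellular communities,
are the communities prognostic, and what does the transcriptome of the
corresponding tissue niche look like?*

## The statistics at the core

**Proximity enrichment.** Cells of one ROI are joined by a Delaunay
triangulation; for clusters *(a, b)* the statistic is the number of Delaunay
edges joining them. Shuffling cluster labels within the ROI (1000
permutations, abundances preserved) yields *z = (obs − μ₀)/σ₀* per ROI and
pair.

**Differential interactions.** Per pair, a random-intercept linear mixed
model `z ~ group + (1 | patient)` is compared against `z ~ 1 + (1 | patient)`
by a maximum-likelihood likelihood-ratio test (patients contribute repeated
ROIs), with Benjamini–Hochberg adjustment across pairs and an optional
leave-2-patient-out subsampling confidence interval.

**Communities.** Pairs passing FDR ≤ 0.20 with the group-enriched sign form
a graph over clusters; communities are connected components after pruning
self-loop singletons and bridge edges that join two sub-components of ≥ 2
nodes. Patients are scored by the sum over community edges of the patient's
mean ROI *z*, summed over communities into a community-all score, and
stratified at the cohort mean for one-tailed log-rank and Cox
proportional-hazards analysis (Efron ties, Wald tests).

**Query co-localization (QCS).** For a community's gene set *Q* in an ST
sample, `QCS_x = (1/|Q|) Σ_{q∈Q} Expr_x(q)` on the scaled, log-normalized
layer; a spot is significant when its QCS exceeds the 95th percentile of a
null built by independently permuting each query gene across in-tissue
spots. The per-sample count of significant spots and a silhouette-style
spatial-coherence score δ — computed on the mutual-rank-transformed distance
`r(s_i, s_j) = 1 − q^(rank_d(s_i,s_j) − 1)`, q = 0.95 — quantify how much and
how compactly a community's niche is expressed.

**Extended signature genes (ESGs).** Spots are stratified into the top and
bottom QCS deciles; per-sample ESGs are genes up-regulated in the high spots
(one-sided Wilcoxon, BH q ≤ 0.05, log2 fold-change ≥ 0.25), made
group-recurrent by a ≥ 50 %-of-focal-samples rule with a strictly larger
focal fraction. ESGs are projected onto cell types via a single-cell
reference (`Expr_{g,c,N} = AvgExpr_{g,c} · V_{g,N}` with `V_{g,N}` the niche
minus whole-sample mean expression) and drive a ligand–receptor
cell-interaction network in which each expressed LR pair distributes one
unit of mass over the expressing cell-type pairs.

A synthetic-data module generates two-group IMC cohorts with planted
adjacent cluster pairs, ST cohorts with a planted compact niche (versus an
equal-burden scattered pattern in the other group), cell-type references,
LR tables, and survival times whose hazard follows the community score —
so every stage has ground truth.

## Worked example

```python
import pandas as pd
import tmeniche as tm

cfg = tm.SimConfig(
    seed=1, n_patients_per_group=10, rois_per_patient=2, cells_per_roi=500,
    n_markers=16, n_clusters=8, planted_pairs=[(0, 1, "groupA", 0.8)],
)
cohort, truth = tm.gen_imc_cohort(cfg)
X = tm.normalize_expression(cohort.cells[cohort.marker_columns()])
model = tm.cluster_cells(X, k=8, n_restarts=20, seed=1)
markers = tm.differential_markers(model, X, marker_names=cohort.marker_columns())
labels = pd.Series(model.labels, index=cohort.cells["cell_id"])
table = tm.cohort_interaction_table(cohort.cells, labels, n_perm=1000, seed=1)
diff = tm.differential_interactions(table, cohort.roi_map(), reference="groupA")
print(diff.sort_values("q").head(3)[["pair", "coef", "p", "q"]].to_string(index=False))
comms = tm.detect_communities(diff, fdr=0.20, markers=markers)
print("communities:", [(c.id, sorted(c.nodes)) for c in comms])
scores = tm.score_patients(table, comms, cohort.roi_map())
surv = tm.gen_survival(scores.set_index("patient_id")["community_all"], cfg)
surv = surv.merge(scores[["patient_id", "stratum"]], on="patient_id")
print("one-tailed log-rank p =", round(tm.km_logrank(surv)["p_one_tailed"], 5))
```

prints

```
pair      coef            p            q
1--7  4.657300 2.449331e-13 8.817591e-12
2--7 -1.706676 3.181944e-06 3.818333e-05
4--7 -2.040186 2.318157e-06 3.818333e-05
communities: [('C1', [0, 2, 3, 4, 5, 6]), ('C2', [1, 7])]
one-tailed log-rank p = 0.00769
```

The planted adjacency (true clusters 0–1, recovered here as fitted labels
1 and 7) dominates the differential table with a strongly positive
group coefficient and survives FDR control; community detection returns it
as its own community (`C2`). The complementary community `C1` among the
remaining clusters is an expected by-product of the placement design:
relocating partner cells toward each other in one group mildly co-enriches
everything else. Patients stratified by the community-all score separate in
survival because the generator ties the hazard to exactly that score
(hazard ratio 3 per SD).

A thin CLI mirrors the library:
`tmeniche simulate`, `tmeniche imc-cluster`, `tmeniche imc-interactions`,
`tmeniche communities`, `tmeniche survival`, `tmeniche st-qcs`,
`tmeniche lr-network` (see `tmeniche --help`).

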
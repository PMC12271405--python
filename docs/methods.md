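# Methods

This note records the models, defaults, and numerical conventions behind
`tmeniche`, and what the synthetic cohorts can and cannot demonstrate.

## IMC phenotyping

Protein intensities are `log1p`-transformed, z-scored per marker across all
cells, then z-scored per cell across markers — in that order. The two-step
z removes panel-wide scale differences first and per-cell staining
intensity second; zero-variance vectors map to zeros rather than NaN.
The source description of this normalization is ambiguous about whether the
second step re-standardizes cells or markers; we fix cells-then-markers as
stated above and treat it as a convention, not a derivation.

Cells are phenotyped with K-means (scikit-learn), keeping the restart with
the lowest within-cluster sum of squares. The default is K = 20 clusters
and 1 000 random restarts; at desk scale the optimum stabilizes well below
that, and the restart count is exposed for larger panels. Differential
markers per cluster come from one-vs-one Welch t-tests: a marker belongs to
a cluster when it is significant (p ≤ 0.05) with the higher mean in at
least ⌈(K−1)·17/19⌉ of the K−1 comparisons (17 of 19 at K = 20). Welch
rather than pooled-variance tests because cluster sizes are very unequal;
the higher-mean direction is required so that markers name the cluster they
characterize. Note that the vote rule is a selection procedure, not a
calibrated test: on pure noise, K-means manufactures small real mean
differences along its separating directions, and a marker or two per
cluster can pass even with no planted structure.

## Spatial interactions

Each ROI's cells are triangulated (scipy Delaunay; duplicate coordinates
jittered by 1e-6 with a deterministic per-ROI seed). The interaction count
for an unordered cluster pair is the number of Delaunay edges joining the
two clusters, each edge counted once. The null fixes the graph and shuffles
labels within the ROI (1 000 permutations by default; fewer than 100 gives
a warning), which conditions on cluster abundances; z = 0 when the null sd
is 0. Fewer than ~100 permutations makes the z unstable, and extreme z are
bounded by the permutation resolution.

Group-differential pairs are tested with statsmodels `MixedLM` fit by
maximum likelihood: full model `z ~ group + (1|patient)`, null
`z ~ 1 + (1|patient)`, likelihood-ratio statistic against chi-square with
one degree of freedom. ML (not REML) because the two models differ in fixed
effects. The group indicator is 1 for the reference group, so a positive
coefficient means enriched in that group. A documented one-sided option
halves the p-value when the sign matches the tested direction; the default
is the two-sided LRT because the source material is ambiguous between an
ANOVA-style comparison and a one-sided F-test. With one ROI per patient the
random-intercept variance estimate collapses and the coefficient agrees
with ordinary least squares to numerical precision (tested). Pairs observed
in fewer than three ROIs are skipped. BH adjustment runs across pairs.
The leave-2-patient-out confidence band refits the model on 100 random
two-patient removals and takes the 2.5/97.5 percentiles.

Pixel co-localization counts cross-channel pixel pairs at Euclidean
distance strictly below 40 pixels (kd-tree query, exact strict comparison
at the boundary), optionally normalized per nucleus.

## Communities and survival

Edges with q ≤ 0.20 and the group-enriched sign form a cluster graph.
Components are pruned twice: single nodes carrying only a self-interaction
are dropped, and graph-theoretic bridges whose removal leaves two
sub-components of at least two nodes each are removed before components are
re-extracted (a pendant node is not split off). Cross-cohort matching
reduces each community to the union of its clusters' differential markers
and maximizes the total intersection size over injective pairings
(Hungarian assignment; ties broken by larger combined size then
lexicographic id). We use the optimal assignment rather than a greedy sweep
because the two coincide whenever the top matches are unambiguous — the
regime that matters — and only the optimum passes a brute-force check on
adversarial instances. When a community in one cohort ties as the union of
two in another, a third cohort arbitrates (merged versus split marker sets
against its best match); with only two cohorts the higher total score wins.

The per-patient community score averages each member edge's z over the
patient's ROIs before summing edges, so patients with more ROIs are not
rewarded; the community-all score sums communities, and strata split at the
cohort mean. Survival uses a signed log-rank Z from the standard
observed-minus-expected decomposition (one-tailed p in the direction
high-score-worse; Z² equals the usual chi-square, cross-checked against
lifelines), and Cox proportional-hazards fits from lifelines with the Efron
tie correction and one-sided Wald p-values for the score term. Ordinal
covariates such as stage enter numerically as provided.

## ST niche scoring

Counts are scaled to the median spot total, `log1p`-transformed
(`lognorm` layer), and per-gene z-scaled across spots (`scaled` layer);
zero-count spots are dropped. "Scaled" is read as per-gene scaling — the
alternative per-spot reading would re-weight spots by library size that the
normalization just removed.

QCS is the mean scaled expression of the query genes per spot. The null
permutes every query gene independently across in-tissue spots (each
permutation re-draws all genes; seeds split per sample) and each spot is
compared against its own null 95th percentile — a per-spot empirical null
rather than a pooled or max-over-spots null, because the question is
whether *this* spot co-expresses the query beyond chance. Genes missing
from the panel are dropped and |Q| counts retained genes. One practical
caveat: the query must be small relative to the panel. Library
normalization fixes each spot's total, so when the query is a large
fraction of all measured genes its members become negatively correlated
within a spot and the shuffled null over-disperses.

Spatial coherence δ follows the silhouette form
`δ = (1/|L1|) Σ_i (m_i − n_i)/max(m_i, n_i)` on the transformed distance
`r = 1 − 0.95^(mutual_rank − 1)`. The mutual rank is the geometric mean of
the two directed distance ranks (average ranks on ties, self excluded);
this is the standard mutual-rank convention and the single most
consequential interpretation choice in the module, so it is isolated in
`mutual_rank_distance` and pinned by a hand-computed four-spot oracle.
Distances are Euclidean in array (row/column) coordinates by default.

## ESGs, projection, validation

High/low spot strata are the top and bottom QCS deciles (stable-order tie
break; overlapping strata are an error). Per-sample ESGs use one-sided
Wilcoxon rank-sum tests (distribution-robust for spot counts), BH q ≤ 0.05,
and a log2 fold-change floor of 0.25 computed on the non-negative
`lognorm` layer with a 1e-9 pseudocount; recurrence requires presence in
≥ 50 % of focal-group samples and a strictly larger focal fraction, which
makes the two groups' recurrent sets disjoint by construction. Cell-type
projection multiplies the reference mean expression by the niche-minus-
background mean (`lognorm` layer); the niche is the community-high spot
set. Validation fold changes are computed on the same layer (z-scaled
values can be negative and would break the ratio), compared across groups
by a one-sided paired t-test across genes. Region-level (GeoMx-style)
scores sum log-normalized expression over a gene set; overlap significance
is the upper-tail hypergeometric with the measured-gene universe by
default.

## Ligand–receptor network

LR pairs are enriched when ligand and receptor are both ESGs. "Expressed in
a cell type" defaults to the gene's projected niche expression exceeding
its median across cell types (a numeric threshold can be supplied). The
indicator runs over ordered type pairs; each retained pair contributes
exactly one unit of mass (Σ I/N = 1, asserted in tests), the ordered matrix
is reported alongside a symmetrized one, and pairs expressed nowhere are
dropped.

## Synthetic cohorts

The generator encodes the study conditions: 600 × 600 unit ROIs, log-normal
marker intensities around cluster archetypes (two signature markers per
cluster at +2 log-mean, σ = 0.5), uniform cell placement except planted
pairs, where a partner cell is re-seeded within about half the mean
nearest-neighbour spacing of a random counterpart cell with probability
equal to the adjacency strength — close enough to share a Delaunay edge.
ST counts are negative binomial (gamma–Poisson, dispersion 0.3) over a
log-normal per-gene mean grid (typical count ≈ 2); the compact group gets
a disc of radius 6 spots on a 40 × 40 lattice with the planted query and
signature genes multiplied by `exp(niche_effect)` (default 1.5), the
diffuse group the same elevation on an equal number of scattered spots.
Because both groups carry the same expression burden, the group contrast
lives in the *spatial arrangement* (QCS spot counts and δ), not in
per-sample ESG content — recurrence across groups is deliberately
uninformative in this design. Survival times are exponential with hazard
`h0 · HR^z` on the standardized score (baseline median 24 months), with
independent exponential censoring calibrated per subject to the requested
censoring fraction. One root seed is split hierarchically per patient, ROI,
and sample, so every artifact is a pure function of the configuration.

What passing these simulations does *not* show: robustness to segmentation
error, batch effects between cohorts, spatially varying cell density,
spot-level cell-type mixtures, or misspecified survival models — real
tissue violates all of these, and the synthetic cohorts make no attempt to
emulate them.

## Problem sizes and runtime

The test suite and the acceptance script run at desk scale: 50 ROIs of 500
cells with 1 000 permutations for proximity calibration; 10 patients per
group × 2 ROIs for mixed-model power (50 replicates) and 200 null pairs for
the type-I rate; three 40 × 40 / 500-gene samples at 1 000 permutations for
niche recovery; 100 replicates of n = 60 for survival power. The whole
acceptance run completes in about a minute on one CPU; these sizes are the
package's chosen defaults for demonstration and are all configurable.
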
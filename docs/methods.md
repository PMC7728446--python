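# Methods

This note documents the models and procedures `gastrukit` implements, the
parameters that matter, what the synthetic generators do and do not emulate,
and the numerical choices made where the design was genuinely open.

## Imaging statistics

**Radial profiles.** A colony image (one 2-D projected grid per channel) is
summarized per channel as mean intensity in `n_rings = 20` rings spanning
the colony center to its radius. Two sampling modes exist: `"annulus"`
(default) averages each equal-width annulus, which is robust to pixelation;
`"perimeter"` averages the one-pixel-wide circle at each ring radius,
mimicking concentric-circle plugin sampling. The two converge as rings
narrow and agree exactly on radially constant images. The colony center
defaults to the centroid of the Otsu-thresholded DAPI mask and is
overridable. Marker profiles are normalized ring-wise to DAPI so they read
as expression per cell rather than per pixel; the `epsilon` guard defaults
to 0 (a zero DAPI ring is an error) and can be set positive to keep empty
rings finite. Multi-colony averaging reports mean and SEM = sd/√n per ring;
n = 1 yields SEM 0 with a warning instead of NaN.

**Density maps.** Each annotated centroid deposits one unit of mass as an
isotropic Gaussian kernel (default `kernel_sigma_px = 8`, configurable —
the width of the ground-truth construction is not standardized). The kernel
is evaluated on a ±4σ window, truncated to the grid, and renormalized to
exactly unit in-grid mass, which makes the total-mass cell count
`C = Σᵢⱼ Yᵢⱼ` equal the centroid count to machine precision even for edge
and corner cells. Pixel coordinates are 0-based, `x` = column, `y` = row,
pixel centers at integers.

**Cosine overlap** is the plain normalized inner product of two same-shape
density maps. It is symmetric, invariant to positive rescaling of either
map, and undefined (an error) if either map is all zero.

**Centroid detection.** The deep-learning density estimator used for the
original imagery is out of scope (no trained weights, no annotated training
images); a light stand-in smooths the channel (σ = 1 px) and takes local
maxima above a threshold with a minimum separation. It feeds the same
density-map machinery as manual annotations, with `source="detection"`.

## Synthetic colonies

`ColonySpec` states the world: a 500 µm disc at 2 µm/px, four annular rings
(SOX2 0–0.40 R, T 0.40–0.62 R, SOX17 0.62–0.82 R, CDX2 0.82–1.00 R) and
200 cells per marker by default — on the order of the cell density such
colonies reach, and enough for stable ring statistics. Cells are placed
uniformly in area within their ring; the true within-ring radial law of
each cell type is unknown, so it is a parameter, not an assertion. Rendering
adds an amplitude-1 Gaussian bump (σ = 2.5 px, roughly a nuclear radius at
2 µm/px) per cell per carried marker, a bump in DAPI for every cell, and
clipped Gaussian background noise (sd 0.02, a ~2% noise floor). A
co-expression rule `(a, b) → p` converts a Binomial(min(nₐ, n_b), p) number
of cells into single centroids carrying both labels, placed in the
intersection of the two rings when nonempty; marker-wise counts then sum to
more than the centroid total, as co-expression implies. The generator does
not model optics (PSF, illumination fields, z-stacks), cell shape, or
intensity variation between cells, so green imaging tests establish the
statistics' correctness, not robustness to microscopy artifacts.

"Mixed" sorting layouts scatter two populations uniformly over the disc;
"sorted" layouts place them in disjoint circular patches (default) or
half-discs. Mixed layouts have near-proportional density maps (overlap
near 1), sorted patches nearly orthogonal ones (overlap near 0), bracketing
what reseeded cultures show between 2 h and 48 h.

## Synthetic count matrices

Per-gene base abundances are log-normal(0, 1). Cluster identity multiplies
that cluster's marker genes by `marker_fold_change` (default 8; recovery
suites use the stated stress values 20 and 50) and scales them by
`marker_background` elsewhere (0 silences them). Per cell, weights are
gamma-perturbed with coefficient of variation `dispersion = 0.3`, giving
negative-binomial-like overdispersion; mitochondrial genes (prefix `MT-`,
13 genes, the human mitochondrial protein-coding count) are rescaled to a
per-cell fraction drawn from `mito_fraction_range` (default 0.5–2%, the
healthy range the QC thresholds imply); the library size target is uniform
on `library_size_range` (default 2 000–8 000 UMIs, typical droplet-scale
depth). Counts are Poisson at the target, or exactly multinomial with
`exact_library=True` (then every column sums to its drawn size). A
`base_seed` decouples the gene-abundance draw from cell sampling so a query
and a reference can share biology — label-transfer tests depend on that.
Truth labels (cluster, optional stage) ride along in the cell metadata.
No doublets, ambient RNA, or batch chemistry effects are simulated.

## Single-cell core

QC keeps cells with `min < detected genes < max` and
`mito fraction < max`, all bounds exclusive — a cell at exactly 200 genes
or exactly the mitochondrial cutoff is removed. The study's gastruloid
thresholds ship as `GASTRULOID_QC` (replicate 1: 200/7 500/3%; replicate 2:
200/6 000/2.5%), and `qc_filter` accepts per-replicate threshold maps plus
returns a per-replicate report. Normalization is counts-per-10 000 then
log1p, the de facto standard where the upstream toolkit's default was
relied on.

HVG selection ranks genes by dispersion (variance/mean of de-logged
expression, log-scaled) z-scored within mean-expression bins. Bins are
equal-occupancy (rank-based) rather than equal-width: equal-width binning
puts extreme-mean genes in near-singleton bins where the z-score is
undefined or degenerate, and equal-occupancy bins remove that pathology
while preserving the ranking elsewhere (a scanpy cross-check test confirms
large agreement). Scaling regresses per-cell covariates (mitochondrial
fraction, total counts, cell-cycle scores computed as module scores on the
shipped editable S/G2M gene lists, replicate indicators) out of each gene
by OLS, standardizes residuals per gene, and clips at ±10. Replicates are
integrated by this joint processing on shared HVGs with replicate as a
covariate; anchor-based CCA integration is intentionally not reimplemented.

Clustering builds a shared-nearest-neighbor graph (neighborhood = self plus
k−1 = 19 nearest in the 15-PC space; Jaccard edge weights; pruned below
1/15) and runs igraph's multilevel Louvain at resolution 0.4, seeded;
clusters are renamed by decreasing size. Marker detection is one-vs-rest
two-sided Wilcoxon rank-sum on log-normalized values, Bonferroni-adjusted
over all genes, reporting the natural-log fold change of de-logged means
`ln((mean_in+1)/(mean_out+1))` and in/out detection fractions; rows need
logFC ≥ 0.25 and in-cluster detection ≥ 25%. Positive markers only by
default — every planted-marker check concerns enrichment.

## Label transfer and the randomization test

The transfer step deliberately replaces anchor-based integration internals
with what the computation is described as: shared genes (case-insensitive
symbol match, or a two-column orthology table for cross-species runs; <50
shared genes is an error) are ranked by the reference's HVG dispersion,
both datasets are standardized with the *reference's* per-gene moments, and
PCA fit on the reference projects both. Prediction scores are weighted
k-nearest-neighbor label fractions (k = 30 default; Gaussian weights with
per-cell bandwidth = distance to the k-th neighbor, or uniform); rows sum
to 1 by construction. The predicted label is the row argmax, lexicographic
on ties with a tie flag.

The randomization test resamples, for each cluster i of size nᵢ, B = 1000
sets of nᵢ cells with replacement from all query cells and recomputes the
predicted-label composition. `p_ij = (#{k : Perc_ijk ≥ Perc_ij} + 1)/(B+1)`
— comparison inclusive, pseudo-count 1, so p ∈ [1/(B+1), 1]; compositions
are fractions (units cancel). One seeded stream drives all draws,
cluster-by-cluster in sorted-name order, which fixes a drawing order no
description pins down and makes runs bit-reproducible. α = 0.05 is applied
directly with no multiple-testing correction (recorded in the output
manifest). The test is conservative under the null because compositions
are discrete and the comparison inclusive; calibration tests check the
type-I rate from above (≤ 0.07), not for equality with 0.05.

Cluster-correlation heatmaps are Spearman correlations of cluster-average
log expression on a shared-HVG list; constant average vectors yield NaN
with a warning rather than a fabricated value.

## Module scores, diffusion maps, pseudotime

**Module score** = mean log-normalized expression of the set minus the mean
of control genes drawn per set gene from the same mean-expression bin
(24 equal-occupancy bins, 100 controls per gene, seeded — the defaults
behind the toolkit's "default settings"). A forced-control override exists
for self-control validation. Scores are anchored at 0 for
expression-matched null sets.

**Diffusion map**: symmetric (union) kNN graph, knn = 40; Gaussian kernel
with global width σ = 8 on the stored parameter scale (the study fixed σ
slightly below the data-estimated optimum; the estimation rule is not
reimplemented — σ is an input); density normalization `K/(qᵢqⱼ)` removes
sampling-density bias; row normalization gives the transition matrix P.
Eigenpairs come from the symmetric conjugate `D^{1/2} P D^{-1/2}` via
`eigsh`, so the leading eigenvalue is 1 with a constant eigenvector and
`components` holds the nontrivial eigenvectors. Disconnected graphs warn
and are handled per-component by downstream consumers. Cluster transition
(A, B) is the mean over cells of A of their total outgoing probability
into B, rows renormalized.

**Pseudotime** is a probabilistic breadth-first flood of the kNN graph:
each of `n_sims = 100` simulations starts from a random 80% of the root
cells and, at every step, admits each unvisited neighbor of the visited set
with probability 0.8 (at least one per step, guaranteeing progress;
rejected candidates stay eligible). A cell's visit step is normalized by
the simulation's depth; its pseudotime is the mean over simulations,
rescaled to [0, 1]. Roots are pinned to 0 by definition — with root
subsampling a deselected root can otherwise be re-entered late and drift
off the origin. The published method's visit-frequency thresholds are not
restated anywhere; this normalization is a documented stand-in, validated
by rank-correlation against planted 1-D trajectories rather than by
equality with the original tool. Unreached cells are NaN and listed.
Root choice follows the study's logic (all cells of a named root cluster,
e.g. the epiblast-like one); the root rule itself is a parameter.

## Reproducibility and limits

Every stochastic operation takes an explicit seed and is bit-reproducible
for a fixed seed on a fixed platform. The synthetic world is deliberately
simple: well-separated log-normal/gamma-Poisson clusters, isotropic spots,
no batch effects. Green tests therefore establish formula fidelity,
contract correctness, and recovery of planted structure at stated effect
sizes — not performance on real microscopy or real droplet data, and not
numerical agreement with the specific external toolkits an individual lab
may have used.
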
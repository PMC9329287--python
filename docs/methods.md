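# Methods

## Parcellation and coordinate systems

The default region table combines the 68 Desikan–Killiany cortical parcels
with 14 subcortical structures (bilateral accumbens, amygdala, caudate,
hippocampus, pallidum, putamen, thalamus). Rows are ordered cortical-first,
left before right within each homologue pair, then subcortical; all matrices
and maps are indexed identically to these rows (0-based). Homologue pairing
is validated as a fixed-point-free involution.

The spin permutation test needs coordinates of every region on one merged
sphere. Real studies obtain these by merging cortical and subcortical
surface meshes, inflating, and projecting to a sphere; the packaged
coordinates are **synthetic**: cortical parcels are laid out
deterministically (Fibonacci spiral) on two mirror-symmetric hemispheric
caps, subcortical structures in a band near the inter-hemispheric rim.
Anatomical xyz places cortex on a 70 mm shell and subcortex on a 30 mm
shell. These coordinates have realistic spatial adjacency — which is all the
spatial null models consume — but are not mesh-derived; users with real
surface coordinates supply their own CSV, and distance matrices can likewise
be supplied directly.

## Preprocessing

Subjects missing ≥ 50 % of cortical or ≥ 50 % of subcortical measures are
excluded; remaining gaps are imputed with the per-region mean within the
same site and diagnostic group. Values are then residualized on [1, age,
sex] per site by ordinary least squares on the site's pooled sample
(patients and controls together), and the residuals are z-scored with the
mean/SD of the site's control residuals, so control columns have mean 0 and
SD 1 per site by construction. Sex coding is irrelevant to the residuals
(any affine coding gives the same projection); constant covariate columns
within a site are dropped rather than producing a singular design.

Right-focus patients are re-sorted by the homologue permutation so indices
mean ipsilateral/contralateral; controls are not flipped (left counts as
ipsilateral), keeping control matrices deterministic. Whether the original
consortium fitted covariates on controls only or on the pooled sample is not
something the pipeline can know; the pooled fit was chosen and is recorded
here, not asserted as the consortium's choice.

## Networks and thresholding

Pearson correlation matrices are built per group and site with ≥ 10 subjects
per group. Negative correlations are zeroed; at density K the
round-half-away-from-zero of K·n(n−1)/2 strongest positive weights are
retained (weighted, not binarized). Ties at equal weight break by (i, j)
lexicographic order, which makes retained edge sets nested along the density
grid — a property the test suite asserts. "Connected" in the density screen
means membership of the largest connected component (the stricter of the two
readings; under it path length is well defined on the kept node set). The
regional analyses run at the smallest density passing the screen; the
threshold-stability sweep recomputes the multivariate maps at every density
and reports their pairwise correlations.

## Graph metrics and null networks

Clustering uses the Onnela geometric-mean form on max-normalized weights:
C_i = (2/(k_i(k_i−1))) Σ_{j<h} (ŵ_ij ŵ_ih ŵ_jh)^{1/3}, with C_i = 0 for
degree < 2. Path length uses Dijkstra on lengths 1/w; each node's L_i
averages distances to the nodes it can reach (unreachable pairs are
excluded; fully isolated nodes are flagged NaN rather than given infinite
distance, keeping L finite at low densities). These are the standard choices
of the field's brain-connectivity toolboxes; both implementations are
checked against brute-force triple enumeration and Floyd–Warshall to 1e-10.

Null networks preserve the degree sequence exactly (Maslov–Sneppen double
edge swaps on the binary topology, 10 × edge-count attempted swaps) and the
weight multiset exactly (original weights re-assigned to rewired edges in
random order). Graphs with no swappable pair (e.g. complete graphs) fall
back to a weight-shuffled copy, logged. Normalized metrics divide the
empirical nodal values by the null-ensemble means; the small-world index is
σ = C_norm/L_norm, and n_nulls = 1000 by default (tests and desk-scale runs
reduce it; n_nulls = 0 returns raw metrics).

## Group statistics

Global metrics are compared with paired two-tailed t-tests across sites
(each site contributes a matched patient/control network pair), BH-FDR
across densities within metric (q = 0.1 as the flagging threshold, with
uncorrected 0.05 also flagged). All-zero site differences give t = 0, p = 1;
an exactly constant nonzero shift is flagged as a degenerate
exact-difference result instead of dividing by zero.

Regionally, Cohen's d (pooled n−1 SD) summarizes each metric across sites,
and a paired Hotelling T² per region combines the site-wise (Δclustering,
Δpath length) vectors: T² = n·d̄ᵀS⁻¹d̄, F = ((n−2)/(2(n−1)))·T² with
(2, n−2) d.f., BH-FDR across regions (q = 0.05). Site rows with missing
nodal values (isolated nodes at sparse densities) are dropped per region;
fewer than 4 usable sites flags the region NaN. Singular covariance falls
back to a 1e-10 ridge, logged.

The scalar exported for spatial correlation is T² signed by the projection
of the mean difference onto (1, 1) — positive for joint increases of
clustering and path length (regularization), negative for joint decreases
(randomization). The source analyses never state their scalarization; the
signed-T² choice is this package's, and a magnitude-only variant is
available via `signed=False`. Atrophy maps are two-sample Cohen's d +
t-tests on subject-level z-scores, BH-FDR across regions; lower
thickness/volume in patients gives negative d.

## Spatial null models

*Spin test.* Rotations are products of axis rotations applied in x, y, z
order with three independent uniform angles in [0, 2π); hemispheres rotate
jointly on the merged sphere. Each rotated region is assigned the nearest
original region by Euclidean distance (many-to-one allowed; the identity
rotation yields the identity mapping). One map — the topology map — is spun
while the other stays fixed; p_spin = (1 + #{r_null ≥ r_emp})/(1 + n_perm),
one-tailed positive, n_perm = 10,000 by default. A tolerance of 1e-12 on the
tail comparison absorbs ties that differ only by floating-point summation
order. Pearson correlation is the default (Spearman by flag).

*Variogram surrogates.* Distances are great-circle arcs on the sphere scaled
to a 100 mm radius for cortical–cortical pairs and 3-D Euclidean distances
for pairs involving subcortex (a user distance matrix can replace both).
Each surrogate permutes the map, smooths it with an exponential kernel over
each region's k nearest neighbours (k from a grid of 3–40), picks the k
whose affine-rescaled 25-bin variogram best matches the empirical one in
least squares, and applies the affine rescaling (√β on the smoothed
component, √α white noise). k_grid = (0,) degenerates to plain shuffling.
The bin count and kernel family are recorded choices; the acceptance suite
verifies that surrogate p-values agree with spin p-values (rank correlation
> 0.8) and that both are calibrated on independent smooth maps.

## Transcriptomics

The package consumes an already-built region × gene expression matrix
(pre-normalized; building one from donor microarray data is a separate,
external workflow). A gene set's map is the per-region mean over its
available columns; absent symbols are dropped and counted, with an error
only when nothing overlaps. Random-gene nulls draw equal-size sets without
replacement per draw from the full supplied universe. Cell-type specificity
compares a set's mean specificity per cell type against random equal-size
sets, two-tailed with add-one correction (the tail convention of the
original analyses is unstated; two-tailed is the conservative recorded
choice); empirical or null lists with exactly zero mean specificity are
discarded and counted. Set-difference tests report p against both
"A − random_{|B|}" and "random_{|A|} − B" nulls and their maximum as a
conservative combination — note that when only one set loads on a cell type,
the null in which the *other* set is randomized is centred on the observed
difference, so only the complementary null can flag it; both per-null
p-values are therefore always reported.

## Synthetic data generator

Subjects are drawn from multivariate normals with block correlation
structure: 8 modules (sizes 10×6 + 11×2 over 82 regions), within-module
r₀ = 0.4, between-module r₁ = 0.1. The focal-epilepsy (TLE-like) group adds
δ⁺ = 0.2 to the first module's correlations (regularization); the
generalized (IGE-like) group subtracts δ⁻ = 0.1 within all modules
(randomization). Matrices are projected to the nearest PSD correlation
matrix when needed (eigenvalue clipping, logged). Site effects are additive
offsets (SD 0.3 region-SD units) and lognormal scales (σ = 0.05); age
slopes default to −0.01 region-SD/year over ages 18–50, sex effects to 0.1
region-SD; ~1 % of entries are masked missing. Cortical regions use
mean 2.5 mm / SD 0.15 mm, subcortical 4000 mm³ / 400 mm³. The default
layout — 14 sites with patients and controls, the first 10 also carrying a
generalized-epilepsy group, 40 subjects per group per site — reproduces the
48-matrix bookkeeping of the multisite design at desk scale.

Expression maps are Gaussian-process draws with a squared-exponential kernel
over great-circle distances (length scale 30 mm on the 100 mm sphere);
planted genes are ρ*·standardized(target) + √(1−ρ*²)·GP noise, all columns
min-max scaled to [0, 1]. The cell-type matrix draws nonnegative gamma
scores with planted sets boosted on designated types.

What the generator does *not* emulate: scanner-specific covariance
distortions (site effects act on mean and scale only), non-Gaussian
morphometry distributions, spatially structured missingness, and any
relationship between the expression maps and the cohort covariance beyond
the explicitly planted set. Passing tests therefore demonstrate the
machinery's correctness and calibration, not clinical effect sizes.

## Problem sizes and numerical choices in the test and acceptance runs

The acceptance suite runs the graph-metric oracles on 100 random graphs of
≤ 8 nodes; null conservation on 200 rewirings of a real thresholded
synthetic network; spin calibration on 200 independent smooth map pairs at
500 permutations; variogram agreement on 50 pairs at 500 surrogates;
random-gene calibration on 200 sets of 20 genes from a 300-gene universe;
planted-module recovery on 50 cohort replicates; and transcriptomic
recovery on 50 replicates with 20 planted genes in a 500-gene universe.
The 50-replicate topology suite uses raw (un-normalized) nodal metrics for
the site-wise differences: the null-ensemble mean divides patient and
control values by nearly the same factor, so paired differences are
essentially invariant to normalization, and the raw variant keeps the
replicate suite fast; single-run tests and the pipeline default exercise the
normalized path. The acceptance script's pipeline run uses 50 nulls per
network and 1000 permutations.

## Known limitations

* Planted-module regional recovery is partial at the default study
  conditions: with 40 subjects per group, per-site sample correlations carry
  SD ≈ 0.13, so the Hotelling test recovers roughly half of the planted
  regions after FDR correction (the acceptance script reports the measured
  rate); the false-positive rate elsewhere stays at the nominal level and
  the clustering effect-size map concentrates cleanly in the planted module.
* The packaged sphere coordinates are synthetic; absolute geodesic distances
  are not anatomical, only their adjacency structure is.
* Harmonization beyond per-site control-referenced z-scoring (e.g.
  covariance-level batch correction) is out of scope; a hook exists where an
  external harmonizer can be applied before network construction.
* Global density-sweep metrics default to raw values (normalization at every
  density multiplies runtime by the null count; enable
  `normalize_global_sweep` when needed).
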
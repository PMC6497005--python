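# Methods

## Graph construction

A subject's connectivity matrix is the Pearson correlation of node time
series over volumes. Node pairs closer than 20 mm (strict `<`; Euclidean
distance between node centres) are inadmissible, guarding against
motion-driven short-range inflation. The remaining pairs are proportionally
thresholded at densities 0.10, 0.15, 0.20, 0.25, 0.30 and binarized.

Conventions that the usual verbal description of proportional
thresholding leaves open, fixed here for bit-reproducibility:

* **Density denominator** — the admissible-pair count after distance
  exclusion (a "top X% of strongest edges" reading over candidate edges);
  the edge count is `round-half-away-from-zero(density × n_admissible)`.
* **Tie-break** — rank ties at the cutoff correlation resolve by
  (smaller node id, larger node id).
* **Negative edges** — removed *after* rank selection, preserving "top k
  strongest" semantics; a graph can therefore hold fewer edges than nominal
  when positive correlations are scarce.

## Community detection and modularity

`louvain_partition` wraps the Louvain heuristic (networkx implementation;
resolution fixed at 1) in `n_restarts` seeded restarts (default 20) and
returns the partition with the highest Q as evaluated by our own
modularity decomposition (`Q = Σ_s [l_in_s/L − (k_s/2L)²]`). Exact Q ties
prefer fewer modules, then the lexicographically smallest canonical
labelling. Labels are canonicalized 1..m by descending module size, then
smallest contained node id. Modules are detected independently per
density; only scalar metrics and nodal maps are averaged across densities,
so no partition matching is needed. Variability in module size uses the
sample SD (n−1); `ddof=0` is available. An edgeless graph is an error
state (Q undefined), not a degenerate partition.

## Nodal cartography

Participation uses the per-module edge counts k_i(m); a degree-0 node gets
p_i = 0 (the formula is 0/0 there). Within-module degree standardizes with
the population SD (the original cartography convention; configurable); a
module whose members all share one within-degree gives z_i = 0 for all.
Note that the common verbal gloss "p_i is 1 when equally connected to all
modules" overstates the formula: p_i approaches 1 − 1/M in that case, and
the implementation follows the formula.

The seven role classes use z ≥ 1 for hubs and left-closed participation
intervals (≤ 0.05 / ≤ 0.62 / ≤ 0.80 for non-hubs; ≤ 0.30 / ≤ 0.75 for
hubs), which tile the (p, z) plane exactly. Roles are assigned per density
and the seven proportions averaged; the subject-level regression inputs are
the across-density mean p and z maps.

## Association statistics

Partial correlation residualizes both variables on [intercept, covariates]
(sex coded 0/1, 3-level handedness as two dummies) and tests the residual
Pearson r against t with n − k − 2 df. Outlier screening (per analysis
variable, > 3 SD from the mean, computed once, strict `>`) precedes each
global association. Bonferroni thresholds are α divided by the family size
(4 global measures → .013; 7 node-type proportions → .007).

BF01 uses the Zellner–Siow / JZS setup: the null model holds the
covariates, the alternative adds the predictor with a Cauchy(0, √2/2)
prior on its standardized slope. Covariates are handled by residualizing
both variables and reducing the effective sample size to n − k; the
resulting one-predictor integral over the g-prior is evaluated by adaptive
quadrature in log space. BF01 > 3 is reported as substantial null
evidence.

Node-wise regression computes, per node, the t statistic of the score
slope given covariates (via partial correlations, vectorized). Cluster
correction thresholds |t| at the two-sided voxel p (default 0.005; so the
expected suprathreshold fraction under the null is the voxel p itself),
groups suprathreshold nodes per sign into connected components on the node
lattice (faces-only neighborhood by default, 26-neighborhood available),
and keeps components with k > k_min.

`k_min` is calibrated by Monte Carlo as the smallest integer whose null
exceedance probability P(max cluster > k) is ≤ α. (A "quantile + 1" rule
combined with the strict `k > k_min` test double-counts the exceedance
step and is needlessly conservative on discrete size distributions; with
our rule, α = 1 yields k_min = 0, i.e. every nonempty cluster passes.)
Two null models are provided: permutation of the subject score vector
against the observed maps (distribution-free default), and smoothed
Gaussian random fields on the lattice with configurable FWHM (the
AFNI-style smoothness-matched null). On weakly smooth maps the max-cluster
distribution is coarse and the achieved FWE sits below α (conservative);
the Gaussian-field mode with FWHM ≈ 3 grid steps resolves the 5 % quantile
well and its closed-loop FWE lands near α.

## Post hoc procedures

Extreme groups take the n highest and n lowest scorers (default 20/20,
ties broken by subject id) and compare a measure by Welch t test or
one-tailed Mann-Whitney U (direction configurable; default: high-score
group higher). Network-block connectivity averages admissible-pair
correlations within/between the canonical seven networks; the assignment
table is an input (a synthetic contiguous seven-way split ships for
testing — it is a stand-in fixture, not a real parcellation). The
distance diagnostic correlates each edge's across-subject FC–mean-FD
correlation with edge length; residual motion artifact shows as a negative
relationship. Cluster rank positions use the mean-rank (midpoint)
percentile of the cluster-average value in the whole-brain distribution,
banded at 20 %/80 %.

## Synthetic cohorts

The generator emulates exactly the statistical features downstream stages
consume:

* **Time series** — zero-mean multivariate normal with a block-constant
  correlation matrix: `within_corr` inside planted modules, `between_corr`
  elsewhere. This directly controls the modular signal that Q, p and z
  measure; it deliberately omits hemodynamics, temporal autocorrelation,
  spatial smoothness of the BOLD signal, and scanner artifacts. Default
  study conditions for pipeline-level checks: 200 subjects, 200 nodes,
  150 volumes, four 50-node modules, within 0.4 / between 0.05.
* **Node geometry** — a 3-D lattice with 12-mm spacing, indexed in z-slab
  raster order so module index blocks are spatially compact; the < 20-mm
  rule then prunes nearest-neighbour (12 mm) and face-diagonal (~17 mm)
  pairs, as it does short edges in real data.
* **Motion** — per-frame FD magnitudes drawn from a gamma distribution
  with mean fd_mean·n/(n−1) and SD fd_sd, split across the six rigid-body
  parameters by Dirichlet weights with random signs and accumulated.
  Rotations are *already expressed in mm* (arc length on a 50-mm sphere);
  the FD sum applies no unit conversion, so callers supplying raw
  degrees/radians must convert first.
* **Phenotypes** — the symptom index keeps a right-skewed gamma marginal
  matched to the adult ADHD raw-score range (mean 8.36, SD 5.13, range
  0–28) via a Gaussian copula. A planted brain–behavior effect raises the
  effect nodes' between-module correlation by a per-subject latent trait;
  the index's latent normal then loads on the *measured* mean
  participation of the effect nodes (single mid density, 3 restarts) with
  a loading corrected for the copula's Pearson attenuation, so the planted
  partial correlation (given age, sex, handedness, FSIQ, mean FD) equals
  `effect_size` for the quantity the pipeline estimates. Covariates: age
  uniform 18–60, FSIQ N(100, 12.5), handedness 80/10/10.

Passing tests on these cohorts show that the estimators and their
calibration behave correctly when their assumptions hold; they do not
validate preprocessing choices on real BOLD data, nor the distributional
claims of any empirical sample.

**Seed splitting** — one global seed expands as
`SeedSequence(seed, spawn_key=(stream, subject))` with stream codes
0 = time series, 1 = motion, 2 = phenotypes, 3 = latent trait, making
cohorts reproducible under subject-level parallelism.

## Problem sizes and defaults

Pipeline-scale checks run the 200-subject cohort with 3 Louvain restarts
per density and calibrate k_min with 1000 permutation iterations; the
Gaussian-field calibration uses 4000 + 2000 iterations on a 14³ lattice.
The toy and oracle checks use graphs of ≤ 30 nodes, with exhaustive
partition enumeration on 6–9 nodes. The CLI defaults are the analysis
choices described above: densities 0.10–0.30, 20-mm exclusion, 0.2-mm FD
rule, voxel p 0.005, α 0.05, Bonferroni per measure family, k_min "auto".

## Known limitations

* Louvain is a heuristic; on large graphs the restart maximum is not the
  global optimum (exactness is only verified on enumerable graphs).
* The block-correlation generator has no spatial autocorrelation, so
  permutation-calibrated extent thresholds on synthetic maps are small and
  conservative relative to smoothed real data.
* The JZS covariate reduction (residualize + effective n) is the standard
  approximation, exact only as the covariate fit error vanishes.
* Clipping the symptom index into [0, 28] truncates extreme copula tails;
  at the default location/scale this affects a negligible mass but would
  bias planted correlations for means near the scale limits.
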
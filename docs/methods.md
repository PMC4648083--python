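# Methods

This package re-implements a genomic-prediction benchmarking pipeline for a
structured panel of inbred pea lines: genotype quality control and
imputation, linkage-disequilibrium (LD) decay analysis, five marker-based
prediction models, bin-based marker thinning, nested training-size
cross-validation, CDmean training-set optimization, and panel-to-RIL
cross-population prediction. Because the original array and phenotype data
are not distributed, a synthetic-data module generates panels with the same
statistical structure, and every stage is exercised and tested on those.

## Synthetic data

### Genetic map

`simdata.simulate_map` draws marker positions on 7 linkage groups totalling
~795 cM (Haldane scale), allocating markers proportionally to linkage-group
length. With `n_bins` set, markers are stacked on that many unique
positions, reproducing the *bin* structure of a consensus map where several
markers share an identical genetic position. Fixed position grids are
available for degenerate test cases.

### Panel

`simdata.simulate_panel` uses a founder-mosaic model rather than a
coalescent simulation, for speed and direct control of the LD scale. Its
components:

- **Shared ancestral templates.** A small pool of template haplotypes
  (default 3) is drawn once, with template columns ascertained polymorphic
  — the analogue of a SNP array retaining only polymorphic assays. Each
  subpopulation (default 4) receives diverged copies (allele flip
  probability `divergence/2 = 0.05`), creating Balding–Nichols-like
  frequency divergence while keeping allele phase consistent panel-wide.
  Phase consistency matters: if each subpopulation had an independent
  founder pool, within-subpopulation LD would cancel when pooled and
  panel-wide LD would collapse to noise.
- **Mosaics.** Each base accession is a mosaic of its subpopulation's
  founders with exponential segment lengths (default mean 2.5 cM); the
  haplotype is doubled to homozygosity, so codes are {0, 2} — fully inbred
  lines, consistent with a ≤0.05 heterozygosity filter.
- **Relatedness clusters.** 60% of accessions are *derived* lines: a copy
  of an earlier accession with 35% of segments re-drawn. This produces the
  kinship topology genebank panels show — clusters of closely related
  accessions and essentially no isolated individuals. The CDmean
  training-set effect (below) depends on this topology: with fully
  exchangeable accessions, optimizing training-set composition has nothing
  to exploit.
- **Redundant bins.** Template columns are drawn per bin and co-located
  markers are near-duplicates of the bin column (flip rate 0.02), so one
  marker per bin carries almost all of the bin's information — the premise
  of the thinning series.

Defaults were calibrated once so that the fitted LD-decay curve crosses
r² = 0.2 near 0.5 cM (observed ~0.48 cM across seeds) on a
339-accession panel, the regime the downstream analyses assume. The
generator does **not** emulate: sequence-level variation, mutation,
selection, real pea allele-frequency spectra, genotyping error beyond
missingness, or linkage-map error. Tests passing on these panels show the
pipeline's statistical machinery behaves as designed under the stated
structure; they do not certify accuracy levels on real pea data.

### Traits

`simdata.simulate_trait` places QTL on mapped markers with normal (or
signed-gamma) effects. Phenotype of line *i*, year *y*, block *b* is
`year mean + Σ_q codes[i,q]·effect[q,y] + block_b + residual`. The residual
variance is set per year so that broad-sense heritability on an
adjusted-mean basis, `Vg / (Vg + Ve/B)` with `B` blocks (default 2) and
`Vg` the realized genetic variance, equals the target (defaults emulate
0.98 / 0.71 / 0.99 traits). Genotype-by-year interaction is a one-knob
model: year-specific effect vectors are the base effects plus noise of sd
`gxy_sd_fraction × sd(effects)`. A `TruthRecord` carries QTL identities,
per-year effects, true genetic values, and realized heritabilities for
parameter-recovery tests.

### RIL populations

`simdata.simulate_ril_populations` crosses two panel parents, builds the F1
as a heterozygote at parent-polymorphic markers, and selfs by single-seed
descent (default 6 generations) with meiotic recombination between adjacent
markers following the Haldane map function
`r = (1 − exp(−2d/100))/2`. Residual heterozygosity per initially
heterozygous marker is ≈ 0.5^g, verified against the binomial expectation.

## Genotype QC and imputation

Filters remove markers with missing rate ≥ 0.1 and individuals with
heterozygosity ≥ 0.05 (removal at-threshold inclusive, as the thresholds
are written); a minimum-MAF filter is opt-in, since low-MAF markers were
kept in the original analysis. Passes alternate between marker and
individual removal to a fixed point because removing individuals changes
marker missing rates; this makes the filter idempotent.

Missing calls are imputed by k-nearest neighbours over individuals
(default k = 5): distance is the mean squared code difference over shared
non-missing markers; a missing cell gets the 1/(d+1e-6)-weighted mean of
the codes of the k nearest individuals with a call at that marker, rounded
to the nearest valid code, with distance ties broken by individual order.
Neighbours are individuals, not markers, because line-level relatedness in
an inbred panel is the dominant signal. Observed cells are never altered.

## Relationship matrix, LD, thinning

The genomic relationship matrix is VanRaden's first method with sample
allele frequencies: `G = W W' / (2 Σ p_j(1−p_j))`, W the 2p-centered
codes, monomorphic markers excluded; a 1e-6 ridge is added only when the
smallest eigenvalue is ≤ 0. On a fully inbred panel the mean diagonal of
this G is ≈ 2, which matters for variance-component interpretation (below).

LD r² is the squared Pearson correlation of genotype codes for
within-linkage-group pairs. Decay is fitted by unweighted least squares of
the sample-size-aware expectation of r² at recombination-scaled distance
C = ρ·d:

    E[r²](C) = (10+C)/((2+C)(11+C)) · [1 + ((3+C)(12+12C+C²))/(n(2+C)(11+C))]

over observed (d, r²) pairs, with n = number of lines by default (whether n
should count lines or chromosomes is exposed as a parameter). The crossing
distance d₀.₂ is found by bisection, reported as ∞ if the curve never
reaches 0.2 (the large-C asymptote is 1/n, so this only happens for n ≤ 5).

Bin thinning keeps the highest-MAF marker per bin (ties to the smaller
marker id); stride k keeps the representative of the first bin of every k
consecutive bins in one genome-wide list, i.e. ceil(B/k) markers for B
bins. This grouping rule is the one that reproduces all seven published
subset sizes (1473, 982, 737, 589, 491, 421, 369) from 2945 bins.
Per-linkage-group grouping is available behind a flag.

## Prediction models

All five models are scikit-learn-style estimators exposing a marker-effect
vector, so any genotyped individual's GEBV is
`intercept + centered codes · effects`.

- **GBLUP.** Mixed model y = 1μ + u + e, u ~ N(0, G σ²_u). REML profiles
  the restricted likelihood over log λ (λ = σ²_e/σ²_u) on the
  eigendecomposition of G; GEBVs via `G (G+λI)⁻¹ (y−μ̂)` with a GLS
  intercept, and the ridge-equivalent marker-effect form
  `β = W'(G+λI)⁻¹(y−μ̂)/(2Σpq)` is exposed (identical predictions, tested
  to 1e-8). Reported genomic heritability is
  `ḡ/(ḡ+λ)` with ḡ the mean diagonal of G: on an inbred panel ḡ ≈ 2, and
  ignoring it understates trait heritability by ~0.1–0.15.
- **BayesA / BayesB.** Single-site Gibbs sampler with per-marker variances
  σ²_j ~ scaled-inv-χ²(ν = 4.2, S); BayesB adds a point mass π (0.95 in
  the benchmarked configuration) via a marginal-likelihood indicator draw
  with β_j integrated out. S defaults so the prior mean total marker
  variance is ½·var(y)/Σ2p_jq_j, spread over the non-zero fraction.
  Chain defaults 10000 iterations, 2000 burn-in, thinning 5; effects are
  posterior means. The sampler core is numba-compiled; chains are
  reproducible from the seed.
- **LASSO.** Objective (1/2n)‖y−μ−Wβ‖² + t‖β‖₁, solved by cyclic
  coordinate descent with active-set sweeps and warm starts along a
  100-point log grid from t_max (smallest all-zero penalty) down to
  1e-3·t_max; convergence when the largest coefficient change in a full
  sweep is < 1e-7. t is tuned by 10-fold CV minimizing MSEP; exact ties go
  to the larger penalty. Solutions satisfy the KKT subgradient conditions
  to 1e-6 and match an independent solver to ~1e-6.
- **kPLSR.** Univariate partial least squares computed by the kernel
  algorithm: the score recursion and deflation run on K = WW' (n×n), with
  the weight and loading vectors reconstructed through n-space surrogates,
  so the marker-effect vector is exact. Verified equivalent to explicit
  NIPALS deflation and to an independent PLS implementation to 1e-8. The
  component count is tuned by 10-fold CV over 1..30; ties to fewer
  components. "Kernel" means the computational algorithm, not a nonlinear
  kernel; a Gaussian-kernel variant is out of scope.
- **Tuning.** `tune_by_cv` assigns folds by shuffled position modulo
  `folds` (deterministic given the seed); candidates are scored by mean
  held-out MSEP and grids are ordered simplest-first so exact ties resolve
  to the simpler model.

Marker codes are centered but not standardized before LASSO/PLSR
(standardization is behind a flag); no fixed-effect covariates or
population-structure correction are applied anywhere, matching the
benchmarked design.

## CDmean training-set optimization

For training incidence Z, variance ratio λ = σ²_e/σ²_g, and contrast c,

    CD(c) = c'(G − λ(Z'MZ + λG⁻¹)⁻¹)c / (c'Gc),

M the intercept-absorbing projector on the training dimension. CDmean
averages CD over contrasts `c_i = e_i − 1/N` between each target accession
and the panel mean. Targets: with a held-out test set and a saturating
training size, all non-training accessions (= the test set); at smaller
sizes, accessions in neither the training nor the test set; in
cross-population mode, all non-training accessions (the external test
population enters no contrast).

The optimizer starts from a random set and proposes uniform single swaps,
accepting strict improvements. Proposal evaluation uses a rank-4 Woodbury
update of the inner inverse off an exactly-recomputed base (so there is no
drift; the fast path matches the naive re-solve to 1e-9). When a greedy
run stalls (max(40, 2·size) consecutive rejections) the search restarts
from a fresh random set and the best set over all iterations is returned —
pure single-start greedy sticks in local optima ~8–11% below the
exhaustive optimum on small instances, and the running best remains
non-decreasing either way. λ values 0.01 and 0.4 are both exercised;
selected sets overlap heavily, and no ordering between them is asserted.

A note on what the CDmean effect requires: optimizing the composition of
the training set improves test accuracy only when relatedness is
heterogeneous — the criterion works by covering the kinship network and
avoiding redundant close relatives. On panels of exchangeable unrelated
lines the criterion surface is nearly flat and the smaller-size target
rule (contrasts for accessions in *neither* set) can even transfer
negatively. The synthetic panel therefore includes pervasive relatedness
clusters, as the benchmarked panel's kinship network shows.

## Evaluation

Replicated-block phenotypes are reduced to genotype least-squares means by
an additive two-way (genotype + block) fit; balanced designs reduce to raw
means, single-block trials pass through with a warning.

Per repetition: a 99-line test set is drawn; training sets of decreasing
size are nested subsets of one permutation of the remainder (nesting
reduces between-size sampling noise; a non-nested mode is behind a flag);
every method and every marker density within a repetition sees the
identical split, verified by split hashes. Metrics: accuracy = Pearson r
between GEBVs and observed test phenotypes (within-year and cross-year),
R² = squared correlation of fitted vs observed training values,
Q² = 1 − PRESS/TSS with the training-mean reference (test-set-mean variant
behind a flag), MSEP = mean squared prediction error. Q² is reported
unclamped and can be negative. Undefined correlations (zero variance) are
reported as missing with a flag, never silently.

The cross-population experiment first restricts markers to those
polymorphic in at least one RIL family, trains on panel phenotypes of one
year, scores on RIL phenotypes of another, and selects training subsets by
the cross-population CDmean variant; the full-panel condition is one
deterministic run per method, subset sizes are re-optimized per
repetition.

## Problem sizes and numerical choices

Benchmarks in the test suite and the acceptance script run at desk scale —
panels of 150–339 accessions, 300–2000 markers (600–2945 bins), 5–10
repetitions, Gibbs chains of 3000–4000 iterations — chosen so the full
battery completes on one CPU while every qualitative contrast (training
size, density, composition, cross-population transfer) remains
reproducible; the experiment functions accept the full-scale settings
(9824 markers, 200 repetitions, 10000-iteration chains) unchanged.
Degenerate inputs (constant responses, monomorphic matrices, saturated
training pools, zero-variance contrasts) return exact limits or explicit
errors rather than NaNs. All randomness flows from explicit integer seeds;
reruns are byte-identical.

## Known limitations

- The founder-mosaic panel has a handful of ancestral haplotypes; rare
  alleles and deep coalescent structure are absent, so absolute accuracy
  levels are optimistic relative to a real genebank panel.
- The Bayes samplers use one chain; convergence is checked only through
  seed-to-seed agreement of GEBVs and posterior-mean calibration on
  simulations.
- REML heritability recovery is unbiased under a dense polygenic
  architecture; with few QTL the genomic heritability estimates a
  marker-covariance quantity that can sit below the trait value.
- Cross-population accuracy on synthetic RILs is sensitive to how the RIL
  trait is constructed; the pipeline reports whatever the metrics yield,
  including negative Q².
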
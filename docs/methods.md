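# Methods

## Overview

`binless` normalizes chromosome-conformation-capture (Hi-C) data without
committing to a matrix resolution.  Paired-end reads are classified at
base-pair resolution around restriction cut sites; counts at cut-site
intersections are modeled with a negative-binomial (NB) regression whose
mean combines smooth genomic biases, a monotone distance decay and a
sparse signal term; the signal (and differences between datasets) is
estimated with a weighted generalized fused lasso on the triangle grid of
matrix bins, so that significant structure comes out as constant patches
with exact zeros elsewhere.  Output matrices at any resolution are
assembled from one normalization.

## Read classification

Coordinates are 1-based inclusive.  `start` is the 5' position of a
mapped end; a `+` end covers `[start, start+length−1]`, a `−` end covers
`[start−length+1, start]`, and each end points along its strand.  A `+`
end is assigned to the closest cut site at or downstream of its 5'
start, a `−` end to the closest at or upstream.  The categories, decided
in this order within each strand configuration:

* converging (`+/−`) pairs: **dangling_L/R** when the 5' start of end
  1/2 sits exactly on a cut site (± `tol_dangling`, default 0 bp) —
  digested but un-religated molecules; **rejoined** when the molecule
  span contains exactly one cut site; **random** (genomic DNA) when it
  contains none; **far contacts** when it contains two or more (the two
  assigned sites are then distinct);
* diverging (`−/+`) pairs point to two sites `i < j`: **self-circle**
  when the sites are neighbors (the ligated ends of a single fragment;
  between neighboring cut sites self-circles replace the close-contact
  quadrant), otherwise a **close contact**;
* `+/+` and `−/−` pairs are **up** and **down contacts** when the
  assigned sites satisfy `i < j`.

A read whose pointed-to site lies farther than `max_cutsite_distance`
(default 1000 bp, on the order of sonication fragment size) is **other**,
as is any geometry not matching a category.  Duplicates are removed on
both ends' (start, length, strand).  Contacts closer than 1 kb cannot be
separated from religation byproducts and are filtered out.

## The count model

With `d_i` the dangling/rejoined count at cut site `i` and `c_ij` the
contact count of a quadrant at intersection `(i, j)`:

    d_i  ~ NB(mu_i, alpha)        c_ij ~ NB(mu_ij, alpha)

with the Var = mu + alpha·mu² parametrization, and log-linear means

    log mu_ij = e_C + bias_q(i, j) + f(d_ij) + s_ij
    log mu_i(dangling_L) = e_L − iota_i
    log mu_i(dangling_R) = e_R − rho_i
    log mu_i(rejoined)   = e_J + (iota_i + rho_i)/2

`iota`/`rho` are the left/right genomic efficiencies of each cut site
(p-splines over genomic coordinate), and the quadrant picks the side of
each anchor the reads map on: up → `iota_i + iota_j`, down → `rho_i +
rho_j`, close → `rho_i + iota_j`, far → `iota_i + rho_j`.  Dangling ends
run against the local efficiency (a poorly ligating site accumulates
dangling ends); rejoined ends carry the geometric-average bias with a
positive sign, since they track local coverage.  `f` is the decay,
constrained to be non-increasing in distance; `s` is the sparse log
signal per base-resolution bin.  One exposure per count class sets the
level.  The close-contact quadrant of neighboring cut sites is excluded
from the likelihood (it is occupied by self-circles).

## Smoothing

Biases use uniform cubic B-splines (knots extended beyond the domain,
the Eilers–Marx construction) with a second-order difference penalty, so
the penalty null space is exactly the straight lines.  The default basis
density is 50 functions per Mb with a floor of 20 per locus; it bounds
the wiggliness of the biases and keeps the penalized systems small.  The
stiffness is selected by restricted maximum likelihood (REML) on the
Gaussian working model — noise-only data collapse to the ~2 null-space
degrees of freedom, smooth structure is followed — optimized on log λ by
bounded scalar search.  The decay is a B-spline in log10 distance
(default 12 basis functions, distances clamped below at 1 kb) made
non-increasing by requiring non-increasing coefficients, which turns the
penalized fit into a bound-constrained least squares; monotonicity of
the coefficients is sufficient for monotonicity of the curve, holds
everywhere (not only on a test grid), and cannot be infeasible.

## Optimized normalization

All parameters are estimated by coordinate descent on IRLS working data
(z = log μ + (y−μ)/μ, w = μ/(1+αμ)).  Zero-count cells are never
materialized per observation: per-pair count arrays cover every cut-site
intersection of the locus, and each refit consumes grouped
(Σ weight, weighted-mean working response) statistics per cut site,
log-distance band (100 bands) or signal bin.  One outer iteration
updates: dispersion (median of per-row MLEs over up to 100 evenly spaced
cut-site rows, each row holding all its contact cells including zeros
plus its dangling/rejoined counts; the 1-D MLE is a bounded search on
log α in [1e−4, 10]); exposures (exact intercept updates); the joint
(iota, rho) spline system with REML stiffness; and the monotone decay.
Phase 1 runs with the signal pinned at zero (max 50 iterations); phase 2
adds fused-lasso signal updates at a fixed fusion penalty λ2 = 2.5 (max
20 iterations — the background is already converged and only refines)
with the REML stiffnesses frozen.  Bias updates are damped by 0.5;
biases are centered to mean zero (the level lives in the exposures);
convergence is a relative L2 change of (iota, rho, decay curve, log α,
signal) below 1e−3.  The decay is warm-started from band-wise raw log
mean counts before the first iteration, because the IRLS linearization
is only trustworthy near the truth and the decay spans orders of
magnitude.  Signal and decay levels are degenerate with the exposure;
after each update the weighted mean is moved into the exposure
explicitly, which removes a slow level drift between the three.

The default base resolution is 5 kb (4-cutter-type libraries); each
contact cell maps to the bin of its cut-site coordinates.

## Signal estimation

After convergence, per-bin working residuals relative to the signal-free
background are pooled into (weighted mean, Σ weight) per triangle-grid
node.  The fused lasso

    min ½ Σ_b w_b (y_b − s_b)² + λ2 Σ_(b,b') |s_b − s_b'|

is solved by ADMM with the edge differences split into an auxiliary
variable (one sparse factorization reused across iterations; warm starts
across the λ2 grid and across outer iterations).  Patch membership is
read off the auxiliary variable, whose soft-threshold produces exact
zeros, and node values are snapped to their patch's weighted mean, so
patches are exactly constant.  λ2 is selected on a 15-point log grid in
[0.1, 30] by BIC = wRSS + df·log n with df = number of patches; the
weighted RSS is the working-model −2 log-likelihood directly because the
IRLS weights carry the (known) noise scale — profiling a free variance
would always favor the near-interpolating smallest λ2.  The threshold λ1
is the largest |patch value| among patches that fail a
Benjamini–Hochberg-corrected two-sided z-test (z = |value|·√(Σw/φ),
with φ a Pearson-type variance-inflation factor floored at 1), so that
after one-sided soft-thresholding — max(s − λ1, 0) for signal; two-sided
for differences — every surviving region is inconsistent with working
noise alone.  Surviving values are minimum fold changes on the log
scale; `exp(s)` is the signal matrix, `exp(s + f)` the "binless" matrix.

## Differences

For differences the model structure is "every dataset has the same mean
as the reference up to an additive per-bin term".  Each dataset's counts
are re-residualized on the *reference* background (its biases and
decay), with a free per-bin enrichment fitted by exact per-bin intercept
updates and the dataset's own exposure.  Using one common background
keeps background-fitting artifacts out of the difference: with
independently fitted backgrounds, a strong signal in one dataset warps
its own background and leaks structured phantom differences everywhere.
The fused lasso then runs on t_k − t_ref with harmonic-mean weights,
λ2 by BIC, and a two-sided λ1 threshold.  The reference's difference is
identically zero; for a pair of datasets the construction is
antisymmetric up to the (re-estimated) backgrounds, and detected regions
flip sign when the reference is swapped.

## Fast mode

Whole chromosomes are binned at the base resolution (optionally with a
distance cutoff; storage is linear in bins × cutoff-bins).  The reduced
model has one bias per bin, a decay per distance band (weighted isotonic
regression, non-increasing), and the fused signal; α, λ1 and λ2 must be
supplied.  Phase 1 iterates exposure, decay and damped per-bin bias
updates to convergence with the signal at zero; phase 2 adds warm-started
fused-lasso updates and applies λ1 at the end.  Note the per-bin bias of
fast mode legitimately includes the log cut-site density of the bin —
at bin level, fragment density is part of the genomic bias.

Parameters are proposed from data: disjoint candidate loci tiling the
chromosome are ranked by the standard deviation of their directionality
index (DI; window default 400 kb — the classical 2 Mb window is wider
than desk-scale test chromosomes), with DI = sign(B−A)·((A−E)²+(B−E)²)/E
for upstream/downstream window sums A, B and E = (A+B)/2.  The top
`n_loci` are normalized with the optimized model; the proposal is the
median of per-locus values, with one correction: a binned cell pools m
cut-site-quadrant cells, and NB(μ, α) per cell implies
Var ≈ M + (α/m)·M² for the pooled count, so each locus's α̂ is divided
by its cells-per-bin ratio before the median.  Without this the binned
weights understate the information ~m-fold and the matched-λ2 signal
collapses to zero.  For difference-parameter estimation, loci are ranked
by the summed |δ| of a fast difference at λ2 = 2.5.

## Synthetic data

The generator draws cut sites with exponential spacing (default mean
400 bp, a 4-cutter), centered smooth biases (sums of low-frequency
sinusoids, amplitude 0.4 on the log scale), a d⁻¹ power-law decay
anchored at 1 kb, NB counts at α = 0.2, exposures giving ≈3 expected
contacts per quadrant cell at 1 kb (a deeply sequenced capture-style
locus), ≈20 dangling and ≈10 rejoined reads per cut site, plus random
genomic-DNA pairs and self-circles.  Read ends are placed so
classification recovers the generating category (offsets bounded by the
fragment and by `max_cutsite_distance`; dangling starts exactly on the
site; rejoined molecules span exactly one site).  Optional rectangular
patches multiply the contact means by a fold change.  The generator does
*not* emulate mapping errors, chimeric reads, trans contacts,
copy-number variation or GC/mappability structure, so passing tests show
correctness of the estimation machinery under the model's own
assumptions, not robustness to artifacts outside the model.

Test problem sizes are chosen desk-scale: a 200 kb / ~480-cut-site locus
for background recovery and null sparsity, a 1 Mb locus at 10 kb base
resolution for the planted 100 kb block (so the block is a small
fraction of the locus, as in realistic loci — on a very small locus a
block spanning a third of the span is partially absorbed by the
genomic-bias splines, which is a property of the model), and 150 kb
replicate trios for differences.

## Numerical choices and degenerate inputs

* ADMM: penalty parameter ρ = max(λ2, 1e−3), tolerance 1e−9 (relative)
  for small problems and 1e−7 inside iterations, max 1000–5000
  iterations, tiny ridge for zero-weight components; λ2 = 0 returns the
  input, all-zero weights raise.
* REML: log-λ bounded in [−10, 20]; degenerate (no-variance) inputs
  return the upper bound.
* Dispersion MLE bracket [1e−4, 10]; underdispersed rows land on the
  lower bound.
* Linear predictors are clipped to ±30 to keep exponentials finite in
  early iterations.
* Ties in BIC resolve to the larger λ2; an all-zero signal yields λ1
  with an all-zero thresholded matrix either way.
* Loci need ≥ 10 cut sites and ≥ 1 contact; empty binned matrices and
  mismatched grids raise.

## Conventions

File outputs (matrix TSVs, BED cut sites) use 0-based half-open
coordinates; in-memory and CLI echoes are 1-based inclusive.  Matrix
TSVs carry `# key=value` header metadata and round-trip losslessly.
Rebinning sums raw counts, log-averages ratio-scale kinds weighted by
underlying read counts, and pools normalized errors by inverse variance;
a thresholded exact zero therefore survives rebinning only when its
whole block is zero.

## Known limitations

* Strong on-diagonal blocks on short loci are partially absorbed by the
  background (biases/decay); fast mode is more susceptible because its
  per-bin biases align with bin-shaped blocks.
* The λ1 rule, the BIC variant and the difference refit stand in for
  procedures the method's full specification leaves open; each is
  isolated in one function (`select_lambda1`, `select_lambda2_bic`,
  `estimate_difference`) so it can be swapped.
* Trans contacts are parsed but not modeled; normalization is cis-only,
  per chromosome.
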
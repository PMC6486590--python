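# binless

Resolution-agnostic normalization of Hi-C data.

Choosing a matrix resolution before normalizing Hi-C data throws
information away twice: counts are pooled before the biases are removed,
and every downstream resolution needs its own normalization.  `binless`
instead works at the natural resolution of the assay — the restriction
cut sites.  Every paired-end read is classified by its base-pair
geometry around cut sites (dangling ends, rejoined fragments,
self-circles, random genomic pairs, and the four contact quadrants of a
cut-site intersection); counts are then modeled with a negative-binomial
regression and significant structure is extracted with a sparse fused
lasso, after which matrices can be produced at *any* resolution from the
single fit.  It is intended for people analyzing targeted or
chromosome-scale Hi-C experiments who want statistically calibrated
signal and difference maps rather than visually tuned ones.

## Model

With `d_i` the dangling/rejoined count at cut site `i` and `c_ij` the
count of one contact quadrant at intersection `(i, j)`:

    d_i  ~ NB(mu_i, alpha)          c_ij ~ NB(mu_ij, alpha)

    log mu_ij = e_C + bias_q(i,j) + f(d_ij) + s_ij
    log mu_i  = e_L − iota_i  |  e_R − rho_i  |  e_J + (iota_i + rho_i)/2
                (left-dangling | right-dangling | rejoined)

* `iota_i`, `rho_i` — smooth left/right genomic efficiencies of each cut
  site (penalized B-splines, REML-selected stiffness); a quadrant reads
  the sides its reads map on (up: `iota_i + iota_j`, down:
  `rho_i + rho_j`, close: `rho_i + iota_j`, far: `iota_i + rho_j`).
  Dangling ends run *against* the efficiency — inefficient sites
  accumulate them — which is why they inform the normalization.
* `f(d)` — distance decay, constrained monotone non-increasing.
* `alpha` — NB dispersion, `Var = mu + alpha·mu²`.
* `s_ij` — sparse log signal on base-resolution bins, estimated with a
  weighted generalized fused lasso on the triangle grid of bins: the
  fusion penalty λ2 (BIC-selected) merges bins into constant patches, a
  significance threshold λ1 is soft-subtracted so that `exp(s)` is a
  *minimum fold change* over the background and non-significant bins are
  exactly 1.  Differences between datasets use the same machinery on a
  per-bin difference term with the reference's background.

Two modes: **optimized** (full per-cut-site model, loci up to ~3 Mb) and
**fast** (binned approximation for whole chromosomes, with `alpha`,
`lambda1`, `lambda2` supplied or proposed from optimized runs on
high-structure loci ranked by directionality index).

See `docs/methods.md` for assumptions, parameter defaults and numerical
details.

## Worked example

Simulate a 200 kb locus with known biases and decay, normalize it, and
extract matrices (the `binless` command is installed with the package;
everything is also available as library functions):

```sh
binless simulate --seed 5 --out sim
#   98992 reads over 526 cut sites -> sim/reads.tsv
binless classify --reads sim/reads.tsv --cutsites sim/cutsites.bed --out qc
#   category
#   dangling_L        6514
#   dangling_R        6490
#   rejoined          5180
#   self_circle        486
#   random             233
#   contact_up       17631
#   contact_down     18660
#   contact_close    17802
#   contact_far      17438
#   other                4
binless normalize --reads sim/reads.tsv --cutsites sim/cutsites.bed \
    --base-res 5000 --name demo --out demo.h5
#   converged=False alpha=0.2757 iterations=29 -> demo.h5
binless extract --state demo.h5 --kind normalized --res 20000 --out norm.tsv
head -8 norm.tsv
#   # kind=normalized
#   # resolution=20000
#   # start=1793
#   # n_bins=10
#   # dataset=demo
#   chrom   start1  start2  value   error   weight
#   chrSim  1793    1793    14.459153019591838  0.014092775595541104  7321.0
#   chrSim  1793    21793   4.5346899886748915  0.02333946370649406   2010.0
```

The tally shows the read classes the model consumes: the four contact
quadrants carry the 3D information, dangling/rejoined reads inform the
per-site efficiencies, and self-circles/random pairs are byproducts that
are tallied but not modeled.  `alpha=0.2757` is the fitted NB
overdispersion.  In the normalized matrix, `value` is observed counts
divided by the fitted genomic biases (so what remains is decay × signal),
`error` is the IRLS standard error of its log, and `weight` the number of
reads in the cell.  A `signal` matrix from the same state contains
`exp(s)` — exactly 1.0 wherever nothing is significant — and the
`binless` matrix `exp(s + f)` adds the decay back for visualization.
Matrix kinds: raw, genomic_bias, decay, normalized(+error), signal,
binless, difference; any resolution that is a multiple of the base
resolution.

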
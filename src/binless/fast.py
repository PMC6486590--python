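"""Fast approximate normalization of binned data.

Whole chromosomes are too large for the optimized per-cut-site model, so
counts are first binned at the base resolution and a reduced model is
iterated on the bins: one genomic bias per bin, a monotone decay per
distance band (isotonic fit), and the fused-lasso signal with
user-supplied dispersion α, fusion penalty λ2 and threshold λ1.  A
distance cutoff bounds memory for long chromosomes.  The parameters are
proposed by normalizing a few loci — ranked by the standard deviation of
their directionality index — with the optimized model and taking medians.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from binless import fused, nb
from binless.classify import CONTACT_CATEGORIES


@dataclass
class BinnedData:
    """Upper-triangular binned contact counts within a distance cutoff."""

    resolution: int
    n_bins: int
    start: int                       # genomic start of bin 0 (1-based)
    bin_i: np.ndarray
    bin_j: np.ndarray                # i <= j, j - i <= cutoff_bins
    counts: np.ndarray
    cutoff_bins: int | None = None
    chrom: str = "chr"

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def marginals(self) -> np.ndarray:
        m = np.bincount(self.bin_i, weights=self.counts, minlength=self.n_bins)
        m += np.bincount(self.bin_j, weights=self.counts, minlength=self.n_bins)
        return m


@dataclass
class FastParams:
    alpha: float
    lambda1: float
    lambda2: float
    base_resolution: int = 5000
    distance_cutoff: int | None = None   # bp
    max_iter: int = 50
    tol: float = 1e-3

    def __post_init__(self):
        if self.alpha <= 0 or self.lambda2 <= 0 or self.lambda1 < 0:
            raise ValueError("need alpha > 0, lambda2 > 0, lambda1 >= 0")


@dataclass
class FastResult:
    binned: BinnedData
    biases: np.ndarray               # per-bin log bias
    decay_log: np.ndarray            # log decay per distance band (0..cutoff)
    exposure: float
    signal: np.ndarray               # thresholded log signal per cell
    signal_raw: np.ndarray
    grid: fused.TriangleGrid
    node_of_cell: np.ndarray
    converged: bool = False
    iterations: list = field(default_factory=list)

    def cell_log_mean(self) -> np.ndarray:
        b = self.biases
        d = self.binned.bin_j - self.binned.bin_i
        return (self.exposure + b[self.binned.bin_i] + b[self.binned.bin_j]
                + self.decay_log[d] + self.signal_raw)


def bin_data(classified: pd.DataFrame, resolution: int,
             cutoff: int | None = None, start: int = 0,
             end: int | None = None, chrom: str = "chr") -> BinnedData:
    """Sum classified contact reads into (bin_i, bin_j) cells.

    All four contact quadrants pool into one count per cell; cells beyond
    the distance ``cutoff`` (bp) are dropped.  Total counts are conserved
    when no cutoff applies.
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    con = classified[classified["category"].isin(CONTACT_CATEGORIES)]
    if end is None:
        end = int(con["pos_j"].max()) + 1 if len(con) else start + resolution
    n_bins = int(np.ceil((end - start) / resolution))
    a = np.clip((con["pos_i"].to_numpy(np.int64) - start) // resolution,
                0, n_bins - 1)
    b = np.clip((con["pos_j"].to_numpy(np.int64) - start) // resolution,
                0, n_bins - 1)
    cutoff_bins = None if cutoff is None else max(int(cutoff // resolution), 1)
    if cutoff_bins is not None:
        keep = (b - a) <= cutoff_bins
        a, b = a[keep], b[keep]
    if len(a):
        lin = a * n_bins + b
        uniq, counts = np.unique(lin, return_counts=True)
        bi, bj = uniq // n_bins, uniq % n_bins
    else:
        bi = bj = np.zeros(0, dtype=np.int64)
        counts = np.zeros(0, dtype=np.int64)
    return BinnedData(resolution, n_bins, start, bi, bj,
                      counts.astype(np.int64), cutoff_bins, chrom)


def _materialize_cells(binned: BinnedData):
    """Dense cell arrays over every in-range (i, j) pair, implicit zeros
    included."""
    n = binned.n_bins
    cutoff = binned.cutoff_bins if binned.cutoff_bins is not None else n - 1
    grid = fused.build_triangle_grid(n, cutoff if cutoff < n - 1 else None)
    ci = grid.nodes[:, 0]
    cj = grid.nodes[:, 1]
    counts = np.zeros(grid.n_nodes, dtype=float)
    index = {(int(a), int(b)): k for k, (a, b) in enumerate(grid.nodes)}
    for a, b, c in zip(binned.bin_i, binned.bin_j, binned.counts):
        k = index.get((int(a), int(b)))
        if k is not None:
            counts[k] = c
    return grid, ci, cj, counts


def fast_normalize(binned: BinnedData, params: FastParams) -> FastResult:
    """Two-phase IRLS on binned cells.

    Phase 1 alternates the per-bin biases and the isotonic (non-increasing)
    decay until convergence with the signal at zero; phase 2 adds
    fused-lasso signal updates at λ2 and finally applies the one-sided λ1
    threshold.  Dispersion α is fixed at the supplied value.
    """
    if binned.total <= 0:
        raise ValueError("empty matrix")
    grid, ci, cj, y = _materialize_cells(binned)
    n = binned.n_bins
    d = cj - ci
    n_bands = int(d.max()) + 1
    biases = np.zeros(n)
    decay_log = np.zeros(n_bands)
    exposure = float(np.log(max(y.mean(), 1e-9)))
    s = np.zeros(grid.n_nodes)
    iterations = []
    converged = False
    prev = None

    def eta():
        return exposure + biases[ci] + biases[cj] + decay_log[d] + s

    for phase in (1, 2):
        converged = False
        for it in range(params.max_iter):
            mu = np.exp(eta())
            z, w = nb.irls_update(y, mu, params.alpha)
            # exposure
            exposure += float(np.log(max(y.sum(), 1e-12) / mu.sum()))
            # decay: isotonic non-increasing on band-wise weighted means
            mu = np.exp(eta())
            z, w = nb.irls_update(y, mu, params.alpha)
            r = z - (eta() - decay_log[d])
            Wb = np.bincount(d, weights=w, minlength=n_bands)
            Rb = np.bincount(d, weights=w * r, minlength=n_bands)
            used = Wb > 0
            yb = np.zeros(n_bands)
            yb[used] = Rb[used] / Wb[used]
            iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
            bands = np.arange(n_bands, dtype=float)
            iso.fit(bands[used], yb[used], sample_weight=Wb[used])
            decay_log = iso.predict(bands)
            # the decay level belongs to the exposure; recentre with the
            # fitting weights so no constant leaks between the two
            level = float(np.average(decay_log[used], weights=Wb[used]))
            decay_log -= level
            exposure += level
            # biases: damped Jacobi update per bin.  Each cell's residual
            # re-adds only the bias of the side being updated, so a row's
            # weighted mean estimates its own bias given the partners —
            # re-adding both sides would double-count the (positively
            # correlated) near-diagonal partners and inflate the field.
            mu = np.exp(eta())
            z, w = nb.irls_update(y, mu, params.alpha)
            r = z - eta()
            Wr = (np.bincount(ci, weights=w, minlength=n)
                  + np.bincount(cj, weights=w, minlength=n))
            Rr = (np.bincount(ci, weights=w * (r + biases[ci]), minlength=n)
                  + np.bincount(cj, weights=w * (r + biases[cj]), minlength=n))
            ok = Wr > 0
            target = np.zeros(n)
            target[ok] = Rr[ok] / Wr[ok]
            biases = 0.5 * biases + 0.5 * np.where(ok, target, biases)
            biases -= biases[ok].mean() if np.any(ok) else 0.0
            if phase == 2:
                mu = np.exp(eta())
                z, w = nb.irls_update(y, mu, params.alpha)
                r = z - (eta() - s)
                s = fused.solve_weighted_fused_lasso(
                    np.where(w > 0, r, 0.0), w, grid, params.lambda2,
                    tol=1e-7, max_iter=1000, s0=s)
                level = float(np.average(s[w > 0], weights=w[w > 0]))
                s = np.where(w > 0, s - level, 0.0)
                exposure += level
            vec = np.concatenate([biases, decay_log, s])
            rel = (np.linalg.norm(vec - prev) / max(np.linalg.norm(vec), 1.0)
                   if prev is not None else np.inf)
            prev = vec
            iterations.append({"phase": phase, "iteration": it,
                               "rel_change": rel})
            if rel < params.tol:
                converged = True
                break
    s_thr = fused.soft_threshold(s, params.lambda1, two_sided=False)
    return FastResult(binned, biases, decay_log, exposure, s_thr, s, grid,
                      np.arange(grid.n_nodes), converged, iterations)


@dataclass
class DirectionalityProfile:
    resolution: int
    window_bp: int
    di: np.ndarray

    def locus_sd(self, bin_lo: int, bin_hi: int) -> float:
        return float(np.std(self.di[bin_lo:bin_hi]))


def directionality_index(binned: BinnedData, window_bp: int
                         ) -> DirectionalityProfile:
    """Signed chi-square contrast of upstream vs downstream contact sums.

    Per bin: A = contacts to the upstream window, B = downstream,
    E = (A+B)/2, DI = sign(B−A)·((A−E)²/E + (B−E)²/E); 0 where A+B = 0.
    Large |DI| flags domain boundaries; its per-locus standard deviation
    ranks loci by structural content.
    """
    if window_bp < binned.resolution:
        raise ValueError("window must be at least one bin")
    wbins = int(window_bp // binned.resolution)
    n = binned.n_bins
    A = np.zeros(n)
    B = np.zeros(n)
    d = binned.bin_j - binned.bin_i
    sel = (d > 0) & (d <= wbins)
    bi, bj, c = binned.bin_i[sel], binned.bin_j[sel], binned.counts[sel].astype(float)
    np.add.at(B, bi, c)   # from the left anchor's view: partner downstream
    np.add.at(A, bj, c)   # from the right anchor's view: partner upstream
    E = 0.5 * (A + B)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi = ((A - E) ** 2 + (B - E) ** 2) / E
    di = np.where(E > 0, np.sign(B - A) * chi, 0.0)
    return DirectionalityProfile(binned.resolution, window_bp, di)


def rank_loci_by_di(binned: BinnedData, locus_span: int,
                    window_bp: int = 400_000) -> pd.DataFrame:
    """Disjoint candidate loci tiling the chromosome, ranked by SD of DI."""
    profile = directionality_index(binned, window_bp)
    span_bins = max(int(locus_span // binned.resolution), 1)
    rows = []
    for lo in range(0, binned.n_bins - span_bins + 1, span_bins):
        hi = lo + span_bins
        rows.append({
            "bin_lo": lo, "bin_hi": hi,
            "start": binned.start + lo * binned.resolution,
            "end": binned.start + hi * binned.resolution,
            "sd_di": profile.locus_sd(lo, hi),
        })
    df = pd.DataFrame(rows)
    return df.sort_values("sd_di", ascending=False, kind="stable").reset_index(
        drop=True)


def estimate_fast_parameters(classified: pd.DataFrame, cutsites,
                             binned: BinnedData, n_loci: int,
                             locus_span: int, config=None,
                             window_bp: int = 400_000) -> FastParams:
    """Propose (α, λ1, λ2) for fast normalization from optimized runs.

    The ``n_loci`` disjoint loci with the highest SD of the directionality
    index are normalized with the optimized model and their signal
    estimated; the proposal is the median of the per-locus values.  The
    per-cut-site dispersion does not transfer to binned cells unchanged:
    pooling m cut-site-quadrant cells into one bin cell divides the
    effective quadratic overdispersion by m, so each locus's α̂ is scaled
    by its cells-per-bin ratio before the median.  Locus selection is
    deterministic given the matrix.
    """
    from binless.optimized import Locus, NormalizeConfig, estimate_signal, normalize

    if config is None:
        config = NormalizeConfig(base_resolution=binned.resolution)
    ranked = rank_loci_by_di(binned, locus_span, window_bp)
    if len(ranked) < 2 and n_loci > 1:
        raise ValueError("chromosome too short for the requested loci")
    chosen = ranked.head(n_loci)
    alphas, l1s, l2s = [], [], []
    for _, row in chosen.iterrows():
        lo, hi = int(row["start"]), int(row["end"])
        in_locus = ((cutsites.positions >= lo) & (cutsites.positions < hi))
        sites = cutsites.positions[in_locus]
        if len(sites) < 10:
            continue
        offset = int(np.flatnonzero(in_locus)[0])
        from binless.classify import CutSiteMap
        sub_sites = CutSiteMap(cutsites.chrom, sites, cutsites.enzyme_name)
        sub = classified[(classified["pos_i"] >= lo) & (classified["pos_i"] < hi)
                         & ((classified["pos_j"] < hi) | (classified["pos_j"] < 0))
                         & (classified["site_i"] >= 0)].copy()
        sub["site_i"] = sub["site_i"] - offset
        sub["site_j"] = np.where(sub["site_j"] >= 0,
                                 sub["site_j"] - offset, -1)
        ok = (sub["site_i"] >= 0) & (sub["site_i"] < len(sites)) \
            & (sub["site_j"] < len(sites))
        sub = sub[ok]
        locus = Locus.from_classified(sub, sub_sites, start=lo, end=hi)
        cfg = NormalizeConfig(base_resolution=config.base_resolution,
                              lambda2=config.lambda2,
                              max_outer=config.max_outer)
        state = normalize(locus, cfg)
        sig = estimate_signal(state)
        cells_per_bin = 4.0 * locus.n_pairs / max(state.grid.n_nodes, 1)
        alphas.append(state.alpha / max(cells_per_bin, 1.0))
        l1s.append(sig.lambda1)
        l2s.append(sig.lambda2)
    if len(alphas) == 0:
        raise ValueError("no usable loci for parameter estimation")
    return FastParams(alpha=float(np.median(alphas)),
                      lambda1=float(np.median(l1s)),
                      lambda2=float(np.median(l2s)),
                      base_resolution=binned.resolution,
                      distance_cutoff=(None if binned.cutoff_bins is None else
                                       binned.cutoff_bins * binned.resolution))
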
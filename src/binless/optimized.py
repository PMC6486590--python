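"""Optimized normalization of a locus by coordinate descent.

All counts of a locus — the four contact quadrants at every cut-site
intersection (including implicit zeros), and dangling/rejoined reads per
cut site — share one NB model.  Parameters are estimated separately and
iteratively on IRLS working data: dispersion (median of per-row MLEs),
exposures, the ι/ρ genomic-bias splines (REML stiffness), the monotone
decay, and finally the fused-lasso signal on the triangle grid of
base-resolution bins.  Phase 1 holds the signal at zero until the
background converges; phase 2 adds signal updates at a fixed fusion
penalty (λ2 = 2.5 by default).

Cells with zero observed counts are never materialized per read: the
per-pair count arrays are dense over cut-site intersections, and every
spline/signal refit consumes only grouped (Σ weight, weighted mean working
response) statistics per cut site, distance band or signal bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse

from binless import fused, nb, smoothing
from binless.classify import AggregatedCounts, CutSiteMap, aggregate_counts
from binless.nb import QUADRANT_BIAS

QUADRANTS = tuple(QUADRANT_BIAS)


@dataclass
class Locus:
    """Aggregated counts of one dataset on one genomic interval."""

    chrom: str
    start: int
    end: int
    cutsites: CutSiteMap
    cutsite_counts: np.ndarray       # (n_sites, 3): dangling_L, dangling_R, rejoined
    pair_i: np.ndarray               # cut-site pair index arrays, i < j
    pair_j: np.ndarray
    pair_distance: np.ndarray        # bp
    contact_counts: dict             # quadrant -> (n_pairs,) int counts
    name: str = "dataset"
    min_distance: int = 1000

    @property
    def n_sites(self) -> int:
        return self.cutsites.n_sites

    @property
    def n_pairs(self) -> int:
        return len(self.pair_i)

    def active_mask(self, quadrant: str) -> np.ndarray:
        """Cells carrying counts in the model.  The close quadrant between
        neighboring cut sites belongs to self-circles, not contacts."""
        if quadrant == "close":
            return (self.pair_j - self.pair_i) > 1
        return np.ones(self.n_pairs, dtype=bool)

    @classmethod
    def from_aggregated(cls, agg: AggregatedCounts, cutsites: CutSiteMap,
                        start: int | None = None, end: int | None = None,
                        name: str = "dataset", min_distance: int = 1000
                        ) -> "Locus":
        P = cutsites.positions
        n = len(P)
        if n < 2:
            raise ValueError("need at least 2 cut sites")
        start = int(start if start is not None else max(P[0] - 1, 0))
        end = int(end if end is not None else P[-1] + 1)
        ii, jj = np.triu_indices(n, k=1)
        dist = P[jj] - P[ii]
        keep = dist >= min_distance
        ii, jj, dist = ii[keep], jj[keep], dist[keep]
        lin = ii * n + jj
        order = np.argsort(lin)
        lin_sorted = lin[order]

        counts = {q: np.zeros(len(ii), dtype=np.int64) for q in QUADRANTS}
        con = agg.contacts
        for q in QUADRANTS:
            sub = con[con["category"] == q]
            if len(sub) == 0:
                continue
            lin_q = (sub["site_i"].to_numpy(np.int64) * n
                     + sub["site_j"].to_numpy(np.int64))
            pos = np.searchsorted(lin_sorted, lin_q)
            ok = (pos < len(lin_sorted)) & (lin_sorted[np.clip(pos, 0,
                  len(lin_sorted) - 1)] == lin_q)
            np.add.at(counts[q], order[pos[ok]],
                      sub["count"].to_numpy(np.int64)[ok])
        cc = agg.cutsite_counts[["dangling_L", "dangling_R", "rejoined"]]
        return cls(cutsites.chrom, start, end, cutsites,
                   cc.to_numpy(np.int64), ii, jj, dist, counts,
                   name=name, min_distance=min_distance)

    @classmethod
    def from_classified(cls, classified: pd.DataFrame, cutsites: CutSiteMap,
                        name: str = "dataset", min_distance: int = 1000,
                        start: int | None = None, end: int | None = None
                        ) -> "Locus":
        agg = aggregate_counts(classified, cutsites)
        return cls.from_aggregated(agg, cutsites, start=start, end=end,
                                   name=name, min_distance=min_distance)


@dataclass
class NormalizeConfig:
    base_resolution: int = 5000
    lambda2: float = fused.DEFAULT_LAMBDA2    # fusion penalty during phase 2
    bias_basis_per_mb: float = 50.0           # basis-function density for ι/ρ
    min_bias_basis: int = 20
    n_decay_basis: int = 12
    n_decay_bands: int = 100                  # log-distance aggregation bands
    penalty_order: int = 2
    max_outer: int = 50
    max_outer_signal: int = 20            # phase 2 refines a converged background
    tol: float = 1e-3
    damping: float = 0.5                      # on bias-coefficient updates
    alpha_rows: int = 100
    fit_signal: bool = True
    seed: int = 0


@dataclass
class NormalizationState:
    locus: Locus
    config: NormalizeConfig
    iota: np.ndarray
    rho: np.ndarray
    decay: smoothing.DecayFunction
    exposures: dict
    alpha: float
    grid: fused.TriangleGrid
    bin_of_pair: np.ndarray
    signal_node: np.ndarray           # unthresholded log signal per grid node
    bias_stiffness: float = 1.0
    decay_stiffness: float = 1.0
    iterations: list = field(default_factory=list)
    converged: bool = False

    def mean_model(self) -> nb.MeanModel:
        return nb.MeanModel(self.iota, self.rho, self.decay,
                            dict(self.exposures))

    def signal_of_pair(self) -> np.ndarray:
        return self.signal_node[self.bin_of_pair]


@dataclass
class SignalEstimate:
    grid: fused.TriangleGrid
    resolution: int
    s_raw: np.ndarray
    s_thresholded: np.ndarray
    lambda1: float
    lambda2: float
    node_weights: np.ndarray
    n_patches: int


@dataclass
class DifferenceState:
    reference: str
    grid: fused.TriangleGrid
    resolution: int
    delta_raw: dict                   # dataset name -> per-node log difference
    delta_thresholded: dict
    lambda1: dict
    lambda2: dict
    node_weights: dict


class _Engine:
    """Vectorized working-data bookkeeping for one locus."""

    def __init__(self, locus: Locus, config: NormalizeConfig):
        self.locus = locus
        self.config = config
        P = locus.cutsites.positions
        n = locus.n_sites
        span_mb = max((locus.end - locus.start) / 1e6, 1e-3)
        n_bias = max(config.min_bias_basis,
                     int(round(config.bias_basis_per_mb * span_mb)))
        n_bias = min(n_bias, max(4, n // 4))
        self.bias_basis = smoothing.build_bspline_basis(P, n_bias)
        self.bias_penalty_1d = smoothing.difference_penalty(
            n_bias, config.penalty_order)
        self.logd = np.log10(locus.pair_distance.astype(float))
        lo, hi = self.logd.min(), self.logd.max()
        self.decay_basis = smoothing.build_bspline_basis(
            np.linspace(lo, hi, 201), config.n_decay_basis, lo=lo, hi=hi)
        # distance aggregation bands
        edges = np.linspace(lo, hi, config.n_decay_bands + 1)
        self.band_of_pair = np.clip(np.digitize(self.logd, edges) - 1, 0,
                                    config.n_decay_bands - 1)
        self.band_centers = 0.5 * (edges[:-1] + edges[1:])
        # signal bins
        res = config.base_resolution
        n_bins = int(np.ceil((locus.end - locus.start) / res))
        self.grid = fused.build_triangle_grid(n_bins)
        idx2d = np.full((n_bins, n_bins), -1, dtype=np.int64)
        for k, (a, b) in enumerate(self.grid.nodes):
            idx2d[a, b] = k
        a = np.clip((P[locus.pair_i] - locus.start) // res, 0, n_bins - 1)
        b = np.clip((P[locus.pair_j] - locus.start) // res, 0, n_bins - 1)
        self.bin_of_pair = idx2d[a, b]
        self.masks = {q: locus.active_mask(q) for q in QUADRANTS}
        self.counts = {q: locus.contact_counts[q].astype(float)
                       for q in QUADRANTS}
        self.dangL = locus.cutsite_counts[:, 0].astype(float)
        self.dangR = locus.cutsite_counts[:, 1].astype(float)
        self.rejoined = locus.cutsite_counts[:, 2].astype(float)

    # ---- mean assembly -------------------------------------------------
    def etas(self, state: NormalizationState) -> dict:
        s_pair = state.signal_of_pair()
        f_pair = state.decay(self.locus.pair_distance)
        i, j = self.locus.pair_i, self.locus.pair_j
        out = {}
        for q, (si, sj) in QUADRANT_BIAS.items():
            bi = state.iota[i] if si == "l" else state.rho[i]
            bj = state.iota[j] if sj == "l" else state.rho[j]
            out[q] = state.exposures["contact"] + bi + bj + f_pair + s_pair
        out["dangling_L"] = state.exposures["dangling_L"] - state.iota
        out["dangling_R"] = state.exposures["dangling_R"] - state.rho
        out["rejoined"] = (state.exposures["rejoined"]
                           + 0.5 * (state.iota + state.rho))
        # linear predictors stay in a numerically safe band
        return {k: np.clip(v, -30.0, 30.0) for k, v in out.items()}

    def init_decay(self, state: NormalizationState) -> None:
        """Warm-start decay and contact exposure from band-wise raw means.

        The IRLS linearization is only trustworthy near the truth; the
        decay spans several orders of magnitude, so it is initialized from
        the log mean count per distance band before any working update.
        """
        nbands = self.config.n_decay_bands
        tot = np.zeros(nbands)
        ncell = np.zeros(nbands)
        for q in QUADRANTS:
            m = self.masks[q]
            tot += np.bincount(self.band_of_pair, weights=self.counts[q] * m,
                               minlength=nbands)
            ncell += np.bincount(self.band_of_pair, weights=m.astype(float),
                                 minlength=nbands)
        used = ncell > 0
        ybar = np.zeros(nbands)
        ybar[used] = np.log((tot[used] + 0.5) / ncell[used])
        state.decay = smoothing.fit_monotone_decay(
            self.band_centers[used], ybar[used], ncell[used],
            self.decay_basis, penalty_order=self.config.penalty_order,
            stiffness=1.0, min_distance=self.locus.min_distance)
        # recenter: the decay is a shape, the level lives in the exposure
        wmean = float(np.average(ybar[used], weights=ncell[used]))
        state.decay.coef -= wmean
        state.exposures["contact"] = wmean

    def working(self, state: NormalizationState):
        """Working response/weight for every count class."""
        etas = self.etas(state)
        z, w = {}, {}
        for q in QUADRANTS:
            mu = np.exp(etas[q])
            z[q], w[q] = nb.irls_update(self.counts[q], mu, state.alpha)
            w[q] = np.where(self.masks[q], w[q], 0.0)
        for key, y in (("dangling_L", self.dangL), ("dangling_R", self.dangR),
                       ("rejoined", self.rejoined)):
            mu = np.exp(etas[key])
            z[key], w[key] = nb.irls_update(y, mu, state.alpha)
        return etas, z, w

    def log_likelihood(self, state: NormalizationState) -> float:
        etas = self.etas(state)
        total = 0.0
        for q in QUADRANTS:
            m = self.masks[q]
            total += nb.nb_log_likelihood(self.counts[q][m],
                                          np.exp(etas[q][m]), state.alpha)
        for key, y in (("dangling_L", self.dangL), ("dangling_R", self.dangR),
                       ("rejoined", self.rejoined)):
            total += nb.nb_log_likelihood(y, np.exp(etas[key]), state.alpha)
        return total

    # ---- parameter updates ---------------------------------------------
    def update_exposures(self, state: NormalizationState) -> None:
        etas = self.etas(state)
        num = sum(self.counts[q][self.masks[q]].sum() for q in QUADRANTS)
        den = sum(np.exp(etas[q][self.masks[q]]).sum() for q in QUADRANTS)
        if den > 0 and num > 0:
            state.exposures["contact"] += float(np.log(num / den))
        for key, y in (("dangling_L", self.dangL), ("dangling_R", self.dangR),
                       ("rejoined", self.rejoined)):
            den = np.exp(etas[key]).sum()
            if den > 0 and y.sum() > 0:
                state.exposures[key] += float(np.log(y.sum() / den))

    def _bias_normal_equations(self, state: NormalizationState):
        """Accumulate XᵀWX, XᵀWr, rᵀWr for the joint (ι, ρ) spline fit.

        The design of a contact cell is the sum of the two anchor basis
        rows, placed in the ι or ρ coefficient block per the quadrant
        geometry; dangling rows enter with a negative sign, rejoined rows
        with weight one half on both blocks.
        """
        A = self.bias_basis.design
        n_sites, K = A.shape
        etas, z, w = self.working(state)
        H = np.zeros((2 * K, 2 * K))
        g = np.zeros(2 * K)
        rtWr = 0.0
        n_obs = 0
        block = {"l": 0, "r": K}
        i_arr, j_arr = self.locus.pair_i, self.locus.pair_j
        for q, (si, sj) in QUADRANT_BIAS.items():
            wq = w[q]
            bi = state.iota[i_arr] if si == "l" else state.rho[i_arr]
            bj = state.iota[j_arr] if sj == "l" else state.rho[j_arr]
            r = z[q] - (etas[q] - bi - bj)
            W1 = np.bincount(i_arr, weights=wq, minlength=n_sites)
            W2 = np.bincount(j_arr, weights=wq, minlength=n_sites)
            R1 = np.bincount(i_arr, weights=wq * r, minlength=n_sites)
            R2 = np.bincount(j_arr, weights=wq * r, minlength=n_sites)
            M = scipy.sparse.csr_matrix((wq, (i_arr, j_arr)),
                                        shape=(n_sites, n_sites))
            bi_blk, bj_blk = block[si], block[sj]
            AtW1A = (A.T * W1) @ A
            AtW2A = (A.T * W2) @ A
            AtMA = A.T @ (M @ A)
            H[bi_blk:bi_blk + K, bi_blk:bi_blk + K] += AtW1A
            H[bj_blk:bj_blk + K, bj_blk:bj_blk + K] += AtW2A
            H[bi_blk:bi_blk + K, bj_blk:bj_blk + K] += AtMA
            H[bj_blk:bj_blk + K, bi_blk:bi_blk + K] += AtMA.T
            g[bi_blk:bi_blk + K] += A.T @ R1
            g[bj_blk:bj_blk + K] += A.T @ R2
            rtWr += float(np.sum(wq * r * r))
            n_obs += int(np.sum(wq > 0))
        # dangling: design is −basis row in the matching block
        for key, blk, sign in (("dangling_L", 0, -1.0), ("dangling_R", K, -1.0)):
            wk = w[key]
            bias = state.iota if blk == 0 else state.rho
            r = z[key] - (etas[key] + bias)   # eta = expo − bias
            H[blk:blk + K, blk:blk + K] += (A.T * wk) @ A
            g[blk:blk + K] += sign * (A.T @ (wk * r))
            rtWr += float(np.sum(wk * r * r))
            n_obs += int(np.sum(wk > 0))
        # rejoined: design is (basis/2, basis/2)
        wk = w["rejoined"]
        r = z["rejoined"] - (etas["rejoined"]
                             - 0.5 * (state.iota + state.rho))
        Ah = 0.5 * A
        AtWA = (Ah.T * wk) @ Ah
        H[:K, :K] += AtWA
        H[K:, K:] += AtWA
        H[:K, K:] += AtWA
        H[K:, :K] += AtWA
        g[:K] += Ah.T @ (wk * r)
        g[K:] += Ah.T @ (wk * r)
        rtWr += float(np.sum(wk * r * r))
        n_obs += int(np.sum(wk > 0))
        return H, g, rtWr, n_obs

    def update_biases(self, state: NormalizationState,
                      select_stiffness: bool = True) -> None:
        K = self.bias_basis.n_basis
        H, g, rtWr, n_obs = self._bias_normal_equations(state)
        P2 = np.zeros((2 * K, 2 * K))
        P2[:K, :K] = self.bias_penalty_1d
        P2[K:, K:] = self.bias_penalty_1d
        if select_stiffness:
            lam = smoothing.select_stiffness_reml(
                None, None, self.bias_basis, P2,
                sufficient=(H, g, rtWr, n_obs))
            state.bias_stiffness = lam
        lam = state.bias_stiffness
        Hp = H + lam * P2
        Hp += 1e-10 * np.mean(np.diag(Hp)) * np.eye(2 * K)
        theta = np.linalg.solve(Hp, g)
        A = self.bias_basis.design
        iota_new = A @ theta[:K]
        rho_new = A @ theta[K:]
        d = self.config.damping
        iota = (1 - d) * iota_new + d * state.iota
        rho = (1 - d) * rho_new + d * state.rho
        state.iota = iota - iota.mean()
        state.rho = rho - rho.mean()

    def update_decay(self, state: NormalizationState,
                     select_stiffness: bool = True) -> None:
        etas, z, w = self.working(state)
        f_pair = state.decay(self.locus.pair_distance)
        nb_bands = self.config.n_decay_bands
        Wb = np.zeros(nb_bands)
        Rb = np.zeros(nb_bands)
        rtWr = 0.0
        n_obs = 0
        for q in QUADRANTS:
            wq = w[q]
            r = z[q] - (etas[q] - f_pair)
            Wb += np.bincount(self.band_of_pair, weights=wq,
                              minlength=nb_bands)
            Rb += np.bincount(self.band_of_pair, weights=wq * r,
                              minlength=nb_bands)
            rtWr += float(np.sum(wq * r * r))
            n_obs += int(np.sum(wq > 0))
        used = Wb > 0
        ybar = np.zeros(nb_bands)
        ybar[used] = Rb[used] / Wb[used]
        B = self.decay_basis.evaluate(self.band_centers)
        pen = smoothing.difference_penalty(self.decay_basis.n_basis,
                                           self.config.penalty_order)
        if select_stiffness:
            BtWB = (B.T * Wb) @ B
            BtWy = (B.T * Wb) @ ybar
            lam = smoothing.select_stiffness_reml(
                None, None, self.decay_basis, pen,
                sufficient=(BtWB, BtWy, rtWr, n_obs))
            state.decay_stiffness = lam
        state.decay = smoothing.fit_monotone_decay(
            self.band_centers[used], ybar[used], Wb[used], self.decay_basis,
            penalty_order=self.config.penalty_order,
            stiffness=state.decay_stiffness,
            min_distance=self.locus.min_distance)

    def update_dispersion(self, state: NormalizationState) -> None:
        etas = self.etas(state)
        n_sites = self.locus.n_sites
        n_rows = min(self.config.alpha_rows, n_sites)
        rows = np.unique(np.linspace(0, n_sites - 1, n_rows).astype(int))
        counts_rows, mu_rows = [], []
        i_arr, j_arr = self.locus.pair_i, self.locus.pair_j
        for s in rows:
            sel = (i_arr == s) | (j_arr == s)
            ys = [np.array([self.dangL[s], self.dangR[s], self.rejoined[s]])]
            ms = [np.exp(np.array([etas["dangling_L"][s],
                                   etas["dangling_R"][s],
                                   etas["rejoined"][s]]))]
            for q in QUADRANTS:
                m = sel & self.masks[q]
                ys.append(self.counts[q][m])
                ms.append(np.exp(etas[q][m]))
            counts_rows.append(np.concatenate(ys))
            mu_rows.append(np.concatenate(ms))
        state.alpha = nb.estimate_dispersion(counts_rows, mu_rows,
                                             n_rows=len(rows))

    def update_signal(self, state: NormalizationState,
                      lam2: float) -> None:
        y_node, w_node = self.signal_node_data(state)
        s = np.zeros(self.grid.n_nodes)
        if np.any(w_node > 0):
            s = fused.solve_weighted_fused_lasso(
                np.where(w_node > 0, y_node, 0.0), w_node, self.grid, lam2,
                tol=1e-7, max_iter=2000, s0=state.signal_node)
            # the signal level is degenerate with the contact exposure;
            # pin the (weight-dominant) background at zero
            level = float(np.average(s[w_node > 0], weights=w_node[w_node > 0]))
            s = np.where(w_node > 0, s - level, 0.0)
            state.exposures["contact"] += level
        state.signal_node = s

    def signal_node_data(self, state: NormalizationState,
                         include_signal: bool = True):
        """Aggregate working residuals (relative to the signal-free
        background) onto the triangle grid: (weighted mean, Σ weight)."""
        etas, z, w = self.working(state)
        s_pair = state.signal_of_pair()
        nn = self.grid.n_nodes
        Wn = np.zeros(nn)
        Rn = np.zeros(nn)
        for q in QUADRANTS:
            wq = w[q]
            r = z[q] - (etas[q] - s_pair)
            Wn += np.bincount(self.bin_of_pair, weights=wq, minlength=nn)
            Rn += np.bincount(self.bin_of_pair, weights=wq * r, minlength=nn)
        y = np.zeros(nn)
        pos = Wn > 0
        y[pos] = Rn[pos] / Wn[pos]
        return y, Wn

    def free_bin_enrichment(self, iota, rho, decay, alpha, exposures,
                            n_iter: int = 15, floor: float = -8.0):
        """Per-bin free log enrichment of this dataset's counts over a
        *fixed* background (typically another dataset's), with the
        dataset's own exposure refitted.

        Each bin's enrichment has an exact IRLS intercept update
        t += log(Σy/Σμ); a few iterations converge.  Returns (t, Σ IRLS
        weight per bin); bins with no signal-carrying cells get weight 0.
        """
        i_arr, j_arr = self.locus.pair_i, self.locus.pair_j
        f_pair = decay(self.locus.pair_distance)
        nn = self.grid.n_nodes
        t = np.zeros(nn)
        e_c = exposures["contact"]
        bias = {}
        for q, (si, sj) in QUADRANT_BIAS.items():
            bi = iota[i_arr] if si == "l" else rho[i_arr]
            bj = iota[j_arr] if sj == "l" else rho[j_arr]
            bias[q] = bi + bj
        num0 = np.zeros(nn)
        for q in QUADRANTS:
            num0 += np.bincount(self.bin_of_pair,
                                weights=self.counts[q] * self.masks[q],
                                minlength=nn)
        for _ in range(n_iter):
            den = np.zeros(nn)
            total_mu = 0.0
            for q in QUADRANTS:
                eta = np.clip(e_c + bias[q] + f_pair + t[self.bin_of_pair],
                              -30, 30)
                mu = np.exp(eta) * self.masks[q]
                den += np.bincount(self.bin_of_pair, weights=mu, minlength=nn)
                total_mu += mu.sum()
            e_c += float(np.log(max(num0.sum(), 1e-12) / max(total_mu, 1e-12)))
            upd = np.where(den > 0,
                           np.log(np.maximum(num0, 1e-12) / np.maximum(den, 1e-12)),
                           0.0)
            t = np.clip(t + np.clip(upd, -4, 4), floor, 10.0)
        w_node = np.zeros(nn)
        for q in QUADRANTS:
            eta = np.clip(e_c + bias[q] + f_pair + t[self.bin_of_pair], -30, 30)
            mu = np.exp(eta)
            w = mu / (1.0 + alpha * mu) * self.masks[q]
            w_node += np.bincount(self.bin_of_pair, weights=w, minlength=nn)
        # pin the weighted mean at zero: the level lives in the exposure
        used = w_node > 0
        if used.any():
            t = np.where(used,
                         t - np.average(t[used], weights=w_node[used]), 0.0)
        return t, w_node

    def node_read_counts(self) -> np.ndarray:
        reads = np.zeros(self.grid.n_nodes)
        for q in QUADRANTS:
            reads += np.bincount(self.bin_of_pair,
                                 weights=self.counts[q] * self.masks[q],
                                 minlength=self.grid.n_nodes)
        return reads

    def state_vector(self, state: NormalizationState) -> np.ndarray:
        fgrid = state.decay(np.geomspace(self.locus.min_distance,
                                         max(self.locus.pair_distance.max(),
                                             self.locus.min_distance + 1), 50))
        fgrid = fgrid - fgrid.mean()
        return np.concatenate([state.iota, state.rho, fgrid,
                               [np.log(state.alpha)], state.signal_node])


def normalize(locus: Locus, config: NormalizeConfig | None = None
              ) -> NormalizationState:
    """Two-phase coordinate-descent normalization of one locus.

    Phase 1 iterates dispersion, exposures, genomic biases (REML
    stiffness) and monotone decay with the signal held at zero; phase 2
    adds fused-lasso signal updates at ``config.lambda2``.  The returned
    state carries the iteration log and a convergence flag; it is
    deterministic for fixed inputs and configuration.
    """
    if config is None:
        config = NormalizeConfig()
    if locus.n_sites < 10:
        raise ValueError("optimized normalization needs >= 10 cut sites")
    if sum(c.sum() for c in locus.contact_counts.values()) < 1:
        raise ValueError("no contacts in locus")
    eng = _Engine(locus, config)
    n = locus.n_sites
    mean_contact = float(np.mean(
        [eng.counts[q][eng.masks[q]].mean() for q in QUADRANTS]))
    state = NormalizationState(
        locus=locus, config=config,
        iota=np.zeros(n), rho=np.zeros(n),
        decay=smoothing.DecayFunction(
            eng.decay_basis, np.zeros(eng.decay_basis.n_basis),
            min_distance=locus.min_distance),
        exposures={"contact": float(np.log(max(mean_contact, 1e-6))),
                   "dangling_L": float(np.log(max(eng.dangL.mean(), 1e-6))),
                   "dangling_R": float(np.log(max(eng.dangR.mean(), 1e-6))),
                   "rejoined": float(np.log(max(eng.rejoined.mean(), 1e-6)))},
        alpha=0.1,
        grid=eng.grid, bin_of_pair=eng.bin_of_pair,
        signal_node=np.zeros(eng.grid.n_nodes))
    eng.init_decay(state)

    for phase in (1, 2):
        if phase == 2 and not config.fit_signal:
            break
        state.converged = False
        prev = eng.state_vector(state)
        max_iter = config.max_outer if phase == 1 else config.max_outer_signal
        for it in range(max_iter):
            eng.update_dispersion(state)
            eng.update_exposures(state)
            # REML re-selection only while the background is still moving
            eng.update_biases(state, select_stiffness=(phase == 1))
            eng.update_exposures(state)
            eng.update_decay(state, select_stiffness=(phase == 1))
            if phase == 2:
                eng.update_exposures(state)
                eng.update_signal(state, config.lambda2)
            eng.update_exposures(state)
            vec = eng.state_vector(state)
            denom = max(float(np.linalg.norm(vec)), 1.0)
            rel = float(np.linalg.norm(vec - prev)) / denom
            prev = vec
            state.iterations.append({
                "phase": phase, "iteration": it,
                "log_likelihood": eng.log_likelihood(state),
                "alpha": state.alpha,
                "bias_stiffness": state.bias_stiffness,
                "decay_stiffness": state.decay_stiffness,
                "rel_change": rel,
            })
            if rel < config.tol:
                state.converged = True
                break
    state._engine = eng
    return state


def _engine_of(state: NormalizationState) -> _Engine:
    eng = getattr(state, "_engine", None)
    if eng is None:
        eng = _Engine(state.locus, state.config)
        state._engine = eng
    return eng


def estimate_signal(state: NormalizationState,
                    lam2_grid=fused.DEFAULT_LAMBDA2_GRID,
                    fdr: float = 0.05) -> SignalEstimate:
    """Final signal estimate: λ2 by BIC, λ1 from patch significance,
    one-sided soft threshold.  Bins with no evidence are exactly zero."""
    eng = _engine_of(state)
    y, w = eng.signal_node_data(state)
    y = np.where(w > 0, y, 0.0)
    lam2, s, _ = fused.select_lambda2_bic(y, w, eng.grid, lam2_grid)
    lam1 = fused.select_lambda1(s, w, eng.grid, alpha=fdr, y=y)
    s_thr = fused.soft_threshold(s, lam1, two_sided=False)
    s_thr = np.where(w > 0, s_thr, 0.0)
    n_patches, _, _ = fused.count_patches(s, eng.grid)
    return SignalEstimate(eng.grid, state.config.base_resolution, s, s_thr,
                          lam1, lam2, w, n_patches)


def estimate_difference(states: dict, reference: str,
                        lam2_grid=fused.DEFAULT_LAMBDA2_GRID,
                        lam2: float | None = None,
                        fdr: float = 0.05) -> DifferenceState:
    """Sparse log differences of each dataset against a reference.

    All datasets are modeled with the *same* mean as the reference up to
    an additive per-bin difference term: every dataset's counts are
    re-residualized on the reference's background (biases, decay), with
    free per-bin enrichment and its own exposure.  The per-bin difference
    of dataset k is then t_k − t_ref, weighted by the harmonic mean of
    the two working weights, fused on the grid and thresholded two-sided.
    Using one common background keeps background-fitting artifacts out of
    the difference; the reference's difference is identically zero.
    """
    if reference not in states:
        raise ValueError(f"reference {reference!r} not among states")
    grids = {name: (st.grid.n_bins, st.config.base_resolution,
                    st.locus.n_sites)
             for name, st in states.items()}
    if len(set(grids.values())) != 1:
        raise ValueError(f"mismatched grids across states: {grids}")
    ref_state = states[reference]
    eng_ref = _engine_of(ref_state)
    y_ref, w_ref = eng_ref.free_bin_enrichment(
        ref_state.iota, ref_state.rho, ref_state.decay, ref_state.alpha,
        ref_state.exposures)
    grid = ref_state.grid
    out = DifferenceState(reference, grid, ref_state.config.base_resolution,
                          {}, {}, {}, {}, {})
    zeros = np.zeros(grid.n_nodes)
    out.delta_raw[reference] = zeros.copy()
    out.delta_thresholded[reference] = zeros.copy()
    out.lambda1[reference] = 0.0
    out.lambda2[reference] = 0.0
    out.node_weights[reference] = w_ref
    for name, st in states.items():
        if name == reference:
            continue
        eng = _engine_of(st)
        y_k, w_k = eng.free_bin_enrichment(
            ref_state.iota, ref_state.rho, ref_state.decay, st.alpha,
            st.exposures)
        both = (w_k > 0) & (w_ref > 0)
        d = np.where(both, y_k - y_ref, 0.0)
        w_d = np.zeros(grid.n_nodes)
        w_d[both] = 1.0 / (1.0 / w_k[both] + 1.0 / w_ref[both])
        if lam2 is not None:
            l2 = lam2
            delta = fused.solve_weighted_fused_lasso(d, w_d, grid, l2)
        else:
            l2, delta, _ = fused.select_lambda2_bic(d, w_d, grid, lam2_grid)
        l1 = fused.select_lambda1(delta, w_d, grid, alpha=fdr, y=d)
        thr = fused.soft_threshold(delta, l1, two_sided=True)
        thr = np.where(both, thr, 0.0)
        out.delta_raw[name] = delta
        out.delta_thresholded[name] = thr
        out.lambda1[name] = l1
        out.lambda2[name] = l2
        out.node_weights[name] = w_d
    return out


def convergence_diagnostics(state: NormalizationState) -> pd.DataFrame:
    """Per-iteration objective, dispersion and parameter-change table."""
    if not state.iterations:
        raise ValueError("state carries no iteration log")
    return pd.DataFrame(state.iterations)
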
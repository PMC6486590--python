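"""Weighted sparse generalized fused lasso on the triangle grid of
upper-triangular matrix bins.

The signal (and the difference between datasets) lives on bins (a, b),
a ≤ b, of the upper triangle, with edges between horizontally and
vertically adjacent bins.  The estimate minimizes

    ½ Σ_b w_b (y_b − s_b)² + λ2 Σ_{(b,b')∈E} |s_b − s_b'|

which fuses neighboring bins into constant patches; the fusion penalty λ2
is selected by BIC with the number of patches as degrees of freedom, and a
significance threshold λ1 is then soft-subtracted so that only patches
inconsistent with working-model noise survive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse
import scipy.sparse.csgraph
import scipy.sparse.linalg
import scipy.stats


@dataclass
class TriangleGrid:
    """Upper-triangular bin graph: nodes (a, b), a ≤ b ≤ a + max_dist."""

    n_bins: int
    max_distance_bins: int | None
    nodes: np.ndarray          # (n_nodes, 2) of (a, b)
    edges: np.ndarray          # (n_edges, 2) node indices

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def node_index(self) -> dict:
        return {(int(a), int(b)): k for k, (a, b) in enumerate(self.nodes)}

    def incidence(self) -> scipy.sparse.csr_matrix:
        """Oriented edge-node incidence matrix D (Ds = edge differences)."""
        m = len(self.edges)
        rows = np.repeat(np.arange(m), 2)
        cols = self.edges.ravel()
        vals = np.tile([1.0, -1.0], m)
        return scipy.sparse.csr_matrix((vals, (rows, cols)),
                                       shape=(m, self.n_nodes))


def build_triangle_grid(n_bins: int, max_distance_bins: int | None = None
                        ) -> TriangleGrid:
    """Enumerate upper-triangular bins and their grid adjacency.

    Bins (a, b) with a ≤ b (and b − a ≤ max_distance_bins if given); edges
    (a, b)–(a+1, b) and (a, b)–(a, b+1) wherever both endpoints exist.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    cutoff = n_bins - 1 if max_distance_bins is None else int(max_distance_bins)
    nodes = [(a, b) for a in range(n_bins)
             for b in range(a, min(a + cutoff, n_bins - 1) + 1)]
    nodes = np.asarray(nodes, dtype=np.int64).reshape(-1, 2)
    index = {(int(a), int(b)): k for k, (a, b) in enumerate(nodes)}
    edges = []
    for k, (a, b) in enumerate(nodes):
        right = index.get((a, b + 1))
        if right is not None:
            edges.append((k, right))
        down = index.get((a + 1, b))
        if down is not None and a + 1 <= b:
            edges.append((k, down))
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    return TriangleGrid(n_bins, max_distance_bins, nodes, edges)


def solve_weighted_fused_lasso(y, weights, grid: TriangleGrid, lam2: float,
                               tol: float = 1e-9, max_iter: int = 5000,
                               s0=None) -> np.ndarray:
    """ADMM solve of the weighted fused lasso on the grid graph.

    Splits the edge differences into an auxiliary variable soft-thresholded
    in closed form; the node update is a single sparse factorization reused
    across iterations.  After convergence, bins connected by edges with
    (numerically) zero fitted difference are averaged so members of a patch
    share one exact value.
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    n = grid.n_nodes
    if y.shape != (n,) or w.shape != (n,):
        raise ValueError("y/weights must match the number of grid nodes")
    if np.all(w <= 0):
        raise ValueError("all weights are zero")
    if lam2 < 0:
        raise ValueError("lam2 must be >= 0")
    if lam2 == 0 or len(grid.edges) == 0:
        return y.copy()

    D = grid.incidence()
    rho = max(lam2, 1e-3)
    W = scipy.sparse.diags(w)
    A = (W + rho * (D.T @ D)).tocsc()
    # tiny ridge keeps zero-weight components invertible
    A = A + scipy.sparse.identity(n, format="csc") * (1e-12 * (np.mean(w) + rho))
    solve = scipy.sparse.linalg.factorized(A)

    s = y.copy() if s0 is None else np.asarray(s0, dtype=float).copy()
    d = D @ s
    u = np.zeros(len(grid.edges))
    Wy = w * y
    scale = max(np.max(np.abs(y[w > 0])), 1.0)
    thresh = lam2 / rho
    for _ in range(max_iter):
        s = solve(Wy + rho * (D.T @ (d - u)))
        Ds = D @ s
        d_old = d
        v = Ds + u
        d = np.sign(v) * np.maximum(np.abs(v) - thresh, 0.0)
        u = u + Ds - d
        r_primal = np.max(np.abs(Ds - d)) if len(d) else 0.0
        r_dual = rho * np.max(np.abs(d - d_old)) if len(d) else 0.0
        if max(r_primal, r_dual) < tol * scale:
            break
    # the soft-threshold makes fused edge differences exactly zero; snap
    # each fused component to its common (weighted-mean) value
    e = grid.edges
    ef = e[d == 0.0]
    adj = scipy.sparse.csr_matrix(
        (np.ones(len(ef)), (ef[:, 0], ef[:, 1])), shape=(n, n))
    n_comp, labels = scipy.sparse.csgraph.connected_components(
        adj, directed=False)
    wsum = np.bincount(labels, weights=np.maximum(w, 0.0), minlength=n_comp)
    nsum = np.bincount(labels, minlength=n_comp)
    num = np.bincount(labels, weights=np.maximum(w, 0.0) * s, minlength=n_comp)
    plain = np.bincount(labels, weights=s, minlength=n_comp) / np.maximum(nsum, 1)
    means = np.divide(num, wsum, out=plain, where=wsum > 0)
    return means[labels]


def _patch_labels(s, grid: TriangleGrid, tol: float = 1e-6):
    n = grid.n_nodes
    if len(grid.edges) == 0:
        return np.arange(n), n
    e = grid.edges
    fused = np.abs(s[e[:, 0]] - s[e[:, 1]]) <= tol
    ef = e[fused]
    adj = scipy.sparse.csr_matrix(
        (np.ones(len(ef)), (ef[:, 0], ef[:, 1])), shape=(n, n))
    n_comp, labels = scipy.sparse.csgraph.connected_components(
        adj, directed=False)
    return labels, n_comp


def count_patches(s, grid: TriangleGrid, reads_per_bin=None, tol: float = 1e-6):
    """Connected components of equal fitted value.

    Returns (n_patches, patch sizes, per-patch read density).  Density is
    reads in the patch divided by its bin count (NaN when no read vector is
    supplied).
    """
    s = np.asarray(s, dtype=float)
    labels, n_comp = _patch_labels(s, grid, tol=tol)
    sizes = np.bincount(labels, minlength=n_comp)
    if reads_per_bin is None:
        density = np.full(n_comp, np.nan)
    else:
        reads = np.asarray(reads_per_bin, dtype=float)
        density = np.bincount(labels, weights=reads, minlength=n_comp) / sizes
    return n_comp, sizes, density


def soft_threshold(s, lam1: float, two_sided: bool = False) -> np.ndarray:
    """Sparsify the fitted log-signal.

    One-sided (signal: enrichment over background): s' = max(s − λ1, 0).
    Two-sided (differences): s' = sign(s)·max(|s| − λ1, 0).  Surviving
    values are minimum fold changes on the log scale.
    """
    if lam1 < 0:
        raise ValueError("lam1 must be >= 0")
    s = np.asarray(s, dtype=float)
    if two_sided:
        return np.sign(s) * np.maximum(np.abs(s) - lam1, 0.0)
    return np.maximum(s - lam1, 0.0)


DEFAULT_LAMBDA2 = 2.5
DEFAULT_LAMBDA2_GRID = tuple(np.geomspace(0.1, 30.0, 15))


def select_lambda2_bic(y, weights, grid: TriangleGrid,
                       lam2_grid=DEFAULT_LAMBDA2_GRID):
    """Fusion penalty minimizing BIC = wRSS + df·log(n).

    The working weights carry the (known) noise scale of the Gaussian
    working model, so −2·log-likelihood is the weighted RSS itself —
    profiling a free σ² out of near-interpolating fits would always favor
    the smallest λ2.  df is the number of fused patches (the standard
    fused-lasso estimate).  Ties resolve to the larger λ2.  Returns
    (λ2*, s*, table of (λ2, df, BIC))."""
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    lam2_grid = sorted(lam2_grid)
    if not lam2_grid:
        raise ValueError("empty lambda2 grid")
    n = int(np.sum(w > 0))
    best = None
    trace = []
    s = None
    for lam2 in lam2_grid:
        s = solve_weighted_fused_lasso(y, w, grid, lam2, tol=1e-7,
                                       max_iter=2000, s0=s)
        rss = float(np.sum(w * (y - s) ** 2))
        df, _, _ = count_patches(s, grid)
        bic = rss + df * np.log(n)
        trace.append((lam2, df, bic))
        if best is None or bic <= best[2] + 1e-9:   # ties -> larger lam2
            best = (lam2, s, bic)
    return best[0], best[1], trace


def select_lambda1(s, weights, grid: TriangleGrid, alpha: float = 0.05,
                   tol: float = 1e-6, y=None) -> float:
    """Significance threshold λ1 from per-patch working-model z-scores.

    Each fused patch is tested against the null that its value is working
    noise: z = |patch value| / SE with SE = √(φ / Σ weights in patch),
    two-sided normal p-values, Benjamini–Hochberg across patches.  φ is a
    Pearson-type variance-inflation factor estimated from the residuals
    y − s when ``y`` is supplied (the IRLS weights understate the real
    working noise whenever the linearization is imperfect); φ is floored
    at 1.  λ1 is the largest |value| among patches *not* rejected, so
    that after soft-thresholding every surviving region is inconsistent
    with noise alone.  All-significant input returns 0.
    """
    s = np.asarray(s, dtype=float)
    w = np.asarray(weights, dtype=float)
    labels, n_comp = _patch_labels(s, grid, tol=tol)
    values = np.zeros(n_comp)
    wsum = np.zeros(n_comp)
    for lab in range(n_comp):
        mask = labels == lab
        values[lab] = s[mask][0]
        wsum[lab] = w[mask].sum()
    phi = 1.0
    if y is not None:
        y = np.asarray(y, dtype=float)
        used = w > 0
        dof = max(int(used.sum()) - n_comp, 1)
        phi = max(float(np.sum(w[used] * (y[used] - s[used]) ** 2)) / dof, 1.0)
    se = np.where(wsum > 0, np.sqrt(phi / np.maximum(wsum, 1e-300)), np.inf)
    z = np.abs(values) / se
    pvals = 2.0 * scipy.stats.norm.sf(z)
    rejected = _benjamini_hochberg(pvals, alpha)
    not_significant = np.abs(values[~rejected])
    if len(not_significant) == 0:
        return 0.0
    return float(np.max(not_significant))


def _benjamini_hochberg(pvals, alpha: float) -> np.ndarray:
    """Boolean rejection mask at FDR level alpha."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p)
    thresholds = alpha * (np.arange(1, m + 1)) / m
    passed = p[order] <= thresholds
    if not np.any(passed):
        return np.zeros(m, dtype=bool)
    k_max = np.max(np.nonzero(passed)[0])
    rejected = np.zeros(m, dtype=bool)
    rejected[order[:k_max + 1]] = True
    return rejected


def kkt_residual(y, weights, grid: TriangleGrid, lam2: float, s) -> float:
    """Max-norm violation of the subgradient optimality conditions.

    For each node: w(s − y) + λ2 Σ_e ±g_e = 0 with g_e = sign(s_i − s_j) on
    unfused edges and g_e ∈ [−1, 1] free on fused ones; the free
    subgradients are chosen by least squares, so the residual is the
    distance to the nearest valid subgradient assignment.
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    s = np.asarray(s, dtype=float)
    grad = w * (s - y)
    if len(grid.edges) == 0 or lam2 == 0:
        return float(np.max(np.abs(grad))) if len(grad) else 0.0
    e = grid.edges
    diffs = s[e[:, 0]] - s[e[:, 1]]
    fused = np.abs(diffs) <= 1e-8 * max(1.0, np.max(np.abs(s)))
    # fixed part from unfused edges
    sign = np.sign(diffs)
    for k, (i, j) in enumerate(e):
        if not fused[k]:
            grad[i] += lam2 * sign[k]
            grad[j] -= lam2 * sign[k]
    ef = e[fused]
    if len(ef) == 0:
        return float(np.max(np.abs(grad)))
    m = len(ef)
    rows = np.repeat(np.arange(m), 2)
    cols = ef.ravel()
    vals = np.tile([1.0, -1.0], m)
    Df = scipy.sparse.csr_matrix((vals, (rows, cols)),
                                 shape=(m, grid.n_nodes))
    lsqr_out = scipy.sparse.linalg.lsqr(Df.T * lam2, -grad, atol=1e-12,
                                        btol=1e-12)
    g = np.clip(lsqr_out[0], -1.0, 1.0)
    resid = grad + lam2 * (Df.T @ g)
    return float(np.max(np.abs(resid)))
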
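"""Independent reference implementations used only as test oracles.

These deliberately avoid the package's code paths: the read-category
oracle is a scalar decision tree written straight from the category
definitions; the fused-lasso oracle solves the epigraph quadratic program
with a generic constrained optimizer; the dispersion oracle is a plain
grid search on the NB likelihood.
"""

from __future__ import annotations

import numpy as np
import scipy.optimize
import scipy.special


def classify_oracle(p1: int, s1: str, p2: int, s2: str, sites,
                    tol_dangling: int = 0, max_cutsite_distance: int = 1000
                    ) -> str:
    """Scalar decision tree over the documented category rules.

    Ends point along their strand; '+' targets the first cut site at or
    after the 5' start, '-' the last one at or before it.
    """
    sites = sorted(sites)

    def down(p):
        cands = [s for s in sites if s >= p]
        return cands[0] if cands else None

    def up(p):
        cands = [s for s in sites if s <= p]
        return cands[-1] if cands else None

    def nearest_dist(p):
        return min(abs(p - s) for s in sites)

    def near(p, target):
        return target is not None and abs(p - target) <= max_cutsite_distance

    if s1 == "+" and s2 == "-":           # converging
        if p1 > p2:
            return "other"
        if nearest_dist(p1) <= tol_dangling:
            return "dangling_L"
        if nearest_dist(p2) <= tol_dangling:
            return "dangling_R"
        t1, t2 = down(p1), up(p2)
        if not (near(p1, t1) and near(p2, t2)):
            return "other"
        if t1 > t2:
            return "random"               # same fragment, no site inside
        if t1 == t2:
            return "rejoined"             # spans exactly one site
        return "contact_far"
    if s1 == "-" and s2 == "+":           # diverging
        if p1 > p2:
            return "other"
        t1, t2 = up(p1), down(p2)
        if not (near(p1, t1) and near(p2, t2)):
            return "other"
        if t1 == t2:
            return "other"
        if sites.index(t2) == sites.index(t1) + 1:
            return "self_circle"
        return "contact_close"
    if s1 == "+" and s2 == "+":
        t1, t2 = down(p1), down(p2)
        if not (near(p1, t1) and near(p2, t2)) or not t1 < t2:
            return "other"
        return "contact_up"
    t1, t2 = up(p1), up(p2)
    if not (near(p1, t1) and near(p2, t2)) or not t1 < t2:
        return "other"
    return "contact_down"


def fused_lasso_oracle(y, w, edges, lam2: float) -> np.ndarray:
    """Generic convex solve of the weighted graph fused lasso.

    Epigraph QP: minimize ½Σw(y−s)² + λ2Σt subject to
    t_e ≥ ±(s_i − s_j), solved with SLSQP.
    """
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    n = len(y)
    m = len(edges)
    if m == 0 or lam2 == 0:
        return y.copy()

    def objective(x):
        s, t = x[:n], x[n:]
        return 0.5 * np.sum(w * (y - s) ** 2) + lam2 * np.sum(t)

    A = np.zeros((2 * m, n + m))
    for k, (i, j) in enumerate(edges):
        A[k, i], A[k, j], A[k, n + k] = 1, -1, -1
        A[m + k, i], A[m + k, j], A[m + k, n + k] = -1, 1, -1
    constraint = scipy.optimize.LinearConstraint(A, -np.inf, 0.0)
    t0 = np.abs(y[[i for i, _ in edges]] - y[[j for _, j in edges]]) + 1.0
    res = scipy.optimize.minimize(
        objective, np.concatenate([y, t0]), constraints=[constraint],
        method="SLSQP", options={"maxiter": 3000, "ftol": 1e-14})
    return res.x[:n]


def nb_logpmf_oracle(y, mu, alpha):
    """NB log pmf via scipy.stats.nbinom in the (size, prob) convention."""
    import scipy.stats

    r = 1.0 / alpha
    return scipy.stats.nbinom.logpmf(y, r, r / (r + mu))


def dispersion_grid_mle(y, mu, grid=None) -> float:
    """Brute-force per-row dispersion MLE on a dense log-spaced grid."""
    if grid is None:
        grid = np.geomspace(1e-4, 10.0, 4000)
    y = np.asarray(y, float)
    mu = np.asarray(mu, float)
    best, best_ll = grid[0], -np.inf
    for a in grid:
        r = 1.0 / a
        ll = np.sum(scipy.special.gammaln(y + r) - scipy.special.gammaln(r)
                    - scipy.special.gammaln(y + 1)
                    + r * (np.log(r) - np.log(r + mu))
                    + y * (np.log(mu) - np.log(r + mu)))
        if ll > best_ll:
            best, best_ll = a, ll
    return float(best)


def bspline_de_boor(x, knots, degree, i):
    """Cox–de Boor recursion for one B-spline basis function."""
    if degree == 0:
        return 1.0 if knots[i] <= x < knots[i + 1] else 0.0
    left = 0.0
    if knots[i + degree] != knots[i]:
        left = (x - knots[i]) / (knots[i + degree] - knots[i]) \
            * bspline_de_boor(x, knots, degree - 1, i)
    right = 0.0
    if knots[i + degree + 1] != knots[i + 1]:
        right = (knots[i + degree + 1] - x) / (knots[i + degree + 1] - knots[i + 1]) \
            * bspline_de_boor(x, knots, degree - 1, i + 1)
    return left + right
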
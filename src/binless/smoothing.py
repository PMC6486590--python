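"""P-spline machinery: B-spline bases, difference penalties, penalized
weighted least squares, REML stiffness selection, and a monotone
(non-increasing) constrained fit for the distance decay.

The genomic biases and the decay are smooth curves fitted to weighted
working data from the IRLS approximation.  Smoothness is controlled by a
difference penalty on adjacent B-spline coefficients whose stiffness is
selected by restricted maximum likelihood on the Gaussian working model, so
the effective wiggliness adapts to the quantity of data.  Monotonicity of
the decay is enforced through non-increasing spline coefficients, which is
sufficient for a non-increasing B-spline curve and keeps the problem a
bound-constrained least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.optimize
from scipy.interpolate import BSpline


@dataclass
class SplineBasis:
    """Clamped uniform B-spline basis with its design matrix."""

    knots: np.ndarray         # full knot vector (clamped)
    degree: int
    positions: np.ndarray     # evaluation points the design was built on
    design: np.ndarray        # (n_points, n_basis), rows sum to 1
    lo: float
    hi: float

    @property
    def n_basis(self) -> int:
        return len(self.knots) - self.degree - 1

    def evaluate(self, x) -> np.ndarray:
        """Design matrix at new points (clamped to [lo, hi]).

        The exact upper boundary is evaluated by left limit so the row
        keeps its partition of unity on the half-open knot span.
        """
        x = np.clip(np.asarray(x, dtype=float), self.lo, self.hi)
        eps = 1e-9 * max(self.hi - self.lo, 1.0)
        x = np.minimum(x, self.hi - eps)
        return BSpline.design_matrix(x, self.knots, self.degree,
                                     extrapolate=False).toarray()


def build_bspline_basis(positions, n_basis: int, degree: int = 3,
                        lo: float | None = None, hi: float | None = None
                        ) -> SplineBasis:
    """Uniform B-spline basis over the range of ``positions``.

    Knots are equally spaced and extend ``degree`` steps beyond the data
    range (the classical P-spline construction), so the difference
    penalty's null space on the coefficients maps exactly onto low-order
    polynomials of the coordinate.  ``n_basis`` must be at least
    ``degree + 1``; every design-matrix row sums to one on [lo, hi].
    """
    positions = np.asarray(positions, dtype=float)
    if positions.size == 0:
        raise ValueError("no evaluation points")
    if n_basis < degree + 1:
        raise ValueError(f"n_basis={n_basis} < degree+1={degree + 1}")
    lo = float(positions.min()) if lo is None else float(lo)
    hi = float(positions.max()) if hi is None else float(hi)
    if hi <= lo:
        hi = lo + 1.0
    n_segments = n_basis - degree
    h = (hi - lo) / n_segments
    knots = lo + h * np.arange(-degree, n_segments + degree + 1)
    basis = SplineBasis(knots, degree, positions, np.zeros((0, 0)), lo, hi)
    design = basis.evaluate(positions)
    basis.design = design
    return basis


def difference_penalty(n_basis: int, order: int = 2) -> np.ndarray:
    """P = DᵀD with D the ``order``-th difference matrix: penalizes
    wiggliness, annihilates polynomials in the coefficients up to
    ``order - 1``."""
    D = np.diff(np.eye(n_basis), n=order, axis=0)
    return D.T @ D


def fit_pspline(y, weights, basis: SplineBasis, penalty: np.ndarray,
                stiffness: float, design: np.ndarray | None = None
                ) -> np.ndarray:
    """Minimize Σ w (y − Bθ)² + stiffness·θᵀPθ; returns coefficients θ."""
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.all(w <= 0):
        raise ValueError("all weights are zero")
    B = basis.design if design is None else design
    BtW = B.T * w
    BtWB = BtW @ B
    H = BtWB + stiffness * penalty
    rhs = BtW @ y
    # small data-scaled ridge guards rank deficiency when data do not
    # cover all splines (it must not grow with the stiffness, or it would
    # shrink the penalty's null space)
    H += 1e-10 * np.mean(np.diag(BtWB)) * np.eye(H.shape[0])
    return scipy.linalg.solve(H, rhs, assume_a="pos")


def _reml_criterion(log_lambda: float, BtWB, BtWy, ytWy, penalty, n_obs,
                    null_dim: int, pen_eigs: np.ndarray) -> float:
    lam = np.exp(log_lambda)
    p = BtWB.shape[0]
    H = BtWB + lam * penalty + 1e-10 * np.mean(np.diag(BtWB)) * np.eye(p)
    try:
        cho = scipy.linalg.cho_factor(H)
    except scipy.linalg.LinAlgError:
        return np.inf
    beta = scipy.linalg.cho_solve(cho, BtWy)
    D = ytWy - 2 * beta @ BtWy + beta @ (BtWB + lam * penalty) @ beta
    D = max(D, 1e-12)
    nq = max(n_obs - null_dim, 1)
    sigma2 = D / nq
    logdet_H = 2 * np.sum(np.log(np.diag(cho[0])))
    logdet_pen = (p - null_dim) * np.log(lam) + np.sum(np.log(pen_eigs))
    return D / sigma2 + nq * np.log(sigma2) + logdet_H - logdet_pen


def select_stiffness_reml(y, weights, basis: SplineBasis, penalty: np.ndarray,
                          log_lambda_bounds=(-10.0, 20.0),
                          n_obs: int | None = None,
                          sufficient: tuple | None = None) -> float:
    """Stiffness maximizing the restricted marginal likelihood of the
    Gaussian working model y_i ~ N((Bθ)_i, σ²/w_i), θ ~ N(0, σ²(λP)⁻).

    ``sufficient`` optionally supplies precomputed ``(BtWB, BtWy, ytWy,
    n_obs)`` so callers can aggregate large working sets once.  Degenerate
    inputs (no residual variance) return the upper search bound.
    """
    if sufficient is not None:
        BtWB, BtWy, ytWy, n_obs = sufficient
    else:
        y = np.asarray(y, dtype=float)
        w = np.asarray(weights, dtype=float)
        if np.all(w <= 0):
            raise ValueError("all weights are zero")
        B = basis.design
        BtWB = (B.T * w) @ B
        BtWy = (B.T * w) @ y
        ytWy = float(y @ (w * y))
        if n_obs is None:
            n_obs = int(np.sum(w > 0))
    eigs = np.linalg.eigvalsh(penalty)
    null_dim = int(np.sum(eigs < 1e-10 * max(eigs.max(), 1.0)))
    pen_eigs = eigs[eigs >= 1e-10 * max(eigs.max(), 1.0)]
    res = scipy.optimize.minimize_scalar(
        _reml_criterion,
        bounds=log_lambda_bounds,
        args=(BtWB, BtWy, ytWy, penalty, n_obs, null_dim, pen_eigs),
        method="bounded", options={"xatol": 1e-3})
    if not np.isfinite(res.fun):
        return float(np.exp(log_lambda_bounds[1]))
    return float(np.exp(res.x))


def effective_dof(weights, basis: SplineBasis, penalty: np.ndarray,
                  stiffness: float) -> float:
    """trace of the smoother matrix: effective degrees of freedom."""
    w = np.asarray(weights, dtype=float)
    B = basis.design
    BtWB = (B.T * w) @ B
    H = BtWB + stiffness * penalty
    H += 1e-10 * np.mean(np.diag(H)) * np.eye(H.shape[0])
    return float(np.trace(scipy.linalg.solve(H, BtWB, assume_a="pos")))


@dataclass
class DecayFunction:
    """Monotone non-increasing contact decay on log10 genomic distance."""

    basis: SplineBasis        # over log10 distance
    coef: np.ndarray          # non-increasing
    min_distance: float = 1000.0

    def log_decay(self, distance_bp) -> np.ndarray:
        """f at the given distances (bp), on the log scale of the means."""
        x = np.log10(np.clip(np.asarray(distance_bp, dtype=float),
                             self.min_distance, None))
        return self.basis.evaluate(x) @ self.coef

    def __call__(self, distance_bp) -> np.ndarray:
        return self.log_decay(distance_bp)


def fit_monotone_decay(log_distance, y, weights, basis: SplineBasis,
                       penalty_order: int = 2, stiffness: float = 1.0,
                       min_distance: float = 1000.0) -> DecayFunction:
    """Penalized WLS fit constrained to a non-increasing curve.

    Parametrizes θ_k = u_1 + Σ_{2..k} u_m with u_m ≤ 0 for m ≥ 2 (so
    coefficients, hence the curve, are non-increasing) and solves the
    resulting bound-constrained least squares with the smoothness penalty
    appended as extra rows.
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.all(w <= 0):
        raise ValueError("all weights are zero")
    B = basis.evaluate(np.asarray(log_distance, dtype=float))
    p = basis.n_basis
    C = np.tril(np.ones((p, p)))          # θ = C u
    sw = np.sqrt(np.maximum(w, 0.0))
    Dm = np.diff(np.eye(p), n=penalty_order, axis=0)
    A = np.vstack([(B * sw[:, None]) @ C, np.sqrt(stiffness) * (Dm @ C)])
    b = np.concatenate([sw * y, np.zeros(Dm.shape[0])])
    lb = np.full(p, -np.inf)
    ub = np.full(p, np.inf)
    ub[1:] = 0.0
    res = scipy.optimize.lsq_linear(A, b, bounds=(lb, ub), tol=1e-12,
                                    max_iter=500)
    coef = C @ res.x
    return DecayFunction(basis, coef, min_distance=min_distance)
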
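"""Negative-binomial likelihood, mean model and IRLS working quantities.

Counts are modeled as NB(μ, α) with Var(y) = μ + αμ² (α is the inverse of
the "size" parameter; α → 0 recovers Poisson).  Means are log-linear:

* contact between cut sites i < j in a quadrant q:
  log μ = exposure_contact + bias_q(i, j) + f(d_ij) + s_ij, where bias_q
  picks the left/right genomic efficiencies of the two anchors from the
  quadrant geometry (up: ι_i + ι_j; down: ρ_i + ρ_j; close: ρ_i + ι_j;
  far: ι_i + ρ_j);
* left/right dangling ends at site i run *against* the local efficiency
  (poorly ligating sites accumulate dangling ends):
  log μ = exposure_dangling_L − ι_i (resp. exposure_dangling_R − ρ_i);
* rejoined ends track the geometric-average bias:
  log μ = exposure_rejoined + (ι_i + ρ_i)/2.

The IRLS working response/weight for the log link are z = log μ + (y−μ)/μ
and w = μ/(1 + αμ); all refits in the package are weighted least squares on
these quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.special

QUADRANT_BIAS = {
    # quadrant -> (side of anchor i, side of anchor j); "l" = ι, "r" = ρ
    "up": ("l", "l"),
    "down": ("r", "r"),
    "close": ("r", "l"),
    "far": ("l", "r"),
}

ALPHA_BRACKET = (1e-4, 10.0)


def nb_log_likelihood(y, mu, alpha) -> float:
    """Exact NB log pmf summed over observations (Var = μ + αμ²)."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if alpha <= 0:
        raise ValueError("dispersion must be > 0")
    if np.any(mu <= 0):
        raise ValueError("means must be > 0")
    r = 1.0 / alpha
    # log pmf = lgamma(y+r) - lgamma(r) - lgamma(y+1)
    #           + r log(r/(r+mu)) + y log(mu/(r+mu))
    ll = (scipy.special.gammaln(y + r) - scipy.special.gammaln(r)
          - scipy.special.gammaln(y + 1.0)
          + r * (np.log(r) - np.log(r + mu))
          + y * (np.log(mu) - np.log(r + mu)))
    return float(np.sum(ll))


@dataclass
class MeanModel:
    """Log-scale mean parametrization shared by all count classes."""

    iota: np.ndarray            # per-cut-site left bias ι_i
    rho: np.ndarray             # per-cut-site right bias ρ_i
    decay: object               # callable: distance bp -> f (log scale)
    exposures: dict = field(default_factory=lambda: {
        "contact": 0.0, "dangling_L": 0.0, "dangling_R": 0.0, "rejoined": 0.0})

    def contact_log_mean(self, i, j, quadrant, distance_bp, signal=0.0):
        i = np.asarray(i)
        j = np.asarray(j)
        side_i, side_j = QUADRANT_BIAS[quadrant]
        bi = self.iota[i] if side_i == "l" else self.rho[i]
        bj = self.iota[j] if side_j == "l" else self.rho[j]
        return (self.exposures["contact"] + bi + bj
                + self.decay(distance_bp) + signal)

    def contact_mean(self, i, j, quadrant, distance_bp, signal=0.0):
        d = np.asarray(distance_bp, dtype=float)
        if np.any(d < getattr(self.decay, "min_distance", 1000.0)):
            raise ValueError("contact distance below the modeling floor")
        return np.exp(self.contact_log_mean(i, j, quadrant, d, signal))

    def dangling_mean(self, i, side: str):
        if side in ("L", "l", "left"):
            return np.exp(self.exposures["dangling_L"] - self.iota[np.asarray(i)])
        if side in ("R", "r", "right"):
            return np.exp(self.exposures["dangling_R"] - self.rho[np.asarray(i)])
        raise ValueError(f"side must be L or R, got {side!r}")

    def rejoined_mean(self, i):
        i = np.asarray(i)
        return np.exp(self.exposures["rejoined"]
                      + 0.5 * (self.iota[i] + self.rho[i]))


def irls_update(y, mu, alpha) -> tuple[np.ndarray, np.ndarray]:
    """Working response and weight of the log-link NB: z = log μ + (y−μ)/μ,
    w = μ/(1 + αμ).  α = 0 is the Poisson limit (w = μ)."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("means must be > 0")
    z = np.log(mu) + (y - mu) / mu
    w = mu / (1.0 + alpha * mu)
    return z, w


def _row_alpha_mle(y, mu, bracket=ALPHA_BRACKET) -> float:
    """1-D bounded MLE of the dispersion on one row, on the log-α scale."""
    def neg_ll(log_alpha):
        return -nb_log_likelihood(y, mu, float(np.exp(log_alpha)))

    res = scipy.optimize.minimize_scalar(
        neg_ll, bounds=(np.log(bracket[0]), np.log(bracket[1])),
        method="bounded", options={"xatol": 1e-6})
    return float(np.exp(res.x))


def estimate_dispersion(counts_by_row, means_by_row, n_rows: int = 100,
                        seed: int | None = None) -> float:
    """Median of per-row dispersion MLEs.

    ``counts_by_row``/``means_by_row`` are sequences of per-row count and
    mean vectors covering *all* cells of the row, including zeros.  When
    more rows are available than ``n_rows``, an evenly spaced deterministic
    subset is used (a seeded random subset if ``seed`` is given).
    """
    rows = [(np.asarray(y, dtype=float), np.asarray(m, dtype=float))
            for y, m in zip(counts_by_row, means_by_row)]
    rows = [(y, m) for y, m in rows if len(y) > 0 and np.any(m > 0)]
    if not rows:
        raise ValueError("no usable rows for dispersion estimation")
    if len(rows) > n_rows:
        if seed is not None:
            rng = np.random.default_rng(seed)
            idx = np.sort(rng.choice(len(rows), size=n_rows, replace=False))
        else:
            idx = np.unique(np.linspace(0, len(rows) - 1, n_rows).astype(int))
        rows = [rows[k] for k in idx]
    estimates = [_row_alpha_mle(y, m) for y, m in rows]
    return float(np.median(estimates))
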
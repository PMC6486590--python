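"""Synthetic Hi-C data with known ground truth.

Generates reads-intersection tables from the same generative model the
normalization assumes: restriction cut sites with exponential spacing,
smooth per-site left/right efficiencies ι/ρ, a power-law contact decay,
NB-distributed counts with dispersion α, and optional rectangular signal
patches (log fold change over the background).  Read geometry is placed so
that classification recovers the generating category: contact ends point
toward their cut-site intersection, dangling ends start exactly on a cut
site, rejoined molecules span exactly one site, random reads stay inside
one fragment, and self-circles diverge toward the two ends of a fragment.

This is the reference workload for every test in the package; what it does
*not* emulate (mapping errors, copy-number variation, trans contacts,
chimeric reads) is documented in the methods note.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from binless.classify import CutSiteMap
from binless.io import INTERSECTION_COLUMNS, write_intersection_file, write_cutsites
from binless.nb import MeanModel, QUADRANT_BIAS


@dataclass
class PowerLawDecay:
    """True decay f(d) = −γ·ln(d / d_ref), zero at the reference distance."""

    gamma: float = 1.0
    d_ref: float = 1000.0
    min_distance: float = 1000.0

    def __call__(self, distance_bp):
        d = np.clip(np.asarray(distance_bp, dtype=float), self.min_distance, None)
        return -self.gamma * np.log(d / self.d_ref)


@dataclass
class SignalPatch:
    """Rectangle [x_lo, x_hi] × [y_lo, y_hi] (bp, x ≤ y side) with a log
    fold change over the background."""

    x_lo: int
    x_hi: int
    y_lo: int
    y_hi: int
    log_fc: float


@dataclass
class SimulationConfig:
    """Fully specified generative model for one cis locus.

    Defaults describe a desk-scale 4-cutter locus: 200 kb with ~400 bp
    mean fragment length (≈500 cut sites), smooth biases of ±0.4 on the
    log scale, a d⁻¹ contact decay, moderate overdispersion, and mean
    counts typical of a deeply sequenced capture experiment (≈3 expected
    contacts per cut-site quadrant at 1 kb).
    """

    chrom: str = "chrSim"
    chrom_length: int = 200_000
    cutsite_spacing: float = 400.0
    bias_amplitude: float = 0.4
    bias_waves: int = 4
    decay_gamma: float = 1.0
    alpha: float = 0.2
    mean_contact_at_ref: float = 3.0     # expected count per quadrant cell at 1 kb
    mean_dangling: float = 20.0          # per cut site and side, at ι=ρ=0
    mean_rejoined: float = 10.0
    rate_random: float = 0.5             # genomic-DNA pairs per fragment
    rate_self_circle: float = 1.0        # per fragment
    sonication_mean: float = 200.0       # molecule length, log-normal median
    sonication_sigma: float = 0.35
    read_length: int = 50
    min_distance: int = 1000
    max_offset: int = 900                # read-end offset cap from its cut site
    signal_patches: list = field(default_factory=list)
    seed: int = 0

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2)


@dataclass
class GroundTruth:
    """Realized parameters and expected counts of one simulation."""

    config: SimulationConfig
    cutsites: CutSiteMap
    iota: np.ndarray
    rho: np.ndarray
    decay: PowerLawDecay
    alpha: float
    exposures: dict
    # contact cells: all pairs i < j at >= min_distance
    pair_i: np.ndarray
    pair_j: np.ndarray
    pair_distance: np.ndarray
    pair_signal: np.ndarray              # log fold change per pair
    mu_contact: dict                     # quadrant -> expected count per pair
    mu_dangling_L: np.ndarray
    mu_dangling_R: np.ndarray
    mu_rejoined: np.ndarray

    def mean_model(self) -> MeanModel:
        return MeanModel(self.iota, self.rho, self.decay, dict(self.exposures))

    def signal_log_fc(self, pos_x, pos_y) -> np.ndarray:
        """True log fold change at (x, y) bp coordinates (x ≤ y side)."""
        pos_x = np.asarray(pos_x)
        pos_y = np.asarray(pos_y)
        s = np.zeros(np.broadcast(pos_x, pos_y).shape)
        for p in self.config.signal_patches:
            inside = ((pos_x >= p.x_lo) & (pos_x <= p.x_hi)
                      & (pos_y >= p.y_lo) & (pos_y <= p.y_hi))
            s = np.where(inside, s + p.log_fc, s)
        return s


def _smooth_curve(positions, length, amplitude, n_waves, rng) -> np.ndarray:
    """Centered random smooth curve: sum of low-frequency sinusoids."""
    x = np.asarray(positions, dtype=float)
    curve = np.zeros_like(x)
    for k in range(1, n_waves + 1):
        a = amplitude / np.sqrt(n_waves) * rng.normal(0, 1)
        phi = rng.uniform(0, 2 * np.pi)
        curve += a * np.sin(2 * np.pi * k * x / length + phi)
    return curve - curve.mean()


def simulate_truth(config: SimulationConfig) -> GroundTruth:
    """Draw cut sites, biases and assemble expected means for every cell."""
    rng = np.random.default_rng(config.seed)
    # cut sites: exponential spacing, kept strictly increasing and inside
    n_draw = int(2 * config.chrom_length / config.cutsite_spacing) + 10
    gaps = np.maximum(rng.exponential(config.cutsite_spacing, n_draw), 20.0)
    positions = np.cumsum(gaps).astype(np.int64) + 1000
    positions = positions[positions < config.chrom_length - 1000]
    positions = np.unique(positions)
    cutsites = CutSiteMap(config.chrom, positions, enzyme_name="synthetic")

    iota = _smooth_curve(positions, config.chrom_length, config.bias_amplitude,
                         config.bias_waves, rng)
    rho = _smooth_curve(positions, config.chrom_length, config.bias_amplitude,
                        config.bias_waves, rng)
    decay = PowerLawDecay(config.decay_gamma, min_distance=config.min_distance)
    exposures = {
        "contact": float(np.log(config.mean_contact_at_ref)),
        "dangling_L": float(np.log(config.mean_dangling)),
        "dangling_R": float(np.log(config.mean_dangling)),
        "rejoined": float(np.log(config.mean_rejoined)),
    }
    model = MeanModel(iota, rho, decay, exposures)

    n = len(positions)
    ii, jj = np.triu_indices(n, k=1)
    dist = positions[jj] - positions[ii]
    keep = dist >= config.min_distance
    ii, jj, dist = ii[keep], jj[keep], dist[keep]
    truth = GroundTruth(
        config=config, cutsites=cutsites, iota=iota, rho=rho, decay=decay,
        alpha=config.alpha, exposures=exposures,
        pair_i=ii, pair_j=jj, pair_distance=dist,
        pair_signal=np.zeros(len(ii)),
        mu_contact={},
        mu_dangling_L=model.dangling_mean(np.arange(n), "L"),
        mu_dangling_R=model.dangling_mean(np.arange(n), "R"),
        mu_rejoined=model.rejoined_mean(np.arange(n)),
    )
    truth.pair_signal = truth.signal_log_fc(positions[ii], positions[jj])
    adjacent = (jj - ii) == 1
    for quadrant in QUADRANT_BIAS:
        mu = model.contact_mean(ii, jj, quadrant, dist, truth.pair_signal)
        if quadrant == "close":
            # between neighboring cut sites the close quadrant is taken
            # over by self-circles and carries no contacts
            mu = np.where(adjacent, 0.0, mu)
        truth.mu_contact[quadrant] = mu
    return truth


def _draw_counts(rng, mu, alpha) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if not np.any(pos):
        return out
    if alpha < 1e-8:
        out[pos] = rng.poisson(mu[pos])
    else:
        r = 1.0 / alpha
        p = r / (r + mu[pos])
        out[pos] = rng.negative_binomial(r, p)
    return out


def _offsets(rng, cap, n=None) -> np.ndarray:
    """Integer offsets in [1, cap] (cap clipped below at 1)."""
    cap = np.asarray(np.maximum(cap, 1), dtype=np.int64)
    if n is not None:
        cap = np.broadcast_to(cap, (n,))
    return rng.integers(1, cap + 1)


def simulate_reads(truth: GroundTruth, seed: int | None = None,
                   with_labels: bool = False) -> pd.DataFrame:
    """Draw NB counts per cell and place the corresponding read pairs.

    Returns a reads-intersection table (shuffled row order) whose
    classification recovers the generating categories.  With
    ``with_labels`` an extra ``true_category`` column records the
    generating category of each read.
    """
    cfg = truth.config
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    P = truth.cutsites.positions
    n = len(P)
    gap_left = np.empty(n, dtype=np.int64)
    gap_right = np.empty(n, dtype=np.int64)
    gap_left[0] = P[0] - 1
    gap_left[1:] = P[1:] - P[:-1] - 1
    gap_right[:-1] = P[1:] - P[:-1] - 1
    gap_right[-1] = cfg.chrom_length - P[-1]
    max_off = cfg.max_offset
    cap_left = np.minimum(gap_left, max_off)     # room upstream of each site
    cap_right = np.minimum(gap_right, max_off)   # room downstream

    chunks = []

    def emit(p1, s1, p2, s2, label):
        m = len(p1)
        if m == 0:
            return
        chunks.append(pd.DataFrame({
            "true_category": label,
            "chrom1": cfg.chrom, "start1": p1.astype(np.int64),
            "length1": cfg.read_length, "strand1": np.where(s1 > 0, "+", "-"),
            "up_site1": _nearest(P, p1, "up"),
            "down_site1": _nearest(P, p1, "down"),
            "chrom2": cfg.chrom, "start2": p2.astype(np.int64),
            "length2": cfg.read_length, "strand2": np.where(s2 > 0, "+", "-"),
            "up_site2": _nearest(P, p2, "up"),
            "down_site2": _nearest(P, p2, "down"),
        }))

    # --- contacts, one block per quadrant ---
    for quadrant, mu in truth.mu_contact.items():
        counts = _draw_counts(rng, mu, truth.alpha)
        reps = np.repeat(np.arange(len(counts)), counts)
        if len(reps) == 0:
            continue
        i = truth.pair_i[reps]
        j = truth.pair_j[reps]
        if quadrant == "up":        # both ends upstream, pointing downstream
            p1 = P[i] - _offsets(rng, cap_left[i])
            p2 = P[j] - _offsets(rng, cap_left[j])
            s1 = s2 = np.ones(len(i))
        elif quadrant == "down":    # both ends downstream, pointing upstream
            p1 = P[i] + _offsets(rng, cap_right[i])
            p2 = P[j] + _offsets(rng, cap_right[j])
            s1 = s2 = -np.ones(len(i))
        elif quadrant == "close":   # diverging, inside the (i, j) interval
            p1 = P[i] + _offsets(rng, cap_right[i])
            p2 = P[j] - _offsets(rng, cap_left[j])
            s1, s2 = -np.ones(len(i)), np.ones(len(i))
        else:                       # far: converging, spanning both sites
            p1 = P[i] - _offsets(rng, cap_left[i])
            p2 = P[j] + _offsets(rng, cap_right[j])
            s1, s2 = np.ones(len(i)), -np.ones(len(i))
        emit(p1, s1, p2, s2, "contact_" + quadrant)

    # --- dangling ends: 5' start exactly on the cut site ---
    site_idx = np.arange(n)
    for side, mu in (("L", truth.mu_dangling_L), ("R", truth.mu_dangling_R)):
        counts = _draw_counts(rng, mu, truth.alpha)
        t = np.repeat(site_idx, counts)
        if len(t) == 0:
            continue
        mlen = _molecule_lengths(rng, cfg, len(t))
        if side == "L":
            span = np.minimum(mlen - 1, np.maximum(gap_right[t], 1))
            p1, p2 = P[t], P[t] + np.maximum(span, 1)
        else:
            span = np.minimum(mlen - 1, np.maximum(gap_left[t], 1))
            p1, p2 = P[t] - np.maximum(span, 1), P[t]
        emit(p1, np.ones(len(t)), p2, -np.ones(len(t)),
             "dangling_L" if side == "L" else "dangling_R")

    # --- rejoined: converging molecule spanning exactly one site ---
    counts = _draw_counts(rng, truth.mu_rejoined, truth.alpha)
    t = np.repeat(site_idx, counts)
    if len(t):
        a = _offsets(rng, np.minimum(cap_left[t], cfg.sonication_mean // 2))
        b = _offsets(rng, np.minimum(cap_right[t], cfg.sonication_mean // 2))
        emit(P[t] - a, np.ones(len(t)), P[t] + b, -np.ones(len(t)),
             "rejoined")

    # --- random genomic DNA: converging pair inside one fragment ---
    frag_len = gap_right[:-1]
    rand_counts = rng.poisson(cfg.rate_random, n - 1)
    t = np.repeat(np.arange(n - 1), rand_counts)
    if len(t):
        room = frag_len[t]
        usable = room >= 4
        t = t[usable]
        if len(t):
            room = frag_len[t]
            mlen = np.minimum(_molecule_lengths(rng, cfg, len(t)), room - 2)
            mlen = np.maximum(mlen, 2)
            start_max = room - mlen
            a = 1 + (rng.random(len(t)) * start_max).astype(np.int64)
            p1 = P[t] + a
            p2 = p1 + mlen - 1
            emit(p1, np.ones(len(t)), p2, -np.ones(len(t)), "random")

    # --- self-circles: diverging toward the two ends of a fragment ---
    sc_counts = rng.poisson(cfg.rate_self_circle, n - 1)
    t = np.repeat(np.arange(n - 1), sc_counts)
    if len(t):
        room = frag_len[t]
        usable = room >= 4
        t = t[usable]
        if len(t):
            half = np.maximum(frag_len[t] // 2, 1)
            o1 = _offsets(rng, np.minimum(half, max_off))
            o2 = _offsets(rng, np.minimum(half, max_off))
            emit(P[t] + o1, -np.ones(len(t)), P[t + 1] - o2,
                 np.ones(len(t)), "self_circle")

    if not chunks:
        from binless.io import empty_reads_table
        return empty_reads_table()
    reads = pd.concat(chunks, ignore_index=True)
    reads = reads.iloc[rng.permutation(len(reads))].reset_index(drop=True)
    cols = INTERSECTION_COLUMNS + (["true_category"] if with_labels else [])
    return reads[cols]


def _molecule_lengths(rng, cfg: SimulationConfig, n: int) -> np.ndarray:
    lens = rng.lognormal(np.log(cfg.sonication_mean), cfg.sonication_sigma, n)
    return np.maximum(lens.astype(np.int64), 2)


def _nearest(P, pos, which: str) -> np.ndarray:
    pos = np.asarray(pos, dtype=np.int64)
    if which == "up":
        idx = np.searchsorted(P, pos, side="right") - 1
        return np.where(idx >= 0, P[np.clip(idx, 0, None)], -1)
    idx = np.searchsorted(P, pos, side="left")
    return np.where(idx < len(P), P[np.clip(idx, None, len(P) - 1)], -1)


def write_fixture(reads: pd.DataFrame, truth: GroundTruth, out_dir) -> dict:
    """Write reads TSV, cut-site BED and ground-truth tables; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "reads": out / "reads.tsv",
        "cutsites": out / "cutsites.bed",
        "biases": out / "true_biases.tsv",
        "config": out / "sim_config.json",
    }
    write_intersection_file(reads, paths["reads"])
    write_cutsites(truth.cutsites, paths["cutsites"])
    pd.DataFrame({"position": truth.cutsites.positions,
                  "iota": truth.iota, "rho": truth.rho}).to_csv(
        paths["biases"], sep="\t", index=False)
    paths["config"].write_text(truth.config.to_json())
    return paths
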
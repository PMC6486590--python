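"""Triangle-grid fused lasso: solver, patches, penalty selection."""

import numpy as np
import pytest

from binless.fused import (build_triangle_grid, count_patches, kkt_residual,
                           select_lambda1, select_lambda2_bic, soft_threshold,
                           solve_weighted_fused_lasso)
from conftest import rng_for
from oracles import fused_lasso_oracle


def test_single_bin_grid():
    g = build_triangle_grid(1)
    assert g.n_nodes == 1 and len(g.edges) == 0


def test_three_bin_grid_enumeration():
    g = build_triangle_grid(3)
    assert g.n_nodes == 6
    assert len(g.edges) == 6


@pytest.mark.parametrize("n_bins,cutoff", [(5, None), (8, 3), (12, 2)])
def test_edge_count_matches_brute_force_scan(n_bins, cutoff):
    g = build_triangle_grid(n_bins, cutoff)
    nodes = {tuple(n) for n in g.nodes}
    expected = 0
    for (a, b) in nodes:
        if (a, b + 1) in nodes:
            expected += 1
        if (a + 1, b) in nodes and a + 1 <= b:
            expected += 1
    assert len(g.edges) == expected
    # every node has at most 4 neighbors, no self edges
    deg = np.bincount(g.edges.ravel(), minlength=g.n_nodes)
    assert deg.max() <= 4
    assert np.all(g.edges[:, 0] != g.edges[:, 1])


def test_lambda2_zero_returns_input():
    rng = rng_for("fl-zero")
    g = build_triangle_grid(4)
    y = rng.normal(0, 1, g.n_nodes)
    w = rng.uniform(0.5, 2, g.n_nodes)
    assert np.array_equal(solve_weighted_fused_lasso(y, w, g, 0.0), y)


def test_lambda2_infinite_returns_weighted_mean():
    rng = rng_for("fl-inf")
    g = build_triangle_grid(5)
    y = rng.normal(0, 1, g.n_nodes)
    w = rng.uniform(0.5, 2, g.n_nodes)
    s = solve_weighted_fused_lasso(y, w, g, 1e6)
    assert np.max(np.abs(s - np.average(y, weights=w))) < 1e-6


def test_matches_generic_convex_solver_on_random_graphs():
    rng = rng_for("fl-oracle")
    worst = 0.0
    for _ in range(12):
        g = build_triangle_grid(int(rng.integers(2, 6)))
        y = rng.normal(0, 1, g.n_nodes)
        w = rng.uniform(0.2, 2.0, g.n_nodes)
        for lam2 in (0.0, 0.5, 2.5, 10.0):
            s = solve_weighted_fused_lasso(y, w, g, lam2)
            ref = fused_lasso_oracle(y, w, g.edges, lam2)
            worst = max(worst, float(np.max(np.abs(s - ref))))
    assert worst <= 1e-4


def test_kkt_residual_small_after_convergence():
    rng = rng_for("fl-kkt")
    g = build_triangle_grid(6)
    y = rng.normal(0, 1, g.n_nodes)
    w = rng.uniform(0.5, 2, g.n_nodes)
    s = solve_weighted_fused_lasso(y, w, g, 1.3)
    assert kkt_residual(y, w, g, 1.3, s) < 1e-5


def test_all_zero_weights_raise():
    g = build_triangle_grid(3)
    with pytest.raises(ValueError):
        solve_weighted_fused_lasso(np.ones(6), np.zeros(6), g, 1.0)


def test_patch_count_monotone_in_lambda2():
    rng = rng_for("fl-monotone")
    g = build_triangle_grid(8)
    y = rng.normal(0, 1, g.n_nodes)
    w = rng.uniform(0.5, 2, g.n_nodes)
    patches = []
    for lam2 in (0.1, 0.5, 1.0, 2.5, 5.0, 10.0, 30.0):
        s = solve_weighted_fused_lasso(y, w, g, lam2)
        n, _, _ = count_patches(s, g)
        patches.append(n)
    assert all(a >= b for a, b in zip(patches, patches[1:]))


# --- soft threshold ------------------------------------------------------

def test_soft_threshold_identities():
    s = np.array([0.5, 1.2, 2.0])
    assert np.array_equal(soft_threshold(s, 0.0), s)
    assert np.all(soft_threshold(s, 2.5) == 0.0)
    assert np.allclose(soft_threshold(s, 1.0), [0.0, 0.2, 1.0])


def test_soft_threshold_two_sided_for_differences():
    s = np.array([-2.0, -0.5, 0.0, 0.5, 2.0])
    out = soft_threshold(s, 1.0, two_sided=True)
    assert np.allclose(out, [-1.0, 0.0, 0.0, 0.0, 1.0])


def test_soft_threshold_negative_lambda_raises():
    with pytest.raises(ValueError):
        soft_threshold(np.ones(3), -0.1)


# --- patches -------------------------------------------------------------

def test_constant_input_is_one_patch():
    g = build_triangle_grid(6)
    n, sizes, _ = count_patches(np.full(g.n_nodes, 1.3), g)
    assert n == 1 and sizes[0] == g.n_nodes


def test_distinct_values_are_all_singletons():
    g = build_triangle_grid(5)
    n, _, _ = count_patches(np.arange(g.n_nodes, dtype=float), g)
    assert n == g.n_nodes


def test_patches_match_flood_fill_oracle():
    rng = rng_for("patch-flood")
    g = build_triangle_grid(9)
    values = rng.integers(0, 4, g.n_nodes).astype(float)
    n, sizes, density = count_patches(values, g, reads_per_bin=np.ones(g.n_nodes))
    # brute-force flood fill on equal-value adjacency
    index = {tuple(node): k for k, node in enumerate(g.nodes)}
    seen = set()
    comps = 0
    for start in range(g.n_nodes):
        if start in seen:
            continue
        comps += 1
        stack = [start]
        while stack:
            k = stack.pop()
            if k in seen:
                continue
            seen.add(k)
            a, b = g.nodes[k]
            for nb in ((a, b + 1), (a, b - 1), (a + 1, b), (a - 1, b)):
                other = index.get(nb)
                if other is not None and other not in seen \
                        and values[other] == values[k]:
                    stack.append(other)
    assert n == comps
    assert np.allclose(density, 1.0)
    assert sizes.sum() == g.n_nodes


# --- penalty selection ---------------------------------------------------

def test_bic_value_matches_hand_formula():
    rng = rng_for("bic-hand")
    g = build_triangle_grid(4)
    y = rng.normal(0, 1, g.n_nodes)
    w = rng.uniform(0.5, 2, g.n_nodes)
    lam2, s, trace = select_lambda2_bic(y, w, g, lam2_grid=[1.7])
    rss = np.sum(w * (y - s) ** 2)
    df, _, _ = count_patches(s, g)
    expected = rss + df * np.log(np.sum(w > 0))
    assert np.isclose(trace[0][2], expected)


def test_bic_recovers_planted_three_patch_signal():
    """Three planted levels come back as three dominant patches at the
    planted values (small boundary halos of a few bins are a known fused
    lasso artifact and are not counted)."""
    rng = rng_for("bic-3patch")
    g = build_triangle_grid(12)
    nodes = g.nodes
    hi = (nodes[:, 0] < 4) & (nodes[:, 1] < 4)
    lo = (nodes[:, 0] >= 8) & (nodes[:, 1] >= 8)
    truth = np.where(hi, 2.0, np.where(lo, -2.0, 0.0))
    w = np.full(g.n_nodes, 200.0)
    y = truth + rng.normal(0, 1, g.n_nodes) / np.sqrt(w)
    lam2, s, _ = select_lambda2_bic(y, w, g)
    n, sizes, _ = count_patches(s, g)
    assert np.sum(sizes >= 5) == 3
    assert abs(np.median(s[hi]) - 2.0) < 0.15
    assert abs(np.median(s[lo]) + 2.0) < 0.15
    assert abs(np.median(s[~hi & ~lo])) < 0.15


def test_bic_prefers_fewer_patches_than_interpolation_on_noise():
    rng = rng_for("bic-noise")
    g = build_triangle_grid(8)
    y = rng.normal(0, 1, g.n_nodes)
    w = np.full(g.n_nodes, 4.0)
    lam2, s, _ = select_lambda2_bic(y, w, g)
    df, _, _ = count_patches(s, g)
    assert df <= g.n_nodes


def test_lambda1_zeroes_background_only_simulation():
    rng = rng_for("lam1-null")
    g = build_triangle_grid(15)
    w = np.full(g.n_nodes, 30.0)
    y = rng.normal(0, 1, g.n_nodes) / np.sqrt(w)
    lam2, s, _ = select_lambda2_bic(y, w, g)
    lam1 = select_lambda1(s, w, g)
    thr = soft_threshold(s, lam1)
    assert np.mean(thr == 0) >= 0.95


def test_lambda1_keeps_strong_planted_patch():
    rng = rng_for("lam1-patch")
    g = build_triangle_grid(12)
    nodes = g.nodes
    block = (nodes[:, 0] >= 3) & (nodes[:, 0] < 9) \
        & (nodes[:, 1] >= 3) & (nodes[:, 1] < 9)
    assert block.sum() >= 20
    w = np.full(g.n_nodes, 200.0)
    y = np.where(block, np.log(2.0), 0.0) \
        + rng.normal(0, 1, g.n_nodes) / np.sqrt(w)
    lam2, s, _ = select_lambda2_bic(y, w, g)
    lam1 = select_lambda1(s, w, g)
    thr = soft_threshold(s, lam1)
    assert thr[block].mean() > 0
    assert np.mean(thr[~block] == 0) >= 0.9


def test_lambda1_of_all_zero_signal_outputs_zeros():
    g = build_triangle_grid(5)
    s = np.zeros(g.n_nodes)
    lam1 = select_lambda1(s, np.full(g.n_nodes, 3.0), g)
    assert np.all(soft_threshold(s, lam1) == 0)
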
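"""Fast binned normalization, directionality index, parameter proposal."""

import numpy as np
import pandas as pd
import pytest

from binless.classify import CONTACT_CATEGORIES, filter_short_range
from binless.fast import (BinnedData, FastParams, bin_data,
                          directionality_index, fast_normalize,
                          rank_loci_by_di)


def manual_binned(cells, n_bins, resolution=1000):
    bi = np.array([c[0] for c in cells], dtype=np.int64)
    bj = np.array([c[1] for c in cells], dtype=np.int64)
    counts = np.array([c[2] for c in cells], dtype=np.int64)
    return BinnedData(resolution, n_bins, 0, bi, bj, counts)


def test_bin_single_contact():
    df = pd.DataFrame({"category": ["contact_up"], "pos_i": [2500],
                       "pos_j": [7500]})
    binned = bin_data(df, 5000, start=0, end=10_000)
    assert binned.total == 1
    assert (binned.bin_i[0], binned.bin_j[0]) == (0, 1)


def test_binning_conserves_counts_and_matches_groupby(micro_classified):
    classified, _ = micro_classified
    classified = filter_short_range(classified)
    con = classified[classified["category"].isin(CONTACT_CATEGORIES)]
    binned = bin_data(classified, 5000, start=0, end=40_000)
    assert binned.total == len(con)
    oracle = con.groupby([con["pos_i"] // 5000, con["pos_j"] // 5000]).size()
    ours = {(i, j): c for i, j, c in
            zip(binned.bin_i, binned.bin_j, binned.counts)}
    assert ours == {k: v for k, v in oracle.items()}


def test_distance_cutoff_drops_far_cells():
    df = pd.DataFrame({"category": ["contact_up", "contact_up"],
                       "pos_i": [500, 500], "pos_j": [1500, 9500]})
    binned = bin_data(df, 1000, cutoff=2000, start=0, end=10_000)
    assert binned.total == 1


# --- directionality index ------------------------------------------------

def test_di_arithmetic_example():
    # bin 1 sees A=10 upstream, B=2 downstream: DI = -16/3
    binned = manual_binned([(0, 1, 10), (1, 2, 2)], 3)
    prof = directionality_index(binned, window_bp=1000)
    assert np.isclose(prof.di[1], -16.0 / 3.0)


def test_di_symmetric_window_is_zero():
    binned = manual_binned([(0, 1, 7), (1, 2, 7)], 3)
    prof = directionality_index(binned, window_bp=1000)
    assert prof.di[1] == 0.0


def test_di_empty_window_is_zero():
    binned = manual_binned([(0, 1, 3)], 5)
    prof = directionality_index(binned, window_bp=1000)
    assert prof.di[3] == 0.0 and prof.di[4] == 0.0


def test_di_antisymmetric_under_mirror():
    rng = np.random.default_rng(8)
    n = 20
    cells = [(i, j, int(rng.integers(0, 20)))
             for i in range(n) for j in range(i, n)]
    binned = manual_binned(cells, n)
    mirrored = manual_binned(
        [(n - 1 - j, n - 1 - i, c) for i, j, c in cells], n)
    a = directionality_index(binned, window_bp=4000).di
    b = directionality_index(mirrored, window_bp=4000).di
    assert np.allclose(a, -b[::-1])


def test_di_window_below_resolution_rejected():
    binned = manual_binned([(0, 1, 1)], 3)
    with pytest.raises(ValueError):
        directionality_index(binned, window_bp=10)


# --- fast normalization --------------------------------------------------

def test_fast_params_validation():
    with pytest.raises(ValueError):
        FastParams(alpha=-1, lambda1=0.1, lambda2=1.0)
    with pytest.raises(ValueError):
        FastParams(alpha=0.1, lambda1=0.1, lambda2=0.0)


def test_fast_normalize_empty_matrix_errors():
    binned = manual_binned([], 5)
    with pytest.raises(ValueError):
        fast_normalize(binned, FastParams(0.1, 0.0, 2.5))


def test_fast_normalize_recovers_bias_and_decay():
    """On a binned simulation with ~12 cut sites per bin the per-bin
    biases track the averaged per-site efficiencies and the decay is
    monotone by construction."""
    from binless.classify import classify_all
    from binless.simulate import SimulationConfig, simulate_reads, simulate_truth

    cfg = SimulationConfig(chrom_length=150_000, cutsite_spacing=400, seed=21)
    truth = simulate_truth(cfg)
    classified, _ = classify_all(simulate_reads(truth), truth.cutsites)
    classified = filter_short_range(classified)
    res = 5000
    binned = bin_data(classified, res, start=0, end=cfg.chrom_length)
    result = fast_normalize(binned, FastParams(cfg.alpha, 0.0, 2.5,
                                               base_resolution=res))
    assert np.all(np.diff(result.decay_log) <= 1e-9)
    P = truth.cutsites.positions
    bins = P // res
    n_sites = np.bincount(bins, minlength=binned.n_bins)
    used = n_sites > 0
    btruth = np.zeros(binned.n_bins)
    for b in np.nonzero(used)[0]:
        sel = bins == b
        # a cell mean carries bias_i + bias_j: the per-bin fast bias
        # estimates the bin-averaged (iota + rho)/2 of its sites, plus the
        # log cut-site density (more fragments per bin -> more read pairs)
        btruth[b] = 0.5 * (truth.iota[sel] + truth.rho[sel]).mean()
    btruth[used] += np.log(n_sites[used] / n_sites[used].mean())
    corr = np.corrcoef(result.biases[used], btruth[used])[0, 1]
    assert corr >= 0.9


def test_fast_distance_cutoff_limits_fitted_cells():
    rng = np.random.default_rng(9)
    n = 10
    cells = [(i, j, int(rng.integers(1, 10)))
             for i in range(n) for j in range(i, n)]
    binned = manual_binned(cells, n)
    binned.cutoff_bins = 1
    result = fast_normalize(binned, FastParams(0.1, 0.0, 2.5))
    d = result.grid.nodes[:, 1] - result.grid.nodes[:, 0]
    assert d.max() <= 1


def test_rank_loci_is_deterministic():
    rng = np.random.default_rng(10)
    n = 40
    cells = [(i, j, int(rng.integers(0, 30)))
             for i in range(n) for j in range(i, min(i + 10, n))]
    binned = manual_binned(cells, n)
    a = rank_loci_by_di(binned, locus_span=10_000, window_bp=3000)
    b = rank_loci_by_di(binned, locus_span=10_000, window_bp=3000)
    pd.testing.assert_frame_equal(a, b)
    assert (a["sd_di"].to_numpy()[:-1] >= a["sd_di"].to_numpy()[1:]).all()


def test_estimate_fast_parameters_on_synthetic_chromosome():
    """The DI-ranked locus proposal returns usable binned-scale
    parameters: positive dispersion far below the per-cell value (one
    bin pools hundreds of cells), and penalties from the selection
    grids; the proposal is deterministic."""
    from binless.classify import classify_all
    from binless.fast import estimate_fast_parameters
    from binless.simulate import SimulationConfig, simulate_reads, simulate_truth

    cfg = SimulationConfig(chrom_length=200_000, cutsite_spacing=500, seed=33)
    truth = simulate_truth(cfg)
    classified, _ = classify_all(simulate_reads(truth), truth.cutsites)
    classified = filter_short_range(classified)
    binned = bin_data(classified, 5000, start=0, end=cfg.chrom_length)
    kwargs = dict(n_loci=1, locus_span=100_000, window_bp=20_000)
    params = estimate_fast_parameters(classified, truth.cutsites, binned,
                                      **kwargs)
    assert 0 < params.alpha < cfg.alpha      # rescaled by cells per bin
    assert params.lambda2 > 0 and params.lambda1 >= 0
    again = estimate_fast_parameters(classified, truth.cutsites, binned,
                                     **kwargs)
    assert (params.alpha, params.lambda1, params.lambda2) \
        == (again.alpha, again.lambda1, again.lambda2)
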
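"""Output matrices at any resolution.

From one converged normalization every matrix kind can be assembled at the
base resolution and re-binned coarser afterwards: raw counts, genomic-bias
and decay backgrounds, the bias-corrected (normalized) matrix with IRLS
error estimates, the sparse signal (exp of the thresholded log signal,
a minimum fold change over the background), the "binless" matrix
(signal × decay, visually closest to the raw data) and sparse differences
between datasets.  Matrices serialize to a long-format TSV with 0-based
half-open coordinates (1-based inclusive coordinates are used in logs and
CLI echoes only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from binless import fused
from binless.optimized import (DifferenceState, NormalizationState,
                               SignalEstimate, _engine_of, estimate_signal)

KINDS = ("raw", "genomic_bias", "decay", "normalized", "normalized_error",
         "signal", "binless", "difference")
#: kinds re-binned by count-weighted averaging of the log values
_RATIO_KINDS = ("genomic_bias", "decay", "signal", "binless", "difference")


@dataclass
class BinnedMatrix:
    kind: str
    resolution: int
    chrom: str
    start: int                    # 0-based genomic coordinate of bin 0
    n_bins: int
    data: pd.DataFrame            # bin1, bin2, value [, error], weight
    dataset: str = "dataset"

    def dense(self) -> np.ndarray:
        out = np.zeros((self.n_bins, self.n_bins))
        b1 = self.data["bin1"].to_numpy(int)
        b2 = self.data["bin2"].to_numpy(int)
        v = self.data["value"].to_numpy(float)
        out[b1, b2] = v
        out[b2, b1] = v
        return out


def _node_table(grid: fused.TriangleGrid, values, weights, errors=None
                ) -> pd.DataFrame:
    df = pd.DataFrame({"bin1": grid.nodes[:, 0], "bin2": grid.nodes[:, 1],
                       "value": np.asarray(values, dtype=float)})
    if errors is not None:
        df["error"] = np.asarray(errors, dtype=float)
    df["weight"] = np.asarray(weights, dtype=float)
    return df


def extract_matrix(state: NormalizationState, kind: str, resolution: int,
                   signal: SignalEstimate | None = None,
                   difference: DifferenceState | None = None,
                   dataset: str | None = None) -> BinnedMatrix:
    """Assemble one matrix kind at the requested resolution.

    ``resolution`` must be a multiple of the state's base resolution.
    ``signal``/``binless`` use the supplied :class:`SignalEstimate` (one is
    estimated on the fly if missing); ``difference`` requires a
    :class:`DifferenceState` and the dataset name within it.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown matrix kind {kind!r}; one of {KINDS}")
    base = state.config.base_resolution
    if resolution % base != 0:
        raise ValueError(f"resolution {resolution} not a multiple of {base}")
    eng = _engine_of(state)
    grid = state.grid
    locus = state.locus
    nn = grid.n_nodes
    name = dataset or locus.name

    counts = eng.node_read_counts()
    if kind == "raw":
        mat = BinnedMatrix("raw", base, locus.chrom, locus.start, grid.n_bins,
                           _node_table(grid, counts, counts), name)
        return rebin(mat, resolution)

    i, j = locus.pair_i, locus.pair_j
    npair = np.bincount(eng.bin_of_pair, minlength=nn).astype(float)
    if kind == "genomic_bias":
        # mean over the four quadrant combinations of exp(bias_i + bias_j)
        v_pair = np.exp(0.5 * (state.iota[i] + state.rho[i]
                               + state.iota[j] + state.rho[j]))
        acc = np.bincount(eng.bin_of_pair, weights=v_pair, minlength=nn)
        vals = np.divide(acc, npair, out=np.ones(nn), where=npair > 0)
        mat = BinnedMatrix(kind, base, locus.chrom, locus.start, grid.n_bins,
                           _node_table(grid, vals, counts), name)
        return rebin(mat, resolution)
    if kind == "decay":
        f_pair = np.exp(state.decay(locus.pair_distance))
        acc = np.bincount(eng.bin_of_pair, weights=f_pair, minlength=nn)
        vals = np.divide(acc, npair, out=np.ones(nn), where=npair > 0)
        mat = BinnedMatrix(kind, base, locus.chrom, locus.start, grid.n_bins,
                           _node_table(grid, vals, counts), name)
        return rebin(mat, resolution)
    if kind in ("normalized", "normalized_error"):
        etas, z, w = eng.working(state)
        s_pair = state.signal_of_pair()
        f_pair = state.decay(locus.pair_distance)
        num = np.zeros(nn)
        den = np.zeros(nn)
        wsum = np.zeros(nn)
        for q, y in eng.counts.items():
            m = eng.masks[q]
            # expected under exposure+biases only: observed / this = decay*signal scale
            exp_bias = np.exp(etas[q] - f_pair - s_pair) * m
            num += np.bincount(eng.bin_of_pair, weights=y * m, minlength=nn)
            den += np.bincount(eng.bin_of_pair, weights=exp_bias, minlength=nn)
            wsum += np.bincount(eng.bin_of_pair, weights=w[q], minlength=nn)
        vals = np.divide(num, den, out=np.zeros(nn), where=den > 0)
        err = np.divide(1.0, np.sqrt(wsum), out=np.full(nn, np.inf),
                        where=wsum > 0)
        if kind == "normalized_error":
            mat = BinnedMatrix(kind, base, locus.chrom, locus.start,
                               grid.n_bins, _node_table(grid, err, counts), name)
        else:
            mat = BinnedMatrix(kind, base, locus.chrom, locus.start,
                               grid.n_bins,
                               _node_table(grid, vals, counts, errors=err), name)
        return rebin(mat, resolution)
    if kind in ("signal", "binless"):
        if signal is None:
            signal = estimate_signal(state)
        s = signal.s_thresholded
        if kind == "signal":
            vals = np.exp(s)
        else:
            f_pair = np.exp(state.decay(locus.pair_distance))
            acc = np.bincount(eng.bin_of_pair, weights=f_pair, minlength=nn)
            decay_bin = np.divide(acc, npair, out=np.ones(nn), where=npair > 0)
            vals = np.exp(s) * decay_bin
        mat = BinnedMatrix(kind, base, locus.chrom, locus.start, grid.n_bins,
                           _node_table(grid, vals, counts), name)
        return rebin(mat, resolution)
    # difference
    if difference is None:
        raise ValueError("kind='difference' requires a DifferenceState")
    if name not in difference.delta_thresholded:
        raise ValueError(f"dataset {name!r} not in the difference state")
    vals = np.exp(difference.delta_thresholded[name])
    mat = BinnedMatrix(kind, base, locus.chrom, locus.start, grid.n_bins,
                       _node_table(grid, vals, counts), name)
    return rebin(mat, resolution)


def rebin(matrix: BinnedMatrix, new_resolution: int) -> BinnedMatrix:
    """Aggregate to a coarser resolution (an integer multiple).

    Raw counts are summed; ratio-scale kinds (bias, decay, signal,
    binless, difference) are averaged on the log scale weighted by the
    underlying read counts (plain mean when a block carries no reads);
    the normalized matrix is count-weighted arithmetic-averaged and its
    error combined as an inverse-variance pool.  Thresholded zeros (value
    1 for signal/difference) therefore stay exact only when a whole block
    is zero.
    """
    if new_resolution == matrix.resolution:
        return matrix
    if new_resolution % matrix.resolution != 0:
        raise ValueError(
            f"{new_resolution} is not a multiple of {matrix.resolution}")
    k = new_resolution // matrix.resolution
    df = matrix.data
    b1 = df["bin1"].to_numpy(int) // k
    b2 = df["bin2"].to_numpy(int) // k
    w = df["weight"].to_numpy(float)
    v = df["value"].to_numpy(float)
    n_bins = int(np.ceil(matrix.n_bins / k))
    lin = b1 * n_bins + b2
    uniq, inv = np.unique(lin, return_inverse=True)
    wsum = np.bincount(inv, weights=w)
    nsum = np.bincount(inv)
    if matrix.kind == "raw":
        vals = np.bincount(inv, weights=v)
    elif matrix.kind in _RATIO_KINDS:
        logv = np.log(np.maximum(v, 1e-300))
        wlog = np.bincount(inv, weights=w * logv)
        plain = np.bincount(inv, weights=logv) / np.maximum(nsum, 1)
        vals = np.exp(np.divide(wlog, wsum, out=plain, where=wsum > 0))
    elif matrix.kind == "normalized":
        wv = np.bincount(inv, weights=w * v)
        plain = np.bincount(inv, weights=v) / np.maximum(nsum, 1)
        vals = np.divide(wv, wsum, out=plain, where=wsum > 0)
    else:  # normalized_error: inverse-variance pooling
        prec = np.bincount(inv, weights=1.0 / np.maximum(v, 1e-300) ** 2)
        vals = 1.0 / np.sqrt(np.maximum(prec, 1e-300))
    out = pd.DataFrame({"bin1": uniq // n_bins, "bin2": uniq % n_bins,
                        "value": vals})
    if "error" in df.columns and matrix.kind == "normalized":
        prec = np.bincount(inv,
                           weights=1.0 / np.maximum(
                               df["error"].to_numpy(float), 1e-300) ** 2)
        out["error"] = 1.0 / np.sqrt(np.maximum(prec, 1e-300))
    out["weight"] = wsum
    return BinnedMatrix(matrix.kind, new_resolution, matrix.chrom,
                        matrix.start, n_bins, out, matrix.dataset)


@dataclass
class GroupedSignalData:
    """Pooled per-bin working data of several datasets on one grid."""

    names: tuple
    grid: fused.TriangleGrid
    resolution: int
    y: np.ndarray
    w: np.ndarray


def group_datasets(states: dict, group_map: dict) -> dict:
    """Pool datasets by group before signal/difference estimation.

    ``group_map`` maps dataset name -> group label.  Per-dataset
    backgrounds (exposures, biases, decay) stay as fitted; the pooled
    per-bin working data is the weight-combined mean, which is equivalent
    to pooling the counts of the group at matched backgrounds.
    """
    groups: dict[str, list] = {}
    for name, st in states.items():
        groups.setdefault(group_map.get(name, name), []).append((name, st))
    out = {}
    grid_keys = {(st.grid.n_bins, st.config.base_resolution)
                 for st in states.values()}
    if len(grid_keys) > 1:
        raise ValueError(f"mismatched grids across states: {grid_keys}")
    for label, members in groups.items():
        y_acc = None
        w_acc = None
        for name, st in members:
            eng = _engine_of(st)
            y, w = eng.signal_node_data(st)
            if y_acc is None:
                y_acc, w_acc = w * y, w.copy()
            else:
                y_acc += w * y
                w_acc += w
        y_pool = np.divide(y_acc, w_acc, out=np.zeros_like(y_acc),
                           where=w_acc > 0)
        st0 = members[0][1]
        out[label] = GroupedSignalData(tuple(n for n, _ in members),
                                       st0.grid,
                                       st0.config.base_resolution,
                                       y_pool, w_acc)
    return out


def estimate_group_signal(grouped: GroupedSignalData,
                          lam2_grid=fused.DEFAULT_LAMBDA2_GRID,
                          fdr: float = 0.05) -> SignalEstimate:
    """Signal estimate on pooled working data (same procedure as for a
    single dataset)."""
    y = np.where(grouped.w > 0, grouped.y, 0.0)
    lam2, s, _ = fused.select_lambda2_bic(y, grouped.w, grouped.grid, lam2_grid)
    lam1 = fused.select_lambda1(s, grouped.w, grouped.grid, alpha=fdr, y=y)
    s_thr = np.where(grouped.w > 0,
                     fused.soft_threshold(s, lam1, two_sided=False), 0.0)
    n_patches, _, _ = fused.count_patches(s, grouped.grid)
    return SignalEstimate(grouped.grid, grouped.resolution, s, s_thr,
                          lam1, lam2, grouped.w, n_patches)


# ---------------------------------------------------------------------------
# long-format TSV I/O

def write_matrix(matrix: BinnedMatrix, path) -> None:
    """Long-format TSV: header metadata lines, then one stored cell per
    row with 0-based half-open bin start coordinates."""
    df = matrix.data.copy()
    df.insert(0, "start2", matrix.start + df["bin2"] * matrix.resolution)
    df.insert(0, "start1", matrix.start + df["bin1"] * matrix.resolution)
    df.insert(0, "chrom", matrix.chrom)
    df = df.drop(columns=["bin1", "bin2"])
    with open(path, "w") as fh:
        fh.write(f"# kind={matrix.kind}\n")
        fh.write(f"# resolution={matrix.resolution}\n")
        fh.write(f"# start={matrix.start}\n")
        fh.write(f"# n_bins={matrix.n_bins}\n")
        fh.write(f"# dataset={matrix.dataset}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_matrix(path) -> BinnedMatrix:
    meta = {}
    with open(path) as fh:
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line or not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    resolution = int(meta["resolution"])
    start = int(meta["start"])
    if len(df):
        df["bin1"] = ((df["start1"] - start) // resolution).astype(int)
        df["bin2"] = ((df["start2"] - start) // resolution).astype(int)
        chrom = str(df["chrom"].iloc[0])
    else:
        df["bin1"] = pd.Series(dtype=int)
        df["bin2"] = pd.Series(dtype=int)
        chrom = "chr"
    cols = ["bin1", "bin2", "value"]
    if "error" in df.columns:
        cols.append("error")
    if "weight" in df.columns:
        cols.append("weight")
    data = df[cols].reset_index(drop=True)
    return BinnedMatrix(meta["kind"], resolution, chrom, start,
                        int(meta["n_bins"]), data, meta.get("dataset", "dataset"))
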
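"""Versioned HDF5 container for normalization states."""

from __future__ import annotations

import json
from dataclasses import asdict

import h5py
import numpy as np

from binless import fused, smoothing
from binless.classify import CutSiteMap
from binless.optimized import (Locus, NormalizationState, NormalizeConfig,
                               QUADRANTS)

FORMAT_VERSION = 1


def save_state(state: NormalizationState, path) -> None:
    locus = state.locus
    with h5py.File(path, "w") as h5:
        h5.attrs["format_version"] = FORMAT_VERSION
        h5.attrs["name"] = locus.name
        h5.attrs["chrom"] = locus.chrom
        h5.attrs["start"] = locus.start
        h5.attrs["end"] = locus.end
        h5.attrs["min_distance"] = locus.min_distance
        h5.attrs["enzyme"] = locus.cutsites.enzyme_name
        h5.attrs["converged"] = state.converged
        h5.attrs["alpha"] = state.alpha
        h5.attrs["bias_stiffness"] = state.bias_stiffness
        h5.attrs["decay_stiffness"] = state.decay_stiffness
        h5.attrs["config"] = json.dumps(asdict(state.config))
        h5.attrs["exposures"] = json.dumps(state.exposures)
        h5.attrs["iterations"] = json.dumps(state.iterations)
        g = h5.create_group("locus")
        g.create_dataset("positions", data=locus.cutsites.positions)
        g.create_dataset("cutsite_counts", data=locus.cutsite_counts)
        for q in QUADRANTS:
            g.create_dataset(f"contacts_{q}", data=locus.contact_counts[q])
        g = h5.create_group("model")
        g.create_dataset("iota", data=state.iota)
        g.create_dataset("rho", data=state.rho)
        g.create_dataset("signal_node", data=state.signal_node)
        d = g.create_group("decay")
        d.attrs["degree"] = state.decay.basis.degree
        d.attrs["lo"] = state.decay.basis.lo
        d.attrs["hi"] = state.decay.basis.hi
        d.attrs["min_distance"] = state.decay.min_distance
        d.create_dataset("knots", data=state.decay.basis.knots)
        d.create_dataset("coef", data=state.decay.coef)


def load_state(path) -> NormalizationState:
    with h5py.File(path, "r") as h5:
        version = int(h5.attrs["format_version"])
        if version != FORMAT_VERSION:
            raise ValueError(f"unsupported state format version {version}")
        cutsites = CutSiteMap(str(h5.attrs["chrom"]),
                              h5["locus/positions"][:],
                              enzyme_name=str(h5.attrs["enzyme"]))
        config = NormalizeConfig(**json.loads(h5.attrs["config"]))
        n = cutsites.n_sites
        P = cutsites.positions
        ii, jj = np.triu_indices(n, k=1)
        dist = P[jj] - P[ii]
        keep = dist >= int(h5.attrs["min_distance"])
        ii, jj, dist = ii[keep], jj[keep], dist[keep]
        locus = Locus(
            chrom=str(h5.attrs["chrom"]), start=int(h5.attrs["start"]),
            end=int(h5.attrs["end"]), cutsites=cutsites,
            cutsite_counts=h5["locus/cutsite_counts"][:],
            pair_i=ii, pair_j=jj, pair_distance=dist,
            contact_counts={q: h5[f"locus/contacts_{q}"][:] for q in QUADRANTS},
            name=str(h5.attrs["name"]),
            min_distance=int(h5.attrs["min_distance"]))
        d = h5["model/decay"]
        basis = smoothing.SplineBasis(
            knots=d["knots"][:], degree=int(d.attrs["degree"]),
            positions=np.zeros(0), design=np.zeros((0, 0)),
            lo=float(d.attrs["lo"]), hi=float(d.attrs["hi"]))
        decay = smoothing.DecayFunction(basis, d["coef"][:],
                                        min_distance=float(d.attrs["min_distance"]))
        res = config.base_resolution
        n_bins = int(np.ceil((locus.end - locus.start) / res))
        grid = fused.build_triangle_grid(n_bins)
        idx2d = np.full((n_bins, n_bins), -1, dtype=np.int64)
        for k, (a, b) in enumerate(grid.nodes):
            idx2d[a, b] = k
        a = np.clip((P[ii] - locus.start) // res, 0, n_bins - 1)
        b = np.clip((P[jj] - locus.start) // res, 0, n_bins - 1)
        state = NormalizationState(
            locus=locus, config=config,
            iota=h5["model/iota"][:], rho=h5["model/rho"][:],
            decay=decay, exposures=json.loads(h5.attrs["exposures"]),
            alpha=float(h5.attrs["alpha"]), grid=grid,
            bin_of_pair=idx2d[a, b],
            signal_node=h5["model/signal_node"][:],
            bias_stiffness=float(h5.attrs["bias_stiffness"]),
            decay_stiffness=float(h5.attrs["decay_stiffness"]),
            iterations=json.loads(h5.attrs["iterations"]),
            converged=bool(h5.attrs["converged"]))
        return state
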
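"""Shared fixtures: synthetic datasets at the scales the checks need.

Session-scoped fixtures hold the expensive end-to-end runs (optimized
normalization of a background-only locus and of a locus with a planted
signal block) so several tests can interrogate one run.
"""

from __future__ import annotations

import numpy as np
import pytest

from binless.classify import classify_all, filter_short_range
from binless.optimized import Locus, NormalizeConfig, estimate_signal, normalize
from binless.simulate import (SignalPatch, SimulationConfig, simulate_reads,
                              simulate_truth)


def pipeline(cfg, read_seed=None, fit_signal=True, with_signal_estimate=False,
             base_resolution=5000):
    """simulate -> classify -> aggregate -> normalize (+ signal)."""
    truth = simulate_truth(cfg)
    reads = simulate_reads(truth, seed=read_seed, with_labels=True)
    classified, tally = classify_all(reads, truth.cutsites)
    classified = filter_short_range(classified)
    locus = Locus.from_classified(classified, truth.cutsites,
                                  start=0, end=cfg.chrom_length)
    state = normalize(locus, NormalizeConfig(fit_signal=fit_signal,
                                             base_resolution=base_resolution))
    out = {"truth": truth, "reads": reads, "classified": classified,
           "tally": tally, "locus": locus, "state": state}
    if with_signal_estimate:
        out["signal"] = estimate_signal(state)
    return out


@pytest.fixture(scope="session")
def micro_truth():
    """40 kb locus, ~70 cut sites: cheap enough for repeated runs."""
    return simulate_truth(SimulationConfig(chrom_length=40_000,
                                           cutsite_spacing=500, seed=3))


@pytest.fixture(scope="session")
def micro_reads(micro_truth):
    return simulate_reads(micro_truth, with_labels=True)


@pytest.fixture(scope="session")
def micro_classified(micro_truth, micro_reads):
    classified, tally = classify_all(micro_reads, micro_truth.cutsites)
    return classified, tally


@pytest.fixture(scope="session")
def micro_locus(micro_truth, micro_classified):
    classified, _ = micro_classified
    cfg = micro_truth.config
    return Locus.from_classified(filter_short_range(classified),
                                 micro_truth.cutsites,
                                 start=0, end=cfg.chrom_length)


@pytest.fixture(scope="session")
def micro_state(micro_locus):
    return normalize(micro_locus, NormalizeConfig(fit_signal=False))


@pytest.fixture(scope="session")
def null_run():
    """Background-only 200 kb locus (~480 cut sites), full normalization
    with signal estimation: the parameter-recovery and null-sparsity
    workhorse."""
    return pipeline(SimulationConfig(seed=11), with_signal_estimate=True)


@pytest.fixture(scope="session")
def planted_run():
    """1 Mb locus (10 kb base resolution) with a 100 kb block at log fold
    change 1.0 — the block is a small fraction of the locus, as in
    realistic signal-detection workloads."""
    cfg = SimulationConfig(
        chrom_length=1_000_000, cutsite_spacing=800, seed=12,
        signal_patches=[SignalPatch(450_000, 550_000, 450_000, 550_000, 1.0)])
    return pipeline(cfg, with_signal_estimate=True, base_resolution=10_000)


@pytest.fixture(scope="session")
def replicate_runs():
    """Three 150 kb datasets on one cut-site map: two replicates of the
    same truth and one carrying an off-diagonal 4-fold patch."""
    patch = SignalPatch(40_000, 70_000, 90_000, 120_000, float(np.log(4.0)))
    cfg_null = SimulationConfig(chrom_length=150_000, cutsite_spacing=400,
                                seed=31)
    cfg_patch = SimulationConfig(chrom_length=150_000, cutsite_spacing=400,
                                 seed=31, signal_patches=[patch])
    runs = {
        "A": pipeline(cfg_null, read_seed=311),
        "B": pipeline(cfg_null, read_seed=312),
        "C": pipeline(cfg_patch, read_seed=313, with_signal_estimate=True),
    }
    for name, run in runs.items():
        run["state"].locus.name = name
    runs["patch"] = patch
    return runs


def true_signal_on_grid(truth, state):
    """True log fold change evaluated at grid-node bin centers."""
    res = state.config.base_resolution
    centers = (state.grid.nodes + 0.5) * res + state.locus.start
    return truth.signal_log_fc(centers[:, 0], centers[:, 1])


def rng_for(name: str, seed: int = 0) -> np.random.Generator:
    import zlib

    return np.random.default_rng((zlib.crc32(name.encode()) + seed) % (2 ** 31))
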
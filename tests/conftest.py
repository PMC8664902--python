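"""Shared fixtures: small genomes and full desk-scale simulated runs.

Heavy simulations are session-scoped so the whole suite pays for them
once. Every fixture is seed-fixed and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import medipdmr as m
from medipdmr.synthetic import ChromSpec


@dataclass
class SimulatedRun:
    """One complete simulated comparison with all intermediate objects."""

    genome: object
    windows: object
    cohort: list
    truth: object
    counts: object
    kept: object
    groups: list
    norm: object
    disp: object
    results: object  # difftest DataFrame
    dmr_set: object


def _simulate_run(
    chroms,
    seed: int,
    truth=None,
    dispersion: float = 0.1,
    n_per_arm: int = 13,
    tagwise: bool = True,
    p_threshold: float = 1e-4,
):
    genome = m.generate_genome(chroms, seed=seed)
    windows = m.tile_genome(genome.chrom_sizes())
    cohort = m.simulate_cohort(n_per_arm, n_per_arm, seed=seed + 1)
    if truth is None:
        truth = m.GroundTruth(regions=[], dispersion=dispersion)
    elif callable(truth):
        truth = truth(windows)
    counts = m.simulate_window_counts(genome, windows, cohort, truth, seed=seed + 2)
    kept = m.filter_windows(counts)
    groups = [s.group for s in cohort]
    norm = m.tmm_factors(kept)
    disp = m.estimate_dispersion(kept, groups, norm, tagwise=tagwise)
    results = m.exact_test(kept, groups, norm, disp)
    dmr_set = m.call_dmrs(results, windows, p_threshold=p_threshold)
    return SimulatedRun(
        genome, windows, cohort, truth, counts, kept, groups, norm, disp, results, dmr_set
    )


DESK_CHROMS = (ChromSpec("chr1", 1_000_000), ChromSpec("chr2", 1_000_000))
SMALL_CHROMS = (ChromSpec("chr1", 100_000), ChromSpec("chr2", 100_000))


@pytest.fixture(scope="session")
def small_genome():
    return m.generate_genome(SMALL_CHROMS, seed=5)


@pytest.fixture(scope="session")
def desk_run():
    """Full-scale comparison: 2 x 1 Mb, 13+13, eight injected |lfc|=2 DMRs."""

    def make_truth(windows):
        return m.default_truth(
            windows, n_regions=8, lfc=2.0, n_windows_choices=(2, 3), dispersion=0.1, seed=7
        )

    return _simulate_run(DESK_CHROMS, seed=41, truth=make_truth)


@pytest.fixture(scope="session")
def null_run():
    """Same scale with no injected effect (phi = 0.1): the null for calibration."""
    return _simulate_run(DESK_CHROMS, seed=61, dispersion=0.1)


@pytest.fixture(scope="session")
def poisson_run():
    """Null with phi = 0: Poisson counts for the dispersion lower bound."""
    return _simulate_run(DESK_CHROMS, seed=71, dispersion=0.0, tagwise=False)


@pytest.fixture(scope="session")
def small_run():
    """Fast small-genome run with two injected regions for plumbing tests."""

    def make_truth(windows):
        return m.default_truth(
            windows, n_regions=3, lfc=2.0, n_windows_choices=(1, 2), dispersion=0.1, seed=3
        )

    return _simulate_run(SMALL_CHROMS, seed=21, truth=make_truth)
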
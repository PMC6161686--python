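"""Shared fixtures: one full default-scenario simulation (seed 1) reused by
the acceptance tests, plus a small cheap scenario for unit tests."""

from __future__ import annotations

import pytest

from dictymir.config import RunConfig
from dictymir.report import call_all_loci
from dictymir.simulate import (
    GENOTYPES,
    TIMEPOINTS,
    SimScenario,
    simulate_coverage,
    simulate_genome,
    simulate_small_reads,
)


@pytest.fixture(scope="session")
def default_sim():
    """The default study scenario at seed 1: genome, features, truth."""
    scenario = SimScenario(seed=1)
    segment, features, truth = simulate_genome(scenario)
    return segment, features, truth


@pytest.fixture(scope="session")
def default_reads(default_sim):
    """All four small-RNA libraries of the default scenario."""
    _, _, truth = default_sim
    reads = {(g, t): simulate_small_reads(truth, g, t) for g in GENOTYPES for t in TIMEPOINTS}
    return reads


@pytest.fixture(scope="session")
def default_calls(default_sim, default_reads):
    """Per-locus verdicts on the default scenario with default thresholds."""
    segment, features, _ = default_sim
    lib = {c: len(r) for c, r in default_reads.items()}
    return call_all_loci(segment, features, default_reads, lib, RunConfig())


@pytest.fixture(scope="session")
def default_coverage(default_sim):
    _, _, truth = default_sim
    return {
        (g, t): simulate_coverage(truth, g, t) for g in GENOTYPES for t in TIMEPOINTS
    }


@pytest.fixture(scope="session")
def small_scenario():
    """A reduced scenario for cheap unit tests."""
    return SimScenario(
        seed=7,
        genome_length=22_000,
        n_mirna_loci=4,
        n_mor_loci=1,
        n_readthrough_loci=1,
        n_decoy_hairpins=5,
        n_sirna_repeat_loci=2,
        sirna_reads=1500.0,
        background_reads=2500.0,
        mrna_reads=500.0,
        mrna_antisense_reads=80.0,
        ncrna_reads=150.0,
        complex_repeat_reads=200.0,
    )


@pytest.fixture(scope="session")
def small_sim(small_scenario):
    return simulate_genome(small_scenario)
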
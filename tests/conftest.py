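"""Shared fixtures: one full-size simulated study and one small one.

Both are session-scoped; every test that only reads from them can share
the same objects.  Tests that mutate data must copy first.
"""

from types import SimpleNamespace

import pytest

from circskin import synthetic_data as sd


def _build(config: sd.SimulationConfig) -> SimpleNamespace:
    genome, annotation, repeats, truth = sd.simulate_genome_annotation(config)
    counts = sd.simulate_counts(config, truth)
    return SimpleNamespace(
        config=config,
        genome=genome,
        annotation=annotation,
        repeats=repeats,
        truth=truth,
        counts=counts,
    )


@pytest.fixture(scope="session")
def default_sim() -> SimpleNamespace:
    """Default-parameter study (seed 0): 6 pairs, 200 genes, 100 circles."""
    return _build(sd.SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def small_sim() -> SimpleNamespace:
    """Small study for read-level tests (seed 7): 12 genes, 6 circles."""
    config = sd.SimulationConfig(seed=7, n_genes=24, n_circ=8, n_mirnas=20)
    sim = _build(config)
    sim.reads = sd.simulate_reads(config, sim.truth, sim.counts, sim.genome,
                                  sim.annotation)
    return sim


@pytest.fixture(scope="session")
def nanostring_tables(default_sim) -> tuple:
    """CodeSet analog and miRNA panel analog for the default study."""
    return sd.simulate_nanostring(default_sim.config, default_sim.truth)
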
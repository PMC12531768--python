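"""Shared fixtures: one deterministic synthetic cohort reused across
module tests.  Everything is generated in memory — no data files."""

import pytest

import enhmut as em
from enhmut.io_formats import frame_to_records


@pytest.fixture(scope="session")
def genome():
    return em.simulate_genome(seed=11)


@pytest.fixture(scope="session")
def cohort(genome):
    table, truth = em.simulate_cohort(genome, seed=12)
    return table, truth


@pytest.fixture(scope="session")
def cohort_records(cohort):
    table, _ = cohort
    return frame_to_records(table)


@pytest.fixture(scope="session")
def expression(genome, cohort):
    _, truth = cohort
    return em.simulate_expression(genome, truth, seed=13)
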
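"""Shared fixtures: one small simulated study reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from saltnac import association as assoc_mod
from saltnac.simulate import (CausalSpec, SimConfig, generate_expression,
                              generate_genome, generate_population)

CAUSAL = [CausalSpec(5, "TRL", 0.25), CausalSpec(12, "RV", 0.25),
          CausalSpec(20, "RTN", 0.25)]


def demo_config(seed: int = 7, **kw) -> SimConfig:
    kw.setdefault("causal_spec", list(CAUSAL))
    return SimConfig(seed=seed, **kw)


@pytest.fixture(scope="session")
def sim_config():
    return demo_config()


@pytest.fixture(scope="session")
def genome(sim_config):
    return generate_genome(sim_config)


@pytest.fixture(scope="session")
def expression_tables(genome, sim_config):
    fpkm, counts = generate_expression(genome.genes, sim_config, genome.truth)
    return fpkm, counts


@pytest.fixture(scope="session")
def population(genome, sim_config, expression_tables):
    pop = generate_population(genome.genes, sim_config, genome.truth,
                              regions=genome.regions)
    assoc_mod.qc_snps(pop.snps, pop.dosage)
    return pop


@pytest.fixture(scope="session")
def rsir(population):
    return assoc_mod.compute_rsir(population.phenotypes)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
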
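"""Shared fixtures: seeded synthetic datasets reused across test modules."""

import pytest
from hypothesis import HealthCheck, settings

from sinescan.search import SearchParams, find_insertions
from sinescan.simulate import (
    InsertionPlan,
    SimulationSpec,
    plant_insertions,
    random_element,
    simulate_genome,
    simulate_polyploid,
)

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def consensus():
    """The 181-bp element consensus used throughout the suite."""
    return random_element(length=181, seed=2)


# A 500-kb genome with 50 planted insertions spanning every site category,
# TSDs, and end truncations inside/outside the 20-nt tolerance.
PLANS = (
    [InsertionPlan("intron", tsd_len=7)] * 20
    + [InsertionPlan("exon")] * 5
    + [InsertionPlan("proximal_upstream")] * 5
    + [InsertionPlan("proximal_downstream")] * 5
    + [InsertionPlan("intergenic")] * 13
    + [InsertionPlan("intergenic", truncation=("5", 10))]
    + [InsertionPlan("intergenic", truncation=("5", 30))]
)


@pytest.fixture(scope="session")
def planted(consensus):
    """(mutated genome, features, truth) for the 500-kb / 50-insertion set."""
    spec = SimulationSpec(seed=1, n_chroms=1, chrom_length=500_000,
                          n_genes=17, n_insertions=0)
    genome, features, _ = simulate_genome(spec)
    return plant_insertions(genome, consensus, PLANS, features=features, rng=3)


@pytest.fixture(scope="session")
def planted_loci(planted, consensus):
    mutated, _, _ = planted
    return find_insertions(mutated, consensus, SearchParams())


@pytest.fixture(scope="session")
def trio(consensus):
    """Two diploids and a derived polyploid with known shared insertions."""
    def diploid(seed, n_ins):
        spec = SimulationSpec(seed=seed, n_chroms=2, chrom_length=120_000,
                              n_genes=0, n_insertions=0)
        g, _, _ = simulate_genome(spec)
        return plant_insertions(g, consensus,
                                [InsertionPlan("intergenic")] * n_ins,
                                features=None, rng=seed + 10)

    d_a, _, t_a = diploid(11, 8)
    d_d, _, t_d = diploid(13, 6)
    poly, submap, truth = simulate_polyploid(
        [(d_a, t_a), (d_d, t_d)], ["A", "D"], consensus=consensus,
        extra_insertions={"A": 4, "D": 2}, rng=19)
    return dict(diploid_a=d_a, truth_a=t_a, diploid_d=d_d, truth_d=t_d,
                poly=poly, submap=submap, truth=truth)
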
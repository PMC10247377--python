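import numpy as np
import pytest

from preneo.genome import Chromosome, FragileLocus, GenomeModel, demo_genome


@pytest.fixture(scope="session")
def genome():
    return demo_genome()


@pytest.fixture(scope="session")
def toy_genome():
    """Two chromosomes, 10 bins each (5 per arm), one fragile locus on 1p."""
    chroms = [Chromosome("1", 1_000_000, 500_000), Chromosome("2", 1_000_000, 500_000)]
    loci = [FragileLocus("FRAG", "1", 150_000, 250_000)]
    return GenomeModel(chroms, bin_size=100_000, fragile_loci=loci)


@pytest.fixture(scope="session")
def neutral_history(genome):
    """Mutation-free simulated experiment: 20 barcoded founders, 3 replicates."""
    from preneo.sim import SimulationConfig, simulate_evolution

    cfg = SimulationConfig(
        genome=genome,
        n_founder=20,
        fitness_table={},
        contingency_table={},
        missegregation_rate=0.0,
        focal_deletion_rate=0.0,
        barcoding_day=0,
        split_day=14,
        n_days=60,
        seed=42,
    )
    return simulate_evolution(cfg)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
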
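import numpy as np
import pytest

from coevmosaic.genotype_model import GenotypeDataset, PopulationSample
from coevmosaic.synthetic_data import SimConfig, simulate_species


def make_dataset(pop_genotypes: dict[str, list[list[tuple[int, int]]]],
                 locus_names=None, species="test") -> GenotypeDataset:
    """Build a dataset from {pop: [[(a1, a2) per locus] per individual]}."""
    pops = []
    n_loci = None
    for pid, rows in pop_genotypes.items():
        g = np.array(rows, dtype=np.int64)
        n_loci = g.shape[1]
        pops.append(
            PopulationSample(pid, [f"{pid}-{i}" for i in range(len(rows))], g)
        )
    names = locus_names or [f"L{j + 1}" for j in range(n_loci)]
    return GenotypeDataset(species, names, pops)


@pytest.fixture(scope="session")
def sim_pair_small():
    """Small five-population pair used by several integration tests."""
    from coevmosaic.synthetic_data import aphid_config, parasitoid_config, simulate_pair

    host_cfg = aphid_config(n_individuals_per_pop=10)
    para_cfg = parasitoid_config(n_individuals_per_pop=10)
    return simulate_pair(host_cfg, para_cfg, seed=42)


@pytest.fixture(scope="session")
def one_pop_hw():
    """Single population of 200 individuals at Hardy-Weinberg, no nulls."""
    cfg = SimConfig(population_labels=("A",), n_individuals_per_pop=200,
                    n_loci=10, n_alleles_per_locus=4, dirichlet_alpha=1.0,
                    theta_divergence=0.0, selfing_F=0.0, null_rate=0.0,
                    seed=123)
    ds, truth = simulate_species(cfg)
    return ds, truth
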
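import numpy as np
import pytest
from hypothesis import settings

import crossim as cs

settings.register_profile("fixed", derandomize=True, max_examples=50)
settings.load_profile("fixed")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def two_locus_map():
    """Factory: two loci a given distance apart on one 150 cM group."""

    def make(d_cM, length=150.0):
        return cs.GeneticMap(
            group_lengths=[length],
            locus_ids=("L", "R"),
            locus_group=[0, 0],
            pos_cM=[10.0, 10.0 + d_cM],
        )

    return make


@pytest.fixture
def small_genome(rng):
    """A 20-group, 30-locus genome with a scaled architecture and its
    200-plant F8 initial population."""
    gmap = cs.build_genome(20, 150.0, 30, rng)
    pop = cs.make_initial_population(gmap, 200, rng)
    arch = cs.scale_effects_to_unit_variance(cs.sample_effects(30, rng=rng), pop)
    return gmap, arch, pop


def make_population(gmap, codes):
    """Population with prescribed genotype codes (hets phased arbitrarily)."""
    codes = np.asarray(codes, dtype=np.int8)
    hap1 = np.where(codes == -1, 1, 0).astype(np.uint8)
    hap2 = np.where(codes <= 0, 1, 0).astype(np.uint8)
    return cs.Population(
        haplotypes=np.stack([hap1, hap2], axis=1),
        gmap=gmap,
        ids=tuple(f"p{i}" for i in range(codes.shape[0])),
    )


@pytest.fixture
def population_factory():
    return make_population
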
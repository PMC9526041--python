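import numpy as np
import pytest
from hypothesis import settings

from breedsim.genome import Chromosome, GeneticMap, PopulationStore, haplotype_from_string

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20250920)


@pytest.fixture
def two_chrom_map():
    """2 chromosomes x 3 markers, 100 cM spans."""
    return GeneticMap(
        [
            Chromosome("chr1", ("m1", "m2", "m3"), np.array([0.0, 50.0, 100.0])),
            Chromosome("chr2", ("m4", "m5", "m6"), np.array([0.0, 40.0, 100.0])),
        ]
    )


def make_store(gmap, genotypes, effects=None):
    """Build a store from {name: (hap1_string, hap2_string)} in one founder group."""
    store = PopulationStore(gmap, effects)
    group = store.new_group_handle()
    for name, (h1, h2) in genotypes.items():
        store.add_record(name, haplotype_from_string(h1), haplotype_from_string(h2), group)
    return store, group


def single_locus_map():
    return GeneticMap([Chromosome("c", ("m1",), np.array([0.0]))])


def two_marker_map(distance_morgans):
    return GeneticMap(
        [Chromosome("c", ("m1", "m2"), np.array([0.0, 100.0 * distance_morgans]))]
    )


@pytest.fixture
def fixture_files(tmp_path, rng):
    """A small synthetic founder/map/effects trio written through the file dialects."""
    from breedsim.synth import write_fixture_set

    return write_fixture_set(
        tmp_path / "fix",
        rng,
        n_founders=8,
        n_chromosomes=3,
        markers_per_chromosome=20,
        chromosome_length_cm=120.0,
        inbred=False,
        proportion_causal=0.5,
    )
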
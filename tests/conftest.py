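"""Shared fixtures: one small synthetic study reused across test modules."""

import pytest

from charlink import fragment_mapper as fm
from charlink import synthetic_data as synth
from charlink.pipeline import truth_as_contacts


@pytest.fixture(scope="session")
def genome_small():
    return synth.make_genome(11, n_assembled=6, assembled_lengths=50_000,
                             n_scaffolds=3)


@pytest.fixture(scope="session")
def annotation_small(genome_small):
    return synth.make_annotation(
        genome_small, 12,
        class_counts={"rRNA": 2, "msrpRNA": 2, "snRNA": 6, "snoRNA": 5,
                      "lncRNA": 30, "mRNA": 40},
        length_ranges={"lncRNA": (200, 900), "mRNA": (300, 1_000),
                       "rRNA": (1_000, 1_800)},
    )


@pytest.fixture(scope="session")
def truth_small(annotation_small, genome_small):
    return synth.plant_contacts(annotation_small, genome_small, 13,
                                n_contacts=4_000)


@pytest.fixture(scope="session")
def contacts_small(truth_small):
    return truth_as_contacts(truth_small)


@pytest.fixture(scope="session")
def genome_index(genome_small):
    return fm.build_index(genome_small.sequences)


@pytest.fixture(scope="session")
def tx_index(annotation_small, genome_small):
    return fm.build_index(fm.transcriptome(annotation_small, genome_small))
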
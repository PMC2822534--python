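import numpy as np
import pytest

from mirsieve import CountTable, datasets
from mirsieve.io import ReadRecord


@pytest.fixture(scope="session")
def intracellular():
    """Bundled intracellular top-miRNA table (16 tags, samples IC1/IC2)."""
    return datasets.load_intracellular_top()


@pytest.fixture(scope="session")
def extracellular():
    """Bundled extracellular top-miRNA table (20 tags, samples EC1-EC3)."""
    return datasets.load_extracellular_top()


@pytest.fixture(scope="session")
def mirna_reference(intracellular, extracellular):
    """Mature-miRNA reference covering every annotated tag of both tables."""
    from mirsieve import merge_tables

    combined = CountTable()
    for tag, row in intracellular.counts.items():
        combined.counts[tag] = dict(row)
    combined.samples = list(intracellular.samples)
    combined.annotations = dict(intracellular.annotations)
    for tag, row in extracellular.counts.items():
        combined.counts.setdefault(tag, {}).update(row)
        combined.annotations.setdefault(tag, extracellular.annotations[tag])
    for s in extracellular.samples:
        combined.samples.append(s)
    return datasets.reference_from_table(combined)


def make_reads(sequences, prefix="r"):
    return [ReadRecord(f"{prefix}{i}", seq) for i, seq in enumerate(sequences, 1)]


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)
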
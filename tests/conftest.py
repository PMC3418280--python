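import pytest

from spongedelim.seqio import MultipleAlignment, SpeciesPartition
from spongedelim.synthetic import aplysina_like_spec, simulate


@pytest.fixture(scope="session")
def mimic_truth():
    """The packaged three-species synthetic data set (default seed)."""
    return simulate(aplysina_like_spec())


@pytest.fixture
def toy_alignment():
    return MultipleAlignment(
        "toy", ["a", "b", "c", "d"], ["ACGT", "ACGA", "AC-A", "GCGA"]
    )


@pytest.fixture
def two_species_partition():
    return SpeciesPartition({"a": "X", "b": "X", "c": "Y", "d": "Y"})
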
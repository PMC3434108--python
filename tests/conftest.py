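import pytest

from triadcore import (
    StructureModel,
    SyntheticAlignmentSpec,
    ToyProteaseSpec,
    make_ideal_sse,
    make_synthetic_alignment,
    make_toy_protease,
)


@pytest.fixture(scope="session")
def toy_protease():
    """Noise-free toy protease with the triad at (6.4, 8.4, 9.8) Å."""
    return make_toy_protease(ToyProteaseSpec(seed=0))


@pytest.fixture(scope="session")
def ideal_helix():
    return make_ideal_sse("helix", 12)


@pytest.fixture(scope="session")
def ideal_strand():
    return make_ideal_sse("strand", 8)


@pytest.fixture(scope="session")
def helix_model(ideal_helix):
    return StructureModel("HELIX", "synthetic", [ideal_helix])


@pytest.fixture(scope="session")
def alignment_16_of_21():
    """21-row alignment whose column 30 carries T in exactly 16 rows."""
    spec = SyntheticAlignmentSpec(
        n_rows=21, n_cols=60, conserved=[(30, "T", 16 / 21)], seed=11
    )
    return make_synthetic_alignment(spec)
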
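import pytest

from enrichkit import ContigCountRecord, LibrarySizes


@pytest.fixture
def equal_sizes() -> LibrarySizes:
    return LibrarySizes(n_a=700_000, n_b=700_000)


@pytest.fixture
def study_sizes() -> LibrarySizes:
    """Library sizes at the scale of the motivating study."""
    return LibrarySizes(n_a=742_771, n_b=721_543)


@pytest.fixture
def small_table() -> list[ContigCountRecord]:
    return [
        ContigCountRecord("c1", 3, 2),
        ContigCountRecord("c2", 0, 5),
        ContigCountRecord("c3", 7, 0),
        ContigCountRecord("c4", 1, 1),
        ContigCountRecord("c5", 0, 9),
    ]
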
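import numpy as np
import pytest

from rgenekit.sequence_io import Alphabet, ProteinRecord


def random_record(rng: np.random.Generator, length: int, rid: str = "r") -> ProteinRecord:
    seq = "".join(rng.choice(list(Alphabet.RESIDUES), size=length))
    return ProteinRecord(id=rid, sequence=seq)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def toy_records(rng) -> list[ProteinRecord]:
    return [random_record(rng, int(L), f"rec{i}") for i, L in enumerate(rng.integers(20, 120, size=12))]
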
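import numpy as np
import pytest

from setenrich import GeneSet, GeneSetCollection, list_to_collection


@pytest.fixture
def tiny_collection() -> GeneSetCollection:
    """Three small entries over a 12-gene universe, with overlaps."""
    return list_to_collection(
        {
            "TF1": ["g01", "g02", "g03", "g04"],
            "TF2": ["g03", "g04", "g05", "g06", "g07"],
            "TF3": ["g08", "g09"],
        }
    )


@pytest.fixture
def tiny_background() -> list[str]:
    return [f"g{i:02d}" for i in range(1, 13)]


def random_collection(rng: np.random.Generator, n_sets: int = 5) -> GeneSetCollection:
    """Random small collection for round-trip style tests."""
    genes = [f"gene{i}" for i in range(40)]
    sets = []
    for j in range(n_sets):
        size = int(rng.integers(1, 10))
        members = tuple(rng.choice(genes, size=size, replace=False))
        sets.append(GeneSet(f"set{j}", f"description {j}", members))
    return GeneSetCollection(sets=sets, metadata={"source": "synthetic"})
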
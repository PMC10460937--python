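import random

import pytest

from danai.contact_graph import ContactGraph
from danai.notation import builtin_modes


@pytest.fixture(scope="session")
def modes():
    return builtin_modes()


def make_random_graph(seed: int, n_min: int = 10, n_max: int = 60, p: float = 0.12) -> ContactGraph:
    """Seeded random mixed-species abstract contact graph (one molecule per node)."""
    rng = random.Random(seed)
    n = rng.randint(n_min, n_max)
    species = [rng.choice(["C180", "C182"]) for _ in range(n)]
    edges = [
        (i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < p
    ]
    return ContactGraph.from_edges(species, edges)
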
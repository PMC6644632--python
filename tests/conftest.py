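import pytest

from termnet.resources import GeneSet, GeneSetResource
from termnet.synthetic import FixtureSpec, PlantedOverlap, make_geneset_fixture


@pytest.fixture
def small_resource():
    """Tiny hand-built resource over a 10-gene alphabet."""
    sets = [
        GeneSet("T1", "first", frozenset({"A", "B", "C"})),
        GeneSet("T2", "second", frozenset({"B", "C", "D"})),
        GeneSet("T3", "", frozenset({"E", "F"})),
    ]
    return GeneSetResource("tiny", sets)


@pytest.fixture
def planted_resources():
    """Two synthetic resources with exactly planted overlaps.

    Planted pairs (overlap coefficient): within resource1 T1~T2 at 0.8 and
    T3~T4 at 0.95 (sizes 20); across resources T5~r2.T1 at 1.0.
    """
    spec = FixtureSpec(
        n_terms=(8, 6),
        term_size_range=(20, 20),
        universe_size=1000,
        planted_overlaps=[
            PlantedOverlap((0, 0), (0, 1), 0.8),
            PlantedOverlap((0, 2), (0, 3), 0.95),
            PlantedOverlap((0, 4), (1, 0), 1.0),
        ],
        seed=11,
    )
    resources, truth = make_geneset_fixture(spec)
    return resources, truth
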
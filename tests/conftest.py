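import networkx as nx
import pytest
from hypothesis import settings

from chromnet.io import Fragment, FragmentSet, InteractionRecord
from chromnet.synthetic import RosetteSpec, generate, generate_tracks

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def small_fragments() -> FragmentSet:
    """Six fragments on two chromosomes."""
    frags = FragmentSet()
    for i in range(3):
        frags.add(Fragment(f"a{i}", "chrI", i * 1000, (i + 1) * 1000))
    for i in range(3):
        frags.add(Fragment(f"b{i}", "chrII", i * 1000, (i + 1) * 1000))
    return frags


@pytest.fixture
def bridged_triangles() -> nx.Graph:
    """Two triangles joined by a single bridge edge (6 nodes, 7 edges)."""
    return nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)])


@pytest.fixture(scope="session")
def rosette():
    """One default synthetic rosette draw (seed 0) shared across tests."""
    spec = RosetteSpec(seed=0)
    frags, records, truth = generate(spec)
    return spec, frags, records, truth


@pytest.fixture(scope="session")
def rosette_tracks(rosette):
    _, frags, _, truth = rosette
    return generate_tracks(truth, frags)


def make_records(pairs, fragments: FragmentSet):
    """Interaction records from (id, id, fdr) triples, class derived."""
    out = []
    for a, b, fdr in pairs:
        cls = "intra" if fragments.chrom_of(a) == fragments.chrom_of(b) else "inter"
        out.append(InteractionRecord(a, b, fdr, cls))
    return out
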
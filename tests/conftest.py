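import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


# Published whole-centimetre NC cutoff rows (cutoff, sensitivity,
# specificity) from the reference ROC table of the screening analysis.
REPORTED_CUTOFF_ROWS = [
    (39, 0.9237, 0.3889),
    (40, 0.8755, 0.4259),
    (41, 0.8099, 0.5185),
    (42, 0.7376, 0.5741),
    (43, 0.6305, 0.6667),
    (44, 0.5489, 0.6852),
    (45, 0.4391, 0.7963),
    (46, 0.3494, 0.8519),
]

# Published per-community head counts of the NC-threshold classifier
# (patients with NC <= cutoff vs > cutoff, per community C1..C4);
# communities C3, C4 form the good response class.
REPORTED_NC_COUNTS = {
    39: ({1: 0, 2: 0, 3: 11, 4: 18}, {1: 55, 2: 32, 3: 18, 4: 11}),
    41: ({1: 1, 2: 1, 3: 28, 4: 23}, {1: 54, 2: 31, 3: 1, 4: 6}),
}
GOOD_COMMUNITIES = {3, 4}


@pytest.fixture
def reported_cutoff_rows():
    return REPORTED_CUTOFF_ROWS


@pytest.fixture
def reported_nc_counts():
    return REPORTED_NC_COUNTS


@pytest.fixture
def two_triangles():
    """Two disjoint triangles: the classic hand-computable modularity case."""
    G = nx.Graph()
    G.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
    return G
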
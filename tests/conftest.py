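import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

from herbwalk.network import MultiscaleNetwork
from herbwalk.synthetic import SyntheticConfig, generate_world

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def typed_graph(node_classes: dict[str, str],
                edges: list[tuple[str, str, str]]) -> MultiscaleNetwork:
    """Hand-build a small typed network for examples."""
    g = nx.Graph()
    for node, cls in node_classes.items():
        g.add_node(node, node_class=cls)
    for u, v, cls in edges:
        g.add_edge(u, v, edge_class=cls)
    return MultiscaleNetwork(g)


@pytest.fixture
def path_net():
    """Path graph a–b–c of proteins (uniform-weight walk examples)."""
    return typed_graph(
        {"A": "protein", "B": "protein", "C": "protein"},
        [("A", "B", "ppi"), ("B", "C", "ppi")],
    )


@pytest.fixture
def compound_disease_path_net():
    """X–a–b–c–Y: compound X attached at a, disease Y at c."""
    return typed_graph(
        {"A": "protein", "B": "protein", "C": "protein",
         "X": "compound", "Y": "disease"},
        [("A", "B", "ppi"), ("B", "C", "ppi"),
         ("X", "A", "compound_target"), ("Y", "C", "disease_gene")],
    )


def small_world(seed: int = 0, **overrides):
    """A compact synthetic world for fast sweeps."""
    defaults = dict(n_proteins=120, n_functions=25, n_herbs=6,
                    disease_size=12, seed=seed)
    defaults.update(overrides)
    return generate_world(SyntheticConfig(**defaults))


@pytest.fixture
def world():
    return small_world(seed=7)
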
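import networkx as nx
import numpy as np
import pytest

from tenonet.data_model import InteractionRecord


def random_simple_graph(rng: np.random.Generator, max_nodes: int = 12) -> nx.Graph:
    """A random labelled simple graph with up to ``max_nodes`` nodes."""
    n = int(rng.integers(1, max_nodes + 1))
    p = float(rng.uniform(0.05, 0.9))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31 - 1)))
    return nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})


@pytest.fixture
def tiny_records() -> list[InteractionRecord]:
    return [
        InteractionRecord("SCX", "COL1A1", "physical", "m", "embryo", "ref1"),
        InteractionRecord("TGFB2", "SCX", "functional", "m", "prepubertal", "ref2"),
        InteractionRecord("SIX2", "EYA1", "physical", "g", "embryo", "ref3"),
    ]


@pytest.fixture
def fixture_dir(tmp_path):
    """A canonical synthetic fixture directory (study-condition defaults)."""
    from tenonet.synthetic_data import SyntheticConfig, make_fixtures
    return make_fixtures(SyntheticConfig(seed=11), tmp_path / "fixtures")
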
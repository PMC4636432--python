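import numpy as np
import pytest

from moranfix.graphs import (
    ErParams,
    Graph,
    complete_graph,
    cycle_graph,
    directed_line,
    generate_er,
    is_connected,
    star_graph,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def named_graphs():
    """A small battery of connected undirected graphs of varied size."""
    return {
        "pair": Graph(2, {(0, 1)}),
        "triangle": cycle_graph(3),
        "cycle4": cycle_graph(4),
        "cycle6": cycle_graph(6),
        "star5": star_graph(5),
        "complete4": complete_graph(4),
        "complete6": complete_graph(6),
        "line4": directed_line(4),
    }


def sample_connected(n, p, count, rule_seed, directed=False, max_tries=100000):
    """Deterministically draw `count` connected G(n, p) graphs."""
    rng = np.random.default_rng(rule_seed)
    out = []
    for _ in range(max_tries):
        g = generate_er(ErParams(n, p, directed), rng)
        if is_connected(g):
            out.append(g)
            if len(out) == count:
                return out
    raise RuntimeError(f"could not draw {count} connected graphs at n={n}, p={p}")
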
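"""Graph substrate and Erdős-Rényi ensembles.

The population structure is an unweighted graph without self-loops: each
node carries one individual, and a directed link i -> j means the offspring
of i may displace the individual on j.  Undirected graphs are stored with
each link once but interpreted bidirectionally.

Besides the G(N, p) generator this module provides the structural checks
used by the classification pipeline (connectivity, isothermality, root
census), the closed-form ensemble probabilities that serve as analytic
overlays (probability of connectivity, of isothermality at N = 4, of at
least one root in a directed ensemble), and the exhaustive enumeration of
connected four-node graphs up to isomorphism.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from pathlib import Path
from typing import Iterator

import networkx as nx
import numpy as np

__all__ = [
    "Graph",
    "ErParams",
    "generate_er",
    "is_connected",
    "is_isothermal",
    "root_census",
    "source_component_count",
    "p_connected",
    "p_isothermal_n4",
    "p_has_root",
    "enumerate_connected_n4",
    "cycle_graph",
    "star_graph",
    "complete_graph",
    "directed_line",
    "read_edge_list",
    "write_edge_list",
]


@dataclass(frozen=True)
class Graph:
    """An unweighted graph without self-loops on nodes 0..n_nodes-1.

    ``edges`` holds ordered pairs.  For undirected graphs each link is
    stored once (in either orientation) and interpreted bidirectionally.
    """

    n_nodes: int
    edges: frozenset[tuple[int, int]]
    directed: bool = False

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be positive")
        object.__setattr__(self, "edges", frozenset(map(tuple, self.edges)))
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop ({i},{i}) not allowed")
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                raise ValueError(f"edge ({i},{j}) out of range for N={self.n_nodes}")
        if not self.directed:
            # canonicalize: store undirected links as sorted pairs
            canon = frozenset((min(i, j), max(i, j)) for i, j in self.edges)
            object.__setattr__(self, "edges", canon)

    # -- neighborhood structure -------------------------------------------

    def out_neighbors(self, i: int) -> list[int]:
        if self.directed:
            return sorted(j for a, j in self.edges if a == i)
        return sorted(j for j in self._adjacent(i))

    def in_neighbors(self, i: int) -> list[int]:
        if self.directed:
            return sorted(a for a, j in self.edges if j == i)
        return sorted(j for j in self._adjacent(i))

    def _adjacent(self, i: int) -> Iterator[int]:
        for a, b in self.edges:
            if a == i:
                yield b
            elif b == i:
                yield a

    def out_degree(self, i: int) -> int:
        return len(self.out_neighbors(i))

    def in_degree(self, i: int) -> int:
        return len(self.in_neighbors(i))

    # -- conversions -------------------------------------------------------

    def to_networkx(self) -> nx.Graph | nx.DiGraph:
        g = nx.DiGraph() if self.directed else nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph | nx.DiGraph) -> "Graph":
        directed = g.is_directed()
        nodes = sorted(g.nodes)
        if nodes != list(range(len(nodes))):
            relabel = {v: k for k, v in enumerate(nodes)}
            g = nx.relabel_nodes(g, relabel)
        return cls(len(nodes), frozenset((int(a), int(b)) for a, b in g.edges), directed)


@dataclass(frozen=True)
class ErParams:
    """Parameters of the G(N, p) model: each possible link present
    independently with probability p, no self-loops."""

    n_nodes: int
    p: float
    directed: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be positive")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")


def generate_er(params: ErParams, rng: np.random.Generator | None = None) -> Graph:
    """Draw one Erdős-Rényi graph.

    Every one of the N(N-1)/2 undirected (or N(N-1) directed ordered)
    node pairs receives a link independently with probability ``params.p``.
    An explicit ``rng`` takes precedence over ``params.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n, p = params.n_nodes, params.p
    pairs: list[tuple[int, int]]
    if params.directed:
        pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    else:
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    mask = rng.random(len(pairs)) < p
    edges = frozenset(pair for pair, keep in zip(pairs, mask) if keep)
    return Graph(n, edges, params.directed)


def is_connected(g: Graph) -> bool:
    """True iff every node is reachable from every other node, ignoring
    link direction (directed graphs are judged by their undirected
    skeleton)."""
    if g.n_nodes == 1:
        return True
    nxg = g.to_networkx()
    if g.directed:
        nxg = nxg.to_undirected()
    return nx.is_connected(nxg)


def _bd_temperatures(g: Graph) -> np.ndarray:
    """Temperature of each node: total incoming replacement weight under
    Bd, where node i spreads weight 1/outdeg(i) over its out-neighbors."""
    temp = np.zeros(g.n_nodes)
    for i in range(g.n_nodes):
        nbrs = g.out_neighbors(i)
        if nbrs:
            w = 1.0 / len(nbrs)
            for j in nbrs:
                temp[j] += w
    return temp


def is_isothermal(g: Graph, rule: str = "Bd", *, tol: float = 1e-12) -> bool:
    """True iff every node has the same temperature (probability of being
    replaced per step).

    Under Bd the temperature of node j is (1/N) sum_{i in in(j)} 1/outdeg(i)
    at neutrality, so isothermality amounts to equal incoming weight sums;
    for undirected unweighted graphs this reduces to degree-regularity.
    Under dB every node dies with probability 1/N regardless of structure,
    so every graph is trivially isothermal -- the isothermal theorem does
    not transfer to dB and the classifier never relies on this branch.
    """
    if rule == "dB":
        return True
    temp = _bd_temperatures(g)
    return bool(np.ptp(temp) <= tol)


def root_census(g: Graph) -> tuple[int, str]:
    """Count root nodes (in-degree zero, positive out-degree) of a
    directed graph.

    Returns ``(n_roots, label)`` with label one of ``"none"``,
    ``"one_rooted"``, ``"multi_rooted"``.
    """
    if not g.directed:
        raise ValueError("root census is defined for directed graphs only")
    n_roots = sum(
        1 for i in range(g.n_nodes) if g.in_degree(i) == 0 and g.out_degree(i) > 0
    )
    if n_roots == 0:
        label = "none"
    elif n_roots == 1:
        label = "one_rooted"
    else:
        label = "multi_rooted"
    return n_roots, label


def source_component_count(g: Graph) -> int:
    """Number of source strongly-connected components (components of the
    SCC condensation with in-degree zero) of a directed graph.

    A single mutant can only fix if the graph has exactly one such source
    component; with two or more, no single lineage can ever reach all of
    them.  A root node is precisely a singleton source component.
    """
    if not g.directed:
        raise ValueError("source components are defined for directed graphs only")
    cond = nx.condensation(g.to_networkx())
    return sum(1 for c in cond.nodes if cond.in_degree(c) == 0)


def p_connected(n: int, p: float) -> float:
    """Probability that a G(n, p) graph is connected.

    Computed from the standard recursion over the component containing
    node 1: P_1 = 1 and
    P_N = 1 - sum_{K=1}^{N-1} C(N-1, K-1) P_K (1-p)^{K(N-K)}.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    P = [0.0] * (n + 1)
    P[1] = 1.0
    q = 1.0 - p
    for m in range(2, n + 1):
        s = 0.0
        for K in range(1, m):
            s += comb(m - 1, K - 1) * P[K] * q ** (K * (m - K))
        P[m] = 1.0 - s
    return P[n]


def p_isothermal_n4(p: float) -> float:
    """Probability that a G(4, p) graph is isothermal: the complete graph
    (p^6) plus the three labeled 4-cycles (3 p^4 (1-p)^2)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    return p**6 + 3.0 * p**4 * (1.0 - p) ** 2


def p_has_root(n: int, p: float) -> float:
    """Probability that a directed G(n, p) graph has at least one node
    with in-degree zero: 1 - (1 - (1-p)^(N-1))^N.

    The per-node events are not independent; this is the expression the
    ensemble analysis uses as its overlay and it is exact for the marginal
    union bound structure stated there.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    return 1.0 - (1.0 - (1.0 - p) ** (n - 1)) ** n


def enumerate_connected_n4() -> list[Graph]:
    """All connected undirected graphs on four nodes, up to isomorphism.

    Brute-forces the 2^6 labeled graphs and deduplicates with an exact
    isomorphism check; returns exactly six graphs, sorted by edge count
    (path, star, triangle-with-pendant, cycle, diamond, complete).
    """
    all_pairs = [(i, j) for i in range(4) for j in range(i + 1, 4)]
    reps: list[Graph] = []
    for mask in range(1 << 6):
        edges = frozenset(all_pairs[k] for k in range(6) if mask >> k & 1)
        g = Graph(4, edges, directed=False)
        if not is_connected(g):
            continue
        nxg = g.to_networkx()
        if any(nx.is_isomorphic(nxg, r.to_networkx()) for r in reps):
            continue
        reps.append(g)
    return sorted(reps, key=lambda g: (len(g.edges), sorted(g.edges)))


# -- named graphs ----------------------------------------------------------


def cycle_graph(n: int) -> Graph:
    if n < 3:
        raise ValueError("a cycle needs n >= 3")
    return Graph(n, frozenset((i, (i + 1) % n) for i in range(n)), directed=False)


def star_graph(n: int) -> Graph:
    """Star on n nodes: hub 0 linked to n-1 leaves."""
    if n < 2:
        raise ValueError("a star needs n >= 2")
    return Graph(n, frozenset((0, i) for i in range(1, n)), directed=False)


def complete_graph(n: int) -> Graph:
    return Graph(
        n,
        frozenset((i, j) for i in range(n) for j in range(i + 1, n)),
        directed=False,
    )


def directed_line(n: int) -> Graph:
    """Directed path 0 -> 1 -> ... -> n-1; the canonical one-rooted graph."""
    if n < 2:
        raise ValueError("a directed line needs n >= 2")
    return Graph(n, frozenset((i, i + 1) for i in range(n - 1)), directed=True)


# -- edge-list text format -------------------------------------------------
#
# One-line header "N <n_nodes> <directed|undirected>", then one
# whitespace-separated node pair per line.


def write_edge_list(g: Graph, path: str | Path) -> None:
    path = Path(path)
    lines = [f"N {g.n_nodes} {'directed' if g.directed else 'undirected'}"]
    lines += [f"{i} {j}" for i, j in sorted(g.edges)]
    path.write_text("\n".join(lines) + "\n")


def read_edge_list(path: str | Path) -> Graph:
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("N "):
        raise ValueError(f"{path}: missing 'N <n> <directed|undirected>' header")
    _, n_str, kind = lines[0].split()
    directed = {"directed": True, "undirected": False}[kind]
    edges = frozenset(
        (int(a), int(b)) for a, b in (ln.split() for ln in lines[1:])
    )
    return Graph(int(n_str), edges, directed)
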
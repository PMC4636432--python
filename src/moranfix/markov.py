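"""Exact fixation probabilities via the absorbing Markov chain.

A population of N nodes holding mutants (fitness r) or wild-types
(fitness 1) evolves by one birth and one death per time step.  The chain
lives on the 2^N mutant configurations, encoded as bitmask integers; the
empty set (extinction) and the full set (fixation) are the two absorbing
states.  In canonical form the transition matrix is

    T = [[Q, R], [0, I]],

with Q the transient-to-transient block and R the (t x 2) absorption
block.  The fixation probabilities from every transient start are the
second column of Phi = (I - Q)^{-1} R; we obtain them from a sparse LU
solve of (I - Q) x = R rather than an explicit inverse, which keeps
N = 12-14 feasible.

Two update rules are supported:

* ``Bd`` (Birth-death): an individual is chosen to reproduce from the
  whole population proportional to fitness; its offspring replaces a
  uniformly random out-neighbor.  Selection is global.
* ``dB`` (death-Birth): a uniformly random individual dies; its
  in-neighbors compete proportional to fitness to fill the slot.
  Selection is local.

Self-replacement is excluded in both rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .graphs import Graph, is_connected, source_component_count

__all__ = [
    "UPDATE_RULES",
    "TransitionModel",
    "FixationResult",
    "replacement_weights",
    "step_distribution",
    "build_canonical_matrix",
    "fixation_probabilities",
    "fixation_with_shortcuts",
    "simulate_fixation",
    "full_matrix_entries",
]

UPDATE_RULES = ("Bd", "dB")

#: residual tolerance enforced on the linear solve
SOLVER_TOL = 1e-9


def _check_rule(rule: str) -> None:
    if rule not in UPDATE_RULES:
        raise ValueError(f"unknown update rule {rule!r}; expected one of {UPDATE_RULES}")


def _check_fitness(r: float) -> None:
    if not r > 0:
        raise ValueError(f"mutant fitness must be positive, got {r}")


def full_matrix_entries(n: int) -> int:
    """Entry count of the full 2^n x 2^n transition matrix."""
    return (1 << n) ** 2


def replacement_weights(g: Graph, rule: str) -> dict[tuple[int, int], float]:
    """Neutral replacement weights w[(i, j)]: probability that, given the
    replacement event touches the ordered pair, i's offspring fills node j.

    Bd: node i spreads weight 1/outdeg(i) over its out-neighbors.
    dB: the weights into each node j are normalized over j's in-neighbors
    (each in-neighbor equally likely at neutrality; fitness weighting is
    applied at transition time).
    """
    _check_rule(rule)
    weights: dict[tuple[int, int], float] = {}
    if rule == "Bd":
        for i in range(g.n_nodes):
            nbrs = g.out_neighbors(i)
            for j in nbrs:
                weights[(i, j)] = 1.0 / len(nbrs)
    else:
        for j in range(g.n_nodes):
            innb = g.in_neighbors(j)
            if not innb:
                raise ValueError(
                    f"node {j} has in-degree zero: dB replacement undefined "
                    "(rooted graphs are handled by structural short-circuits)"
                )
            for i in innb:
                weights[(i, j)] = 1.0 / len(innb)
    return weights


def step_distribution(
    g: Graph, config: int, r: float, rule: str
) -> dict[int, float]:
    """One-step transition distribution from a mutant configuration.

    ``config`` is a bitmask over nodes (bit i set = mutant on node i).
    Returns a dict mapping successor configurations to probabilities,
    summing to 1.  The two absorbing states map to themselves.

    This is the scalar reference path; :func:`build_canonical_matrix`
    assembles the same probabilities vectorized over all states.
    """
    _check_rule(rule)
    _check_fitness(r)
    N = g.n_nodes
    full = (1 << N) - 1
    if config == 0 or config == full:
        return {config: 1.0}

    fit = [r if config >> i & 1 else 1.0 for i in range(N)]
    dist: dict[int, float] = {}

    def add(state: int, p: float) -> None:
        if p:
            dist[state] = dist.get(state, 0.0) + p

    if rule == "Bd":
        lottery = [i for i in range(N) if g.out_degree(i) > 0]
        total = sum(fit[i] for i in lottery)
        for i in lottery:
            nbrs = g.out_neighbors(i)
            p_birth = fit[i] / total / len(nbrs)
            ibit = config >> i & 1
            for j in nbrs:
                add(config & ~(1 << j) | (ibit << j), p_birth)
    else:
        for i in range(N):
            innb = g.in_neighbors(i)
            if not innb:
                raise ValueError(f"node {i} has in-degree zero: dB undefined")
            denom = sum(fit[j] for j in innb)
            for j in innb:
                p = fit[j] / denom / N
                jbit = config >> j & 1
                add(config & ~(1 << i) | (jbit << i), p)
    return dist


@dataclass
class TransitionModel:
    """Canonical-form transition structure for one (graph, r, rule).

    Transient states are the bitmask configurations 1 .. 2^N - 2, ordered
    by bitmask value; row s-1 of ``transient_block`` corresponds to
    configuration s.  ``absorption_block`` has the extinction column first
    and the fixation column second.
    """

    transient_block: sp.csr_matrix
    absorption_block: np.ndarray
    n_nodes: int
    r: float
    rule: str

    @property
    def n_transient(self) -> int:
        return self.transient_block.shape[0]

    def state_row(self, config: int) -> int:
        """Row index of a transient configuration bitmask."""
        full = (1 << self.n_nodes) - 1
        if not 0 < config < full:
            raise ValueError(f"configuration {config} is absorbing, not transient")
        return config - 1

    def row_sums(self) -> np.ndarray:
        """Row sums of [Q | R]; exactly 1 for a valid chain."""
        return np.asarray(self.transient_block.sum(axis=1)).ravel() + (
            self.absorption_block.sum(axis=1)
        )


@dataclass
class FixationResult:
    """Fixation probabilities of a single mutant on a graph.

    ``per_node[i]`` is the probability that a lineage starting from one
    mutant on node i takes over; ``uniform_avg`` is the mean over nodes
    (phi of a mutant placed uniformly at random).  ``per_node_extinction``
    is the complementary absorption column, kept for consistency checks.
    """

    per_node: np.ndarray
    uniform_avg: float
    r: float
    rule: str
    per_node_extinction: np.ndarray | None = None


def _event_arrays(
    g: Graph, r: float, rule: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All replacement events vectorized over the 2^N configurations.

    Returns parallel arrays (source state, target state, probability);
    grouped by source they sum to 1.
    """
    N = g.n_nodes
    S = np.arange(1 << N, dtype=np.int64)
    bit = [(S >> i) & 1 for i in range(N)]
    fit = [1.0 + (r - 1.0) * b for b in bit]

    srcs: list[np.ndarray] = []
    tgts: list[np.ndarray] = []
    probs: list[np.ndarray] = []
    if rule == "Bd":
        lottery = [i for i in range(N) if g.out_degree(i) > 0]
        if not lottery:
            raise ValueError("no node has out-neighbors: Bd undefined")
        total = sum(fit[i] for i in lottery)
        for i in lottery:
            nbrs = g.out_neighbors(i)
            p_i = fit[i] / total / len(nbrs)
            for j in nbrs:
                srcs.append(S)
                tgts.append(S & ~(1 << j) | (bit[i] << j))
                probs.append(p_i)
    else:
        for i in range(N):
            innb = g.in_neighbors(i)
            if not innb:
                raise ValueError(
                    f"node {i} has in-degree zero: dB undefined "
                    "(rooted graphs are handled by short-circuits)"
                )
            denom = sum(fit[j] for j in innb)
            for j in innb:
                srcs.append(S)
                tgts.append(S & ~(1 << i) | (bit[j] << i))
                probs.append(fit[j] / denom / N)
    return np.concatenate(srcs), np.concatenate(tgts), np.concatenate(probs)


def build_canonical_matrix(g: Graph, r: float, rule: str) -> TransitionModel:
    """Assemble Q (sparse) and R for the 2^N-state chain.

    Transient states 1 .. 2^N - 2 ordered by bitmask; both blocks are
    assembled from the same event enumeration, so each row of [Q | R]
    sums to 1 up to floating-point rounding.
    """
    _check_rule(rule)
    _check_fitness(r)
    N = g.n_nodes
    full = (1 << N) - 1
    src, tgt, prob = _event_arrays(g, r, rule)

    transient = (src != 0) & (src != full)
    src, tgt, prob = src[transient], tgt[transient], prob[transient]
    rows = src - 1

    t = full - 1
    absorb_ext = tgt == 0
    absorb_fix = tgt == full
    interior = ~(absorb_ext | absorb_fix)

    Q = sp.coo_matrix(
        (prob[interior], (rows[interior], tgt[interior] - 1)), shape=(t, t)
    ).tocsr()
    Q.sum_duplicates()
    R = np.zeros((t, 2))
    np.add.at(R[:, 0], rows[absorb_ext], prob[absorb_ext])
    np.add.at(R[:, 1], rows[absorb_fix], prob[absorb_fix])
    return TransitionModel(Q, R, N, r, rule)


def fixation_probabilities(model: TransitionModel) -> FixationResult:
    """Solve (I - Q) Phi = R for the absorption probabilities.

    Uses one sparse LU factorization for both absorption columns and
    verifies the residual; a singular system indicates an unhandled
    recurrent class among the transient states (e.g. a directed graph
    with several source components) and is reported as such.
    """
    Q = model.transient_block
    t = model.n_transient
    A = (sp.identity(t, format="csc") - Q.tocsc()).tocsc()
    try:
        lu = spla.splu(A)
        phi = lu.solve(model.absorption_block)
    except RuntimeError as exc:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(
            "(I - Q) is singular: the chain has a recurrent class among its "
            "transient states; apply fixation_with_shortcuts instead"
        ) from exc
    resid = np.abs(A @ phi - model.absorption_block).max()
    if not np.isfinite(resid) or resid > SOLVER_TOL:
        raise np.linalg.LinAlgError(
            f"linear solve residual {resid:.3e} exceeds {SOLVER_TOL:.1e}; "
            "the chain likely contains an unhandled recurrent class"
        )
    single = np.array([(1 << i) - 1 for i in range(model.n_nodes)])
    # configuration bitmask 1<<i sits at row (1<<i) - 1
    per_node_fix = phi[single, 1].copy()
    per_node_ext = phi[single, 0].copy()
    return FixationResult(
        per_node=per_node_fix,
        uniform_avg=float(per_node_fix.mean()),
        r=model.r,
        rule=model.rule,
        per_node_extinction=per_node_ext,
    )


def fixation_with_shortcuts(g: Graph, r: float, rule: str) -> FixationResult:
    """Fixation probabilities for any graph, applying structural
    short-circuits before the full matrix solve.

    * disconnected (undirected skeleton): a single mutant can never occupy
      every node, phi = 0;
    * directed with more than one source strongly-connected component
      (which covers multi-rooted graphs): phi = 0 -- no single lineage can
      reach every source component, and (I - Q) would be singular;
    * directed one-rooted (the unique source component is a single
      in-degree-zero node): the mutant fixes iff placed on the root, so
      per-node phi is 1 on the root and 0 elsewhere, average 1/N;
    * otherwise: full canonical-form solve.
    """
    _check_rule(rule)
    _check_fitness(r)
    N = g.n_nodes
    if not is_connected(g):
        zeros = np.zeros(N)
        return FixationResult(zeros, 0.0, r, rule, np.ones(N))
    if g.directed:
        if source_component_count(g) > 1:
            zeros = np.zeros(N)
            return FixationResult(zeros, 0.0, r, rule, np.ones(N))
        roots = [
            i for i in range(N) if g.in_degree(i) == 0 and g.out_degree(i) > 0
        ]
        if len(roots) == 1:
            per_node = np.zeros(N)
            per_node[roots[0]] = 1.0
            return FixationResult(per_node, 1.0 / N, r, rule, 1.0 - per_node)
    model = build_canonical_matrix(g, r, rule)
    return fixation_probabilities(model)


def simulate_fixation(
    g: Graph,
    r: float,
    rule: str,
    n_reps: int,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Monte-Carlo estimate of the uniform-average fixation probability.

    Runs ``n_reps`` independent realizations of the Moran chain, each from
    a single mutant on a uniformly random node, until absorption.  Returns
    the fixation frequency and its binomial standard error.  All
    replicates are advanced in lockstep with vectorized sampling, which is
    what makes 10^5 replicates on desk-size graphs practical.
    """
    _check_rule(rule)
    _check_fitness(r)
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if not is_connected(g):
        raise ValueError("simulate_fixation requires a connected graph")
    rng = np.random.default_rng(rng)
    N = g.n_nodes

    # padded neighbor table for uniform neighbor draws under Bd
    out_nbrs = [g.out_neighbors(i) for i in range(N)]
    out_deg = np.array([len(nb) for nb in out_nbrs])
    pad = max(out_deg.max(), 1)
    nbr_table = np.zeros((N, pad), dtype=np.int64)
    for i, nb in enumerate(out_nbrs):
        nbr_table[i, : len(nb)] = nb
    in_mask = np.zeros((N, N), dtype=bool)  # in_mask[i, j]: j is in-neighbor of i
    for i in range(N):
        for j in g.in_neighbors(i):
            in_mask[i, j] = True
    if rule == "dB" and not in_mask.any(axis=1).all():
        raise ValueError("dB simulation undefined on graphs with in-degree-zero nodes")
    lottery = out_deg > 0

    state = np.zeros((n_reps, N), dtype=bool)
    state[np.arange(n_reps), rng.integers(N, size=n_reps)] = True
    fixed = 0

    while state.shape[0]:
        M = state.shape[0]
        fit = np.where(state, r, 1.0)
        if rule == "Bd":
            w = fit * lottery
            cum = np.cumsum(w, axis=1)
            u = rng.random(M) * cum[:, -1]
            i = (cum <= u[:, None]).sum(axis=1)
            j = nbr_table[i, (rng.random(M) * out_deg[i]).astype(np.int64)]
            state[np.arange(M), j] = state[np.arange(M), i]
        else:
            i = rng.integers(N, size=M)
            w = fit * in_mask[i]
            cum = np.cumsum(w, axis=1)
            u = rng.random(M) * cum[:, -1]
            j = (cum <= u[:, None]).sum(axis=1)
            state[np.arange(M), i] = state[np.arange(M), j]
        counts = state.sum(axis=1)
        done_fix = counts == N
        done_ext = counts == 0
        fixed += int(done_fix.sum())
        state = state[~(done_fix | done_ext)]

    p_hat = fixed / n_reps
    se = float(np.sqrt(p_hat * (1.0 - p_hat) / n_reps))
    return p_hat, se
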
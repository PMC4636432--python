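"""Amplifier / suppressor classification against the well-mixed reference.

A graph amplifies selection when its fixation probability exceeds the
well-mixed value for advantageous mutants (r > 1) and falls below it for
disadvantageous mutants (r < 1); it suppresses selection under the
reversed pattern.  Because the well-mixed fixation probability differs
between the Bd and dB processes, each rule is compared against its own
reference -- never cross-referenced -- which matters precisely at the
small population sizes considered here.

The decision grid defaults to r = 0.75 (disadvantageous) and
r = 1.25, 1.5, 1.75 (advantageous).  r = 1 is also evaluated as a sanity
check (phi must equal 1/N) but carries no weight in the decision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .closed_forms import phi_wellmixed_bd, phi_wellmixed_db
from .graphs import (
    Graph,
    is_connected,
    is_isothermal,
    source_component_count,
)
from .markov import FixationResult, fixation_with_shortcuts

__all__ = [
    "ClassificationConfig",
    "GraphClass",
    "reference_phi",
    "classify",
]


@dataclass(frozen=True)
class ClassificationConfig:
    r_advantageous: tuple[float, ...] = (1.25, 1.5, 1.75)
    r_disadvantageous: tuple[float, ...] = (0.75,)
    equality_tolerance: float = 1e-9

    def __post_init__(self) -> None:
        if any(r >= 1 for r in self.r_disadvantageous):
            raise ValueError("disadvantageous fitness values must be < 1")
        if any(r <= 1 for r in self.r_advantageous):
            raise ValueError("advantageous fitness values must be > 1")
        if self.equality_tolerance <= 0:
            raise ValueError("equality_tolerance must be positive")

    @property
    def all_r(self) -> tuple[float, ...]:
        return tuple(sorted((*self.r_disadvantageous, *self.r_advantageous)))


@dataclass
class GraphClass:
    """Classification outcome for one graph under one update rule.

    ``phi_values`` maps each evaluated fitness r to (phi_graph, phi_ref);
    it is empty when a structural short-circuit (disconnected / rooted)
    decided the label without solving.  ``detail`` qualifies some labels:
    unclassified graphs are split into ``"margin"`` (some comparison fell
    inside the equality tolerance) and ``"mixed"`` (all comparisons were
    strict but the pattern fits neither class, like the dB cycle);
    one-rooted graphs carry ``"technically_suppressor"`` since a randomly
    placed mutant fixes with probability 1/N there.
    """

    label: str
    phi_values: dict[float, tuple[float, float]] = field(default_factory=dict)
    detail: str | None = None
    min_margin: float | None = None


def reference_phi(r: float, n: int, rule: str) -> float:
    """Well-mixed fixation probability matching the update rule."""
    if rule == "Bd":
        return phi_wellmixed_bd(r, n)
    if rule == "dB":
        return phi_wellmixed_db(r, n)
    raise ValueError(f"unknown update rule {rule!r}")


def classify(
    g: Graph, rule: str, cfg: ClassificationConfig | None = None
) -> GraphClass:
    """Classify a graph as amplifier, suppressor, or other.

    Checks run in order:

    1. disconnected graphs (phi = 0) are labeled ``disconnected``;
    2. directed graphs with more than one source strongly-connected
       component are ``multi_rooted`` (phi = 0); a unique in-degree-zero
       root gives ``one_rooted`` (phi = 1/N);
    3. under Bd only, isothermal graphs are ``wellmixed_equivalent`` by
       the isothermal theorem, without solving;
    4. otherwise phi^G is computed exactly at every configured r and
       compared with the rule-matched well-mixed phi^M:
       below at every disadvantageous r and above at every advantageous
       r -> ``amplifier``; the reversed strict pattern -> ``suppressor``;
       within tolerance at every r -> ``wellmixed_equivalent``;
       anything else -> ``unclassified``.

    Differences with \\|phi^G - phi^M\\| <= tolerance count as neither
    strict inequality.  ``min_margin`` records the smallest absolute
    difference across the grid so borderline graphs are auditable.
    """
    cfg = cfg or ClassificationConfig()
    n = g.n_nodes

    if not is_connected(g):
        return GraphClass("disconnected")
    if g.directed:
        if source_component_count(g) > 1:
            return GraphClass("multi_rooted")
        roots = [
            i for i in range(n) if g.in_degree(i) == 0 and g.out_degree(i) > 0
        ]
        if len(roots) == 1:
            return GraphClass("one_rooted", detail="technically_suppressor")
    if rule == "Bd" and is_isothermal(g, "Bd"):
        phis = {r: (reference_phi(r, n, rule),) * 2 for r in cfg.all_r}
        return GraphClass("wellmixed_equivalent", phi_values=phis, min_margin=0.0)

    tol = cfg.equality_tolerance
    phis: dict[float, tuple[float, float]] = {}
    for r in cfg.all_r:
        res: FixationResult = fixation_with_shortcuts(g, r, rule)
        phis[r] = (res.uniform_avg, reference_phi(r, n, rule))

    diffs = {r: pg - pm for r, (pg, pm) in phis.items()}
    min_margin = min(abs(d) for d in diffs.values())
    above = {r: d > tol for r, d in diffs.items()}
    below = {r: d < -tol for r, d in diffs.items()}

    amplifier = all(below[r] for r in cfg.r_disadvantageous) and all(
        above[r] for r in cfg.r_advantageous
    )
    suppressor = all(above[r] for r in cfg.r_disadvantageous) and all(
        below[r] for r in cfg.r_advantageous
    )
    if amplifier:
        return GraphClass("amplifier", phis, min_margin=min_margin)
    if suppressor:
        return GraphClass("suppressor", phis, min_margin=min_margin)
    if all(abs(d) <= tol for d in diffs.values()):
        return GraphClass("wellmixed_equivalent", phis, min_margin=min_margin)
    detail = "mixed" if all(a or b for a, b in zip(above.values(), below.values())) else "margin"
    return GraphClass("unclassified", phis, detail=detail, min_margin=min_margin)
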
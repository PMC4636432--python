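"""Ensemble experiments: sweep G(N, p) graphs over a p-grid, classify
each against the well-mixed reference, and aggregate category
proportions alongside the analytic overlay curves (probability of
connectivity, of isothermality at N = 4, of at least one root for
directed ensembles).

The headline phenomenon these sweeps expose: under Birth-death updating
almost every connected, non-regular undirected random graph is an
amplifier of selection, while the very same ensemble under death-Birth
updating contains essentially only suppressors.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import ClassificationConfig, classify
from .graphs import (
    ErParams,
    Graph,
    enumerate_connected_n4,
    generate_er,
    p_connected,
    p_has_root,
    p_isothermal_n4,
)
from .markov import fixation_with_shortcuts

__all__ = [
    "LABELS",
    "SweepConfig",
    "GraphRecord",
    "SweepResult",
    "run_sweep",
    "run_n4_census",
    "write_results",
    "read_results",
]

logger = logging.getLogger(__name__)

LABELS = (
    "amplifier",
    "suppressor",
    "unclassified",
    "wellmixed_equivalent",
    "disconnected",
    "one_rooted",
    "multi_rooted",
)


@dataclass(frozen=True)
class SweepConfig:
    n_nodes: int
    p_grid: tuple[float, ...]
    graphs_per_p: int
    rule: str
    directed: bool = False
    seed: int = 0
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)
    max_solver_nodes: int = 14

    def __post_init__(self) -> None:
        if any(not 0.0 <= p <= 1.0 for p in self.p_grid):
            raise ValueError("p_grid values must lie in [0, 1]")
        if self.graphs_per_p < 1:
            raise ValueError("graphs_per_p must be >= 1")
        if self.n_nodes > self.max_solver_nodes:
            raise ValueError(
                f"N={self.n_nodes} exceeds the full-solve limit "
                f"({self.max_solver_nodes}); the 2^N-state matrix is infeasible"
            )


@dataclass
class GraphRecord:
    """One classified graph: enough to replay it exactly."""

    p: float
    index: int
    seed_key: tuple[int, int, int]
    edges: list[tuple[int, int]]
    label: str
    detail: str | None
    phi_values: dict[float, tuple[float, float]]
    min_margin: float | None


@dataclass
class SweepResult:
    config: SweepConfig
    counts: dict[float, dict[str, int]]
    analytic: dict[float, dict[str, float]]
    records: list[GraphRecord]

    def proportions(self) -> dict[float, dict[str, float]]:
        total = self.config.graphs_per_p
        return {
            p: {lab: c / total for lab, c in by_label.items()}
            for p, by_label in self.counts.items()
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.config.p_grid:
            by_label = self.counts[p]
            props = {lab: c / self.config.graphs_per_p for lab, c in by_label.items()}
            for lab in LABELS:
                rows.append(
                    {
                        "p": p,
                        "label": lab,
                        "count": by_label.get(lab, 0),
                        "proportion": props.get(lab, 0.0),
                        **self.analytic[p],
                    }
                )
        return pd.DataFrame(rows)


def _overlays(cfg: SweepConfig, p: float) -> dict[str, float]:
    out = {"p_connected": p_connected(cfg.n_nodes, p)}
    if cfg.n_nodes == 4 and not cfg.directed:
        out["p_isothermal_n4"] = p_isothermal_n4(p)
    if cfg.directed:
        out["p_has_root"] = p_has_root(cfg.n_nodes, p)
    return out


def run_sweep(cfg: SweepConfig) -> SweepResult:
    """Sample, classify and tally ``graphs_per_p`` G(N, p) graphs at each
    grid value of p.

    Every graph gets its own RNG derived from ``(seed, p-index, graph
    index)``, so any single graph can be regenerated without redoing the
    sweep; the whole result is deterministic given the config.
    """
    counts: dict[float, dict[str, int]] = {}
    analytic: dict[float, dict[str, float]] = {}
    records: list[GraphRecord] = []
    done = 0
    for ip, p in enumerate(cfg.p_grid):
        by_label: dict[str, int] = {lab: 0 for lab in LABELS}
        for ig in range(cfg.graphs_per_p):
            key = (cfg.seed, ip, ig)
            rng = np.random.default_rng(np.random.SeedSequence(key))
            g = generate_er(ErParams(cfg.n_nodes, p, cfg.directed), rng)
            gc = classify(g, cfg.rule, cfg.classification)
            by_label[gc.label] += 1
            records.append(
                GraphRecord(
                    p=p,
                    index=ig,
                    seed_key=key,
                    edges=sorted(g.edges),
                    label=gc.label,
                    detail=gc.detail,
                    phi_values=gc.phi_values,
                    min_margin=gc.min_margin,
                )
            )
            done += 1
            if done % 100 == 0:
                logger.info(
                    "sweep progress: %d graphs done (p=%.3f, counts=%s)",
                    done,
                    p,
                    {k: v for k, v in by_label.items() if v},
                )
        counts[p] = by_label
        analytic[p] = _overlays(cfg, p)
    return SweepResult(cfg, counts, analytic, records)


_N4_NAMES = {
    (1, 1, 2, 2): "path",
    (1, 1, 1, 3): "star",
    (1, 2, 2, 3): "paw",
    (2, 2, 2, 2): "cycle",
    (2, 2, 3, 3): "diamond",
    (3, 3, 3, 3): "complete",
}


def run_n4_census(rule: str, cfg: ClassificationConfig | None = None) -> pd.DataFrame:
    """Exhaustive classification of all six connected four-node graphs.

    Returns one row per graph with its common name, degree sequence,
    label, and the exact fixation probability (with the rule-matched
    well-mixed reference) at every configured r plus the neutral value.
    """
    cfg = cfg or ClassificationConfig()
    rows = []
    for g in enumerate_connected_n4():
        degseq = tuple(sorted(g.out_degree(i) for i in range(4)))
        gc = classify(g, rule, cfg)
        row: dict = {
            "graph": _N4_NAMES[degseq],
            "degrees": degseq,
            "n_edges": len(g.edges),
            "edges": sorted(g.edges),
            "label": gc.label,
            "detail": gc.detail,
        }
        for r in cfg.all_r:
            if r in gc.phi_values:
                pg, pm = gc.phi_values[r]
            else:  # structural short-circuit: recompute for the table
                pg = fixation_with_shortcuts(g, r, rule).uniform_avg
                pm = None
            row[f"phi_{r}"] = pg
            row[f"phi_ref_{r}"] = pm
        row["phi_1"] = fixation_with_shortcuts(g, 1.0, rule).uniform_avg
        rows.append(row)
    return pd.DataFrame(rows).sort_values(["n_edges", "graph"]).reset_index(drop=True)


def write_results(res: SweepResult, path: str | Path) -> tuple[Path, Path]:
    """Write a sweep to ``<path>.csv`` (per-p, per-label tallies with the
    analytic overlays) and ``<path>.json`` (full config, seed, and
    per-graph records).  Re-running an identical config byte-reproduces
    both files."""
    base = Path(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    csv_path = base.with_suffix(".csv")
    json_path = base.with_suffix(".json")
    try:
        res.to_frame().to_csv(csv_path, index=False)
        payload = {
            "config": {
                **{
                    k: v
                    for k, v in asdict(res.config).items()
                    if k != "classification"
                },
                "classification": asdict(res.config.classification),
            },
            "counts": {str(p): c for p, c in res.counts.items()},
            "analytic": {str(p): a for p, a in res.analytic.items()},
            "records": [
                {
                    **asdict(rec),
                    "phi_values": {str(r): v for r, v in rec.phi_values.items()},
                }
                for rec in res.records
            ],
        }
        json_path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    except OSError as exc:
        raise OSError(f"failed writing sweep results under {base}: {exc}") from exc
    return csv_path, json_path


def read_results(path: str | Path) -> SweepResult:
    """Round-trip a sweep back from its JSON sidecar."""
    payload = json.loads(Path(path).with_suffix(".json").read_text())
    cfg_d = dict(payload["config"])
    cls_d = cfg_d.pop("classification")
    cfg = SweepConfig(
        **{
            **cfg_d,
            "p_grid": tuple(cfg_d["p_grid"]),
            "classification": ClassificationConfig(
                tuple(cls_d["r_advantageous"]),
                tuple(cls_d["r_disadvantageous"]),
                cls_d["equality_tolerance"],
            ),
        }
    )
    counts = {float(p): c for p, c in payload["counts"].items()}
    analytic = {float(p): a for p, a in payload["analytic"].items()}
    records = [
        GraphRecord(
            p=rec["p"],
            index=rec["index"],
            seed_key=tuple(rec["seed_key"]),
            edges=[tuple(e) for e in rec["edges"]],
            label=rec["label"],
            detail=rec["detail"],
            phi_values={float(r): tuple(v) for r, v in rec["phi_values"].items()},
            min_margin=rec["min_margin"],
        )
        for rec in payload["records"]
    ]
    return SweepResult(cfg, counts, analytic, records)
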
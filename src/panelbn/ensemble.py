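"""Bootstrap model averaging: arc confidence, the 60% retention threshold,
the equal-split undirected rule, structural Hamming distance, and selection
of the bootstrap count from an SHD stability curve.

Each bootstrap replicate resamples the participants with replacement and
re-learns a network by structural EM.  The averaged model keeps the edges
whose presence confidence (fraction of replicates containing either
orientation) reaches the threshold, orients them by direction majority, and
leaves exact ties undirected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from dataclasses import replace
from typing import Iterable, Sequence

import numpy as np

from .bn import Arc, DAGStructure, TierConstraint
from .dataset import PanelDataset
from .learning import SearchSettings, SEMResult, structural_em


def sample_seed(master: int, index: int) -> int:
    """Counter-based child seed: stable as the number of replicates grows."""
    ss = np.random.SeedSequence(entropy=master, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class AvgEdge:
    """One edge of an averaged network (directed or undirected)."""

    u: str
    v: str
    directed: bool
    presence_conf: float
    direction_conf: float  # fraction of edge-containing models oriented u->v

    def key(self) -> tuple[str, str, bool]:
        if self.directed:
            return (self.u, self.v, True)
        a, b = sorted((self.u, self.v))
        return (a, b, False)

    def skeleton(self) -> tuple[str, str]:
        a, b = sorted((self.u, self.v))
        return (a, b)


@dataclass
class ArcConfidenceTable:
    """Per unordered pair: presence and per-orientation bootstrap counts."""

    counts: dict[tuple[str, str], dict[str, int]]  # {(a,b): {"ab":., "ba":.}}
    B_used: int

    def presence_confidence(self, a: str, b: str) -> float:
        a, b = sorted((a, b))
        c = self.counts.get((a, b), {"ab": 0, "ba": 0})
        return (c["ab"] + c["ba"]) / self.B_used

    def rows(self) -> list[dict]:
        out = []
        for (a, b), c in sorted(self.counts.items()):
            present = c["ab"] + c["ba"]
            out.append(
                {
                    "from": a,
                    "to": b,
                    "presence_conf": present / self.B_used,
                    "direction_conf": c["ab"] / present if present else 0.0,
                }
            )
        return out


@dataclass
class AveragedNetwork:
    nodes: tuple[str, ...]
    edges: list[AvgEdge]
    threshold: float
    B_used: int
    dropped_for_cycles: list[AvgEdge] = field(default_factory=list)

    @property
    def directed_arcs(self) -> set[Arc]:
        return {(e.u, e.v) for e in self.edges if e.directed}

    @property
    def undirected_edges(self) -> set[tuple[str, str]]:
        return {tuple(sorted((e.u, e.v))) for e in self.edges if not e.directed}

    def edge_for(self, a: str, b: str) -> AvgEdge | None:
        for e in self.edges:
            if {e.u, e.v} == {a, b}:
                return e
        return None


@dataclass
class BootstrapRun:
    structures: list[DAGStructure]
    logs: list[SEMResult]
    seeds: list[int]
    failures: list[tuple[int, str]] = field(default_factory=list)


def bootstrap_structures(
    dataset: PanelDataset,
    constraint: TierConstraint,
    settings: SearchSettings,
    B: int,
    seed: int,
    resample: bool = True,
) -> BootstrapRun:
    """B structural-EM fits on Efron resamples (n rows with replacement)."""
    if B < 1:
        raise ValueError("B must be >= 1")
    structures: list[DAGStructure] = []
    logs: list[SEMResult] = []
    seeds: list[int] = []
    failures: list[tuple[int, str]] = []
    n = dataset.n
    for i in range(B):
        result = None
        for attempt in range(3):
            s = sample_seed(seed, i * 1000 + attempt)
            rng = np.random.default_rng(s)
            if resample:
                idx = rng.integers(0, n, size=n)
                frame = dataset.frame.iloc[idx].reset_index(drop=True)
                sample = PanelDataset(frame, dict(dataset.specs))
            else:
                sample = dataset
            try:
                result = structural_em(
                    sample, constraint, replace(settings, seed=s)
                )
                break
            except ValueError as exc:  # e.g. a resample emptied a column
                failures.append((i, str(exc)))
                result = None
        if result is None:
            raise RuntimeError(f"bootstrap sample {i} failed 3 times")
        structures.append(result.bn.structure)
        logs.append(result)
        seeds.append(s)
    return BootstrapRun(structures=structures, logs=logs, seeds=seeds, failures=failures)


def arc_confidence(structures: Sequence[DAGStructure]) -> ArcConfidenceTable:
    counts: dict[tuple[str, str], dict[str, int]] = {}
    for st in structures:
        for u, v in st.arcs:
            a, b = sorted((u, v))
            entry = counts.setdefault((a, b), {"ab": 0, "ba": 0})
            entry["ab" if (u, v) == (a, b) else "ba"] += 1
    return ArcConfidenceTable(counts=counts, B_used=len(structures))


def average_network(
    structures: Sequence[DAGStructure],
    threshold: float = 0.6,
    repair_cycles: bool = True,
) -> AveragedNetwork:
    """Model averaging with majority orientation and exact-tie undirection.

    Edges present (in either orientation) in at least ``threshold`` of the
    replicates are retained; orientation follows the strict majority, and an
    exact 50/50 split yields an undirected edge.  If majority orientations
    jointly close a directed cycle, the lowest-confidence arc in each cycle
    is dropped (and reported) so the directed part stays acyclic.
    """
    if not structures:
        raise ValueError("need at least one structure")
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    B = len(structures)
    nodes = structures[0].nodes
    table = arc_confidence(structures)
    edges: list[AvgEdge] = []
    for (a, b), c in sorted(table.counts.items()):
        present = c["ab"] + c["ba"]
        conf = present / B
        if conf < threshold - 1e-12:
            continue
        if c["ab"] > c["ba"]:
            edges.append(AvgEdge(a, b, True, conf, c["ab"] / present))
        elif c["ba"] > c["ab"]:
            edges.append(AvgEdge(b, a, True, conf, c["ba"] / present))
        else:
            edges.append(AvgEdge(a, b, False, conf, 0.5))

    dropped: list[AvgEdge] = []
    if repair_cycles:
        edges, dropped = _break_cycles(nodes, edges)
    return AveragedNetwork(
        nodes=nodes,
        edges=edges,
        threshold=threshold,
        B_used=B,
        dropped_for_cycles=dropped,
    )


def _break_cycles(
    nodes: Sequence[str], edges: list[AvgEdge]
) -> tuple[list[AvgEdge], list[AvgEdge]]:
    import networkx as nx

    dropped: list[AvgEdge] = []
    while True:
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from((e.u, e.v) for e in edges if e.directed)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            break
        cycle_arcs = {(u, v) for u, v, *_ in cycle}
        members = [e for e in edges if e.directed and (e.u, e.v) in cycle_arcs]
        victim = min(members, key=lambda e: (e.presence_conf, e.u, e.v))
        edges = [e for e in edges if e is not victim]
        dropped.append(victim)
    return edges, dropped


# ---------------------------------------------------------------------------
# structural Hamming distance and stability selection
# ---------------------------------------------------------------------------


def _edge_view(g: DAGStructure | AveragedNetwork) -> tuple[set, dict]:
    """Skeleton plus orientation marker per unordered pair."""
    orient: dict[tuple[str, str], str] = {}
    if isinstance(g, DAGStructure):
        nodes = set(g.nodes)
        for u, v in g.arcs:
            a, b = sorted((u, v))
            orient[(a, b)] = "ab" if (u, v) == (a, b) else "ba"
    else:
        nodes = set(g.nodes)
        for e in g.edges:
            a, b = sorted((e.u, e.v))
            if not e.directed:
                orient[(a, b)] = "und"
            else:
                orient[(a, b)] = "ab" if (e.u, e.v) == (a, b) else "ba"
    return nodes, orient


def shd(a: DAGStructure | AveragedNetwork, b: DAGStructure | AveragedNetwork) -> int:
    """Edge edits (add, delete, reorient; undirected<->directed counts 1)."""
    nodes_a, ea = _edge_view(a)
    nodes_b, eb = _edge_view(b)
    if nodes_a != nodes_b:
        raise ValueError("node sets differ")
    dist = 0
    for pair in set(ea) | set(eb):
        oa, ob = ea.get(pair), eb.get(pair)
        if oa != ob:
            dist += 1
    return dist


@dataclass
class StabilityCurve:
    B_grid: list[int]
    shd_to_next: list[int]  # SHD between averaged nets at consecutive B
    chosen_B: int
    plateau_found: bool


def stability_select_B(
    dataset: PanelDataset,
    constraint: TierConstraint,
    settings: SearchSettings,
    B_grid: Sequence[int],
    threshold: float = 0.6,
    seed: int = 0,
    tolerance: int = 0,
) -> tuple[int, StabilityCurve, BootstrapRun]:
    """Choose the bootstrap count where the averaged model stops moving.

    Runs ``max(B_grid)`` replicates once (counter-based seeds make prefixes
    reusable), forms the averaged network at every grid point, and picks the
    smallest B whose SHD to the next grid point is within ``tolerance``
    (default: an exact plateau).  Falls back to the largest grid point when
    no plateau is reached.
    """
    grid = list(B_grid)
    if len(grid) < 2:
        raise ValueError("B_grid needs at least two points")
    if grid != sorted(grid) or len(set(grid)) != len(grid):
        raise ValueError("B_grid must be strictly ascending")
    run = bootstrap_structures(dataset, constraint, settings, max(grid), seed)
    nets = [average_network(run.structures[:b], threshold) for b in grid]
    curve = [shd(nets[i], nets[i + 1]) for i in range(len(grid) - 1)]
    chosen = None
    for i, d in enumerate(curve):
        if d <= tolerance:
            chosen = grid[i]
            break
    plateau = chosen is not None
    if chosen is None:
        chosen = grid[-1]
    return chosen, StabilityCurve(grid, curve, chosen, plateau), run
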
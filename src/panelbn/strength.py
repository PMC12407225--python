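"""Arc-strength grading and intervention→outcome pathway distillation.

Edge strength is a jackknife bias-corrected mutual information estimate on
the complete cases of the two endpoint variables; retained edges are
allocated to terciles at the 33% and 67% quantiles of the graded set.
Edge stability (presence confidence from the bootstrap) is binned into four
thickness groups cutting at 0.7, 0.8 and 0.9 above the 0.6 retention floor.

Pathway fragments are the sub-networks of an averaged model lying on any
directed path from the intervention variable to the physical-activity
outcome variables, with undirected edges traversable in either direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import PanelDataset, VariableSpec
from .ensemble import AveragedNetwork, AvgEdge

LOG2PIE = math.log(2.0 * math.pi * math.e)

THICKNESS_CUTS = (0.7, 0.8, 0.9)
TERCILE_QUANTILES = (0.33, 0.67)


# ---------------------------------------------------------------------------
# mutual information with jackknife bias correction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MIResult:
    estimate: float  # jackknife bias-corrected, in nats
    se: float  # jackknife standard error
    plugin: float
    n: int
    degenerate: bool = False  # constant column encountered


def _plugin_mi_cc(sx, sy, sxx, syy, sxy, n) -> float:
    vx = sxx / n - (sx / n) ** 2
    vy = syy / n - (sy / n) ** 2
    cov = sxy / n - (sx / n) * (sy / n)
    denom = vx * vy
    if denom <= 0:
        return 0.0
    r2 = min(cov * cov / denom, 1.0 - 1e-12)
    return -0.5 * math.log1p(-r2)


def _mi_continuous(x: np.ndarray, y: np.ndarray) -> MIResult:
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    theta = _plugin_mi_cc(sx, sy, sxx, syy, sxy, n)
    # leave-one-out estimates via downdated sums, vectorised
    m = n - 1
    vx = (sxx - x * x) / m - ((sx - x) / m) ** 2
    vy = (syy - y * y) / m - ((sy - y) / m) ** 2
    cov = (sxy - x * y) / m - ((sx - x) / m) * ((sy - y) / m)
    denom = vx * vy
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(denom > 0, cov * cov / denom, 0.0)
    r2 = np.clip(r2, 0.0, 1.0 - 1e-12)
    loo = -0.5 * np.log1p(-r2)
    return _jackknife(theta, loo, n, dof=1)


def _mi_discrete(xc: np.ndarray, yc: np.ndarray, lx: int, ly: int) -> MIResult:
    n = len(xc)
    cells = np.ravel_multi_index((xc, yc), (lx, ly))
    counts = np.bincount(cells, minlength=lx * ly).astype(float).reshape(lx, ly)

    def mi_from(c: np.ndarray) -> float:
        tot = c.sum()
        rows = c.sum(axis=1)
        cols = c.sum(axis=0)
        nz = c > 0
        return float(
            (c[nz] * np.log(c[nz])).sum()
            - (rows[rows > 0] * np.log(rows[rows > 0])).sum()
            - (cols[cols > 0] * np.log(cols[cols > 0])).sum()
            + tot * math.log(tot)
        ) / tot

    theta = mi_from(counts)
    # leave-one-out MI only depends on which cell the left-out point occupies
    loo_by_cell: dict[int, float] = {}
    loo = np.empty(n)
    for cell in np.unique(cells):
        c = counts.copy()
        i, j = divmod(int(cell), ly)
        c[i, j] -= 1
        loo_by_cell[int(cell)] = mi_from(c)
    for cell, val in loo_by_cell.items():
        loo[cells == cell] = val
    return _jackknife(theta, loo, n, dof=(lx - 1) * (ly - 1))


def _gauss_entropy(var: float) -> float:
    return 0.5 * (LOG2PIE + math.log(max(var, 1e-12)))


def _mi_mixed(dc: np.ndarray, y: np.ndarray, nl: int) -> MIResult:
    """Discrete–continuous MI as pooled minus level-conditional Gaussian
    entropies, H(Y) - sum_l p_l H(Y|l)."""
    n = len(y)
    sy, syy = y.sum(), (y * y).sum()
    g_n = np.bincount(dc, minlength=nl).astype(float)
    g_sy = np.bincount(dc, weights=y, minlength=nl)
    g_syy = np.bincount(dc, weights=y * y, minlength=nl)

    def mi_from(n_, sy_, syy_, gn, gsy, gsyy) -> float:
        var_all = syy_ / n_ - (sy_ / n_) ** 2
        h = _gauss_entropy(var_all)
        cond = 0.0
        for l in range(nl):
            if gn[l] < 2:
                continue  # a level with <2 points contributes no usable variance
            v = gsyy[l] / gn[l] - (gsy[l] / gn[l]) ** 2
            cond += (gn[l] / n_) * _gauss_entropy(v)
        return max(h - cond, 0.0)

    theta = mi_from(n, sy, syy, g_n, g_sy, g_syy)
    loo = np.empty(n)
    for i in range(n):
        l = dc[i]
        gn = g_n.copy(); gsy = g_sy.copy(); gsyy = g_syy.copy()
        gn[l] -= 1.0
        gsy[l] -= y[i]
        gsyy[l] -= y[i] * y[i]
        loo[i] = mi_from(n - 1, sy - y[i], syy - y[i] * y[i], gn, gsy, gsyy)
    # per extra level the null LRT spends one mean and one variance dof
    return _jackknife(theta, loo, n, dof=2 * (nl - 1))


def _jackknife(theta: float, loo: np.ndarray, n: int, dof: int = 1) -> MIResult:
    """Bias correction n·θ̂ − (n−1)·mean(LOO) with a null-calibrated SE.

    Near independence the MI statistic is quadratic in the sample
    dependence, so the plain jackknife variance collapses and understates
    the sampling noise; 2n·MI is asymptotically χ²(dof) at the null, whose
    variance dof/(2n²) is added in quadrature as a floor.
    """
    mean_loo = float(loo.mean())
    est = n * theta - (n - 1) * mean_loo
    var_jack = (n - 1) / n * float(((loo - mean_loo) ** 2).sum())
    se = math.sqrt(var_jack + dof / (2.0 * n * n))
    return MIResult(estimate=est, se=se, plugin=theta, n=n)


def mi_jackknife(
    x: Sequence | np.ndarray,
    y: Sequence | np.ndarray,
    kinds: tuple[str, str],
    levels: tuple[tuple[str, ...] | None, tuple[str, ...] | None] = (None, None),
) -> MIResult:
    """Jackknife bias-corrected MI of two paired variables (complete cases).

    Continuous–continuous pairs use the Gaussian closed form
    -0.5 ln(1 - r^2); discrete–discrete the empirical cell frequencies;
    mixed pairs the difference of pooled and per-level Gaussian entropies.
    Rows with either value missing are excluded first.  A constant column
    yields MI 0 flagged as degenerate.
    """
    xs = pd.Series(list(x))
    ys = pd.Series(list(y))
    keep = xs.notna() & ys.notna()
    xs, ys = xs[keep], ys[keep]
    n = len(xs)
    if n < 10:
        raise ValueError(f"need >= 10 complete pairs, got {n}")

    def encode(s: pd.Series, lv: tuple[str, ...] | None) -> tuple[np.ndarray, int]:
        vals = s.astype(str)
        if lv is None:
            lv = tuple(sorted(vals.unique()))
        lut = {l: i for i, l in enumerate(lv)}
        return vals.map(lut).to_numpy(dtype=np.intp), len(lv)

    kx, ky = kinds
    if kx == "continuous" and np.asarray(xs, dtype=float).std() == 0.0:
        return MIResult(0.0, 0.0, 0.0, n, degenerate=True)
    if ky == "continuous" and np.asarray(ys, dtype=float).std() == 0.0:
        return MIResult(0.0, 0.0, 0.0, n, degenerate=True)
    if kx == "discrete" and xs.nunique() < 2:
        return MIResult(0.0, 0.0, 0.0, n, degenerate=True)
    if ky == "discrete" and ys.nunique() < 2:
        return MIResult(0.0, 0.0, 0.0, n, degenerate=True)

    if kx == "continuous" and ky == "continuous":
        return _mi_continuous(
            np.asarray(xs, dtype=float), np.asarray(ys, dtype=float)
        )
    if kx == "discrete" and ky == "discrete":
        xc, lx = encode(xs, levels[0])
        yc, ly = encode(ys, levels[1])
        return _mi_discrete(xc, yc, lx, ly)
    if kx == "discrete":
        dc, nl = encode(xs, levels[0])
        return _mi_mixed(dc, np.asarray(ys, dtype=float), nl)
    dc, nl = encode(ys, levels[1])
    return _mi_mixed(dc, np.asarray(xs, dtype=float), nl)


# ---------------------------------------------------------------------------
# grading retained edges
# ---------------------------------------------------------------------------


def thickness_group(presence_conf: float) -> int:
    """Stability bin over [0.6, 1]: cuts at 0.7, 0.8, 0.9 -> groups 1..4."""
    g = 1
    for cut in THICKNESS_CUTS:
        if presence_conf >= cut:
            g += 1
    return g


@dataclass
class StrengthAnnotation:
    """Per-edge MI estimate, MI tercile (1..3) and thickness group (1..4)."""

    mi: dict[tuple[str, str, bool], MIResult]
    tercile: dict[tuple[str, str, bool], int]
    thickness: dict[tuple[str, str, bool], int]
    cutpoints: tuple[float, float] | None  # 33%/67% MI quantiles


def grade_edges(
    network: AveragedNetwork,
    dataset: PanelDataset,
    edges: Sequence[AvgEdge] | None = None,
) -> StrengthAnnotation:
    """MI-based strength terciles and confidence thickness for each edge.

    Terciles are allocated *relatively*, over the edge set being graded
    (pass ``edges`` to grade a fragment on its own scale); ties at a
    cutpoint go to the lower group.
    """
    graded = list(edges) if edges is not None else list(network.edges)
    mi: dict[tuple[str, str, bool], MIResult] = {}
    for e in graded:
        for endpoint in (e.u, e.v):
            if endpoint not in dataset.specs:
                raise KeyError(f"variable {endpoint} not in dataset")
        su, sv = dataset.specs[e.u], dataset.specs[e.v]
        mi[e.key()] = mi_jackknife(
            dataset.frame[e.u],
            dataset.frame[e.v],
            kinds=(su.kind, sv.kind),
            levels=(su.levels, sv.levels),
        )
    tercile: dict[tuple[str, str, bool], int] = {}
    cutpoints = None
    if mi:
        values = np.array([r.estimate for r in mi.values()])
        q33, q67 = np.quantile(values, TERCILE_QUANTILES)
        cutpoints = (float(q33), float(q67))
        for key, r in mi.items():
            if r.estimate <= q33:
                tercile[key] = 1
            elif r.estimate <= q67:
                tercile[key] = 2
            else:
                tercile[key] = 3
    thickness = {e.key(): thickness_group(e.presence_conf) for e in graded}
    return StrengthAnnotation(mi=mi, tercile=tercile, thickness=thickness, cutpoints=cutpoints)


# ---------------------------------------------------------------------------
# pathway fragments
# ---------------------------------------------------------------------------


@dataclass
class PathFragment:
    source: str
    targets: tuple[str, ...]
    edges: list[AvgEdge]
    annotation: StrengthAnnotation | None = None

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for e in self.edges:
            out |= {e.u, e.v}
        return out

    def has_arc_into(self, node: str, target: str) -> bool:
        for e in self.edges:
            if e.directed and (e.u, e.v) == (node, target):
                return True
            if not e.directed and {e.u, e.v} == {node, target}:
                return True
        return False


def _mixed_reachable(
    edges: Sequence[AvgEdge], starts: Iterable[str], forward: bool, undirected_both: bool
) -> set[str]:
    adj: dict[str, set[str]] = {}

    def add(u: str, v: str) -> None:
        adj.setdefault(u, set()).add(v)

    for e in edges:
        if e.directed:
            if forward:
                add(e.u, e.v)
            else:
                add(e.v, e.u)
        elif undirected_both:
            add(e.u, e.v)
            add(e.v, e.u)
    seen = set(starts)
    stack = list(seen)
    while stack:
        u = stack.pop()
        for w in adj.get(u, ()):
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return seen


def extract_fragment(
    network: AveragedNetwork,
    source: str,
    targets: Sequence[str],
    undirected_traversable: bool = True,
    min_confidence: float | None = None,
) -> PathFragment:
    """Edges lying on some source→target path of the averaged network.

    An edge (u,v) is retained when u is reachable from the source and v
    reaches a target (undirected edges traversable both ways unless
    disabled); equivalently the intersection of the descendant-side and
    ancestor-side edge sets.  ``min_confidence`` optionally restricts the
    traversed network to its more stable edges first.
    """
    if source not in network.nodes:
        raise KeyError(f"source {source} not in network")
    targets = tuple(t for t in targets if t in network.nodes)
    edges = list(network.edges)
    if not undirected_traversable:
        edges = [e for e in edges if e.directed]
    if min_confidence is not None:
        edges = [e for e in edges if e.presence_conf >= min_confidence - 1e-12]
    down = _mixed_reachable(edges, [source], True, undirected_traversable)
    up = _mixed_reachable(edges, targets, False, undirected_traversable)
    kept: list[AvgEdge] = []
    for e in edges:
        ok = e.u in down and e.v in up
        if not e.directed:
            ok = ok or (e.v in down and e.u in up)
        if ok:
            kept.append(e)
    return PathFragment(source=source, targets=targets, edges=kept)


def classify_role(fragment: PathFragment, node: str, target: str) -> str:
    """direct / indirect / absent role of a determinant for one outcome."""
    if target not in fragment.targets:
        raise ValueError(f"{target} is not a target of this fragment")
    if node not in fragment.nodes:
        return "absent"
    if fragment.has_arc_into(node, target):
        return "direct"
    return "indirect"


@dataclass
class FragmentDiff:
    shared: list[tuple[str, str, bool]]
    only_a: list[tuple[str, str, bool]]
    only_b: list[tuple[str, str, bool]]
    role_transitions: list[tuple[str, str, str, str]]  # (node, target, role_a, role_b)

    @property
    def empty(self) -> bool:
        return not (self.only_a or self.only_b or self.role_transitions)


def compare_fragments(a: PathFragment, b: PathFragment) -> FragmentDiff:
    """Structured diff of two subgroup fragments: arcs and role changes."""
    keys_a = {e.key() for e in a.edges}
    keys_b = {e.key() for e in b.edges}
    shared = sorted(keys_a & keys_b)
    only_a = sorted(keys_a - keys_b)
    only_b = sorted(keys_b - keys_a)
    transitions: list[tuple[str, str, str, str]] = []
    targets = sorted(set(a.targets) & set(b.targets))
    for node in sorted(a.nodes | b.nodes):
        for target in targets:
            if node == target:
                continue
            ra = classify_role(a, node, target)
            rb = classify_role(b, node, target)
            if ra != rb:
                transitions.append((node, target, ra, rb))
    return FragmentDiff(
        shared=shared, only_a=only_a, only_b=only_b, role_transitions=transitions
    )
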
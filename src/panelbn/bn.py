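"""Hybrid (conditional linear Gaussian) Bayesian networks over panel variables.

The model class: a DAG over mixed discrete/continuous variables where each
discrete node carries a conditional probability table over its (discrete)
parents, and each continuous node carries, per configuration of its discrete
parents, a linear regression on its continuous parents with Gaussian
residuals.  Discrete nodes may not have continuous parents.

Arcs are constrained by measurement tiers: a variable measured at a later
wave may never point at one measured strictly earlier, so every learned
structure is consistent with the direction of time.

Scoring is the decomposable BIC, ``sum_v ll_v - (k_v/2) ln n``, with the
"larger is better" sign convention, so structure search maximises it.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import STATIC, WAVES, PanelDataset, VariableSpec

LOG2PI = math.log(2.0 * math.pi)

Arc = tuple[str, str]


# ---------------------------------------------------------------------------
# structures and constraints
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TierConstraint:
    """Temporal tiers plus explicit black/white lists and exogenous roots.

    ``tiers`` partition the variable set, earliest first.  Any arc from a
    later tier into a strictly earlier tier is forbidden.  ``fixed_roots``
    are variables that may not receive parents at all (by default the
    randomized intervention arm and the demographic covariates).
    """

    tiers: tuple[frozenset[str], ...]
    extra_forbidden: frozenset[Arc] = frozenset()
    extra_required: frozenset[Arc] = frozenset()
    fixed_roots: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for tier in self.tiers:
            if tier & seen:
                raise ValueError(f"tiers overlap on {sorted(tier & seen)}")
            seen |= tier
        for arc in self.extra_required:
            if arc in self.extra_forbidden:
                raise ValueError(f"arc {arc} both required and forbidden")

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset().union(*self.tiers) if self.tiers else frozenset()

    def tier_index(self, node: str) -> int:
        for i, tier in enumerate(self.tiers):
            if node in tier:
                return i
        raise KeyError(f"{node} not covered by any tier")

    @staticmethod
    def from_specs(
        specs: Mapping[str, VariableSpec],
        exogenous_roots: bool = True,
        extra_forbidden: Iterable[Arc] = (),
        extra_required: Iterable[Arc] = (),
    ) -> "TierConstraint":
        """Standard layout: static exogenous tier first, then waves in order."""
        order = [STATIC] + [w for w in WAVES]
        tiers = []
        for slot in order:
            members = frozenset(n for n, s in specs.items() if s.timeslot == slot)
            if members:
                tiers.append(members)
        roots = frozenset(
            n for n, s in specs.items() if s.role in ("intervention", "demographic")
        ) if exogenous_roots else frozenset()
        return TierConstraint(
            tiers=tuple(tiers),
            extra_forbidden=frozenset(extra_forbidden),
            extra_required=frozenset(extra_required),
            fixed_roots=roots,
        )


@dataclass(frozen=True)
class DAGStructure:
    """A directed acyclic graph given by its node set and arc set."""

    nodes: tuple[str, ...]
    arcs: frozenset[Arc] = frozenset()

    def __post_init__(self) -> None:
        known = set(self.nodes)
        for u, v in self.arcs:
            if u == v:
                raise ValueError(f"self-loop on {u}")
            if u not in known or v not in known:
                raise ValueError(f"arc ({u},{v}) references unknown node")
        if self.topological_order() is None:
            raise ValueError("arc set contains a cycle")

    def parents(self, node: str) -> set[str]:
        return {u for u, v in self.arcs if v == node}

    def children(self, node: str) -> set[str]:
        return {v for u, v in self.arcs if u == node}

    def parent_map(self) -> dict[str, set[str]]:
        pm: dict[str, set[str]] = {v: set() for v in self.nodes}
        for u, v in self.arcs:
            pm[v].add(u)
        return pm

    def topological_order(self) -> list[str] | None:
        """Kahn's algorithm; None if cyclic.  Ties broken by node order."""
        indeg = {v: 0 for v in self.nodes}
        adj: dict[str, list[str]] = {v: [] for v in self.nodes}
        for u, v in self.arcs:
            indeg[v] += 1
            adj[u].append(v)
        ready = sorted(v for v, d in indeg.items() if d == 0)
        out: list[str] = []
        while ready:
            v = ready.pop(0)
            out.append(v)
            for w in sorted(adj[v]):
                indeg[w] -= 1
                if indeg[w] == 0:
                    ready.append(w)
            ready.sort()
        return out if len(out) == len(self.nodes) else None

    def with_arc(self, arc: Arc) -> "DAGStructure":
        return DAGStructure(self.nodes, self.arcs | {arc})

    def without_arc(self, arc: Arc) -> "DAGStructure":
        return DAGStructure(self.nodes, self.arcs - {arc})


def _has_path(parent_of: Mapping[str, set[str]], src: str, dst: str) -> bool:
    """True if dst is reachable from src following child links."""
    children: dict[str, set[str]] = {}
    for v, ps in parent_of.items():
        for p in ps:
            children.setdefault(p, set()).add(v)
    stack = [src]
    seen = {src}
    while stack:
        u = stack.pop()
        if u == dst:
            return True
        for w in children.get(u, ()):  # DFS
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return False


def check_arc_legal(
    structure: DAGStructure,
    constraint: TierConstraint,
    arc: Arc,
    specs: Mapping[str, VariableSpec] | None = None,
) -> tuple[bool, str]:
    """Is adding ``arc`` to ``structure`` legal?  Returns (ok, reason).

    Reasons: "tier" (against time), "class" (continuous parent of a
    discrete node), "forbidden" (blacklist), "root" (exogenous target),
    "cycle", or "ok".
    """
    u, v = arc
    known = set(structure.nodes)
    if u not in known or v not in known:
        raise KeyError(f"arc ({u},{v}) references unknown node")
    if u == v:
        return False, "cycle"
    if constraint.tier_index(u) > constraint.tier_index(v):
        return False, "tier"
    if specs is not None and not specs[u].is_discrete and specs[v].is_discrete:
        return False, "class"
    if arc in constraint.extra_forbidden:
        return False, "forbidden"
    if v in constraint.fixed_roots:
        return False, "root"
    pm = structure.parent_map()
    if _has_path(pm, v, u):
        return False, "cycle"
    return True, "ok"


def static_legal(
    constraint: TierConstraint,
    specs: Mapping[str, VariableSpec],
    arc: Arc,
) -> bool:
    """Legality ignoring acyclicity (for candidate-move enumeration)."""
    u, v = arc
    if u == v:
        return False
    if constraint.tier_index(u) > constraint.tier_index(v):
        return False
    if not specs[u].is_discrete and specs[v].is_discrete:
        return False
    if arc in constraint.extra_forbidden:
        return False
    if v in constraint.fixed_roots:
        return False
    return True


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass
class DiscreteLocal:
    """CPT of a discrete node, indexed by discrete-parent configurations."""

    parents: tuple[str, ...]
    levels: tuple[str, ...]
    parent_levels: tuple[tuple[str, ...], ...]
    table: dict[tuple[str, ...], np.ndarray]  # config -> prob vector
    marginal: np.ndarray  # fallback for unseen configurations

    def probs(self, config: tuple[str, ...]) -> np.ndarray:
        return self.table.get(config, self.marginal)


@dataclass
class GaussianLocal:
    """Per-discrete-configuration linear-Gaussian model of a continuous node."""

    disc_parents: tuple[str, ...]
    cont_parents: tuple[str, ...]
    parent_levels: tuple[tuple[str, ...], ...]
    # config -> (intercept, coef vector over cont_parents, residual variance)
    table: dict[tuple[str, ...], tuple[float, np.ndarray, float]]
    pooled: tuple[float, np.ndarray, float]
    pooled_configs: frozenset[tuple[str, ...]] = frozenset()  # sparse fallbacks

    def coefs(self, config: tuple[str, ...]) -> tuple[float, np.ndarray, float]:
        return self.table.get(config, self.pooled)


@dataclass
class CLGParameters:
    discrete: dict[str, DiscreteLocal]
    continuous: dict[str, GaussianLocal]


@dataclass
class HybridBN:
    """Structure + CLG parameters + variable metadata."""

    structure: DAGStructure
    parameters: CLGParameters
    specs: dict[str, VariableSpec]

    def __post_init__(self) -> None:
        for node in self.structure.nodes:
            spec = self.specs[node]
            ps = self.structure.parents(node)
            if spec.is_discrete:
                local = self.parameters.discrete[node]
                if set(local.parents) != ps:
                    raise ValueError(f"parameter/parent mismatch at {node}")
                cont_parents = [p for p in ps if not self.specs[p].is_discrete]
                if cont_parents:
                    raise ValueError(
                        f"discrete node {node} has continuous parents {cont_parents}"
                    )
            else:
                local = self.parameters.continuous[node]
                if set(local.disc_parents) | set(local.cont_parents) != ps:
                    raise ValueError(f"parameter/parent mismatch at {node}")


# ---------------------------------------------------------------------------
# sufficient statistics and decomposable scoring
# ---------------------------------------------------------------------------


class ScoreCache:
    """Cached BIC family scores over one *complete* dataset.

    Continuous families are scored from per-configuration Gram matrices of
    [1 | all continuous columns], so that evaluating a family is a small
    linear solve instead of a pass over the rows.  Family scores are memoised
    by (child, parent set), which is what makes hill climbing affordable.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        specs: Mapping[str, VariableSpec],
        var_floor: float = 1e-9,
    ):
        if frame.isna().any().any():
            raise ValueError("ScoreCache requires complete data")
        self.specs = dict(specs)
        self.n = len(frame)
        if self.n == 0:
            raise ValueError("empty dataset")
        self.var_floor = var_floor
        self.logn = math.log(self.n)

        self.cont_names = [n for n in frame.columns if not specs[n].is_discrete]
        self.cont_idx = {n: i for i, n in enumerate(self.cont_names)}
        X = frame[self.cont_names].to_numpy(dtype=float) if self.cont_names else np.empty((self.n, 0))
        self.Z = np.column_stack([np.ones(self.n), X])  # intercept first

        self.disc_names = [n for n in frame.columns if specs[n].is_discrete]
        self.codes: dict[str, np.ndarray] = {}
        self.n_levels: dict[str, int] = {}
        for name in self.disc_names:
            levels = specs[name].levels
            lut = {l: i for i, l in enumerate(levels)}
            self.codes[name] = frame[name].astype(str).map(lut).to_numpy(dtype=np.intp)
            self.n_levels[name] = len(levels)

        self._groups: dict[tuple[str, ...], tuple[np.ndarray, int]] = {}
        self._grams: dict[tuple[str, ...], dict[int, tuple[int, np.ndarray]]] = {}
        self._family: dict[tuple[str, frozenset[str]], float] = {}

    # -- grouping by discrete configurations -------------------------------

    def group_ids(self, disc: tuple[str, ...]) -> tuple[np.ndarray, int]:
        """Row -> configuration index over the full level product."""
        if disc not in self._groups:
            if not disc:
                ids = np.zeros(self.n, dtype=np.intp)
                size = 1
            else:
                dims = tuple(self.n_levels[d] for d in disc)
                ids = np.ravel_multi_index(tuple(self.codes[d] for d in disc), dims)
                size = int(np.prod(dims))
            self._groups[disc] = (ids, size)
        return self._groups[disc]

    def grams(self, disc: tuple[str, ...]) -> dict[int, tuple[int, np.ndarray]]:
        """Per occupied configuration: (row count, Gram of [1|cont])."""
        if disc not in self._grams:
            ids, _ = self.group_ids(disc)
            out: dict[int, tuple[int, np.ndarray]] = {}
            for g in np.unique(ids):
                rows = self.Z[ids == g]
                out[int(g)] = (rows.shape[0], rows.T @ rows)
            self._grams[disc] = out
        return self._grams[disc]

    # -- family scores ------------------------------------------------------

    def family_bic(self, child: str, parents: Iterable[str]) -> float:
        key = (child, frozenset(parents))
        if key not in self._family:
            ll, k = self._family_ll(child, key[1])
            self._family[key] = ll - 0.5 * k * self.logn
        return self._family[key]

    def family_ll(self, child: str, parents: Iterable[str]) -> tuple[float, int]:
        return self._family_ll(child, frozenset(parents))

    def _family_ll(self, child: str, parents: frozenset[str]) -> tuple[float, int]:
        if self.specs[child].is_discrete:
            return self._discrete_ll(child, parents)
        return self._gaussian_ll(child, parents)

    def _discrete_ll(self, child: str, parents: frozenset[str]) -> tuple[float, int]:
        disc = tuple(sorted(parents))
        for p in disc:
            if not self.specs[p].is_discrete:
                raise ValueError(f"continuous parent {p} of discrete node {child}")
        pids, psize = self.group_ids(disc)
        lc = self.n_levels[child]
        joint = pids * lc + self.codes[child]
        counts = np.bincount(joint, minlength=psize * lc).reshape(psize, lc)
        row_tot = counts.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = float(
                np.where(counts > 0, counts * np.log(counts), 0.0).sum()
                - np.where(row_tot > 0, row_tot * np.log(row_tot), 0.0).sum()
            )
        k = (lc - 1) * psize
        return ll, k

    def _gaussian_ll(self, child: str, parents: frozenset[str]) -> tuple[float, int]:
        disc = tuple(sorted(p for p in parents if self.specs[p].is_discrete))
        cont = sorted(p for p in parents if not self.specs[p].is_discrete)
        idx = np.array([0] + [1 + self.cont_idx[p] for p in cont], dtype=np.intp)
        yi = 1 + self.cont_idx[child]
        p_params = len(cont) + 2  # intercept, slopes, variance
        _, psize = self.group_ids(disc)
        grams = self.grams(disc)

        pooled = None  # computed lazily for sparse configurations
        ll = 0.0
        for g, (m, G) in grams.items():
            A = G[np.ix_(idx, idx)]
            b = G[idx, yi]
            yy = G[yi, yi]
            if m >= p_params:
                beta = _solve_psd(A, b)
                rss = max(yy - float(beta @ b), 0.0)
                s2 = max(rss / m, self.var_floor)
                ll += -0.5 * m * (LOG2PI + math.log(s2) + 1.0)
            else:
                if pooled is None:
                    pooled = self._pooled_fit(idx, yi)
                beta, s2 = pooled
                rssg = float(beta @ A @ beta - 2.0 * beta @ b + yy)
                ll += -(max(rssg, 0.0) / (2.0 * s2)) - 0.5 * m * (LOG2PI + math.log(s2))
        k = p_params * psize
        return ll, k

    def _pooled_fit(self, idx: np.ndarray, yi: int) -> tuple[np.ndarray, float]:
        (m, G) = self.grams(())[0]
        A = G[np.ix_(idx, idx)]
        b = G[idx, yi]
        beta = _solve_psd(A, b)
        rss = max(G[yi, yi] - float(beta @ b), 0.0)
        return beta, max(rss / m, self.var_floor)

    def total_bic(self, structure: DAGStructure) -> float:
        return sum(
            self.family_bic(v, structure.parents(v)) for v in structure.nodes
        )


def _solve_psd(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(A, b, rcond=None)[0]


def bic_score(
    structure: DAGStructure,
    dataset: PanelDataset | pd.DataFrame,
    specs: Mapping[str, VariableSpec] | None = None,
    cache: ScoreCache | None = None,
) -> float:
    """Total BIC (larger is better) of ``structure`` on complete data."""
    if cache is not None:
        return cache.total_bic(structure)
    if isinstance(dataset, PanelDataset):
        frame, specs = dataset.frame, dataset.specs
    else:
        frame = dataset
        if specs is None:
            raise ValueError("specs required when passing a bare frame")
    if frame.isna().any().any():
        raise ValueError("bic_score requires complete data")
    return ScoreCache(frame, specs).total_bic(structure)


# ---------------------------------------------------------------------------
# maximum-likelihood fitting and density evaluation
# ---------------------------------------------------------------------------


def fit_parameters(
    structure: DAGStructure,
    dataset: PanelDataset | pd.DataFrame,
    specs: Mapping[str, VariableSpec] | None = None,
    var_floor: float = 1e-9,
    pseudo_count: float = 0.0,
) -> CLGParameters:
    """Maximum-likelihood CLG parameters on complete data.

    Discrete CPT rows are empirical frequencies (optionally smoothed by a
    pseudo-count); continuous locals are per-configuration least squares
    with the ML residual variance.  Configurations with fewer rows than
    (number of continuous parents + 2) fall back to the pooled fit over all
    rows and are flagged in ``pooled_configs``.
    """
    if isinstance(dataset, PanelDataset):
        frame, specs = dataset.frame, dataset.specs
    else:
        frame = dataset
        if specs is None:
            raise ValueError("specs required when passing a bare frame")
    if set(structure.nodes) != set(frame.columns):
        raise ValueError("structure/dataset variable mismatch")
    cache = ScoreCache(frame, specs, var_floor=var_floor)

    discrete: dict[str, DiscreteLocal] = {}
    continuous: dict[str, GaussianLocal] = {}
    for node in structure.nodes:
        spec = specs[node]
        parents = structure.parents(node)
        if spec.is_discrete:
            discrete[node] = _fit_discrete(cache, node, parents, specs, pseudo_count)
        else:
            continuous[node] = _fit_gaussian(cache, node, parents, specs)
    return CLGParameters(discrete=discrete, continuous=continuous)


def _config_tuples(
    disc: tuple[str, ...], specs: Mapping[str, VariableSpec]
) -> list[tuple[str, ...]]:
    if not disc:
        return [()]
    return list(itertools.product(*(specs[d].levels for d in disc)))


def _fit_discrete(
    cache: ScoreCache,
    node: str,
    parents: set[str],
    specs: Mapping[str, VariableSpec],
    pseudo: float,
) -> DiscreteLocal:
    disc = tuple(sorted(parents))
    for p in disc:
        if not specs[p].is_discrete:
            raise ValueError(f"continuous parent {p} of discrete node {node}")
    levels = specs[node].levels
    lc = len(levels)
    pids, psize = cache.group_ids(disc)
    joint = pids * lc + cache.codes[node]
    counts = np.bincount(joint, minlength=psize * lc).reshape(psize, lc).astype(float)
    counts += pseudo
    marg = counts.sum(axis=0)
    marginal = marg / marg.sum() if marg.sum() > 0 else np.full(lc, 1.0 / lc)
    table: dict[tuple[str, ...], np.ndarray] = {}
    configs = _config_tuples(disc, specs)
    for j, config in enumerate(configs):
        tot = counts[j].sum()
        if tot > 0:
            table[config] = counts[j] / tot
    return DiscreteLocal(
        parents=disc,
        levels=levels,
        parent_levels=tuple(specs[d].levels for d in disc),
        table=table,
        marginal=marginal,
    )


def _fit_gaussian(
    cache: ScoreCache,
    node: str,
    parents: set[str],
    specs: Mapping[str, VariableSpec],
) -> GaussianLocal:
    disc = tuple(sorted(p for p in parents if specs[p].is_discrete))
    cont = tuple(sorted(p for p in parents if not specs[p].is_discrete))
    idx = np.array([0] + [1 + cache.cont_idx[p] for p in cont], dtype=np.intp)
    yi = 1 + cache.cont_idx[node]
    p_params = len(cont) + 2
    grams = cache.grams(disc)
    beta_p, s2_p = cache._pooled_fit(idx, yi)
    pooled = (float(beta_p[0]), beta_p[1:].copy(), s2_p)

    table: dict[tuple[str, ...], tuple[float, np.ndarray, float]] = {}
    pooled_configs: set[tuple[str, ...]] = set()
    configs = _config_tuples(disc, specs)
    for j, config in enumerate(configs):
        entry = grams.get(j)
        if entry is None:
            continue  # unseen configuration: GaussianLocal falls back to pooled
        m, G = entry
        if m >= p_params:
            A = G[np.ix_(idx, idx)]
            b = G[idx, yi]
            beta = _solve_psd(A, b)
            rss = max(G[yi, yi] - float(beta @ b), 0.0)
            s2 = max(rss / m, cache.var_floor)
            table[config] = (float(beta[0]), beta[1:].copy(), s2)
        else:
            table[config] = pooled
            pooled_configs.add(config)
    return GaussianLocal(
        disc_parents=disc,
        cont_parents=cont,
        parent_levels=tuple(specs[d].levels for d in disc),
        table=table,
        pooled=pooled,
        pooled_configs=frozenset(pooled_configs),
    )


def loglik_frame(bn: HybridBN, frame: pd.DataFrame) -> np.ndarray:
    """Per-row joint log density/probability of complete observations."""
    if frame.isna().any().any():
        raise ValueError("loglik requires complete rows")
    n = len(frame)
    total = np.zeros(n)
    codes: dict[str, np.ndarray] = {}
    for name, spec in bn.specs.items():
        if spec.is_discrete:
            lut = {l: i for i, l in enumerate(spec.levels)}
            col = frame[name].astype(str)
            bad = set(col.unique()) - set(spec.levels)
            if bad:
                raise ValueError(f"{name}: values {sorted(bad)} outside levels")
            codes[name] = col.map(lut).to_numpy(dtype=np.intp)

    for node in bn.structure.nodes:
        spec = bn.specs[node]
        if spec.is_discrete:
            local = bn.parameters.discrete[node]
            probs = _rowwise_probs(local, frame, codes)
            p = probs[np.arange(n), codes[node]]
            total += np.log(np.clip(p, 1e-300, None))
        else:
            local = bn.parameters.continuous[node]
            mu, s2 = _rowwise_gaussian(local, frame, codes)
            y = frame[node].to_numpy(dtype=float)
            total += -0.5 * (LOG2PI + np.log(s2) + (y - mu) ** 2 / s2)
    return total


def _rowwise_probs(
    local: DiscreteLocal, frame: pd.DataFrame, codes: Mapping[str, np.ndarray]
) -> np.ndarray:
    n = len(frame)
    lc = len(local.levels)
    out = np.empty((n, lc))
    if not local.parents:
        out[:] = local.probs(())
        return out
    # map each row's parent configuration to its CPT row
    configs = _config_tuples(local.parents, {  # reconstruct specs-lite
        p: VariableSpec(p, "discrete", "demographic", STATIC, lv)
        for p, lv in zip(local.parents, local.parent_levels)
    })
    dims = tuple(len(lv) for lv in local.parent_levels)
    ids = np.ravel_multi_index(tuple(codes[p] for p in local.parents), dims)
    rowtable = np.vstack([local.probs(c) for c in configs])
    return rowtable[ids]


def _rowwise_gaussian(
    local: GaussianLocal, frame: pd.DataFrame, codes: Mapping[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    n = len(frame)
    Xp = (
        frame[list(local.cont_parents)].to_numpy(dtype=float)
        if local.cont_parents
        else np.empty((n, 0))
    )
    if not local.disc_parents:
        b0, coef, s2 = local.coefs(())
        mu = b0 + Xp @ coef
        return mu, np.full(n, s2)
    dims = tuple(len(lv) for lv in local.parent_levels)
    ids = np.ravel_multi_index(tuple(codes[p] for p in local.disc_parents), dims)
    configs = list(itertools.product(*local.parent_levels))
    b0s = np.empty(len(configs))
    coefs = np.empty((len(configs), Xp.shape[1]))
    s2s = np.empty(len(configs))
    for j, c in enumerate(configs):
        b0, coef, s2 = local.coefs(c)
        b0s[j], coefs[j], s2s[j] = b0, coef, s2
    mu = b0s[ids] + np.einsum("ij,ij->i", Xp, coefs[ids]) if Xp.shape[1] else b0s[ids]
    return mu, s2s[ids]


def loglik(bn: HybridBN, row: Mapping[str, object]) -> float:
    """Joint log density of one complete observation."""
    frame = pd.DataFrame([dict(row)])
    return float(loglik_frame(bn, frame)[0])
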
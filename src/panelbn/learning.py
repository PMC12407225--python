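"""Structure learning: BIC hill climbing under tier constraints, an exact
enumeration oracle for tiny problems, and structural EM for incomplete data.

Hill climbing searches over single-arc additions, deletions and reversals,
with a tabu list and deterministic lexicographic tie-breaking.  Structural
EM alternates completion of the missing cells under the current fitted
network (E) with hill climbing plus parameter fitting on the completed data
(M), tracking the completed-data BIC; the score log it returns is
non-decreasing by construction (a deteriorating iteration reverts to the
best network seen so far).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bn import (
    Arc,
    CLGParameters,
    DAGStructure,
    HybridBN,
    ScoreCache,
    TierConstraint,
    _has_path,
    fit_parameters,
    static_legal,
)
from .dataset import PanelDataset, VariableSpec

_EPS = 1e-7  # minimum score improvement accepted as progress


@dataclass(frozen=True)
class SearchSettings:
    """Knobs for hill climbing and structural EM."""

    max_iter_hc: int = 500
    tabu_length: int = 10
    random_restarts: int = 0
    em_max_iter: int = 10
    em_tol: float = 1e-4  # on the per-row average completed-data score
    seed: int = 0
    completion_mode: str = "single_draw"  # or "expected_value"

    def __post_init__(self) -> None:
        if self.max_iter_hc < 1 or self.em_max_iter < 1:
            raise ValueError("iteration limits must be positive")
        if self.tabu_length < 0 or self.random_restarts < 0:
            raise ValueError("tabu_length and random_restarts must be >= 0")
        if self.em_tol <= 0:
            raise ValueError("em_tol must be > 0")
        if self.completion_mode not in ("expected_value", "single_draw"):
            raise ValueError(f"unknown completion_mode {self.completion_mode!r}")


@dataclass
class HillClimbResult:
    structure: DAGStructure
    score: float
    n_steps: int


# ---------------------------------------------------------------------------
# hill climbing
# ---------------------------------------------------------------------------


def hill_climb(
    dataset: PanelDataset | pd.DataFrame,
    constraint: TierConstraint,
    settings: SearchSettings | None = None,
    specs: Mapping[str, VariableSpec] | None = None,
    start_arcs: Iterable[Arc] = (),
    cache: ScoreCache | None = None,
) -> HillClimbResult:
    """Tabu-style greedy BIC search over single-arc moves.

    Deterministic given the settings: escape moves and tie-breaking are
    rule-based, and the optional random restarts draw their perturbations
    from ``settings.seed``.  Returns the best-scoring structure seen.
    """
    settings = settings or SearchSettings()
    if isinstance(dataset, PanelDataset):
        frame, specs = dataset.frame, dataset.specs
    else:
        frame = dataset
        if specs is None:
            raise ValueError("specs required when passing a bare frame")
    if frame.isna().any().any():
        raise ValueError("hill_climb requires complete data")
    if set(frame.columns) - constraint.nodes:
        raise ValueError("constraint does not cover all variables")
    cache = cache or ScoreCache(frame, specs)

    nodes = tuple(sorted(frame.columns))
    required = frozenset(a for a in constraint.extra_required)
    for u, v in set(start_arcs) | required:
        if not static_legal(constraint, specs, (u, v)):
            raise ValueError(f"start arc ({u},{v}) is illegal under the constraint")
    candidates = [
        (u, v)
        for u in nodes
        for v in nodes
        if u != v and static_legal(constraint, specs, (u, v))
    ]

    best = _climb_once(
        cache, nodes, candidates, required, set(start_arcs) | set(required), settings
    )
    if settings.random_restarts > 0:
        rng = np.random.default_rng(settings.seed)
        for _ in range(settings.random_restarts):
            perturbed = _perturb(best.structure.arcs, candidates, required, rng)
            trial = _climb_once(cache, nodes, candidates, required, perturbed, settings)
            if trial.score > best.score + _EPS:
                best = trial
    return best


def _perturb(
    arcs: frozenset[Arc],
    candidates: Sequence[Arc],
    required: frozenset[Arc],
    rng: np.random.Generator,
    k: int = 3,
) -> set[Arc]:
    """Randomly delete, add or reverse up to k arcs, keeping acyclicity."""
    out = set(arcs)

    def acyclic_with(extra: Arc, minus: Arc | None = None) -> bool:
        parent_of: dict[str, set[str]] = {}
        for a, b in out:
            if (a, b) != minus:
                parent_of.setdefault(b, set()).add(a)
        parent_of.setdefault(extra[0], set())
        return not _has_path(parent_of, extra[1], extra[0])

    picks = rng.choice(len(candidates), size=min(k, len(candidates)), replace=False)
    for idx in picks:
        arc = candidates[int(idx)]
        u, v = arc
        if arc in out:
            if arc in required:
                continue
            rev = (v, u)
            if rev in candidates and rng.random() < 0.5 and acyclic_with(rev, minus=arc):
                out.discard(arc)
                out.add(rev)
            else:
                out.discard(arc)
        elif acyclic_with(arc):
            out.add(arc)
    return out


def _climb_once(
    cache: ScoreCache,
    nodes: tuple[str, ...],
    candidates: Sequence[Arc],
    required: frozenset[Arc],
    start: set[Arc],
    settings: SearchSettings,
) -> HillClimbResult:
    arcs = set(start)
    constraint = None  # legality is pre-baked into `candidates`
    parent_of: dict[str, set[str]] = {v: set() for v in nodes}
    for u, v in arcs:
        parent_of[v].add(u)
    candidate_set = set(candidates)
    fam = {v: cache.family_bic(v, parent_of[v]) for v in nodes}
    # move deltas, invalidated lazily by dirty child set
    deltas: dict[tuple[str, Arc], float] = {}

    def delta_add(arc: Arc) -> float:
        u, v = arc
        key = ("add", arc)
        if key not in deltas:
            deltas[key] = cache.family_bic(v, parent_of[v] | {u}) - fam[v]
        return deltas[key]

    def delta_del(arc: Arc) -> float:
        u, v = arc
        key = ("del", arc)
        if key not in deltas:
            deltas[key] = cache.family_bic(v, parent_of[v] - {u}) - fam[v]
        return deltas[key]

    def invalidate(children: Iterable[str]) -> None:
        dirty = set(children)
        for key in [k for k in deltas if k[1][1] in dirty]:
            del deltas[key]

    cur_score = sum(fam.values())
    best_score = cur_score
    best_arcs = frozenset(arcs)
    tabu: list[tuple[str, Arc]] = []
    stall = 0  # consecutive non-improving (escape) moves taken
    steps = 0
    while steps < settings.max_iter_hc:
        moves: list[tuple[float, int, Arc, str]] = []
        for arc in candidates:
            u, v = arc
            if arc in arcs:
                if arc in required:
                    continue
                d = delta_del(arc)
                moves.append((d, 1, arc, "del"))
                # reversal: delete u->v, add v->u (if statically legal)
                if (v, u) in candidate_set:
                    d_rev = d + (
                        cache.family_bic(u, parent_of[u] | {v}) - fam[u]
                    )
                    moves.append((d_rev, 2, arc, "rev"))
            else:
                moves.append((delta_add(arc), 0, arc, "add"))
        # best delta first; ties broken by move type then (child, parent)
        moves.sort(key=lambda m: (-m[0], m[1], m[2][1], m[2][0]))
        applied = False
        for d, _, arc, op in moves:
            # tabu moves are skipped unless they beat the best score seen
            # (aspiration); non-improving moves spend the escape budget
            if (op, arc) in tabu and cur_score + d <= best_score + _EPS:
                continue
            if d <= _EPS and (
                settings.tabu_length == 0 or stall >= settings.tabu_length
            ):
                break  # converged: no improvement and no escape budget left
            u, v = arc
            if op == "add":
                if _has_path(parent_of, v, u):
                    continue  # would close a cycle
                arcs.add(arc)
                parent_of[v].add(u)
                fam[v] = cache.family_bic(v, parent_of[v])
                invalidate([v])
                tabu.append(("del", arc))
            elif op == "del":
                arcs.discard(arc)
                parent_of[v].discard(u)
                fam[v] = cache.family_bic(v, parent_of[v])
                invalidate([v])
                tabu.append(("add", arc))
            else:  # reversal
                parent_of[v].discard(u)
                if _has_path(parent_of, u, v):
                    parent_of[v].add(u)
                    continue
                arcs.discard(arc)
                arcs.add((v, u))
                parent_of[u].add(v)
                fam[v] = cache.family_bic(v, parent_of[v])
                fam[u] = cache.family_bic(u, parent_of[u])
                invalidate([u, v])
                tabu.append(("rev", (v, u)))
            cur_score += d
            applied = True
            break
        if not applied:
            break
        if cur_score > best_score + _EPS:
            best_score = cur_score
            best_arcs = frozenset(arcs)
            stall = 0
        else:
            stall += 1
        tabu[:] = tabu[-max(settings.tabu_length, 1) :]
        steps += 1

    structure = DAGStructure(nodes=nodes, arcs=best_arcs)
    return HillClimbResult(structure=structure, score=best_score, n_steps=steps)


# ---------------------------------------------------------------------------
# exact search on tiny problems (test oracle)
# ---------------------------------------------------------------------------


def enumerate_legal_dags(
    nodes: Sequence[str],
    constraint: TierConstraint,
    specs: Mapping[str, VariableSpec],
):
    """Yield every legal DAG (as a frozenset of arcs) over <= 5 nodes."""
    nodes = tuple(sorted(nodes))
    if len(nodes) > 5:
        raise ValueError("enumeration limited to 5 variables")
    arcs = [
        (u, v)
        for u in nodes
        for v in nodes
        if u != v and static_legal(constraint, specs, (u, v))
    ]
    required = set(constraint.extra_required)
    for r in range(len(arcs) + 1):
        for combo in itertools.combinations(arcs, r):
            arcset = frozenset(combo)
            if required - arcset:
                continue
            try:
                DAGStructure(nodes=nodes, arcs=arcset)
            except ValueError:
                continue
            yield arcset


def exhaustive_search(
    dataset: PanelDataset | pd.DataFrame,
    constraint: TierConstraint,
    specs: Mapping[str, VariableSpec] | None = None,
    cache: ScoreCache | None = None,
) -> HillClimbResult:
    """Global BIC optimum over all legal DAGs (<= 5 variables).

    Implemented as a maximisation over topological orders with per-node
    best parent subsets, which attains the same optimum as enumerating
    every legal DAG but is much cheaper.
    """
    if isinstance(dataset, PanelDataset):
        frame, specs = dataset.frame, dataset.specs
    else:
        frame = dataset
        if specs is None:
            raise ValueError("specs required when passing a bare frame")
    nodes = tuple(sorted(frame.columns))
    if len(nodes) > 5:
        raise ValueError("exhaustive search limited to 5 variables")
    if frame.isna().any().any():
        raise ValueError("exhaustive_search requires complete data")
    cache = cache or ScoreCache(frame, specs)
    required_by_child: dict[str, set[str]] = {}
    for u, v in constraint.extra_required:
        required_by_child.setdefault(v, set()).add(u)

    best_score = -math.inf
    best_arcs: frozenset[Arc] = frozenset()
    for order in itertools.permutations(nodes):
        score = 0.0
        arcs: set[Arc] = set()
        feasible = True
        for i, v in enumerate(order):
            pool = [
                u for u in order[:i] if static_legal(constraint, specs, (u, v))
            ]
            forced = required_by_child.get(v, set())
            if forced - set(pool):
                feasible = False
                break
            free = [u for u in pool if u not in forced]
            best_v = -math.inf
            best_ps: tuple[str, ...] = ()
            for r in range(len(free) + 1):
                for sub in itertools.combinations(free, r):
                    ps = forced | set(sub)
                    s = cache.family_bic(v, ps)
                    if s > best_v + _EPS or (
                        s > best_v - _EPS and tuple(sorted(ps)) < best_ps
                    ):
                        best_v, best_ps = s, tuple(sorted(ps))
            score += best_v
            arcs |= {(u, v) for u in best_ps}
        if feasible and score > best_score + _EPS:
            best_score = score
            best_arcs = frozenset(arcs)
    structure = DAGStructure(nodes=nodes, arcs=best_arcs)
    return HillClimbResult(structure=structure, score=best_score, n_steps=0)


# ---------------------------------------------------------------------------
# structural EM
# ---------------------------------------------------------------------------


@dataclass
class SEMResult:
    bn: HybridBN
    score_log: list[float]
    converged: bool
    n_iter: int


def _initial_completion(frame: pd.DataFrame, specs: Mapping[str, VariableSpec]) -> pd.DataFrame:
    """Column means (continuous) / modes (discrete) as the starting fill."""
    out = frame.copy()
    for name, spec in specs.items():
        col = out[name]
        if not col.isna().any():
            continue
        if spec.is_discrete:
            observed = col.dropna()
            fill = observed.mode().iloc[0] if len(observed) else spec.levels[0]
        else:
            observed = col.dropna()
            fill = float(observed.mean()) if len(observed) else 0.0
        out[name] = col.fillna(fill)
    return out


def _complete_with_bn(
    frame: pd.DataFrame,
    bn: HybridBN,
    mode: str,
    rng: np.random.Generator | None,
) -> pd.DataFrame:
    """E-step: fill missing cells conditionally on the whole observed row.

    Discrete nodes are completed in one topological sweep (most probable —
    or drawn — level given their parents; discrete variables here are the
    exogenous statics and are usually observed).  Continuous nodes are then
    completed exactly: given the discrete configuration, the continuous
    variables are jointly Gaussian under the CLG model, so each row's
    missing block is replaced by its conditional expectation (or a draw)
    given *all* observed continuous values — evidence from children
    included, which keeps conditional-independence structure intact.
    """
    out = frame.copy()
    order = bn.structure.topological_order()
    assert order is not None
    # -- discrete sweep ----------------------------------------------------
    for node in order:
        if not bn.specs[node].is_discrete:
            continue
        missing = out[node].isna()
        if not missing.any():
            continue
        spec = bn.specs[node]
        sub = out.loc[missing]
        local = bn.parameters.discrete[node]
        if local.parents:
            codes = tuple(
                sub[p].astype(str).map(
                    {l: i for i, l in enumerate(bn.specs[p].levels)}
                ).to_numpy(dtype=np.intp)
                for p in local.parents
            )
            dims = tuple(len(lv) for lv in local.parent_levels)
            ids = np.ravel_multi_index(codes, dims)
            configs = list(itertools.product(*local.parent_levels))
            rowtable = np.vstack([local.probs(c) for c in configs])[ids]
        else:
            rowtable = np.tile(local.probs(()), (len(sub), 1))
        if mode == "single_draw":
            cum = rowtable.cumsum(axis=1)
            picks = (rng.random(len(sub))[:, None] > cum).sum(axis=1)
        else:
            picks = rowtable.argmax(axis=1)
        out.loc[missing, node] = [spec.levels[i] for i in picks]

    # -- continuous block: exact Gaussian conditioning ---------------------
    cont = [n for n in order if not bn.specs[n].is_discrete]
    if not cont:
        return out
    X = out[cont].to_numpy(dtype=float)
    miss = np.isnan(X)
    if not miss.any():
        return out
    disc = [n for n in bn.specs if bn.specs[n].is_discrete]
    if disc:
        codes = tuple(
            out[p].astype(str).map(
                {l: i for i, l in enumerate(bn.specs[p].levels)}
            ).to_numpy(dtype=np.intp)
            for p in disc
        )
        dims = tuple(len(bn.specs[p].levels) for p in disc)
        config_ids = np.ravel_multi_index(codes, dims)
    else:
        config_ids = np.zeros(len(out), dtype=np.intp)

    joint_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def joint(cfg_id: int) -> tuple[np.ndarray, np.ndarray]:
        if cfg_id not in joint_cache:
            levels = (
                {p: bn.specs[p].levels[c] for p, c in
                 zip(disc, np.unravel_index(cfg_id, dims))}
                if disc
                else {}
            )
            joint_cache[cfg_id] = _clg_joint_gaussian(bn, cont, levels)
        return joint_cache[cfg_id]

    # group rows by (configuration, missingness pattern) to share solves
    pattern_keys: dict[tuple, list[int]] = {}
    for i in range(len(out)):
        if miss[i].any():
            key = (int(config_ids[i]), miss[i].tobytes())
            pattern_keys.setdefault(key, []).append(i)
    for (cfg_id, _), rows in pattern_keys.items():
        m = miss[rows[0]]
        o = ~m
        mu, sigma = joint(cfg_id)
        rows = np.asarray(rows)
        if o.any():
            soo = sigma[np.ix_(o, o)]
            smo = sigma[np.ix_(m, o)]
            resid = X[np.ix_(rows, np.flatnonzero(o))] - mu[o]
            gain = np.linalg.solve(soo, smo.T).T  # S_mo S_oo^-1
            cond_mu = mu[m] + resid @ gain.T
            if mode == "single_draw":
                cov = sigma[np.ix_(m, m)] - gain @ smo.T
                cov = (cov + cov.T) / 2
                chol = np.linalg.cholesky(cov + 1e-12 * np.eye(cov.shape[0]))
                cond_mu = cond_mu + rng.normal(
                    size=(len(rows), int(m.sum()))
                ) @ chol.T
        else:
            cond_mu = np.tile(mu[m], (len(rows), 1))
            if mode == "single_draw":
                chol = np.linalg.cholesky(
                    sigma[np.ix_(m, m)] + 1e-12 * np.eye(int(m.sum()))
                )
                cond_mu = cond_mu + rng.normal(
                    size=(len(rows), int(m.sum()))
                ) @ chol.T
        X[np.ix_(rows, np.flatnonzero(m))] = cond_mu
    out[cont] = X
    return out


def _clg_joint_gaussian(
    bn: HybridBN, cont_order: Sequence[str], disc_levels: Mapping[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    """Joint (mean, covariance) of the continuous block given a discrete
    configuration: x = c + Bx + e with B strictly lower-triangular in
    topological order, so x ~ N((I-B)^-1 c, (I-B)^-1 D (I-B)^-T)."""
    d = len(cont_order)
    idx = {n: i for i, n in enumerate(cont_order)}
    B = np.zeros((d, d))
    c = np.zeros(d)
    D = np.zeros(d)
    for node in cont_order:
        local = bn.parameters.continuous[node]
        cfg = tuple(disc_levels[p] for p in local.disc_parents)
        b0, coef, s2 = local.coefs(cfg)
        i = idx[node]
        c[i] = b0
        D[i] = s2
        for p, w in zip(local.cont_parents, coef):
            B[i, idx[p]] = w
    M = np.linalg.inv(np.eye(d) - B)
    mean = M @ c
    sigma = M @ np.diag(D) @ M.T
    return mean, (sigma + sigma.T) / 2


def structural_em(
    dataset: PanelDataset,
    constraint: TierConstraint,
    settings: SearchSettings | None = None,
) -> SEMResult:
    """Learn structure and parameters from incomplete panel data.

    Alternates (E) completion of missing cells under the current network
    with (M) hill climbing and ML fitting on the completed data.  Stops
    when the completed-data BIC improves by less than ``em_tol`` per row,
    or after ``em_max_iter`` iterations (returning the best-so-far network
    with ``converged=False``).
    """
    settings = settings or SearchSettings()
    frame = dataset.frame
    specs = dataset.specs
    counts = frame.notna().sum(axis=0)
    empty = [c for c in frame.columns if counts[c] == 0]
    if empty:
        raise ValueError(
            f"variables with no observations: {empty}; drop them before learning"
        )
    rng = np.random.default_rng(settings.seed)

    completed = _initial_completion(frame, specs)
    n = len(frame)
    score_log: list[float] = []
    best: HybridBN | None = None
    best_score = -math.inf
    arcs: frozenset[Arc] = frozenset()
    converged = False
    it = 0
    for it in range(1, settings.em_max_iter + 1):
        cache = ScoreCache(completed, specs)
        result = hill_climb(
            completed,
            constraint,
            settings,
            specs=specs,
            start_arcs=arcs,
            cache=cache,
        )
        params = fit_parameters(result.structure, completed, specs)
        bn = HybridBN(structure=result.structure, parameters=params, specs=dict(specs))
        if score_log and result.score < best_score - _EPS:
            # approximate E-step made things worse: keep the best model
            break
        score_log.append(result.score)
        best, best_score, arcs = bn, result.score, result.structure.arcs
        if len(score_log) >= 2 and (
            score_log[-1] - score_log[-2]
        ) < settings.em_tol * n:
            converged = True
            break
        if not frame.isna().any().any():
            converged = True  # complete data: E-step is the identity
            break
        completed = _complete_with_bn(frame, bn, settings.completion_mode, rng)
    assert best is not None
    return SEMResult(bn=best, score_log=score_log, converged=converged, n_iter=it)
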
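"""Synthetic longitudinal intervention panels from a known ground truth.

The generator emulates the statistical structure of a pooled multi-study
physical-activity intervention panel: a randomized binary intervention arm,
demographic covariates, determinant concept scores and an MVPA outcome at
up to four waves, concept scores aggregated from short ordinal item scales,
whole-variable missingness that depends on which synthetic "study" a
participant belongs to, and optional subgroup moderation in which a
demographic level alters part of the ground-truth arc set.

Everything downstream of this module (learning, averaging, path grading) is
exercised against these datasets, so the ground truth is machine-checked for
tier consistency before any sampling happens.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bn import (
    Arc,
    CLGParameters,
    DAGStructure,
    DiscreteLocal,
    GaussianLocal,
    HybridBN,
    TierConstraint,
    check_arc_legal,
)
from .dataset import PanelDataset, VariableSpec
from .preprocess import aggregate_item_table


def concept_of(variable: str) -> str:
    """Base concept of a wave-stamped variable name like habit@T2."""
    return variable.rsplit("@", 1)[0]


@dataclass(frozen=True)
class ConceptDef:
    name: str
    items_per_concept: int = 3
    scale_max: int = 5  # intention uses 10

    def __post_init__(self) -> None:
        if self.items_per_concept < 1:
            raise ValueError("items_per_concept must be >= 1")
        if self.scale_max not in (5, 10):
            raise ValueError("scale_max must be 5 or 10")


@dataclass
class LinModel:
    """Additive conditional-linear-Gaussian local model of a continuous node.

    Mean = intercept + sum(coef * continuous parent) + per-level offsets of
    discrete parents; one shared slope set across discrete configurations
    (a valid special case of the CLG class).
    """

    intercept: float
    coefs: dict[str, float] = field(default_factory=dict)
    offsets: dict[str, dict[str, float]] = field(default_factory=dict)
    sd: float = 1.0


@dataclass
class GroundTruth:
    specs: dict[str, VariableSpec]
    arcs: set[Arc]
    cpt: dict[str, dict[tuple, tuple[float, ...]]]  # discrete node locals
    lin: dict[str, LinModel]


@dataclass(frozen=True)
class ModeratorEffect:
    """Arc-set edits applied to the ground truth for one moderator level."""

    moderator: str
    level: str
    remove_arcs: tuple[Arc, ...] = ()
    add_arcs: tuple[tuple[Arc, float], ...] = ()  # arc plus coefficient/offset
    set_coefs: tuple[tuple[Arc, float], ...] = ()


@dataclass
class SyntheticConfig:
    n_participants: int
    seed: int
    ground_truth: GroundTruth
    concepts: tuple[ConceptDef, ...] = ()
    waves: tuple[str, ...] = ("T0", "T1", "T2", "T3")
    moderator_effects: tuple[ModeratorEffect, ...] = ()
    missing_item_rate: float = 0.0
    item_noise_sd: float = 0.3
    use_items: bool = False
    # whole-variable missingness: variable -> studies in which it is measured
    missing_wave_pattern: dict[str, frozenset[str]] = field(default_factory=dict)
    study_mix: dict[str, float] = field(default_factory=dict)
    study_age_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    age_mean: float = 63.0
    age_sd: float = 8.0
    age_range: tuple[float, float] = (50.0, 90.0)
    demographic_missing_rate: float = 0.0
    outcome_lognormal: bool = False

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not (0.0 <= self.missing_item_rate <= 1.0):
            raise ValueError("missing_item_rate must be in [0, 1]")
        if self.study_mix:
            total = sum(self.study_mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("study_mix proportions must sum to 1")
        for var in self.missing_wave_pattern:
            if var not in self.ground_truth.specs:
                raise KeyError(f"missing_wave_pattern references unknown variable {var}")

    def concept_def(self, name: str) -> ConceptDef | None:
        for c in self.concepts:
            if c.name == name:
                return c
        return None


# ---------------------------------------------------------------------------
# ground-truth construction
# ---------------------------------------------------------------------------


def _variant_truth(truth: GroundTruth, effect: ModeratorEffect | None) -> GroundTruth:
    if effect is None:
        return truth
    arcs = set(truth.arcs)
    lin = {n: LinModel(m.intercept, dict(m.coefs), {k: dict(v) for k, v in m.offsets.items()}, m.sd)
           for n, m in truth.lin.items()}
    for arc in effect.remove_arcs:
        u, v = arc
        if arc not in arcs:
            raise ValueError(f"moderator effect removes absent arc {arc}")
        arcs.discard(arc)
        if v in lin:
            lin[v].coefs.pop(u, None)
            lin[v].offsets.pop(u, None)
    for (u, v), w in effect.add_arcs:
        arcs.add((u, v))
        if v in lin:
            if truth.specs[u].is_discrete:
                levels = truth.specs[u].levels
                lin[v].offsets[u] = {l: w * i for i, l in enumerate(levels)}
            else:
                lin[v].coefs[u] = w
    for (u, v), w in effect.set_coefs:
        if (u, v) not in arcs:
            raise ValueError(f"set_coefs references absent arc {(u, v)}")
        if truth.specs[u].is_discrete:
            levels = truth.specs[u].levels
            lin[v].offsets[u] = {l: w * i for i, l in enumerate(levels)}
        else:
            lin[v].coefs[u] = w
    return GroundTruth(specs=truth.specs, arcs=arcs, cpt=truth.cpt, lin=lin)


def build_ground_truth(
    config: SyntheticConfig,
    moderator_level: tuple[str, str] | None = None,
) -> HybridBN:
    """Instantiate and validate the (possibly moderated) ground-truth network.

    Raises a configuration error naming the offending arc if any arc runs
    against the wave ordering or closes a cycle — including arcs introduced
    by moderator edits.
    """
    truth = config.ground_truth
    effect = None
    if moderator_level is not None:
        for e in config.moderator_effects:
            if (e.moderator, e.level) == moderator_level:
                effect = e
                break
    truth = _variant_truth(truth, effect)
    specs = truth.specs
    constraint = TierConstraint.from_specs(specs, exogenous_roots=True)
    structure = DAGStructure(nodes=tuple(sorted(specs)), arcs=frozenset())
    for arc in sorted(truth.arcs):
        ok, reason = check_arc_legal(structure, constraint, arc, specs)
        if not ok:
            raise ValueError(f"ground-truth arc {arc} is illegal ({reason})")
        structure = structure.with_arc(arc)

    discrete: dict[str, DiscreteLocal] = {}
    continuous: dict[str, GaussianLocal] = {}
    for node in structure.nodes:
        spec = specs[node]
        parents = structure.parents(node)
        if spec.is_discrete:
            disc_parents = tuple(sorted(parents))
            table = truth.cpt.get(node, {})
            if not disc_parents and () not in table:
                raise ValueError(f"no CPT for root discrete node {node}")
            lc = len(spec.levels)
            full = {
                cfg: np.asarray(probs, dtype=float)
                for cfg, probs in table.items()
            }
            for cfg, probs in full.items():
                if len(probs) != lc or abs(probs.sum() - 1.0) > 1e-9:
                    raise ValueError(f"bad CPT row for {node} at {cfg}")
            marginal = np.mean(list(full.values()), axis=0)
            discrete[node] = DiscreteLocal(
                parents=disc_parents,
                levels=spec.levels,
                parent_levels=tuple(specs[p].levels for p in disc_parents),
                table=full,
                marginal=marginal,
            )
        else:
            model = truth.lin.get(node)
            if model is None:
                raise ValueError(f"no linear model for continuous node {node}")
            disc_parents = tuple(sorted(p for p in parents if specs[p].is_discrete))
            cont_parents = tuple(sorted(p for p in parents if not specs[p].is_discrete))
            declared = set(model.coefs) | set(model.offsets)
            if declared != parents:
                raise ValueError(
                    f"{node}: parameterised parents {sorted(declared)} "
                    f"do not match arcs {sorted(parents)}"
                )
            coef_vec = np.array([model.coefs[p] for p in cont_parents])
            table = {}
            for cfg in itertools.product(*(specs[p].levels for p in disc_parents)):
                b0 = model.intercept + sum(
                    model.offsets[p][lvl] for p, lvl in zip(disc_parents, cfg)
                )
                table[cfg] = (float(b0), coef_vec.copy(), model.sd**2)
            continuous[node] = GaussianLocal(
                disc_parents=disc_parents,
                cont_parents=cont_parents,
                parent_levels=tuple(specs[p].levels for p in disc_parents),
                table=table,
                pooled=(model.intercept, coef_vec.copy(), model.sd**2),
            )
    return HybridBN(structure=structure, parameters=CLGParameters(discrete, continuous), specs=dict(specs))


# ---------------------------------------------------------------------------
# forward sampling
# ---------------------------------------------------------------------------


def _forward_sample(
    bn: HybridBN,
    n: int,
    rng: np.random.Generator,
    given: Mapping[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    given = dict(given or {})
    order = bn.structure.topological_order()
    assert order is not None
    data: dict[str, np.ndarray] = {}
    for node in order:
        if node in given:
            data[node] = np.asarray(given[node])
            continue
        spec = bn.specs[node]
        if spec.is_discrete:
            local = bn.parameters.discrete[node]
            if local.parents:
                codes = tuple(
                    pd.Series(data[p]).map(
                        {l: i for i, l in enumerate(bn.specs[p].levels)}
                    ).to_numpy(dtype=np.intp)
                    for p in local.parents
                )
                dims = tuple(len(lv) for lv in local.parent_levels)
                ids = np.ravel_multi_index(codes, dims)
                configs = list(itertools.product(*local.parent_levels))
                rows = np.vstack([local.probs(c) for c in configs])[ids]
            else:
                rows = np.tile(local.probs(()), (n, 1))
            cum = rows.cumsum(axis=1)
            picks = (rng.random(n)[:, None] > cum).sum(axis=1)
            data[node] = np.array([spec.levels[i] for i in picks], dtype=object)
        else:
            local = bn.parameters.continuous[node]
            Xp = (
                np.column_stack([data[p] for p in local.cont_parents]).astype(float)
                if local.cont_parents
                else np.empty((n, 0))
            )
            if local.disc_parents:
                codes = tuple(
                    pd.Series(data[p]).map(
                        {l: i for i, l in enumerate(bn.specs[p].levels)}
                    ).to_numpy(dtype=np.intp)
                    for p in local.disc_parents
                )
                dims = tuple(len(lv) for lv in local.parent_levels)
                ids = np.ravel_multi_index(codes, dims)
                configs = list(itertools.product(*local.parent_levels))
                b0s = np.array([local.coefs(c)[0] for c in configs])[ids]
                s2s = np.array([local.coefs(c)[2] for c in configs])[ids]
                coefs = np.vstack([local.coefs(c)[1] for c in configs])[ids]
                mu = b0s + (np.einsum("ij,ij->i", Xp, coefs) if Xp.shape[1] else 0.0)
                sd = np.sqrt(s2s)
            else:
                b0, coef, s2 = local.coefs(())
                mu = b0 + (Xp @ coef if Xp.shape[1] else 0.0)
                sd = math.sqrt(s2)
            data[node] = mu + rng.normal(size=n) * sd
    cols = sorted(bn.specs)
    return pd.DataFrame({c: data[c] for c in cols})


def simulate_panel(bn: HybridBN, n: int, seed: int) -> PanelDataset:
    """Ancestral sampling of ``n`` participants from a parameterized network."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    frame = _forward_sample(bn, n, rng)
    ds = PanelDataset(frame, dict(bn.specs))
    ds.log(f"simulated n={n} seed={seed}")
    return ds


# ---------------------------------------------------------------------------
# item rendering and missingness injection
# ---------------------------------------------------------------------------


def render_items(
    dataset: PanelDataset,
    config: SyntheticConfig,
    seed: int,
) -> pd.DataFrame:
    """Ordinal item responses for every concept-score column.

    Each item is the concept score plus independent Gaussian noise, rounded
    half-up and clipped to 1..scale_max; items go missing independently at
    ``missing_item_rate``; items of a missing concept score are missing.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for var in dataset.variables:
        cdef = config.concept_def(concept_of(var))
        if cdef is None:
            continue
        score = dataset.frame[var].to_numpy(dtype=float)
        for k in range(1, cdef.items_per_concept + 1):
            noise = rng.normal(scale=config.item_noise_sd, size=len(score))
            item = np.floor(score + noise + 0.5)  # round half-up
            item = np.clip(item, 1, cdef.scale_max)
            if config.missing_item_rate > 0:
                drop = rng.random(len(score)) < config.missing_item_rate
                item = np.where(drop, np.nan, item)
            item = np.where(np.isnan(score), np.nan, item)
            out[f"{var}#{k}"] = item
    return pd.DataFrame(out, index=dataset.frame.index)


def assign_studies(n: int, mix: Mapping[str, float], seed: int) -> np.ndarray:
    labels = sorted(mix)
    probs = np.array([mix[l] for l in labels])
    rng = np.random.default_rng(seed)
    return rng.choice(np.array(labels, dtype=object), size=n, p=probs)


def inject_structural_missingness(
    dataset: PanelDataset,
    config: SyntheticConfig,
    seed: int,
    study: np.ndarray | None = None,
) -> PanelDataset:
    """Blank whole variables for participants of studies that lack them.

    Emulates dataset-integration missingness: a variable measured only in
    studies S is missing for every participant whose (synthetic) study is
    outside S.  Study labels are drawn from ``study_mix`` unless provided.
    """
    out = dataset.copy()
    if not config.missing_wave_pattern:
        return out
    if study is None:
        if not config.study_mix:
            raise ValueError("study_mix required to assign studies")
        study = assign_studies(out.n, config.study_mix, seed)
    for var, available in config.missing_wave_pattern.items():
        if var not in out.specs:
            raise KeyError(f"pattern references unknown variable {var}")
        gone = ~pd.Series(study, index=out.frame.index).isin(sorted(available))
        out.frame.loc[gone.to_numpy(), var] = np.nan
    out.log("injected structural (by-study) missingness")
    return out


def mcar(
    dataset: PanelDataset,
    rate: float,
    seed: int,
    columns: Sequence[str] | None = None,
) -> PanelDataset:
    """Independent missing-completely-at-random cells at the given rate."""
    out = dataset.copy()
    rng = np.random.default_rng(seed)
    cols = list(columns) if columns is not None else out.variables
    for c in cols:
        drop = rng.random(out.n) < rate
        out.frame.loc[drop, c] = np.nan
    out.log(f"MCAR rate={rate} on {len(cols)} columns")
    return out


# ---------------------------------------------------------------------------
# end-to-end generation
# ---------------------------------------------------------------------------


def generate_dataset(config: SyntheticConfig) -> PanelDataset:
    """Simulate a full panel under the configured study conditions.

    Order of operations: assign synthetic studies; sample age per study's
    recruitment range; sample all remaining variables by ancestral sampling
    (per moderator level when moderation is configured); optionally render
    items and aggregate them back to concept scores; blank demographics at
    the configured rate; inject by-study structural missingness.
    """
    n = config.n_participants
    master = np.random.SeedSequence(config.seed)
    seeds = master.generate_state(6) % (2**31)
    rng = np.random.default_rng(int(seeds[0]))

    study = None
    if config.study_mix:
        study = assign_studies(n, config.study_mix, int(seeds[1]))

    base = build_ground_truth(config)
    given: dict[str, np.ndarray] = {}
    if "age" in base.specs and not base.specs["age"].is_discrete:
        lo, hi = config.age_range
        age = np.empty(n)
        ranges = np.tile(np.array([[lo, hi]]), (n, 1))
        if study is not None and config.study_age_ranges:
            for label, (slo, shi) in config.study_age_ranges.items():
                sel = study == label
                ranges[sel] = (slo, shi)
        a = (ranges[:, 0] - config.age_mean) / config.age_sd
        b = (ranges[:, 1] - config.age_mean) / config.age_sd
        age = stats.truncnorm.rvs(
            a, b, loc=config.age_mean, scale=config.age_sd,
            size=n, random_state=np.random.default_rng(int(seeds[2])),
        )
        given["age"] = age

    effects = {(e.moderator, e.level): e for e in config.moderator_effects}
    if effects:
        # sample static exogenous variables once, then the waves per level
        static_nodes = [
            v for v, s in base.specs.items() if s.timeslot == "static"
        ]
        statics = _forward_sample(
            base, n, rng, given
        )[static_nodes]
        frame = pd.DataFrame(index=range(n), columns=sorted(base.specs), dtype=object)
        frame[static_nodes] = statics
        moderators = {m for (m, _) in effects}
        for moderator in sorted(moderators):
            levels = base.specs[moderator].levels
            for level_idx, level in enumerate(levels):
                sel = statics[moderator].to_numpy() == level
                if not sel.any():
                    continue
                variant = build_ground_truth(
                    config,
                    (moderator, level) if (moderator, level) in effects else None,
                )
                sub_given = {c: statics[c].to_numpy()[sel] for c in static_nodes}
                sub = _forward_sample(
                    variant,
                    int(sel.sum()),
                    np.random.default_rng(int(seeds[3]) + level_idx),
                    sub_given,
                )
                frame.loc[sel, sub.columns] = sub.to_numpy()
        for c in frame.columns:
            if not base.specs[c].is_discrete:
                frame[c] = frame[c].astype(float)
    else:
        frame = _forward_sample(base, n, rng, given)

    ds = PanelDataset(frame, dict(base.specs))
    ds.log(f"generated n={n} seed={config.seed}")

    if config.outcome_lognormal:
        for var in ds.variables:
            if concept_of(var) == "mvpa" and not ds.specs[var].is_discrete:
                ds.frame[var] = np.exp(ds.frame[var] / 2.0)
        ds.log("outcome transformed to log-normal scale")

    if config.use_items and config.concepts:
        items = render_items(ds, config, int(seeds[4]))
        scores = aggregate_item_table(items)
        for var in scores.columns:
            ds.frame[var] = scores[var]
        ds.log("concept scores re-aggregated from rendered items")

    if config.demographic_missing_rate > 0:
        rng_demo = np.random.default_rng(int(seeds[5]))
        for var, spec in ds.specs.items():
            if spec.role == "demographic":
                drop = rng_demo.random(n) < config.demographic_missing_rate
                ds.frame.loc[drop, var] = np.nan
        ds.log(f"demographic MCAR rate={config.demographic_missing_rate}")

    if config.missing_wave_pattern:
        ds = inject_structural_missingness(ds, config, int(seeds[1]), study)
    return ds


# ---------------------------------------------------------------------------
# config (de)serialisation
# ---------------------------------------------------------------------------


def config_to_dict(config: SyntheticConfig) -> dict:
    truth = config.ground_truth
    return {
        "n_participants": config.n_participants,
        "seed": config.seed,
        "waves": list(config.waves),
        "concepts": [
            {"name": c.name, "items_per_concept": c.items_per_concept,
             "scale_max": c.scale_max}
            for c in config.concepts
        ],
        "ground_truth": {
            "variables": [
                {"name": s.name, "kind": s.kind, "role": s.role,
                 "timeslot": s.timeslot,
                 **({"levels": list(s.levels)} if s.levels else {})}
                for s in truth.specs.values()
            ],
            "arcs": sorted([list(a) for a in truth.arcs]),
            "cpt": {
                node: [{"config": list(cfg), "probs": list(map(float, probs))}
                       for cfg, probs in table.items()]
                for node, table in truth.cpt.items()
            },
            "linear": {
                node: {"intercept": m.intercept, "coefs": dict(m.coefs),
                       "offsets": {p: dict(d) for p, d in m.offsets.items()},
                       "sd": m.sd}
                for node, m in truth.lin.items()
            },
        },
        "moderator_effects": [
            {"moderator": e.moderator, "level": e.level,
             "remove_arcs": [list(a) for a in e.remove_arcs],
             "add_arcs": [[list(a), w] for a, w in e.add_arcs],
             "set_coefs": [[list(a), w] for a, w in e.set_coefs]}
            for e in config.moderator_effects
        ],
        "missing_item_rate": config.missing_item_rate,
        "item_noise_sd": config.item_noise_sd,
        "use_items": config.use_items,
        "missing_wave_pattern": {
            v: sorted(studies) for v, studies in config.missing_wave_pattern.items()
        },
        "study_mix": dict(config.study_mix),
        "study_age_ranges": {k: list(v) for k, v in config.study_age_ranges.items()},
        "age_mean": config.age_mean,
        "age_sd": config.age_sd,
        "age_range": list(config.age_range),
        "demographic_missing_rate": config.demographic_missing_rate,
        "outcome_lognormal": config.outcome_lognormal,
    }


def config_from_dict(doc: Mapping) -> SyntheticConfig:
    gt = doc["ground_truth"]
    specs = {
        v["name"]: VariableSpec(
            name=v["name"], kind=v["kind"], role=v["role"],
            timeslot=v.get("timeslot", "static"),
            levels=tuple(v["levels"]) if v.get("levels") else None,
        )
        for v in gt["variables"]
    }
    truth = GroundTruth(
        specs=specs,
        arcs={tuple(a) for a in gt["arcs"]},
        cpt={
            node: {tuple(row["config"]): tuple(row["probs"]) for row in rows}
            for node, rows in gt.get("cpt", {}).items()
        },
        lin={
            node: LinModel(
                intercept=m["intercept"], coefs=dict(m.get("coefs", {})),
                offsets={p: dict(d) for p, d in m.get("offsets", {}).items()},
                sd=m.get("sd", 1.0),
            )
            for node, m in gt.get("linear", {}).items()
        },
    )
    effects = tuple(
        ModeratorEffect(
            moderator=e["moderator"], level=e["level"],
            remove_arcs=tuple(tuple(a) for a in e.get("remove_arcs", [])),
            add_arcs=tuple((tuple(a), w) for a, w in e.get("add_arcs", [])),
            set_coefs=tuple((tuple(a), w) for a, w in e.get("set_coefs", [])),
        )
        for e in doc.get("moderator_effects", [])
    )
    return SyntheticConfig(
        n_participants=doc["n_participants"],
        seed=doc["seed"],
        ground_truth=truth,
        concepts=tuple(
            ConceptDef(c["name"], c.get("items_per_concept", 3), c.get("scale_max", 5))
            for c in doc.get("concepts", [])
        ),
        waves=tuple(doc.get("waves", ("T0", "T1", "T2", "T3"))),
        moderator_effects=effects,
        missing_item_rate=doc.get("missing_item_rate", 0.0),
        item_noise_sd=doc.get("item_noise_sd", 0.3),
        use_items=doc.get("use_items", False),
        missing_wave_pattern={
            v: frozenset(s) for v, s in doc.get("missing_wave_pattern", {}).items()
        },
        study_mix=dict(doc.get("study_mix", {})),
        study_age_ranges={
            k: tuple(v) for k, v in doc.get("study_age_ranges", {}).items()
        },
        age_mean=doc.get("age_mean", 63.0),
        age_sd=doc.get("age_sd", 8.0),
        age_range=tuple(doc.get("age_range", (50.0, 90.0))),
        demographic_missing_rate=doc.get("demographic_missing_rate", 0.0),
        outcome_lognormal=doc.get("outcome_lognormal", False),
    )


def save_config(config: SyntheticConfig, path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def load_config(path) -> SyntheticConfig:
    import yaml

    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))
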
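"""Shipped synthetic study configurations.

``default_config`` emulates the pooled five-study intervention panel:
twelve determinant concepts plus the MVPA outcome measured at the waves in
which the contributing studies actually administered them, a randomized
binary intervention, demographics (age in years 50–90, gender, three-level
education, impairment), by-study whole-variable missingness, and concept
scores aggregated from 5-point items (10-point for intention).

``compact_config`` is a 20-variable, 4-tier ground truth used for structure
-recovery experiments, and ``moderated_config`` a small two-wave network
with a single planted moderation edit (the impairment level loses the
direct intention→MVPA arc), used for end-to-end subgroup comparisons.

Coefficients are arbitrary but fixed defaults chosen to give realistic
effect sizes on 1–5 concept scales; they are the ground truth the tests
recover, not estimates from any real dataset.
"""

from __future__ import annotations

from .dataset import VariableSpec
from .synthetic import (
    ConceptDef,
    GroundTruth,
    LinModel,
    ModeratorEffect,
    SyntheticConfig,
)

# Wave availability per concept: which synthetic studies measured it when.
# (A concept/wave pair absent here does not exist as a variable at all.)
AVAILABILITY: dict[str, dict[str, frozenset[str]]] = {
    "self_efficacy": {
        "T0": frozenset("12345"), "T1": frozenset("1235"),
        "T2": frozenset("5"), "T3": frozenset("4"),
    },
    "attitude_pros": {
        "T0": frozenset("12345"), "T1": frozenset("1235"),
        "T2": frozenset("5"), "T3": frozenset("4"),
    },
    "attitude_cons": {
        "T0": frozenset("12345"), "T1": frozenset("1235"),
        "T2": frozenset("5"), "T3": frozenset("4"),
    },
    "intrinsic_motivation": {
        "T0": frozenset("125"), "T1": frozenset("12"), "T2": frozenset("5"),
    },
    "intention": {
        "T0": frozenset("12345"), "T1": frozenset("123"),
        "T2": frozenset("1245"), "T3": frozenset("1245"),
    },
    "commitment": {
        "T0": frozenset("12"), "T1": frozenset("12"), "T2": frozenset("12"),
    },
    "strategic_planning": {
        "T0": frozenset("12345"), "T1": frozenset("12"),
        "T2": frozenset("125"), "T3": frozenset("14"),
    },
    "action_planning": {
        "T0": frozenset("125"), "T1": frozenset("12"), "T2": frozenset("125"),
    },
    "coping_planning": {
        "T0": frozenset("125"), "T1": frozenset("12"), "T2": frozenset("125"),
    },
    "habit": {
        "T0": frozenset("1245"), "T2": frozenset("1245"), "T3": frozenset("1245"),
    },
    "social_modeling": {
        "T0": frozenset("12345"), "T1": frozenset("123"),
        "T2": frozenset("13"), "T3": frozenset("4"),
    },
    "social_support": {
        "T0": frozenset("12345"), "T1": frozenset("1235"),
        "T2": frozenset("35"), "T3": frozenset("4"),
    },
    "mvpa": {
        "T0": frozenset("12345"), "T1": frozenset("1235"),
        "T2": frozenset("12345"), "T3": frozenset("1245"),
    },
}

# determinant staging used to lay out within-wave arcs
PREMOTIVATIONAL = ("self_efficacy", "attitude_pros", "attitude_cons")
MOTIVATIONAL = ("intrinsic_motivation", "intention")
POSTMOTIVATIONAL = (
    "commitment", "strategic_planning", "action_planning", "coping_planning", "habit",
)
SOCIAL = ("social_modeling", "social_support")

CONCEPTS = tuple(
    ConceptDef(name, items_per_concept=4, scale_max=10 if name == "intention" else 5)
    for name in AVAILABILITY
    if name != "mvpa"
)

# Proportions of the synthetic studies in the pooled panel; studies "3" and
# "4" recruited exclusively 65-plus participants.
STUDY_MIX = {"1": 0.30, "2": 0.25, "3": 0.10, "4": 0.15, "5": 0.20}
STUDY_AGE_RANGES = {"3": (65.0, 90.0), "4": (65.0, 90.0)}


def _static_specs() -> dict[str, VariableSpec]:
    return {
        "intervention": VariableSpec(
            "intervention", "discrete", "intervention", "static",
            ("control", "intervention"),
        ),
        "gender": VariableSpec(
            "gender", "discrete", "demographic", "static", ("female", "male")
        ),
        "age": VariableSpec("age", "continuous", "demographic", "static"),
        "education": VariableSpec(
            "education", "discrete", "demographic", "static",
            ("low", "medium", "high"),
        ),
        "impairment": VariableSpec(
            "impairment", "discrete", "demographic", "static", ("no", "yes")
        ),
    }


def _static_cpts() -> dict:
    return {
        "intervention": {(): (0.3, 0.7)},  # waiting-list control vs intervention
        "gender": {(): (0.55, 0.45)},
        "education": {(): (0.35, 0.40, 0.25)},
        "impairment": {(): (0.55, 0.45)},
    }


def default_config(n_participants: int = 5710, seed: int = 2025) -> SyntheticConfig:
    """Full pooled-panel emulation (52 variables, five synthetic studies)."""
    specs = _static_specs()
    pattern: dict[str, frozenset[str]] = {}
    for concept, waves in AVAILABILITY.items():
        for wave, studies in waves.items():
            name = f"{concept}@{wave}"
            role = "outcome" if concept == "mvpa" else "determinant"
            specs[name] = VariableSpec(name, "continuous", role, wave)
            pattern[name] = studies

    arcs: set[tuple[str, str]] = set()
    lin: dict[str, LinModel] = {"age": LinModel(intercept=63.0, sd=8.0)}

    def exists(concept: str, wave: str) -> bool:
        return wave in AVAILABILITY.get(concept, {})

    def add_arc(u: str, v: str, w: float) -> None:
        arcs.add((u, v))
        lin[v].coefs[u] = w

    def add_offset(u: str, v: str, deltas: dict[str, float]) -> None:
        arcs.add((u, v))
        lin[v].offsets[u] = deltas

    waves = ("T0", "T1", "T2", "T3")
    for concept, per_wave in AVAILABILITY.items():
        base = 5.5 if concept == "intention" else 3.0
        if concept == "mvpa":
            base = 6.0
        for wave in per_wave:
            lin[f"{concept}@{wave}"] = LinModel(intercept=base, sd=0.8)

    def prev_wave(concept: str, wave: str) -> str | None:
        idx = waves.index(wave)
        for w in reversed(waves[:idx]):
            if exists(concept, w):
                return w
        return None

    for concept, per_wave in AVAILABILITY.items():
        for wave in per_wave:
            prev = prev_wave(concept, wave)
            if prev is not None:
                add_arc(f"{concept}@{prev}", f"{concept}@{wave}", 0.55)

    def stage_arcs(wave: str) -> None:
        def arc_if(u_c: str, v_c: str, w: float) -> None:
            if exists(u_c, wave) and exists(v_c, wave):
                add_arc(f"{u_c}@{wave}", f"{v_c}@{wave}", w)

        arc_if("self_efficacy", "intention", 0.35)
        arc_if("attitude_pros", "intention", 0.30)
        arc_if("attitude_cons", "intention", -0.25)
        arc_if("attitude_pros", "intrinsic_motivation", 0.30)
        arc_if("social_modeling", "intrinsic_motivation", 0.25)
        arc_if("social_support", "intention", 0.20)
        arc_if("intrinsic_motivation", "intention", 0.30)
        arc_if("intention", "commitment", 0.35)
        arc_if("intention", "strategic_planning", 0.35)
        arc_if("intention", "action_planning", 0.30)
        arc_if("action_planning", "coping_planning", 0.35)
        arc_if("strategic_planning", "habit", 0.30)
        arc_if("commitment", "habit", 0.25)
        arc_if("habit", "mvpa", 0.50)
        arc_if("intention", "mvpa", 0.40)

    for wave in waves:
        stage_arcs(wave)

    # the intervention nudges determinants from the first post-baseline wave on
    for concept in (
        "self_efficacy", "attitude_pros", "intention",
        "strategic_planning", "action_planning", "social_support",
    ):
        for wave in ("T1", "T2"):
            if exists(concept, wave):
                add_offset(
                    "intervention", f"{concept}@{wave}",
                    {"control": 0.0, "intervention": 0.35},
                )

    # demographic corrections
    for wave in waves:
        if exists("mvpa", wave):
            add_arc("age", f"mvpa@{wave}", -0.02)
            add_offset("gender", f"mvpa@{wave}", {"female": 0.0, "male": 0.2})
            add_offset(
                "impairment", f"mvpa@{wave}", {"no": 0.0, "yes": -0.5}
            )
    add_offset("education", "intention@T0", {"low": 0.0, "medium": 0.2, "high": 0.35})

    truth = GroundTruth(specs=specs, arcs=arcs, cpt=_static_cpts(), lin=lin)
    return SyntheticConfig(
        n_participants=n_participants,
        seed=seed,
        ground_truth=truth,
        concepts=CONCEPTS,
        moderator_effects=(),
        missing_item_rate=0.05,
        item_noise_sd=0.3,
        use_items=True,
        missing_wave_pattern=pattern,
        study_mix=STUDY_MIX,
        study_age_ranges=STUDY_AGE_RANGES,
        demographic_missing_rate=0.02,
    )


def compact_config(n_participants: int = 2000, seed: int = 7) -> SyntheticConfig:
    """20 variables in 4 tiers (5 static + 3 waves × 5 concepts)."""
    specs = _static_specs()
    waves = ("T1", "T2", "T3")
    per_wave = ("self_efficacy", "intention", "strategic_planning", "habit", "mvpa")
    lin: dict[str, LinModel] = {"age": LinModel(intercept=63.0, sd=8.0)}
    arcs: set[tuple[str, str]] = set()
    for wave in waves:
        for concept in per_wave:
            name = f"{concept}@{wave}"
            role = "outcome" if concept == "mvpa" else "determinant"
            specs[name] = VariableSpec(name, "continuous", role, wave)
            lin[name] = LinModel(intercept=3.0 if concept != "mvpa" else 6.0, sd=1.0)

    def add_arc(u, v, w):
        arcs.add((u, v))
        lin[v].coefs[u] = w

    def add_offset(u, v, deltas):
        arcs.add((u, v))
        lin[v].offsets[u] = deltas

    for wave in waves:
        add_arc(f"self_efficacy@{wave}", f"intention@{wave}", 0.6)
        add_arc(f"intention@{wave}", f"strategic_planning@{wave}", 0.6)
        add_arc(f"strategic_planning@{wave}", f"habit@{wave}", 0.5)
        add_arc(f"habit@{wave}", f"mvpa@{wave}", 0.7)
        add_arc(f"intention@{wave}", f"mvpa@{wave}", 0.5)
    for prev, nxt in zip(waves[:-1], waves[1:]):
        for concept in per_wave:
            add_arc(f"{concept}@{prev}", f"{concept}@{nxt}", 0.7)
    add_offset("intervention", "self_efficacy@T1", {"control": 0.0, "intervention": 0.8})
    add_offset("intervention", "intention@T1", {"control": 0.0, "intervention": 0.6})
    add_offset("intervention", "strategic_planning@T1", {"control": 0.0, "intervention": 0.7})
    add_offset("gender", "habit@T1", {"female": 0.0, "male": 0.5})
    add_arc("age", "mvpa@T1", -0.03)

    truth = GroundTruth(specs=specs, arcs=arcs, cpt=_static_cpts(), lin=lin)
    return SyntheticConfig(
        n_participants=n_participants,
        seed=seed,
        ground_truth=truth,
        waves=waves,
    )


def moderated_config(
    n_participants: int = 5000, seed: int = 11
) -> SyntheticConfig:
    """Two-wave network with one planted moderation edit on impairment.

    For participants with impairment the direct intention@T2→mvpa@T2 arc is
    absent; intention keeps an indirect route via habit, so its role for the
    short-term outcome flips from direct to indirect between subgroups.
    """
    specs = {
        k: v
        for k, v in _static_specs().items()
        if k in ("intervention", "gender", "age", "impairment")
    }
    lin: dict[str, LinModel] = {"age": LinModel(intercept=63.0, sd=8.0)}
    arcs: set[tuple[str, str]] = set()
    for wave in ("T2", "T3"):
        for concept in ("intention", "habit", "mvpa"):
            name = f"{concept}@{wave}"
            role = "outcome" if concept == "mvpa" else "determinant"
            specs[name] = VariableSpec(name, "continuous", role, wave)
            lin[name] = LinModel(intercept=3.0 if concept != "mvpa" else 6.0, sd=1.0)

    def add_arc(u, v, w):
        arcs.add((u, v))
        lin[v].coefs[u] = w

    def add_offset(u, v, deltas):
        arcs.add((u, v))
        lin[v].offsets[u] = deltas

    add_offset("intervention", "intention@T2", {"control": 0.0, "intervention": 0.8})
    add_arc("intention@T2", "habit@T2", 0.6)
    add_arc("habit@T2", "mvpa@T2", 0.7)
    add_arc("intention@T2", "mvpa@T2", 0.6)  # removed for the impaired level
    add_arc("intention@T2", "intention@T3", 0.7)
    add_arc("habit@T2", "habit@T3", 0.7)
    add_arc("mvpa@T2", "mvpa@T3", 0.7)
    add_arc("habit@T3", "mvpa@T3", 0.6)
    add_arc("age", "mvpa@T2", -0.03)
    add_offset("gender", "habit@T2", {"female": 0.0, "male": 0.4})

    cpts = {
        "intervention": {(): (0.5, 0.5)},
        "gender": {(): (0.55, 0.45)},
        "impairment": {(): (0.5, 0.5)},
    }
    truth = GroundTruth(specs=specs, arcs=arcs, cpt=cpts, lin=lin)
    effect = ModeratorEffect(
        moderator="impairment",
        level="yes",
        remove_arcs=((f"intention@T2", f"mvpa@T2"),),
    )
    return SyntheticConfig(
        n_participants=n_participants,
        seed=seed,
        ground_truth=truth,
        waves=("T2", "T3"),
        moderator_effects=(effect,),
    )
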
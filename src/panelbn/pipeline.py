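"""End-to-end subgroup analysis: preprocess → bootstrap → average → grade →
distil pathway fragments → compare the two moderator levels.

Every stage writes its intermediates under the output directory together
with a manifest of seeds and settings, so any stage can be re-run in
isolation and a re-run with the same seeds is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import io as pbio
from .bn import TierConstraint
from .dataset import PanelDataset
from .ensemble import (
    AveragedNetwork,
    arc_confidence,
    average_network,
    bootstrap_structures,
    stability_select_B,
)
from .learning import SearchSettings
from .preprocess import LevelRule, drop_unobserved_variables, subset_subpopulation
from .strength import (
    FragmentDiff,
    PathFragment,
    compare_fragments,
    extract_fragment,
    grade_edges,
)

log = logging.getLogger("panelbn")


@dataclass
class RunConfig:
    """Settings for one moderator-pair analysis."""

    moderator: str
    level_rules: tuple[str, str]  # e.g. ("<65", ">=65") or ("low", "medium,high")
    source: str = "intervention"
    targets: tuple[str, ...] = ("mvpa@T2", "mvpa@T3")
    threshold: float = 0.6
    B: int | None = None  # fixed bootstrap count; None -> stability selection
    B_grid: tuple[int, ...] = (100, 110, 120, 130, 140, 150)
    min_observed: int = 30
    settings: SearchSettings = field(default_factory=SearchSettings)
    seed: int = 0
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold <= 1.0):
            raise ValueError("threshold must be in (0, 1]")
        if len(self.level_rules) != 2:
            raise ValueError("exactly two level rules required")


@dataclass
class SubgroupResult:
    label: str
    dataset: PanelDataset
    dropped_variables: list[str]
    network: AveragedNetwork
    fragment: PathFragment
    chosen_B: int
    stability_curve: list[int] | None


@dataclass
class AnalysisReport:
    moderator: str
    subgroups: tuple[SubgroupResult, SubgroupResult]
    diff: FragmentDiff
    manifest: dict


def _analyse_level(
    dataset: PanelDataset,
    config: RunConfig,
    rule: str,
    seed: int,
    out_dir: Path | None,
) -> SubgroupResult:
    label = f"{config.moderator}_{rule}".replace("<", "lt").replace(">=", "ge").replace(
        ">", "gt").replace("<=", "le").replace(",", "+")
    log.info("subgroup %s: preprocessing", label)
    sub = subset_subpopulation(dataset, config.moderator, rule)
    sub, dropped = drop_unobserved_variables(sub, config.min_observed)
    constraint = TierConstraint.from_specs(sub.specs)

    settings = config.settings
    if config.B is not None:
        run = bootstrap_structures(sub, constraint, settings, config.B, seed)
        chosen_B, curve = config.B, None
        structures = run.structures
    else:
        chosen_B, curve_obj, run = stability_select_B(
            sub, constraint, settings, list(config.B_grid),
            threshold=config.threshold, seed=seed,
        )
        curve = curve_obj.shd_to_next
        structures = run.structures[:chosen_B]
        if out_dir is not None:
            pbio.write_stability_csv(curve_obj, out_dir / f"{label}_stability.csv")
    log.info("subgroup %s: averaging %d bootstrap models", label, chosen_B)
    net = average_network(structures, config.threshold)
    targets = tuple(t for t in config.targets if t in net.nodes)
    fragment = extract_fragment(net, config.source, targets)
    fragment.annotation = grade_edges(net, sub, edges=fragment.edges)

    if out_dir is not None:
        sub.to_csv(out_dir / f"{label}_data.csv", out_dir / f"{label}_meta.json")
        pbio.write_confidence_csv(
            arc_confidence(structures), out_dir / f"{label}_confidence.csv"
        )
        pbio.write_averaged_csv(net, out_dir / f"{label}_averaged.csv")
        pbio.write_fragment_csv(fragment, out_dir / f"{label}_fragment.csv")
        (out_dir / f"{label}_fragment.dot").write_text(
            pbio.to_dot(fragment, title=label)
        )
    return SubgroupResult(
        label=label,
        dataset=sub,
        dropped_variables=dropped,
        network=net,
        fragment=fragment,
        chosen_B=chosen_B,
        stability_curve=curve,
    )


def run_subgroup_analysis(
    dataset: PanelDataset,
    config: RunConfig,
) -> AnalysisReport:
    """Analyse both moderator levels and compare their pathway fragments."""
    out_dir = Path(config.out_dir) if config.out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    results = []
    for i, rule in enumerate(config.level_rules):
        seed = config.seed * 2 + i
        try:
            results.append(_analyse_level(dataset, config, rule, seed, out_dir))
        except Exception as exc:
            raise RuntimeError(
                f"subgroup analysis failed at level {rule!r}: {exc}"
            ) from exc
    diff = compare_fragments(results[0].fragment, results[1].fragment)
    manifest = {
        "moderator": config.moderator,
        "level_rules": list(config.level_rules),
        "threshold": config.threshold,
        "B": [r.chosen_B for r in results],
        "seed": config.seed,
        "settings": dataclasses.asdict(config.settings),
        "source": config.source,
        "targets": list(config.targets),
        "dropped_variables": {r.label: r.dropped_variables for r in results},
    }
    if out_dir is not None:
        pbio.write_manifest(out_dir / "manifest.json", manifest)
        _write_diff(diff, out_dir / "fragment_diff.csv")
    return AnalysisReport(
        moderator=config.moderator,
        subgroups=(results[0], results[1]),
        diff=diff,
        manifest=manifest,
    )


def _write_diff(diff: FragmentDiff, path: Path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["section", "a", "b", "c", "d"])
        for key in diff.only_a:
            w.writerow(["only_a", key[0], key[1], "directed" if key[2] else "undirected", ""])
        for key in diff.only_b:
            w.writerow(["only_b", key[0], key[1], "directed" if key[2] else "undirected", ""])
        for node, target, ra, rb in diff.role_transitions:
            w.writerow(["role_transition", node, target, ra, rb])
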
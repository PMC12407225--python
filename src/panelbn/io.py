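"""Serialisation: arc-list CSVs, DOT rendering, network/fragment tables.

DOT conventions mirror the usual presentation of these models: node fill
colour by determinant stage (premotivational / motivational /
postmotivational / social / outcome / exogenous), edge penwidth by the
stability thickness group, and an asterisk label (*, **, ***) by the MI
strength tercile.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Mapping, Sequence

from .bn import DAGStructure
from .dataset import VariableSpec
from .ensemble import ArcConfidenceTable, AveragedNetwork, StabilityCurve
from .strength import PathFragment, StrengthAnnotation
from .synthetic import concept_of

STAGE_COLOURS = {
    "premotivational": "#a6cee3",
    "motivational": "#b2df8a",
    "postmotivational": "#fdbf6f",
    "social": "#cab2d6",
    "outcome": "#fb9a99",
    "exogenous": "#dddddd",
}

_STAGES = {
    "self_efficacy": "premotivational",
    "attitude_pros": "premotivational",
    "attitude_cons": "premotivational",
    "intrinsic_motivation": "motivational",
    "intention": "motivational",
    "commitment": "postmotivational",
    "strategic_planning": "postmotivational",
    "action_planning": "postmotivational",
    "coping_planning": "postmotivational",
    "habit": "postmotivational",
    "social_modeling": "social",
    "social_support": "social",
    "mvpa": "outcome",
}


def node_stage(name: str) -> str:
    return _STAGES.get(concept_of(name), "exogenous")


def write_arcs_csv(structure: DAGStructure, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["from", "to"])
        for u, v in sorted(structure.arcs):
            w.writerow([u, v])


def read_arcs_csv(path: str | Path, nodes: Sequence[str]) -> DAGStructure:
    arcs = set()
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            arcs.add((row["from"], row["to"]))
    return DAGStructure(nodes=tuple(sorted(nodes)), arcs=frozenset(arcs))


def write_confidence_csv(table: ArcConfidenceTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(
            fh, fieldnames=["from", "to", "presence_conf", "direction_conf"]
        )
        w.writeheader()
        for row in table.rows():
            w.writerow(row)


def write_averaged_csv(net: AveragedNetwork, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["from", "to", "directed", "presence_conf", "direction_conf"])
        for e in sorted(net.edges, key=lambda e: (e.u, e.v)):
            w.writerow(
                [e.u, e.v, int(e.directed), f"{e.presence_conf:.6f}", f"{e.direction_conf:.6f}"]
            )


def write_stability_csv(curve: StabilityCurve, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["B", "shd_to_next"])
        for b, d in zip(curve.B_grid[:-1], curve.shd_to_next):
            w.writerow([b, d])
        w.writerow([curve.B_grid[-1], ""])


def write_fragment_csv(fragment: PathFragment, path: str | Path) -> None:
    ann = fragment.annotation
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["from", "to", "directed", "presence_conf", "thickness_group", "mi", "tercile"]
        )
        for e in sorted(fragment.edges, key=lambda e: (e.u, e.v)):
            key = e.key()
            mi = ann.mi[key].estimate if ann and key in ann.mi else ""
            terc = ann.tercile.get(key, "") if ann else ""
            thick = ann.thickness.get(key, "") if ann else ""
            w.writerow(
                [e.u, e.v, int(e.directed), f"{e.presence_conf:.6f}",
                 thick, f"{mi:.6f}" if mi != "" else "", terc]
            )


def _edge_attrs(e, ann: StrengthAnnotation | None) -> str:
    attrs = []
    if ann is not None:
        key = e.key()
        thickness = ann.thickness.get(key, 1)
        attrs.append(f"penwidth={0.5 + 0.8 * thickness:.1f}")
        terc = ann.tercile.get(key)
        if terc:
            attrs.append(f'label="{"*" * terc}"')
    if not e.directed:
        attrs.append("dir=none")
    return f' [{", ".join(attrs)}]' if attrs else ""


def to_dot(
    net: AveragedNetwork | PathFragment,
    annotation: StrengthAnnotation | None = None,
    title: str = "panelbn",
) -> str:
    if isinstance(net, PathFragment):
        edges = net.edges
        annotation = annotation or net.annotation
        nodes = sorted(net.nodes)
    else:
        edges = net.edges
        nodes = sorted(net.nodes)
    lines = [f'digraph "{title}" {{', "  rankdir=LR;", "  node [style=filled];"]
    for n in nodes:
        colour = STAGE_COLOURS[node_stage(n)]
        lines.append(f'  "{n}" [fillcolor="{colour}"];')
    for e in sorted(edges, key=lambda e: (e.u, e.v)):
        lines.append(f'  "{e.u}" -> "{e.v}"{_edge_attrs(e, annotation)};')
    lines.append("}")
    return "\n".join(lines) + "\n"


def write_manifest(path: str | Path, payload: Mapping) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
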
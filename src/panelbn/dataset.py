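"""Panel dataset container: participant × variable table with missingness.

Variables are either discrete (finite level set, stored as strings) or
continuous (float64).  Determinants and outcomes are stamped with a
measurement wave (T0..T3); the intervention arm and demographics are static.
Missing cells are NaN; the observedness mask is derived, never stored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

WAVES = ("T0", "T1", "T2", "T3")
STATIC = "static"

KINDS = ("discrete", "continuous")
ROLES = ("intervention", "demographic", "determinant", "outcome")


@dataclass(frozen=True)
class VariableSpec:
    """Metadata for one column of a panel dataset."""

    name: str
    kind: str
    role: str
    timeslot: str = STATIC
    levels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r} for {self.name}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for {self.name}")
        if self.timeslot not in WAVES + (STATIC,):
            raise ValueError(f"unknown timeslot {self.timeslot!r} for {self.name}")
        if self.role in ("intervention", "demographic") and self.timeslot != STATIC:
            raise ValueError(f"{self.role} variable {self.name} must be static")
        if self.role in ("determinant", "outcome") and self.timeslot == STATIC:
            raise ValueError(f"{self.role} variable {self.name} must carry a wave")
        if self.kind == "discrete":
            if not self.levels:
                raise ValueError(f"discrete variable {self.name} needs levels")
            object.__setattr__(self, "levels", tuple(str(l) for l in self.levels))
        elif self.levels is not None:
            raise ValueError(f"continuous variable {self.name} cannot have levels")

    @property
    def is_discrete(self) -> bool:
        return self.kind == "discrete"


@dataclass
class PanelDataset:
    """Rectangular participant × variable table plus per-variable metadata.

    ``frame`` holds one row per participant; discrete columns are object
    dtype (strings, NaN when missing), continuous columns are float64.
    ``provenance`` is an append-only log of the filters applied so far.
    """

    frame: pd.DataFrame
    specs: dict[str, VariableSpec]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        extra = set(self.frame.columns) - set(self.specs)
        if extra:
            raise ValueError(f"columns without a spec: {sorted(extra)}")
        missing = set(self.specs) - set(self.frame.columns)
        if missing:
            raise ValueError(f"specs without a column: {sorted(missing)}")
        for name, spec in self.specs.items():
            col = self.frame[name]
            if spec.is_discrete:
                observed = col.dropna().astype(str)
                bad = set(observed.unique()) - set(spec.levels)
                if bad:
                    raise ValueError(
                        f"{name}: values {sorted(bad)} outside declared levels"
                    )
            else:
                self.frame[name] = pd.to_numeric(col)

    # -- basic views -------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def variables(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """True where a cell is observed."""
        return self.frame.notna()

    def observed_counts(self) -> pd.Series:
        return self.frame.notna().sum(axis=0)

    def is_complete(self) -> bool:
        return bool(self.frame.notna().all().all())

    def copy(self) -> "PanelDataset":
        return PanelDataset(self.frame.copy(), dict(self.specs), list(self.provenance))

    def log(self, message: str) -> None:
        self.provenance.append(message)

    def restrict(self, names: Sequence[str]) -> "PanelDataset":
        specs = {n: self.specs[n] for n in names}
        return PanelDataset(self.frame[list(names)].copy(), specs, list(self.provenance))

    def complete_rows(self, names: Sequence[str] | None = None) -> pd.DataFrame:
        cols = list(names) if names is not None else self.variables
        sub = self.frame[cols]
        return sub[sub.notna().all(axis=1)]

    # -- serialisation -----------------------------------------------------

    def to_csv(self, csv_path: str | Path, meta_path: str | Path | None = None) -> None:
        self.frame.to_csv(csv_path, index_label="participant")
        if meta_path is not None:
            write_metadata(self.specs, meta_path, provenance=self.provenance)


def write_metadata(
    specs: Mapping[str, VariableSpec],
    path: str | Path,
    provenance: Iterable[str] = (),
) -> None:
    doc = {
        "variables": [
            {
                "name": s.name,
                "kind": s.kind,
                "role": s.role,
                "timeslot": s.timeslot,
                **({"levels": list(s.levels)} if s.levels else {}),
            }
            for s in specs.values()
        ],
        "provenance": list(provenance),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_metadata(path: str | Path) -> tuple[dict[str, VariableSpec], list[str]]:
    doc = json.loads(Path(path).read_text())
    specs = {
        v["name"]: VariableSpec(
            name=v["name"],
            kind=v["kind"],
            role=v["role"],
            timeslot=v.get("timeslot", STATIC),
            levels=tuple(v["levels"]) if v.get("levels") else None,
        )
        for v in doc["variables"]
    }
    return specs, list(doc.get("provenance", []))


def read_dataset(csv_path: str | Path, meta_path: str | Path) -> PanelDataset:
    specs, provenance = read_metadata(meta_path)
    frame = pd.read_csv(csv_path, index_col="participant")
    for name, spec in specs.items():
        if spec.is_discrete:
            col = frame[name]
            frame[name] = col.where(col.isna(), col.astype(str))
    frame = frame[list(specs)]
    return PanelDataset(frame, specs, provenance)
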
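"""Turn item- or concept-level tables into analysis-ready subgroup datasets.

Concept scores are the mean of the observed unipolar item scales, tolerating
at most 25% missing items per concept (inclusive at the boundary).  Subgroup
subsetting filters on one demographic moderator, removes that column from
the model, and keeps the remaining demographics as correction covariates.
Nothing here imputes: missingness is preserved for the structural-EM learner.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import PanelDataset, VariableSpec

MAX_MISSING_ITEMS = 0.25  # fraction of items per concept that may be missing


def aggregate_concept(
    items: Sequence[float | None],
    max_missing_fraction: float = MAX_MISSING_ITEMS,
) -> float:
    """Concept score: mean of observed items, or NaN above the missing cap.

    The cap is inclusive: exactly ``max_missing_fraction`` missing still
    yields a score.
    """
    if not (0.0 <= max_missing_fraction < 1.0):
        raise ValueError("max_missing_fraction must be in [0, 1)")
    vals = np.asarray(
        [np.nan if v is None else float(v) for v in items], dtype=float
    )
    if vals.size == 0:
        raise ValueError("empty item list")
    frac_missing = np.isnan(vals).sum() / vals.size
    if frac_missing > max_missing_fraction + 1e-12:
        return float("nan")
    return float(np.nanmean(vals))


_ITEM_RE = re.compile(r"^(?P<concept>.+)#(?P<k>\d+)$")


def aggregate_item_table(
    items: pd.DataFrame,
    max_missing_fraction: float = MAX_MISSING_ITEMS,
) -> pd.DataFrame:
    """Aggregate columns named ``<variable>#<k>`` into concept-score columns."""
    groups: dict[str, list[str]] = {}
    for col in items.columns:
        m = _ITEM_RE.match(col)
        if not m:
            raise ValueError(f"item column {col!r} is not of the form name#k")
        groups.setdefault(m.group("concept"), []).append(col)
    out = {}
    for concept, cols in groups.items():
        block = items[cols].to_numpy(dtype=float)
        n_items = block.shape[1]
        frac_missing = np.isnan(block).sum(axis=1) / n_items
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            means = np.nanmean(block, axis=1)
        means[frac_missing > max_missing_fraction + 1e-12] = np.nan
        out[concept] = means
    return pd.DataFrame(out, index=items.index)


@dataclass(frozen=True)
class LevelRule:
    """Predicate selecting one moderator level.

    Either a set of discrete levels (possibly merged, e.g. medium+high
    education) or a numeric threshold rule like "<65" / ">=65".
    """

    levels: frozenset[str] | None = None
    op: str | None = None  # "<", ">=", "<=", ">"
    threshold: float | None = None
    label: str = ""

    @staticmethod
    def from_string(rule: str) -> "LevelRule":
        rule = rule.strip()
        m = re.match(r"^(<=|>=|<|>)\s*([-0-9.]+)$", rule)
        if m:
            return LevelRule(op=m.group(1), threshold=float(m.group(2)), label=rule)
        levels = frozenset(s.strip() for s in rule.split(",") if s.strip())
        if not levels:
            raise ValueError(f"cannot parse level rule {rule!r}")
        return LevelRule(levels=levels, label=rule)

    def matches(self, col: pd.Series) -> pd.Series:
        if self.levels is not None:
            return col.astype(str).isin(self.levels) & col.notna()
        vals = pd.to_numeric(col, errors="coerce")
        ops: dict[str, Callable] = {
            "<": vals.lt,
            ">": vals.gt,
            "<=": vals.le,
            ">=": vals.ge,
        }
        return ops[self.op](self.threshold) & vals.notna()


def subset_subpopulation(
    dataset: PanelDataset,
    factor: str,
    rule: LevelRule | str,
) -> PanelDataset:
    """Rows matching the moderator rule, with the moderator column removed.

    Participants whose moderator value is missing match no level and are
    dropped from both complementary subsets; the remaining demographics
    (and gender) stay in the model as correction covariates.
    """
    if factor not in dataset.specs:
        raise KeyError(f"unknown factor {factor!r}")
    if dataset.specs[factor].role != "demographic":
        raise ValueError(f"{factor} is not a demographic moderator")
    if isinstance(rule, str):
        rule = LevelRule.from_string(rule)
    keep = rule.matches(dataset.frame[factor])
    if not keep.any():
        warnings.warn(f"subpopulation rule {rule.label!r} on {factor} matches no rows")
    frame = dataset.frame.loc[keep].drop(columns=[factor])
    specs = {n: s for n, s in dataset.specs.items() if n != factor}
    out = PanelDataset(frame.copy(), specs, list(dataset.provenance))
    out.log(f"subset {factor} {rule.label}: {int(keep.sum())}/{dataset.n} rows kept")
    return out


def drop_unobserved_variables(
    dataset: PanelDataset,
    min_observed: int = 30,
) -> tuple[PanelDataset, list[str]]:
    """Remove columns with fewer than ``min_observed`` observed cells.

    ``min_observed=1`` reproduces the literal rule of excluding only
    variables with no data at all; the default guards near-empty columns.
    """
    if min_observed < 1:
        raise ValueError("min_observed must be >= 1")
    counts = dataset.observed_counts()
    dropped = [c for c in dataset.variables if counts[c] < min_observed]
    keep = [c for c in dataset.variables if c not in dropped]
    frame = dataset.frame[keep].copy()
    specs = {n: dataset.specs[n] for n in keep}
    out = PanelDataset(frame, specs, list(dataset.provenance))
    if dropped:
        out.log(f"dropped unobserved (<{min_observed} obs): {', '.join(dropped)}")
    return out, dropped
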
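"""Population aggregation of access levels by race/ethnicity, urbanicity, region.

A block group's entire adult population inherits the block group's single
access level; stratified tables then sum population per (stratum, level)
cell.  For the race/ethnicity stratifier the rows are per-group adult
counts and are NOT expected to sum to the overall total: Hispanic is an
overlapping ethnicity (every racial group includes both Hispanic and
non-Hispanic members) and multiracial categories are not tabulated, so the
race rows are a non-additive accounting by design.

Percentages are count / row-total, kept at full precision internally and
rounded to one decimal only for display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catchment import BlockGroup
from .classification import LEVEL_ORDER, AccessLevel

__all__ = [
    "StratifiedTable",
    "aggregate",
    "state_summary_stats",
    "disparity_ratio",
    "STRATIFIERS",
]

STRATIFIERS = ("race", "urbanization", "region", "region_x_race")

LEVEL_COLUMNS = [lv.value for lv in LEVEL_ORDER]


@dataclass
class StratifiedTable:
    """Adult population counts per (stratum row, access level) cell.

    ``counts`` is indexed by stratum with one column per access level;
    the ``total`` column is the row's population.  ``percentages()``
    divides each level column by the row total (x100).
    """

    stratifier: str
    counts: pd.DataFrame  # columns: total + LEVEL_COLUMNS

    def percentages(self, decimals: int | None = None) -> pd.DataFrame:
        pct = self.counts[LEVEL_COLUMNS].div(self.counts["total"], axis=0) * 100.0
        if decimals is not None:
            pct = pct.round(decimals)
        return pct

    def row(self, label) -> pd.Series:
        return self.counts.loc[label]


def _accumulate(cells: dict, key, level: AccessLevel, population: int) -> None:
    row = cells.setdefault(key, {c: 0 for c in LEVEL_COLUMNS})
    row[level.value] += int(population)


def aggregate(
    block_groups: list[BlockGroup],
    levels: dict[str, AccessLevel],
    stratifier: str,
) -> StratifiedTable:
    """Stratified population table over classified, populated block groups.

    ``levels`` maps block-group id to its access level; every populated
    block group must be classified.  Each table carries a ``Total`` row
    (overall adult population), which for any stratifier equals the
    unstratified national aggregate.
    """
    if stratifier not in STRATIFIERS:
        raise ValueError(f"unknown stratifier {stratifier!r}; expected one of {STRATIFIERS}")

    cells: dict = {}
    for bg in block_groups:
        if not bg.populated:
            continue
        if bg.id not in levels:
            raise ValueError(f"populated block group {bg.id!r} has no access level")
        lv = levels[bg.id]
        _accumulate(cells, "Total", lv, bg.pop_total)
        if stratifier == "race":
            for group, n in bg.pop_by_group.items():
                _accumulate(cells, group, lv, n)
        elif stratifier == "urbanization":
            _accumulate(cells, bg.urbanization, lv, bg.pop_total)
        elif stratifier == "region":
            _accumulate(cells, bg.region_code, lv, bg.pop_total)
        else:  # region_x_race
            for group, n in bg.pop_by_group.items():
                _accumulate(cells, (bg.region_code, group), lv, n)

    if stratifier == "region_x_race":
        index = pd.MultiIndex.from_tuples(
            [k for k in cells if k != "Total"], names=["region", "group"]
        )
        df = pd.DataFrame([cells[k] for k in cells if k != "Total"], index=index)
        df = df.sort_index()
        total = pd.DataFrame([cells["Total"]], index=pd.MultiIndex.from_tuples([("Total", "")]))
        df = pd.concat([total, df])
    else:
        order = ["Total"] + sorted(str(k) for k in cells if k != "Total")
        df = pd.DataFrame([cells[k] for k in order], index=order)
    df["total"] = df[LEVEL_COLUMNS].sum(axis=1)
    df = df[["total"] + LEVEL_COLUMNS]
    return StratifiedTable(stratifier=stratifier, counts=df)


def state_summary_stats(per_region_percentages: pd.DataFrame) -> pd.DataFrame:
    """Order statistics of region-level access percentages, per level.

    Input: one row per region, one column per access level (percentages).
    Output: median, first and third quartile, min and max per level, using
    the linear-interpolation quartile convention.
    """
    if per_region_percentages.shape[0] < 1:
        raise ValueError("need at least one region")
    rows = {}
    for col in per_region_percentages.columns:
        v = per_region_percentages[col].to_numpy(dtype=float)
        rows[col] = {
            "median": float(np.median(v)),
            "q1": float(np.percentile(v, 25)),
            "q3": float(np.percentile(v, 75)),
            "min": float(np.min(v)),
            "max": float(np.max(v)),
        }
    return pd.DataFrame(rows).T


def disparity_ratio(
    table: StratifiedTable, group: str, reference: str = "Total"
) -> pd.Series:
    """Per-level ratio of a group's percentage to a reference row's.

    Levels where the reference percentage is zero are returned as NaN
    (undefined, not infinite).
    """
    pct = table.percentages()
    if group not in pct.index:
        raise KeyError(f"group {group!r} not in table")
    if reference not in pct.index:
        raise KeyError(f"reference {reference!r} not in table")
    g = pct.loc[group]
    ref = pct.loc[reference]
    out = g / ref.replace(0.0, np.nan)
    out.name = f"{group}/{reference}"
    return out
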
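"""GPS track processing: per-cell travel distances and cell-entry decisions.

Raw fixes (group, date, seconds-of-day, x, y in metres) become
  * per (group, day, cell) travel distances, with segments split exactly at
    cell boundaries by linear interpolation,
  * cell-entry decisions (which of the up-to-8 surrounding cells was
    entered), deduplicated within a day,
  * one first fix per group-day for home-range estimation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import EnergyField, Grid, cell_of

__all__ = [
    "EntryDecision",
    "distance_per_cell",
    "distance_per_cell_table",
    "extract_entry_decisions",
    "extract_entry_decisions_table",
    "first_fix_per_day",
    "read_fixes",
]

logger = logging.getLogger(__name__)

FIX_COLUMNS = ["group", "date", "time", "x", "y"]


def read_fixes(path) -> pd.DataFrame:
    """Read a fix CSV (columns group,date,time,x,y), sort, drop duplicate timestamps."""
    df = pd.read_csv(path, parse_dates=["date"])
    return prepare_fixes(df)


def prepare_fixes(df: pd.DataFrame) -> pd.DataFrame:
    """Sort fixes by (group, date, time); keep the first of identical timestamps."""
    missing = set(FIX_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"fix table missing columns: {sorted(missing)}")
    df = df.sort_values(["group", "date", "time"], kind="stable")
    dup = df.duplicated(subset=["group", "date", "time"])
    if dup.any():
        logger.warning("dropping %d fixes with duplicate timestamps", dup.sum())
        df = df[~dup]
    return df.reset_index(drop=True)


def _segment_pieces(x0, y0, x1, y1, grid: Grid):
    """Split segment (x0,y0)->(x1,y1) at grid lines; yield (cell, length).

    Crossing parameters with every vertical/horizontal grid line strictly
    between the endpoints are collected and each resulting piece is assigned
    to the cell containing its midpoint (robust for diagonal corner crossings).
    """
    dx, dy = x1 - x0, y1 - y0
    length = float(np.hypot(dx, dy))
    if length == 0.0:
        return [(cell_of(x0, y0, grid), 0.0)]
    ts = [0.0, 1.0]
    s = grid.cell_size
    for (p0, p1, origin) in ((x0, x1, grid.origin_x), (y0, y1, grid.origin_y)):
        lo, hi = min(p0, p1), max(p0, p1)
        k0 = int(np.ceil((lo - origin) / s))
        k1 = int(np.floor((hi - origin) / s))
        for k in range(k0, k1 + 1):
            line = origin + k * s
            if p1 != p0:
                t = (line - p0) / (p1 - p0)
                if 0.0 < t < 1.0:
                    ts.append(float(t))
    ts = sorted(set(ts))
    pieces = []
    for ta, tb in zip(ts[:-1], ts[1:]):
        tm = 0.5 * (ta + tb)
        cell = cell_of(x0 + tm * dx, y0 + tm * dy, grid)
        pieces.append((cell, (tb - ta) * length))
    return pieces


def distance_per_cell(fixes: pd.DataFrame, grid: Grid) -> pd.DataFrame:
    """Distance travelled per cell for one group-day of time-sorted fixes.

    Consecutive-fix segments are summed per cell; segments crossing a cell
    boundary are split at the boundary so each segment's pieces sum to its
    full length.  A single fix yields one zero-distance visit.

    Returns a DataFrame with columns group, date, cell_i, cell_j, distance_m.
    """
    if len(fixes) == 0:
        raise ValueError("need at least one fix")
    group = fixes["group"].iloc[0]
    date = fixes["date"].iloc[0]
    x = fixes["x"].to_numpy(float)
    y = fixes["y"].to_numpy(float)
    acc: dict[tuple[int, int], float] = {}
    if len(fixes) == 1:
        acc[cell_of(x[0], y[0], grid)] = 0.0
    for k in range(len(x) - 1):
        for cell, d in _segment_pieces(x[k], y[k], x[k + 1], y[k + 1], grid):
            acc[cell] = acc.get(cell, 0.0) + d
    rows = [
        {"group": group, "date": date, "cell_i": c[0], "cell_j": c[1],
         "distance_m": d}
        for c, d in sorted(acc.items())
    ]
    return pd.DataFrame(rows)


def distance_per_cell_table(fixes: pd.DataFrame, grid: Grid) -> pd.DataFrame:
    """:func:`distance_per_cell` applied to every (group, date) in a fix table."""
    parts = [
        distance_per_cell(day_fixes, grid)
        for _, day_fixes in fixes.groupby(["group", "date"], sort=True)
    ]
    return pd.concat(parts, ignore_index=True)


@dataclass(frozen=True)
class EntryDecision:
    """One decision to enter a surrounding grid cell.

    ``candidate_cells`` are the up-to-8 neighbours of ``origin_cell`` with
    food data; ``chosen_cell`` is the member actually entered.
    """

    group: object
    date: object
    origin_cell: tuple[int, int]
    chosen_cell: tuple[int, int]
    candidate_cells: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.chosen_cell == self.origin_cell:
            raise ValueError("chosen cell must differ from origin")
        if self.chosen_cell not in self.candidate_cells:
            raise ValueError("chosen cell must be a candidate")
        if not 1 <= len(self.candidate_cells) <= 8:
            raise ValueError("candidate count must be in 1..8")

    @property
    def is_corner_move(self) -> bool:
        di = self.chosen_cell[0] - self.origin_cell[0]
        dj = self.chosen_cell[1] - self.origin_cell[1]
        return di != 0 and dj != 0


def _cell_sequence(fixes: pd.DataFrame, grid: Grid,
                   drop_blips: bool = True) -> list[tuple[int, int]]:
    """Collapse per-fix cells into a sequence of distinct visited cells.

    With ``drop_blips`` (default), interior runs of a *single* fix are
    treated as GPS noise and removed when the flanking cells are identical
    (a jitter flip across a boundary) or mutually adjacent (one stray fix
    clipping a side cell while cutting a corner): a genuine pass through a
    500 m cell leaves many consecutive fixes at 30 s recording.
    """
    i, j = cell_of(fixes["x"].to_numpy(float), fixes["y"].to_numpy(float), grid)
    i = np.atleast_1d(i)
    j = np.atleast_1d(j)
    runs: list[list] = []  # [cell, n_fixes]
    for a, b in zip(i, j):
        c = (int(a), int(b))
        if runs and runs[-1][0] == c:
            runs[-1][1] += 1
        else:
            runs.append([c, 1])
    if drop_blips:
        changed = True
        while changed:
            changed = False
            for k in range(1, len(runs) - 1):
                cell, n = runs[k]
                prev_c, next_c = runs[k - 1][0], runs[k + 1][0]
                adjacent = (abs(prev_c[0] - next_c[0]) <= 1
                            and abs(prev_c[1] - next_c[1]) <= 1)
                if n == 1 and adjacent:
                    if prev_c == next_c:
                        runs[k - 1][1] += runs[k + 1][1]
                        del runs[k:k + 2]
                    else:
                        del runs[k]
                    changed = True
                    break
    return [c for c, _ in runs]


def extract_entry_decisions(
    fixes: pd.DataFrame,
    grid: Grid,
    energy_field: EnergyField,
    dedup: str = "origin_chosen",
    include_return_to_start: bool = True,
    drop_blips: bool = True,
) -> list[EntryDecision]:
    """Cell-entry decisions for one group-day.

    One decision per transition to a different cell.  Within a day, multiple
    entries into the same cell count as one decision: with
    ``dedup="origin_chosen"`` (default, the strict reading) the key is the
    (origin, chosen) pair; with ``dedup="chosen"`` any later transition into
    an already-chosen cell is dropped.  Transitions whose chosen cell lacks
    food data are dropped (logged); masked neighbours are excluded from the
    candidate set.
    """
    if dedup not in ("origin_chosen", "chosen"):
        raise ValueError("dedup must be 'origin_chosen' or 'chosen'")
    group = fixes["group"].iloc[0]
    date = fixes["date"].iloc[0]
    seq = _cell_sequence(fixes, grid, drop_blips=drop_blips)
    decisions: list[EntryDecision] = []
    seen: set = set()
    for origin, chosen in zip(seq[:-1], seq[1:]):
        key = (origin, chosen) if dedup == "origin_chosen" else chosen
        if key in seen:
            continue
        if not include_return_to_start and chosen == seq[0] and origin != seq[0]:
            continue
        candidates = tuple(
            c for c in grid.neighbours(*origin)
            if not energy_field.mask[c[0], c[1]]
        )
        if chosen not in candidates:
            if abs(chosen[0] - origin[0]) > 1 or abs(chosen[1] - origin[1]) > 1:
                logger.warning(
                    "non-adjacent transition %s -> %s (gap in fixes?); dropped",
                    origin, chosen)
            else:
                logger.info(
                    "chosen cell %s lacks food data; decision dropped", chosen)
            seen.add(key)
            continue
        seen.add(key)
        decisions.append(EntryDecision(group, date, origin, chosen, candidates))
    return decisions


def extract_entry_decisions_table(
    fixes: pd.DataFrame,
    grid: Grid,
    energy_field: EnergyField,
    **kwargs,
) -> list[EntryDecision]:
    """:func:`extract_entry_decisions` over every (group, date)."""
    out: list[EntryDecision] = []
    for _, day_fixes in fixes.groupby(["group", "date"], sort=True):
        out.extend(extract_entry_decisions(day_fixes, grid, energy_field, **kwargs))
    return out


def first_fix_per_day(fixes: pd.DataFrame) -> pd.DataFrame:
    """Earliest fix per (group, date) — the location sample for kernel ranges."""
    df = fixes.sort_values(["group", "date", "time"], kind="stable")
    return df.groupby(["group", "date"], as_index=False, sort=True).first()
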
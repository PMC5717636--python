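"""Composite previous-use statistic for grid cells.

For a group, a cell and a reference date, previous use sums over all visits
of that group to the cell strictly before the reference date:

    previous_use = sum_visits  group_size / days_elapsed * track_length_m

where ``group_size`` is the group's mean number of weaned individuals in the
visit's month, ``days_elapsed`` the calendar-day difference to the reference
date, and ``track_length_m`` the distance the group travelled in the cell on
the visit day.  Larger groups deplete more, elapsed time lets vegetation
regrow, and track length proxies how intensively the cell was used.

Visits are aggregated to one record per (group, cell, day) before the
formula, so days_elapsed is an integer >= 1; same-day earlier passes
contribute nothing.  Neighbour previous use is the same sum pooled over all
habituated groups other than the focal one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["UsageLedger", "apply_burn_in"]

logger = logging.getLogger(__name__)


def _day_number(dates) -> np.ndarray:
    """Calendar dates -> integer day numbers (days since epoch)."""
    arr = pd.to_datetime(pd.Series(np.atleast_1d(np.asarray(dates, dtype=object))))
    return (arr.values.astype("datetime64[D]")
            - np.datetime64("1970-01-01", "D")).astype(int)


def _day_scalar(ref_date) -> int:
    """One calendar date -> integer day number, without pandas overhead."""
    if isinstance(ref_date, (int, np.integer)):
        return int(ref_date)
    return int((np.datetime64(ref_date, "D")
                - np.datetime64("1970-01-01", "D")).astype(int))


@dataclass
class UsageLedger:
    """Dated per-cell visits and monthly group sizes for a set of groups.

    Parameters
    ----------
    visits : DataFrame with columns group, cell_i, cell_j, date, distance_m;
        aggregated internally to one row per (group, cell, day).
    group_sizes : DataFrame with columns group, year, month, size
        (mean weaned individuals); sizes must be positive.
    min_visit_distance_m : per-day track lengths below this are not counted
        as visits.  GPS jitter near cell boundaries produces spurious
        few-metre slivers in cells never actually entered; because the
        composite statistic divides by the (small) day gap, such slivers
        would otherwise masquerade as substantial recent use.
    """

    visits: pd.DataFrame
    group_sizes: pd.DataFrame
    min_visit_distance_m: float = 25.0
    _store: dict = field(default_factory=dict, repr=False)
    _sizes: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        v = self.visits.copy()
        if len(v):
            if (v["distance_m"] < 0).any():
                raise ValueError("distance_m must be >= 0")
            v["_day"] = _day_number(v["date"])
            v = (v.groupby(["group", "cell_i", "cell_j", "_day"], as_index=False)
                  ["distance_m"].sum())
            n_day_cells = v.groupby(["group", "_day"])["distance_m"] \
                .transform("size")
            # keep sub-threshold records only when they are a day's sole
            # visit (a stationary day is a genuine zero-distance visit)
            v = v[(v["distance_m"] >= self.min_visit_distance_m)
                  | (n_day_cells == 1)].reset_index(drop=True)
        else:
            v = pd.DataFrame(columns=["group", "cell_i", "cell_j", "_day",
                                      "distance_m"])
        self.visits = v
        gs = self.group_sizes
        if len(gs) and (gs["size"] <= 0).any():
            raise ValueError("group sizes must be > 0")
        self._sizes = {
            (r.group, int(r.year), int(r.month)): float(r.size_)
            for r in gs.rename(columns={"size": "size_"}).itertuples()
        }
        self._month_cache: dict = {}
        self._rebuild_store()

    def _rebuild_store(self) -> None:
        # per (group, cell): sorted day numbers, distances, and the group
        # size at each visit's month, resolved once so the composite
        # statistic is pure array arithmetic
        self._store = {}
        self._first_day = int(self.visits["_day"].min()) \
            if len(self.visits) else None
        self._group_list = sorted({g for g, _, _ in self._sizes} |
                                  set(self.visits["group"].unique()))
        for (g, ci, cj), rows in self.visits.groupby(["group", "cell_i", "cell_j"]):
            days = rows["_day"].to_numpy(int)
            order = np.argsort(days)
            days = days[order]
            sizes = np.array([self.group_size(g, d) for d in days])
            self._store[(g, (int(ci), int(cj)))] = (
                days, rows["distance_m"].to_numpy(float)[order], sizes)

    # -- group sizes ------------------------------------------------------
    def group_size(self, group, day: int) -> float:
        """Mean weaned group size for the month containing integer day."""
        # months since epoch, avoiding per-call Timestamp construction
        midx = int((np.datetime64("1970-01-01", "D") + int(day))
                   .astype("datetime64[M]").astype(int))
        key = (group, midx)
        cached = self._month_cache.get(key)
        if cached is not None:
            return cached
        y, m = 1970 + midx // 12, midx % 12 + 1
        if (group, y, m) in self._sizes:
            s = self._sizes[(group, y, m)]
        else:
            # fall back to the group's nearest recorded month
            months = [((yy - 1970) * 12 + mm - 1, s)
                      for (g, yy, mm), s in self._sizes.items() if g == group]
            if not months:
                raise KeyError(f"no group sizes recorded for group {group!r}")
            _, s = min(months, key=lambda t: abs(t[0] - midx))
        self._month_cache[key] = s
        return s

    @property
    def groups(self) -> list:
        return sorted(self.visits["group"].unique())

    @property
    def first_day(self) -> int | None:
        return self._first_day

    # -- incremental update (used by the movement simulator) ---------------
    def record_visit(self, group, cell, day: int, distance_m: float) -> None:
        """Append (or extend) a single per-day visit without a full rebuild."""
        key = (group, (int(cell[0]), int(cell[1])))
        days, dists, sizes = self._store.get(
            key, (np.empty(0, int), np.empty(0), np.empty(0)))
        if days.size and days[-1] == day:
            dists = dists.copy()
            dists[-1] += distance_m
        else:
            days = np.append(days, day)
            dists = np.append(dists, distance_m)
            sizes = np.append(sizes, self.group_size(group, day))
        self._store[key] = (days, dists, sizes)
        if self._first_day is None or day < self._first_day:
            self._first_day = day
        if group not in self._group_list:
            self._group_list.append(group)

    # -- the composite statistic ------------------------------------------
    def previous_use(self, group, cell, ref_date) -> float:
        """Previous use of ``cell`` by ``group`` strictly before ``ref_date``."""
        day = _day_scalar(ref_date)
        if self._first_day is not None and day < self._first_day:
            warnings.warn("reference date precedes all ledger data; value 0")
        key = (group, (int(cell[0]), int(cell[1])))
        if key not in self._store:
            return 0.0
        days, dists, sizes = self._store[key]
        k = int(np.searchsorted(days, day))  # visits strictly before ref day
        if k == 0:
            return 0.0
        return float(np.sum(sizes[:k] / (day - days[:k]) * dists[:k]))

    def neighbour_previous_use(self, focal_group, cell, ref_date) -> float:
        """Previous use of ``cell`` by all groups other than ``focal_group``."""
        return float(sum(self.previous_use(g, cell, ref_date)
                         for g in self._group_list if g != focal_group))

    # -- IO ----------------------------------------------------------------
    def to_csv(self, visits_path, sizes_path) -> None:
        out = self.visits.copy()
        out["date"] = (pd.Timestamp("1970-01-01")
                       + pd.to_timedelta(out.pop("_day"), unit="D")).dt.date
        out.to_csv(visits_path, index=False)
        self.group_sizes.to_csv(sizes_path, index=False)

    @classmethod
    def from_csv(cls, visits_path, sizes_path) -> "UsageLedger":
        visits = pd.read_csv(visits_path, parse_dates=["date"])
        sizes = pd.read_csv(sizes_path)
        return cls(visits, sizes)

    @classmethod
    def from_cell_visits(cls, cell_visits: pd.DataFrame,
                         group_sizes: pd.DataFrame) -> "UsageLedger":
        """Build from the distance-per-cell table produced by track processing."""
        return cls(cell_visits[["group", "date", "cell_i", "cell_j",
                                "distance_m"]].copy(), group_sizes)


def apply_burn_in(records: pd.DataFrame, burn_in_date,
                  date_column: str = "date") -> pd.DataFrame:
    """Drop analysis rows dated before the burn-in cut-off.

    The usage ledger is *not* filtered — pre-burn-in visits remain available
    as history; only the rows entering a model are restricted, giving the
    previous-use predictors time to accumulate.
    """
    cut = _day_number(burn_in_date)[0]
    days = _day_number(records[date_column])
    kept = records[days >= cut]
    if len(kept) == 0:
        raise ValueError("burn-in date is after the last record; nothing left")
    n_dropped = len(records) - len(kept)
    logger.info("burn-in: dropped %d of %d rows", n_dropped, len(records))
    return kept.reset_index(drop=True)
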
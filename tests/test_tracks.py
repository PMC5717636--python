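import numpy as np
import pandas as pd
import pytest

from gorillaspace import (
    distance_per_cell,
    distance_per_cell_table,
    extract_entry_decisions,
    first_fix_per_day,
)
from gorillaspace.tracks import prepare_fixes

from conftest import make_fixes


class TestDistancePerCell:
    def test_within_one_cell(self, grid):
        out = distance_per_cell(make_fixes([(100, 250), (400, 250)]), grid)
        assert len(out) == 1
        assert out.iloc[0][["cell_i", "cell_j"]].tolist() == [0, 0]
        assert out.iloc[0]["distance_m"] == pytest.approx(300.0)

    def test_split_at_boundary(self, grid):
        out = distance_per_cell(make_fixes([(400, 250), (600, 250)]), grid)
        d = {(r.cell_i, r.cell_j): r.distance_m for r in out.itertuples()}
        assert d[(0, 0)] == pytest.approx(100.0)
        assert d[(1, 0)] == pytest.approx(100.0)

    def test_single_fix_zero_distance(self, grid):
        out = distance_per_cell(make_fixes([(100, 100)]), grid)
        assert len(out) == 1 and out.iloc[0]["distance_m"] == 0.0

    def test_diagonal_corner_crossing(self, grid):
        # straight through the four-corner point: split halves on the diagonal
        out = distance_per_cell(make_fixes([(400, 400), (600, 600)]), grid)
        d = {(r.cell_i, r.cell_j): r.distance_m for r in out.itertuples()}
        total = 200 * np.sqrt(2)
        assert sum(d.values()) == pytest.approx(total)
        assert d[(0, 0)] == pytest.approx(total / 2)
        assert d[(1, 1)] == pytest.approx(total / 2)

    def test_pieces_sum_to_polyline_length(self, grid):
        rng = np.random.default_rng(7)
        pts = np.column_stack([rng.uniform(10, 1990, 50),
                               rng.uniform(10, 1990, 50)])
        out = distance_per_cell(make_fixes(pts.tolist()), grid)
        polyline = np.hypot(*np.diff(pts, axis=0).T).sum()
        assert out["distance_m"].sum() == pytest.approx(polyline, abs=1e-6)

    def test_duplicate_timestamps_dropped(self, grid):
        fixes = make_fixes([(100, 100), (200, 200), (300, 300)])
        fixes.loc[1, "time"] = fixes.loc[0, "time"]
        cleaned = prepare_fixes(fixes)
        assert len(cleaned) == 2


class TestEntryDecisions:
    def test_no_transition_no_decision(self, grid, uniform_field):
        fixes = make_fixes([(100, 100), (200, 200), (300, 100)])
        assert extract_entry_decisions(fixes, grid, uniform_field) == []

    def test_back_and_forth_deduplicated(self, grid, uniform_field):
        # A -> B -> A -> B within a day: the second A->B is one decision
        pts = [(250, 250)] * 3 + [(750, 250)] * 3 + [(250, 250)] * 3 \
            + [(750, 250)] * 3
        decs = extract_entry_decisions(make_fixes(pts), grid, uniform_field)
        moves = [(d.origin_cell, d.chosen_cell) for d in decs]
        assert moves == [((0, 0), (1, 0)), ((1, 0), (0, 0))]

    def test_dedup_by_chosen_cell_only(self, grid, uniform_field):
        pts = [(250, 250)] * 3 + [(750, 250)] * 3 + [(250, 250)] * 3 \
            + [(750, 250)] * 3
        decs = extract_entry_decisions(make_fixes(pts), grid, uniform_field,
                                       dedup="chosen")
        moves = [(d.origin_cell, d.chosen_cell) for d in decs]
        assert moves == [((0, 0), (1, 0)), ((1, 0), (0, 0))]
        # a third cell is still a fresh decision under chosen-dedup
        pts2 = pts + [(1250, 250)] * 3
        decs2 = extract_entry_decisions(make_fixes(pts2), grid, uniform_field,
                                        dedup="chosen")
        assert len(decs2) == 3

    def test_exclude_return_to_start_flag(self, grid, uniform_field):
        pts = [(250, 250)] * 3 + [(750, 250)] * 3 + [(250, 250)] * 3
        decs = extract_entry_decisions(make_fixes(pts), grid, uniform_field,
                                       include_return_to_start=False)
        assert [(d.origin_cell, d.chosen_cell) for d in decs] == \
            [((0, 0), (1, 0))]

    def test_corner_origin_has_three_candidates(self, grid, uniform_field):
        pts = [(250, 250)] * 3 + [(750, 250)] * 3
        decs = extract_entry_decisions(make_fixes(pts), grid, uniform_field)
        assert len(decs[0].candidate_cells) == 3  # grid corner

    def test_masked_neighbours_shrink_candidate_set(self, grid, patchy_field):
        # origin (2,2): 8 in-grid neighbours, one of them (3,3) masked
        pts = [(1250, 1250)] * 3 + [(1750, 1250)] * 3
        decs = extract_entry_decisions(make_fixes(pts), grid, patchy_field)
        assert len(decs) == 1
        assert len(decs[0].candidate_cells) == 7
        assert (3, 3) not in decs[0].candidate_cells

    def test_decision_whose_chosen_cell_is_masked_is_dropped(
            self, grid, patchy_field):
        pts = [(1250, 1250)] * 3 + [(1750, 1750)] * 3  # into masked (3,3)
        decs = extract_entry_decisions(make_fixes(pts), grid, patchy_field)
        assert decs == []

    def test_single_fix_blips_are_filtered(self, grid, uniform_field):
        # one stray fix in (1,0) inside a long stay in (0,0): GPS noise
        pts = [(250, 250)] * 5 + [(510, 250)] + [(250, 250)] * 5
        decs = extract_entry_decisions(make_fixes(pts), grid, uniform_field)
        assert decs == []
        decs_raw = extract_entry_decisions(make_fixes(pts), grid,
                                           uniform_field, drop_blips=False)
        assert len(decs_raw) == 2

    def test_decisions_bounded_by_transitions(self, grid, uniform_field):
        rng = np.random.default_rng(11)
        pts = np.column_stack([rng.uniform(10, 1990, 60),
                               rng.uniform(10, 1990, 60)])
        fixes = make_fixes(pts.tolist())
        decs = extract_entry_decisions(fixes, grid, uniform_field,
                                       drop_blips=False)
        i, j = (pts[:, 0] // 500).astype(int), (pts[:, 1] // 500).astype(int)
        transitions = np.sum((np.diff(i) != 0) | (np.diff(j) != 0))
        assert len(decs) <= transitions


class TestFirstFixPerDay:
    def test_earliest_fix_wins(self):
        fixes = make_fixes([(1, 1), (2, 2), (3, 3)])
        fixes["time"] = [10 * 3600, 8 * 3600, 9 * 3600]
        first = first_fix_per_day(fixes)
        assert len(first) == 1
        assert first.iloc[0]["x"] == 2  # the 08:00 fix

    def test_one_point_per_group_day(self):
        a = make_fixes([(1, 1), (2, 2)], date="2012-10-01")
        b = make_fixes([(3, 3)], date="2012-10-02")
        first = first_fix_per_day(pd.concat([a, b]))
        assert len(first) == 2


def test_distance_table_covers_all_group_days(small_sim):
    grid = small_sim.config.grid
    visits = distance_per_cell_table(small_sim.fixes, grid)
    n_group_days = small_sim.fixes.groupby(["group", "date"]).ngroups
    assert visits.groupby(["group", "date"]).ngroups == n_group_days
    assert (visits["distance_m"] >= 0).all()
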
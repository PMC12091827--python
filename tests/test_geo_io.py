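"""Grid/occurrence/tree I/O, validation, thinning, variable exclusion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import max_independent_set_size

from barniche.errors import EmptySpeciesError, FormatError
from barniche.geo_io import (
    EnvGrid,
    OccurrenceSet,
    VariableSet,
    dedup_per_cell,
    exclude_interactive_variables,
    haversine_km,
    read_env_grid,
    read_newick,
    read_occurrences,
    thin_occurrences,
    validate_occurrences,
    write_env_grid,
    write_newick,
    write_occurrences,
)
from barniche.synthetic_data import simulate_env_grid, simulate_yule_tree


class TestAsciiGrid:
    def test_round_trip_bit_exact(self, small_grid, tmp_path):
        p = tmp_path / "g.asc"
        write_env_grid(small_grid, p)
        back = read_env_grid(p, variable="temperature")
        np.testing.assert_array_equal(
            back.values[~back.nodata_mask], small_grid.values[~small_grid.nodata_mask]
        )
        np.testing.assert_array_equal(back.nodata_mask, small_grid.nodata_mask)
        assert back.xllcorner == small_grid.xllcorner
        assert back.yllcorner == small_grid.yllcorner
        assert back.cell_size == small_grid.cell_size

    def test_round_trip_synthetic_noise_grid(self, tmp_path):
        g = simulate_env_grid(17, 23, ("we", -3.0, 11.0), 0.8, seed=9)
        p = tmp_path / "g.asc"
        write_env_grid(g, p)
        back = read_env_grid(p)
        np.testing.assert_array_equal(back.values, g.values)

    def test_nodata_value_masks_cell(self, tmp_path):
        p = tmp_path / "g.asc"
        p.write_text(
            "ncols 2\nnrows 2\nxllcorner 0\nyllcorner 0\ncellsize 1\n"
            "NODATA_value -9999\n1 -9999\n3 4\n"
        )
        g = read_env_grid(p)
        assert g.nodata_mask[0, 1]
        assert np.isnan(g.values[0, 1])
        assert g.values[1, 0] == 3.0

    def test_cell_centers_at_arcmin_resolution(self, tmp_path):
        cs = 0.0416667  # ~2.5 arcmin
        g = EnvGrid("t", np.zeros((2, 2)), np.zeros((2, 2), bool), -60.0, -30.0, cs)
        # hand-computed centers: origin + cellsize*(i + 0.5)
        lon, lat = g.cell_center(1, 0)  # bottom-left cell
        assert lon == pytest.approx(-60.0 + cs * 0.5)
        assert lat == pytest.approx(-30.0 + cs * 0.5)
        lon, lat = g.cell_center(0, 1)  # top-right cell
        assert lon == pytest.approx(-60.0 + cs * 1.5)
        assert lat == pytest.approx(-30.0 + cs * 1.5)

    def test_incomplete_header_reports_line(self, tmp_path):
        p = tmp_path / "bad.asc"
        p.write_text("ncols 2\nnrows 2\n1 2\n3 4\n")
        with pytest.raises(FormatError, match="line 3"):
            read_env_grid(p)

    def test_row_count_mismatch_rejected(self, tmp_path):
        p = tmp_path / "bad.asc"
        p.write_text(
            "ncols 2\nnrows 3\nxllcorner 0\nyllcorner 0\ncellsize 1\n"
            "NODATA_value -9999\n1 2\n3 4\n"
        )
        with pytest.raises(FormatError):
            read_env_grid(p)

    def test_point_on_top_right_boundary_maps_to_last_cell(self, small_grid):
        xmin, ymin, xmax, ymax = small_grid.extent
        assert small_grid.cell_of(xmax, ymax) == (0, small_grid.n_cols - 1)


class TestOccurrenceValidation:
    def test_nodata_and_out_of_extent_dropped_with_reason(self, small_grid):
        lon_bad, lat_bad = small_grid.cell_center(4, 3)  # the nodata cell
        lon_ok, lat_ok = small_grid.cell_center(0, 0)
        occ = OccurrenceSet(
            "sp", [(lon_ok, lat_ok), (lon_bad, lat_bad), (999.0, 0.0)]
        )
        report = []
        out = validate_occurrences(occ, small_grid, report=report)
        assert len(out) == 1
        reasons = {r[2] for r in report}
        assert reasons == {"nodata", "out-of-extent"}

    def test_mixed_valid_invalid_counts(self, small_grid):
        good = [small_grid.cell_center(r, 0) for r in range(5)]
        bad = [(999.0, 0.0), small_grid.cell_center(4, 3)]
        out = validate_occurrences(OccurrenceSet("sp", good + bad), small_grid)
        assert len(out) == 5

    def test_all_dropped_raises(self, small_grid):
        with pytest.raises(EmptySpeciesError):
            validate_occurrences(OccurrenceSet("sp", [(999.0, 0.0)]), small_grid)

    def test_csv_round_trip(self, tmp_path, small_grid):
        occs = [
            OccurrenceSet("a", [small_grid.cell_center(0, 0)], ["x"]),
            OccurrenceSet("b", [small_grid.cell_center(1, 1), small_grid.cell_center(2, 2)]),
        ]
        p = tmp_path / "occ.csv"
        write_occurrences(occs, p)
        back = read_occurrences(p)
        assert set(back) == {"a", "b"}
        assert back["b"].points == [
            pytest.approx(small_grid.cell_center(1, 1)),
            pytest.approx(small_grid.cell_center(2, 2)),
        ]

    def test_dedup_per_cell_keeps_first(self, small_grid):
        lon, lat = small_grid.cell_center(2, 2)
        occ = OccurrenceSet("sp", [(lon, lat), (lon + 0.01, lat), (lon, lat + 0.4)])
        out = dedup_per_cell(occ, small_grid)
        assert len(out) == 2
        assert out.points[0] == (lon, lat)


def _line_points(n, spacing_km=1.0, lat=0.0):
    # spacing in km along the equator: 1 deg lon ~ 111.19 km
    deg = spacing_km / (math.pi / 180.0 * 6371.0088)
    return [(i * deg, lat) for i in range(n)]


class TestThinning:
    def test_single_point_passes_through(self):
        occ = OccurrenceSet("sp", [(0.0, 0.0)])
        assert thin_occurrences(occ).points == [(0.0, 0.0)]

    def test_two_close_points_keep_one(self):
        pts = _line_points(2, spacing_km=3.0)
        out = thin_occurrences(OccurrenceSet("sp", pts), 5.2)
        assert len(out) == 1

    def test_line_of_points_matches_brute_force(self):
        pts = _line_points(10, spacing_km=1.0)
        out = thin_occurrences(OccurrenceSet("sp", pts), 5.2)
        expected = max_independent_set_size(pts, 5.2, haversine_km)
        assert len(out) == expected

    def test_retained_points_subset_of_input(self):
        rng = np.random.default_rng(0)
        pts = [tuple(p) for p in rng.uniform(0, 0.15, size=(20, 2))]
        out = thin_occurrences(OccurrenceSet("sp", pts), 5.2)
        assert set(out.points) <= set(pts)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        pts = [tuple(p) for p in rng.uniform(0, 0.15, size=(25, 2))]
        once = thin_occurrences(OccurrenceSet("sp", pts), 5.2)
        twice = thin_occurrences(once, 5.2)
        assert once.points == twice.points

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(
        st.tuples(st.floats(-0.2, 0.2), st.floats(-0.2, 0.2)),
        min_size=1, max_size=18, unique=True,
    ))
    def test_pairwise_constraint_always_satisfied(self, pts):
        out = thin_occurrences(OccurrenceSet("sp", pts), 5.2)
        for i in range(len(out.points)):
            for j in range(i + 1, len(out.points)):
                assert haversine_km(out.points[i], out.points[j]) >= 5.2


class TestVariableExclusion:
    def test_nineteen_bioclim_variables(self):
        vs = VariableSet([f"bio{i}" for i in range(1, 20)])
        out = exclude_interactive_variables(vs)
        assert len(out.names) == 15
        assert set(out.excluded) == {"bio8", "bio9", "bio18", "bio19"}

    def test_clean_pair_untouched(self):
        out = exclude_interactive_variables(VariableSet(["bio1", "bio12"]))
        assert out.names == ["bio1", "bio12"]
        assert out.excluded == []

    def test_empty_set(self):
        out = exclude_interactive_variables(VariableSet([]))
        assert out.names == [] and out.excluded == []


class TestNewick:
    def test_hand_computable_ages(self, three_tip_tree):
        t = three_tip_tree
        assert t.depth == pytest.approx(2.0)
        internal_ages = sorted(t.nodes[i].age for i in t.internal_ids())
        assert internal_ages == [pytest.approx(1.0), pytest.approx(2.0)]
        assert all(t.nodes[i].age == pytest.approx(0.0) for i in t.tips())

    def test_round_trip_synthetic_yule(self, tmp_path):
        t = simulate_yule_tree(12, 6.12, seed=5)
        p = tmp_path / "t.nwk"
        write_newick(t, p)
        back = read_newick(p)
        assert back.tip_labels() == t.tip_labels()
        assert back.depth == pytest.approx(t.depth, abs=1e-9)
        for a, b in zip(t.postorder(), back.postorder()):
            assert t.nodes[a].length == pytest.approx(back.nodes[b].length, abs=1e-9)

    def test_forty_tips_have_39_internal_nodes_postorder(self):
        t = simulate_yule_tree(40, 6.12, seed=2)
        internals = t.internal_ids()
        assert len(internals) == 39
        # stable postorder: children before parents
        seen = set()
        for nid in t.postorder():
            for c in t.nodes[nid].children:
                assert c in seen
            seen.add(nid)

    def test_unlabeled_tip_rejected(self, tmp_path):
        p = tmp_path / "bad.nwk"
        p.write_text("((:1,B:1):1,C:2);\n")
        with pytest.raises(FormatError):
            read_newick(p)

    def test_non_ultrametric_warns(self):
        from barniche.trees import DatedTree

        with pytest.warns(UserWarning, match="ultrametric"):
            DatedTree.from_newick("((A:1,B:3):1,C:2);")
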
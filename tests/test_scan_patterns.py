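"""Scan-pattern generation: visit order, timing, coverage, fluence arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from leapscan import (
    FluenceSpec,
    compute_fluence,
    export_pattern_text,
    import_pattern_text,
    make_interleaved_pattern,
    make_raster_pattern,
    min_neighbour_interval,
    validate_pattern,
)
from leapscan.scan_patterns import ScanPattern, VisitBlock


class TestRasterTiming:
    def test_x_neighbour_interval_is_dwell(self):
        p = make_raster_pattern(7, 7, dwell_ns=100, reps=1, integration="frame")
        v = p.visits
        # consecutive x positions one dwell time apart
        assert v[1, 2] - v[0, 2] == 100
        assert min_neighbour_interval(p, 1) == 100

    def test_y_neighbour_interval_is_line_time(self):
        p = make_raster_pattern(7, 7, dwell_ns=100, reps=1, integration="frame")
        v = p.visits
        same_col = v[(v[:, 0] == 2)]
        assert np.all(np.diff(same_col[:, 2]) == 7 * 100)

    def test_line_integration_repeats_each_line_with_flyback(self):
        p = make_raster_pattern(2, 1, dwell_ns=100, reps=3, integration="line",
                                flyback_delay_ns=70_000)
        v = p.visits
        assert len(v) == 6
        # each line pass starts after the settling delay
        starts = v[::2, 2]
        assert starts[0] == 70_000
        assert np.all(np.diff(starts) == 70_000 + 200)

    def test_frame_mode_rejects_flyback_delay(self):
        with pytest.raises(ValueError):
            make_raster_pattern(4, 4, 100, 2, "frame", flyback_delay_ns=100)

    def test_bad_integration_token(self):
        with pytest.raises(ValueError):
            make_raster_pattern(4, 4, 100, 1, "lines")


class TestInterleaved:
    def test_fig_style_first_visits(self):
        p = make_interleaved_pattern(7, 7, 2, 2, 100, 1)
        first = p.visits[:4, :2].tolist()
        assert first == [[0, 0], [3, 0], [6, 0], [0, 3]]

    def test_every_pixel_visited_once(self):
        p = make_interleaved_pattern(9, 9, 2, 2, 100, 1)
        v = p.visits
        assert len(v) == 81
        flat = v[:, 1] * 9 + v[:, 0]
        assert np.array_equal(np.sort(flat), np.arange(81))

    def test_skip_zero_degenerates_to_raster(self):
        r = make_raster_pattern(6, 5, 100, 2, "frame")
        i = make_interleaved_pattern(6, 5, 0, 0, 100, 2)
        assert np.array_equal(r.visits, i.visits)

    def test_consecutive_visits_one_dwell_apart(self):
        p = make_interleaved_pattern(8, 8, 2, 2, 50, 1)
        assert np.all(np.diff(p.visits[:, 2]) == 50)

    def test_skip_too_large(self):
        with pytest.raises(ValueError):
            make_interleaved_pattern(4, 4, 4, 2)

    @pytest.mark.parametrize("nx,ny,skip", [(16, 16, 1), (16, 12, 2), (33, 17, 3),
                                            (64, 64, 4), (9, 9, 2)])
    def test_permutation_property(self, nx, ny, skip):
        """Every repetition visits the full grid exactly once."""
        p = make_interleaved_pattern(nx, ny, skip, skip, 100, 2)
        v = p.visits
        assert len(v) == 2 * nx * ny
        for rep in range(2):
            chunk = v[rep * nx * ny:(rep + 1) * nx * ny]
            flat = chunk[:, 1] * nx + chunk[:, 0]
            assert np.array_equal(np.sort(flat), np.arange(nx * ny))

    @given(nx=st.integers(4, 32), ny=st.integers(4, 32), skip=st.integers(0, 3))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_permutation_property_hypothesis(self, nx, ny, skip):
        if skip >= nx or skip >= ny:
            return
        p = make_interleaved_pattern(nx, ny, skip, skip, 100, 1)
        flat = p.visits[:, 1] * nx + p.visits[:, 0]
        assert np.array_equal(np.sort(flat), np.arange(nx * ny))


class TestMinNeighbourInterval:
    @pytest.mark.parametrize("n", [8, 16, 32])
    def test_interleaving_stretches_neighbour_interval(self, n):
        r = make_raster_pattern(n, n, 100, 1, "frame")
        i = make_interleaved_pattern(n, n, 2, 2, 100, 1)
        assert min_neighbour_interval(i, 1) > min_neighbour_interval(r, 1)

    def test_single_pixel_grid_errors(self):
        p = make_raster_pattern(1, 1, 100)
        with pytest.raises(ValueError):
            min_neighbour_interval(p, 1)

    def test_radius_exceeding_grid_errors(self):
        p = make_raster_pattern(4, 4, 100)
        with pytest.raises(ValueError):
            min_neighbour_interval(p, 5)


class TestValidation:
    def test_valid_raster_empty_report(self):
        rep = validate_pattern(make_raster_pattern(7, 7, 100))
        assert rep.ok and rep.n_findings == 0

    def test_interleaved_bulk_count(self):
        p = make_interleaved_pattern(16, 16, 2, 2, 100, 10)
        assert p.n_visits == 2560
        assert validate_pattern(p).ok

    def test_duplicate_visit_reported(self):
        p = make_raster_pattern(4, 4, 100)
        v = p.visits.copy()
        v[5, :2] = v[4, :2]  # overwrite (1,1) with a duplicate of (0,1)
        rep = validate_pattern(p, visits=v)
        assert not rep.ok
        assert (0, (1, 1)) in rep.missing_pixels
        assert (0, (0, 1)) in rep.duplicate_pixels

    def test_nonmonotone_timestamp_reported(self):
        p = make_raster_pattern(4, 4, 100)
        v = p.visits.copy()
        v[7, 2] = v[6, 2]
        rep = validate_pattern(p, visits=v)
        assert rep.timestamp_violations


class TestExportImport:
    def test_two_by_two_layout(self, tmp_path):
        p = make_raster_pattern(2, 2, 100)
        dest = export_pattern_text(p, tmp_path / "p.txt", header=False)
        assert dest.read_text().splitlines() == ["0 0", "1 0", "0 1", "1 1"]

    def test_round_trip_preserves_order(self, tmp_path):
        p = make_interleaved_pattern(16, 16, 2, 2, 100, 3)
        dest = export_pattern_text(p, tmp_path / "p.txt")
        q = import_pattern_text(dest)
        assert np.array_equal(q.visits[:, :2], p.frame_visit_order())
        assert q.reps == 3 and q.mode == "interleaved"

    def test_malformed_line_names_location(self, tmp_path):
        f = tmp_path / "bad.txt"
        f.write_text("0 0\na b\n")
        with pytest.raises(ValueError, match=":2"):
            import_pattern_text(f)

    def test_out_of_bounds_rejected(self, tmp_path):
        f = tmp_path / "oob.txt"
        f.write_text("0 0\n9 0\n")
        with pytest.raises(ValueError, match="out of bounds"):
            import_pattern_text(f, metadata={"nx": 4, "ny": 4})


class TestFluence:
    def test_paper_conditions_one_tenth_electron_per_A2(self):
        val = compute_fluence(FluenceSpec(6.3, 100, 100, 6.34))
        assert val == pytest.approx(0.098, abs=0.001)
        assert round(val, 1) == 0.1

    def test_matched_schedules_identical(self):
        vals = [compute_fluence(FluenceSpec(6.3, d, r, 6.34))
                for d, r in [(100, 100), (500, 20), (1000, 10)]]
        assert vals[0] == vals[1] == vals[2]

    def test_zero_current(self):
        assert compute_fluence(FluenceSpec(0.0, 100, 100, 6.34)) == 0.0

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            FluenceSpec(6.3, 0, 100, 6.34)
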
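"""Profile data model, file dialect handling and grid alignment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sedflux import (
    SoluteProfile,
    align_to_grid,
    check_taxon_totals,
    load_taxon_table,
    read_profile,
    write_profile,
)
from sedflux.profiles import ProfileParseError, read_summary, write_summary


def _write(tmp_path, text, name="prof.txt"):
    f = tmp_path / name
    f.write_text(text)
    return f


class TestReadProfile:
    def test_depth_unit_micrometres_normalised_to_mm(self, tmp_path):
        f = _write(tmp_path, "-500 310\n0 305\n100 250\n200 120\n300 0\n")
        p = read_profile(f, solute="O2", depth_unit="um")
        assert np.allclose(p.depths, [-0.5, 0.0, 0.1, 0.2, 0.3])
        assert np.allclose(p.values, [310, 305, 250, 120, 0])

    def test_mm_dialect_with_header_equals_um_variant(self, tmp_path):
        f_um = _write(tmp_path, "-500 310\n0 305\n100 250\n200 120\n300 0\n", "a.txt")
        f_mm = _write(
            tmp_path, "depth value\n-0.5 310\n0 305\n0.1 250\n0.2 120\n0.3 0\n", "b.txt"
        )
        p_um = read_profile(f_um, solute="O2", depth_unit="um")
        p_mm = read_profile(f_mm, solute="O2", depth_unit="mm")
        assert np.allclose(p_um.depths, p_mm.depths)
        assert np.allclose(p_um.values, p_mm.values)

    def test_empty_file_is_hard_error(self, tmp_path):
        with pytest.raises(ProfileParseError):
            read_profile(_write(tmp_path, ""), solute="O2")

    def test_garbage_row_error_names_line(self, tmp_path):
        f = _write(tmp_path, "0 300\n0.1 250\nbroken row here\n0.3 10\n")
        with pytest.raises(ProfileParseError, match=":3"):
            read_profile(f, solute="O2")

    def test_duplicate_depths_collapsed_by_mean(self, tmp_path):
        f = _write(tmp_path, "0 300\n0.1 200\n0.1 100\n0.2 50\n")
        p = read_profile(f, solute="O2")
        assert np.allclose(p.depths, [0.0, 0.1, 0.2])
        assert np.allclose(p.values, [300.0, 150.0, 50.0])

    def test_unsorted_rows_are_sorted(self, tmp_path):
        f = _write(tmp_path, "0.2 100\n0 300\n0.1 200\n")
        p = read_profile(f, solute="O2")
        assert np.all(np.diff(p.depths) > 0)
        assert np.allclose(p.values, [300, 200, 100])

    def test_fewer_than_three_points_is_error(self, tmp_path):
        with pytest.raises(ProfileParseError, match="fewer than 3"):
            read_profile(_write(tmp_path, "0 300\n0.1 200\n"), solute="O2")


class TestProfileInvariants:
    def test_ph_outside_0_14_rejected(self):
        with pytest.raises(ValueError, match="pH"):
            SoluteProfile("pH", [0, 0.25, 0.5], [7.5, 14.2, 7.0], 250)

    def test_large_negative_concentration_rejected(self):
        with pytest.raises(ValueError, match="noise"):
            SoluteProfile("O2", [0, 0.1, 0.2], [300, -20.0, 10], 100)

    def test_small_negative_tolerated_as_sensor_noise(self):
        p = SoluteProfile("H2S", [0, 0.25, 0.5], [0.0, -2.0, 5.0], 250)
        assert p.n_points == 3

    def test_non_monotonic_depths_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            SoluteProfile("O2", [0, 0.2, 0.1], [1, 2, 3], 100)


class TestRoundTrip:
    def test_write_then_read_is_identity(self, tmp_path):
        rng = np.random.default_rng(42)
        depths = np.sort(rng.uniform(-0.5, 10, 20))
        p = SoluteProfile("H2S", depths, rng.uniform(0, 500, 20), 250.0, core_id="c1")
        f = tmp_path / "p.tsv"
        write_profile(p, f)
        q = read_profile(f, solute="H2S", core_id="c1")
        assert np.array_equal(p.depths, q.depths)
        assert np.array_equal(p.values, q.values)

    def test_summary_round_trip(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame({"core_id": ["a", "b"], "flux": [-58.123456, 8.8]})
        f = tmp_path / "summary.csv"
        write_summary(df, f)
        back = read_summary(f)
        assert list(back.columns) == ["core_id", "flux"]
        assert np.array_equal(back["flux"].to_numpy(), df["flux"].to_numpy())


class TestAlignToGrid:
    def test_midpoint_of_linear_segment(self):
        b = SoluteProfile("pH", [0, 0.25, 0.5], [8.0, 7.0, 6.0], 250)
        a = SoluteProfile("H2S", [0.125, 0.25, 0.375], [1.0, 2.0, 3.0], 250)
        depths, _, b_vals = align_to_grid(a, b)
        assert b_vals[0] == pytest.approx(7.5)

    def test_identical_grids_unchanged(self):
        d = np.array([0.0, 0.25, 0.5])
        a = SoluteProfile("H2S", d, [1.0, 2.0, 3.0], 250)
        b = SoluteProfile("pH", d, [8.0, 7.0, 6.0], 250)
        depths, a_vals, b_vals = align_to_grid(a, b)
        assert np.array_equal(depths, d)
        assert np.array_equal(b_vals, b.values)

    def test_depths_outside_b_range_dropped(self):
        a = SoluteProfile("H2S", np.arange(0, 2.1, 0.25), np.ones(9), 250)
        b = SoluteProfile("pH", [0.0, 0.5, 1.0], [8.0, 7.0, 6.0], 250)
        depths, _, _ = align_to_grid(a, b)
        assert depths.max() <= 1.0
        assert len(depths) == 5

    def test_no_overlap_is_error(self):
        a = SoluteProfile("H2S", [0.0, 0.5, 1.0], [1, 2, 3], 250)
        b = SoluteProfile("pH", [2.0, 2.5, 3.0], [7, 7, 7], 250)
        with pytest.raises(ValueError, match="overlap"):
            align_to_grid(a, b)

    @settings(derandomize=True, max_examples=25)
    @given(
        slope=st.floats(-0.5, 0.5),
        intercept=st.floats(6.0, 8.0),
        offset=st.floats(0.0, 0.24),
    )
    def test_exact_for_linear_target(self, slope, intercept, offset):
        """Linear interpolation is exact on a profile that is linear in depth."""
        b_depths = np.arange(0.0, 5.1, 0.25)
        b = SoluteProfile("pH", b_depths, intercept + slope * b_depths, 250)
        a_depths = np.arange(offset, 4.5, 0.25)
        a = SoluteProfile("H2S", a_depths, np.ones_like(a_depths), 250)
        depths, _, b_vals = align_to_grid(a, b)
        expected = intercept + slope * depths
        assert np.allclose(b_vals, expected, atol=1e-12)


class TestTaxonTable:
    def test_high_treatment_total_is_consistent(self):
        table = load_taxon_table()
        result = check_taxon_totals(table)
        assert result["high"]["sum"] == result["high"]["printed"] == 2030

    def test_reports_rounding_discrepancies_per_column(self):
        table = load_taxon_table()
        result = check_taxon_totals(table)
        # control/low totals were printed from unrounded means; the audit
        # surfaces the ±1 discrepancies instead of hiding them
        assert abs(result["control"]["difference"]) <= 1
        assert abs(result["low"]["difference"]) <= 1

    def test_missing_total_row_is_error(self):
        table = load_taxon_table().drop(index="Total")
        with pytest.raises(ValueError):
            check_taxon_totals(table)
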
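"""Grid/timeline context, unit conversion, resampling and zonal statistics."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pastoral.context import (
    Context, GridSpec, RasterField, ResolutionError, Timeline,
    make_default_context, resample_field, zonal_statistics,
)
from pastoral.units import UnitError, convert_units, unit


class TestDefaultContext:
    def test_defaults_match_standard_configuration(self):
        ctx = make_default_context()
        assert ctx.grid.cell_size == 50.0
        assert ctx.timeline.step_days == 1
        assert ctx.timeline.start == dt.date(2018, 1, 1)
        assert ctx.timeline.end == dt.date(2050, 12, 31)

    def test_n_steps_counts_days_inclusive(self):
        # oracle: calendar library count of days 2018-01-01..2050-12-31
        expected = len(pd.date_range("2018-01-01", "2050-12-31", freq="D"))
        assert expected == 12053
        assert make_default_context().timeline.n_steps == expected

    def test_deterministic_and_side_effect_free(self):
        a, b = make_default_context(), make_default_context()
        assert a.grid == b.grid and a.timeline == b.timeline
        assert np.array_equal(a.mask, b.mask)

    def test_timeline_rejects_reversed_dates(self):
        with pytest.raises(ValueError):
            Timeline(dt.date(2020, 1, 2), dt.date(2020, 1, 1))

    def test_context_requires_valid_cell(self):
        grid = GridSpec(2, 2, 50.0)
        with pytest.raises(ValueError):
            Context(grid, Timeline(dt.date(2020, 1, 1), dt.date(2020, 1, 1)),
                    mask=np.zeros((2, 2), dtype=bool))


class TestUnits:
    @pytest.mark.parametrize("value,src,dst,expected", [
        (1.0, "kg/ha", "g/m^2", 0.1),
        (1.0, "t/ha", "g/m^2", 100.0),
        (2.5, "g/m^2", "g/m^2", 2.5),
        (1.0, "m", "mm", 1000.0),
    ])
    def test_known_conversions(self, value, src, dst, expected):
        assert convert_units(value, src, dst) == pytest.approx(expected, rel=1e-12)

    def test_dimension_mismatch_names_both(self):
        with pytest.raises(UnitError, match="mass_per_area.*temperature"):
            convert_units(1.0, "kg/ha", "degC")

    @given(st.floats(min_value=1e-6, max_value=1e6),
           st.sampled_from(["kg/ha", "g/m^2", "t/ha"]))
    @settings(deadline=None, max_examples=50)
    def test_round_trip_is_identity(self, value, name):
        back = convert_units(convert_units(value, name, "g/m^2"), "g/m^2", name)
        assert back == pytest.approx(value, rel=1e-12)


def _field(values, cell_size=50.0, kind="continuous", origin=(0.0, 0.0)):
    values = np.asarray(values)
    grid = GridSpec(values.shape[1], values.shape[0], cell_size,
                    origin_x=origin[0], origin_y=origin[1])
    return RasterField("x", grid, values, kind=kind)


class TestResample:
    def test_same_grid_is_identity(self):
        f = _field([[1.0, 2.0], [3.0, 4.0]])
        out = resample_field(f, f.grid)
        assert np.array_equal(out.values, f.values)

    def test_aggregation_is_area_weighted_mean(self):
        f = _field([[1.0, 2.0], [3.0, 4.0]], cell_size=50.0)
        target = GridSpec(1, 1, 100.0)
        out = resample_field(f, target)
        assert out.values[0, 0] == pytest.approx(2.5)

    def test_constant_field_stays_constant(self):
        f = _field(np.full((4, 4), 7.25), cell_size=50.0)
        out = resample_field(f, GridSpec(2, 2, 100.0))
        assert np.allclose(out.values, 7.25)

    def test_disjoint_extents_raise(self):
        f = _field([[1.0]])
        far = GridSpec(1, 1, 50.0, origin_x=1e6, origin_y=1e6)
        with pytest.raises(ResolutionError, match="extent"):
            resample_field(f, far)

    def test_mean_conserved_under_full_coverage(self):
        rng = np.random.default_rng(0)
        f = _field(rng.random((8, 8)), cell_size=50.0)
        out = resample_field(f, GridSpec(4, 4, 100.0))
        assert out.values.mean() == pytest.approx(f.values.mean(), rel=1e-6)

    def test_categorical_nearest_introduces_no_new_codes(self):
        rng = np.random.default_rng(1)
        codes = rng.integers(1, 5, size=(6, 6)).astype(np.int32)
        f = _field(codes, cell_size=50.0, kind="categorical")
        out = resample_field(f, GridSpec(4, 4, 77.0))
        assert set(np.unique(out.values)) <= set(np.unique(codes))
        assert out.kind == "categorical"

    def test_low_coverage_becomes_nodata(self):
        vals = np.full((2, 2), 3.0)
        vals[0, 0] = -9999.0
        vals[0, 1] = -9999.0
        vals[1, 0] = -9999.0  # only 25% valid coverage for a 2x aggregate
        f = _field(vals, cell_size=50.0)
        out = resample_field(f, GridSpec(1, 1, 100.0))
        assert out.values[0, 0] == out.grid.nodata


class TestZonalStatistics:
    def test_single_zone(self):
        f = _field(np.full((2, 2), 2.0))
        z = _field(np.ones((2, 2), dtype=np.int32), kind="categorical")
        out = zonal_statistics(f, z)
        assert len(out) == 1
        assert out.loc[0, "mean"] == 2.0
        assert out.loc[0, "sum"] == 8.0

    def test_two_zones_hand_computed(self):
        f = _field(np.array([[1.0, 3.0], [5.0, 5.0]]))
        z = _field(np.array([[1, 1], [2, 2]], dtype=np.int32), kind="categorical")
        out = zonal_statistics(f, z).set_index("zone_id")
        assert out.loc[1, "mean"] == 2.0
        assert out.loc[2, "mean"] == 5.0
        assert out.loc[1, "min"] == 1.0 and out.loc[1, "max"] == 3.0

    def test_all_nodata_gives_empty_table(self):
        f = _field(np.full((2, 2), -9999.0))
        z = _field(np.ones((2, 2), dtype=np.int32), kind="categorical")
        assert len(zonal_statistics(f, z)) == 0

    def test_grid_mismatch_raises(self):
        f = _field(np.ones((2, 2)))
        z = _field(np.ones((3, 3), dtype=np.int32), kind="categorical")
        with pytest.raises(ResolutionError):
            zonal_statistics(f, z)
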
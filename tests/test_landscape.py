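"""Synthetic landscape generator: determinism, bounds and consistency."""

import numpy as np
import pytest

from pastoral.landscape import (
    LandscapeConfig, default_vegetation_params, generate_climate,
    generate_dem, generate_livestock, generate_vegetation_map, generate_whc,
)
from pastoral.livestock import DEFAULT_SLOPE_THRESHOLDS

CFG = LandscapeConfig(seed=3, ncols=20, nrows=20)


class TestDem:
    def test_deterministic_per_seed(self):
        a, _ = generate_dem(CFG)
        b, _ = generate_dem(CFG)
        assert np.array_equal(a.values, b.values)
        c, _ = generate_dem(LandscapeConfig(seed=4, ncols=20, nrows=20))
        assert not np.array_equal(a.values, c.values)

    def test_elevation_within_configured_range(self):
        dem, _ = generate_dem(CFG)
        assert dem.values.min() >= 100.0
        assert dem.values.max() <= 1200.0

    def test_flat_config_has_zero_slope(self):
        flat = LandscapeConfig(seed=3, ncols=10, nrows=10,
                               elevation_min=500.0, elevation_max=500.0)
        _, slope = generate_dem(flat)
        assert np.allclose(slope.values, 0.0)


class TestVegetationMap:
    def test_codes_within_range(self):
        dem, _ = generate_dem(CFG)
        veg, over = generate_vegetation_map(CFG, dem)
        for f in (veg, over):
            assert f.values.min() >= 1
            assert f.values.max() <= CFG.n_vegetation_types

    def test_zero_overstory_probability_means_no_overstory(self):
        cfg = LandscapeConfig(seed=3, ncols=20, nrows=20,
                              overstory_probability=0.0)
        dem, _ = generate_dem(cfg)
        veg, over = generate_vegetation_map(cfg, dem)
        assert np.array_equal(veg.values, over.values)

    def test_overstory_fraction_tracks_probability(self):
        cfg = LandscapeConfig(seed=3, ncols=40, nrows=40,
                              overstory_probability=0.3)
        dem, _ = generate_dem(cfg)
        veg, over = generate_vegetation_map(cfg, dem)
        frac = (veg.values != over.values).mean()
        assert 0.2 < frac < 0.4

    def test_smoothing_controls_patch_count(self):
        from scipy import ndimage
        counts = []
        for smoothing in (1.0, 6.0):
            cfg = LandscapeConfig(seed=3, ncols=40, nrows=40,
                                  patch_smoothing=smoothing)
            dem, _ = generate_dem(cfg)
            veg, _ = generate_vegetation_map(cfg, dem)
            n = sum(ndimage.label(veg.values == c)[1]
                    for c in np.unique(veg.values))
            counts.append(n)
        assert counts[0] > counts[1]  # finer texture -> more patches


class TestClimate:
    def test_annual_mean_temperature_near_configured(self):
        clim = generate_climate(LandscapeConfig(seed=3), 365)
        assert clim["tmean_c"].mean() == pytest.approx(14.0, abs=0.2)

    def test_non_negative_precip_and_radiation(self):
        clim = generate_climate(CFG, 730)
        assert (clim["precip_mm"] >= 0).all()
        assert (clim["rg_mj_m2"] >= 0).all()
        assert (clim["pet_mm"] >= 0).all()

    def test_same_seed_identical_series(self):
        a = generate_climate(CFG, 100)
        b = generate_climate(CFG, 100)
        assert a.equals(b)

    def test_zero_noise_is_exact_sinusoid(self):
        cfg = LandscapeConfig(seed=3, tmean_noise_sd=0.0)
        clim = generate_climate(cfg, 365)
        doy = np.arange(1, 366)
        expected = 14.0 + 6.0 * np.cos(2 * np.pi * (doy - 196) / 365.25)
        assert np.allclose(clim["tmean_c"].to_numpy(), expected)


class TestLivestock:
    def test_zero_groups_gives_empty_landscape(self):
        cfg = LandscapeConfig(seed=3, ncols=20, nrows=20,
                              n_livestock_groups=0)
        _, slope = generate_dem(cfg)
        dens, params = generate_livestock(cfg, slope)
        assert all(np.all(d.values == 0) for d in dens.values())
        assert len(params) == 0

    def test_no_animals_beyond_accessibility_cutoff(self):
        _, slope = generate_dem(CFG)
        dens, _ = generate_livestock(CFG, slope)
        for sp, field in dens.items():
            s1 = DEFAULT_SLOPE_THRESHOLDS[sp][1]
            assert np.all(field.values[slope.values >= s1] == 0)

    def test_total_animals_matches_configured_herds(self):
        cfg = LandscapeConfig(seed=3, ncols=20, nrows=20,
                              n_livestock_groups=6, animals_per_group=10)
        _, slope = generate_dem(cfg)
        dens, params = generate_livestock(cfg, slope)
        total = sum(d.values.sum() for d in dens.values())
        assert total == pytest.approx(60.0, rel=1e-9)
        assert len(params) == 6
        assert set(params["species"]) == {"cattle", "mare"}


def test_parameter_table_passes_consumer_validation():
    from pastoral.climate import VegetationClimateParams, trapezoid_calendar
    from pastoral.vegetation import VegetationType

    table = default_vegetation_params(9)
    assert len(table) == 9
    for _, row in table.iterrows():
        VegetationClimateParams(
            t_base=row["t_base"], t_opt_lo=row["t_opt_lo"],
            t_opt_hi=row["t_opt_hi"], t_max=row["t_max"],
            rg_half=row["rg_half"], w_crit=row["w_crit"],
            phenology_calendar=trapezoid_calendar(
                int(row["phen_start"]), int(row["phen_full_lo"]),
                int(row["phen_full_hi"]), int(row["phen_end"])))
        VegetationType(code=int(row["code"]), xf=row["xf"],
                       senescence_rate=row["senescence_rate"],
                       litterfall_rate=row["litterfall_rate"],
                       n_conc_target=row["n_conc_target"],
                       digestibility=row["digestibility"],
                       palatability=row["palatability"])
        # outflow fractions can never overdraw the living pool
        assert row["palatability"] + row["senescence_rate"] < 1


def test_whc_within_bounds():
    whc = generate_whc(CFG)
    assert whc.values.min() >= 80.0
    assert whc.values.max() <= 150.0
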
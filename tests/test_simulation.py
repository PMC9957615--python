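"""Full-system simulation: structure, budgets at desk scale, modularity and
oracle equivalence on the tiny landscape."""

import numpy as np
import pytest

from _reference import reference_run
from pastoral.components import FULL_SYSTEM_QUERY, NAMESPACES
from pastoral.engine import resolve, execute
from pastoral.simulate import run_query

POOLS_BIOMASS = ("vegetation.agb_living", "vegetation.agb_dead",
                 "vegetation.litter")
POOLS_N = ("nitrogen.soil_mineral_n", "nitrogen.litter_organic_n",
           "nitrogen.n_living", "nitrogen.n_dead",
           "nitrogen.reabsorption_credit")


class TestStructure:
    def test_registry_covers_all_ten_namespaces(self, small_setup):
        assert set(small_setup.registry.namespaces) == set(NAMESPACES)

    def test_radiation_chain_structure(self, small_setup):
        ctx = small_setup.context()
        df = resolve("radiation.growth_limiting_factor",
                     small_setup.registry, ctx)
        assert "radiation.over_vegetation" in df.components
        assert df.graph.has_edge("radiation.over_vegetation",
                                 "radiation.growth_limiting_factor")
        # externals + surface + understory radiation + factor
        assert len(df.graph) == len(df.components) + len(df.externals)

    def test_all_factors_bounded_in_run(self, small_run):
        store, _ = small_run
        for concept in ("temperature.growth_limiting_factor",
                        "radiation.growth_limiting_factor",
                        "moisture.growth_limiting_factor",
                        "nitrogen.growth_limiting_factor",
                        "vegetation.combined_climate_factor"):
            series = store.series(concept)
            assert series.min() >= 0.0 and series.max() <= 1.0

    def test_pools_stay_non_negative(self, small_run):
        store, _ = small_run
        for concept in POOLS_BIOMASS + POOLS_N:
            assert store.series(concept).min() >= -1e-12


class TestBudgets:
    def test_daily_biomass_balance_closes(self, small_run):
        store, _ = small_run
        n = store.series("vegetation.agb_living").shape[0]
        for t in range(n - 1):
            delta = (sum(store.get(p, t + 1) for p in POOLS_BIOMASS)
                     - sum(store.get(p, t) for p in POOLS_BIOMASS))
            rhs = (store.get("vegetation.actual_growth", t)
                   - store.get("vegetation.harvest_flux", t)
                   - store.get("ingestion.total_intake", t)
                   - store.get("vegetation.litter_decomposition", t))
            assert np.abs(delta - rhs).max() < 1e-9

    def test_whole_system_nitrogen_budget_closes(self, small_run):
        store, _ = small_run
        n = store.series("nitrogen.soil_mineral_n").shape[0]

        def total(t):
            return (sum(store.get(p, t) for p in POOLS_N)
                    + store.get("livestock.retained_n", t))

        for t in range(n - 1):
            delta = total(t + 1) - total(t)
            rhs = (store.get("nitrogen.fertilization", t)
                   - store.get("nitrogen.leaching", t))
            assert np.abs(delta - rhs).max() < 1e-9


class TestModularity:
    def test_standalone_equals_in_dataflow(self, small_setup, small_run):
        """Every component, run alone on inputs taken from the full run's
        store, must reproduce the full run's output field exactly."""
        from pastoral.engine import StepContext
        store, dataflow = small_run
        ctx = small_setup.context()
        for t in (0, 10, 30):
            step = StepContext(t=t, date=ctx.timeline.date(t), context=ctx)
            for comp in dataflow.components.values():
                ins = {i: store.get(i, t) for i in comp.inputs}
                out = np.broadcast_to(
                    np.asarray(comp.compute(ins, step), dtype=float),
                    ctx.grid.shape)
                assert np.array_equal(out, store.get(comp.output, t)), comp.id

    def test_showcase_manure_composition_matches_components(self, small_run):
        store, _ = small_run
        t = 20
        expected = (store.get("ingestion.cattle.intake_living", t)
                    * store.get("livestock.cattle.prop_living_in_digestion", t)
                    * store.get("nitrogen.prop_n_living", t))
        got = store.get(
            "excretion.n_living_biomass_from_cattle_solid_manure", t)
        assert np.allclose(got, expected, rtol=0, atol=0)


class TestOracleEquivalence:
    def test_engine_matches_monolithic_loop(self, tiny_setup):
        """The modular engine must agree with a hand-written monolithic
        daily loop implementing the same equations, cell by cell."""
        ctx = tiny_setup.context()
        store, _ = run_query(tiny_setup, list(FULL_SYSTEM_QUERY), ctx)
        ref = reference_run(tiny_setup, ctx)
        for concept, expected in ref.items():
            got = store.series(concept)
            assert got.shape == expected.shape
            scale = np.maximum(np.abs(expected), 1.0)
            err = np.abs(got - expected) / scale
            assert err.max() < 1e-9, f"{concept}: max rel err {err.max():.2e}"


class TestGrazingConsistency:
    def test_zero_density_cells_match_ungrazed_run(self, small_setup):
        from pastoral.landscape import LandscapeConfig
        from pastoral.simulate import build_setup
        cfg = LandscapeConfig(seed=1, ncols=10, nrows=10,
                              n_vegetation_types=5, n_livestock_groups=4,
                              animals_per_group=5)
        ungrazed = build_setup(cfg, n_days=60, with_livestock=False)
        ctx = small_setup.context()
        grazed_store, _ = run_query(small_setup, list(FULL_SYSTEM_QUERY), ctx)
        ungrazed_store, _ = run_query(ungrazed, list(FULL_SYSTEM_QUERY), ctx)
        dens = (small_setup.inputs["livestock.cattle.density"].values
                + small_setup.inputs["livestock.mare.density"].values)
        free = dens == 0
        assert free.any()
        for concept in POOLS_BIOMASS + POOLS_N:
            a = grazed_store.series(concept)[:, free]
            b = ungrazed_store.series(concept)[:, free]
            assert np.array_equal(a, b), concept
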
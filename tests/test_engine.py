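"""Dataflow engine: registration, resolution, dynamization, execution,
provenance export and reporting."""

import datetime as dt

import numpy as np
import pytest

from pastoral.context import Context, GridSpec, Timeline
from pastoral.engine import (
    ComponentModel, Concept, ConceptResolutionError, CycleError,
    ExecutionError, ModelRegistry, RegistrationError, StateStore,
    change_concept, execute, export_dataflow, generate_report, registry_to_yaml,
    resolve,
)


def _ctx(days=1, n=2):
    grid = GridSpec(n, n, 50.0)
    tl = Timeline(dt.date(2020, 1, 1), dt.date(2020, 1, 1) + dt.timedelta(days=days - 1))
    return Context(grid, tl)


def _comp(cid, output, inputs, fn, ns="a", **kw):
    return ComponentModel(id=cid, namespace=ns, output=output,
                          inputs=tuple(inputs), compute=fn, **kw)


def _registry():
    reg = ModelRegistry()
    reg.declare_external("x")
    reg.register(_comp("double", "y", ["x"], lambda v, s: 2 * v["x"]))
    reg.register(_comp("sum", "z", ["x", "y"], lambda v, s: v["x"] + v["y"]))
    return reg


class TestRegistration:
    def test_register_and_lookup_by_output(self):
        reg = _registry()
        assert reg.lookup("y").id == "double"

    def test_duplicate_id_rejected(self):
        reg = _registry()
        with pytest.raises(RegistrationError):
            reg.register(_comp("double", "w", [], lambda v, s: 0))

    def test_duplicate_output_in_namespace_rejected(self):
        reg = _registry()
        with pytest.raises(RegistrationError):
            reg.register(_comp("double2", "y", ["x"], lambda v, s: v["x"]))

    def test_same_output_other_namespace_retrievable_by_scoping(self):
        reg = _registry()
        reg.register(_comp("double_b", "y", ["x"], lambda v, s: 3 * v["x"],
                           ns="b"))
        assert reg.lookup("y", requesting_namespace="b").id == "double_b"
        assert reg.lookup("y", requesting_namespace="a").id == "double"
        # no namespace context: lexicographic tie-break
        assert reg.lookup("y").id == "double"


class TestResolution:
    def test_chain_resolves_all_dependencies(self):
        df = resolve("z", _registry(), _ctx())
        assert set(df.components) == {"double", "sum"}
        assert df.externals == {"x"}
        assert df.order.index("double") < df.order.index("sum")

    def test_external_input_query_is_single_node(self):
        df = resolve("x", _registry(), _ctx())
        assert df.components == {}
        assert df.externals == {"x"}
        assert len(df.graph) == 1

    def test_unresolvable_concept_names_chain(self):
        reg = _registry()
        reg.register(_comp("needs_w", "q", ["w"], lambda v, s: v["w"]))
        with pytest.raises(ConceptResolutionError, match="q -> w"):
            resolve("q", reg, _ctx())

    def test_cycle_detected(self):
        reg = ModelRegistry()
        reg.register(_comp("ab", "a", ["b"], lambda v, s: v["b"]))
        reg.register(_comp("ba", "b", ["a"], lambda v, s: v["a"]))
        with pytest.raises(CycleError, match="cycle"):
            resolve("a", reg, _ctx())

    def test_resolution_deterministic(self):
        a = resolve("z", _registry(), _ctx())
        b = resolve("z", _registry(), _ctx())
        assert a.order == b.order
        assert set(a.graph.edges) == set(b.graph.edges)


def _dynamic_registry():
    reg = ModelRegistry()
    reg.declare_external("stock")
    reg.register(_comp("decay", change_concept("stock"), [],
                       lambda v, s: np.full(s.context.grid.shape, -1.0)))
    return reg


class TestDynamization:
    def test_single_step_keeps_query_static(self):
        df = resolve("stock", _dynamic_registry(), _ctx(days=1))
        assert df.state_concepts == set()
        assert "decay" not in df.components

    def test_multi_step_inserts_change_model(self):
        df = resolve("stock", _dynamic_registry(), _ctx(days=5))
        assert df.state_concepts == {"stock"}
        assert "decay" in df.components

    def test_euler_iteration(self):
        ctx = _ctx(days=5)
        df = resolve("stock", _dynamic_registry(), ctx)
        store = execute(df, ctx, {"stock": 10.0})
        assert np.all(store.get("stock", 0) == 10.0)
        assert np.all(store.get("stock", 4) == 6.0)

    def test_zero_change_means_constant(self):
        reg = ModelRegistry()
        reg.declare_external("stock")
        reg.register(_comp("still", change_concept("stock"), [],
                           lambda v, s: np.zeros(s.context.grid.shape)))
        ctx = _ctx(days=10)
        store = execute(resolve("stock", reg, ctx), ctx, {"stock": 3.5})
        assert np.all(store.series("stock") == 3.5)


class TestExecution:
    def test_static_run_stores_one_field_per_concept(self):
        ctx = _ctx(days=1)
        df = resolve("z", _registry(), ctx)
        store = execute(df, ctx, {"x": 2.0})
        assert np.all(store.get("y", 0) == 4.0)
        assert np.all(store.get("z", 0) == 6.0)
        assert store.concepts() == ("x", "y", "z")

    def test_missing_external_input_named(self):
        ctx = _ctx()
        df = resolve("z", _registry(), ctx)
        with pytest.raises(ExecutionError, match="x"):
            execute(df, ctx, {})

    def test_non_finite_output_names_component_and_cell(self):
        reg = ModelRegistry()
        reg.declare_external("x")
        reg.register(_comp("bad", "y", ["x"],
                           lambda v, s: np.full_like(v["x"], np.nan)))
        ctx = _ctx()
        with pytest.raises(ArithmeticError, match="bad"):
            execute(resolve("y", reg, ctx), ctx, {"x": 1.0})

    def test_unwritten_state_read_is_error(self):
        store = StateStore()
        with pytest.raises(ExecutionError, match="never written"):
            store.get("nope", 0)

    def test_double_write_is_error(self):
        store = StateStore()
        store.put("a", 0, np.zeros(2))
        with pytest.raises(ExecutionError, match="twice"):
            store.put("a", 0, np.zeros(2))


class TestProvenanceExport:
    def test_single_node_dot(self):
        df = resolve("x", _registry(), _ctx())
        dot = export_dataflow(df)
        assert dot.startswith("digraph") and dot.rstrip().endswith("}")
        assert '"x"' in dot and "->" not in dot

    def test_node_count_matches_resolution(self):
        df = resolve("z", _registry(), _ctx())
        dot = export_dataflow(df)
        # one shape attribute per node declaration
        assert dot.count("shape=") == len(df.graph)
        assert dot.count("->") == df.graph.number_of_edges()

    def test_dot_well_formed(self):
        dot = export_dataflow(resolve("z", _registry(), _ctx()))
        assert dot.count("{") == dot.count("}") == 1
        for line in dot.splitlines()[1:-1]:
            assert line.endswith(";")
        assert 'provenance="expression"' in dot
        assert 'provenance="resource"' in dot

    def test_report_has_canonical_sections(self):
        ctx = _ctx()
        df = resolve("z", _registry(), ctx)
        store = execute(df, ctx, {"x": 2.0})
        report = generate_report(store, df, ctx)
        for section in ("Introduction", "Methods", "Results", "Discussion",
                        "Conclusion", "References"):
            assert f"## {section}" in report
        assert report.count("### ") == len(store.concepts())
        assert "`double` [a]" in report

    def test_report_statistics_match_field(self):
        ctx = _ctx()
        df = resolve("y", _registry(), ctx)
        store = execute(df, ctx, {"x": 2.0})
        report = generate_report(store, df, ctx)
        vals = store.get("y", 0)
        assert (f"min {vals.min():.6g}, mean {vals.mean():.6g}, "
                f"max {vals.max():.6g}") in report

    def test_registry_yaml_round_trips_structure(self):
        import yaml
        data = yaml.safe_load(registry_to_yaml(_registry()))
        assert data["external_inputs"] == ["x"]
        ids = [c["id"] for c in data["components"]]
        assert ids == sorted(ids) and "double" in ids
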
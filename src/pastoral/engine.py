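"""Concept-based dataflow engine.

Component models are named computations from input *concepts* to one output
concept, grouped into thematic namespaces.  A query for a concept over a
context is *resolved* into a directed acyclic dataflow by walking concept
dependencies through a registry; the dataflow is then *executed* over the
context's timeline in topological order.

Dynamization: a concept ``X`` becomes a state variable whenever a component
producing ``change_in_X`` is registered and the timeline has more than one
step.  The engine then inserts the change model into the dataflow and
advances ``X(t+1) = X(t) + change_in_X(t)`` (explicit Euler, Δt = 1 day);
``X`` itself must be supplied as an external input at initialization.  On a
single-step timeline the change model is not inserted and the query stays
static.

Provenance: every resolved node carries a source description (resource,
table or expression); :func:`export_dataflow` emits the graph as DOT and
:func:`generate_report` assembles a scientific-article-style Markdown
report from an executed run.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
import pandas as pd
import yaml

from .context import Context, RasterField
from .units import UnitSpec, DIMENSIONLESS

__all__ = [
    "Concept",
    "ComponentModel",
    "ModelRegistry",
    "Dataflow",
    "StateStore",
    "StepContext",
    "RegistrationError",
    "ConceptResolutionError",
    "CycleError",
    "ExecutionError",
    "NumericalError",
    "change_concept",
    "is_change_concept",
    "base_concept",
    "resolve",
    "execute",
    "export_dataflow",
    "generate_report",
    "registry_to_yaml",
]

CHANGE_PREFIX = "change_in_"


class RegistrationError(ValueError):
    """Duplicate component id or (output concept, namespace) pair."""


class ConceptResolutionError(LookupError):
    """A queried concept cannot be satisfied; carries the missing chain."""


class CycleError(ValueError):
    """The resolved dependency graph contains a cycle."""


class ExecutionError(RuntimeError):
    """A required external input is missing at execution time."""


class NumericalError(ArithmeticError):
    """A component produced a non-finite value."""


def change_concept(concept_id: str) -> str:
    """The id of the per-day change concept of a state concept."""
    return CHANGE_PREFIX + concept_id


def is_change_concept(concept_id: str) -> bool:
    return concept_id.startswith(CHANGE_PREFIX)


def base_concept(concept_id: str) -> str:
    """Inverse of :func:`change_concept`."""
    if not is_change_concept(concept_id):
        raise ValueError(f"{concept_id!r} is not a change concept")
    return concept_id[len(CHANGE_PREFIX):]


@dataclass(frozen=True)
class Concept:
    """A named quality, amount or process rate."""

    id: str
    description: str = ""
    units: UnitSpec = DIMENSIONLESS
    nature: str = "quality"  # quality | amount | process-rate

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("concept id must be non-empty")
        if self.nature not in ("quality", "amount", "process-rate"):
            raise ValueError(f"unknown concept nature {self.nature!r}")


@dataclass(frozen=True)
class StepContext:
    """Per-timestep execution context handed to component computes."""

    t: int
    date: _dt.date
    context: Context

    @property
    def day_of_year(self) -> int:
        return self.date.timetuple().tm_yday

    @property
    def cell_area(self) -> float:
        return self.context.grid.cell_area


@dataclass(frozen=True)
class ComponentModel:
    """A pure computation from input concepts to one output concept.

    ``compute(inputs, step)`` receives a dict mapping input concept ids to
    per-cell arrays plus a :class:`StepContext` and returns the output
    array; it must have no hidden state.
    """

    id: str
    namespace: str
    output: str
    inputs: tuple[str, ...]
    compute: "callable"
    project: str = "default"
    provenance: str = "expression"  # resource | table | expression
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "inputs", tuple(self.inputs))
        if self.provenance not in ("resource", "table", "expression"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def is_change_model(self) -> bool:
        return is_change_concept(self.output)


class ModelRegistry:
    """Holds components, declared external inputs and concept metadata.

    At most one component may produce a given output concept within one
    namespace; across namespaces, lookup applies the scoping order
    same-namespace > same-project > global, breaking ties lexicographically
    by component id.
    """

    def __init__(self) -> None:
        self._components: dict[str, ComponentModel] = {}
        self._by_output: dict[str, list[ComponentModel]] = {}
        self.external_inputs: set[str] = set()
        self.concepts: dict[str, Concept] = {}

    def register(self, component: ComponentModel) -> "ModelRegistry":
        if component.id in self._components:
            raise RegistrationError(f"duplicate component id {component.id!r}")
        for existing in self._by_output.get(component.output, []):
            if existing.namespace == component.namespace:
                raise RegistrationError(
                    f"namespace {component.namespace!r} already has a component "
                    f"for concept {component.output!r} ({existing.id!r})"
                )
        self._components[component.id] = component
        self._by_output.setdefault(component.output, []).append(component)
        return self

    def declare_external(self, concept_id: str,
                         concept: Concept | None = None) -> "ModelRegistry":
        self.external_inputs.add(concept_id)
        if concept is not None:
            self.concepts[concept_id] = concept
        return self

    def declare_concept(self, concept: Concept) -> "ModelRegistry":
        self.concepts[concept.id] = concept
        return self

    def __contains__(self, component_id: str) -> bool:
        return component_id in self._components

    def get(self, component_id: str) -> ComponentModel:
        return self._components[component_id]

    @property
    def components(self) -> tuple[ComponentModel, ...]:
        return tuple(self._components.values())

    @property
    def namespaces(self) -> tuple[str, ...]:
        return tuple(sorted({c.namespace for c in self._components.values()}))

    def producers(self, concept_id: str) -> tuple[ComponentModel, ...]:
        return tuple(self._by_output.get(concept_id, ()))

    def lookup(self, concept_id: str,
               requesting_namespace: str | None = None,
               requesting_project: str | None = None) -> ComponentModel:
        candidates = self._by_output.get(concept_id)
        if not candidates:
            raise ConceptResolutionError(f"no component produces {concept_id!r}")
        ranked = sorted(
            candidates,
            key=lambda c: (c.namespace != requesting_namespace,
                           c.project != requesting_project,
                           c.id),
        )
        return ranked[0]


@dataclass
class Dataflow:
    """A resolved DAG of components and external inputs answering one query."""

    query: str
    graph: nx.DiGraph                 # nodes: component ids and external concept ids
    order: list[str]                  # topological order of node ids
    components: dict[str, ComponentModel]
    externals: set[str]               # external concept ids (incl. state inits)
    state_concepts: set[str]          # dynamized concepts
    provenance: dict[str, str]

    @property
    def concepts(self) -> set[str]:
        out = set(self.externals)
        out.update(c.output for c in self.components.values())
        return out


def resolve(concept_id, registry: ModelRegistry, context: Context) -> Dataflow:
    """Resolve a queried concept into an executable dataflow over a context.

    ``concept_id`` may be a single concept or a sequence of concepts (a
    multi-sink query).  Walks concept dependencies depth-first, choosing one
    provider per concept with the registry's scoping rules (from the
    perspective of the first consumer that demanded the concept).  If the
    timeline has more than one step, every resolved concept with a
    registered change model is dynamized: the change model joins the
    dataflow and the concept becomes an externally-initialized state
    variable.
    """
    queries = [concept_id] if isinstance(concept_id, str) else list(concept_id)
    dynamic = context.timeline.n_steps > 1
    provider: dict[str, ComponentModel | None] = {}   # None => external
    missing_chain: list[str] = []

    def resolve_concept(cid: str, chain: tuple[str, ...],
                        requester: ComponentModel | None) -> None:
        if cid in provider:
            return
        producers = registry.producers(cid)
        if producers:
            comp = registry.lookup(
                cid,
                requesting_namespace=requester.namespace if requester else None,
                requesting_project=requester.project if requester else None,
            )
            provider[cid] = comp
            for dep in comp.inputs:
                resolve_concept(dep, chain + (cid,), comp)
        elif cid in registry.external_inputs:
            provider[cid] = None
        else:
            missing_chain.extend(chain + (cid,))
            raise ConceptResolutionError(
                "cannot resolve concept chain: " + " -> ".join(chain + (cid,))
            )

    for q in queries:
        resolve_concept(q, (), None)

    state_concepts: set[str] = set()
    if dynamic:
        # dynamize iteratively: change models may pull in further concepts
        frontier = list(provider)
        while frontier:
            next_frontier: list[str] = []
            for cid in frontier:
                if is_change_concept(cid):
                    continue
                ch = change_concept(cid)
                if ch not in provider and registry.producers(ch):
                    comp = registry.lookup(ch)
                    provider[ch] = comp
                    state_concepts.add(cid)
                    # the state itself is now externally initialized
                    provider[cid] = None
                    before = set(provider)
                    for dep in comp.inputs:
                        resolve_concept(dep, (ch,), comp)
                    next_frontier.extend(set(provider) - before)
                elif ch in provider and cid in provider and provider[cid] is not None:
                    # concept already dynamized through another path
                    state_concepts.add(cid)
                    provider[cid] = None
            frontier = next_frontier
        for cid in list(provider):
            if is_change_concept(cid) and base_concept(cid) in provider:
                state_concepts.add(base_concept(cid))
                provider[base_concept(cid)] = None

    graph = nx.DiGraph()
    components: dict[str, ComponentModel] = {}
    externals: set[str] = set()
    provenance: dict[str, str] = {}
    concept_node: dict[str, str] = {}
    for cid, comp in provider.items():
        if comp is None:
            concept_node[cid] = cid
            externals.add(cid)
            provenance[cid] = "resource"
        else:
            concept_node[cid] = comp.id
            components[comp.id] = comp
            provenance[comp.id] = comp.provenance
    for node in set(concept_node.values()):
        graph.add_node(node)
    for cid, comp in provider.items():
        if comp is None:
            continue
        for dep in comp.inputs:
            graph.add_edge(concept_node[dep], comp.id, concept=dep)

    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise CycleError(
            "dependency cycle: " + " -> ".join(str(e[0]) for e in cycle)
            + " -> " + str(cycle[-1][1])
        )
    order = list(nx.lexicographical_topological_sort(graph))
    query = queries[0] if len(queries) == 1 else ", ".join(queries)
    return Dataflow(query=query, graph=graph, order=order,
                    components=components, externals=externals,
                    state_concepts=state_concepts, provenance=provenance)


class StateStore:
    """Per-concept, per-timestep field history of an executed dataflow.

    Writing a (concept, step) twice or reading an unwritten one is an
    error — missing initialization surfaces instead of defaulting to zero.
    """

    def __init__(self, keep: str = "all") -> None:
        if keep not in ("all", "last"):
            raise ValueError("keep must be 'all' or 'last'")
        self.keep = keep
        self._data: dict[tuple[str, int], np.ndarray] = {}
        self.last_step: int = -1

    def put(self, concept_id: str, t: int, values: np.ndarray) -> None:
        key = (concept_id, t)
        if key in self._data:
            raise ExecutionError(
                f"field for {concept_id!r} at step {t} written twice")
        if self.keep == "last":
            prev = (concept_id, self.last_step_for(concept_id))
            self._data.pop(prev, None)
        self._data[key] = values
        self.last_step = max(self.last_step, t)

    def last_step_for(self, concept_id: str) -> int:
        steps = [t for (c, t) in self._data if c == concept_id]
        return max(steps) if steps else -1

    def get(self, concept_id: str, t: int) -> np.ndarray:
        try:
            return self._data[(concept_id, t)]
        except KeyError:
            raise ExecutionError(
                f"field for {concept_id!r} at step {t} was never written"
            ) from None

    def series(self, concept_id: str) -> np.ndarray:
        steps = sorted(t for (c, t) in self._data if c == concept_id)
        if not steps:
            raise ExecutionError(f"concept {concept_id!r} has no stored fields")
        return np.stack([self._data[(concept_id, t)] for t in steps])

    def concepts(self) -> tuple[str, ...]:
        return tuple(sorted({c for (c, _) in self._data}))

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self._data


def _resolve_external(source, concept_id: str, step: StepContext) -> np.ndarray:
    """Turn an external input source into a per-cell array for one step.

    Accepted sources: a RasterField or ndarray (static), a scalar, a pandas
    Series indexed by date (per-day scalar, broadcast over the grid), a
    DataFrame with a 'date' column and a value column named after the last
    concept-id segment, or a callable(step) -> array.
    """
    shape = step.context.grid.shape
    if isinstance(source, RasterField):
        return np.broadcast_to(source.values, shape).astype(float)
    if callable(source):
        return np.broadcast_to(np.asarray(source(step), dtype=float), shape)
    if isinstance(source, pd.Series):
        key = pd.Timestamp(step.date)
        try:
            val = source.loc[key]
        except KeyError:
            raise ExecutionError(
                f"external series {concept_id!r} has no value for {step.date}"
            ) from None
        return np.full(shape, float(val))
    if isinstance(source, np.ndarray):
        return np.broadcast_to(source, shape).astype(float)
    if np.isscalar(source):
        return np.full(shape, float(source))
    raise ExecutionError(
        f"unsupported external input type {type(source).__name__} for {concept_id!r}")


def execute(dataflow: Dataflow, context: Context, inputs: dict,
            keep: str = "all", snapshot_steps=None) -> StateStore:
    """Execute a resolved dataflow over a context.

    ``inputs`` maps external concept ids to sources (see
    :func:`_resolve_external`); dynamized state concepts take their
    initialization values from the same mapping.  For each timestep the
    nodes are evaluated in topological order, then every state concept is
    advanced by its change model's output.  With ``keep='all'`` every field
    at every step is retained; ``keep='last'`` retains only the newest (plus
    any steps listed in ``snapshot_steps``).
    """
    missing = [c for c in dataflow.externals if c not in inputs]
    if missing:
        raise ExecutionError(
            "missing external inputs: " + ", ".join(sorted(missing)))

    snapshot_steps = set(snapshot_steps or ())
    store = StateStore(keep="all")  # manual retention below
    n_steps = context.timeline.n_steps
    state: dict[str, np.ndarray] = {}
    retained: dict[tuple[str, int], bool] = {}

    for t in range(n_steps):
        step = StepContext(t=t, date=context.timeline.date(t), context=context)
        values: dict[str, np.ndarray] = {}
        for cid in dataflow.state_concepts:
            if t == 0:
                values[cid] = _resolve_external(inputs[cid], cid, step)
            else:
                values[cid] = state[cid]
        for node in dataflow.order:
            if node in dataflow.externals:
                if node in dataflow.state_concepts:
                    continue  # already materialized above
                values[node] = _resolve_external(inputs[node], node, step)
            else:
                comp = dataflow.components[node]
                out = np.asarray(
                    comp.compute({i: values[i] for i in comp.inputs}, step),
                    dtype=float,
                )
                out = np.broadcast_to(out, context.grid.shape)
                bad = ~np.isfinite(out) & context.mask
                if bad.any():
                    r, c = np.argwhere(bad)[0]
                    raise NumericalError(
                        f"component {comp.id!r} produced a non-finite value "
                        f"at cell ({r}, {c}), step {t}")
                values[comp.output] = out
        for cid, arr in values.items():
            if keep == "all" or t == n_steps - 1 or t in snapshot_steps:
                store.put(cid, t, np.array(arr, copy=True))
        for cid in dataflow.state_concepts:
            state[cid] = values[cid] + values[change_concept(cid)]
    return store


def export_dataflow(dataflow: Dataflow) -> str:
    """Serialize a resolved dataflow as a DOT digraph.

    Node labels are component ids (or external concept ids); each node
    carries a ``provenance`` attribute (resource | table | expression).
    """
    def q(s: str) -> str:
        return '"' + s.replace('"', r'\"') + '"'

    lines = ["digraph dataflow {", "  rankdir=BT;"]
    for node in dataflow.order:
        prov = dataflow.provenance.get(node, "expression")
        shape = "ellipse" if node in dataflow.externals else "box"
        lines.append(
            f"  {q(node)} [label={q(node)}, provenance={q(prov)}, shape={shape}];")
    for u, v, data in dataflow.graph.edges(data=True):
        lines.append(f"  {q(u)} -> {q(v)} [label={q(data.get('concept', ''))}];")
    lines.append("}")
    return "\n".join(lines)


_REPORT_SECTIONS = ("Introduction", "Methods", "Results",
                    "Discussion", "Conclusion", "References")


def generate_report(store: StateStore, dataflow: Dataflow,
                    context: Context | None = None) -> str:
    """Assemble a Markdown run report with the six canonical sections.

    The methods section lists every executed component with its provenance;
    the results section embeds min/mean/max summary statistics per output
    concept at the last stored step.
    """
    lines = ["# Simulation report", ""]
    lines += ["## Introduction", "",
              f"This report documents the resolution and execution of the "
              f"concept `{dataflow.query}` over the requested context. "
              f"The dataflow was assembled on the fly from "
              f"{len(dataflow.components)} component models and "
              f"{len(dataflow.externals)} external inputs.", ""]
    lines += ["## Methods", ""]
    for node in dataflow.order:
        if node in dataflow.externals:
            continue
        comp = dataflow.components[node]
        desc = f" — {comp.description}" if comp.description else ""
        lines.append(f"- `{comp.id}` [{comp.namespace}] "
                     f"(provenance: {comp.provenance}){desc}")
    lines.append("")
    lines.append("External inputs: " +
                 (", ".join(f"`{e}`" for e in sorted(dataflow.externals)) or "none"))
    lines += ["", "## Results", ""]
    for concept in store.concepts():
        t = store.last_step_for(concept)
        vals = store.get(concept, t)
        lines += [f"### {concept}", "",
                  f"Step {t}: min {np.nanmin(vals):.6g}, "
                  f"mean {np.nanmean(vals):.6g}, max {np.nanmax(vals):.6g}", ""]
    lines += ["## Discussion", "",
              "All quantities were computed deterministically from the "
              "declared inputs; the dataflow graph records every dependency "
              "used. Limiting factors are dimensionless fractions in [0, 1]; "
              "pools are per-cell densities.", ""]
    lines += ["## Conclusion", "",
              f"The query `{dataflow.query}` was computed for every cell of "
              "the context; see the results section for summary statistics.", ""]
    lines += ["## References", "",
              "Model provenance is embedded per component in the methods "
              "section and in the exported dataflow graph.", ""]
    return "\n".join(lines)


def registry_to_yaml(registry: ModelRegistry) -> str:
    """Serialize the registry's structure (not the compute code) as YAML."""
    payload = {
        "external_inputs": sorted(registry.external_inputs),
        "components": [
            {
                "id": c.id,
                "namespace": c.namespace,
                "project": c.project,
                "output": c.output,
                "inputs": list(c.inputs),
                "provenance": c.provenance,
                "description": c.description,
            }
            for c in sorted(registry.components, key=lambda c: c.id)
        ],
    }
    return yaml.safe_dump(payload, sort_keys=False)
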
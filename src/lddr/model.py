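"""Core representation of multi-valued logical networks.

A network is a set of components, each with a small integer activity range
(``0..max_level``; Boolean components have ``max_level`` 1, ternary ones 2),
and a list of *terms* in sum-of-products form.  A term is an AND-conjunction
of (possibly negated) threshold literals over regulator components; it is a
sufficient condition for its target to be driven to ``target_level``.
Several terms pointing at the same target are OR-connected alternatives.
Each term also carries a time-scale tag 1-3 ordering early signal
transduction, later effector events, and late feedback shut-off.

The target level of a component in a total state is resolved as follows:
among the satisfied terms, an explicit inactivation term (``target_level``
0, e.g. stimulus-induced degradation) wins; otherwise the highest satisfied
target level wins; if no term is satisfied the component falls back to its
basal ``default_level``.  Curated networks are expected to be conflict-free:
a state in which both a level-0 and a level-2 term fire indicates an
inconsistent model and can be flagged with :func:`find_conflicts`.

Splitting every term into its constituent (literal, term) pairs yields the
signed interaction graph used by all structural analyses.  The sign of an
arc is the literal sign (negation) times the term direction: terms driving
their target to a positive level transmit the literal sign unchanged, while
inactivation terms invert it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .errors import ModelValidationError, ParseError, UsageError

NetworkState = Mapping[str, int]


@dataclass(frozen=True, order=True)
class Literal:
    """A threshold literal: satisfied iff ``(level >= threshold) XOR negated``."""

    component: str
    negated: bool = False
    threshold: int = 1

    def satisfied(self, level: int) -> bool:
        return (level >= self.threshold) != self.negated

    @property
    def sign(self) -> int:
        return -1 if self.negated else 1


@dataclass(frozen=True)
class Term:
    """One interaction (hyperarc): an AND of literals driving ``target``."""

    id: int
    target: str
    literals: tuple[Literal, ...]
    target_level: int = 1
    time_scale: int = 1

    @property
    def direction(self) -> int:
        """+1 for terms driving the target to an active level, -1 for
        explicit inactivation terms."""
        return 1 if self.target_level >= 1 else -1

    def satisfied_by(self, state: NetworkState) -> bool:
        return all(lit.satisfied(state[lit.component]) for lit in self.literals)


@dataclass(frozen=True)
class Component:
    name: str
    max_level: int = 1
    default_level: int = 0
    annotation: str = ""


@dataclass(frozen=True)
class Arc:
    """A signed arc of the interaction graph, remembering its origin term."""

    source: str
    target: str
    sign: int
    time_scale: int
    term_id: int


@dataclass(frozen=True)
class SignedGraph:
    """Signed interaction graph obtained by splitting terms into arcs."""

    nodes: tuple[str, ...]
    arcs: tuple[Arc, ...]

    def sign_sets(self) -> dict[tuple[str, str], set[int]]:
        """Available signs per ordered node pair (parallel arcs collapsed)."""
        out: dict[tuple[str, str], set[int]] = {}
        for a in self.arcs:
            out.setdefault((a.source, a.target), set()).add(a.sign)
        return out

    def to_networkx(self):
        import networkx as nx

        g = nx.MultiDiGraph()
        g.add_nodes_from(self.nodes)
        for a in self.arcs:
            g.add_edge(a.source, a.target, sign=a.sign,
                       time_scale=a.time_scale, term_id=a.term_id)
        return g


class LogicalModel:
    """A validated multi-valued logical network.

    Components keep their declaration order (used for state-vector digit
    labels).  ``outputs`` are read-out components such as the cell-cycle
    arrest and apoptosis-onset pseudo-nodes of a signalling network.
    ``aliases`` maps ASCII spellings to canonical (possibly non-ASCII)
    component names, e.g. ``IkappaBalpha`` for ``IκBα``.
    """

    def __init__(self, components: Iterable[Component], terms: Iterable[Term],
                 outputs: Iterable[str] = (), aliases: Mapping[str, str] | None = None):
        self.components: dict[str, Component] = {}
        for comp in components:
            if comp.name in self.components:
                raise ModelValidationError(
                    [f"duplicate component name {comp.name!r}"])
            self.components[comp.name] = comp
        self.terms: tuple[Term, ...] = tuple(terms)
        self.outputs: tuple[str, ...] = tuple(outputs)
        self.aliases: dict[str, str] = dict(aliases or {})
        self._terms_by_target: dict[str, tuple[Term, ...]] = {}
        for term in self.terms:
            self._terms_by_target.setdefault(term.target, ())
        for name in self.components:
            self._terms_by_target.setdefault(name, ())
        for term in self.terms:
            self._terms_by_target[term.target] += (term,)
        self.validate()

    # -- basic queries -----------------------------------------------------

    @property
    def component_names(self) -> tuple[str, ...]:
        return tuple(self.components)

    def resolve(self, name: str) -> str:
        """Resolve a component name or ASCII alias to the canonical name."""
        if name in self.components:
            return name
        if name in self.aliases:
            return self.aliases[name]
        raise UsageError(f"unknown component {name!r}")

    def terms_for(self, target: str) -> tuple[Term, ...]:
        return self._terms_by_target.get(target, ())

    def is_input(self, name: str) -> bool:
        """Inputs (stimuli, housekeeping presences) have no incoming terms."""
        return not self._terms_by_target.get(name, ())

    @property
    def inputs(self) -> tuple[str, ...]:
        return tuple(n for n in self.components if self.is_input(n))

    def regulators(self, target: str, *, timescale_cutoff: int = 3) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for term in self.terms_for(target):
            if term.time_scale <= timescale_cutoff:
                for lit in term.literals:
                    seen.setdefault(lit.component, None)
        return tuple(seen)

    def default_state(self) -> dict[str, int]:
        return {n: c.default_level for n, c in self.components.items()}

    def levels(self, name: str) -> range:
        return range(self.components[name].max_level + 1)

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        failures: list[str] = []
        for name, comp in self.components.items():
            if comp.max_level not in (1, 2):
                failures.append(f"component {name!r}: max_level must be 1 or 2")
            if not 0 <= comp.default_level <= comp.max_level:
                failures.append(
                    f"component {name!r}: default_level {comp.default_level} "
                    f"outside [0, {comp.max_level}]")
        seen_ids: set[int] = set()
        for term in self.terms:
            where = f"term {term.id} (target {term.target!r})"
            if term.id in seen_ids:
                failures.append(f"duplicate term id {term.id}")
            seen_ids.add(term.id)
            if term.target not in self.components:
                failures.append(f"{where}: unknown target component")
                continue
            tgt = self.components[term.target]
            if not 0 <= term.target_level <= tgt.max_level:
                failures.append(
                    f"{where}: target_level {term.target_level} outside "
                    f"[0, {tgt.max_level}]")
            if term.time_scale not in (1, 2, 3):
                failures.append(f"{where}: time_scale must be 1, 2, or 3")
            if not term.literals:
                failures.append(f"{where}: term must have at least one literal")
            if len(set(term.literals)) != len(term.literals):
                failures.append(f"{where}: duplicate literals")
            for lit in term.literals:
                if lit.component not in self.components:
                    failures.append(
                        f"{where}: literal references unknown component "
                        f"{lit.component!r}")
                    continue
                reg = self.components[lit.component]
                if not 1 <= lit.threshold <= reg.max_level:
                    failures.append(
                        f"{where}: literal threshold {lit.threshold} on "
                        f"{lit.component!r} outside [1, {reg.max_level}]")
        for alias, target in self.aliases.items():
            if target not in self.components:
                failures.append(f"alias {alias!r} points to unknown component "
                                f"{target!r}")
        for name in self.outputs:
            if name not in self.components:
                failures.append(f"output {name!r} is not a declared component")
        if failures:
            raise ModelValidationError(failures)

    # -- derived models ----------------------------------------------------

    def restricted(self, timescale_cutoff: int) -> "LogicalModel":
        """Sub-model keeping only terms with ``time_scale <= cutoff``.

        The cutoff is cumulative: late feedback (scale 3) sits on top of the
        early and intermediate layers.
        """
        if timescale_cutoff not in (1, 2, 3):
            raise UsageError(f"timescale cutoff must be 1, 2, or 3, "
                             f"got {timescale_cutoff}")
        return LogicalModel(
            self.components.values(),
            [t for t in self.terms if t.time_scale <= timescale_cutoff],
            self.outputs, self.aliases)

    def with_clamps(self, clamps: Mapping[str, int]) -> "LogicalModel":
        """Bake clamps in: clamped components lose their incoming terms and
        take the clamp as their default, i.e. they become pinned inputs."""
        clamps = self.check_clamps(clamps)
        comps = [replace(c, default_level=clamps[n]) if n in clamps else c
                 for n, c in self.components.items()]
        terms = [t for t in self.terms if t.target not in clamps]
        return LogicalModel(comps, terms, self.outputs, self.aliases)

    def check_clamps(self, clamps: Mapping[str, int]) -> dict[str, int]:
        out: dict[str, int] = {}
        for name, level in clamps.items():
            canon = self.resolve(name)
            if not 0 <= level <= self.components[canon].max_level:
                raise UsageError(
                    f"clamp {canon}={level} outside "
                    f"[0, {self.components[canon].max_level}]")
            out[canon] = level
        return out

    # -- equality / canonical form ----------------------------------------

    def canonical(self) -> "LogicalModel":
        """Sorted term ids, sorted literals, sorted aliases.  Component
        declaration order is semantic (it fixes state-label digit order)
        and is preserved."""
        terms = [replace(t, literals=tuple(sorted(t.literals)))
                 for t in sorted(self.terms, key=lambda t: t.id)]
        return LogicalModel(self.components.values(), terms,
                            tuple(sorted(self.outputs)),
                            dict(sorted(self.aliases.items())))

    def structurally_equals(self, other: "LogicalModel") -> bool:
        a, b = self.canonical(), other.canonical()
        return (a.components == b.components and a.terms == b.terms
                and a.outputs == b.outputs and a.aliases == b.aliases)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (f"<LogicalModel {len(self.components)} components, "
                f"{len(self.terms)} terms>")


# -- evaluation ------------------------------------------------------------

def resolve_target_level(component: Component, satisfied: Sequence[Term]) -> int:
    """Combine the satisfied terms of one component into its target level."""
    if not satisfied:
        return component.default_level
    if any(t.target_level == 0 for t in satisfied):
        return 0
    return max(t.target_level for t in satisfied)


def evaluate_target_level(model: LogicalModel, component: str,
                          state: NetworkState, *,
                          timescale_cutoff: int = 3) -> int:
    """Resolved target level of ``component`` in a total ``state``.

    Deterministic: inactivation terms override, otherwise the maximum
    satisfied target level wins, otherwise the basal default applies.
    """
    component = model.resolve(component)
    if model.is_input(component):
        raise UsageError(f"{component!r} is an input; inputs hold their "
                         "clamped or default level and are never evaluated")
    satisfied = [t for t in model.terms_for(component)
                 if t.time_scale <= timescale_cutoff and t.satisfied_by(state)]
    return resolve_target_level(model.components[component], satisfied)


def find_conflicts(model: LogicalModel, states: Iterable[NetworkState]
                   ) -> list[tuple[dict[str, int], str]]:
    """Flag states in which a level-0 and a level-2 term of one component
    fire simultaneously (a curation inconsistency in a ternary component)."""
    conflicts = []
    for state in states:
        for name in model.components:
            sat = [t for t in model.terms_for(name) if t.satisfied_by(state)]
            if any(t.target_level == 0 for t in sat) and \
               any(t.target_level == 2 for t in sat):
                conflicts.append((dict(state), name))
    return conflicts


# -- interaction graph -----------------------------------------------------

def interaction_graph(model: LogicalModel) -> SignedGraph:
    """Split every term into its constituent signed arcs.

    Exactly one arc per (literal, term) pair; arc sign = literal sign x
    term direction, so a non-negated regulator in a degradation term shows
    up as an inhibitor, reproducing T-arcs of the curated diagrams.
    """
    arcs = tuple(
        Arc(lit.component, term.target, lit.sign * term.direction,
            term.time_scale, term.id)
        for term in model.terms for lit in term.literals)
    return SignedGraph(model.component_names, arcs)


# -- serialization ---------------------------------------------------------

_FORMAT_KEYS = {"components", "terms", "outputs", "aliases"}


def _require(mapping, key, types, path):
    if key not in mapping:
        raise ParseError(f"missing required key {key!r}", path)
    value = mapping[key]
    if not isinstance(value, types):
        raise ParseError(
            f"{key!r} has wrong type {type(value).__name__}", f"{path}.{key}")
    if isinstance(value, bool) and bool not in (types if isinstance(types, tuple) else (types,)):
        raise ParseError(f"{key!r} must not be a boolean", f"{path}.{key}")
    return value


def parse_model(text: str | bytes) -> LogicalModel:
    """Parse a native-JSON model document into a validated model."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise ParseError("document root must be an object")
    for key in doc:
        if key not in _FORMAT_KEYS:
            raise ParseError(f"unknown key {key!r}", f"$.{key}")
    raw_components = _require(doc, "components", list, "$")
    raw_terms = _require(doc, "terms", list, "$")
    components = []
    for i, item in enumerate(raw_components):
        path = f"$.components[{i}]"
        if not isinstance(item, dict):
            raise ParseError("component entry must be an object", path)
        components.append(Component(
            name=_require(item, "name", str, path),
            max_level=_require(item, "max_level", int, path),
            default_level=_require(item, "default_level", int, path),
            annotation=item.get("annotation", "")))
    terms = []
    for i, item in enumerate(raw_terms):
        path = f"$.terms[{i}]"
        if not isinstance(item, dict):
            raise ParseError("term entry must be an object", path)
        raw_lits = _require(item, "literals", list, path)
        literals = []
        for j, lit in enumerate(raw_lits):
            lpath = f"{path}.literals[{j}]"
            if not isinstance(lit, dict):
                raise ParseError("literal entry must be an object", lpath)
            literals.append(Literal(
                component=_require(lit, "component", str, lpath),
                negated=bool(lit.get("negated", False)),
                threshold=_require(lit, "threshold", int, lpath)
                if "threshold" in lit else 1))
        terms.append(Term(
            id=_require(item, "id", int, path),
            target=_require(item, "target", str, path),
            literals=tuple(literals),
            target_level=_require(item, "target_level", int, path),
            time_scale=_require(item, "time_scale", int, path)))
    outputs = doc.get("outputs", [])
    if not isinstance(outputs, list) or not all(isinstance(o, str) for o in outputs):
        raise ParseError("'outputs' must be a list of strings", "$.outputs")
    aliases = doc.get("aliases", {})
    if not isinstance(aliases, dict):
        raise ParseError("'aliases' must be an object", "$.aliases")
    return LogicalModel(components, terms, outputs, aliases)


def serialize_model(model: LogicalModel) -> str:
    """Serialize to the canonical native-JSON form (sorted keys, sorted
    term ids); round-trips byte-identically through :func:`parse_model`."""
    model = model.canonical()
    doc = {
        "components": [
            {"name": c.name, "max_level": c.max_level,
             "default_level": c.default_level, "annotation": c.annotation}
            for c in model.components.values()],
        "terms": [
            {"id": t.id, "target": t.target, "target_level": t.target_level,
             "time_scale": t.time_scale,
             "literals": [
                 {"component": lit.component, "negated": lit.negated,
                  "threshold": lit.threshold} for lit in t.literals]}
            for t in model.terms],
        "outputs": list(model.outputs),
        "aliases": dict(model.aliases),
    }
    return json.dumps(doc, indent=2, sort_keys=True, ensure_ascii=False) + "\n"


def export_sif(graph: SignedGraph) -> str:
    """Cytoscape SIF dialect: one ``source<TAB>relation<TAB>target`` row per
    arc, relation in {activates, inhibits}."""
    rows = [f"{a.source}\t{'activates' if a.sign > 0 else 'inhibits'}\t{a.target}"
            for a in graph.arcs]
    return "\n".join(rows) + ("\n" if rows else "")


def export_graphml(graph: SignedGraph) -> str:
    import networkx as nx

    g = graph.to_networkx()
    return "\n".join(nx.generate_graphml(g, named_key_ids=True)) + "\n"
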
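"""Asynchronous state-transition graphs under ranked priority classes.

States are total assignments of activity levels.  A transition moves one
component one step (+/-1) toward its resolved target level — the standard
multi-valued asynchronous convention.  Transitions are grouped into
priority classes keyed by (component, direction); at any state only the
candidates of the highest-ranked class fire, asynchronously within the
class.  Unranked pairs fall into an implicit lowest class.  A flat scheme
(no classes) is plain asynchronous updating.

Attractors are the terminal strongly connected components of the reachable
state-transition graph: a singleton with no outgoing transition is a
logical steady state, a cycle where every member has exactly one successor
inside is a simple loop, anything else is a complex loop.  Fixed points can
also be found symbolically, without building any STG, by a backtracking
constraint search; that route is updating-scheme independent and scales to
networks whose state spaces are far too large to enumerate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import networkx as nx

from .errors import StateSpaceOverflowError, UsageError
from .model import LogicalModel, resolve_target_level

INCREASE = "INCREASE"
DECREASE = "DECREASE"


@dataclass(frozen=True)
class PriorityScheme:
    """Ordered priority classes of (component, direction) pairs.

    ``classes[0]`` has the highest rank.  A pair listed in two classes is
    rejected; unlisted pairs share the implicit lowest rank.
    """

    classes: tuple[frozenset[tuple[str, str]], ...] = ()
    name: str = "flat"

    def __post_init__(self):
        seen: set[tuple[str, str]] = set()
        for cls in self.classes:
            dup = seen & cls
            if dup:
                raise UsageError(
                    f"priority scheme {self.name!r}: pairs listed twice: "
                    f"{sorted(dup)}")
            seen |= cls

    def rank(self, component: str, direction: str) -> int:
        for idx, cls in enumerate(self.classes):
            if (component, direction) in cls:
                return idx
        return len(self.classes)


FLAT_SCHEME = PriorityScheme()


def state_tuple(model: LogicalModel, state: Mapping[str, int]) -> tuple[int, ...]:
    return tuple(state[name] for name in model.components)

def state_dict(model: LogicalModel, values: tuple[int, ...]) -> dict[str, int]:
    return dict(zip(model.components, values))

def state_label(values: Iterable[int]) -> str:
    """Digit-string label in declared component order (figure convention)."""
    return "".join(str(v) for v in values)


def _candidates(model: LogicalModel, state: dict[str, int],
                scheme: PriorityScheme):
    cands = []
    for name in model.components:
        terms = model.terms_for(name)
        if not terms:
            continue  # inputs (and clamped components) never move
        target = resolve_target_level(
            model.components[name], [t for t in terms if t.satisfied_by(state)])
        cur = state[name]
        if target == cur:
            continue
        direction = INCREASE if target > cur else DECREASE
        cands.append((name, direction, scheme.rank(name, direction)))
    if not cands:
        return []
    best = min(rank for _, _, rank in cands)
    return [(name, direction) for name, direction, rank in cands
            if rank == best]


def successors(model: LogicalModel, state: Mapping[str, int],
               scheme: PriorityScheme = FLAT_SCHEME) -> set[tuple[int, ...]]:
    """Asynchronous successors of a total state under the scheme.

    Empty iff the state is a logical steady state.
    """
    local = dict(state)
    out = set()
    for name, direction in _candidates(model, local, scheme):
        step = dict(local)
        step[name] += 1 if direction == INCREASE else -1
        out.add(state_tuple(model, step))
    return out


def build_stg(model: LogicalModel, initial: Iterable[Mapping[str, int]],
              scheme: PriorityScheme = FLAT_SCHEME,
              max_states: int = 10 ** 6) -> nx.DiGraph:
    """Reachable closure of ``initial`` under :func:`successors`.

    Nodes are level tuples in declared component order, labelled with their
    digit string; ``graph.graph['components']`` records the order and
    ``graph.graph['initial']`` the initial set.
    """
    init = [state_tuple(model, s) for s in initial]
    if not init:
        raise UsageError("initial state set must be non-empty")
    stg = nx.DiGraph(components=tuple(model.components),
                     initial=tuple(dict.fromkeys(init)))
    stack = list(dict.fromkeys(init))
    seen = set(stack)
    for node in stack:
        stg.add_node(node, label=state_label(node))
    while stack:
        node = stack.pop()
        for succ in sorted(successors(model, state_dict(model, node), scheme)):
            if succ not in seen:
                if len(seen) >= max_states:
                    raise StateSpaceOverflowError(
                        f"state transition graph exceeded {max_states} states")
                seen.add(succ)
                stg.add_node(succ, label=state_label(succ))
                stack.append(succ)
            stg.add_edge(node, succ)
    return stg


def full_stg(model: LogicalModel, scheme: PriorityScheme = FLAT_SCHEME,
             max_states: int = 10 ** 6) -> nx.DiGraph:
    """STG over the entire state space (product of all level ranges)."""
    space = itertools.product(
        *(model.levels(name) for name in model.components))
    states = [state_dict(model, values) for values in space]
    if len(states) > max_states:
        raise StateSpaceOverflowError(
            f"state space of {len(states)} states exceeds cap {max_states}")
    return build_stg(model, states, scheme, max_states)


class AttractorKind(str, Enum):
    STEADY_STATE = "STEADY_STATE"
    SIMPLE_LOOP = "SIMPLE_LOOP"
    COMPLEX_LOOP = "COMPLEX_LOOP"


@dataclass
class Attractor:
    states: frozenset[tuple[int, ...]]
    kind: AttractorKind

    def __len__(self):
        return len(self.states)

    def labels(self) -> list[str]:
        return sorted(state_label(s) for s in self.states)


def find_attractors(stg: nx.DiGraph) -> list[Attractor]:
    """Terminal strongly connected components of a finite STG, classified.

    Every state of a finite STG reaches at least one attractor.
    """
    attractors = []
    for scc in nx.strongly_connected_components(stg):
        if any(succ not in scc for node in scc for succ in stg.successors(node)):
            continue
        if len(scc) == 1:
            node = next(iter(scc))
            if stg.out_degree(node) == 0:
                attractors.append(Attractor(frozenset(scc),
                                            AttractorKind.STEADY_STATE))
                continue
        simple = all(stg.out_degree(node) == 1 for node in scc)
        attractors.append(Attractor(
            frozenset(scc),
            AttractorKind.SIMPLE_LOOP if simple else AttractorKind.COMPLEX_LOOP))
    attractors.sort(key=lambda a: min(a.states))
    return attractors


def steady_states_symbolic(model: LogicalModel,
                           clamps: Mapping[str, int] | None = None
                           ) -> list[dict[str, int]]:
    """All total fixed points, by constraint search over components.

    A fixed point assigns every non-input its resolved target level;
    inputs sit at their clamp or default.  The search assigns forced
    components first (all regulators decided), branches only inside
    unresolved feedback, and therefore never touches the state space as a
    whole.  Updating-scheme independent.
    """
    clamps = model.check_clamps(clamps or {})
    names = list(model.components)
    fixed: dict[str, int] = {}
    for name in names:
        if name in clamps:
            fixed[name] = clamps[name]
        elif model.is_input(name):
            fixed[name] = model.components[name].default_level
    regulators = {name: set(model.regulators(name)) for name in names}
    free = [n for n in names if n not in fixed]
    solutions: list[dict[str, int]] = []

    def consistent(assign: dict[str, int], name: str) -> bool:
        """Check f(name) == assign[name] once all regulators are decided."""
        terms = model.terms_for(name)
        target = resolve_target_level(
            model.components[name], [t for t in terms if t.satisfied_by(assign)])
        return target == assign[name]

    def search(assign: dict[str, int], remaining: list[str]):
        if not remaining:
            solutions.append(dict(assign))
            return
        # prefer a component whose regulators are all assigned: its value
        # is forced, no branching needed
        pick = None
        for name in remaining:
            if all(r in assign for r in regulators[name]):
                pick = name
                break
        if pick is not None:
            target = resolve_target_level(
                model.components[pick],
                [t for t in model.terms_for(pick) if t.satisfied_by(assign)])
            assign[pick] = target
            if _check_closed(assign, pick):
                search(assign, [n for n in remaining if n != pick])
            del assign[pick]
            return
        pick = min(remaining, key=lambda n: model.components[n].max_level)
        for level in model.levels(pick):
            assign[pick] = level
            if _check_closed(assign, pick):
                search(assign, [n for n in remaining if n != pick])
            del assign[pick]

    def _check_closed(assign: dict[str, int], last: str) -> bool:
        """Verify every assigned non-input whose regulators are now all
        assigned and that depends on ``last`` (or is ``last``)."""
        for name in assign:
            if name in fixed:
                continue
            if name != last and last not in regulators[name]:
                continue
            if all(r in assign for r in regulators[name]):
                if not consistent(assign, name):
                    return False
        return True

    search(dict(fixed), free)
    uniq = {tuple(sorted(s.items())): s for s in solutions}
    return sorted(uniq.values(), key=lambda s: state_tuple(model, s))


def export_dot(stg: nx.DiGraph) -> str:
    """DOT text of an STG using digit-string labels."""
    lines = ["digraph stg {"]
    for node, data in stg.nodes(data=True):
        lines.append(f'  "{data["label"]}";')
    for u, v in stg.edges():
        lines.append(f'  "{stg.nodes[u]["label"]}" -> "{stg.nodes[v]["label"]}";')
    lines.append("}")
    return "\n".join(lines) + "\n"
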
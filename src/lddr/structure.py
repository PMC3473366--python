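"""Structural analyses on the signed interaction graph.

Three families of analysis live here:

* **Signed reachability and the dependency matrix.**  Every ordered pair of
  components is classified by the signs of the simple paths connecting them
  and by whether any species on those paths sits on a negative feedback
  loop: a *strong activator* reaches its target only through positive
  paths none of whose members is negatively feedback-regulated, a *weak*
  one through positive paths that are; likewise for inhibitors; a pair
  with both path signs is *ambivalent*, and one with no path has *no
  effect*.  Ambivalence is the norm in damage-response signalling, where
  activation at an early time scale is almost always followed by
  feedback shut-off at a late one.

* **Feed-forward loops** (x -> y -> z plus x -> z) with the standard
  coherence/type classification from the sign pattern, plus the gate of
  the target: AND if the direct and indirect inputs must co-occur in one
  term of z, OR if they feed z through distinct terms.

* **Feedback loops** (signed simple cycles) and their *functionality
  contexts*: assignments of a loop's external regulators under which every
  loop arc can actually change its target's resolved level.  A negative
  loop that is functional somewhere is a candidate oscillator; a positive
  one, a candidate memory switch.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass, field
from enum import Enum

import networkx as nx

from .errors import AnalysisBudgetError, UsageError
from .model import (LogicalModel, SignedGraph, interaction_graph,
                    resolve_target_level)


class DependencyClass(str, Enum):
    STRONG_ACTIVATOR = "STRONG_ACTIVATOR"
    WEAK_ACTIVATOR = "WEAK_ACTIVATOR"
    STRONG_INHIBITOR = "STRONG_INHIBITOR"
    WEAK_INHIBITOR = "WEAK_INHIBITOR"
    AMBIVALENT = "AMBIVALENT"
    NO_EFFECT = "NO_EFFECT"


class Coherence(str, Enum):
    COHERENT = "COHERENT"
    INCOHERENT = "INCOHERENT"


class Gate(str, Enum):
    AND = "AND"
    OR = "OR"
    MIXED = "MIXED"


@dataclass(frozen=True)
class FFLRecord:
    x: str
    y: str
    z: str
    signs: tuple[int, int, int]  # (s_xy, s_yz, s_xz)
    coherence: Coherence
    type_index: int
    gate: Gate


@dataclass
class FeedbackLoop:
    nodes: tuple[str, ...]  # canonical rotation, no repeats
    sign: int
    functionality_contexts: list[dict[str, int]] = field(default_factory=list)

    @property
    def is_negative(self) -> bool:
        return self.sign < 0

    def arcs(self) -> list[tuple[str, str]]:
        n = len(self.nodes)
        return [(self.nodes[i], self.nodes[(i + 1) % n]) for i in range(n)]


# -- signed reachability ---------------------------------------------------

def signed_reachability(graph: SignedGraph
                        ) -> dict[tuple[str, str], tuple[bool, bool]]:
    """Walk-based parity reachability.

    ``table[(i, j)] = (has_positive_path, has_negative_path)`` where a path
    is any non-empty walk and its sign is the product of arc signs;
    computed as a BFS fixpoint over the (node, parity) product graph.
    """
    signs = graph.sign_sets()
    succ: dict[str, list[tuple[str, int]]] = {n: [] for n in graph.nodes}
    for (u, v), ss in signs.items():
        for s in ss:
            succ[u].append((v, s))
    table = {(i, j): [False, False] for i in graph.nodes for j in graph.nodes}
    for start in graph.nodes:
        seen: set[tuple[str, int]] = set()
        queue: deque[tuple[str, int]] = deque()
        for v, s in succ[start]:
            if (v, s) not in seen:
                seen.add((v, s))
                queue.append((v, s))
        while queue:
            node, sign = queue.popleft()
            table[(start, node)][0 if sign > 0 else 1] = True
            for v, s in succ[node]:
                nxt = (v, sign * s)
                if nxt not in seen:
                    seen.add(nxt)
                    queue.append(nxt)
    return {k: (v[0], v[1]) for k, v in table.items()}


# -- simple-path census and the dependency matrix --------------------------

def _simple_path_census(graph: SignedGraph, source: str, max_steps: int):
    """Enumerate all simple paths out of ``source``.

    Returns per destination the set of achievable path signs and the set of
    nodes (endpoints included) lying on at least one source->destination
    simple path.  Exhaustive by construction; ``max_steps`` caps the DFS
    extension count to keep dense graphs from exploding silently.
    """
    signs = graph.sign_sets()
    succ: dict[str, dict[str, set[int]]] = {n: {} for n in graph.nodes}
    for (u, v), ss in signs.items():
        succ[u][v] = ss
    path_signs: dict[str, set[int]] = {}
    members: dict[str, set[str]] = {}
    steps = 0

    def dfs(node: str, sign: int, on_path: list[str], visited: set[str]):
        nonlocal steps
        for v, ss in succ[node].items():
            if v in visited and v != source:
                continue
            for s in ss:
                steps += 1
                if steps > max_steps:
                    raise AnalysisBudgetError(
                        f"simple-path enumeration from {source!r} exceeded "
                        f"{max_steps} extensions")
                total = sign * s
                path_signs.setdefault(v, set()).add(total)
                members.setdefault(v, set()).update(on_path, (v,))
                if v != source:
                    visited.add(v)
                    on_path.append(v)
                    dfs(v, total, on_path, visited)
                    on_path.pop()
                    visited.discard(v)
            if v == source:
                # cycles back to the source are recorded but not extended
                continue
    dfs(source, 1, [source], {source})
    return path_signs, members


def dependency_matrix(graph: SignedGraph, *, max_steps: int = 2_000_000
                      ) -> dict[tuple[str, str], DependencyClass]:
    """Classify every ordered component pair.

    Path signs are taken over *simple* paths (a negative self-loop hanging
    off a positive chain does not make the chain ambivalent — it makes its
    downstream effects weak).  Diagonal entries classify the simple cycles
    through the component itself, so a component on a negative loop is its
    own (weak) inhibitor.  Every pair receives exactly one class.
    """
    neg_nodes = nodes_on_negative_cycles(graph)
    matrix: dict[tuple[str, str], DependencyClass] = {}
    for i in graph.nodes:
        path_signs, members = _simple_path_census(graph, i, max_steps)
        for j in graph.nodes:
            ss = path_signs.get(j, set())
            if not ss:
                matrix[(i, j)] = DependencyClass.NO_EFFECT
            elif ss == {1, -1}:
                matrix[(i, j)] = DependencyClass.AMBIVALENT
            else:
                weak = bool(members[j] & neg_nodes)
                if 1 in ss:
                    matrix[(i, j)] = (DependencyClass.WEAK_ACTIVATOR if weak
                                      else DependencyClass.STRONG_ACTIVATOR)
                else:
                    matrix[(i, j)] = (DependencyClass.WEAK_INHIBITOR if weak
                                      else DependencyClass.STRONG_INHIBITOR)
    return matrix


# -- cycles ----------------------------------------------------------------

def _cycle_sign_products(graph: SignedGraph, cycle: list[str]) -> set[int]:
    """Achievable sign products of a node cycle given parallel-arc choices."""
    signs = graph.sign_sets()
    products = {1}
    for idx, u in enumerate(cycle):
        v = cycle[(idx + 1) % len(cycle)]
        ss = signs.get((u, v))
        if not ss:
            return set()
        products = {p * s for p in products for s in ss}
    return products


def enumerate_feedback_loops(graph: SignedGraph, max_length: int = 8
                             ) -> list[FeedbackLoop]:
    """All signed simple cycles (including self-loops) up to ``max_length``.

    One record per (node cycle, achievable sign); parallel arcs of equal
    sign collapse.  Cycles are canonically rotated to start at their
    smallest node and sorted for deterministic output.
    """
    if max_length < 1:
        raise UsageError("max_length must be >= 1")
    g = nx.DiGraph()
    g.add_nodes_from(graph.nodes)
    g.add_edges_from(graph.sign_sets())
    loops = []
    for cycle in nx.simple_cycles(g, length_bound=max_length):
        k = cycle.index(min(cycle))
        canon = tuple(cycle[k:] + cycle[:k])
        for sign in sorted(_cycle_sign_products(graph, list(canon)),
                           reverse=True):
            loops.append(FeedbackLoop(canon, sign))
    loops.sort(key=lambda l: (len(l.nodes), l.nodes, -l.sign))
    return loops


def nodes_on_negative_cycles(graph: SignedGraph, max_length: int | None = None
                             ) -> set[str]:
    """Nodes lying on at least one simple cycle of negative sign."""
    bound = max_length if max_length is not None else len(graph.nodes)
    out: set[str] = set()
    for loop in enumerate_feedback_loops(graph, max(bound, 1)):
        if loop.is_negative:
            out.update(loop.nodes)
    return out


# -- feed-forward loops ----------------------------------------------------

#: Mangan-Alon type from the indirect-path signs (s_xy, s_yz)
_FFL_TYPE = {(1, 1): 1, (-1, -1): 2, (1, -1): 3, (-1, 1): 4}


def _gate_of(model: LogicalModel, z: str, x: str, s_xz: int,
             y: str, s_yz: int) -> Gate:
    """How z combines its direct (x) and indirect (y) inputs."""
    together = False
    x_alone: set[int] = set()
    y_alone: set[int] = set()
    for term in model.terms_for(z):
        has_x = any(l.component == x and l.sign * term.direction == s_xz
                    for l in term.literals)
        has_y = any(l.component == y and l.sign * term.direction == s_yz
                    for l in term.literals)
        if has_x and has_y:
            together = True
        elif has_x:
            x_alone.add(term.id)
        elif has_y:
            y_alone.add(term.id)
    separate = bool(x_alone) and bool(y_alone)
    if together and separate:
        return Gate.MIXED
    if together:
        return Gate.AND
    if separate:
        return Gate.OR
    return Gate.MIXED


def enumerate_ffls(model: LogicalModel) -> list[FFLRecord]:
    """All feed-forward loops x -> y -> z with a direct arc x -> z.

    Parallel arcs collapse to one record per sign combination; the record
    is coherent iff the direct sign equals the product of the indirect
    signs (the delay-element reading of signalling FFLs).
    """
    graph = interaction_graph(model)
    signs = graph.sign_sets()
    out_nb: dict[str, set[str]] = {n: set() for n in graph.nodes}
    for (u, v) in signs:
        if u != v:
            out_nb[u].add(v)
    records = []
    for x in graph.nodes:
        for y in sorted(out_nb[x]):
            for z in sorted(out_nb[y]):
                if z == x or z not in out_nb[x]:
                    continue
                for s_xy, s_yz, s_xz in itertools.product(
                        sorted(signs[(x, y)], reverse=True),
                        sorted(signs[(y, z)], reverse=True),
                        sorted(signs[(x, z)], reverse=True)):
                    coherent = (s_xz == s_xy * s_yz)
                    records.append(FFLRecord(
                        x=x, y=y, z=z, signs=(s_xy, s_yz, s_xz),
                        coherence=(Coherence.COHERENT if coherent
                                   else Coherence.INCOHERENT),
                        type_index=_FFL_TYPE[(s_xy, s_yz)],
                        gate=_gate_of(model, z, x, s_xz, y, s_yz)))
    records.sort(key=lambda r: (r.x, r.y, r.z, r.signs))
    return records


# -- feedback-loop functionality -------------------------------------------

def _arc_functional(model: LogicalModel, u: str, v: str,
                    context: dict[str, int]) -> bool:
    """Can a level change of u across some threshold change v's resolved
    target, given the external-regulator context?

    Regulators of v that are neither u nor fixed by the context (i.e. other
    loop members, including v itself through self-literals) are quantified
    existentially.
    """
    terms = model.terms_for(v)
    regs: dict[str, None] = {}
    for term in terms:
        for lit in term.literals:
            regs.setdefault(lit.component, None)
    if u not in regs:
        return False
    free = [r for r in regs if r != u and r not in context]
    comp_v = model.components[v]
    base = dict(context)
    for combo in itertools.product(*(model.levels(r) for r in free)):
        base.update(zip(free, combo))
        for t in range(1, model.components[u].max_level + 1):
            levels = []
            for ulevel in (t - 1, t):
                base[u] = ulevel
                levels.append(resolve_target_level(
                    comp_v, [term for term in terms if term.satisfied_by(base)]))
            if levels[0] != levels[1]:
                return True
    return False


def external_regulators(model: LogicalModel, loop: FeedbackLoop) -> tuple[str, ...]:
    loop_nodes = set(loop.nodes)
    regs: dict[str, None] = {}
    for v in loop.nodes:
        for r in model.regulators(v):
            if r not in loop_nodes:
                regs.setdefault(r, None)
    return tuple(regs)


def functionality_context(model: LogicalModel, loop: FeedbackLoop
                          ) -> list[dict[str, int]]:
    """Assignments of the loop's external regulators under which every loop
    arc is functional.  The loop is functional iff the list is non-empty."""
    for node in loop.nodes:
        if node not in model.components:
            raise UsageError(f"loop node {node!r} not in model")
    externals = external_regulators(model, loop)
    contexts = []
    for combo in itertools.product(*(model.levels(r) for r in externals)):
        context = dict(zip(externals, combo))
        if all(_arc_functional(model, u, v, context) for u, v in loop.arcs()):
            contexts.append(context)
    return contexts


def functional_feedback_loops(model: LogicalModel, max_length: int = 8
                              ) -> list[FeedbackLoop]:
    """Feedback loops with a non-empty functionality context, contexts
    attached."""
    graph = interaction_graph(model)
    out = []
    for loop in enumerate_feedback_loops(graph, max_length):
        contexts = functionality_context(model, loop)
        if contexts:
            loop.functionality_contexts = contexts
            out.append(loop)
    return out
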
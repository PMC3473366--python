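"""Independent brute-force oracles used to cross-check the engine.

Everything here is written from the definitions, deliberately ignoring the
package's own algorithms: global-completion enumeration instead of
regulator-local propagation, naive recursive path/cycle search instead of
product-graph BFS, full state-space sweeps instead of constraint search.
Only usable on small models.
"""

from __future__ import annotations

import itertools

from lddr.model import LogicalModel, resolve_target_level

NA = "NA"  # the oracle's own undetermined marker


def _levels(model: LogicalModel, name: str) -> range:
    return range(model.components[name].max_level + 1)


def _target(model, name, state, cutoff):
    terms = [t for t in model.terms_for(name)
             if t.time_scale <= cutoff and t.satisfied_by(state)]
    return resolve_target_level(model.components[name], terms)


def brute_lss(model: LogicalModel, clamps=None, cutoff=3):
    """Forced values by exhaustive enumeration over *all* completions."""
    clamps = clamps or {}
    state = {}
    for name, comp in model.components.items():
        if name in clamps:
            state[name] = clamps[name]
        elif not [t for t in model.terms_for(name) if t.time_scale <= cutoff]:
            state[name] = comp.default_level
        else:
            state[name] = NA
    while True:
        free = [n for n in state if state[n] is NA]
        progressed = False
        for name in free:
            values = set()
            others = [f for f in free]
            for combo in itertools.product(*(_levels(model, o) for o in others)):
                full = dict(state)
                full.update(zip(others, combo))
                values.add(_target(model, name, full, cutoff))
            if len(values) == 1:
                state[name] = values.pop()
                progressed = True
        if not progressed:
            return state


def brute_fixed_points(model: LogicalModel, clamps=None):
    """All total fixed points by sweeping the whole state space."""
    clamps = clamps or {}
    names = list(model.components)
    points = []
    for combo in itertools.product(*(_levels(model, n) for n in names)):
        state = dict(zip(names, combo))
        ok = True
        for name in names:
            if name in clamps:
                if state[name] != clamps[name]:
                    ok = False
                    break
            elif model.is_input(name):
                if state[name] != model.components[name].default_level:
                    ok = False
                    break
            elif _target(model, name, state, 3) != state[name]:
                ok = False
                break
        if ok:
            points.append(state)
    return points


def expected_dependency_class(signs, members, neg_nodes):
    """Pairwise classification straight from the definitions."""
    from lddr.structure import DependencyClass

    if not signs:
        return DependencyClass.NO_EFFECT
    if signs == {1, -1}:
        return DependencyClass.AMBIVALENT
    weak = bool(members & neg_nodes)
    if 1 in signs:
        return (DependencyClass.WEAK_ACTIVATOR if weak
                else DependencyClass.STRONG_ACTIVATOR)
    return (DependencyClass.WEAK_INHIBITOR if weak
            else DependencyClass.STRONG_INHIBITOR)


def arc_sign_sets(model: LogicalModel):
    """(source, target) -> sign set, straight from the definition."""
    out = {}
    for term in model.terms:
        direction = 1 if term.target_level >= 1 else -1
        for lit in term.literals:
            sign = (-1 if lit.negated else 1) * direction
            out.setdefault((lit.component, term.target), set()).add(sign)
    return out


def brute_walk_reachability(model: LogicalModel, max_len=None):
    """Parity reachability by enumerating walks up to 2n steps."""
    signs = arc_sign_sets(model)
    nodes = list(model.components)
    bound = max_len or 2 * len(nodes)
    table = {}
    for start in nodes:
        frontier = {(start, 1)}
        seen = set()
        for _ in range(bound):
            nxt = set()
            for node, sign in frontier:
                for (u, v), ss in signs.items():
                    if u != node:
                        continue
                    for s in ss:
                        item = (v, sign * s)
                        if item not in seen:
                            seen.add(item)
                            nxt.add(item)
            frontier = nxt
            if not frontier:
                break
        for node, sign in seen:
            key = (start, node)
            pos, neg = table.get(key, (False, False))
            table[key] = (pos or sign > 0, neg or sign < 0)
    return table


def brute_simple_paths(model: LogicalModel):
    """Per ordered pair: achievable simple-path signs and path-member sets."""
    signs = arc_sign_sets(model)
    nodes = list(model.components)
    result = {}

    def extend(path, sign):
        node = path[-1]
        for (u, v), ss in signs.items():
            if u != node:
                continue
            for s in ss:
                if v == path[0]:
                    key = (path[0], path[0])
                    entry = result.setdefault(key, (set(), set()))
                    entry[0].add(sign * s)
                    entry[1].update(path)
                elif v not in path:
                    key = (path[0], v)
                    entry = result.setdefault(key, (set(), set()))
                    entry[0].add(sign * s)
                    entry[1].update(path + [v])
                    extend(path + [v], sign * s)

    for start in nodes:
        extend([start], 1)
    return result


def brute_simple_cycles(model: LogicalModel):
    """All signed simple cycles as (canonical node tuple, sign) pairs."""
    signs = arc_sign_sets(model)
    nodes = list(model.components)
    found = set()

    def extend(path, sign):
        node = path[-1]
        for (u, v), ss in signs.items():
            if u != node:
                continue
            for s in ss:
                if v == path[0]:
                    if path[0] == min(path):  # count each rotation once
                        found.add((tuple(path), sign * s))
                elif v not in path and v > path[0]:
                    extend(path + [v], sign * s)

    for start in nodes:
        extend([start], 1)
    return found


def brute_ffl_triples(model: LogicalModel):
    """(x, y, z, s_xy, s_yz, s_xz) sign-combination triples."""
    signs = arc_sign_sets(model)
    nodes = list(model.components)
    out = set()
    for x, y, z in itertools.permutations(nodes, 3):
        for s_xy in signs.get((x, y), ()):
            for s_yz in signs.get((y, z), ()):
                for s_xz in signs.get((x, z), ()):
                    out.add((x, y, z, s_xy, s_yz, s_xz))
    return out


def brute_loop_functional(model: LogicalModel, cycle, context):
    """Is every arc of the node cycle functional somewhere, with the
    external regulators pinned to ``context``?  Full state-space sweep."""
    names = list(model.components)
    arcs = [(cycle[i], cycle[(i + 1) % len(cycle)]) for i in range(len(cycle))]
    for u, v in arcs:
        functional = False
        for combo in itertools.product(*(_levels(model, n) for n in names)):
            state = dict(zip(names, combo))
            if any(state[k] != lv for k, lv in context.items()):
                continue
            if state[u] == 0:
                continue
            lowered = dict(state)
            lowered[u] -= 1
            if _target(model, v, state, 3) != _target(model, v, lowered, 3):
                functional = True
                break
        if not functional:
            return False
    return True


def brute_minimal_intervention_sets(model, scenario, goal_check, candidates,
                                    max_card):
    """Exhaustive subset search + explicit minimality filter."""
    hits = []
    for size in range(1, max_card + 1):
        for combo in itertools.combinations(candidates, size):
            if len({c for c, _ in combo}) != size:
                continue
            if goal_check(model, scenario, dict(combo)):
                hits.append(frozenset(combo))
    if goal_check(model, scenario, {}):
        return []
    return sorted((sorted(h) for h in hits
                   if not any(o < h for o in hits)),
                  key=lambda s: (len(s), s))
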
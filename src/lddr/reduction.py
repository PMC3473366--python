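"""Attractor-preserving model reduction.

A non-autoregulated intermediate can be removed from a logical network by
wiring its regulators directly to its targets: every literal testing the
removed component is replaced by the exact condition on the removed
component's own regulators under which it would have reached the tested
threshold, and the consuming terms are expanded back into sum-of-products
form.  The resolved level of every kept component, as a function of the
kept components, is unchanged.  Autoregulated components are refused —
collapsing a feedback loop below its minimal form (an autoregulation)
could silently destroy attractors.  Removing a component nobody consumes
(e.g. an output outside the focus of a dynamical study) is plain deletion.

Trajectories of the asynchronous dynamics are *not* all preserved — the
reduced state-transition graph may lose paths — but fixed points project
exactly, and the existence of cyclic attractors (no fixed point anywhere)
is preserved, which is what attractor-type arguments need.
"""

from __future__ import annotations

import itertools
from dataclasses import replace
from typing import Iterable, Mapping

from .errors import ReductionError, UsageError
from .model import (Component, Literal, LogicalModel, Term,
                    resolve_target_level)


def is_autoregulated(model: LogicalModel, component: str) -> bool:
    return any(lit.component == component
               for term in model.terms_for(component)
               for lit in term.literals)


def _consumers(model: LogicalModel, component: str) -> list[Term]:
    return [t for t in model.terms
            if any(l.component == component for l in t.literals)]


def _level_condition_minterms(model: LogicalModel, component: str,
                              threshold: int, negated: bool
                              ) -> list[tuple[tuple[Literal, ...], int]]:
    """DNF over the removed component's regulators equivalent to the
    literal ``component >= threshold`` (or its negation).

    Enumerates regulator assignments, keeps those whose resolved level
    satisfies the literal, and emits one minterm per kept assignment (a
    multi-valued variable pinned to level v becomes ``x >= v AND NOT
    x >= v+1``).  Each minterm carries the latest time scale among the
    removed component's terms satisfied under it (a path is as late as its
    latest step); minterms realised purely by the default level carry
    time scale 1.
    """
    regs = list(model.regulators(component))
    comp = model.components[component]
    terms = model.terms_for(component)
    minterms = []
    for combo in itertools.product(*(model.levels(r) for r in regs)):
        assign = dict(zip(regs, combo))
        satisfied = [t for t in terms if t.satisfied_by(assign)]
        level = resolve_target_level(comp, satisfied)
        if (level >= threshold) == negated:
            continue
        lits = []
        for reg, value in assign.items():
            if value >= 1:
                lits.append(Literal(reg, False, value))
            if value < model.components[reg].max_level:
                lits.append(Literal(reg, True, value + 1))
        scale = max((t.time_scale for t in satisfied), default=1)
        minterms.append((tuple(lits), scale))
    return minterms


def _simplify(terms: list[Term]) -> list[Term]:
    """Drop contradictory terms, absorb supersets, merge duplicates.

    No full logic minimisation — absorption and de-duplication keep the
    representation canonical enough for truth-table equality while staying
    predictable.
    """
    cleaned: list[Term] = []
    for term in terms:
        by_comp: dict[str, list[Literal]] = {}
        for lit in term.literals:
            by_comp.setdefault(lit.component, []).append(lit)
        contradictory = False
        kept: list[Literal] = []
        for comp, lits in by_comp.items():
            lower = max((l.threshold for l in lits if not l.negated), default=0)
            upper = min((l.threshold for l in lits if l.negated),
                        default=10 ** 9)
            if lower >= upper:  # x >= a and x < b with b <= a
                contradictory = True
                break
            uniq = {(l.negated, l.threshold): l for l in lits}
            kept.extend(uniq.values())
        if contradictory:
            continue
        cleaned.append(replace(term, literals=tuple(sorted(kept))))
    # absorption: drop any term whose literal set is a superset of another
    # term's (same target and target_level; keep the earlier time scale
    # semantics by preferring the smaller literal set)
    result: list[Term] = []
    for term in cleaned:
        lits = set(term.literals)
        absorbed = False
        for other in cleaned:
            if other is term:
                continue
            if other.target != term.target or \
               other.target_level != term.target_level:
                continue
            olits = set(other.literals)
            if olits < lits or (olits == lits and other.id < term.id):
                absorbed = True
                break
        if not absorbed:
            result.append(term)
    return result


def remove_component(model: LogicalModel, component: str) -> LogicalModel:
    """Remove one component, rewriting the logical functions of its
    targets so that their resolved levels over the kept components are
    unchanged."""
    component = model.resolve(component)
    if model.is_input(component):
        raise ReductionError(f"{component!r} is an input and cannot be removed")
    if component in model.outputs:
        raise ReductionError(f"{component!r} is an output and cannot be removed")
    if is_autoregulated(model, component):
        raise ReductionError(
            f"{component!r} is autoregulated; removing it could destroy "
            "feedback loops and attractors")

    next_id = max((t.id for t in model.terms), default=0) + 1
    new_terms: list[Term] = []
    for term in model.terms:
        if term.target == component:
            continue
        if not any(l.component == component for l in term.literals):
            new_terms.append(term)
            continue
        # substitute each literal on the removed component by its DNF,
        # taking the cross product over multiple such literals
        expansions: list[list[tuple[tuple[Literal, ...], int]]] = []
        rest = []
        for lit in term.literals:
            if lit.component == component:
                expansions.append(_level_condition_minterms(
                    model, component, lit.threshold, lit.negated))
            else:
                rest.append(lit)
        for parts in itertools.product(*expansions):
            lits = list(rest)
            scale = term.time_scale
            for part_lits, part_scale in parts:
                lits.extend(part_lits)
                scale = max(scale, part_scale)
            new_terms.append(Term(next_id, term.target, tuple(sorted(set(lits))),
                                  term.target_level, scale))
            next_id += 1
    new_terms = _simplify(new_terms)
    comps = [c for n, c in model.components.items() if n != component]
    aliases = {a: t for a, t in model.aliases.items() if t != component}
    return LogicalModel(comps, new_terms, model.outputs, aliases)


def prune_component(model: LogicalModel, component: str) -> LogicalModel:
    """Delete a component that no other component consumes (a sink)."""
    component = model.resolve(component)
    if _consumers(model, component):
        raise ReductionError(f"{component!r} has consumers; use "
                             "remove_component to absorb it")
    comps = [c for n, c in model.components.items() if n != component]
    terms = [t for t in model.terms if t.target != component]
    outputs = tuple(o for o in model.outputs if o != component)
    aliases = {a: t for a, t in model.aliases.items() if t != component}
    return LogicalModel(comps, terms, outputs, aliases)


def partial_evaluate(model: LogicalModel, clamps: Mapping[str, int]
                     ) -> LogicalModel:
    """Specialise the model to fixed levels of some components.

    Literals over clamped components are resolved: satisfied literals are
    dropped from their terms, unsatisfied ones delete the term.  A term
    left with no literal is unconditionally satisfied; an unconditional
    inactivation term pins its target to 0 (propagated like a further
    clamp), and an unconditional increase term at level L becomes the new
    basal default, dominating every increase term of level <= L.  The
    clamped components themselves end up as isolated pinned inputs
    (removable by :func:`prune_component` once nothing references them).
    """
    clamps = dict(model.check_clamps(clamps))
    while True:
        new_terms: list[Term] = []
        floor: dict[str, int] = {}   # unconditional increase level per target
        forced_zero: set[str] = set()
        for term in model.terms:
            if term.target in clamps:
                continue
            lits = []
            dead = False
            for lit in term.literals:
                if lit.component in clamps:
                    if not lit.satisfied(clamps[lit.component]):
                        dead = True
                        break
                else:
                    lits.append(lit)
            if dead:
                continue
            if not lits:
                if term.target_level == 0:
                    forced_zero.add(term.target)
                else:
                    floor[term.target] = max(floor.get(term.target, 0),
                                             term.target_level)
                continue
            new_terms.append(replace(term, literals=tuple(lits)))
        if forced_zero:
            # a degradation term fires unconditionally: the target is
            # constant 0; fold it into the clamps and re-resolve
            for name in forced_zero:
                clamps[name] = 0
            continue
        new_terms = [t for t in new_terms
                     if not (t.target in floor and t.target_level >= 1
                             and t.target_level <= floor[t.target])]
        comps = []
        for n, c in model.components.items():
            if n in clamps:
                comps.append(replace(c, default_level=clamps[n]))
            elif n in floor:
                comps.append(replace(c, default_level=floor[n]))
            else:
                comps.append(c)
        return LogicalModel(comps, new_terms, model.outputs, model.aliases)


def reduce_to(model: LogicalModel, keep: Iterable[str],
              clamps: Mapping[str, int] | None = None) -> LogicalModel:
    """Iteratively remove every component outside ``keep``.

    Components are removed in a deterministic order (fewest regulators
    first, ties alphabetical, recomputed each round); unconsumed components
    outside ``keep`` — including outputs outside the focus — are pruned.
    Optional ``clamps`` specialise scenario-fixed components (e.g. an
    unused stimulus) before reduction so that they can be dropped too.
    The reduced model's fixed points are exactly the projections of the
    original's.
    """
    keep_set = {model.resolve(k) for k in keep}
    if clamps:
        model = partial_evaluate(model, clamps)
    while True:
        removable = []
        for name in model.components:
            if name in keep_set:
                continue
            if not _consumers(model, name):
                if is_autoregulated(model, name):
                    raise ReductionError(
                        f"cannot reduce: {name!r} outside the keep set is "
                        "autoregulated")
                removable.append((0, name, "prune"))
            elif not model.is_input(name) and name not in model.outputs \
                    and not is_autoregulated(model, name):
                removable.append((1, name, "absorb"))
            elif model.is_input(name):
                # a stimulus or pinned constant outside the keep set holds
                # its default level forever; fold that level into its
                # consumers, after which it is unconsumed and prunable
                removable.append((2, name, "fold"))
        if not removable:
            break
        removable.sort(key=lambda item: (
            item[0], len(model.regulators(item[1])), item[1]))
        _, name, action = removable[0]
        if action == "prune":
            model = prune_component(model, name)
        elif action == "fold":
            model = partial_evaluate(
                model, {name: model.components[name].default_level})
        else:
            model = remove_component(model, name)
    blockers = [n for n in model.components if n not in keep_set]
    if blockers:
        raise ReductionError(
            "cannot reduce further; blocked on inputs, outputs or "
            f"autoregulated components outside the keep set: {sorted(blockers)}")
    return model
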
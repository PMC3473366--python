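"""Logical steady states under clamps and a time-scale cutoff.

The logical steady state (LSS) is the unique maximal set of *forced*
activity levels: starting from the clamped components and the inputs (which
sit at their clamp or default), a component becomes determined as soon as
its resolved target level is the same under every completion of the current
partial state.  The computation is a monotone closure, so the fixpoint does
not depend on propagation order, and — unlike a seeded sweep from some
arbitrary initial state — it is independent of any updating scheme.
Components entangled in unresolved feedback (e.g. a negative cycle with no
clamp breaking it) simply stay undetermined; the absence of a total LSS is
exactly the structural signature of a cyclic attractor.
"""

from __future__ import annotations

import itertools
from typing import Mapping, Union

from .errors import AnalysisBudgetError, UsageError
from .model import LogicalModel, resolve_target_level


class _Undetermined:
    """Singleton marker for a level that is not forced by the logic."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):
        return "UNDETERMINED"

    def __reduce__(self):
        return (_Undetermined, ())


UNDETERMINED = _Undetermined()

PartialState = dict[str, Union[int, _Undetermined]]

#: regulator sets larger than this cannot be enumerated exhaustively
_MAX_FREE_REGULATORS = 16


def logical_steady_state(model: LogicalModel,
                         clamps: Mapping[str, int] | None = None,
                         timescale_cutoff: int = 3) -> PartialState:
    """Compute the LSS of ``model`` under ``clamps`` at a time-scale cutoff.

    The cutoff is cumulative: ``timescale_cutoff=2`` simulates the network
    before late feedback inhibition (scale-3 interactions) comes into play.
    Returns a mapping from every component to a level or ``UNDETERMINED``.
    """
    if timescale_cutoff not in (1, 2, 3):
        raise UsageError(f"timescale cutoff must be 1, 2, or 3, "
                         f"got {timescale_cutoff}")
    clamps = model.check_clamps(clamps or {})
    active = {t.target: tuple(tt for tt in model.terms_for(t.target)
                              if tt.time_scale <= timescale_cutoff)
              for t in model.terms}

    state: PartialState = {}
    for name, comp in model.components.items():
        if name in clamps:
            state[name] = clamps[name]
        elif not active.get(name):
            # true inputs, and components whose every term lies beyond the
            # cutoff, always resolve to their basal default
            state[name] = comp.default_level
        else:
            state[name] = UNDETERMINED

    changed = True
    while changed:
        changed = False
        for name in model.components:
            if state[name] is not UNDETERMINED:
                continue
            forced = _forced_level(model, name, active[name], state)
            if forced is not None:
                state[name] = forced
                changed = True
    return state


def _forced_level(model: LogicalModel, name, terms, state):
    """Level of ``name`` if its resolved target agrees over all completions
    of the currently undetermined regulators, else None."""
    regs: dict[str, None] = {}
    for term in terms:
        for lit in term.literals:
            if state[lit.component] is UNDETERMINED:
                regs.setdefault(lit.component, None)
    free = list(regs)
    if len(free) > _MAX_FREE_REGULATORS:
        raise AnalysisBudgetError(
            f"component {name!r} has {len(free)} undetermined regulators; "
            "exhaustive completion is not feasible")
    component = model.components[name]
    seen: int | None = None
    local = dict(state)
    for combo in itertools.product(*(model.levels(r) for r in free)):
        local.update(zip(free, combo))
        level = resolve_target_level(
            component, [t for t in terms if t.satisfied_by(local)])
        if seen is None:
            seen = level
        elif level != seen:
            return None
    return seen


def is_total(state: PartialState) -> bool:
    return all(v is not UNDETERMINED for v in state.values())


def determined(state: PartialState) -> dict[str, int]:
    """The determined sub-assignment of a partial state."""
    return {k: v for k, v in state.items() if v is not UNDETERMINED}


def active_terms(model: LogicalModel, state: PartialState, component: str,
                 timescale_cutoff: int = 3) -> list[int]:
    """Ids of the terms feeding ``component`` whose literals are all
    determined-satisfied in ``state``.

    This is the pathway-counting idiom: each OR-term into an output or hub
    is one feeding pathway, and a mutation "blocks" a pathway when its term
    is no longer determined-satisfied.  Undetermined literals count as not
    satisfied (conservative).
    """
    component = model.resolve(component)
    ids = []
    for term in model.terms_for(component):
        if term.time_scale > timescale_cutoff:
            continue
        ok = True
        for lit in term.literals:
            level = state.get(lit.component, UNDETERMINED)
            if level is UNDETERMINED or not lit.satisfied(level):
                ok = False
                break
        if ok:
            ids.append(term.id)
    return ids
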
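"""Minimal intervention sets: clamp combinations achieving declarative goals.

An intervention clamps a component to a fixed level — 0 for a knockout,
knockdown or pharmacological inhibition, a positive level for constitutive
activation.  A goal is a requirement on the logical steady state reached
under the scenario plus the intervention (e.g. "cell cycle arrest forced
off, anti-apoptotic NF-κB forced off, apoptosis onset still forced on").
The search enumerates candidate clamp sets in increasing cardinality with
superset pruning, so exactly the subset-minimal satisfying sets are
reported, in deterministic (size, then lexicographic) order.

If the empty intervention already satisfies the goal — as a studied
mutation sometimes does on its own — no non-empty set is minimal and the
result is empty ("no targets found").
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import UsageError
from .model import LogicalModel
from .steady import UNDETERMINED, logical_steady_state

ClampSet = dict[str, int]


@dataclass(frozen=True)
class GoalSpec:
    """Requirements on the steady state.

    ``require`` maps components to levels that must be *determined* at
    exactly that value (an undetermined component never satisfies a
    requirement).  ``require_any`` lists (component, level) alternatives of
    which at least one must hold.
    """

    require: tuple[tuple[str, int], ...] = ()
    require_any: tuple[tuple[str, int], ...] = ()

    @staticmethod
    def of(require: Mapping[str, int] | None = None,
           require_any: Iterable[tuple[str, int]] = ()) -> "GoalSpec":
        return GoalSpec(tuple(sorted((require or {}).items())),
                        tuple(require_any))

    def satisfied(self, state) -> bool:
        for comp, level in self.require:
            if state.get(comp, UNDETERMINED) is UNDETERMINED or \
                    state[comp] != level:
                return False
        if self.require_any:
            if not any(state.get(c, UNDETERMINED) is not UNDETERMINED
                       and state[c] == lv for c, lv in self.require_any):
                return False
        return True

    def validate(self, model: LogicalModel) -> "GoalSpec":
        entries = []
        for comp, level in self.require:
            canon = model.resolve(comp)
            if not 0 <= level <= model.components[canon].max_level:
                raise UsageError(f"goal level {comp}={level} out of range")
            entries.append((canon, level))
        any_entries = []
        for comp, level in self.require_any:
            canon = model.resolve(comp)
            if not 0 <= level <= model.components[canon].max_level:
                raise UsageError(f"goal level {comp}={level} out of range")
            any_entries.append((canon, level))
        return GoalSpec(tuple(sorted(entries)), tuple(any_entries))


@dataclass(frozen=True)
class InterventionSet:
    clamps: tuple[tuple[str, int], ...]
    minimal: bool = True

    def as_dict(self) -> ClampSet:
        return dict(self.clamps)

    def notation(self) -> str:
        """Rendering in the published table style: removals as the plain
        component name, activations as [level]name, '&'-joined."""
        parts = []
        for comp, level in self.clamps:
            parts.append(comp if level == 0 else f"[{level}]{comp}")
        return " & ".join(parts) if parts else "(none)"


def merge_clamps(model: LogicalModel, scenario: Mapping[str, int],
                 interventions: Mapping[str, int]) -> ClampSet:
    scenario = model.check_clamps(scenario)
    interventions = model.check_clamps(interventions)
    conflict = {c for c in scenario.keys() & interventions.keys()
                if scenario[c] != interventions[c]}
    if conflict:
        raise UsageError(
            f"scenario and intervention clamp {sorted(conflict)} at "
            "different levels")
    merged = dict(scenario)
    merged.update(interventions)
    return merged


def check_goal(model: LogicalModel, scenario_clamps: Mapping[str, int],
               interventions: Mapping[str, int], goal: GoalSpec,
               timescale_cutoff: int = 2) -> bool:
    """Does the steady state under scenario + intervention meet the goal?"""
    goal = goal.validate(model)
    merged = merge_clamps(model, scenario_clamps, interventions)
    state = logical_steady_state(model, merged, timescale_cutoff)
    return goal.satisfied(state)


def default_candidates(model: LogicalModel, *, activations: bool = False,
                       excluded: Iterable[str] = (),
                       scenario_clamps: Mapping[str, int] | None = None
                       ) -> list[tuple[str, int]]:
    """Candidate clamps for an intervention search.

    Removals (clamp to 0) of every non-input, non-output component;
    with ``activations``, additionally constitutive activation at every
    attainable positive level.  Components in ``excluded`` or already
    clamped by the scenario are left alone.
    """
    excluded_set = {model.resolve(e) for e in excluded}
    scen = set((scenario_clamps or {}).keys())
    out: list[tuple[str, int]] = []
    for name, comp in model.components.items():
        if model.is_input(name) or name in model.outputs:
            continue
        if name in excluded_set or name in scen:
            continue
        out.append((name, 0))
        if activations:
            out.extend((name, level) for level in range(1, comp.max_level + 1))
    out.sort()
    return out


def enumerate_mis(model: LogicalModel, scenario_clamps: Mapping[str, int],
                  goal: GoalSpec, max_cardinality: int = 3,
                  allowed: Sequence[tuple[str, int]] | None = None,
                  excluded: Iterable[str] = (),
                  timescale_cutoff: int = 2) -> list[InterventionSet]:
    """All subset-minimal intervention sets of size <= ``max_cardinality``.

    Candidates default to removals of all non-input, non-output components
    not excluded and not already fixed by the scenario.  Sets are explored
    in increasing size; any candidate set containing an already-reported
    set is pruned, which makes the output exactly the subset-minimal
    solutions in deterministic order.
    """
    if max_cardinality < 1:
        raise UsageError("max_cardinality must be >= 1")
    goal = goal.validate(model)
    scenario_clamps = model.check_clamps(scenario_clamps)
    if allowed is None:
        candidates = default_candidates(model, excluded=excluded,
                                        scenario_clamps=scenario_clamps)
    else:
        candidates = sorted((model.resolve(c), lv) for c, lv in allowed)
        excluded_set = {model.resolve(e) for e in excluded}
        candidates = [(c, lv) for c, lv in candidates
                      if c not in excluded_set and c not in scenario_clamps]

    if check_goal(model, scenario_clamps, {}, goal, timescale_cutoff):
        return []  # the scenario alone meets the goal: nothing is minimal

    solutions: list[InterventionSet] = []
    for size in range(1, max_cardinality + 1):
        for combo in itertools.combinations(candidates, size):
            comps = [c for c, _ in combo]
            if len(set(comps)) != size:
                continue  # one clamp per component
            combo_set = set(combo)
            if any(set(sol.clamps) <= combo_set for sol in solutions):
                continue
            if check_goal(model, scenario_clamps, dict(combo), goal,
                          timescale_cutoff):
                solutions.append(InterventionSet(tuple(combo)))
    return solutions
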
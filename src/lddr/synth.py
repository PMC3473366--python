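"""Random multi-valued logical networks with controlled structure.

The generator emulates the structural class of curated signalling models:
mostly Boolean components with a configurable fraction of ternary ones,
sparse sum-of-products functions of one to a few literals, time-scale tags
drawn from a weighted distribution, and optional structural constraints —
forbidding signed cycles of either sign, or planting specific feed-forward
or feedback motifs on dedicated nodes so that motif-enumeration code can
be checked against a known ground truth.

All randomness flows from the single integer seed in the configuration;
identical configurations produce byte-identical serialised models.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Sequence

from .errors import UnsatisfiableConfigError, UsageError
from .model import Component, Literal, LogicalModel, Term, interaction_graph
from .structure import enumerate_feedback_loops


@dataclass(frozen=True)
class PlantedFFL:
    """A feed-forward loop x -> y -> z, x -> z planted on fresh nodes."""

    signs: tuple[int, int, int] = (1, 1, 1)  # (s_xy, s_yz, s_xz)
    gate: str = "AND"  # AND | OR


@dataclass(frozen=True)
class PlantedFL:
    """A feedback loop of a given sign and length on fresh nodes."""

    sign: int = -1
    length: int = 2


@dataclass(frozen=True)
class GeneratorConfig:
    n_components: int = 8
    max_level_fraction: float = 0.0
    n_terms: int = 10
    max_literals_per_term: int = 3
    negation_probability: float = 0.3
    forbid_negative_cycles: bool = False
    forbid_positive_cycles: bool = False
    planted_motifs: tuple = ()
    time_scale_distribution: tuple[float, float, float] = (0.6, 0.3, 0.1)
    seed: int = 0

    def validate(self):
        if self.n_components < 1:
            raise UsageError("n_components must be >= 1")
        if not 0.0 <= self.max_level_fraction <= 1.0:
            raise UsageError("max_level_fraction must be a fraction in [0,1]")
        if not 0.0 <= self.negation_probability <= 1.0:
            raise UsageError("negation_probability must be in [0,1]")
        if self.max_literals_per_term < 1:
            raise UsageError("max_literals_per_term must be >= 1")
        if len(self.time_scale_distribution) != 3 or \
                any(w < 0 for w in self.time_scale_distribution) or \
                sum(self.time_scale_distribution) <= 0:
            raise UsageError("time_scale_distribution needs 3 non-negative "
                             "weights with positive sum")
        for motif in self.planted_motifs:
            if isinstance(motif, PlantedFL):
                if motif.sign == -1 and self.forbid_negative_cycles:
                    raise UnsatisfiableConfigError(
                        "planted negative feedback loop contradicts "
                        "forbid_negative_cycles")
                if motif.sign == 1 and self.forbid_positive_cycles:
                    raise UnsatisfiableConfigError(
                        "planted positive feedback loop contradicts "
                        "forbid_positive_cycles")
                if motif.length < 1:
                    raise UsageError("planted loop length must be >= 1")
            elif not isinstance(motif, PlantedFFL):
                raise UsageError(f"unknown motif spec {motif!r}")


_MAX_ATTEMPTS = 200


def random_model(config: GeneratorConfig) -> LogicalModel:
    """Generate a valid random model honouring the configuration.

    Cycle-sign constraints are enforced structurally where possible (both
    signs forbidden -> topological wiring) and by seeded re-generation
    otherwise; an exhausted retry budget raises, it never returns a
    violating model.
    """
    config.validate()
    rng = random.Random(config.seed)
    for _ in range(_MAX_ATTEMPTS):
        model = _generate_once(config, rng)
        if _acceptable(config, model):
            return model
    raise UnsatisfiableConfigError(
        "could not generate a model honouring the cycle constraints within "
        f"{_MAX_ATTEMPTS} attempts; relax the configuration")


def _generate_once(config: GeneratorConfig, rng: random.Random) -> LogicalModel:
    n = config.n_components
    names = [f"v{idx:02d}" for idx in range(n)]
    n_ternary = round(config.max_level_fraction * n)
    ternary = set(rng.sample(names, n_ternary)) if n_ternary else set()
    components = [Component(name, 2 if name in ternary else 1, 0)
                  for name in names]
    max_level = {c.name: c.max_level for c in components}

    acyclic = config.forbid_negative_cycles and config.forbid_positive_cycles
    terms: list[Term] = []
    term_id = 1
    for _ in range(config.n_terms):
        if acyclic:
            if n < 2:
                break
            tgt_idx = rng.randrange(1, n)
            pool = names[:tgt_idx]
        else:
            tgt_idx = rng.randrange(n)
            pool = names
        target = names[tgt_idx]
        k = min(rng.randint(1, config.max_literals_per_term), len(pool))
        sources = rng.sample(pool, k)
        literals = tuple(sorted(
            Literal(src,
                    negated=rng.random() < config.negation_probability,
                    threshold=rng.randint(1, max_level[src]))
            for src in sources))
        level = rng.randint(1, max_level[target])
        scale = rng.choices((1, 2, 3),
                            weights=config.time_scale_distribution)[0]
        terms.append(Term(term_id, target, literals, level, scale))
        term_id += 1

    # de-duplicate identical literal tuples per target to keep terms tidy
    seen: set[tuple] = set()
    unique_terms = []
    for t in terms:
        key = (t.target, t.literals, t.target_level)
        if key not in seen:
            seen.add(key)
            unique_terms.append(t)

    components, extra = _plant_motifs(config, components, unique_terms,
                                      term_id)
    return LogicalModel(components, unique_terms + extra)


def _plant_motifs(config, components, terms, next_id):
    """Append planted motifs on fresh nodes untouched by the random part,
    so each motif is recovered exactly as specified."""
    extra: list[Term] = []
    comps = list(components)
    counter = 0

    def fresh(prefix):
        nonlocal counter
        name = f"{prefix}{counter:02d}"
        counter += 1
        comps.append(Component(name, 1, 0))
        return name

    for motif in config.planted_motifs:
        if isinstance(motif, PlantedFFL):
            x, y, z = (fresh("m") for _ in range(3))
            s_xy, s_yz, s_xz = motif.signs
            extra.append(Term(next_id, y, (Literal(x, s_xy < 0),), 1, 1))
            next_id += 1
            if motif.gate == "AND":
                extra.append(Term(next_id, z,
                                  tuple(sorted((Literal(x, s_xz < 0),
                                                Literal(y, s_yz < 0)))), 1, 1))
                next_id += 1
            elif motif.gate == "OR":
                extra.append(Term(next_id, z, (Literal(y, s_yz < 0),), 1, 1))
                next_id += 1
                extra.append(Term(next_id, z, (Literal(x, s_xz < 0),), 1, 1))
                next_id += 1
            else:
                raise UsageError(f"unknown FFL gate {motif.gate!r}")
        else:  # PlantedFL
            nodes = [fresh("f") for _ in range(motif.length)]
            for idx, node in enumerate(nodes):
                succ = nodes[(idx + 1) % len(nodes)]
                negate = (motif.sign < 0 and idx == 0)
                extra.append(Term(next_id, succ, (Literal(node, negate),), 1, 1))
                next_id += 1
    return comps, extra


def _acceptable(config: GeneratorConfig, model: LogicalModel) -> bool:
    if not (config.forbid_negative_cycles or config.forbid_positive_cycles):
        return True
    graph = interaction_graph(model)
    for loop in enumerate_feedback_loops(graph, len(graph.nodes)):
        planted = all(n.startswith(("f",)) and n[1:].isdigit()
                      for n in loop.nodes)
        if planted:
            continue
        if loop.sign < 0 and config.forbid_negative_cycles:
            return False
        if loop.sign > 0 and config.forbid_positive_cycles:
            return False
    return True


def state_sampler(model: LogicalModel, n: int, seed: int = 0
                  ) -> list[dict[str, int]]:
    """Uniform i.i.d. samples over the full state space, seed-reproducible."""
    if n < 1:
        raise UsageError("n must be >= 1")
    rng = random.Random(seed)
    names = list(model.components)
    return [{name: rng.randint(0, model.components[name].max_level)
             for name in names} for _ in range(n)]
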
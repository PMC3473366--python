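import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from lddr.model import Component, Literal, LogicalModel, Term


def build_model(n_comps, term_specs, *, max_levels=None, defaults=None,
                outputs=()):
    """Compact model builder for tests.

    ``term_specs``: iterable of (target, [(comp, negated, threshold), ...],
    target_level, time_scale).
    """
    max_levels = max_levels or {}
    defaults = defaults or {}
    names = [chr(ord("A") + i) for i in range(n_comps)]
    comps = [Component(n, max_levels.get(n, 1), defaults.get(n, 0))
             for n in names]
    terms = [Term(i + 1, tgt,
                  tuple(Literal(c, neg, thr) for c, neg, thr in lits),
                  level, scale)
             for i, (tgt, lits, level, scale) in enumerate(term_specs)]
    return LogicalModel(comps, terms, outputs)


@pytest.fixture
def chain_abc():
    """A -> B -> C, the C arc on the late time scale."""
    return build_model(3, [
        ("B", [("A", False, 1)], 1, 1),
        ("C", [("B", False, 1)], 1, 3),
    ])


@pytest.fixture
def negative_two_cycle():
    """A -> B, B -| A: the minimal oscillator."""
    return build_model(2, [
        ("B", [("A", False, 1)], 1, 1),
        ("A", [("B", True, 1)], 1, 1),
    ])


@pytest.fixture
def ikba_cascade():
    """Ternary IKK/IκBα fragment: basal IKK partially degrades the
    inhibitor, genotoxic IKK degrades it fully."""
    return LogicalModel(
        [Component("IKK", 2, 1), Component("IkBa", 2, 2)],
        [Term(67, "IkBa", (Literal("IKK", False, 1),), 1, 1),
         Term(68, "IkBa", (Literal("IKK", False, 2),), 0, 1)])


def random_small_model(seed, n=6, terms=8, ternary=0.25, negp=0.35):
    from lddr.synth import GeneratorConfig, random_model

    return random_model(GeneratorConfig(
        n_components=n, n_terms=terms, max_level_fraction=ternary,
        negation_probability=negp, seed=seed))
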
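"""DNA-damage-response models, scenarios, and headline analyses.

Two models live here.

* :func:`core_model` — the six-component core of the damage response used
  for attractor analysis: the stimulus ``DSBs_early``, the late lesion pool
  ``DSBs_late``, the sensor-kinase complexes ``RPA-ATR-ATRIP-P`` and
  ``ATM-P``, and the two master transcription factors ``p53-P`` and nuclear
  NF-κB (``nuclear_p50-p65-P``).  Late feedback (Wip1- and MDM2-type
  dephosphorylation/degradation, and IκBα resynthesis) is folded into
  negative arcs and self-loops on the kept components, which is what an
  attractor-preserving reduction of the curated network produces.  Under
  the damage-response priority scheme the wildtype core cycles through a
  complex attractor, while constitutive p53 — or losing p53 while fixing
  NF-κB on — freezes the network in a logical steady state.

* :func:`synthetic_ddr_network` — a mid-scale DDR subnetwork assembled
  from well-documented mechanisms (MRN/ATM and RPA/ATR sensing, Chk1/Chk2
  checkpoint kinases, the Cdc25 axis, p53 with its late negative
  regulators, and the genotoxic NF-κB branch with ternary IKK and IκBα).
  It is a synthetic stand-in for the full curated 96-component network,
  whose complete function list is not bundled; it exists so that scenario
  comparisons, pathway counting and intervention searches run end-to-end
  on realistic structure.  :func:`load_full_model` validates a
  user-supplied transcription of the full curated network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .dynamics import (DECREASE, INCREASE, Attractor, PriorityScheme,
                       build_stg, find_attractors)
from .errors import ModelValidationError, TranscriptionMissingError, UsageError
from .intervention import (GoalSpec, InterventionSet, default_candidates,
                           enumerate_mis)
from .model import Component, Literal, LogicalModel, Term, parse_model
from .steady import (UNDETERMINED, PartialState, active_terms,
                     logical_steady_state)

ARREST = "CELL CYCLE ARREST"
APOPTOSIS = "ONSET OF APOPTOSIS"
NFKB = "nuclear_p50-p65-P"

_CORE_ORDER = ("DSBs_early", "DSBs_late", "RPA-ATR-ATRIP-P", "ATM-P",
               "p53-P", NFKB)


def core_model() -> LogicalModel:
    """Six-component core of the damage response (Boolean, damage-driven).

    Negative feedback enters as reduced arcs: active p53 shuts down its
    own phosphorylation and the upstream sensor kinases (the Wip1/MDM2
    layer), and nuclear NF-κB shuts down its own nuclear activity (the
    IκBα resynthesis layer).
    """
    d_early, d_late, rpa, atm, p53, nfkb = _CORE_ORDER
    components = [Component(name, 1, 0) for name in _CORE_ORDER]
    terms = [
        Term(1, d_late, (Literal(d_early),), 1, 2),
        Term(2, atm, (Literal(d_early), Literal(p53, True)), 1, 1),
        Term(3, rpa, (Literal(d_late), Literal(p53, True)), 1, 1),
        Term(4, p53, (Literal(atm), Literal(p53, True)), 1, 1),
        Term(5, p53, (Literal(rpa), Literal(p53, True)), 1, 1),
        Term(6, nfkb, (Literal(atm), Literal(nfkb, True)), 1, 1),
    ]
    return LogicalModel(components, terms,
                        aliases={"p50-p65-P": nfkb, "NF-kB": nfkb})


#: Clamps defining the five studied variants of the core network.
CORE_VARIANTS: dict[str, dict[str, int]] = {
    "wildtype": {},
    "nfkb_constitutive": {NFKB: 1},
    "p53_deficient": {"p53-P": 0},
    "p53_deficient_nfkb_constitutive": {"p53-P": 0, NFKB: 1},
    "p53_constitutive": {"p53-P": 1},
}


def ddr_priority_scheme() -> PriorityScheme:
    """The damage-response priority scheme.

    Rank 1: activation of the sensor kinases and of the two transcription
    factors (the immediate response); rank 2: maturation of early into
    late lesions; rank 3: the feedback-driven shut-off (deactivations) of
    the rank-1 components.  Everything else shares the implicit lowest
    rank.
    """
    d_early, d_late, rpa, atm, p53, nfkb = _CORE_ORDER
    fast = (rpa, atm, p53, nfkb)
    return PriorityScheme((
        frozenset((c, INCREASE) for c in fast),
        frozenset({(d_late, INCREASE)}),
        frozenset((c, DECREASE) for c in fast),
    ), name="ddr_core")


def damage_initial_state(model: LogicalModel,
                         clamps: Mapping[str, int] | None = None
                         ) -> dict[str, int]:
    """Damage-on initial condition: the early-DSB stimulus present, every
    other component at its default (or clamped) level."""
    state = model.default_state()
    state["DSBs_early"] = 1
    for comp, level in (clamps or {}).items():
        state[model.resolve(comp)] = level
    return state


def core_attractors(variant: str = "wildtype") -> list[Attractor]:
    """Attractors of a core-model variant reachable from the damage-on
    state under the damage-response priority scheme."""
    if variant not in CORE_VARIANTS:
        raise UsageError(f"unknown core variant {variant!r}; choose from "
                         f"{sorted(CORE_VARIANTS)}")
    clamps = CORE_VARIANTS[variant]
    model = core_model().with_clamps(clamps)
    initial = damage_initial_state(model, clamps)
    stg = build_stg(model, [initial], ddr_priority_scheme())
    return find_attractors(stg)


def core_attractor_table() -> dict[str, dict]:
    """Attractor census of all five core variants (kind, count, size)."""
    table = {}
    for variant in CORE_VARIANTS:
        attractors = core_attractors(variant)
        table[variant] = {
            "n_attractors": len(attractors),
            "kinds": [a.kind.value for a in attractors],
            "sizes": [len(a) for a in attractors],
        }
    return table


# ---------------------------------------------------------------------------
# the synthetic mid-scale DDR subnetwork
# ---------------------------------------------------------------------------

def synthetic_ddr_network() -> LogicalModel:
    """A synthetic mid-scale DDR subnetwork (27 components).

    Synthetic stand-in for the full curated 96-component network: it wires
    the textually documented mechanisms — MRN-dependent ATM activation
    with its ternary low/high activity, RPA-ATR-ATRIP sensing of SSBs and
    of resected late DSBs, Chk1/Chk2 converging on Cdc25A degradation,
    p53 activation by three kinases with late Wip1/MDM2 feedback, the
    genotoxic IKK/IκBα/NF-κB branch with ternary IKK and IκBα, and
    p53-dependent (Ser46) plus PIDDosome- and E2F-1-mediated routes into
    apoptosis onset — but its
    exact function list is this package's own curation, not a transcription.
    """
    ikba = "IκBα"
    comps = [
        Component("SSBs", 1, 0, "stimulus: single-strand breaks (TOPI inhibition)"),
        Component("DSBs_early", 1, 0, "stimulus: double-strand breaks"),
        Component("DSBs_late", 1, 0, "late lesions: persistent/resected breaks"),
        Component("MRN", 1, 0, "Mre11-Rad50-Nbs1 sensor complex at DSBs"),
        Component("Hsp90", 1, 1, "chaperone stabilising signalling kinases"),
        Component("PP5", 1, 0, "phosphatase required for ATM/ATR signalling"),
        Component("PP2A", 1, 1, "basal ATM-antagonising phosphatase"),
        Component("ATM-P", 2, 0, "-P = phosphorylation; 1 = low, 2 = high activity"),
        Component("Chk2-P", 1, 0),
        Component("RPA-ATR-ATRIP-P", 1, 0, "ssDNA sensor kinase complex"),
        Component("claspin-P", 1, 0, "mediator required for Chk1 activation"),
        Component("Chk1-P", 1, 0),
        Component("Cdc25A_degradation", 1, 0, "checkpoint-induced Cdc25A turnover"),
        Component("Cdc25C-P", 1, 0, "inhibitory Cdc25C phosphorylation"),
        Component("p53-P", 1, 0),
        Component("Wip1", 1, 0, "late p53-induced phosphatase (feedback)"),
        Component("MDM2", 1, 0, "late p53-induced ubiquitin ligase (feedback)"),
        Component("HIPK2", 1, 1, "kinase for pro-apoptotic p53 Ser46 site"),
        Component("p53-PS46", 1, 0, "pro-apoptotic p53 species"),
        Component("p21", 1, 0, "CDK inhibitor, p53 target"),
        Component("TAK1-P", 1, 0),
        Component("c-Myc", 1, 1, "cell-cycle-promoting TF, damage-repressed"),
        Component("E2F-1-P", 1, 0, "Chk2-stabilised pro-apoptotic TF"),
        Component("IKK_complex-P", 2, 1, "1 = basal, 2 = genotoxic activity"),
        Component(ikba, 2, 2, "2 = full pool, 1 = partial, 0 = degraded"),
        Component("c-Rel", 1, 0, "NF-κB species active at basal IKK"),
        Component(NFKB, 1, 0, "anti-apoptotic nuclear NF-κB dimer"),
        Component("CELL CYCLE ARREST", 1, 0, "output"),
        Component(APOPTOSIS, 1, 0, "output"),
        Component("PIDD", 1, 0, "p53-induced protein with a death domain"),
        Component("PIDD-RAIDD-caspase2", 1, 0,
                  "PIDDosome: p53-independent apoptotic initiator"),
    ]
    L = Literal
    terms = [
        # lesion processing
        Term(101, "DSBs_late", (L("DSBs_early"),), 1, 2),
        Term(102, "DSBs_late", (L("SSBs"),), 1, 2),   # replication-fork collapse
        Term(137, "PP5", (L("Hsp90"),), 1, 1),
        Term(103, "MRN", (L("DSBs_early"),), 1, 1),
        Term(104, "MRN", (L("DSBs_late"),), 1, 1),
        # ATM activation: low activity silences PP2A, enabling high activity
        Term(22, "PP2A", (L("ATM-P", threshold=1),), 0, 1),
        Term(105, "ATM-P", (L("MRN"), L("PP5"), L("Wip1", True)), 1, 1),
        Term(23, "ATM-P", (L("MRN"), L("PP5"), L("Wip1", True)), 2, 1),
        Term(21, "ATM-P", (L("Wip1"),), 0, 3),
        # checkpoint kinases
        Term(25, "Chk2-P", (L("ATM-P", threshold=2), L("Wip1", True)), 1, 1),
        Term(106, "Chk2-P", (L("Wip1"),), 0, 3),
        Term(107, "RPA-ATR-ATRIP-P", (L("SSBs"), L("PP5")), 1, 1),
        Term(108, "RPA-ATR-ATRIP-P",
             (L("DSBs_late"), L("ATM-P", threshold=2), L("PP5")), 1, 1),
        Term(109, "claspin-P", (L("RPA-ATR-ATRIP-P"), L("Wip1", True)), 1, 1),
        Term(110, "claspin-P", (L("Wip1"),), 0, 3),
        Term(111, "Chk1-P",
             (L("RPA-ATR-ATRIP-P"), L("claspin-P"), L("Wip1", True)), 1, 1),
        Term(112, "Chk1-P", (L("Wip1"),), 0, 3),
        # cell-cycle machinery
        Term(113, "Cdc25A_degradation", (L("Chk1-P"),), 1, 1),
        Term(114, "Cdc25A_degradation", (L("Chk2-P"),), 1, 1),
        Term(115, "Cdc25C-P", (L("Chk2-P"),), 1, 1),
        # p53 and its late feedback
        Term(31, "p53-P",
             (L("ATM-P", threshold=2), L("Wip1", True), L("MDM2", True)), 1, 1),
        Term(116, "p53-P",
             (L("Chk2-P"), L("Wip1", True), L("MDM2", True)), 1, 1),
        Term(117, "p53-P",
             (L("Chk1-P"), L("Wip1", True), L("MDM2", True)), 1, 1),
        Term(118, "p53-P", (L("Wip1"),), 0, 3),
        Term(119, "p53-P", (L("MDM2"),), 0, 3),
        Term(82, "Wip1", (L("p53-P"),), 1, 3),
        Term(120, "MDM2", (L("p53-P"),), 1, 3),
        Term(121, "p53-PS46", (L("p53-P"), L("HIPK2")), 1, 1),
        Term(122, "p21", (L("p53-P"),), 1, 2),
        # TAK1 and c-Myc downregulation
        Term(124, "TAK1-P", (L("ATM-P", threshold=2),), 1, 1),
        Term(123, "c-Myc", (L("TAK1-P"),), 0, 1),
        Term(125, "E2F-1-P", (L("Chk2-P"),), 1, 1),
        # genotoxic NF-κB branch (ternary IKK and IκBα)
        Term(126, "IKK_complex-P",
             (L("TAK1-P"), L("ATM-P", threshold=2)), 2, 1),
        Term(67, ikba, (L("IKK_complex-P", threshold=1),), 1, 1),
        Term(68, ikba, (L("IKK_complex-P", threshold=2),), 0, 1),
        Term(128, ikba,
             (L(NFKB), L("IKK_complex-P", True, 2)), 2, 3),
        Term(129, "c-Rel", (L(ikba, True, 2),), 1, 1),
        Term(69, NFKB, (L(ikba, True, 1),), 1, 1),
        # outputs
        Term(130, ARREST, (L("p21"),), 1, 2),
        Term(131, ARREST, (L("Cdc25A_degradation"),), 1, 2),
        Term(132, ARREST, (L("Cdc25C-P"),), 1, 2),
        Term(133, ARREST, (L("c-Myc", True),), 1, 2),
        Term(134, APOPTOSIS, (L("p53-PS46"),), 1, 2),
        Term(135, APOPTOSIS, (L("E2F-1-P"),), 1, 2),
        Term(136, APOPTOSIS, (L("PIDD-RAIDD-caspase2"),), 1, 2),
        Term(138, "PIDD", (L("DSBs_late"),), 1, 1),
        Term(43, "PIDD-RAIDD-caspase2", (L("PIDD"),), 1, 2),
    ]
    aliases = {
        "IkappaBalpha": ikba,
        "CELL_CYCLE_ARREST": ARREST,
        "ONSET_OF_APOPTOSIS": APOPTOSIS,
        "p50-p65-P": NFKB,
    }
    return LogicalModel(comps, terms, outputs=(ARREST, APOPTOSIS),
                        aliases=aliases)


# ---------------------------------------------------------------------------
# scenarios and comparison reports
# ---------------------------------------------------------------------------

#: protein named in a scenario -> clamped model component
MUTATION_TARGETS = {
    "ATM": "ATM-P",
    "ATR": "RPA-ATR-ATRIP-P",
    "Chk1": "Chk1-P",
    "Chk2": "Chk2-P",
    "TAK1": "TAK1-P",
    "p53": "p53-P",
    "HIPK2": "HIPK2",
    "Mre11": "MRN",
    "Nbs1": "MRN",
    "Rad50": "MRN",
}

_STIMULI = {
    "ssb": {"SSBs": 1, "DSBs_early": 0},
    "dsb": {"DSBs_early": 1, "SSBs": 0},
    "both": {"SSBs": 1, "DSBs_early": 1},
}


@dataclass(frozen=True)
class Scenario:
    name: str
    input_clamps: tuple[tuple[str, int], ...]
    mutation_clamps: tuple[tuple[str, int], ...] = ()
    cutoff: int = 2
    description: str = ""

    @property
    def clamps(self) -> dict[str, int]:
        return {**dict(self.input_clamps), **dict(self.mutation_clamps)}

    @staticmethod
    def of(name, inputs: Mapping[str, int], mutations: Mapping[str, int] = (),
           cutoff: int = 2, description: str = "") -> "Scenario":
        return Scenario(name, tuple(sorted(inputs.items())),
                        tuple(sorted(dict(mutations).items())), cutoff,
                        description)


def scenario_registry() -> dict[str, Scenario]:
    """Named, reproducible scenarios.

    Single-protein losses under each single stimulus; the same losses in a
    p53-deficient background; genetic disorders (simultaneous SSBs and
    DSBs, with a feedback view at cutoff 3); and the carcinogenesis
    baseline with both stimuli and no mutation.
    """
    registry: dict[str, Scenario] = {}
    for stim, inputs in _STIMULI.items():
        registry[f"wildtype_{stim}"] = Scenario.of(
            f"wildtype_{stim}", inputs, {},
            description=f"no mutation, {stim.upper()} stimulus")
    for protein in ("ATM", "ATR", "Chk1", "Chk2", "TAK1", "p53", "HIPK2"):
        for stim in ("ssb", "dsb"):
            name = f"{protein}_loss_{stim}"
            registry[name] = Scenario.of(
                name, _STIMULI[stim], {MUTATION_TARGETS[protein]: 0},
                description=f"loss of {protein}, {stim.upper()} stimulus")
    for protein in ("ATM", "Chk1", "Chk2"):
        for stim in ("ssb", "dsb"):
            name = f"p53_{protein}_loss_{stim}"
            registry[name] = Scenario.of(
                name, _STIMULI[stim],
                {"p53-P": 0, MUTATION_TARGETS[protein]: 0},
                description=f"p53-deficient plus loss of {protein}, "
                            f"{stim.upper()} stimulus")
    disorders = {
        "ataxia_telangiectasia": "ATM",
        "atm_like_disorder": "Mre11",
        "nijmegen_breakage_syndrome": "Nbs1",
        "nbs_like_disorder": "Rad50",
        "atr_seckel": "ATR",
    }
    for name, protein in disorders.items():
        registry[name] = Scenario.of(
            name, _STIMULI["both"], {MUTATION_TARGETS[protein]: 0},
            description=f"genetic disorder: dysfunctional {protein}, "
                        "both stimuli")
    registry["carcinogenesis_baseline"] = Scenario.of(
        "carcinogenesis_baseline", _STIMULI["both"], {},
        description="no mutation, both stimuli (defect search baseline)")
    return registry


#: hubs whose pathway counts the comparison report tracks besides outputs
WATCHED_HUBS = (NFKB, "p53-P", "Cdc25A_degradation")


@dataclass
class ComparisonReport:
    scenario: str
    reference: str
    level_changes: dict[str, tuple[object, object]]
    pathway_counts: dict[str, tuple[int, int]]
    verdicts: list[str] = field(default_factory=list)


def _fmt_level(v) -> object:
    return "NA" if v is UNDETERMINED else v


def compare(model: LogicalModel, scenario: Scenario,
            reference: Scenario | None = None) -> ComparisonReport:
    """Steady-state comparison of a scenario against a reference.

    The reference defaults to the unmutated model under the same stimulus
    and cutoff.  Verdict strings follow the validation-table vocabulary:
    a component active in the reference and forced to 0 is "blocked"; one
    still attainable but fed by fewer intact pathways is "diminished".
    """
    if reference is None:
        reference = Scenario.of(f"{scenario.name}__reference",
                                dict(scenario.input_clamps), {},
                                scenario.cutoff)
    ref_state = logical_steady_state(model, reference.clamps, reference.cutoff)
    scen_state = logical_steady_state(model, scenario.clamps, scenario.cutoff)

    level_changes = {
        name: (_fmt_level(ref_state[name]), _fmt_level(scen_state[name]))
        for name in model.components if ref_state[name] != scen_state[name]}

    watched = [h for h in (*model.outputs, *WATCHED_HUBS)
               if h in model.components]
    pathway_counts = {}
    verdicts = []
    for hub in dict.fromkeys(watched):
        n_ref = len(active_terms(model, ref_state, hub, scenario.cutoff))
        n_scen = len(active_terms(model, scen_state, hub, scenario.cutoff))
        pathway_counts[hub] = (n_ref, n_scen)
        ref_on = ref_state[hub] is not UNDETERMINED and ref_state[hub] >= 1
        scen_off = scen_state[hub] == 0
        scen_on = scen_state[hub] is not UNDETERMINED and scen_state[hub] >= 1
        if ref_on and scen_off:
            verdicts.append(f"{hub} blocked")
        elif ref_on and scen_on and n_scen < n_ref:
            verdicts.append(f"{hub} diminished ({n_ref} -> {n_scen} pathways)")
    return ComparisonReport(scenario.name, reference.name, level_changes,
                            pathway_counts, verdicts)


# ---------------------------------------------------------------------------
# goals and headline searches
# ---------------------------------------------------------------------------

def sensitization_goal(model: LogicalModel) -> GoalSpec:
    """Block cell-cycle arrest and anti-apoptotic NF-κB while keeping the
    apoptosis-onset output switched on."""
    return GoalSpec.of({ARREST: 0, NFKB: 0, APOPTOSIS: 1}).validate(model)


def carcinogenesis_goal(model: LogicalModel) -> GoalSpec:
    """Both protective outputs forced off despite damage."""
    return GoalSpec.of({ARREST: 0, APOPTOSIS: 0}).validate(model)


#: Lesion-processing pseudo-components are neither drug targets nor genes;
#: searches exclude them by default (extend with model-specific exclusion
#: lists of biologically unsuitable targets, cf. the bundled templates).
LESION_NODES = ("DSBs_late",)


def sensitization_target_search(model: LogicalModel, scenario: Scenario,
                                excluded=LESION_NODES, max_cardinality: int = 3
                                ) -> list[InterventionSet]:
    """Candidate sensitization targets for one tumour scenario: minimal
    removal sets achieving the sensitization goal at time scale 2."""
    return enumerate_mis(model, scenario.clamps, sensitization_goal(model),
                         max_cardinality=max_cardinality, excluded=excluded,
                         timescale_cutoff=2)


def carcinogenic_defect_search(model: LogicalModel, excluded=LESION_NODES,
                               max_cardinality: int = 3
                               ) -> list[InterventionSet]:
    """Combinations of constitutive activations and inactivations that
    silence both protective outputs under simultaneous SSBs and DSBs."""
    scenario = scenario_registry()["carcinogenesis_baseline"]
    candidates = default_candidates(model, activations=True,
                                    excluded=excluded,
                                    scenario_clamps=scenario.clamps)
    return enumerate_mis(model, scenario.clamps, carcinogenesis_goal(model),
                         max_cardinality=max_cardinality, allowed=candidates,
                         timescale_cutoff=2)


# ---------------------------------------------------------------------------
# the full curated network (user-supplied transcription)
# ---------------------------------------------------------------------------

FULL_MODEL_COMPONENTS = 96
FULL_MODEL_TERMS = 98
TERNARY_COMPONENTS = frozenset({"ATM-P", "IKK-complex-P", "IκBα"})


def load_full_model(path) -> LogicalModel:
    """Load and validate a transcription of the full curated DDR network.

    The published function list (96 components, 98 interactions, ternary
    ATM-P / IKK-complex-P / IκBα) is distributed as supplementary material
    of the original study and is not bundled here; transcribe it into the
    native JSON format (see ``data/full_model_transcription_README.txt``)
    and point this loader at the file.
    """
    path = Path(path)
    if not path.exists():
        raise TranscriptionMissingError(
            f"no transcription at {path}; transcribe the full curated "
            "network into the native JSON format first (see "
            "data/full_model_transcription_README.txt)")
    model = parse_model(path.read_text(encoding="utf-8"))
    failures = []
    if len(model.components) != FULL_MODEL_COMPONENTS:
        failures.append(f"expected {FULL_MODEL_COMPONENTS} components, "
                        f"found {len(model.components)}")
    if len(model.terms) != FULL_MODEL_TERMS:
        failures.append(f"expected {FULL_MODEL_TERMS} interactions, "
                        f"found {len(model.terms)}")
    ternary = {n for n, c in model.components.items() if c.max_level == 2}
    if ternary != set(TERNARY_COMPONENTS):
        failures.append(
            f"ternary components must be exactly {sorted(TERNARY_COMPONENTS)}, "
            f"found {sorted(ternary)}")
    if failures:
        raise ModelValidationError(failures)
    return model
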
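# lddr — logical modelling of the DNA damage response

`lddr` is a discrete logical-modelling engine for signalling networks,
built around the DNA damage response (DDR): the network that decides,
after single- or double-strand DNA breaks (SSBs/DSBs), between cell cycle
arrest, anti-apoptotic NF-κB signalling, and the onset of apoptosis.  It
is aimed at systems biologists who want to analyse curated multi-valued
logical models — and at the tumour-sensitization question specifically:
which protein inhibitions disable a tumour's survival pathways while
leaving an apoptotic route intact?

## The formalism

A network is a set of components `x_i` with discrete activity levels
`0..max_i` (`max_i = 1` for Boolean components, `2` for ternary ones such
as ATM-P, whose low and high activities phosphorylate different
substrates).  The logical functions are sums of products: each
interaction is an AND-conjunction of threshold literals `[¬] x_j ≥ θ`
that is sufficient to drive its target to a stated level; alternative
interactions on one target are OR-connected, an explicit level-0
interaction models induced degradation and overrides, and otherwise the
highest satisfied level wins, with a basal default when nothing fires.
Each interaction carries a time-scale tag 1–3 (early signalling,
effector events, late feedback shut-off).

On this structure the package computes:

* **Logical steady states (LSS)** — the unique maximal partial state
  forced by the functions under clamps at a time-scale cutoff,
  independent of any updating scheme (`lddr.steady`).
* **Interaction-graph analyses** — the signed graph from splitting every
  interaction into arcs; the dependency matrix classifying every ordered
  pair as strong/weak activator/inhibitor, ambivalent, or no effect;
  feed-forward loops with coherence type 1–4 and AND/OR gate; feedback
  loops with sign and *functionality contexts* (`lddr.structure`).
* **Asynchronous dynamics with priority classes** — state-transition
  graphs where the highest-ranked (component, direction) transitions
  preempt slower ones; attractors as terminal strongly connected
  components, classified as steady state, simple loop, or complex loop;
  plus a symbolic fixed-point search that needs no state enumeration
  (`lddr.dynamics`).
* **Attractor-preserving reduction** — removal of non-autoregulated
  intermediates with exact rewriting of the consumers' functions
  (`lddr.reduction`).
* **Minimal intervention sets** — subset-minimal clamp combinations
  (knockouts, constitutive activations) achieving a goal on the steady
  state, e.g. "arrest off, NF-κB off, apoptosis on" (`lddr.intervention`).
* **Random model generation** — seeded multi-valued networks with
  controlled cycle signs and planted motifs, used throughout the test
  suite as ground truth (`lddr.synth`).

`lddr.ddr` ships two concrete models: the six-component damage-response
core (stimulus, late lesions, RPA-ATR-ATRIP, ATM, p53, nuclear NF-κB,
with the late negative-feedback layers folded in) and a 31-component
synthetic DDR subnetwork — a stand-in for the full 96-component curated
network, whose published function list must be transcribed separately
(see `src/lddr/data/full_model_transcription_README.txt`).

## Worked example

```python
>>> from lddr.ddr import (core_attractors, synthetic_ddr_network,
...                       scenario_registry, compare,
...                       sensitization_target_search)
>>> [a.kind.value for a in core_attractors("wildtype")]
['COMPLEX_LOOP']
>>> [a.kind.value for a in core_attractors("p53_constitutive")]
['STEADY_STATE']
```

Under damage the wildtype core never settles: the Wip1/MDM2-type p53
feedback and the IκBα-type NF-κB feedback keep it in a single complex
cyclic attractor (16 states), whereas constitutive p53 shuts the sensor
kinases down into a unique logical steady state.

```python
>>> model = synthetic_ddr_network()
>>> registry = scenario_registry()
>>> compare(model, registry["ATM_loss_dsb"]).verdicts
['CELL CYCLE ARREST blocked', 'ONSET OF APOPTOSIS diminished (3 -> 1 pathways)',
 'nuclear_p50-p65-P blocked', 'p53-P blocked', 'Cdc25A_degradation blocked']
>>> [s.notation() for s in
...  sensitization_target_search(model, registry["HIPK2_loss_dsb"])]
['ATM-P', 'MRN', 'PP5']
```

Losing ATM under DSBs blocks every survival readout while one apoptotic
route (the PIDDosome) stays intact — which is why the ATM-deficient DSB
scenario needs no further sensitization target at all — and an
HIPK2-mutant tumour under DSBs can be sensitized by inhibiting any of
ATM, the MRN sensor complex, or the phosphatase PP5.

The same analyses are available from the shell:

```sh
lddr ddr core-attractors
lddr ddr report ATM_loss_dsb
lddr lss src/lddr/data/ddr_synthetic_subnetwork.json \
     --clamp DSBs_early=1 --timescale 2
lddr mis src/lddr/data/ddr_synthetic_subnetwork.json \
     --clamp p53-P=0 --clamp DSBs_early=1 \
     --goal CELL_CYCLE_ARREST=0 --goal nuclear_p50-p65-P=0 \
     --goal ONSET_OF_APOPTOSIS=1
```

## Layout

    src/lddr/          engine modules + bundled model fixtures (data/)
    tests/             pytest suite with independent brute-force oracles
    scripts/           acceptance script
    docs/methods.md    modelling conventions, semantics, limitations
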
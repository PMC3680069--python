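# Methods

## Model overview

A circuit is a set of transcription units (promoter + cargo + terminator)
in the nucleus plus pools of free signal carriers in the nucleus and the
cytoplasm. Five molecule classes act as signal carriers between modules —
RNA polymerases (PoPS flux), ribosomes (RiPS), transcription factors
(FaPS), small RNAs (RNAPS) and chemicals (SiPS). Every module is compiled
to elementary mass-action reactions; no Hill or Michaelis–Menten lumping is
used anywhere (enzymatic steps are always the three-reaction elementary
scheme: bind, unbind, catalyze).

### Rule engine

Species are connected graphs of typed molecules; each molecule type
declares components that may carry a finite state and/or a single bond.
Rules match one or two reactant patterns (fragments with state/bond
wildcards) and apply a short list of primitive edits (bind, unbind,
set-state, create, delete); a single-primitive rule corresponds to each
elementary interaction, and multi-edit rules express concerted events such
as chemical stripping. Network expansion is a breadth-first fixed point
from the seed species, capped at 10,000 species by default (exceeding the
cap raises an error naming the last rule applied).

Canonical species labels come from an exhaustive search over molecule
orderings, pruned by Weisfeiler–Lehman-style signature refinement; the
complexes here are small (≤ ~10 molecules) so no nauty-style machinery is
needed, and a hard cap (8! orderings) guards against pathological
symmetry. Reaction rates follow the deterministic mass-action convention:
a rule matching a reactant combination through k equivalent embeddings
yields one reaction at k/|Aut| times the rule constant, where |Aut| counts
the automorphisms of the rule's patterns (so a symmetric dimerization rule
gets the standard factor 1/2). Duplicate reactions from one rule are
merged; duplicates from distinct rules are kept with their provenance.

### Promoters

Operator position is abstract except through two orderings: repressor
operators are strongest closest to the transcription start site,
activator operators strongest furthest from it; the binding rate at
affinity rank r is `base_bind_rate / affinity_gradient^r`. Cooperativity
multiplies the binding rate by a fixed factor when a rank-adjacent operator
of the same factor is occupied (unbinding is unchanged).

Reaction families over the 2^n occupancy configurations:

1. factor binding (one per configuration × free operator, competition
   model: only when no polymerase is engaged);
2. factor unbinding;
3. chemical stripping — `chem + promoter·TF → promoter + TF·chem` as a
   single bimolecular event with no DNA·TF·chemical intermediate (this
   keeps the species count at 2^n + 1);
4. bound-factor turnover — degradation of the DNA-bound factor, freeing
   its operator. This is the fourth per-(configuration, bound-operator)
   family; its rate is the promoter-level `tf_dna_turnover_rate`, so the
   family can be made negligible (but never absent) through that single
   parameter;
5. leak transcription from every leaky configuration (at least one
   repressor bound; or activators present but the activation condition
   unmet). Leak consumes a free polymerase and emits a cleared polymerase
   (Pol^cl) on the PoPS output — consuming RNAP keeps the polymerase pool
   exactly conserved, which the simulator verifies to 1e-6;
6. polymerase binding to permissive configurations, unbinding, and
   initiation/clearing emitting Pol^cl.

Activation: non-cooperative activators activate with ≥1 operator bound;
cooperative activators require all operators bound. While the polymerase
is engaged, factor-removal events (unbinding, stripping, turnover) eject it
exactly when the resulting configuration is no longer permissive — which
reduces to "the rightmost operator freed" for cooperative activators and
"no activator left" for non-cooperative ones. Factor *binding* while the
polymerase is engaged is not modeled. Mixed promoters with more than one
cooperative activator species are rejected as unsupported.

Leak and polymerase rules are conditioned on whole configurations
(disjunctions such as "at least one repressor bound" have no single-pattern
encoding), so the compiler synthesizes them per configuration after a first
expansion of the occupancy families; the complete rule set then re-expands
to the same network (a fixed point, which the tests exploit as an oracle).

Pol^cl is an adapter species on the PoPS output, not an internal promoter
species; part species counts include the occupancy configurations and
polymerase-engaged states only.

### Coding regions, mRNA pools, siRNA genes

The nuclear coding part: transcription (a cleared polymerase converts to
one immature transcript and returns to the polymerase pool), spliceosome
Michaelis–Menten (three reactions), one lumped maturation + export
reaction, and nuclear decay of the immature transcript.

The cytoplasmic mRNA pool (base composition, 5 species / 9 reactions /
2 terminals): species {mRNA, mRNA·ribosome initiating, mRNA·ribosome
elongating, clearing ribosome, nascent protein}; reactions {terminator
decay of the three mRNA states with machinery release, ribosome bind,
unbind, initiation→elongation, completion, ribosome return, protein
release}. Each siRNA binding site adds two species (site-bound mRNA with
and without a — lumped — ribosome) and six reactions (RISC·siRNA binding
to the three translatable states, cleavage from both bound states with
machinery release, ribosome drop-off); states with more than one bound
siRNA are forbidden by construction (binding requires all sites free).
Riboswitches add an on/off conformation per element plus aptamer occupancy
components; the conformation breathes at the switch rates, chemical
binding locks it on (with a fixed 10× boost for the second aptamer of a
cooperative tandem pair), and ribosome loading requires every conformation
on.

siRNA genes mirror this: nuclear double-stranded RNA production, Dicer
Michaelis–Menten, lumped export, nuclear decay (6 reactions); the
cytoplasmic siRNA pool loads the guide onto RISC, and both the free siRNA
and the loaded RISC·siRNA complex turn over at the terminator decay rate,
the loaded complex returning its RISC. Loaded-complex turnover matters:
without it the complexes targeting silenced (hence scarce) transcripts
sequester the entire RISC pool and starve every other silencing arm.

Transcription-factor products are synthesized in the cytoplasm, imported
into the nucleus first-order, bind/release their effector chemical in
solution, and degrade in both free and chemical-bound forms. Reporters
stay cytoplasmic with degradation only. Machinery pools (RNAP, ribosome,
spliceosome, Dicer, RISC) are conserved storages.

### Terminal counting

Exchange-flux counts follow two conventions chosen to match the part
family sizes: promoters count polymerase-in, polymerase-out and PoPS-out
plus, per transcription factor, factor-in, factor-out and (if strippable)
chemical-in — 6 terminals for one strippable repressor, 12 for three.
mRNA pools count one bidirectional ribosome terminal, one product terminal
and one per distinct targeting siRNA species — 2 for an unregulated
transcript, 5 and 4 for the AND-gate transcripts. These counts are
bookkeeping on the module interface; they do not affect the dynamics.

### Composition and simulation

Wiring compiles every part, resolves terminals by attached pool species
(shared species merge only at declared terminals; internal species carry
part-qualified names), renames each cargo's generic PoPS input onto its
promoter's Pol^cl, and flattens to one network with per-species
compartment assignment. Transport reactions (export, import) live in the
exporting module. The wiring is deterministic — identical inputs give
byte-identical manifests and SBML.

The simulator integrates dx/dt = S·v with v the mass-action fluxes, using
BDF with an analytic dense Jacobian, relative tolerance 1e-8 and absolute
tolerance 1e-12. The protocol is horizon-based, not residual-based: 96 h
equilibration with all chemicals at zero, then the input chemicals set and
(by default) clamped at a constant copy number for 48 h of evaluation; a
bolus mode (`clamped=False`) lets them deplete instead. Truth tables run
one shared equilibration and sixteen evaluation branches. Boolean calls
threshold at the midpoint between the largest OFF and smallest ON readout;
the separation statistic is min(ON) − max(OFF) in reporter copies, and a
non-positive separation flags the classification as failed.

## Default parameters

All rates are stochastic per-copy rates (bimolecular rates in
1/(molecule·s), already scaled to their compartment; a helper converts
molar constants using the compartment volumes, nucleus 3 fL / cytoplasm
30 fL). The packaged table is an order-of-magnitude calibration for
yeast/mammalian kinetics chosen so the fixture circuits function as
designed; it is not a measured set.

| parameter | default | rationale |
|---|---|---|
| RNAP / ribosome / spliceosome / Dicer / RISC copies | 700 / 20,000 / 200 / 200 / 5,000 | free machinery pools; RISC sized so five siRNA species never exhaust it |
| sensor TF copies | 20,000 | constitutive sensing factors; large enough that residual transcription of their targets stays below the leak floor |
| RNAP bind / unbind / clearing | 1e-3, 1, 0.1 /s | ~0.4 promoter occupancy, ~0.04 PoPS when active |
| operator bind / unbind | 1e-3, 0.1 /s | full repression at >10^4 repressor copies, <6% occupancy at leak-level (~5 copies) |
| affinity gradient | 2 | twofold fall-off per operator rank |
| chemical–TF: strip on DNA / solution bind / unbind | 1e-3, 3e-4, 1e-3 | an input at 10^4 copies strips DNA-bound factors in ~0.1 s and keeps ~3×10^-4 of the factor pool active |
| splice bind/unbind/cat; Dicer ditto | 1e-3, 1e-2, 0.1 | elementary enzyme scheme, processing ≫ transcript decay |
| export (mRNA, siRNA) | 1e-2 /s | lumped maturation + transport, minutes-scale |
| ribosome bind/unbind; initiation; completion | 1e-5, 1e-2; 0.1; 0.05 | ~0.02–0.03 proteins per transcript per second |
| RISC loading; site binding; cleavage | 1e-3; 1e-3; 1e-2 | silencing limited by loaded-complex supply, not cleavage |
| decay: mRNA / siRNA / protein | 2e-4 / 1e-4 / 2e-4 /s | ~1–2 h half-lives |
| leak (coding promoters / siRNA promoters) | 1e-9 / 2e-6 /s per leaky configuration | siRNA cassettes are modeled as a leakier promoter class (shRNA/pol III-like); this basal, non-strippable silencing is what places the RNAi evaluator's ON levels below the transcriptional evaluator's |
| nuclear import | 1e-3 /s | minutes-scale TF import |
| input level | 10,000 copies | clamped chemical per present input |

## What the fixtures emulate — and what they do not

The packaged evaluators reproduce the architecture of an RNAi Boolean
evaluator and its transcriptional counterpart: each input chemical
deactivates the factor(s) sensing it, the regulator for literal x is
produced exactly when x is absent, and the regulator for NOT-a exactly
when a is present (chemical a deactivates two different factors). Passing
truth-table tests therefore shows that the compiled networks implement the
intended logic under the packaged kinetics — not that any real circuit
with measured parameters would show these absolute copy numbers. The
fixtures omit growth/dilution, transcriptional squelching, operator
positional effects, chromatin, and cell-to-cell variability; simulation is
deterministic, justified a posteriori by ON/OFF separations of thousands
of reporter copies (stochastic effects matter below ~100).

## Numerical choices and degenerate inputs

Tolerances 1e-8/1e-12 (truth-table calls are verified invariant under 10×
tightening); horizon-based steady state (96 h) rather than a residual
criterion; ties in canonical ordering broken lexicographically; empty rule
sets expand to their seeds; a species-less model is refused by the SBML
exporter; chemicals are treated as ambient (they cross the nuclear
membrane freely, so chemical-containing reactions are exempt from the
co-localization check); conservation accounting counts state-encoded
machinery (a translating ribosome is an mRNA state, a loaded RISC is an
RS complex, a cleared polymerase is Pol^cl).

## Known limitations

- Activator-promoter closed-form counts are not provided (only the
  repressor family has a formula oracle); activator parts are verified
  structurally and behaviorally instead.
- Factor binding onto a polymerase-engaged promoter is not modeled.
- The circuit file dialect covers the constructs the fixtures use; it is
  versioned (`# eucirc-circuit v1`) but not a general exchange format —
  SBML export is the interchange path.
- Whole-circuit totals depend on pool bookkeeping conventions and are
  reported in the manifest but are not meaningful as cross-tool numbers.
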
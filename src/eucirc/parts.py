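"""Compile part specifications into rule sets and expanded sub-networks.

Each compiler turns one declarative part description into a
:class:`PartModel`: a rule set, its expanded reaction network, and typed
flux terminals.  Species are split into *internal* species (the part's own
states, e.g. promoter operator-occupancy configurations) and *boundary*
species (free molecules belonging to pools, plus adapter species such as the
cleared polymerase ``Pol^cl`` that carries the PoPS output).  Part species
and reaction counts refer to internal species and to all reactions hosted by
the part.

Promoter model
--------------
A promoter with transcription factors :math:`t` on :math:`N_t` operators
expands over the full operator-occupancy state space.  Reaction families:

(a) TF binding, one per (configuration, free operator); affinity falls off
    with operator rank (repressors strongest nearest the TSS, activators
    strongest furthest) and cooperativity boosts binding next to an occupied
    same-factor operator;
(b) TF unbinding, one per (configuration, bound operator);
(c) chemical stripping, ``chem + prom·TF -> prom + TF·chem``, a single
    bimolecular event with no DNA-bound intermediate;
(d) bound-TF turnover (degradation of the DNA-bound factor, freeing its
    operator);
(e) leak transcription from every leaky configuration (at least one
    repressor bound, or activators present but the activation condition
    unmet), consuming a free polymerase and emitting ``Pol^cl``;
(f) polymerase binding to permissive configurations, unbinding, and
    initiation/promoter clearing emitting ``Pol^cl``.

For an all-repressor promoter with ``n`` operators, all chemically
regulated, the closed forms are ``n_species = 2**n + 1`` and
``n_reactions = 4*n*2**(n-1) + (2**n - 1) + 3``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .core import (
    CircuitSpec,
    CodingRegionSpec,
    Compartment,
    Cooperativity,
    PoolSpec,
    ProductKind,
    PromoterSpec,
    Role,
    SignalCarrierKind,
    SiRNAGeneSpec,
    TerminatorSpec,
)
from .rules import (
    Bind,
    Component,
    Create,
    Delete,
    Molecule,
    MoleculeType,
    Pattern,
    PatternComponent,
    PatternMolecule,
    ReactionNetwork,
    Rule,
    RuleSet,
    SetState,
    SpeciesGraph,
    Terminal,
    Unbind,
    expand,
)

__all__ = [
    "PartModel",
    "UnsupportedPromoterError",
    "compile_promoter",
    "compile_coding_region",
    "compile_sirna_gene",
    "compile_tf_and_protein_pools",
    "promoter_counts",
    "mrna_pool_counts",
    "part_report",
]

#: fixed riboswitch aptamer cooperativity boost (homo- or hetero-)
RIBOSWITCH_COOP_FACTOR = 10.0


class UnsupportedPromoterError(ValueError):
    pass


@dataclass
class PartModel:
    name: str
    ruleset: RuleSet
    expanded: ReactionNetwork
    boundary_types: set[str] = field(default_factory=set)
    compartment: Compartment = Compartment.NUCLEUS

    def _is_internal(self, label: str) -> bool:
        g = self.expanded.graphs[label]
        return any(m.mtype.name not in self.boundary_types for m in g.molecules)

    @property
    def internal_species(self) -> list[str]:
        return [s for s in self.expanded.species if self._is_internal(s)]

    @property
    def n_species(self) -> int:
        return len(self.internal_species)

    @property
    def n_reactions(self) -> int:
        return self.expanded.n_reactions

    @property
    def terminals(self) -> list[Terminal]:
        return self.expanded.terminals

    @property
    def n_terminals(self) -> int:
        return len(self.expanded.terminals)

    @property
    def counts(self) -> tuple[int, int, int]:
        return (self.n_species, self.n_reactions, self.n_terminals)


# ---------------------------------------------------------------------------
# shared boundary molecule types

RNAP_T = MoleculeType("RNAP", (Component("d", bindable=True),))
RIB_T = MoleculeType("Rib", (Component("d", bindable=True),))
SPL_T = MoleculeType("Spl", (Component("s", bindable=True),))
DICER_T = MoleculeType("Dicer", (Component("s", bindable=True),))
RISC_T = MoleculeType("RISC", ())


def chem_type(chem: str) -> MoleculeType:
    return MoleculeType(f"Chem_{chem}", ())


def tf_type(tf: str) -> MoleculeType:
    return MoleculeType(f"TF_{tf}", (Component("d", bindable=True),))


def tfc_type(tf: str) -> MoleculeType:
    """Chemical-bound (inactivated) transcription factor."""
    return MoleculeType(f"TFC_{tf}", ())


def polcl_type(promoter: str) -> MoleculeType:
    return MoleculeType(f"PolCl_{promoter}", ())


def _single(mt: MoleculeType, **states) -> SpeciesGraph:
    return SpeciesGraph([Molecule(mt, dict(states))])


# ---------------------------------------------------------------------------
# promoter compiler


def _op_comp(tf: str, rank: int) -> str:
    return f"o_{tf}_{rank}"


def compile_promoter(spec: PromoterSpec, max_species: int = 10_000) -> PartModel:
    """Expand a promoter into its operator-occupancy reaction network.

    Raises :class:`UnsupportedPromoterError` for promoters mixing repressors
    with cooperative activators of more than one activator species.
    """

    activators = [b for b in spec.tf_bindings if b.role is Role.ACTIVATOR]
    repressors = [b for b in spec.tf_bindings if b.role is Role.REPRESSOR]
    if repressors and any(a.cooperative for a in activators) and len(activators) > 1:
        raise UnsupportedPromoterError(
            f"promoter {spec.name}: repressors combined with multiple "
            "cooperative activator species are not supported"
        )

    prom_name = f"Prom_{spec.name}"
    op_components = []
    for b in spec.tf_bindings:
        for r in range(b.n_operators):
            op_components.append(Component(_op_comp(b.tf_name, r), bindable=True))
    prom_t = MoleculeType(
        prom_name, tuple(op_components) + (Component("core", bindable=True),)
    )
    polcl_t = polcl_type(spec.name)

    types: dict[str, MoleculeType] = {prom_name: prom_t, "RNAP": RNAP_T, polcl_t.name: polcl_t}
    boundary = {"RNAP", polcl_t.name}
    seeds: list[tuple[SpeciesGraph, float]] = [(_single(prom_t), 1.0)]
    seeds.append((_single(RNAP_T), 0.0))
    for b in spec.tf_bindings:
        tt = tf_type(b.tf_name)
        types[tt.name] = tt
        boundary.add(tt.name)
        seeds.append((_single(tt), 0.0))
        if b.effector_chemical is not None:
            ct = chem_type(b.effector_chemical)
            tc = tfc_type(b.tf_name)
            types.setdefault(ct.name, ct)
            types[tc.name] = tc
            boundary |= {ct.name, tc.name}
            seeds.append((_single(ct), 0.0))

    # ---- phase 1: TF occupancy families (binding only when core is free)
    rules: list[Rule] = []
    for b in spec.tf_bindings:
        tfn = tf_type(b.tf_name).name
        for r in range(b.n_operators):
            oc = _op_comp(b.tf_name, r)
            bind_rate = b.base_bind_rate / (b.affinity_gradient ** r)
            modifier = None
            if b.cooperative and b.n_operators > 1:
                modifier = _coop_modifier(b.tf_name, r, b.n_operators, b.cooperativity_factor)
            rules.append(
                Rule(
                    name=f"bind_{b.tf_name}_{r}",
                    reactants=[
                        Pattern([PatternMolecule(prom_name, {
                            oc: PatternComponent(bond="unbound"),
                            "core": PatternComponent(bond="unbound"),
                        })]),
                        Pattern([PatternMolecule(tfn, {"d": PatternComponent(bond="unbound")})]),
                    ],
                    actions=[Bind((0, 0), oc, (1, 0), "d")],
                    rate_constant=bind_rate,
                    rate_modifier=modifier,
                    tag="tf_bind",
                )
            )
            bound_pair = Pattern([
                PatternMolecule(prom_name, {oc: PatternComponent(bond=1),
                                            "core": PatternComponent(bond="unbound")}),
                PatternMolecule(tfn, {"d": PatternComponent(bond=1)}),
            ])
            rules.append(
                Rule(
                    name=f"unbind_{b.tf_name}_{r}",
                    reactants=[bound_pair],
                    actions=[Unbind((0, 0), oc)],
                    rate_constant=b.unbind_rate,
                    tag="tf_unbind",
                )
            )
            if b.effector_chemical is not None:
                cn = chem_type(b.effector_chemical).name
                rules.append(
                    Rule(
                        name=f"strip_{b.tf_name}_{r}",
                        reactants=[
                            bound_pair,
                            Pattern([PatternMolecule(cn, {})]),
                        ],
                        actions=[
                            Delete((0, 1)),
                            Delete((1, 0)),
                            Create(_single(types[tfc_type(b.tf_name).name])),
                        ],
                        rate_constant=b.chem_strip_rate,
                        tag="strip",
                    )
                )
            rules.append(
                Rule(
                    name=f"turnover_{b.tf_name}_{r}",
                    reactants=[bound_pair],
                    actions=[Delete((0, 1))],
                    rate_constant=spec.tf_dna_turnover_rate,
                    tag="turnover",
                )
            )

    phase1 = RuleSet(dict(types), list(seeds), list(rules))
    net1 = expand(phase1, max_species)
    configs = [
        lab
        for lab in net1.species
        if any(m.mtype.name == prom_name for m in net1.graphs[lab].molecules)
    ]

    # ---- phase 2: configuration-conditioned leak and polymerase families
    def occupancy(lab: str) -> dict[str, list[int]]:
        g = net1.graphs[lab]
        prom_idx = next(
            i for i, m in enumerate(g.molecules) if m.mtype.name == prom_name
        )
        occ: dict[str, list[int]] = {b.tf_name: [] for b in spec.tf_bindings}
        for b in spec.tf_bindings:
            for r in range(b.n_operators):
                if g.bond_partner(prom_idx, _op_comp(b.tf_name, r)) is not None:
                    occ[b.tf_name].append(r)
        return occ

    def activation_met(occ) -> bool:
        if not activators:
            return True
        for a in activators:
            bound = occ[a.tf_name]
            if a.cooperative:
                if len(bound) == a.n_operators:
                    return True
            elif bound:
                return True
        return False

    def classify(occ) -> tuple[bool, bool]:
        """(permissive, leaky) for one occupancy configuration."""
        any_repressor = any(occ[b.tf_name] for b in repressors)
        act_ok = activation_met(occ)
        permissive = (not any_repressor) and act_ok
        leaky = any_repressor or (not any_repressor and bool(activators) and not act_ok)
        return permissive, leaky

    rnap_free_pat = Pattern([PatternMolecule("RNAP", {"d": PatternComponent(bond="unbound")})])
    for idx, lab in enumerate(sorted(configs)):
        g = net1.graphs[lab]
        occ = occupancy(lab)
        permissive, leaky = classify(occ)
        cfg_pat = Pattern.from_graph(g)
        if leaky and spec.leak_rate > 0:
            rules.append(
                Rule(
                    name=f"leak_{idx}",
                    reactants=[cfg_pat, rnap_free_pat],
                    actions=[Delete((1, 0)), Create(_single(polcl_t))],
                    rate_constant=spec.leak_rate,
                    once_per_combo=True,
                    tag="leak",
                )
            )
        if not permissive:
            continue
        prom_i = next(i for i, m in enumerate(g.molecules) if m.mtype.name == prom_name)
        rules.append(
            Rule(
                name=f"rnap_bind_{idx}",
                reactants=[cfg_pat, rnap_free_pat],
                actions=[Bind((0, prom_i), "core", (1, 0), "d")],
                rate_constant=spec.rnap_bind_rate,
                once_per_combo=True,
                tag="rnap_bind",
            )
        )
        # the polymerase-engaged complex, as an exact pattern
        gb = g.copy()
        gb.molecules.append(Molecule(RNAP_T))
        gb.add_bond((prom_i, "core"), (len(gb.molecules) - 1, "d"))
        cplx_pat = Pattern.from_graph(gb)
        rnap_i = len(gb.molecules) - 1
        rules.append(
            Rule(
                name=f"rnap_unbind_{idx}",
                reactants=[cplx_pat],
                actions=[Unbind((0, prom_i), "core")],
                rate_constant=spec.rnap_unbind_rate,
                once_per_combo=True,
                tag="rnap_unbind",
            )
        )
        rules.append(
            Rule(
                name=f"initiate_{idx}",
                reactants=[cplx_pat],
                actions=[Delete((0, rnap_i)), Create(_single(polcl_t))],
                rate_constant=spec.clearing_rate,
                once_per_combo=True,
                tag="initiate",
            )
        )
        # factor-removal events while the polymerase is engaged: removal that
        # breaks the activation condition ejects the polymerase (cooperative
        # activators lose it as soon as the decisive operator frees;
        # non-cooperative ones only once no activator operator remains bound)
        for b in activators:
            if not occ[b.tf_name]:
                continue
            for r in occ[b.tf_name]:
                occ2 = {k: [x for x in v if not (k == b.tf_name and x == r)] for k, v in occ.items()}
                eject = not classify(occ2)[0]
                oc = _op_comp(b.tf_name, r)
                tf_i = next(
                    i
                    for i, m in enumerate(gb.molecules)
                    if gb.bond_partner(prom_i, oc) == (i, "d")
                )
                eject_actions = [Unbind((0, prom_i), "core")] if eject else []
                rules.append(
                    Rule(
                        name=f"unbind_rnap_{b.tf_name}_{r}_{idx}",
                        reactants=[cplx_pat],
                        actions=[Unbind((0, prom_i), oc)] + eject_actions,
                        rate_constant=b.unbind_rate,
                        once_per_combo=True,
                        tag="tf_unbind",
                    )
                )
                if b.effector_chemical is not None:
                    cn = chem_type(b.effector_chemical).name
                    rules.append(
                        Rule(
                            name=f"strip_rnap_{b.tf_name}_{r}_{idx}",
                            reactants=[cplx_pat, Pattern([PatternMolecule(cn, {})])],
                            actions=[
                                Delete((0, tf_i)),
                                Delete((1, 0)),
                                Create(_single(types[tfc_type(b.tf_name).name])),
                            ]
                            + eject_actions,
                            rate_constant=b.chem_strip_rate,
                            once_per_combo=True,
                            tag="strip",
                        )
                    )
                rules.append(
                    Rule(
                        name=f"turnover_rnap_{b.tf_name}_{r}_{idx}",
                        reactants=[cplx_pat],
                        actions=[Delete((0, tf_i))] + eject_actions,
                        rate_constant=spec.tf_dna_turnover_rate,
                        once_per_combo=True,
                        tag="turnover",
                    )
                )

    terminals = [
        Terminal(f"{spec.name}.rnap_in", "PoPS", "in", "RNAP"),
        Terminal(f"{spec.name}.rnap_out", "PoPS", "out", "RNAP"),
        Terminal(f"{spec.name}.pops_out", "PoPS", "out", polcl_t.name),
    ]
    for b in spec.tf_bindings:
        if b.effector_chemical is not None:
            terminals += [
                Terminal(f"{spec.name}.{b.tf_name}_in", "FaPS", "in", tf_type(b.tf_name).name),
                Terminal(f"{spec.name}.{b.tf_name}_out", "FaPS", "out", tf_type(b.tf_name).name),
                Terminal(f"{spec.name}.{b.effector_chemical}_in", "SiPS", "in",
                         chem_type(b.effector_chemical).name),
            ]
        else:
            terminals += [
                Terminal(f"{spec.name}.{b.tf_name}_in", "FaPS", "in", tf_type(b.tf_name).name),
                Terminal(f"{spec.name}.{b.tf_name}_out", "FaPS", "out", tf_type(b.tf_name).name),
            ]

    full = RuleSet(types, seeds, rules, terminals)
    net = expand(full, max_species)
    return PartModel(spec.name, full, net, boundary, Compartment.NUCLEUS)


def _coop_modifier(tf: str, rank: int, n_ops: int, factor: float):
    def modifier(graphs, _emb):
        g = graphs[0]
        prom_i = next(
            i for i, m in enumerate(g.molecules) if m.mtype.name.startswith("Prom_")
        )
        for adj in (rank - 1, rank + 1):
            if 0 <= adj < n_ops and g.bond_partner(prom_i, _op_comp(tf, adj)) is not None:
                return factor
        return 1.0

    return modifier


def promoter_counts(spec: PromoterSpec) -> tuple[int, int]:
    """Closed-form (n_species, n_reactions) for the supported repressor-only
    (or constitutive) promoter family; the expansion oracle for tests."""
    if any(b.role is Role.ACTIVATOR for b in spec.tf_bindings):
        raise ValueError("closed forms cover repressor-only promoters")
    n = spec.n_operators_total
    if n == 0:
        return 2, 3
    half = 2 ** (n - 1)
    n_strip_ops = sum(
        b.n_operators for b in spec.tf_bindings if b.effector_chemical is not None
    )
    n_species = 2 ** n + 1
    n_reactions = 3 * n * half + n_strip_ops * half + (2 ** n - 1) + 3
    return n_species, n_reactions


# ---------------------------------------------------------------------------
# coding region -> nuclear part + cytoplasmic mRNA pool


def _pops_in_type(name: str) -> MoleculeType:
    return MoleculeType(f"PoPSin_{name}", ())


def compile_coding_region(
    spec: CodingRegionSpec, term: TerminatorSpec, max_species: int = 10_000
) -> tuple[PartModel, PartModel]:
    """Nuclear coding-region part plus its cytoplasmic mRNA pool.

    The nuclear part receives cleared polymerases on its PoPS input, makes
    the immature transcript, splices it through an explicit three-reaction
    Michaelis-Menten scheme with the spliceosome, and delivers mature mRNA to
    the cytoplasmic pool through one lumped maturation-plus-export reaction.

    The cytoplasmic pool carries translation (ribosome binding gated by
    riboswitch conformations, initiation, elongation, completion) and RNA
    interference: RISC·siRNA complexes bind any free 3'-UTR site provided no
    other site is occupied (multiply-silenced states are forbidden), and a
    bound site triggers cleavage with rapid degradation that releases the
    machinery.  Transcript decay uses the terminator's rate.
    """

    nuclear = _compile_coding_nuclear(spec, term, max_species)
    pool = _compile_mrna_pool(spec, term, max_species)
    return nuclear, pool


def _compile_coding_nuclear(spec, term, max_species) -> PartModel:
    name = spec.name
    pre_t = MoleculeType(f"preM_{name}", (Component("spl", bindable=True),))
    matn_t = MoleculeType(f"matN_{name}", ())
    m_t = MoleculeType(f"M_{name}", _mrna_components(spec))
    pops_t = _pops_in_type(name)
    types = {t.name: t for t in (pre_t, matn_t, m_t, pops_t, SPL_T, RNAP_T)}
    boundary = {pops_t.name, "Spl", "RNAP", m_t.name}
    seeds = [
        (_single(pops_t), 0.0),
        (_single(SPL_T), 0.0),
    ]
    rules = [
        Rule(
            "transcribe",
            [Pattern([PatternMolecule(pops_t.name, {})])],
            [Delete((0, 0)), Create(_single(pre_t)), Create(_single(RNAP_T))],
            spec.transit_rate,
            tag="transcribe",
        ),
        Rule(
            "spl_bind",
            [
                Pattern([PatternMolecule(pre_t.name, {"spl": PatternComponent(bond="unbound")})]),
                Pattern([PatternMolecule("Spl", {"s": PatternComponent(bond="unbound")})]),
            ],
            [Bind((0, 0), "spl", (1, 0), "s")],
            spec.splice_bind_rate,
            tag="splice",
        ),
        Rule(
            "spl_unbind",
            [Pattern([
                PatternMolecule(pre_t.name, {"spl": PatternComponent(bond=1)}),
                PatternMolecule("Spl", {"s": PatternComponent(bond=1)}),
            ])],
            [Unbind((0, 0), "spl")],
            spec.splice_unbind_rate,
            tag="splice",
        ),
        Rule(
            "spl_cat",
            [Pattern([
                PatternMolecule(pre_t.name, {"spl": PatternComponent(bond=1)}),
                PatternMolecule("Spl", {"s": PatternComponent(bond=1)}),
            ])],
            [Delete((0, 0)), Create(_single(matn_t))],
            spec.splice_cat_rate,
            tag="splice",
        ),
        Rule(
            "export",
            [Pattern([PatternMolecule(matn_t.name, {})])],
            [Delete((0, 0)), Create(_single(m_t))],
            spec.export_rate,
            tag="transport",
        ),
        Rule(
            "nuclear_decay",
            [Pattern([PatternMolecule(pre_t.name, {"spl": PatternComponent(bond="unbound")})])],
            [Delete((0, 0))],
            spec.nuclear_decay_rate,
            tag="decay",
        ),
    ]
    terminals = [
        Terminal(f"{name}.pops_in", "PoPS", "in", pops_t.name),
        Terminal(f"{name}.rnap_out", "PoPS", "out", "RNAP"),
        Terminal(f"{name}.spl", "RiPS", "bidir", "Spl"),
        Terminal(f"{name}.mrna_out", "RNAPS", "out", m_t.name),
    ]
    rs = RuleSet(types, seeds, rules, terminals)
    return PartModel(f"{name}.nuclear", rs, expand(rs, max_species), boundary, Compartment.NUCLEUS)


def _mrna_components(spec: CodingRegionSpec) -> tuple[Component, ...]:
    comps = [Component("rib", ("none", "init", "elong", "lump"))]
    j = 0
    for t in spec.sirna_targets:
        for _ in range(t.n_sites):
            comps.append(Component(f"s{j}", ("free", "taken")))
            j += 1
    for i, rs in enumerate(spec.riboswitches):
        comps.append(Component(f"c{i}", ("off", "on")))
        for a in range(len(rs.aptamer_chemicals)):
            comps.append(Component(f"ap{i}_{a}", ("empty", "bound")))
    return tuple(comps)


def rs_type(sirna: str) -> MoleculeType:
    """RISC-loaded siRNA complex shuttling from the siRNA pool."""
    return MoleculeType(f"RS_{sirna}", ())


def product_type(product: str) -> MoleculeType:
    return MoleculeType(f"P_{product}", ())


def _compile_mrna_pool(spec, term, max_species) -> PartModel:
    name = spec.name
    m_t = MoleculeType(f"M_{name}", _mrna_components(spec))
    ribcl_t = MoleculeType(f"RibCl_{name}", ())
    pn_t = MoleculeType(f"Pn_{name}", ())
    p_t = product_type(spec.product_name)
    types = {t.name: t for t in (m_t, ribcl_t, pn_t, p_t, RIB_T, RISC_T)}
    boundary = {"Rib", "RISC", p_t.name}

    sites: list[tuple[str, object]] = []  # (component, target spec)
    j = 0
    for t in spec.sirna_targets:
        for _ in range(t.n_sites):
            sites.append((f"s{j}", t))
            j += 1
    all_free = {c: PatternComponent(state="free") for c, _ in sites}
    all_on = {
        f"c{i}": PatternComponent(state="on") for i in range(len(spec.riboswitches))
    }

    def mpat(**over) -> Pattern:
        comps = dict(over)
        return Pattern([PatternMolecule(m_t.name, comps)])

    seeds = [(_single(m_t), 0.0), (_single(RIB_T), 0.0), (_single(RISC_T), 0.0)]
    for _, t in {t.sirna_name: (None, t) for t in spec.sirna_targets}.values():
        rt = rs_type(t.sirna_name)
        types[rt.name] = rt
        boundary.add(rt.name)
        seeds.append((_single(rt), 0.0))
    for rsw in spec.riboswitches:
        for c in rsw.aptamer_chemicals:
            ct = chem_type(c)
            types.setdefault(ct.name, ct)
            boundary.add(ct.name)
            seeds.append((_single(ct), 0.0))

    rib_free = Pattern([PatternMolecule("Rib", {"d": PatternComponent(bond="unbound")})])
    decay = term.transcript_decay_rate
    rules = [
        Rule("decay_m", [mpat(rib=PatternComponent(state="none"), **all_free)],
             [Delete((0, 0))], decay, tag="decay"),
        Rule("decay_mi", [mpat(rib=PatternComponent(state="init"), **all_free)],
             [Delete((0, 0)), Create(_single(RIB_T))], decay, tag="decay"),
        Rule("decay_me", [mpat(rib=PatternComponent(state="elong"), **all_free)],
             [Delete((0, 0)), Create(_single(RIB_T))], decay, tag="decay"),
        Rule("rib_bind",
             [mpat(rib=PatternComponent(state="none"), **all_free, **all_on), rib_free],
             [SetState((0, 0), "rib", "init"), Delete((1, 0))],
             spec.ribosome_bind_rate, tag="translate"),
        Rule("rib_unbind", [mpat(rib=PatternComponent(state="init"))],
             [SetState((0, 0), "rib", "none"), Create(_single(RIB_T))],
             spec.ribosome_unbind_rate, tag="translate"),
        Rule("init_elong", [mpat(rib=PatternComponent(state="init"))],
             [SetState((0, 0), "rib", "elong")], spec.translation_rate, tag="translate"),
        Rule("complete", [mpat(rib=PatternComponent(state="elong"), **all_free)],
             [SetState((0, 0), "rib", "none"), Create(_single(ribcl_t)), Create(_single(pn_t))],
             spec.completion_rate, tag="translate"),
        Rule("rib_clear", [Pattern([PatternMolecule(ribcl_t.name, {})])],
             [Delete((0, 0)), Create(_single(RIB_T))], spec.ribosome_clear_rate, tag="translate"),
        Rule("p_release", [Pattern([PatternMolecule(pn_t.name, {})])],
             [Delete((0, 0)), Create(_single(p_t))], spec.protein_release_rate, tag="translate"),
    ]

    for comp, t in sites:
        rsn = rs_type(t.sirna_name).name
        rs_pat = Pattern([PatternMolecule(rsn, {})])
        rules += [
            Rule(f"rsbind_{comp}_free",
                 [mpat(rib=PatternComponent(state="none"), **all_free), rs_pat],
                 [SetState((0, 0), comp, "taken"), Delete((1, 0))],
                 t.bind_rate, tag="rnai"),
            Rule(f"rsbind_{comp}_init",
                 [mpat(rib=PatternComponent(state="init"), **all_free), rs_pat],
                 [SetState((0, 0), comp, "taken"), SetState((0, 0), "rib", "lump"),
                  Delete((1, 0))],
                 t.bind_rate, tag="rnai"),
            Rule(f"rsbind_{comp}_elong",
                 [mpat(rib=PatternComponent(state="elong"), **all_free), rs_pat],
                 [SetState((0, 0), comp, "taken"), SetState((0, 0), "rib", "lump"),
                  Delete((1, 0))],
                 t.bind_rate, tag="rnai"),
            Rule(f"cleave_{comp}",
                 [mpat(rib=PatternComponent(state="none"),
                       **{comp: PatternComponent(state="taken")})],
                 [Delete((0, 0)), Create(_single(RISC_T))],
                 t.cleavage_rate, tag="rnai"),
            Rule(f"cleave_{comp}_rib",
                 [mpat(rib=PatternComponent(state="lump"),
                       **{comp: PatternComponent(state="taken")})],
                 [Delete((0, 0)), Create(_single(RISC_T)), Create(_single(RIB_T))],
                 t.cleavage_rate, tag="rnai"),
            Rule(f"dropoff_{comp}",
                 [mpat(rib=PatternComponent(state="lump"),
                       **{comp: PatternComponent(state="taken")})],
                 [SetState((0, 0), "rib", "none"), Create(_single(RIB_T))],
                 spec.ribosome_unbind_rate, tag="rnai"),
        ]

    for i, rsw in enumerate(spec.riboswitches):
        apt_comps = [f"ap{i}_{a}" for a in range(len(rsw.aptamer_chemicals))]
        rules.append(
            Rule(f"switch_on_{i}", [mpat(**{f"c{i}": PatternComponent(state="off")})],
                 [SetState((0, 0), f"c{i}", "on")], rsw.switch_on_rate, tag="riboswitch")
        )
        rules.append(
            Rule(
                f"switch_off_{i}",
                [mpat(**{f"c{i}": PatternComponent(state="on")},
                      **{a: PatternComponent(state="empty") for a in apt_comps})],
                [SetState((0, 0), f"c{i}", "off")],
                rsw.switch_off_rate,
                tag="riboswitch",
            )
        )
        for a, chem in enumerate(rsw.aptamer_chemicals):
            ap = f"ap{i}_{a}"
            modifier = None
            if rsw.cooperativity is not Cooperativity.NONE and len(apt_comps) == 2:
                other = apt_comps[1 - a]
                modifier = _aptamer_coop_modifier(m_t.name, other)
            rules.append(
                Rule(f"apt_bind_{i}_{a}",
                     [mpat(**{ap: PatternComponent(state="empty")}),
                      Pattern([PatternMolecule(chem_type(chem).name, {})])],
                     [SetState((0, 0), ap, "bound"), Delete((1, 0))],
                     rsw.chem_bind_rate, rate_modifier=modifier, tag="riboswitch")
            )
            rules.append(
                Rule(f"apt_unbind_{i}_{a}",
                     [mpat(**{ap: PatternComponent(state="bound")})],
                     [SetState((0, 0), ap, "empty"),
                      Create(_single(types[chem_type(chem).name]))],
                     rsw.chem_unbind_rate, tag="riboswitch")
            )

    distinct_sirnas = list(dict.fromkeys(t.sirna_name for t in spec.sirna_targets))
    terminals = [
        Terminal(f"{name}.rib", "RiPS", "bidir", "Rib"),
        Terminal(f"{name}.product_out", "protein", "out", p_t.name),
    ] + [
        Terminal(f"{name}.rs_{k}_in", "RNAPS", "in", rs_type(k).name)
        for k in distinct_sirnas
    ]
    rs = RuleSet(types, seeds, rules, terminals)
    return PartModel(f"{name}.pool", rs, expand(rs, max_species), boundary, Compartment.CYTOPLASM)


def mrna_pool_counts(s: int, k: int) -> tuple[int, int, int]:
    """Affine closed form for a riboswitch-free mRNA pool with ``s`` total
    siRNA sites over ``k`` distinct siRNA species: the expansion oracle."""
    return 5 + 2 * s, 9 + 6 * s, 2 + k


# ---------------------------------------------------------------------------
# siRNA gene -> nuclear part + cytoplasmic siRNA pool


def sirna_cyt_type(sirna: str) -> MoleculeType:
    return MoleculeType(f"siR_{sirna}", ())


def compile_sirna_gene(
    spec: SiRNAGeneSpec, term: TerminatorSpec, max_species: int = 10_000
) -> tuple[PartModel, PartModel]:
    """Nuclear siRNA-coding part plus its cytoplasmic siRNA pool.

    The nuclear part turns incoming polymerases into double-stranded siRNA,
    processes it through Dicer (three-reaction Michaelis-Menten) and exports
    the single strand in one lumped reaction.  The cytoplasmic pool loads the
    siRNA onto RISC; the loaded complex is handed to target mRNA pools.
    """

    name = spec.sirna_name
    ds_t = MoleculeType(f"dsR_{name}", (Component("dcr", bindable=True),))
    ssn_t = MoleculeType(f"ssN_{name}", ())
    si_t = sirna_cyt_type(name)
    pops_t = _pops_in_type(f"sir_{name}")
    types = {t.name: t for t in (ds_t, ssn_t, si_t, pops_t, DICER_T, RNAP_T)}
    boundary = {pops_t.name, "Dicer", "RNAP", si_t.name}
    seeds = [(_single(pops_t), 0.0), (_single(DICER_T), 0.0)]
    ds_free = Pattern([PatternMolecule(ds_t.name, {"dcr": PatternComponent(bond="unbound")})])
    ds_cplx = Pattern([
        PatternMolecule(ds_t.name, {"dcr": PatternComponent(bond=1)}),
        PatternMolecule("Dicer", {"s": PatternComponent(bond=1)}),
    ])
    rules = [
        Rule("transcribe",
             [Pattern([PatternMolecule(pops_t.name, {})])],
             [Delete((0, 0)), Create(_single(ds_t)), Create(_single(RNAP_T))],
             spec.transit_rate, tag="transcribe"),
        Rule("dicer_bind",
             [ds_free, Pattern([PatternMolecule("Dicer", {"s": PatternComponent(bond="unbound")})])],
             [Bind((0, 0), "dcr", (1, 0), "s")], spec.dicer_bind_rate, tag="dicer"),
        Rule("dicer_unbind", [ds_cplx], [Unbind((0, 0), "dcr")],
             spec.dicer_unbind_rate, tag="dicer"),
        Rule("dicer_cat", [ds_cplx], [Delete((0, 0)), Create(_single(ssn_t))],
             spec.dicer_cat_rate, tag="dicer"),
        Rule("export", [Pattern([PatternMolecule(ssn_t.name, {})])],
             [Delete((0, 0)), Create(_single(si_t))], spec.export_rate, tag="transport"),
        Rule("nuclear_decay", [ds_free], [Delete((0, 0))],
             spec.nuclear_decay_rate, tag="decay"),
    ]
    terminals = [
        Terminal(f"sir_{name}.pops_in", "PoPS", "in", pops_t.name),
        Terminal(f"sir_{name}.rnap_out", "PoPS", "out", "RNAP"),
        Terminal(f"sir_{name}.dicer", "RNAPS", "bidir", "Dicer"),
        Terminal(f"sir_{name}.sirna_out", "RNAPS", "out", si_t.name),
    ]
    rs = RuleSet(types, seeds, rules, terminals)
    nuclear = PartModel(f"sir_{name}.nuclear", rs, expand(rs, max_species), boundary,
                        Compartment.NUCLEUS)

    # cytoplasmic siRNA pool
    rst = rs_type(name)
    types2 = {t.name: t for t in (si_t, rst, RISC_T)}
    boundary2 = {"RISC", rst.name}
    seeds2 = [(_single(si_t), 0.0), (_single(RISC_T), 0.0)]
    rules2 = [
        Rule("risc_load",
             [Pattern([PatternMolecule(si_t.name, {})]),
              Pattern([PatternMolecule("RISC", {})])],
             [Delete((0, 0)), Delete((1, 0)), Create(_single(rst))],
             spec.risc_load_rate, tag="rnai"),
        Rule("sirna_decay", [Pattern([PatternMolecule(si_t.name, {})])],
             [Delete((0, 0))], term.transcript_decay_rate, tag="decay"),
        # the loaded guide strand turns over too, recycling its RISC;
        # without this the loaded complexes sequester the whole RISC pool
        Rule("rs_decay", [Pattern([PatternMolecule(rst.name, {})])],
             [Delete((0, 0)), Create(_single(RISC_T))],
             term.transcript_decay_rate, tag="decay"),
    ]
    terminals2 = [
        Terminal(f"pool_{name}.sirna_in", "RNAPS", "in", si_t.name),
        Terminal(f"pool_{name}.risc", "RNAPS", "bidir", "RISC"),
        Terminal(f"pool_{name}.rs_out", "RNAPS", "out", rst.name),
    ]
    rs2 = RuleSet(types2, seeds2, rules2, terminals2)
    pool = PartModel(f"pool_{name}", rs2, expand(rs2, max_species), boundary2,
                     Compartment.CYTOPLASM)
    return nuclear, pool


# ---------------------------------------------------------------------------
# transcription-factor, reporter, machinery, and chemical pools


def compile_tf_and_protein_pools(circuit: CircuitSpec) -> list[PartModel]:
    """Pool parts for every protein product, declared TF pool, machinery
    pool, and chemical input of a circuit.

    TF products: the cytoplasmic synthesis intake feeds a first-order
    nuclear import; the nuclear pool carries chemical binding/unbinding
    (``TF + chem <-> TF·chem``) and first-order degradation of both forms.
    Reporters stay cytoplasmic with degradation only.  Machinery pools are
    conserved storages with no reactions.
    """

    models: list[PartModel] = []
    chem_of_tf: dict[str, tuple[str, float, float]] = {}
    for u in circuit.units:
        for b in u.promoter.tf_bindings:
            if b.effector_chemical is not None:
                chem_of_tf[b.tf_name] = (
                    b.effector_chemical,
                    b.chem_solution_bind_rate,
                    b.chem_solution_unbind_rate,
                )

    for prod_name, cds in circuit.coding_products().items():
        pool = circuit.pool(prod_name)
        if cds.product_kind is ProductKind.REPORTER:
            p_t = product_type(prod_name)
            types = {p_t.name: p_t}
            deg = pool.degradation_rate if pool and pool.degradation_rate else 1e-4
            rules = [
                Rule("degrade", [Pattern([PatternMolecule(p_t.name, {})])],
                     [Delete((0, 0))], deg, tag="decay")
            ]
            terminals = [Terminal(f"pool_{prod_name}.intake", "protein", "in", p_t.name)]
            rs = RuleSet(types, [(_single(p_t), 0.0)], rules, terminals)
            models.append(
                PartModel(f"pool_{prod_name}", rs, expand(rs), set(), Compartment.CYTOPLASM)
            )
        else:
            models.append(_tf_pool(prod_name, pool, chem_of_tf.get(prod_name)))

    produced = set(circuit.coding_products())
    for p in circuit.pools:
        if p.name in produced:
            continue
        if p.carrier is SignalCarrierKind.TRANSCRIPTION_FACTOR:
            models.append(_tf_pool(p.name, p, chem_of_tf.get(p.name), declared_only=True))
        elif p.name in ("RNAP", "Ribosome", "Spliceosome", "Dicer", "RISC"):
            mt = {"RNAP": RNAP_T, "Ribosome": RIB_T, "Spliceosome": SPL_T,
                  "Dicer": DICER_T, "RISC": RISC_T}[p.name]
            comp = Compartment.CYTOPLASM if p.name in ("Ribosome", "RISC") else Compartment.NUCLEUS
            rs = RuleSet({mt.name: mt}, [(_single(mt), float(p.initial_copies))], [],
                         [Terminal(f"pool_{p.name}.store", "RiPS", "bidir", mt.name)])
            models.append(PartModel(f"pool_{p.name}", rs, expand(rs), set(), comp))

    for chem in circuit.chemical_inputs:
        ct = chem_type(chem)
        rs = RuleSet({ct.name: ct}, [(_single(ct), 0.0)], [],
                     [Terminal(f"pool_{chem}.sips", "SiPS", "in", ct.name)])
        models.append(PartModel(f"pool_{chem}", rs, expand(rs), set(), Compartment.NUCLEUS))
    return models


def _tf_pool(name: str, pool: PoolSpec | None, chem_info, declared_only: bool = False) -> PartModel:
    tf_t = tf_type(name)
    tc_t = tfc_type(name)
    p_t = product_type(name)
    types = {tf_t.name: tf_t, tc_t.name: tc_t}
    seeds = [(_single(tf_t), float(pool.initial_copies) if pool else 0.0)]
    rules = []
    boundary: set[str] = set()
    import_rate = pool.import_rate if pool and pool.import_rate else 1e-3
    deg = pool.degradation_rate if pool else None
    if not declared_only:
        types[p_t.name] = p_t
        boundary.add(p_t.name)
        seeds.append((_single(p_t), 0.0))
        rules.append(
            Rule("import", [Pattern([PatternMolecule(p_t.name, {})])],
                 [Delete((0, 0)), Create(_single(tf_t))], import_rate, tag="transport")
        )
    if chem_info is not None:
        chem, kon, koff = chem_info
        ct = chem_type(chem)
        types.setdefault(ct.name, ct)
        boundary.add(ct.name)
        seeds.append((_single(ct), 0.0))
        rules.append(
            Rule("chem_bind",
                 [Pattern([PatternMolecule(tf_t.name, {"d": PatternComponent(bond="unbound")})]),
                  Pattern([PatternMolecule(ct.name, {})])],
                 [Delete((0, 0)), Delete((1, 0)), Create(_single(tc_t))], kon, tag="effector")
        )
        rules.append(
            Rule("chem_unbind", [Pattern([PatternMolecule(tc_t.name, {})])],
                 [Delete((0, 0)), Create(_single(tf_t)), Create(_single(ct))],
                 koff, tag="effector")
        )
        seeds.append((_single(tc_t), 0.0))
    if deg:
        rules.append(
            Rule("degrade_tf",
                 [Pattern([PatternMolecule(tf_t.name, {"d": PatternComponent(bond="unbound")})])],
                 [Delete((0, 0))], deg, tag="decay")
        )
        if chem_info is not None:
            rules.append(
                Rule("degrade_tfc", [Pattern([PatternMolecule(tc_t.name, {})])],
                     [Delete((0, 0))], deg, tag="decay")
            )
    terminals = [Terminal(f"pool_{name}.faps", "FaPS", "bidir", tf_t.name)]
    if not declared_only:
        terminals.insert(0, Terminal(f"pool_{name}.intake", "protein", "in", p_t.name))
    rs = RuleSet(types, seeds, rules, terminals)
    return PartModel(f"pool_{name}", rs, expand(rs), boundary, Compartment.NUCLEUS)


def _aptamer_coop_modifier(mname: str, other_comp: str):
    def modifier(graphs, _emb):
        g = graphs[0]
        for m in g.molecules:
            if m.mtype.name == mname and m.states.get(other_comp) == "bound":
                return RIBOSWITCH_COOP_FACTOR
        return 1.0

    return modifier


# ---------------------------------------------------------------------------
# per-part report records


def part_report(models: list[PartModel]) -> list[dict]:
    return [
        {
            "part": m.name,
            "compartment": m.compartment.value,
            "n_species": m.n_species,
            "n_reactions": m.n_reactions,
            "n_terminals": m.n_terminals,
        }
        for m in models
    ]


def part_report_json(models: list[PartModel]) -> str:
    return json.dumps(part_report(models), indent=2)
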
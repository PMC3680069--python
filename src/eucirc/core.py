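"""User-facing specification layer: parts, pools, compartments, circuits.

A circuit is declared as a set of transcription units (promoter + cargo +
terminator, all nuclear) plus pools of free signal carriers distributed over
the nucleus and the cytoplasm.  Five signal-carrier classes are exchanged
between modules; each is identified with a named flux (molecules per second)
across module terminals:

    RNA polymerase      -> PoPS  (polymerases per second)
    ribosome            -> RiPS  (ribosomes per second)
    transcription factor-> FaPS  (factors per second)
    small RNA           -> RNAPS (small RNAs per second)
    chemical            -> SiPS  (signals per second)

These types carry no kinetics themselves beyond rate constants; compilation
into reaction networks lives in :mod:`eucirc.parts`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Optional, Union

__all__ = [
    "SignalCarrierKind",
    "FLUX_NAMES",
    "Role",
    "EffectorMode",
    "TFBindingSpec",
    "PromoterSpec",
    "RiboswitchKind",
    "Cooperativity",
    "RiboswitchSpec",
    "SiRNATargetSpec",
    "ProductKind",
    "CodingRegionSpec",
    "SiRNAGeneSpec",
    "TerminatorSpec",
    "Compartment",
    "PoolSpec",
    "TranscriptionUnitSpec",
    "CircuitSpec",
    "Diagnostic",
    "validate",
    "molar_to_stochastic",
]


class SignalCarrierKind(enum.Enum):
    """The five signal-carrier classes and their canonical flux names."""

    RNA_POLYMERASE = "RNA_polymerase"
    RIBOSOME = "ribosome"
    TRANSCRIPTION_FACTOR = "transcription_factor"
    SMALL_RNA = "small_RNA"
    CHEMICAL = "chemical"

    @property
    def flux_name(self) -> str:
        return FLUX_NAMES[self]


#: bijection carrier kind <-> flux acronym
FLUX_NAMES = {
    SignalCarrierKind.RNA_POLYMERASE: "PoPS",
    SignalCarrierKind.RIBOSOME: "RiPS",
    SignalCarrierKind.TRANSCRIPTION_FACTOR: "FaPS",
    SignalCarrierKind.SMALL_RNA: "RNAPS",
    SignalCarrierKind.CHEMICAL: "SiPS",
}


class Role(enum.Enum):
    ACTIVATOR = "activator"
    REPRESSOR = "repressor"


class EffectorMode(enum.Enum):
    """How a chemical effector acts on a DNA-bound transcription factor.

    ``INDUCER_STRIPS``: the chemical binds the factor and strips it off its
    operator (inactivation of either a repressor or an activator).
    ``COREPRESSOR_STRIPS``: same stripping event but the stripped factor is an
    activator holding RNA polymerase, so removal may eject the polymerase.
    """

    INDUCER_STRIPS = "inducer_strips"
    COREPRESSOR_STRIPS = "corepressor_strips"


@dataclass(frozen=True)
class TFBindingSpec:
    """One transcription-factor species acting on a promoter through
    ``n_operators`` operators.

    Operator affinity varies with rank (distance from the transcription start
    site): repressors bind strongest closest to the TSS, activators strongest
    furthest from it.  ``affinity_gradient`` is the multiplicative fall-off per
    rank step (>= 1 means weaker binding at weaker ranks).  When
    ``cooperative``, occupancy of the rank-adjacent operator of the same
    factor multiplies the binding rate by ``cooperativity_factor``.
    """

    tf_name: str
    role: Role
    n_operators: int = 1
    cooperative: bool = False
    effector_chemical: Optional[str] = None
    effector_mode: EffectorMode = EffectorMode.INDUCER_STRIPS
    base_bind_rate: float = 1e-3  # per molecule per second
    unbind_rate: float = 1e-2  # per second
    affinity_gradient: float = 1.0
    cooperativity_factor: float = 1.0
    # effector kinetics: stripping off DNA, and solution-phase TF<->chemical
    chem_strip_rate: float = 1e-3  # per molecule per second
    chem_solution_bind_rate: float = 1e-3  # per molecule per second
    chem_solution_unbind_rate: float = 1e-3  # per second


@dataclass(frozen=True)
class PromoterSpec:
    name: str
    tf_bindings: tuple[TFBindingSpec, ...] = ()
    rnap_bind_rate: float = 1e-3  # per molecule per second
    rnap_unbind_rate: float = 1.0  # per second
    clearing_rate: float = 0.1  # per second
    leak_rate: float = 0.0  # per second, per leaky configuration
    # turnover of DNA-bound factors (degradation freeing the operator)
    tf_dna_turnover_rate: float = 1e-7  # per second

    def __post_init__(self):
        if isinstance(self.tf_bindings, list):
            object.__setattr__(self, "tf_bindings", tuple(self.tf_bindings))

    @property
    def n_operators_total(self) -> int:
        return sum(b.n_operators for b in self.tf_bindings)


class RiboswitchKind(enum.Enum):
    SINGLE = "single"
    TANDEM = "tandem"


class Cooperativity(enum.Enum):
    NONE = "none"
    HOMO = "homo"
    HETERO = "hetero"


@dataclass(frozen=True)
class RiboswitchSpec:
    """A 5'-UTR hairpin element gating ribosome binding.

    The element breathes between *off* and *on* conformations; chemical
    occupancy of its aptamer(s) locks the *on* state.  Ribosomes load only
    when every riboswitch on the transcript is *on*.
    """

    kind: RiboswitchKind = RiboswitchKind.SINGLE
    aptamer_chemicals: tuple[str, ...] = ()
    cooperativity: Cooperativity = Cooperativity.NONE
    switch_on_rate: float = 1e-3
    switch_off_rate: float = 1e-1
    chem_bind_rate: float = 1e-3
    chem_unbind_rate: float = 1e-2

    def __post_init__(self):
        if isinstance(self.aptamer_chemicals, list):
            object.__setattr__(self, "aptamer_chemicals", tuple(self.aptamer_chemicals))


@dataclass(frozen=True)
class SiRNATargetSpec:
    """``n_sites`` binding sites for one siRNA species on the 3'-UTR."""

    sirna_name: str
    n_sites: int = 1
    bind_rate: float = 1e-4  # RISC·siRNA onto a site, per molecule per second
    cleavage_rate: float = 1e-2  # per second, cleavage + rapid degradation


class ProductKind(enum.Enum):
    TRANSCRIPTION_FACTOR = "transcription_factor"
    REPORTER = "reporter"


@dataclass(frozen=True)
class CodingRegionSpec:
    name: str
    product_name: str
    product_kind: ProductKind = ProductKind.REPORTER
    riboswitches: tuple[RiboswitchSpec, ...] = ()
    sirna_targets: tuple[SiRNATargetSpec, ...] = ()
    # spliceosome Michaelis-Menten constants (three elementary reactions)
    splice_bind_rate: float = 1e-3
    splice_unbind_rate: float = 1e-2
    splice_cat_rate: float = 0.1
    export_rate: float = 1e-2  # lumped maturation + nuclear export
    nuclear_decay_rate: float = 1e-4  # immature transcript turnover
    ribosome_bind_rate: float = 1e-4
    ribosome_unbind_rate: float = 1e-2
    translation_rate: float = 0.05  # initiation -> elongation
    completion_rate: float = 0.05  # elongation -> protein + cleared ribosome
    ribosome_clear_rate: float = 1.0  # cleared ribosome returns to pool
    protein_release_rate: float = 1.0  # nascent protein enters product pool
    transit_rate: float = 1.0  # cleared polymerase traverses the unit

    def __post_init__(self):
        if isinstance(self.riboswitches, list):
            object.__setattr__(self, "riboswitches", tuple(self.riboswitches))
        if isinstance(self.sirna_targets, list):
            object.__setattr__(self, "sirna_targets", tuple(self.sirna_targets))


@dataclass(frozen=True)
class SiRNAGeneSpec:
    sirna_name: str
    dicer_bind_rate: float = 1e-3
    dicer_unbind_rate: float = 1e-2
    dicer_cat_rate: float = 0.1
    export_rate: float = 1e-2
    nuclear_decay_rate: float = 1e-4
    risc_load_rate: float = 1e-3
    transit_rate: float = 1.0  # cleared polymerase traverses the unit


@dataclass(frozen=True)
class TerminatorSpec:
    """Terminators set transcript stability: the decay rate of the mRNA or
    siRNA made by the unit they terminate."""

    name: str
    transcript_decay_rate: float = 1e-4  # per second


class Compartment(enum.Enum):
    NUCLEUS = "nucleus"
    CYTOPLASM = "cytoplasm"


@dataclass(frozen=True)
class PoolSpec:
    """Cellular storage for free molecules of one signal carrier."""

    name: str
    carrier: SignalCarrierKind
    compartment: Compartment
    initial_copies: int = 0
    conserved: bool = False  # machinery pools: no synthesis/degradation
    import_rate: Optional[float] = None  # TF nuclear import, per second
    degradation_rate: Optional[float] = None  # per second


@dataclass(frozen=True)
class TranscriptionUnitSpec:
    promoter: PromoterSpec
    cargo: Union[CodingRegionSpec, SiRNAGeneSpec]
    terminator: TerminatorSpec
    compartment: Compartment = Compartment.NUCLEUS


#: the machinery pools a circuit must declare exactly once each
MACHINERY = ("RNAP", "Ribosome", "Spliceosome", "Dicer", "RISC")

MACHINERY_CARRIER = {
    "RNAP": SignalCarrierKind.RNA_POLYMERASE,
    "Ribosome": SignalCarrierKind.RIBOSOME,
    "Spliceosome": SignalCarrierKind.RIBOSOME,  # processing machinery class
    "Dicer": SignalCarrierKind.SMALL_RNA,
    "RISC": SignalCarrierKind.SMALL_RNA,
}


@dataclass(frozen=True)
class CircuitSpec:
    name: str
    units: tuple[TranscriptionUnitSpec, ...] = ()
    pools: tuple[PoolSpec, ...] = ()
    chemical_inputs: tuple[str, ...] = ()
    nucleus_volume: float = 3e-15  # liters (order-of-magnitude yeast nucleus)
    cytoplasm_volume: float = 30e-15  # liters

    def __post_init__(self):
        for attr in ("units", "pools", "chemical_inputs"):
            v = getattr(self, attr)
            if isinstance(v, list):
                object.__setattr__(self, attr, tuple(v))

    def pool(self, name: str) -> Optional[PoolSpec]:
        for p in self.pools:
            if p.name == name:
                return p
        return None

    def coding_products(self) -> dict[str, CodingRegionSpec]:
        return {
            u.cargo.product_name: u.cargo
            for u in self.units
            if isinstance(u.cargo, CodingRegionSpec)
        }

    def sirna_genes(self) -> dict[str, SiRNAGeneSpec]:
        return {
            u.cargo.sirna_name: u.cargo
            for u in self.units
            if isinstance(u.cargo, SiRNAGeneSpec)
        }

    def with_units(self, units) -> "CircuitSpec":
        return replace(self, units=tuple(units))


@dataclass(frozen=True)
class Diagnostic:
    severity: str  # "error" | "warning"
    code: str
    message: str
    element: str = ""

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"[{self.severity}] {self.code}: {self.message} ({self.element})"


def molar_to_stochastic(k_molar: float, volume_liters: float, order: int = 2) -> float:
    """Convert a molar rate constant to a per-molecule stochastic rate.

    Bimolecular constants in 1/(M s) become per-molecule-per-second rates by
    dividing by N_A * V of the hosting compartment; first-order constants are
    returned unchanged.  All rate constants elsewhere in the package are
    already stochastic (per-copy) rates, so compartment volume only enters
    through this helper.
    """

    if order == 1:
        return k_molar
    if order != 2:
        raise ValueError("only first- and second-order constants supported")
    N_A = 6.02214076e23
    return k_molar / (N_A * volume_liters)


def _rate_fields(obj) -> list[tuple[str, float]]:
    out = []
    for name, val in vars(obj).items():
        if name.endswith("_rate") and isinstance(val, (int, float)):
            out.append((name, float(val)))
    return out


def validate(circuit: CircuitSpec) -> list[Diagnostic]:
    """Check every structural invariant of a circuit specification.

    Returns an empty list iff the spec is well formed: all names resolve,
    machinery pools are declared exactly once, rates are non-negative, and
    part-level constraints (operator counts, riboswitch arity, effector
    modes) hold.  Pure function; safe to call repeatedly.
    """

    diags: list[Diagnostic] = []

    def err(code, msg, element=""):
        diags.append(Diagnostic("error", code, msg, element))

    def warn(code, msg, element=""):
        diags.append(Diagnostic("warning", code, msg, element))

    pool_names = [p.name for p in circuit.pools]
    seen = set()
    for n in pool_names:
        if n in seen:
            err("duplicate-pool", f"pool '{n}' declared more than once", n)
        seen.add(n)

    for m in MACHINERY:
        matches = [p for p in circuit.pools if p.name == m]
        if len(matches) != 1:
            err(
                "machinery-pool",
                f"machinery pool '{m}' must be declared exactly once "
                f"(found {len(matches)})",
                m,
            )

    products = circuit.coding_products()
    sirnas = circuit.sirna_genes()
    chemicals = set(circuit.chemical_inputs)

    def tf_resolves(name: str) -> bool:
        if name in products and products[name].product_kind is ProductKind.TRANSCRIPTION_FACTOR:
            return True
        p = circuit.pool(name)
        return p is not None and p.carrier is SignalCarrierKind.TRANSCRIPTION_FACTOR

    for u in circuit.units:
        prom = u.promoter
        tf_names = [b.tf_name for b in prom.tf_bindings]
        if len(set(tf_names)) != len(tf_names):
            err("duplicate-tf", "TF names must be unique within a promoter", prom.name)
        for b in prom.tf_bindings:
            if b.n_operators < 1:
                err(
                    "invariant",
                    f"n_operators must be >= 1 (got {b.n_operators})",
                    f"{prom.name}/{b.tf_name}",
                )
            if b.effector_mode is EffectorMode.COREPRESSOR_STRIPS and b.role is not Role.ACTIVATOR:
                err(
                    "invariant",
                    "corepressor stripping applies only to activators",
                    f"{prom.name}/{b.tf_name}",
                )
            if not tf_resolves(b.tf_name):
                err(
                    "unresolved-name",
                    f"transcription factor '{b.tf_name}' is neither a TF pool "
                    "nor the product of a transcription unit",
                    f"{prom.name}/{b.tf_name}",
                )
            if b.effector_chemical is not None and b.effector_chemical not in chemicals:
                err(
                    "unresolved-name",
                    f"effector chemical '{b.effector_chemical}' not listed as a circuit input",
                    f"{prom.name}/{b.tf_name}",
                )
            for rname, rval in _rate_fields(b):
                if rval < 0:
                    err("negative-rate", f"{rname} < 0", f"{prom.name}/{b.tf_name}")
        for rname, rval in _rate_fields(prom):
            if rval < 0:
                err("negative-rate", f"{rname} < 0", prom.name)

        if u.terminator.transcript_decay_rate <= 0:
            err("invariant", "terminator decay rate must be > 0", u.terminator.name)

        cargo = u.cargo
        if isinstance(cargo, CodingRegionSpec):
            for rs in cargo.riboswitches:
                n_apt = len(rs.aptamer_chemicals)
                if rs.kind is RiboswitchKind.SINGLE and n_apt != 1:
                    err("invariant", "single riboswitch needs exactly 1 aptamer", cargo.name)
                if rs.kind is RiboswitchKind.TANDEM and n_apt != 2:
                    err("invariant", "tandem riboswitch needs exactly 2 aptamers", cargo.name)
                if rs.cooperativity is Cooperativity.HOMO and len(set(rs.aptamer_chemicals)) != 1:
                    err("invariant", "homo-cooperative aptamers must bind one chemical", cargo.name)
                if rs.cooperativity is Cooperativity.HETERO and len(set(rs.aptamer_chemicals)) < 2:
                    err("invariant", "hetero-cooperative aptamers need two chemicals", cargo.name)
                for c in rs.aptamer_chemicals:
                    if c not in chemicals:
                        err("unresolved-name", f"aptamer chemical '{c}' not a circuit input", cargo.name)
            for t in cargo.sirna_targets:
                if t.n_sites < 1:
                    err("invariant", "siRNA target needs n_sites >= 1", f"{cargo.name}/{t.sirna_name}")
                if t.sirna_name not in sirnas:
                    err(
                        "unresolved-name",
                        f"siRNA '{t.sirna_name}' has no producing siRNA gene",
                        f"{cargo.name}/{t.sirna_name}",
                    )
        elif isinstance(cargo, SiRNAGeneSpec):
            targeted = any(
                t.sirna_name == cargo.sirna_name
                for cds in products.values()
                for t in cds.sirna_targets
            )
            if not targeted:
                warn(
                    "inert-sirna",
                    f"siRNA '{cargo.sirna_name}' targets no declared mRNA",
                    cargo.sirna_name,
                )
        for rname, rval in _rate_fields(cargo):
            if rval < 0:
                err("negative-rate", f"{rname} < 0", getattr(cargo, "name", str(cargo)))

    for p in circuit.pools:
        if p.initial_copies < 0:
            err("invariant", "initial_copies must be >= 0", p.name)
        for rname in ("import_rate", "degradation_rate"):
            v = getattr(p, rname)
            if v is not None and v < 0:
                err("negative-rate", f"{rname} < 0", p.name)

    return diags
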
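"""Wire compiled parts and pools into a flattened two-compartment circuit.

Each transcription unit contributes a promoter part and a nuclear cargo part
plus the cargo's cytoplasmic pool; protein, transcription-factor, machinery
and chemical pools are compiled from the circuit declaration.  Flattening
unifies shared species only at declared terminals: internal species carry
part-qualified molecule-type names, while boundary (pool/adapter) species
use pool-level names, so a merge can only happen where two parts declare the
same attached pool species.  Transport reactions (mRNA/siRNA export, TF
import) live inside the exporting part and are tagged ``transport``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import (
    CircuitSpec,
    CodingRegionSpec,
    Compartment,
    validate,
)
from .parts import (
    PartModel,
    compile_coding_region,
    compile_promoter,
    compile_sirna_gene,
    compile_tf_and_protein_pools,
)
from .rules import SpeciesGraph, Terminal

__all__ = ["CircuitModel", "FlatReaction", "WiringError", "CarrierMismatchError",
           "wire", "report"]


class WiringError(ValueError):
    pass


class CarrierMismatchError(TypeError):
    pass


@dataclass(frozen=True)
class FlatReaction:
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate_constant: float
    module: str
    rule: str
    tag: str = ""


@dataclass
class CircuitModel:
    name: str
    species: list[str]
    graphs: dict[str, SpeciesGraph]
    compartment: dict[str, Compartment]
    initial: dict[str, float]
    reactions: list[FlatReaction]
    parts: list[PartModel]
    parameters: dict[str, float] = field(default_factory=dict)
    chemical_labels: dict[str, str] = field(default_factory=dict)
    merged_species: int = 0  # labels shared by more than one part

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def index(self, label: str) -> int:
        return self.species.index(label)

    def label_of(self, type_name: str) -> str:
        """Canonical label of the single-molecule, stateless species of a
        pool-level molecule type (e.g. ``P_GFP`` -> ``P_GFP()``)."""
        for lab in self.species:
            g = self.graphs[lab]
            if len(g.molecules) == 1 and g.molecules[0].mtype.name == type_name:
                return lab
        raise KeyError(type_name)


def _part_models(circuit: CircuitSpec) -> tuple[list[PartModel], dict[str, dict[str, str]]]:
    """Compile every part; return models plus per-part label renames that
    resolve each cargo's generic PoPS input onto its promoter's Pol^cl."""
    models: list[PartModel] = []
    renames: dict[str, dict[str, str]] = {}
    for u in circuit.units:
        prom_model = compile_promoter(u.promoter)
        models.append(prom_model)
        polcl_label = f"PolCl_{u.promoter.name}()"
        if isinstance(u.cargo, CodingRegionSpec):
            nuc, pool = compile_coding_region(u.cargo, u.terminator)
            popsin = f"PoPSin_{u.cargo.name}"
        else:
            nuc, pool = compile_sirna_gene(u.cargo, u.terminator)
            popsin = f"PoPSin_sir_{u.cargo.sirna_name}"
        renames[nuc.name] = {f"{popsin}()": polcl_label,
                             popsin: f"PolCl_{u.promoter.name}"}
        models.append(nuc)
        models.append(pool)
    models.extend(compile_tf_and_protein_pools(circuit))
    return models, renames


def _check_terminals(models: list[PartModel], type_renames: dict[str, dict[str, str]]) -> None:
    """Every in-terminal must face an out/bidir counterpart on the same
    attached species type (and conversely for outs feeding consumers)."""
    by_type: dict[str, list[tuple[str, Terminal]]] = {}
    for m in models:
        ren = type_renames.get(m.name, {})
        for t in m.terminals:
            key = ren.get(t.attached, t.attached)
            by_type.setdefault(key, []).append((m.name, t))
    for key, terms in by_type.items():
        carriers = {t.carrier for _, t in terms if t.carrier != "protein"}
        if len(carriers) > 2:
            parts = ", ".join(f"{p}:{t.name}" for p, t in terms)
            raise CarrierMismatchError(
                f"terminals on species type {key} disagree on carrier kind: {parts}"
            )
    for key, terms in by_type.items():
        if len(terms) == 1 and terms[0][1].direction == "in" and not terms[0][0].startswith("pool_"):
            part, t = terms[0]
            raise WiringError(
                f"terminal {t.name} of part {part} (carrier {t.carrier}) has no "
                f"counterpart for species type {key}"
            )


def wire(circuit: CircuitSpec) -> CircuitModel:
    """Compile and flatten a validated circuit into one reaction network.

    Raises ``ValueError`` on validation errors, :class:`WiringError` on
    unmatched terminals, :class:`CarrierMismatchError` on carrier-kind
    conflicts between terminals attached to the same species.
    """

    diags = [d for d in validate(circuit) if d.severity == "error"]
    if diags:
        raise ValueError(
            "circuit does not validate: " + "; ".join(str(d) for d in diags)
        )

    models, renames = _part_models(circuit)
    _check_terminals(models, renames)

    graphs: dict[str, SpeciesGraph] = {}
    compartment: dict[str, Compartment] = {}
    initial: dict[str, float] = {}
    owners: dict[str, set[str]] = {}
    reactions: list[FlatReaction] = []

    for m in models:
        ren = renames.get(m.name, {})
        internal = set(m.internal_species)
        for lab in m.expanded.species:
            glab = ren.get(lab, lab)
            if glab not in graphs:
                # a renamed PoPS-input label must take the producing
                # promoter's Pol^cl graph, never the placeholder's
                graphs[glab] = None if lab in ren else m.expanded.graphs[lab]
                compartment[glab] = m.compartment
                initial[glab] = 0.0
            elif graphs[glab] is None and lab not in ren:
                graphs[glab] = m.expanded.graphs[lab]
            if lab in internal:
                compartment[glab] = m.compartment
            initial[glab] += m.expanded.initial.get(lab, 0.0)
            owners.setdefault(glab, set()).add(m.name)
        for rx in m.expanded.reactions:
            reactions.append(
                FlatReaction(
                    reactants=tuple(ren.get(l, l) for l in rx.reactants),
                    products=tuple(ren.get(l, l) for l in rx.products),
                    rate_constant=rx.rate_constant,
                    module=m.name,
                    rule=rx.rule,
                    tag=rx.tag,
                )
            )

    # renamed PoPS inputs must have been produced by their promoter
    for ren in renames.values():
        for old, polcl in ren.items():
            if not old.endswith("()"):
                continue  # type-level alias, not a species label
            if polcl not in graphs or graphs[polcl] is None:
                raise WiringError(f"PoPS source species {polcl} missing after wiring")

    keys = [(r.module, r.rule, r.reactants, r.products) for r in reactions]
    if len(set(keys)) != len(keys):  # pragma: no cover - structural guarantee
        raise WiringError("duplicate reactions after flattening")

    merged = sum(1 for labs in owners.values() if len(labs) > 1)
    chem_labels = {c: f"Chem_{c}()" for c in circuit.chemical_inputs}
    model = CircuitModel(
        name=circuit.name,
        species=sorted(graphs),
        graphs=graphs,
        compartment=compartment,
        initial=initial,
        reactions=reactions,
        parts=models,
        parameters={
            "nucleus_volume_l": circuit.nucleus_volume,
            "cytoplasm_volume_l": circuit.cytoplasm_volume,
        },
        chemical_labels=chem_labels,
        merged_species=merged,
    )
    return model


def report(model: CircuitModel) -> dict:
    """Per-module and whole-circuit species/reaction/terminal manifest."""
    rows = [
        {
            "part": m.name,
            "compartment": m.compartment.value,
            "n_species": m.n_species,
            "n_reactions": m.n_reactions,
            "n_terminals": m.n_terminals,
        }
        for m in model.parts
    ]
    return {
        "circuit": model.name,
        "modules": rows,
        "total_species": model.n_species,
        "total_reactions": model.n_reactions,
        "merged_species": model.merged_species,
    }
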
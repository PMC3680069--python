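"""Circuit description files, SBML export, and manifest serialization.

The circuit file dialect is a line-oriented structured text with a
versioned header, four sections, and nested part blocks::

    # eucirc-circuit v1
    [compartments]
    nucleus = 3e-15
    cytoplasm = 3e-14
    [pools]
    pool RNAP { carrier = RNA_polymerase ... }
    [units]
    unit u0 {
      promoter P_rep { rnap_bind_rate = 0.001
        tf A_act { role = activator n_operators = 1 } }
      coding_region rep { product = GFP ... }
      terminator T_rep { decay = 0.0002 }
    }
    [inputs]
    chemical a

Parsing is round-trip stable (parse -> serialize -> parse yields an equal
specification) and every syntax error carries its line number.
"""

from __future__ import annotations

import csv
import json
import re
from typing import Optional

from lxml import etree

from .compose import CircuitModel, report
from .core import (
    CircuitSpec,
    CodingRegionSpec,
    Compartment,
    Cooperativity,
    EffectorMode,
    PoolSpec,
    ProductKind,
    PromoterSpec,
    RiboswitchKind,
    RiboswitchSpec,
    Role,
    SignalCarrierKind,
    SiRNAGeneSpec,
    SiRNATargetSpec,
    TerminatorSpec,
    TFBindingSpec,
    TranscriptionUnitSpec,
)

__all__ = [
    "ParseError",
    "parse_circuit",
    "parse_circuit_file",
    "serialize_circuit",
    "write_circuit_file",
    "export_sbml",
    "read_sbml_stoichiometry",
    "write_manifest_json",
    "write_manifest_csv",
]

HEADER = "# eucirc-circuit v1"


class ParseError(ValueError):
    def __init__(self, message: str, line: int, column: int = 1):
        super().__init__(f"line {line}, column {column}: {message}")
        self.line = line
        self.column = column


# ---------------------------------------------------------------------------
# low-level line model


class _Lines:
    def __init__(self, text: str):
        self.lines = text.splitlines()
        self.pos = 0

    def peek(self) -> Optional[tuple[int, str]]:
        while self.pos < len(self.lines):
            raw = self.lines[self.pos]
            stripped = raw.split("#", 1)[0].strip() if not raw.lstrip().startswith("#") else ""
            if stripped:
                return self.pos + 1, stripped
            self.pos += 1
        return None

    def next(self) -> tuple[int, str]:
        item = self.peek()
        if item is None:
            raise ParseError("unexpected end of file", len(self.lines) + 1)
        self.pos += 1
        return item


_KV = re.compile(r"^(\w+)\s*=\s*(.+)$")
_BLOCK = re.compile(r"^(\w+)(?:\s+([\w.\-]+))?\s*\{$")


def _parse_block(lines: _Lines) -> dict:
    """Read ``key = value`` pairs and nested blocks until the closing brace."""
    out: dict = {"_children": []}
    while True:
        ln, text = lines.next()
        if text == "}":
            return out
        m = _KV.match(text)
        if m:
            out[m.group(1)] = (m.group(2).strip(), ln)
            continue
        m = _BLOCK.match(text)
        if m:
            child = _parse_block(lines)
            child["_kind"] = m.group(1)
            child["_name"] = m.group(2)
            child["_line"] = ln
            out["_children"].append(child)
            continue
        raise ParseError(f"cannot parse '{text}'", ln)


def _get(block: dict, key: str, line: int, required: bool = True, default=None):
    if key not in block:
        if required:
            raise ParseError(f"missing required field '{key}'", line)
        return default
    return block[key][0]


def _num(block: dict, key: str, line: int, required: bool = True, default=None):
    raw = _get(block, key, line, required, None)
    if raw is None:
        return default
    try:
        return float(raw)
    except ValueError:
        raise ParseError(f"field '{key}' is not a number: '{raw}'", block[key][1])


def _boolean(block, key, line, default=False):
    raw = _get(block, key, line, required=False)
    if raw is None:
        return default
    if raw not in ("true", "false"):
        raise ParseError(f"field '{key}' must be true/false", block[key][1])
    return raw == "true"


def _enum(cls, raw: str, line: int):
    try:
        return cls(raw)
    except ValueError:
        valid = ", ".join(e.value for e in cls)
        raise ParseError(f"'{raw}' is not one of: {valid}", line)


# ---------------------------------------------------------------------------
# section parsers

_RATE_FIELDS_TF = (
    "base_bind_rate", "unbind_rate", "affinity_gradient", "cooperativity_factor",
    "chem_strip_rate", "chem_solution_bind_rate", "chem_solution_unbind_rate",
)
_RATE_FIELDS_PROM = (
    "rnap_bind_rate", "rnap_unbind_rate", "clearing_rate", "leak_rate",
    "tf_dna_turnover_rate",
)
_RATE_FIELDS_CDS = (
    "splice_bind_rate", "splice_unbind_rate", "splice_cat_rate", "export_rate",
    "nuclear_decay_rate", "ribosome_bind_rate", "ribosome_unbind_rate",
    "translation_rate", "completion_rate", "ribosome_clear_rate",
    "protein_release_rate", "transit_rate",
)
_RATE_FIELDS_SIR = (
    "dicer_bind_rate", "dicer_unbind_rate", "dicer_cat_rate", "export_rate",
    "nuclear_decay_rate", "risc_load_rate", "transit_rate",
)
_RATE_FIELDS_RSW = (
    "switch_on_rate", "switch_off_rate", "chem_bind_rate", "chem_unbind_rate",
)


def _numeric_overrides(cls, block, fields, line):
    out = {}
    for f in fields:
        v = _num(block, f, line, required=False)
        if v is not None:
            out[f] = v
    return out


def _parse_tf(block: dict) -> TFBindingSpec:
    ln = block["_line"]
    if block["_name"] is None:
        raise ParseError("tf block needs a name", ln)
    kw = _numeric_overrides(TFBindingSpec, block, _RATE_FIELDS_TF, ln)
    n_ops = _num(block, "n_operators", ln, required=False)
    if n_ops is not None:
        kw["n_operators"] = int(n_ops)
    mode = _get(block, "effector_mode", ln, required=False)
    if mode is not None:
        kw["effector_mode"] = _enum(EffectorMode, mode, ln)
    return TFBindingSpec(
        tf_name=block["_name"],
        role=_enum(Role, _get(block, "role", ln), ln),
        cooperative=_boolean(block, "cooperative", ln),
        effector_chemical=_get(block, "effector", ln, required=False),
        **kw,
    )


def _parse_promoter(block: dict) -> PromoterSpec:
    ln = block["_line"]
    kw = _numeric_overrides(PromoterSpec, block, _RATE_FIELDS_PROM, ln)
    tfs = tuple(_parse_tf(c) for c in block["_children"] if c["_kind"] == "tf")
    return PromoterSpec(name=block["_name"], tf_bindings=tfs, **kw)


def _parse_riboswitch(block: dict) -> RiboswitchSpec:
    ln = block["_line"]
    kw = _numeric_overrides(RiboswitchSpec, block, _RATE_FIELDS_RSW, ln)
    chems = tuple((_get(block, "aptamers", ln) or "").split(","))
    return RiboswitchSpec(
        kind=_enum(RiboswitchKind, _get(block, "kind", ln), ln),
        aptamer_chemicals=tuple(c.strip() for c in chems if c.strip()),
        cooperativity=_enum(
            Cooperativity, _get(block, "cooperativity", ln, required=False) or "none", ln
        ),
        **kw,
    )


def _parse_coding(block: dict) -> CodingRegionSpec:
    ln = block["_line"]
    kw = _numeric_overrides(CodingRegionSpec, block, _RATE_FIELDS_CDS, ln)
    targets = []
    riboswitches = []
    for c in block["_children"]:
        if c["_kind"] == "sirna_target":
            cl = c["_line"]
            targets.append(
                SiRNATargetSpec(
                    sirna_name=c["_name"],
                    n_sites=int(_num(c, "n_sites", cl, required=False, default=1)),
                    bind_rate=_num(c, "bind_rate", cl, required=False, default=1e-4),
                    cleavage_rate=_num(c, "cleavage_rate", cl, required=False, default=1e-2),
                )
            )
        elif c["_kind"] == "riboswitch":
            riboswitches.append(_parse_riboswitch(c))
        else:
            raise ParseError(f"unknown block '{c['_kind']}' in coding region", c["_line"])
    return CodingRegionSpec(
        name=block["_name"],
        product_name=_get(block, "product", ln),
        product_kind=_enum(
            ProductKind, _get(block, "product_kind", ln, required=False) or "reporter", ln
        ),
        riboswitches=tuple(riboswitches),
        sirna_targets=tuple(targets),
        **kw,
    )


def _parse_unit(block: dict) -> TranscriptionUnitSpec:
    ln = block["_line"]
    promoter = cargo = terminator = None
    for c in block["_children"]:
        kind = c["_kind"]
        if kind == "promoter":
            promoter = _parse_promoter(c)
        elif kind == "coding_region":
            cargo = _parse_coding(c)
        elif kind == "sirna_gene":
            kw = _numeric_overrides(SiRNAGeneSpec, c, _RATE_FIELDS_SIR, c["_line"])
            cargo = SiRNAGeneSpec(sirna_name=c["_name"], **kw)
        elif kind == "terminator":
            terminator = TerminatorSpec(
                name=c["_name"],
                transcript_decay_rate=_num(c, "decay", c["_line"]),
            )
        else:
            raise ParseError(f"unknown block '{kind}' in unit", c["_line"])
    for part, label in ((promoter, "promoter"), (cargo, "cargo"), (terminator, "terminator")):
        if part is None:
            raise ParseError(f"unit is missing its {label}", ln)
    return TranscriptionUnitSpec(promoter=promoter, cargo=cargo, terminator=terminator)


def parse_circuit(text: str, name: str = "circuit") -> CircuitSpec:
    lines = _Lines(text)
    first = lines.peek()
    if first is None or first[1] != HEADER.lstrip("# ").strip():
        # header is a comment line; check it verbatim on the raw first line
        raw_first = text.splitlines()[0].strip() if text.splitlines() else ""
        if raw_first != HEADER:
            raise ParseError(f"missing header '{HEADER}'", 1)

    sections: dict[str, list[tuple[int, str]]] = {}
    current: Optional[str] = None
    pools: list[PoolSpec] = []
    units: list[TranscriptionUnitSpec] = []
    chemicals: list[str] = []
    volumes = {"nucleus": 3e-15, "cytoplasm": 30e-15}
    seen_pool_names: set[str] = set()

    while True:
        item = lines.peek()
        if item is None:
            break
        ln, stext = item
        if stext.startswith("[") and stext.endswith("]"):
            current = stext[1:-1]
            if current not in ("compartments", "pools", "units", "inputs"):
                raise ParseError(f"unknown section '{current}'", ln)
            sections[current] = []
            lines.next()
            continue
        if current is None:
            raise ParseError("content before any [section]", ln)
        if current == "compartments":
            lines.next()
            m = _KV.match(stext)
            if not m or m.group(1) not in volumes:
                raise ParseError("expected 'nucleus = <liters>' or 'cytoplasm = <liters>'", ln)
            volumes[m.group(1)] = float(m.group(2))
        elif current == "pools":
            lines.next()
            m = _BLOCK.match(stext)
            if not m or m.group(1) != "pool":
                raise ParseError("expected 'pool <name> {'", ln)
            block = _parse_block(lines)
            pname = m.group(2)
            if pname in seen_pool_names:
                raise ParseError(f"duplicate pool identifier '{pname}'", ln)
            seen_pool_names.add(pname)
            pools.append(
                PoolSpec(
                    name=pname,
                    carrier=_enum(SignalCarrierKind, _get(block, "carrier", ln), ln),
                    compartment=_enum(Compartment, _get(block, "compartment", ln), ln),
                    initial_copies=int(_num(block, "initial", ln, required=False, default=0)),
                    conserved=_boolean(block, "conserved", ln),
                    import_rate=_num(block, "import_rate", ln, required=False),
                    degradation_rate=_num(block, "degradation_rate", ln, required=False),
                )
            )
        elif current == "units":
            lines.next()
            m = _BLOCK.match(stext)
            if not m or m.group(1) != "unit":
                raise ParseError("expected 'unit <name> {'", ln)
            block = _parse_block(lines)
            block["_line"] = ln
            units.append(_parse_unit(block))
        elif current == "inputs":
            lines.next()
            parts = stext.split()
            if len(parts) != 2 or parts[0] != "chemical":
                raise ParseError("expected 'chemical <name>'", ln)
            chemicals.append(parts[1])

    if "pools" not in sections or "units" not in sections:
        missing = [s for s in ("pools", "units") if s not in sections]
        raise ParseError(f"missing section(s): {', '.join(missing)}", len(text.splitlines()) + 1)

    return CircuitSpec(
        name=name,
        units=tuple(units),
        pools=tuple(pools),
        chemical_inputs=tuple(chemicals),
        nucleus_volume=volumes["nucleus"],
        cytoplasm_volume=volumes["cytoplasm"],
    )


def parse_circuit_file(path) -> CircuitSpec:
    with open(path) as fh:
        text = fh.read()
    name = re.sub(r"\.\w+$", "", str(path).rsplit("/", 1)[-1])
    return parse_circuit(text, name=name)


# ---------------------------------------------------------------------------
# serialization


def _fmt(v: float) -> str:
    return repr(float(v))


def _emit_overrides(out, obj, fields, indent):
    for f in fields:
        out.append(f"{indent}{f} = {_fmt(getattr(obj, f))}")


def serialize_circuit(spec: CircuitSpec) -> str:
    out = [HEADER, "[compartments]"]
    out.append(f"nucleus = {_fmt(spec.nucleus_volume)}")
    out.append(f"cytoplasm = {_fmt(spec.cytoplasm_volume)}")
    out.append("[pools]")
    for p in spec.pools:
        out.append(f"pool {p.name} {{")
        out.append(f"  carrier = {p.carrier.value}")
        out.append(f"  compartment = {p.compartment.value}")
        out.append(f"  initial = {p.initial_copies}")
        out.append(f"  conserved = {'true' if p.conserved else 'false'}")
        if p.import_rate is not None:
            out.append(f"  import_rate = {_fmt(p.import_rate)}")
        if p.degradation_rate is not None:
            out.append(f"  degradation_rate = {_fmt(p.degradation_rate)}")
        out.append("}")
    out.append("[units]")
    for i, u in enumerate(spec.units):
        out.append(f"unit u{i} {{")
        prom = u.promoter
        out.append(f"  promoter {prom.name} {{")
        _emit_overrides(out, prom, _RATE_FIELDS_PROM, "    ")
        for b in prom.tf_bindings:
            out.append(f"    tf {b.tf_name} {{")
            out.append(f"      role = {b.role.value}")
            out.append(f"      n_operators = {b.n_operators}")
            out.append(f"      cooperative = {'true' if b.cooperative else 'false'}")
            if b.effector_chemical is not None:
                out.append(f"      effector = {b.effector_chemical}")
                out.append(f"      effector_mode = {b.effector_mode.value}")
            _emit_overrides(out, b, _RATE_FIELDS_TF, "      ")
            out.append("    }")
        out.append("  }")
        cargo = u.cargo
        if isinstance(cargo, CodingRegionSpec):
            out.append(f"  coding_region {cargo.name} {{")
            out.append(f"    product = {cargo.product_name}")
            out.append(f"    product_kind = {cargo.product_kind.value}")
            _emit_overrides(out, cargo, _RATE_FIELDS_CDS, "    ")
            for t in cargo.sirna_targets:
                out.append(f"    sirna_target {t.sirna_name} {{")
                out.append(f"      n_sites = {t.n_sites}")
                out.append(f"      bind_rate = {_fmt(t.bind_rate)}")
                out.append(f"      cleavage_rate = {_fmt(t.cleavage_rate)}")
                out.append("    }")
            for r in cargo.riboswitches:
                out.append("    riboswitch {")
                out.append(f"      kind = {r.kind.value}")
                out.append(f"      aptamers = {','.join(r.aptamer_chemicals)}")
                out.append(f"      cooperativity = {r.cooperativity.value}")
                _emit_overrides(out, r, _RATE_FIELDS_RSW, "      ")
                out.append("    }")
            out.append("  }")
        else:
            out.append(f"  sirna_gene {cargo.sirna_name} {{")
            _emit_overrides(out, cargo, _RATE_FIELDS_SIR, "    ")
            out.append("  }")
        out.append(f"  terminator {u.terminator.name} {{")
        out.append(f"    decay = {_fmt(u.terminator.transcript_decay_rate)}")
        out.append("  }")
        out.append("}")
    out.append("[inputs]")
    for c in spec.chemical_inputs:
        out.append(f"chemical {c}")
    return "\n".join(out) + "\n"


def write_circuit_file(spec: CircuitSpec, path) -> None:
    with open(path, "w") as fh:
        fh.write(serialize_circuit(spec))


# ---------------------------------------------------------------------------
# SBML Level 3 core export

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


class SBMLExportError(ValueError):
    pass


def _species_id(i: int) -> str:
    return f"s{i}"


def export_sbml(model: CircuitModel, path) -> None:
    """Write a flattened circuit as an SBML Level 3 core document.

    Species sit in their compartments with copy-number amounts; every
    reaction carries an explicit mass-action kinetic law.  Refuses to emit a
    species-less model.
    """

    if model.n_species == 0:
        raise SBMLExportError("refusing to export an empty (species-less) model")

    root = etree.Element(f"{{{SBML_NS}}}sbml", nsmap={None: SBML_NS}, level="3", version="2")
    mdl = etree.SubElement(root, f"{{{SBML_NS}}}model", id=_sanitize(model.name))
    locs = etree.SubElement(mdl, f"{{{SBML_NS}}}listOfCompartments")
    for cid, size_key in (("nucleus", "nucleus_volume_l"), ("cytoplasm", "cytoplasm_volume_l")):
        etree.SubElement(
            locs, f"{{{SBML_NS}}}compartment",
            id=cid, size=str(model.parameters.get(size_key, 1.0)),
            spatialDimensions="3", constant="true",
        )
    los = etree.SubElement(mdl, f"{{{SBML_NS}}}listOfSpecies")
    index = {lab: i for i, lab in enumerate(model.species)}
    for lab in model.species:
        etree.SubElement(
            los, f"{{{SBML_NS}}}species",
            id=_species_id(index[lab]),
            name=lab,
            compartment=model.compartment[lab].value,
            initialAmount=str(model.initial.get(lab, 0.0)),
            hasOnlySubstanceUnits="true",
            boundaryCondition="false",
            constant="false",
        )
    lor = etree.SubElement(mdl, f"{{{SBML_NS}}}listOfReactions")
    for j, rx in enumerate(model.reactions):
        r = etree.SubElement(
            lor, f"{{{SBML_NS}}}reaction", id=f"r{j}", name=f"{rx.module}:{rx.rule}",
            reversible="false",
        )
        if rx.reactants:
            lore = etree.SubElement(r, f"{{{SBML_NS}}}listOfReactants")
            for lab, count in _stoich(rx.reactants).items():
                etree.SubElement(
                    lore, f"{{{SBML_NS}}}speciesReference",
                    species=_species_id(index[lab]), stoichiometry=str(count),
                    constant="true",
                )
        if rx.products:
            lop = etree.SubElement(r, f"{{{SBML_NS}}}listOfProducts")
            for lab, count in _stoich(rx.products).items():
                etree.SubElement(
                    lop, f"{{{SBML_NS}}}speciesReference",
                    species=_species_id(index[lab]), stoichiometry=str(count),
                    constant="true",
                )
        kl = etree.SubElement(r, f"{{{SBML_NS}}}kineticLaw")
        math = etree.SubElement(kl, f"{{{MATHML_NS}}}math", nsmap={None: MATHML_NS})
        if rx.reactants:
            apply_ = etree.SubElement(math, f"{{{MATHML_NS}}}apply")
            etree.SubElement(apply_, f"{{{MATHML_NS}}}times")
            ci_k = etree.SubElement(apply_, f"{{{MATHML_NS}}}ci")
            ci_k.text = f" k_r{j} "
            for lab in rx.reactants:
                ci = etree.SubElement(apply_, f"{{{MATHML_NS}}}ci")
                ci.text = f" {_species_id(index[lab])} "
        else:
            ci = etree.SubElement(math, f"{{{MATHML_NS}}}ci")
            ci.text = f" k_r{j} "
        lolp = etree.SubElement(kl, f"{{{SBML_NS}}}listOfLocalParameters")
        etree.SubElement(
            lolp, f"{{{SBML_NS}}}localParameter", id=f"k_r{j}",
            value=repr(rx.rate_constant),
        )
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True)


def _sanitize(name: str) -> str:
    s = re.sub(r"\W", "_", name)
    return s if re.match(r"[A-Za-z_]", s) else f"m_{s}"


def _stoich(labels) -> dict[str, int]:
    out: dict[str, int] = {}
    for lab in labels:
        out[lab] = out.get(lab, 0) + 1
    return out


def read_sbml_stoichiometry(path):
    """Species names and the dense stoichiometry matrix of an SBML document
    written by :func:`export_sbml` (used for round-trip verification)."""
    import numpy as np

    tree = etree.parse(str(path))
    ns = {"s": SBML_NS}
    species = tree.findall(".//s:listOfSpecies/s:species", ns)
    names = [sp.get("name") for sp in species]
    ids = {sp.get("id"): i for i, sp in enumerate(species)}
    reactions = tree.findall(".//s:listOfReactions/s:reaction", ns)
    S = np.zeros((len(names), len(reactions)))
    rates = []
    for j, r in enumerate(reactions):
        for ref in r.findall("s:listOfReactants/s:speciesReference", ns):
            S[ids[ref.get("species")], j] -= float(ref.get("stoichiometry"))
        for ref in r.findall("s:listOfProducts/s:speciesReference", ns):
            S[ids[ref.get("species")], j] += float(ref.get("stoichiometry"))
        lp = r.find("s:kineticLaw/s:listOfLocalParameters/s:localParameter", ns)
        rates.append(float(lp.get("value")) if lp is not None else float("nan"))
    return names, S, rates


# ---------------------------------------------------------------------------
# manifests


def write_manifest_json(model: CircuitModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(report(model), fh, indent=2)
        fh.write("\n")


def write_manifest_csv(model: CircuitModel, path) -> None:
    rep = report(model)
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(
            fh, fieldnames=["part", "compartment", "n_species", "n_reactions", "n_terminals"]
        )
        w.writeheader()
        for row in rep["modules"]:
            w.writerow(row)
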
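"""Wiring: terminal resolution, flattening conservation, determinism."""

import pytest

from eucirc.compose import (
    CarrierMismatchError,
    CircuitModel,
    WiringError,
    _check_terminals,
    report,
    wire,
)
from eucirc.core import CodingRegionSpec, TerminatorSpec
from eucirc.parts import compile_coding_region
from eucirc.rules import Terminal
from eucirc.circuits import build_cascade_example


def test_cascade_wires_into_single_connected_model():
    model = wire(build_cascade_example())
    assert model.n_species > 0 and model.n_reactions > 0
    manifest = report(model)
    names = {row["part"] for row in manifest["modules"]}
    assert {"P_rep", "rep.nuclear", "rep.pool", "sir_si_s.nuclear",
            "pool_si_s", "pool_GFP", "pool_RNAP"} <= names


def test_manifest_shows_printed_part_counts(tx_model, rnai_model):
    tx_rows = {r["part"]: r for r in report(tx_model)["modules"]}
    assert tx_rows["p_and1"]["n_species"] == 65
    assert tx_rows["p_and1"]["n_reactions"] == 834
    assert tx_rows["p_and2"]["n_species"] == 17
    rnai_rows = {r["part"]: r for r in report(rnai_model)["modules"]}
    assert rnai_rows["and1.pool"]["n_species"] == 17
    assert rnai_rows["and1.pool"]["n_reactions"] == 45
    assert rnai_rows["and2.pool"]["n_species"] == 13


def test_shared_reporter_pool_receives_both_gates(rnai_model):
    """Two transcription units producing the same protein share one
    product pool species fed by both synthesis chains."""
    producers = {
        rx.module
        for rx in rnai_model.reactions
        if "P_GFP()" in rx.products
    }
    assert {"and1.pool", "and2.pool"} <= producers
    # only one GFP species exists
    assert sum(1 for s in rnai_model.species if s == "P_GFP()") == 1


def test_flattening_conserves_species_and_reactions(rnai_model):
    """No reactions are lost or duplicated, and the flattened species set
    is exactly the union of part species (modulo declared-terminal merges)."""
    parts = rnai_model.parts
    assert rnai_model.n_reactions == sum(p.n_reactions for p in parts)
    per_part_labels = set()
    for p in parts:
        per_part_labels |= set(p.expanded.species)
    # renames map cargo PoPS inputs onto promoter Pol^cl labels
    renamed = {l for l in per_part_labels if l.startswith("PoPSin")}
    assert set(rnai_model.species) == (per_part_labels - renamed) | {
        l for l in rnai_model.species if l.startswith("PolCl")
    }
    assert rnai_model.merged_species > 0


def test_reaction_reactants_colocalized_or_transport(rnai_model):
    """Reactants of each reaction share one compartment unless the reaction
    is a declared transport step (or involves membrane-crossing chemicals)."""
    for rx in rnai_model.reactions:
        comps = {
            rnai_model.compartment[l]
            for l in rx.reactants
            if not l.startswith("Chem_")
        }
        if len(comps) > 1:
            assert rx.tag == "transport", rx


def test_wire_is_deterministic():
    c = build_cascade_example()
    m1, m2 = wire(c), wire(c)
    assert m1.species == m2.species
    assert [
        (r.module, r.rule, r.reactants, r.products, r.rate_constant) for r in m1.reactions
    ] == [(r.module, r.rule, r.reactants, r.products, r.rate_constant) for r in m2.reactions]
    assert report(m1) == report(m2)


def test_empty_model_reports_empty_manifest():
    model = CircuitModel(
        name="empty", species=[], graphs={}, compartment={}, initial={},
        reactions=[], parts=[],
    )
    manifest = report(model)
    assert manifest["modules"] == [] and manifest["total_species"] == 0


def test_unmatched_in_terminal_raises_wiring_error():
    nuc, _pool = compile_coding_region(
        CodingRegionSpec(name="orphan", product_name="X"), TerminatorSpec("t", 1e-4)
    )
    with pytest.raises(WiringError) as exc:
        _check_terminals([nuc], {})
    assert "pops_in" in str(exc.value) and "orphan" in str(exc.value)


def test_carrier_kind_mismatch_raises_type_error():
    nuc, pool = compile_coding_region(
        CodingRegionSpec(name="cds", product_name="X"), TerminatorSpec("t", 1e-4)
    )
    # corrupt one part's terminals so three carrier kinds claim one species
    nuc.expanded.terminals.extend(
        [
            Terminal("bogus1", "RNAPS", "out", "Spl"),
            Terminal("bogus2", "SiPS", "out", "Spl"),
        ]
    )
    with pytest.raises(CarrierMismatchError):
        _check_terminals([nuc, pool], {})


def test_wire_rejects_invalid_circuit():
    from dataclasses import replace

    c = build_cascade_example()
    broken = replace(c, pools=tuple(p for p in c.pools if p.name != "RNAP"))
    with pytest.raises(ValueError):
        wire(broken)
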
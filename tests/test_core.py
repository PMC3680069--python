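"""Specification-layer invariants: carrier/flux bijection and validation."""

from dataclasses import replace

import pytest

from eucirc.core import (
    Compartment,
    FLUX_NAMES,
    PoolSpec,
    Role,
    SignalCarrierKind,
    TFBindingSpec,
    molar_to_stochastic,
    validate,
)
from eucirc.circuits import build_rnai_evaluator
from eucirc.io import parse_circuit, serialize_circuit


def test_carrier_flux_bijection():
    """Each of the five signal carriers has its own flux acronym."""
    assert len(FLUX_NAMES) == len(SignalCarrierKind) == 5
    assert len(set(FLUX_NAMES.values())) == 5
    assert SignalCarrierKind.RNA_POLYMERASE.flux_name == "PoPS"
    assert SignalCarrierKind.RIBOSOME.flux_name == "RiPS"
    assert SignalCarrierKind.TRANSCRIPTION_FACTOR.flux_name == "FaPS"
    assert SignalCarrierKind.SMALL_RNA.flux_name == "RNAPS"
    assert SignalCarrierKind.CHEMICAL.flux_name == "SiPS"


def test_valid_fixture_has_no_diagnostics():
    circuit = build_rnai_evaluator().circuit
    assert [d for d in validate(circuit) if d.severity == "error"] == []


def test_validate_is_idempotent_and_round_trip_stable():
    circuit = build_rnai_evaluator().circuit
    first = validate(circuit)
    second = validate(circuit)
    assert first == second
    reparsed = parse_circuit(serialize_circuit(circuit), name=circuit.name)
    assert validate(reparsed) == first


def test_unresolved_sirna_target_is_reported():
    circuit = build_rnai_evaluator().circuit
    units = tuple(u for u in circuit.units if u.promoter.name != "P_si_a")
    broken = replace(circuit, units=units)
    codes = {d.code for d in validate(broken) if d.severity == "error"}
    assert "unresolved-name" in codes


def test_zero_operator_binding_is_an_invariant_violation():
    circuit = build_rnai_evaluator().circuit
    unit = circuit.units[0]
    bad_binding = replace(unit.promoter.tf_bindings[0], n_operators=0)
    bad_prom = replace(unit.promoter, tf_bindings=(bad_binding,))
    broken = replace(circuit, units=(replace(unit, promoter=bad_prom),) + circuit.units[1:])
    diags = [d for d in validate(broken) if d.severity == "error"]
    assert any(d.code == "invariant" and "n_operators" in d.message for d in diags)


def test_duplicate_pool_and_negative_rate_are_reported():
    circuit = build_rnai_evaluator().circuit
    dup = replace(
        circuit,
        pools=circuit.pools + (
            PoolSpec("RNAP", SignalCarrierKind.RNA_POLYMERASE, Compartment.NUCLEUS, 1),
        ),
    )
    codes = {d.code for d in validate(dup) if d.severity == "error"}
    assert "duplicate-pool" in codes

    unit = circuit.units[0]
    bad_binding = replace(unit.promoter.tf_bindings[0], unbind_rate=-1.0)
    bad_prom = replace(unit.promoter, tf_bindings=(bad_binding,))
    broken = replace(circuit, units=(replace(unit, promoter=bad_prom),) + circuit.units[1:])
    codes = {d.code for d in validate(broken) if d.severity == "error"}
    assert "negative-rate" in codes


def test_corepressor_mode_requires_activator():
    from eucirc.core import EffectorMode

    binding = TFBindingSpec(
        tf_name="R",
        role=Role.REPRESSOR,
        effector_chemical="x",
        effector_mode=EffectorMode.COREPRESSOR_STRIPS,
    )
    circuit = build_rnai_evaluator().circuit
    unit = circuit.units[0]
    bad_prom = replace(unit.promoter, tf_bindings=(binding,))
    broken = replace(
        circuit,
        units=(replace(unit, promoter=bad_prom),) + circuit.units[1:],
        chemical_inputs=circuit.chemical_inputs + ("x",),
        pools=circuit.pools + (
            PoolSpec("R", SignalCarrierKind.TRANSCRIPTION_FACTOR, Compartment.NUCLEUS, 1),
        ),
    )
    diags = [d for d in validate(broken) if d.severity == "error"]
    assert any("corepressor" in d.message for d in diags)


def test_molar_conversion_only_rescales_bimolecular_rates():
    assert molar_to_stochastic(5.0, 3e-15, order=1) == 5.0
    k2 = molar_to_stochastic(1e6, 3e-15, order=2)
    # 1e6 / (6.022e23 * 3e-15) ~ 5.5e-4 per molecule per second
    assert k2 == pytest.approx(5.53e-4, rel=1e-2)
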
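"""Simulator checks: conservation, closed-form steady states, normalization."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eucirc.circuits import DEFAULT_PARAMETERS, build_cascade_example
from eucirc.compose import wire
from eucirc.core import CircuitSpec, ProductKind
from eucirc.simulate import (
    SimulationSchedule,
    TruthTable,
    conserved_weights,
    normalize,
    simulate,
    truth_table,
)
from eucirc.circuits import evaluator_function


def _constitutive_reporter_circuit():
    """One constitutive unit expressing the reporter; no silencing."""
    c = build_cascade_example()
    unit = c.units[0]
    clean_cds = replace(unit.cargo, sirna_targets=())
    clean_prom = replace(unit.promoter, tf_bindings=(), name="P_const")
    return CircuitSpec(
        "chain",
        (replace(unit, promoter=clean_prom, cargo=clean_cds),),
        tuple(p for p in c.pools if p.name != "A_act"),
        (),
    )


def test_zero_machinery_gives_zero_expression():
    c = _constitutive_reporter_circuit()
    zeroed = replace(
        c, pools=tuple(replace(p, initial_copies=0) for p in c.pools)
    )
    model = wire(zeroed)
    traj = simulate(model, SimulationSchedule(12, 0))
    for lab in model.species:
        if lab.startswith(("preM_", "M_", "P_GFP", "matN_")):
            assert np.all(traj.series(lab) == 0.0), lab


def test_machinery_conservation_over_full_schedule(rnai_model):
    """Free + bound totals of each machinery pool drift < 1e-6 relative
    over the 96 h + 48 h protocol."""
    lvl = DEFAULT_PARAMETERS["chemical_input_copies"]
    traj = simulate(
        rnai_model, SimulationSchedule(96, 48, input_levels={"a": lvl, "c": lvl})
    )
    weights = conserved_weights(rnai_model)
    for machinery, w in weights.items():
        totals = traj.states @ w
        assert totals[0] > 0, machinery
        drift = np.max(np.abs(totals - totals[0])) / totals[0]
        assert drift < 1e-6, (machinery, drift)


def _chain_steady_state_oracle(p=DEFAULT_PARAMETERS):
    """Independent closed form of the constitutive expression chain: linear
    balances solved by (small) matrix algebra, not by ODE integration."""
    kbR = p["rnap_bind_rate"] * p["rnap_copies"]
    B = kbR / (kbR + p["rnap_unbind_rate"] + p["clearing_rate"])
    pops = p["clearing_rate"] * B

    # splicing: pre + S <-> C -> mat, with S depleted by C (fixed point)
    ks, ku, kcat = p["splice_bind_rate"], p["splice_unbind_rate"], p["splice_cat_rate"]
    dn = p["nuclear_decay_rate"]
    S = p["spliceosome_copies"]
    for _ in range(5):
        A = np.array([[-(ks * S + dn), ku], [ks * S, -(ku + kcat)]])
        pre, C = np.linalg.solve(A, [-pops, 0.0])
        S = p["spliceosome_copies"] - C
    influx = kcat * C

    # translation cycle: M <-> Mi -> Me -> M (+protein), all states decay
    d = p["mrna_decay_rate"]
    kur, ki, kc = p["ribosome_unbind_rate"], p["translation_rate"], p["completion_rate"]
    Rf = p["ribosome_copies"]
    for _ in range(5):
        rb = p["ribosome_bind_rate"] * Rf
        A = np.array(
            [
                [-(d + rb), kur, kc],
                [rb, -(d + kur + ki), 0.0],
                [0.0, ki, -(d + kc)],
            ]
        )
        M, Mi, Me = np.linalg.solve(A, [-influx, 0.0, 0.0])
        Rf = p["ribosome_copies"] - Mi - Me
    protein = kc * Me / p["protein_degradation_rate"]
    return {"pops": pops, "mrna_total": M + Mi + Me, "protein": protein}


def test_constitutive_chain_matches_closed_form():
    """Simulated steady state of a one-step constitutive unit agrees with
    the independent linear-balance solution within 2%."""
    model = wire(_constitutive_reporter_circuit())
    traj = simulate(model, SimulationSchedule(192, 0))
    oracle = _chain_steady_state_oracle()
    x = traj.states[-1]
    mrna = sum(
        x[model.index(s)] for s in model.species if s.startswith("M_rep(")
    )
    assert mrna == pytest.approx(oracle["mrna_total"], rel=0.02)
    assert traj.final("P_GFP()") == pytest.approx(oracle["protein"], rel=0.02)


def test_truth_table_boolean_oracle_rows():
    """Direct Boolean evaluation of the target function."""
    assert evaluator_function(True, True, False, True) is True  # 1101
    assert evaluator_function(False, False, False, False) is False
    assert evaluator_function(False, False, True, False) is True  # "0010"


def test_classification_invariant_under_tolerance_tightening(
    rnai_model, rnai_fixture, full_schedule, rnai_table
):
    """Boolean calls are unchanged when rtol/atol tighten tenfold."""
    tight = replace(full_schedule, rtol=1e-9, atol=1e-13)
    table2 = truth_table(
        rnai_model, rnai_fixture.function, tight, rnai_fixture.output_label
    )
    assert [r["call"] for r in table2.rows] == [r["call"] for r in rnai_table.rows]
    assert table2.classification_ok == rnai_table.classification_ok


def _table(raws, expected):
    rows = [
        {"bits": format(i, "04b"), "raw": float(r), "expected": e}
        for i, (r, e) in enumerate(zip(raws, expected))
    ]
    return TruthTable(inputs=("a", "b", "c", "d"), rows=rows)


def test_normalize_minimal_on_row_is_one():
    t = normalize(_table([10, 500, 900, 2], [False, True, True, False]))
    assert min(r["normalized"] for r in t.rows if r["expected"]) == pytest.approx(1.0)
    assert t.separation == pytest.approx(500 - 10)
    assert t.classification_ok


def test_normalize_all_equal_outputs_fail_classification():
    t = normalize(_table([7.0] * 4, [False, True, True, False]))
    assert t.separation == 0.0
    assert not t.classification_ok
    assert all(r["normalized"] == pytest.approx(1.0) for r in t.rows)


@settings(deadline=None, derandomize=True, max_examples=30)
@given(
    scale=st.floats(min_value=1e-3, max_value=1e6),
    raws=st.lists(st.floats(min_value=0.1, max_value=1e5), min_size=4, max_size=4),
)
def test_normalize_scale_invariance(scale, raws):
    """Multiplying every raw output by a constant leaves the normalized
    column and the classification unchanged."""
    expected = [False, True, True, False]
    t1 = normalize(_table(raws, expected))
    t2 = normalize(_table([r * scale for r in raws], expected))
    for r1, r2 in zip(t1.rows, t2.rows):
        assert r2["normalized"] == pytest.approx(r1["normalized"], rel=1e-9)
        assert r1["call"] == r2["call"]
    assert t1.classification_ok == t2.classification_ok


def test_bolus_inputs_deplete_instead_of_clamping(rnai_model):
    lvl = 1000.0
    clamped = simulate(
        rnai_model,
        SimulationSchedule(0.5, 0.5, input_levels={"a": lvl}, clamped=True),
    )
    bolus = simulate(
        rnai_model,
        SimulationSchedule(0.5, 0.5, input_levels={"a": lvl}, clamped=False),
    )
    chem = "Chem_a()"
    assert clamped.final(chem) == pytest.approx(lvl)
    assert bolus.final(chem) < lvl
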
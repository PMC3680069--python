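"""Part compilers against closed-form count oracles and printed values."""

import pytest

from eucirc.core import (
    CodingRegionSpec,
    Cooperativity,
    ProductKind,
    PromoterSpec,
    RiboswitchKind,
    RiboswitchSpec,
    Role,
    SiRNAGeneSpec,
    SiRNATargetSpec,
    TerminatorSpec,
    TFBindingSpec,
)
from eucirc.parts import (
    UnsupportedPromoterError,
    compile_coding_region,
    compile_promoter,
    compile_sirna_gene,
    compile_tf_and_protein_pools,
    mrna_pool_counts,
    promoter_counts,
)
from eucirc.circuits import build_transcriptional_evaluator

from conftest import repressor_promoter

TERM = TerminatorSpec("t", 1e-4)


def coding(name="cds", targets=(), riboswitches=(), product="GFP"):
    return CodingRegionSpec(
        name=name,
        product_name=product,
        sirna_targets=tuple(targets),
        riboswitches=tuple(riboswitches),
    )


# ---------------------------------------------------------------------------
# promoters


def test_single_repressor_two_operator_promoter_counts():
    """One chemically strippable repressor on two operators: 5 species,
    22 reactions, 6 exchange terminals."""
    model = compile_promoter(repressor_promoter("p", ["r1"]))
    assert model.counts == (5, 22, 6)


def test_three_repressor_six_operator_promoter_counts():
    """The AND1 promoter (3 strippable repressors x 2 operators) hosts 65
    species, 834 reactions, and exchanges 12 fluxes."""
    model = compile_promoter(repressor_promoter("p_and1", ["ra", "rb", "rd"]))
    assert model.counts == (65, 834, 12)


def test_two_repressor_four_operator_promoter_species():
    """The AND2 promoter (2 repressors x 2 operators) hosts 17 species; its
    reaction count is reported but not pinned to a printed value."""
    model = compile_promoter(
        repressor_promoter("p_and2", ["rnot_a", "rc"], chemicals=[None, "c"])
    )
    assert model.n_species == 17
    assert model.n_reactions > 0


def test_constitutive_promoter_counts():
    model = compile_promoter(PromoterSpec(name="const", leak_rate=0.0))
    # free and polymerase-bound states; bind, unbind, initiate
    assert model.n_species == 2 and model.n_reactions == 3


@pytest.mark.parametrize(
    "layout",
    [
        [("r1", 1)],
        [("r1", 3)],
        [("r1", 2), ("r2", 2)],
        [("r1", 2), ("r2", 2), ("r3", 2)],
        [("r1", 7)],
        [("r1", 4), ("r2", 4)],
    ],
)
def test_formula_equals_engine_expansion(layout):
    """Closed-form species/reaction counts equal rule-engine expansion for
    the repressor-promoter family up to eight total operators."""
    tfs = [t for t, _ in layout]
    spec = PromoterSpec(
        name="p_" + "_".join(f"{t}{n}" for t, n in layout),
        tf_bindings=tuple(
            TFBindingSpec(t, Role.REPRESSOR, n_operators=n, effector_chemical=f"x{i}")
            for i, (t, n) in enumerate(layout)
        ),
        leak_rate=1e-6,
    )
    model = compile_promoter(spec)
    assert (model.n_species, model.n_reactions) == promoter_counts(spec)


def test_partially_strippable_family_formula():
    """Mixed stripping: only strippable operators contribute the chemical
    family; matches the closed form (and reproduces 130 for 2+2 operators
    with one strippable repressor)."""
    spec = repressor_promoter("p", ["r1", "r2"], chemicals=["x", None])
    model = compile_promoter(spec)
    assert (model.n_species, model.n_reactions) == promoter_counts(spec) == (17, 130)


def test_unsupported_promoter_combination():
    spec = PromoterSpec(
        name="bad",
        tf_bindings=(
            TFBindingSpec("a1", Role.ACTIVATOR, 2, cooperative=True),
            TFBindingSpec("a2", Role.ACTIVATOR, 2, cooperative=True),
            TFBindingSpec("r1", Role.REPRESSOR, 1),
        ),
    )
    with pytest.raises(UnsupportedPromoterError):
        compile_promoter(spec)


def test_activator_promoter_structure():
    """A one-operator activator promoter: bound state recruits polymerase;
    the unbound configuration only leaks."""
    spec = PromoterSpec(
        name="act",
        tf_bindings=(TFBindingSpec("A", Role.ACTIVATOR, 1, effector_chemical="x"),),
        leak_rate=1e-6,
    )
    model = compile_promoter(spec)
    # free, A-bound, A-bound+RNAP
    assert model.n_species == 3
    tags = {r.tag for r in model.expanded.reactions}
    assert {"tf_bind", "tf_unbind", "strip", "turnover", "leak",
            "rnap_bind", "rnap_unbind", "initiate"} <= tags
    assert sum(r.tag == "leak" for r in model.expanded.reactions) == 1


def test_all_promoter_rates_positive_and_species_reachable():
    model = compile_promoter(repressor_promoter("p", ["r1", "r2"]))
    assert all(r.rate_constant > 0 for r in model.expanded.reactions)
    produced = {s for r in model.expanded.reactions for s in r.products}
    seeds = {g.canonical_label for g, _ in model.ruleset.seed_species}
    for s in model.expanded.species:
        assert s in produced or s in seeds


# ---------------------------------------------------------------------------
# coding regions / mRNA pools


def test_base_mrna_pool_counts():
    """A pool with no siRNA sites and no riboswitches: 5 species, 9
    reactions, 2 exchange terminals."""
    _, pool = compile_coding_region(coding(), TERM)
    assert pool.counts == (5, 9, 2)


@pytest.mark.parametrize(
    "sirnas,expected",
    [
        ((("sa", 2), ("sb", 2), ("sd", 2)), (17, 45, 5)),  # AND1 transcript
        ((("snot_a", 2), ("sc", 2)), (13, 33, 4)),  # AND2 transcript
    ],
)
def test_and_gate_mrna_pool_counts(sirnas, expected):
    targets = [SiRNATargetSpec(n, s) for n, s in sirnas]
    _, pool = compile_coding_region(coding(targets=targets), TERM)
    assert pool.counts == expected


@pytest.mark.parametrize("s,k", [(1, 1), (2, 1), (3, 2), (5, 3), (7, 4), (10, 5), (10, 1)])
def test_mrna_pool_affine_law(s, k):
    """(5 + 2s, 9 + 6s, 2 + k) for s total sites over k siRNA species,
    verified by expansion up to s = 10."""
    per, rem = divmod(s, k)
    targets = [
        SiRNATargetSpec(f"s{i}", per + (1 if i < rem else 0)) for i in range(k)
    ]
    targets = [t for t in targets if t.n_sites > 0]
    _, pool = compile_coding_region(coding(targets=targets), TERM)
    assert pool.counts == mrna_pool_counts(s, len(targets))


def test_no_multiply_silenced_states():
    """States with more than one bound siRNA are forbidden."""
    targets = [SiRNATargetSpec("sa", 2), SiRNATargetSpec("sb", 2)]
    _, pool = compile_coding_region(coding(targets=targets), TERM)
    for lab in pool.internal_species:
        assert lab.count("~taken") <= 1


def test_riboswitch_gates_ribosome_binding():
    """Ribosome loading only from transcripts with every riboswitch on."""
    rsw = RiboswitchSpec(
        kind=RiboswitchKind.TANDEM,
        aptamer_chemicals=("u", "v"),
        cooperativity=Cooperativity.HETERO,
    )
    _, pool = compile_coding_region(coding(riboswitches=[rsw]), TERM)
    rib_binds = [r for r in pool.expanded.reactions if r.rule == "rib_bind"]
    assert rib_binds, "riboswitch pool must still translate"
    for r in rib_binds:
        mrna = next(l for l in r.reactants if l.startswith("M_"))
        assert "c0~on" in mrna
    # the off-state species exist but do not load ribosomes
    assert any("c0~off" in l for l in pool.internal_species)


def test_sirna_gene_nuclear_part_has_six_reactions():
    """Production, Dicer bind/unbind/catalysis, lumped export, decay."""
    nuclear, pool = compile_sirna_gene(SiRNAGeneSpec("s1"), TERM)
    assert nuclear.n_reactions == 6
    assert {r.rule for r in nuclear.expanded.reactions} == {
        "transcribe", "dicer_bind", "dicer_unbind", "dicer_cat", "export", "nuclear_decay",
    }
    assert any(r.rule == "risc_load" for r in pool.expanded.reactions)


# ---------------------------------------------------------------------------
# protein / machinery pools


def test_pool_compilation_shapes():
    fx = build_transcriptional_evaluator()
    pools = {m.name: m for m in compile_tf_and_protein_pools(fx.circuit)}
    # reporter: one species, one degradation reaction, one intake terminal
    gfp = pools["pool_GFP"]
    assert gfp.counts == (1, 1, 1)
    # TF product with inducer: nuclear {TF, TF.chem};
    # {import, chem bind/unbind, degrade both forms}
    ra = pools["pool_r_a"]
    assert ra.n_species == 2
    assert {r.rule for r in ra.expanded.reactions} == {
        "import", "chem_bind", "chem_unbind", "degrade_tf", "degrade_tfc",
    }
    # conserved machinery: storage only
    for name in ("pool_RNAP", "pool_Ribosome", "pool_Spliceosome", "pool_Dicer", "pool_RISC"):
        assert pools[name].n_reactions == 0
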
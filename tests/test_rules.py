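"""Rule-engine checks against independent brute-force oracles.

The canonicalization oracle is an exhaustive isomorphism search over all
vertex bijections; the expansion oracle enumerates operator-occupancy
bitstrings directly, without the rule engine.
"""

import itertools
import random

import pytest

from eucirc.rules import (
    Bind,
    Component,
    ExpansionLimitError,
    Molecule,
    MoleculeType,
    Pattern,
    PatternComponent,
    PatternMolecule,
    Rule,
    RuleSet,
    SpeciesGraph,
    Unbind,
    canonicalize,
    expand,
    match,
    write_bngl,
)

PROM6 = MoleculeType("Prom", tuple(Component(f"o{i}", bindable=True) for i in range(6)))
TF = MoleculeType("TF", (Component("d", bindable=True),))
A = MoleculeType("A", (Component("b", bindable=True),))


def graphs_isomorphic_bruteforce(g1: SpeciesGraph, g2: SpeciesGraph) -> bool:
    """Oracle: try every vertex bijection preserving types, states, bonds."""
    if len(g1.molecules) != len(g2.molecules):
        return False
    n = len(g1.molecules)
    for perm in itertools.permutations(range(n)):
        ok = True
        for i in range(n):
            m1, m2 = g1.molecules[i], g2.molecules[perm[i]]
            if m1.mtype.name != m2.mtype.name or m1.states != m2.states:
                ok = False
                break
        if not ok:
            continue
        mapped = {
            frozenset(((perm[i], ci), (perm[j], cj)))
            for b in g1.bonds
            for (i, ci), (j, cj) in [tuple(b)]
        }
        if mapped == g2.bonds:
            return True
    return False


def bound_promoter(*operators: int) -> SpeciesGraph:
    mols = [Molecule(PROM6)] + [Molecule(TF) for _ in operators]
    g = SpeciesGraph(mols)
    for k, op in enumerate(operators):
        g.add_bond((0, f"o{op}"), (k + 1, "d"))
    return g


def test_single_molecule_label():
    g = SpeciesGraph([Molecule(MoleculeType("Rib", ()))])
    assert canonicalize(g) == "Rib()"


def test_label_invariant_under_instance_order():
    g1 = bound_promoter(1, 3)
    # same complex assembled with TF instances introduced in swapped order
    mols = [Molecule(TF), Molecule(PROM6), Molecule(TF)]
    g2 = SpeciesGraph(mols)
    g2.add_bond((1, "o3"), (0, "d"))
    g2.add_bond((1, "o1"), (2, "d"))
    assert canonicalize(g1) == canonicalize(g2)


@pytest.mark.parametrize(
    "ops1,ops2",
    [((1, 3), (3, 1)), ((1, 3), (1, 2)), ((0, 2, 4), (4, 2, 0)), ((0, 2, 4), (0, 2, 5))],
)
def test_labels_agree_with_bruteforce_isomorphism(ops1, ops2):
    g1, g2 = bound_promoter(*ops1), bound_promoter(*ops2)
    assert (canonicalize(g1) == canonicalize(g2)) == graphs_isomorphic_bruteforce(g1, g2)


def test_match_counts_free_operators():
    g = bound_promoter(0, 2)  # 4 of 6 operators free
    embeddings = []
    for i in range(6):
        p = Pattern([PatternMolecule("Prom", {f"o{i}": PatternComponent(bond="unbound")})])
        embeddings += match(p, g)
    assert len(embeddings) == 4


def test_match_absent_type_gives_no_embeddings():
    g = bound_promoter(0)
    p = Pattern([PatternMolecule("Rib", {})])
    assert match(p, g) == []


def test_symmetric_dimer_embeddings_and_rate_factor():
    """The dimer pattern embeds twice, but the generated dimerization
    reaction carries the standard 1/2 symmetry factor (net factor one)."""
    dimer = SpeciesGraph([Molecule(A), Molecule(A)])
    dimer.add_bond((0, "b"), (1, "b"))
    p = Pattern.from_graph(dimer)
    assert len(match(p, dimer)) == 2

    free = Pattern([PatternMolecule("A", {"b": PatternComponent(bond="unbound")})])
    rule = Rule("dim", [free, free], [Bind((0, 0), "b", (1, 0), "b")], rate_constant=1.0)
    net = expand(RuleSet({}, [(SpeciesGraph([Molecule(A)]), 10)], [rule]))
    (rxn,) = net.reactions
    assert rxn.rate_constant == pytest.approx(0.5)  # k/2 for 2A -> A.A


def promoter_ruleset(n: int, shuffle_seed=None) -> RuleSet:
    prom = MoleculeType("P", tuple(Component(f"o{i}", bindable=True) for i in range(n)))
    rules = []
    for i in range(n):
        rules.append(
            Rule(
                f"bind_{i}",
                [
                    Pattern([PatternMolecule("P", {f"o{i}": PatternComponent(bond="unbound")})]),
                    Pattern([PatternMolecule("TF", {"d": PatternComponent(bond="unbound")})]),
                ],
                [Bind((0, 0), f"o{i}", (1, 0), "d")],
                1e-3,
                tag="tf_bind",
            )
        )
        rules.append(
            Rule(
                f"unbind_{i}",
                [Pattern([PatternMolecule("P", {f"o{i}": PatternComponent(bond="bound")})])],
                [Unbind((0, 0), f"o{i}")],
                1e-2,
                tag="tf_unbind",
            )
        )
    seeds = [(SpeciesGraph([Molecule(prom)]), 1.0), (SpeciesGraph([Molecule(TF)]), 100.0)]
    if shuffle_seed is not None:
        rng = random.Random(shuffle_seed)
        rng.shuffle(rules)
        rng.shuffle(seeds)
    return RuleSet({"P": prom, "TF": TF}, seeds, rules)


def occupancy_oracle(n: int) -> tuple[int, int, int]:
    """Enumerate occupancy bitstrings directly: configurations, binding
    reactions (one per configuration x free operator), unbinding ditto."""
    configs = 2 ** n
    binds = sum(bin(c).count("0") - (c.bit_length() < n) for c in range(configs))
    # simpler: sum over configs of free operators
    binds = sum(n - bin(c).count("1") for c in range(configs))
    unbinds = sum(bin(c).count("1") for c in range(configs))
    return configs, binds, unbinds


def test_empty_rule_list_returns_seeds_only():
    rs = promoter_ruleset(3)
    rs.rules = []
    net = expand(rs)
    assert net.n_species == 2 and net.n_reactions == 0


@pytest.mark.parametrize("n", [1, 2, 3, 4, 5, 6, 7, 8])
def test_occupancy_expansion_matches_enumeration(n):
    """|species| = 2^n configurations and n*2^(n-1) bind/unbind reactions,
    against the bitstring-enumeration oracle, for up to eight operators."""
    net = expand(promoter_ruleset(n))
    configs, binds, unbinds = occupancy_oracle(n)
    assert configs == 2 ** n and binds == unbinds == n * 2 ** (n - 1)
    prom_species = [s for s in net.species if "P(" in s]
    assert len(prom_species) == configs
    assert sum(r.tag == "tf_bind" for r in net.reactions) == binds
    assert sum(r.tag == "tf_unbind" for r in net.reactions) == unbinds


def test_six_operator_combinatorial_explosion():
    """Six operators and one factor give 64 configurations and 192 binding
    reactions."""
    net = expand(promoter_ruleset(6))
    assert sum("P(" in s for s in net.species) == 64
    assert sum(r.tag == "tf_bind" for r in net.reactions) == 192


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_expansion_invariant_under_rule_and_seed_permutation(seed):
    ref = expand(promoter_ruleset(4))
    shuffled = expand(promoter_ruleset(4, shuffle_seed=seed))
    assert ref.species == shuffled.species
    assert sorted(r.key for r in ref.reactions) == sorted(r.key for r in shuffled.reactions)
    assert [r.rate_constant for r in sorted(ref.reactions, key=lambda r: r.key)] == [
        r.rate_constant for r in sorted(shuffled.reactions, key=lambda r: r.key)
    ]


def test_reexpansion_of_expanded_species_is_fixed_point():
    rs = promoter_ruleset(3)
    net = expand(rs)
    rs2 = RuleSet(
        rs.molecule_types,
        [(net.graphs[s], net.initial.get(s, 0.0)) for s in net.species],
        rs.rules,
    )
    net2 = expand(rs2)
    assert net2.species == net.species
    assert sorted(r.key for r in net2.reactions) == sorted(r.key for r in net.reactions)


def test_expansion_limit_names_last_rule():
    with pytest.raises(ExpansionLimitError) as exc:
        expand(promoter_ruleset(6), max_species=10)
    assert "bind" in str(exc.value)


def test_bngl_listing_mentions_all_species_and_reactions():
    rs = promoter_ruleset(2)
    net = expand(rs)
    text = write_bngl(rs, net)
    for s in net.species:
        assert s in text
    assert text.count("->") == net.n_reactions
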
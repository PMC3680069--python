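"""Generic rule-based reaction-network expansion.

Molecules are typed multi-component objects; a species is a connected graph
of molecule instances joined by bonds between bindable components, with a
state attached to every stateful component.  Rules rewrite species graphs:
each rule matches one or two reactant patterns (graph fragments with state
and bond wildcards) and applies a short list of primitive edits (bind,
unbind, set_state, create, delete).  Expansion from seed species iterates
rule application to a fixed point, producing the full species list and every
induced mass-action reaction exactly once, with deterministic ordering by
canonical label.

Conventions for generated reaction rates (deterministic mass action):

* a rule matching a reactant combination through ``k`` distinct embeddings
  with the same product outcome yields one reaction with rate
  ``k / |Aut(patterns)|`` times the rule constant, where ``|Aut|`` is the
  automorphism count of the reactant patterns (so a symmetric dimer pattern
  does not double-count);
* duplicate reactions produced by the *same* rule are merged; duplicates
  from distinct rules are kept separate, preserving provenance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Optional, Sequence, Union

__all__ = [
    "Component",
    "MoleculeType",
    "Molecule",
    "SpeciesGraph",
    "PatternComponent",
    "PatternMolecule",
    "Pattern",
    "Bind",
    "Unbind",
    "SetState",
    "Create",
    "Delete",
    "Rule",
    "Terminal",
    "RuleSet",
    "Reaction",
    "ReactionNetwork",
    "ExpansionLimitError",
    "canonicalize",
    "match",
    "expand",
    "write_bngl",
]

# ---------------------------------------------------------------------------
# molecule types and species graphs


@dataclass(frozen=True)
class Component:
    name: str
    states: tuple[str, ...] = ()  # empty -> stateless
    bindable: bool = False


@dataclass(frozen=True)
class MoleculeType:
    name: str
    components: tuple[Component, ...] = ()

    def __post_init__(self):
        if isinstance(self.components, list):
            object.__setattr__(self, "components", tuple(self.components))
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate component names in molecule type {self.name}")

    def component(self, name: str) -> Component:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(f"{self.name} has no component {name}")


@dataclass
class Molecule:
    """One molecule instance: its type plus a state per stateful component."""

    mtype: MoleculeType
    states: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for c in self.mtype.components:
            if c.states and c.name not in self.states:
                self.states[c.name] = c.states[0]

    def copy(self) -> "Molecule":
        return Molecule(self.mtype, dict(self.states))


Site = tuple[int, str]  # (molecule index, component name)


class MalformedGraphError(ValueError):
    pass


class SpeciesGraph:
    """A complex: molecule instances plus bonds between bindable components.

    Bonds are unordered pairs of (molecule index, component name); at most
    one bond per component.  ``canonical_label`` is equal exactly for
    isomorphic graphs (same types, states, and bond topology).
    """

    def __init__(self, molecules: Sequence[Molecule], bonds: Iterable[tuple[Site, Site]] = ()):
        self.molecules: list[Molecule] = [m.copy() for m in molecules]
        self.bonds: set[frozenset] = set()
        for a, b in bonds:
            self.add_bond(a, b)
        self._label: Optional[str] = None

    # -- construction -----------------------------------------------------
    def add_bond(self, a: Site, b: Site) -> None:
        for (i, comp) in (a, b):
            if not (0 <= i < len(self.molecules)):
                raise MalformedGraphError(f"bond references molecule {i}")
            c = self.molecules[i].mtype.component(comp)
            if not c.bindable:
                raise MalformedGraphError(
                    f"component {comp} of {self.molecules[i].mtype.name} is not bindable"
                )
            if self.bond_partner(i, comp) is not None:
                raise MalformedGraphError(f"component {comp} of molecule {i} already bonded")
        if a == b:
            raise MalformedGraphError("self-bond on a single component")
        self.bonds.add(frozenset((a, b)))
        self._label = None

    def remove_bond_at(self, site: Site) -> None:
        for b in list(self.bonds):
            if site in b:
                self.bonds.discard(b)
        self._label = None

    def bond_partner(self, i: int, comp: str) -> Optional[Site]:
        for b in self.bonds:
            if (i, comp) in b:
                (other,) = b - {(i, comp)}
                return other
        return None

    def copy(self) -> "SpeciesGraph":
        g = SpeciesGraph([])
        g.molecules = [m.copy() for m in self.molecules]
        g.bonds = set(self.bonds)
        return g

    # -- connectivity ------------------------------------------------------
    def connected_components(self) -> list["SpeciesGraph"]:
        n = len(self.molecules)
        adj: dict[int, set[int]] = {i: set() for i in range(n)}
        for b in self.bonds:
            (i, _), (j, _) = tuple(b)
            adj[i].add(j)
            adj[j].add(i)
        seen: set[int] = set()
        out = []
        for start in range(n):
            if start in seen:
                continue
            comp = {start}
            stack = [start]
            while stack:
                v = stack.pop()
                for w in adj[v] - comp:
                    comp.add(w)
                    stack.append(w)
            seen |= comp
            order = sorted(comp)
            remap = {old: new for new, old in enumerate(order)}
            g = SpeciesGraph([self.molecules[i] for i in order])
            for b in self.bonds:
                (i, ci), (j, cj) = tuple(b)
                if i in comp:
                    g.add_bond((remap[i], ci), (remap[j], cj))
            out.append(g)
        return out

    # -- canonicalization --------------------------------------------------
    def _signatures(self) -> list[str]:
        """Weisfeiler-Lehman-style refined per-molecule signatures."""
        base = []
        for i, m in enumerate(self.molecules):
            states = tuple(sorted(m.states.items()))
            edges = []
            for c in m.mtype.components:
                p = self.bond_partner(i, c.name)
                if p is not None:
                    j, pc = p
                    edges.append((c.name, self.molecules[j].mtype.name, pc))
            base.append(repr((m.mtype.name, states, tuple(sorted(edges)))))
        sigs = base
        for _ in range(len(self.molecules)):
            nxt = []
            for i, m in enumerate(self.molecules):
                nb = []
                for c in m.mtype.components:
                    p = self.bond_partner(i, c.name)
                    if p is not None:
                        nb.append((c.name, sigs[p[0]]))
                nxt.append(sigs[i] + "|" + repr(tuple(sorted(nb))))
            if len(set(nxt)) == len(set(sigs)):
                sigs = nxt
                break
            sigs = nxt
        return sigs

    def _label_for_order(self, order: Sequence[int]) -> str:
        bond_ids: dict[frozenset, int] = {}
        next_id = 1
        # assign bond numbers in traversal order
        for old_idx in order:
            m = self.molecules[old_idx]
            for c in m.mtype.components:
                p = self.bond_partner(old_idx, c.name)
                if p is not None:
                    key = frozenset(((old_idx, c.name), p))
                    if key not in bond_ids:
                        bond_ids[key] = next_id
                        next_id += 1
        parts = []
        for old_idx in order:
            m = self.molecules[old_idx]
            comps = []
            for c in m.mtype.components:
                s = f"{c.name}"
                if c.states:
                    s += f"~{m.states[c.name]}"
                p = self.bond_partner(old_idx, c.name)
                if p is not None:
                    key = frozenset(((old_idx, c.name), p))
                    s += f"!{bond_ids[key]}"
                comps.append(s)
            parts.append(f"{m.mtype.name}({','.join(comps)})")
        return ".".join(parts)

    @property
    def canonical_label(self) -> str:
        if self._label is not None:
            return self._label
        n = len(self.molecules)
        if n == 0:
            self._label = "0"
            return self._label
        sigs = self._signatures()
        groups: dict[str, list[int]] = {}
        for i, s in enumerate(sigs):
            groups.setdefault(s, []).append(i)
        ordered_groups = [groups[s] for s in sorted(groups)]
        total = 1
        for g in ordered_groups:
            for k in range(2, len(g) + 1):
                total *= k
        if total > 40320:
            raise MalformedGraphError(
                "complex too symmetric for exhaustive canonicalization"
            )
        best: Optional[str] = None
        for perm_parts in itertools.product(
            *(itertools.permutations(g) for g in ordered_groups)
        ):
            order = [i for part in perm_parts for i in part]
            lab = self._label_for_order(order)
            if best is None or lab < best:
                best = lab
        self._label = best
        return best

    def automorphism_count(self) -> int:
        """Number of label-preserving vertex bijections of this graph."""
        return len(match(Pattern.from_graph(self), self, exact=True))

    def __repr__(self) -> str:  # pragma: no cover
        return f"<SpeciesGraph {self.canonical_label}>"


def canonicalize(g: SpeciesGraph) -> str:
    """Canonical label: equal iff graphs are isomorphic."""
    return g.canonical_label


# ---------------------------------------------------------------------------
# patterns and matching

ANY = "?"  # wildcard marker for states / bond status


@dataclass(frozen=True)
class PatternComponent:
    state: Optional[str] = None  # None -> any state
    bond: Union[str, int, None] = None  # None any; "unbound"; "bound"; int bond id


@dataclass
class PatternMolecule:
    type_name: str
    comps: dict[str, PatternComponent] = field(default_factory=dict)


@dataclass
class Pattern:
    """A species-graph fragment; unmentioned components are wildcards."""

    molecules: list[PatternMolecule]

    @staticmethod
    def from_graph(g: SpeciesGraph) -> "Pattern":
        """Exact pattern of a full graph (every state and bond pinned)."""
        bond_ids: dict[frozenset, int] = {}
        for k, b in enumerate(sorted(g.bonds, key=lambda b: sorted(b))):
            bond_ids[b] = k + 1
        mols = []
        for i, m in enumerate(g.molecules):
            comps = {}
            for c in m.mtype.components:
                p = g.bond_partner(i, c.name)
                bond: Union[str, int] = "unbound"
                if p is not None:
                    bond = bond_ids[frozenset(((i, c.name), p))]
                comps[c.name] = PatternComponent(
                    state=m.states.get(c.name), bond=bond
                )
            mols.append(PatternMolecule(m.mtype.name, comps))
        return Pattern(mols)

    def _bond_pairs(self) -> dict[int, list[tuple[int, str]]]:
        out: dict[int, list[tuple[int, str]]] = {}
        for i, pm in enumerate(self.molecules):
            for cname, pc in pm.comps.items():
                if isinstance(pc.bond, int):
                    out.setdefault(pc.bond, []).append((i, cname))
        return out


def _comp_ok(pc: PatternComponent, g: SpeciesGraph, gi: int, cname: str) -> bool:
    mol = g.molecules[gi]
    if pc.state is not None and mol.states.get(cname) != pc.state:
        return False
    partner = g.bond_partner(gi, cname)
    if pc.bond == "unbound" and partner is not None:
        return False
    if (pc.bond == "bound" or isinstance(pc.bond, int)) and partner is None:
        return False
    return True


def match(p: Pattern, g: SpeciesGraph, exact: bool = False) -> list[dict[int, int]]:
    """All embeddings of pattern molecules into ``g``.

    Returns injective maps {pattern molecule index -> graph molecule index}
    consistent with molecule types, pinned states, and bond constraints
    (integer bond ids in the pattern must map onto actual bonds of ``g``).
    With ``exact=True`` the embedding must be a bijection (used for
    automorphism counting).
    """

    np_, ng = len(p.molecules), len(g.molecules)
    if exact and np_ != ng:
        return []
    candidates: list[list[int]] = []
    for pm in p.molecules:
        cand = []
        for gi, mol in enumerate(g.molecules):
            if mol.mtype.name != pm.type_name:
                continue
            if all(_comp_ok(pc, g, gi, cn) for cn, pc in pm.comps.items()):
                cand.append(gi)
        if not cand:
            return []
        candidates.append(cand)

    bond_pairs = p._bond_pairs()
    if any(len(sites) != 2 for sites in bond_pairs.values()):
        return []  # dangling pattern bond id: no embedding
    # pattern bonds touching molecule i, for incremental pruning
    bonds_of: dict[int, list[tuple[str, int, str]]] = {}
    for sites in bond_pairs.values():
        (i1, c1), (i2, c2) = sites
        bonds_of.setdefault(i1, []).append((c1, i2, c2))
        bonds_of.setdefault(i2, []).append((c2, i1, c1))
    results: list[dict[int, int]] = []

    def backtrack(idx: int, assignment: dict[int, int], used: set[int]):
        if idx == np_:
            results.append(dict(assignment))
            return
        for gi in candidates[idx]:
            if gi in used:
                continue
            ok = True
            for comp, other, ocomp in bonds_of.get(idx, ()):
                partner = g.bond_partner(gi, comp)
                if other < idx:  # other endpoint already assigned
                    if partner != (assignment[other], ocomp):
                        ok = False
                        break
                elif partner is None:
                    ok = False
                    break
            if not ok:
                continue
            assignment[idx] = gi
            used.add(gi)
            backtrack(idx + 1, assignment, used)
            used.discard(gi)
            del assignment[idx]

    backtrack(0, {}, set())
    return results


# ---------------------------------------------------------------------------
# rules

Ref = tuple[int, int]  # (reactant pattern index, molecule index within pattern)


@dataclass(frozen=True)
class Bind:
    a: Ref
    comp_a: str
    b: Ref
    comp_b: str


@dataclass(frozen=True)
class Unbind:
    a: Ref
    comp: str


@dataclass(frozen=True)
class SetState:
    a: Ref
    comp: str
    state: str


@dataclass(frozen=True)
class Delete:
    a: Ref


@dataclass
class Create:
    graph: SpeciesGraph


Action = Union[Bind, Unbind, SetState, Delete, Create]


@dataclass
class Rule:
    name: str
    reactants: list[Pattern]
    actions: list[Action]
    rate_constant: float
    #: evaluate at most one reaction per reactant combination (rate not
    #: multiplied by the embedding count) -- used for whole-configuration
    #: events such as leak transcription
    once_per_combo: bool = False
    rate_modifier: Optional[Callable[[list[SpeciesGraph], list[dict[int, int]]], float]] = None
    tag: str = ""

    def __post_init__(self):
        if not 1 <= len(self.reactants) <= 2:
            raise ValueError("rules take 1 or 2 reactant patterns")


@dataclass(frozen=True)
class Terminal:
    name: str
    carrier: str  # flux name: PoPS/RiPS/FaPS/RNAPS/SiPS or "protein"
    direction: str  # "in" | "out" | "bidir"
    attached: str = ""  # species label or pool name on the far side


@dataclass
class RuleSet:
    molecule_types: dict[str, MoleculeType]
    seed_species: list[tuple[SpeciesGraph, float]]
    rules: list[Rule]
    terminals: list[Terminal] = field(default_factory=list)


@dataclass(frozen=True)
class Reaction:
    reactants: tuple[str, ...]  # canonical labels
    products: tuple[str, ...]
    rate_constant: float  # includes statistical symmetry factor
    rule: str  # provenance: generating rule
    tag: str = ""

    @property
    def key(self):
        return (self.rule, tuple(sorted(self.reactants)), tuple(sorted(self.products)))


class ExpansionLimitError(RuntimeError):
    def __init__(self, max_species: int, last_rule: str):
        super().__init__(
            f"network expansion exceeded {max_species} species "
            f"(last rule applied: {last_rule})"
        )
        self.last_rule = last_rule


@dataclass
class ReactionNetwork:
    species: list[str]  # canonical labels, sorted
    graphs: dict[str, SpeciesGraph]
    initial: dict[str, float]
    reactions: list[Reaction]
    terminals: list[Terminal] = field(default_factory=list)
    tags: dict[str, str] = field(default_factory=dict)  # species label -> module tag

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)


def _pattern_mol_fingerprint(pm: PatternMolecule):
    comps = {}
    for cname, pc in pm.comps.items():
        bond = pc.bond
        if isinstance(bond, int):
            bond = "bound"
        comps[cname] = (pc.state, bond)
    return (pm.type_name, tuple(sorted(comps.items())))


def _pattern_bonds(p: Pattern) -> set[frozenset]:
    out = set()
    for sites in p._bond_pairs().values():
        if len(sites) == 2:
            out.add(frozenset(sites))
    return out


def _pattern_automorphisms(p: Pattern) -> int:
    """Automorphism count of a pattern: bijections of its molecules onto
    themselves preserving type, component constraints, and pattern bonds.
    1 for all asymmetric patterns."""
    n = len(p.molecules)
    if n <= 1:
        return 1
    fps = [_pattern_mol_fingerprint(pm) for pm in p.molecules]
    bonds = _pattern_bonds(p)
    count = 0
    for perm in itertools.permutations(range(n)):
        if any(fps[i] != fps[perm[i]] for i in range(n)):
            continue
        mapped = {
            frozenset(((perm[i], ci), (perm[j], cj)))
            for b in bonds
            for (i, ci), (j, cj) in [tuple(b)]
        }
        if mapped == bonds:
            count += 1
    return max(count, 1)


def _pattern_fingerprint(p: Pattern):
    """Order-insensitive structural fingerprint used to detect identical
    reactant patterns on a two-reactant rule (rule symmetry factor)."""
    return (
        tuple(sorted(_pattern_mol_fingerprint(pm) for pm in p.molecules)),
        len(_pattern_bonds(p)),
    )


def _apply_rule(
    rule: Rule,
    reactant_graphs: list[SpeciesGraph],
    embeddings: list[dict[int, int]],
) -> list[SpeciesGraph]:
    """Apply rule actions to one embedding; return product complexes."""
    # disjoint union of reactant graphs
    union = SpeciesGraph([])
    offsets = []
    for g in reactant_graphs:
        offsets.append(len(union.molecules))
        union.molecules.extend(m.copy() for m in g.molecules)
        for b in g.bonds:
            (i, ci), (j, cj) = tuple(b)
            union.bonds.add(frozenset(((i + offsets[-1], ci), (j + offsets[-1], cj))))

    def resolve(ref: Ref) -> int:
        pat_idx, mol_idx = ref
        return offsets[pat_idx] + embeddings[pat_idx][mol_idx]

    deleted: set[int] = set()
    for act in rule.actions:
        if isinstance(act, Bind):
            union.add_bond((resolve(act.a), act.comp_a), (resolve(act.b), act.comp_b))
        elif isinstance(act, Unbind):
            union.remove_bond_at((resolve(act.a), act.comp))
        elif isinstance(act, SetState):
            union.molecules[resolve(act.a)].states[act.comp] = act.state
        elif isinstance(act, Delete):
            deleted.add(resolve(act.a))
        elif isinstance(act, Create):
            off = len(union.molecules)
            union.molecules.extend(m.copy() for m in act.graph.molecules)
            for b in act.graph.bonds:
                (i, ci), (j, cj) = tuple(b)
                union.bonds.add(frozenset(((i + off, ci), (j + off, cj))))
        else:  # pragma: no cover
            raise TypeError(f"unknown action {act!r}")

    if deleted:
        keep = [i for i in range(len(union.molecules)) if i not in deleted]
        remap = {old: new for new, old in enumerate(keep)}
        g2 = SpeciesGraph([union.molecules[i] for i in keep])
        for b in union.bonds:
            (i, ci), (j, cj) = tuple(b)
            if i in deleted or j in deleted:
                continue
            g2.add_bond((remap[i], ci), (remap[j], cj))
        union = g2
    return union.connected_components()


def expand(rs: RuleSet, max_species: int = 10_000) -> ReactionNetwork:
    """Fixed-point network generation from seeds under the rule set.

    Breadth-first closure: the smallest species set containing the seeds and
    closed under rule application, with every induced reaction emitted once.
    Raises :class:`ExpansionLimitError` if the closure exceeds
    ``max_species``.
    """

    graphs: dict[str, SpeciesGraph] = {}
    initial: dict[str, float] = {}
    for g, copies in rs.seed_species:
        lab = g.canonical_label
        graphs[lab] = g
        initial[lab] = initial.get(lab, 0.0) + copies

    # accumulated: (rule, reactant labels, product labels) -> [embedding count, rule]
    hits: dict[tuple, list] = {}
    processed: set[tuple] = set()
    match_memo: dict[tuple, list] = {}

    def cached_match(pattern_idx_rule, pattern, label):
        key = (pattern_idx_rule, label)
        if key not in match_memo:
            match_memo[key] = match(pattern, graphs[label])
        return match_memo[key]

    changed = True
    while changed:
        changed = False
        labels = sorted(graphs)
        for rule in rs.rules:
            # only species embedding each pattern can participate
            cands = [
                [lab for lab in labels
                 if cached_match((id(rule), k), rule.reactants[k], lab)]
                for k in range(len(rule.reactants))
            ]
            if len(rule.reactants) == 1:
                combos = [(lab,) for lab in cands[0]]
            else:
                combos = [(a, b) for a in cands[0] for b in cands[1]]
            for combo in combos:
                key = (rule.name, combo)
                if key in processed:
                    continue
                processed.add(key)
                rgraphs = [graphs[lab] for lab in combo]
                per_pat = [
                    cached_match((id(rule), k), rule.reactants[k], combo[k])
                    for k in range(len(combo))
                ]
                if any(not e for e in per_pat):
                    continue
                for emb_combo in itertools.product(*per_pat):
                    try:
                        prods = _apply_rule(rule, rgraphs, list(emb_combo))
                    except MalformedGraphError:
                        continue  # action not applicable to this embedding
                    plabels = tuple(sorted(p.canonical_label for p in prods))
                    for p in prods:
                        lab = p.canonical_label
                        if lab not in graphs:
                            graphs[lab] = p
                            initial.setdefault(lab, 0.0)
                            changed = True
                            if len(graphs) > max_species:
                                raise ExpansionLimitError(max_species, rule.name)
                    hkey = (rule.name, combo, plabels)
                    entry = hits.setdefault(hkey, [0, rule])
                    entry[0] += 1

    # assemble reactions
    merged: dict[tuple, Reaction] = {}
    sym_cache: dict[int, float] = {}
    for (rname, combo, plabels), (count, rule) in hits.items():
        sym = _rule_symmetry(rule, sym_cache)
        mult = 1.0 if rule.once_per_combo else count / sym
        rate = rule.rate_constant * mult
        if rule.rate_modifier is not None:
            rate *= rule.rate_modifier([graphs[l] for l in combo], None)
        rxn = Reaction(
            reactants=tuple(sorted(combo)),
            products=plabels,
            rate_constant=rate,
            rule=rname,
            tag=rule.tag,
        )
        if rxn.key in merged:
            old = merged[rxn.key]
            merged[rxn.key] = replace(old, rate_constant=old.rate_constant + rate)
        else:
            merged[rxn.key] = rxn

    reactions = sorted(
        merged.values(), key=lambda r: (r.rule, r.reactants, r.products)
    )
    return ReactionNetwork(
        species=sorted(graphs),
        graphs=graphs,
        initial=initial,
        reactions=reactions,
        terminals=list(rs.terminals),
    )


def _rule_symmetry(rule: Rule, cache: dict[int, float]) -> float:
    """Statistical divisor: per-pattern automorphisms times 2 when a
    two-reactant rule has two structurally identical patterns (ordered
    species-pair enumeration visits each unordered pair from both sides).
    The cache is scoped to one expansion (keys are live-object ids)."""
    key = id(rule)
    if key not in cache:
        sym = 1.0
        for p in rule.reactants:
            sym *= _pattern_automorphisms(p)
        if len(rule.reactants) == 2 and _pattern_fingerprint(
            rule.reactants[0]
        ) == _pattern_fingerprint(rule.reactants[1]):
            sym *= 2.0
        cache[key] = sym
    return cache[key]


# ---------------------------------------------------------------------------
# diagnostic BNGL-flavored listing


def write_bngl(rs: RuleSet, network: Optional[ReactionNetwork] = None) -> str:
    """Plain-text, BNGL-flavored listing of a rule set and its expansion.

    Diagnostic output only; no interoperability guarantees.
    """

    lines = ["begin molecule types"]
    for mt in sorted(rs.molecule_types.values(), key=lambda m: m.name):
        comps = []
        for c in mt.components:
            s = c.name
            if c.states:
                s += "~" + "~".join(c.states)
            comps.append(s)
        lines.append(f"  {mt.name}({','.join(comps)})")
    lines.append("end molecule types")
    lines.append("begin seed species")
    for g, copies in rs.seed_species:
        lines.append(f"  {g.canonical_label} {copies:g}")
    lines.append("end seed species")
    lines.append("begin reaction rules")
    for r in rs.rules:
        lines.append(f"  # {r.name} [{r.tag}] k={r.rate_constant:g}")
    lines.append("end reaction rules")
    if network is not None:
        lines.append("begin species")
        for s in network.species:
            lines.append(f"  {s} {network.initial.get(s, 0):g}")
        lines.append("end species")
        lines.append("begin reactions")
        for rx in network.reactions:
            lines.append(
                f"  {' + '.join(rx.reactants)} -> {' + '.join(rx.products) if rx.products else '0'}"
                f"  {rx.rate_constant:g}  # {rx.rule}"
            )
        lines.append("end reactions")
    return "\n".join(lines) + "\n"
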
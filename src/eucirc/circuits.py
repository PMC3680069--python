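"""Example circuits and the packaged default parameter set.

Three fixtures are provided:

* a one-step cascade: a reporter unit controlled by an activator and
  silenced by a constitutively expressed siRNA;
* an RNAi-based logic evaluator for ``(a AND b AND d) OR ((NOT a) AND c)``:
  five chemically controlled siRNA units silence two constitutive AND-gate
  transcription units that produce one shared fluorescent reporter;
* a transcriptional evaluator of the same Boolean function where the
  siRNAs are replaced by repressors acting on two multi-operator promoters
  (three repressors / six operators on p_and1, two repressors / four
  operators on p_and2).

Each input chemical inactivates the transcription factor(s) that sense it:
the regulator tied to literal ``x`` is produced exactly when ``x`` is
absent, and the regulator for ``NOT a`` is produced exactly when ``a`` is
present (chemical ``a`` deactivates two different factors).  The default
parameter table is an order-of-magnitude set for yeast/mammalian kinetics,
documented per entry; it is the package's own calibration, not a measured
set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from .core import (
    CircuitSpec,
    CodingRegionSpec,
    Compartment,
    EffectorMode,
    PoolSpec,
    ProductKind,
    PromoterSpec,
    Role,
    SignalCarrierKind,
    SiRNAGeneSpec,
    SiRNATargetSpec,
    TerminatorSpec,
    TFBindingSpec,
    TranscriptionUnitSpec,
)

__all__ = [
    "EvaluatorFixture",
    "build_cascade_example",
    "build_rnai_evaluator",
    "build_transcriptional_evaluator",
    "default_parameters",
    "evaluator_function",
    "FIXTURES",
]


def evaluator_function(a: bool, b: bool, c: bool, d: bool) -> bool:
    """The benchmark Boolean function (a AND b AND d) OR ((NOT a) AND c)."""
    return (a and b and d) or ((not a) and c)


@dataclass(frozen=True)
class EvaluatorFixture:
    name: str
    circuit: CircuitSpec
    function: Callable[..., bool]
    parameter_set: str
    output_product: str = "GFP"
    inputs: tuple[str, ...] = ("a", "b", "c", "d")

    @property
    def output_label(self) -> str:
        return f"P_{self.output_product}()"


#: Default kinetic parameters.  Units: first-order rates in 1/s, bimolecular
#: rates in 1/(molecule*s) (stochastic, already scaled to their
#: compartment), copy numbers in molecules per compartment.
DEFAULT_PARAMETERS: dict[str, float] = {
    # machinery pool sizes
    "rnap_copies": 700.0,
    "ribosome_copies": 20000.0,
    "spliceosome_copies": 200.0,
    "dicer_copies": 200.0,
    "risc_copies": 5000.0,
    "sensor_tf_copies": 20000.0,
    # promoter / polymerase
    "rnap_bind_rate": 1e-3,
    "rnap_unbind_rate": 1.0,
    "clearing_rate": 0.1,
    "leak_rate": 1e-9,
    "sirna_promoter_leak_rate": 2e-6,
    "tf_dna_turnover_rate": 1e-7,
    # transcription factor <-> operator
    "tf_bind_rate": 1e-3,
    "tf_unbind_rate": 0.1,
    "affinity_gradient": 2.0,
    # transcription factor <-> chemical
    "chem_strip_rate": 1e-3,
    "chem_solution_bind_rate": 3e-4,
    "chem_solution_unbind_rate": 1e-3,
    # nuclear mRNA processing
    "splice_bind_rate": 1e-3,
    "splice_unbind_rate": 1e-2,
    "splice_cat_rate": 0.1,
    "mrna_export_rate": 1e-2,
    "nuclear_decay_rate": 1e-4,
    "transit_rate": 1.0,
    # translation
    "ribosome_bind_rate": 1e-5,
    "ribosome_unbind_rate": 1e-2,
    "translation_rate": 0.1,
    "completion_rate": 0.05,
    # RNA interference
    "dicer_bind_rate": 1e-3,
    "dicer_unbind_rate": 1e-2,
    "dicer_cat_rate": 0.1,
    "sirna_export_rate": 1e-2,
    "risc_load_rate": 1e-3,
    "sirna_site_bind_rate": 1e-3,
    "sirna_cleavage_rate": 1e-2,
    # turnover
    "mrna_decay_rate": 2e-4,
    "sirna_decay_rate": 1e-4,
    "protein_degradation_rate": 2e-4,
    "tf_import_rate": 1e-3,
    # inputs
    "chemical_input_copies": 10000.0,
}

FIXTURES = ("cascade", "rnai", "transcriptional")


def default_parameters(name: str) -> dict[str, float]:
    """The packaged parameter table for a fixture (same set for all three)."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture '{name}'; expected one of {FIXTURES}")
    return dict(DEFAULT_PARAMETERS)


# ---------------------------------------------------------------------------
# shared builders


def _machinery_pools(p) -> list[PoolSpec]:
    N, C = Compartment.NUCLEUS, Compartment.CYTOPLASM
    K = SignalCarrierKind
    return [
        PoolSpec("RNAP", K.RNA_POLYMERASE, N, int(p["rnap_copies"]), conserved=True),
        PoolSpec("Ribosome", K.RIBOSOME, C, int(p["ribosome_copies"]), conserved=True),
        PoolSpec("Spliceosome", K.RIBOSOME, N, int(p["spliceosome_copies"]), conserved=True),
        PoolSpec("Dicer", K.SMALL_RNA, N, int(p["dicer_copies"]), conserved=True),
        PoolSpec("RISC", K.SMALL_RNA, C, int(p["risc_copies"]), conserved=True),
    ]


def _sensor_pool(p, name: str) -> PoolSpec:
    # conserved sensing factors: present from the start, not synthesized
    return PoolSpec(
        name,
        SignalCarrierKind.TRANSCRIPTION_FACTOR,
        Compartment.NUCLEUS,
        int(p["sensor_tf_copies"]),
    )


def _tf_product_pool(p, name: str) -> PoolSpec:
    return PoolSpec(
        name,
        SignalCarrierKind.TRANSCRIPTION_FACTOR,
        Compartment.NUCLEUS,
        0,
        import_rate=p["tf_import_rate"],
        degradation_rate=p["protein_degradation_rate"],
    )


def _reporter_pool(p, name: str) -> PoolSpec:
    return PoolSpec(
        name,
        SignalCarrierKind.TRANSCRIPTION_FACTOR,
        Compartment.CYTOPLASM,
        0,
        degradation_rate=p["protein_degradation_rate"],
    )


def _binding(p, tf: str, role: Role, n_ops: int, chem: str | None) -> TFBindingSpec:
    return TFBindingSpec(
        tf_name=tf,
        role=role,
        n_operators=n_ops,
        effector_chemical=chem,
        effector_mode=EffectorMode.INDUCER_STRIPS,
        base_bind_rate=p["tf_bind_rate"],
        unbind_rate=p["tf_unbind_rate"],
        affinity_gradient=p["affinity_gradient"],
        chem_strip_rate=p["chem_strip_rate"],
        chem_solution_bind_rate=p["chem_solution_bind_rate"],
        chem_solution_unbind_rate=p["chem_solution_unbind_rate"],
    )


def _promoter(p, name: str, bindings=(), leak_key: str = "leak_rate") -> PromoterSpec:
    return PromoterSpec(
        name=name,
        tf_bindings=tuple(bindings),
        rnap_bind_rate=p["rnap_bind_rate"],
        rnap_unbind_rate=p["rnap_unbind_rate"],
        clearing_rate=p["clearing_rate"],
        leak_rate=p[leak_key],
        tf_dna_turnover_rate=p["tf_dna_turnover_rate"],
    )


def _coding(p, name: str, product: str, kind: ProductKind, targets=()) -> CodingRegionSpec:
    return CodingRegionSpec(
        name=name,
        product_name=product,
        product_kind=kind,
        sirna_targets=tuple(
            SiRNATargetSpec(s, 2, p["sirna_site_bind_rate"], p["sirna_cleavage_rate"])
            for s in targets
        ),
        splice_bind_rate=p["splice_bind_rate"],
        splice_unbind_rate=p["splice_unbind_rate"],
        splice_cat_rate=p["splice_cat_rate"],
        export_rate=p["mrna_export_rate"],
        nuclear_decay_rate=p["nuclear_decay_rate"],
        ribosome_bind_rate=p["ribosome_bind_rate"],
        ribosome_unbind_rate=p["ribosome_unbind_rate"],
        translation_rate=p["translation_rate"],
        completion_rate=p["completion_rate"],
        transit_rate=p["transit_rate"],
    )


def _sirna_gene(p, name: str) -> SiRNAGeneSpec:
    return SiRNAGeneSpec(
        sirna_name=name,
        dicer_bind_rate=p["dicer_bind_rate"],
        dicer_unbind_rate=p["dicer_unbind_rate"],
        dicer_cat_rate=p["dicer_cat_rate"],
        export_rate=p["sirna_export_rate"],
        nuclear_decay_rate=p["nuclear_decay_rate"],
        risc_load_rate=p["risc_load_rate"],
        transit_rate=p["transit_rate"],
    )


def _mterm(p, name: str) -> TerminatorSpec:
    return TerminatorSpec(name, p["mrna_decay_rate"])


def _sterm(p, name: str) -> TerminatorSpec:
    return TerminatorSpec(name, p["sirna_decay_rate"])


# ---------------------------------------------------------------------------
# fixtures


def build_cascade_example(params: dict[str, float] | None = None) -> CircuitSpec:
    """One-step cascade: activator-driven reporter silenced by a
    constitutively expressed siRNA (two transcription units)."""
    p = params or default_parameters("cascade")
    units = (
        TranscriptionUnitSpec(
            promoter=_promoter(p, "P_rep", [_binding(p, "A_act", Role.ACTIVATOR, 1, None)]),
            cargo=_coding(p, "rep", "GFP", ProductKind.REPORTER, ["si_s"]),
            terminator=_mterm(p, "T_rep"),
        ),
        TranscriptionUnitSpec(
            promoter=_promoter(p, "P_si_s"),
            cargo=_sirna_gene(p, "si_s"),
            terminator=_sterm(p, "T_si_s"),
        ),
    )
    pools = tuple(_machinery_pools(p)) + (
        _sensor_pool(p, "A_act"),
        _reporter_pool(p, "GFP"),
    )
    return CircuitSpec("cascade", units, pools, chemical_inputs=())


def build_rnai_evaluator(params: dict[str, float] | None = None) -> EvaluatorFixture:
    """RNAi logic evaluator for ``(a AND b AND d) OR ((NOT a) AND c)``.

    Four siRNA units sit under activators deactivated by their input
    chemical (one operator each); the fifth (siRNA-not-a) sits under a
    repressor deactivated by chemical ``a`` (two operators).  Two
    constitutive AND units produce the shared reporter; the AND1 transcript
    carries two sites for each of siRNA-a/-b/-d (six sites), the AND2
    transcript two sites for each of siRNA-not-a/-c (four sites).
    """

    p = params or default_parameters("rnai")
    units = []
    for x in "abcd":
        units.append(
            TranscriptionUnitSpec(
                promoter=_promoter(p, f"P_si_{x}", [_binding(p, f"A_{x}", Role.ACTIVATOR, 1, x)],
                                   leak_key="sirna_promoter_leak_rate"),
                cargo=_sirna_gene(p, f"si_{x}"),
                terminator=_sterm(p, f"T_si_{x}"),
            )
        )
    units.append(
        TranscriptionUnitSpec(
            promoter=_promoter(p, "P_si_not_a", [_binding(p, "S_a", Role.REPRESSOR, 2, "a")],
                               leak_key="sirna_promoter_leak_rate"),
            cargo=_sirna_gene(p, "si_not_a"),
            terminator=_sterm(p, "T_si_not_a"),
        )
    )
    units.append(
        TranscriptionUnitSpec(
            promoter=_promoter(p, "P_and1"),
            cargo=_coding(p, "and1", "GFP", ProductKind.REPORTER, ["si_a", "si_b", "si_d"]),
            terminator=_mterm(p, "T_and1"),
        )
    )
    units.append(
        TranscriptionUnitSpec(
            promoter=_promoter(p, "P_and2"),
            cargo=_coding(p, "and2", "GFP", ProductKind.REPORTER, ["si_not_a", "si_c"]),
            terminator=_mterm(p, "T_and2"),
        )
    )
    pools = tuple(_machinery_pools(p)) + tuple(
        _sensor_pool(p, f"A_{x}") for x in "abcd"
    ) + (_sensor_pool(p, "S_a"), _reporter_pool(p, "GFP"))
    circuit = CircuitSpec("rnai_evaluator", tuple(units), pools, chemical_inputs=("a", "b", "c", "d"))
    return EvaluatorFixture("rnai", circuit, evaluator_function, "rnai")


def build_transcriptional_evaluator(params: dict[str, float] | None = None) -> EvaluatorFixture:
    """Transcription-regulation-only evaluator of the same Boolean function.

    Upstream units convert chemicals into repressors (r_x expressed when x
    is absent; r_not_a expressed when a is present); p_and1 carries three
    repressors on two operators each (six operators), p_and2 two repressors
    on two operators each.  Every repressor binds non-cooperatively.
    """

    p = params or default_parameters("transcriptional")
    units = []
    for x in "abcd":
        units.append(
            TranscriptionUnitSpec(
                promoter=_promoter(p, f"P_r_{x}", [_binding(p, f"A_{x}", Role.ACTIVATOR, 1, x)]),
                cargo=_coding(p, f"cds_r_{x}", f"r_{x}", ProductKind.TRANSCRIPTION_FACTOR),
                terminator=_mterm(p, f"T_r_{x}"),
            )
        )
    units.append(
        TranscriptionUnitSpec(
            promoter=_promoter(p, "P_r_not_a", [_binding(p, "S_a", Role.REPRESSOR, 2, "a")]),
            cargo=_coding(p, "cds_r_not_a", "r_not_a", ProductKind.TRANSCRIPTION_FACTOR),
            terminator=_mterm(p, "T_r_not_a"),
        )
    )
    units.append(
        TranscriptionUnitSpec(
            promoter=_promoter(
                p,
                "p_and1",
                [
                    _binding(p, "r_a", Role.REPRESSOR, 2, "a"),
                    _binding(p, "r_b", Role.REPRESSOR, 2, "b"),
                    _binding(p, "r_d", Role.REPRESSOR, 2, "d"),
                ],
            ),
            cargo=_coding(p, "and1", "GFP", ProductKind.REPORTER),
            terminator=_mterm(p, "T_and1"),
        )
    )
    units.append(
        TranscriptionUnitSpec(
            promoter=_promoter(
                p,
                "p_and2",
                [
                    _binding(p, "r_not_a", Role.REPRESSOR, 2, None),
                    _binding(p, "r_c", Role.REPRESSOR, 2, "c"),
                ],
            ),
            cargo=_coding(p, "and2", "GFP", ProductKind.REPORTER),
            terminator=_mterm(p, "T_and2"),
        )
    )
    pools = tuple(_machinery_pools(p)) + tuple(
        _sensor_pool(p, f"A_{x}") for x in "abcd"
    ) + (_sensor_pool(p, "S_a"),) + tuple(
        _tf_product_pool(p, f"r_{x}") for x in "abcd"
    ) + (_tf_product_pool(p, "r_not_a"), _reporter_pool(p, "GFP"))
    circuit = CircuitSpec(
        "transcriptional_evaluator", tuple(units), pools, chemical_inputs=("a", "b", "c", "d")
    )
    return EvaluatorFixture("transcriptional", circuit, evaluator_function, "transcriptional")
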
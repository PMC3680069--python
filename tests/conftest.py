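import pytest

from eucirc.circuits import (
    DEFAULT_PARAMETERS,
    build_rnai_evaluator,
    build_transcriptional_evaluator,
)
from eucirc.compose import wire
from eucirc.core import PromoterSpec, Role, TFBindingSpec
from eucirc.simulate import SimulationSchedule, truth_table


def repressor_promoter(name, tfs, n_ops=2, chemicals=None, leak=1e-6):
    """An all-repressor promoter spec; ``chemicals[i]`` (or None) strips TF i."""
    if chemicals is None:
        chemicals = [f"x{i}" for i in range(len(tfs))]
    bindings = tuple(
        TFBindingSpec(
            tf_name=t,
            role=Role.REPRESSOR,
            n_operators=n_ops,
            effector_chemical=chemicals[i],
            affinity_gradient=2.0,
        )
        for i, t in enumerate(tfs)
    )
    return PromoterSpec(name=name, tf_bindings=bindings, leak_rate=leak)


@pytest.fixture(scope="session")
def full_schedule():
    lvl = DEFAULT_PARAMETERS["chemical_input_copies"]
    return SimulationSchedule(
        equilibration_hours=96.0,
        evaluation_hours=48.0,
        input_levels={c: lvl for c in "abcd"},
    )


@pytest.fixture(scope="session")
def rnai_fixture():
    return build_rnai_evaluator()


@pytest.fixture(scope="session")
def tx_fixture():
    return build_transcriptional_evaluator()


@pytest.fixture(scope="session")
def rnai_model(rnai_fixture):
    return wire(rnai_fixture.circuit)


@pytest.fixture(scope="session")
def tx_model(tx_fixture):
    return wire(tx_fixture.circuit)


@pytest.fixture(scope="session")
def rnai_table(rnai_model, rnai_fixture, full_schedule):
    return truth_table(
        rnai_model, rnai_fixture.function, full_schedule, rnai_fixture.output_label
    )


@pytest.fixture(scope="session")
def tx_table(tx_model, tx_fixture, full_schedule):
    return truth_table(
        tx_model, tx_fixture.function, full_schedule, tx_fixture.output_label
    )
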
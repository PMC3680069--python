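"""Deterministic mass-action simulation and Boolean truth-table evaluation.

The flattened circuit network is integrated as a stiff ODE system in
molecule copies per compartment.  The evaluation protocol mirrors common
practice for genetic logic: the circuit first relaxes to steady state with
no chemical inputs (96 h), then each input combination is applied as a
clamped chemical copy number and the reporter is read out after 48 h.  A
truth table collects the 16 reporter readouts, their normalization by the
minimal ON value, threshold Boolean calls, and the signal separation
``min(ON) - max(OFF)`` in reporter copies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .compose import CircuitModel

__all__ = [
    "SimulationSchedule",
    "SimulationError",
    "Trajectory",
    "TruthTable",
    "simulate",
    "truth_table",
    "normalize",
    "conserved_weights",
]

HOUR = 3600.0


@dataclass(frozen=True)
class SimulationSchedule:
    """Equilibrate without chemicals, then evaluate with inputs applied.

    ``input_levels`` maps chemical names to copy numbers applied at the
    equilibration/evaluation boundary.  With ``clamped=True`` (default) the
    chemicals are held constant during evaluation; otherwise they are
    supplied as a single bolus and free to deplete.
    """

    equilibration_hours: float = 96.0
    evaluation_hours: float = 48.0
    input_levels: dict = field(default_factory=dict)
    clamped: bool = True
    rtol: float = 1e-8
    atol: float = 1e-12


class SimulationError(RuntimeError):
    def __init__(self, message: str, last_time: float, last_state=None):
        super().__init__(f"{message} (last successful time point: {last_time:.1f} s)")
        self.last_time = last_time
        self.last_state = last_state


@dataclass
class Trajectory:
    model: CircuitModel
    times: np.ndarray  # seconds
    states: np.ndarray  # (n_times, n_species)

    def series(self, label: str) -> np.ndarray:
        return self.states[:, self.model.index(label)]

    def final(self, label: str) -> float:
        return float(self.states[-1, self.model.index(label)])


class _OdeSystem:
    """Vectorized mass-action right-hand side with analytic Jacobian."""

    def __init__(self, model: CircuitModel, clamped_idx: set[int] = frozenset()):
        n = model.n_species
        idx = {lab: i for i, lab in enumerate(model.species)}
        r1, r2, rates = [], [], []
        rows, cols, vals = [], [], []
        for j, rx in enumerate(model.reactions):
            ri = [idx[l] for l in rx.reactants]
            if len(ri) > 2:
                raise ValueError("mass-action reactions have at most two reactants")
            r1.append(ri[0] if ri else -1)
            r2.append(ri[1] if len(ri) > 1 else -1)
            rates.append(rx.rate_constant)
            stoich: dict[int, float] = {}
            for l in rx.reactants:
                stoich[idx[l]] = stoich.get(idx[l], 0.0) - 1.0
            for l in rx.products:
                stoich[idx[l]] = stoich.get(idx[l], 0.0) + 1.0
            for i, s in stoich.items():
                if s != 0.0 and i not in clamped_idx:
                    rows.append(i)
                    cols.append(j)
                    vals.append(s)
        self.n = n
        self.m = len(model.reactions)
        self.r1 = np.array(r1, dtype=int)
        self.r2 = np.array(r2, dtype=int)
        self.k = np.array(rates)
        self.S = np.zeros((n, self.m))
        self.S[rows, cols] = vals
        self.has_r1 = self.r1 >= 0
        self.has_r2 = self.r2 >= 0

    def fluxes(self, x: np.ndarray) -> np.ndarray:
        v = self.k.copy()
        v[self.has_r1] *= x[self.r1[self.has_r1]]
        v[self.has_r2] *= x[self.r2[self.has_r2]]
        return v

    def rhs(self, _t, x):
        return self.S @ self.fluxes(x)

    def jac(self, _t, x):
        D = np.zeros((self.m, self.n))
        j1 = np.nonzero(self.has_r1)[0]
        f1 = self.k[j1].copy()
        sel2 = self.has_r2[j1]
        f1[sel2] *= x[self.r2[j1[sel2]]]
        D[j1, self.r1[j1]] += f1
        j2 = np.nonzero(self.has_r2)[0]
        f2 = self.k[j2] * x[self.r1[j2]]
        D[j2, self.r2[j2]] += f2
        return self.S @ D


def _integrate(system: _OdeSystem, x0, t_span, schedule, n_points=50):
    t_eval = np.linspace(t_span[0], t_span[1], n_points)
    sol = solve_ivp(
        system.rhs,
        t_span,
        x0,
        method="BDF",
        jac=system.jac,
        rtol=schedule.rtol,
        atol=schedule.atol,
        t_eval=t_eval,
    )
    if not sol.success:
        last_t = sol.t[-1] if len(sol.t) else t_span[0]
        last_x = sol.y[:, -1] if sol.y.size else x0
        raise SimulationError(sol.message, last_t, last_x)
    return sol.t, sol.y.T


def initial_state(model: CircuitModel) -> np.ndarray:
    x0 = np.zeros(model.n_species)
    for lab, copies in model.initial.items():
        x0[model.index(lab)] = copies
    return x0


def simulate(
    model: CircuitModel,
    schedule: SimulationSchedule,
    x0: np.ndarray | None = None,
    skip_equilibration: bool = False,
) -> Trajectory:
    """Integrate the circuit over equilibration + evaluation.

    Chemical inputs are zero during equilibration and applied (clamped by
    default) at the boundary.  States are non-negative within solver
    tolerance.  Raises :class:`SimulationError` carrying the last successful
    time point on integration failure.
    """

    free = _OdeSystem(model)
    if x0 is None:
        x0 = initial_state(model)
    t_eq = schedule.equilibration_hours * HOUR
    if skip_equilibration or t_eq == 0:
        t1, y1 = np.array([0.0]), x0[None, :]
    else:
        t1, y1 = _integrate(free, x0, (0.0, t_eq), schedule)

    x_mid = y1[-1].copy()
    chem_idx = {model.index(model.chemical_labels[c]): lvl
                for c, lvl in schedule.input_levels.items()}
    for i, lvl in chem_idx.items():
        x_mid[i] = lvl
    clamped = _OdeSystem(model, set(chem_idx)) if schedule.clamped else free
    t_ev = schedule.evaluation_hours * HOUR
    if t_ev > 0:
        t2, y2 = _integrate(clamped, x_mid, (0.0, t_ev), schedule)
        times = np.concatenate([t1, t2 + t1[-1]])
        states = np.vstack([y1, y2])
    else:
        times, states = t1, y1
    return Trajectory(model, times, states)


# ---------------------------------------------------------------------------
# truth tables


@dataclass
class TruthTable:
    """Reporter readouts for all input combinations of a Boolean circuit."""

    inputs: tuple[str, ...]
    rows: list[dict]  # bits, raw, expected
    separation: float = math.nan
    threshold: float = math.nan
    classification_ok: bool = False

    @property
    def n_correct(self) -> int:
        return sum(1 for r in self.rows if r["call"] == r["expected"])

    def row(self, bits: str) -> dict:
        for r in self.rows:
            if r["bits"] == bits:
                return r
        raise KeyError(bits)

    def to_csv(self) -> str:
        lines = [",".join(self.inputs) + ",raw_copies,normalized,call,expected"]
        for r in self.rows:
            lines.append(
                ",".join(r["bits"])
                + f",{r['raw']:.6g},{r.get('normalized', float('nan')):.6g}"
                + f",{int(r['call'])},{int(r['expected'])}"
            )
        lines.append(f"# separation_copies,{self.separation:.6g}")
        return "\n".join(lines) + "\n"


def truth_table(
    model: CircuitModel,
    function,
    schedule: SimulationSchedule,
    output_label: str,
    inputs: tuple[str, ...] = ("a", "b", "c", "d"),
) -> TruthTable:
    """Evaluate a Boolean circuit over every input combination.

    One simulation per combination, all restarting from a single shared
    chemical-free equilibration.  Calls are thresholded at the midpoint
    between the largest OFF readout and the smallest ON readout; the
    separation is ``min(ON) - max(OFF)`` in reporter copies.  A table with
    separation <= 0 is returned with ``classification_ok=False``.
    """

    base = simulate(
        model,
        replace(schedule, evaluation_hours=0.0, input_levels={}),
    )
    x_eq = base.states[-1]
    out_i = model.index(output_label)

    rows = []
    for combo in range(2 ** len(inputs)):
        bits = format(combo, f"0{len(inputs)}b")
        levels = {
            name: schedule.input_levels.get(name, 0.0) * int(bit)
            for name, bit in zip(inputs, bits)
        }
        traj = simulate(
            model,
            replace(schedule, input_levels=levels),
            x0=x_eq,
            skip_equilibration=True,
        )
        raw = traj.states[-1, out_i]
        expected = bool(function(**{n: bool(int(b)) for n, b in zip(inputs, bits)}))
        rows.append({"bits": bits, "raw": float(raw), "expected": expected})

    table = TruthTable(inputs=inputs, rows=rows)
    return normalize(table)


def normalize(table: TruthTable) -> TruthTable:
    """Scale readouts by the minimal ON value and call rows by threshold.

    The minimal expected-ON row normalizes to 1.0; doubling every raw output
    leaves the normalized column unchanged.  All-equal outputs give
    separation 0 and a failed classification flag.
    """

    on = [r["raw"] for r in table.rows if r["expected"]]
    off = [r["raw"] for r in table.rows if not r["expected"]]
    min_on = min(on) if on else math.nan
    max_off = max(off) if off else 0.0
    separation = (min_on - max_off) if on else math.nan
    threshold = (min_on + max_off) / 2.0 if on else math.nan
    rows = []
    for r in table.rows:
        r = dict(r)
        r["normalized"] = r["raw"] / min_on if on and min_on > 0 else math.nan
        r["call"] = bool(r["raw"] > threshold) if on else False
        rows.append(r)
    return TruthTable(
        inputs=table.inputs,
        rows=rows,
        separation=separation,
        threshold=threshold,
        classification_ok=bool(on) and separation > 0
        and all(r["call"] == r["expected"] for r in rows),
    )


# ---------------------------------------------------------------------------
# conserved machinery accounting


def conserved_weights(model: CircuitModel) -> dict[str, np.ndarray]:
    """Per-species molecule counts of each conserved machinery class.

    Machinery occupancy is partly state-encoded (a translating ribosome is a
    state of the mRNA molecule; a loaded RISC is the ``RS_*`` complex; a
    cleared polymerase is ``PolCl_*``), so the weights account for explicit
    machinery molecules and for the states that sequester one.
    """

    weights = {k: np.zeros(model.n_species) for k in
               ("RNAP", "Ribosome", "Spliceosome", "Dicer", "RISC")}
    for i, lab in enumerate(model.species):
        g = model.graphs[lab]
        if g is None:
            continue
        for m in g.molecules:
            name = m.mtype.name
            if name == "RNAP" or name.startswith("PolCl_") or name.startswith("PoPSin"):
                weights["RNAP"][i] += 1
            elif name == "Rib" or name.startswith("RibCl_"):
                weights["Ribosome"][i] += 1
            elif name == "Spl":
                weights["Spliceosome"][i] += 1
            elif name == "Dicer":
                weights["Dicer"][i] += 1
            elif name == "RISC" or name.startswith("RS_"):
                weights["RISC"][i] += 1
            if name.startswith("M_"):
                if m.states.get("rib") in ("init", "elong", "lump"):
                    weights["Ribosome"][i] += 1
                if any(c.startswith("s") and st == "taken"
                       for c, st in m.states.items()):
                    weights["RISC"][i] += 1
    return weights
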
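"""Coupled PK-insulin-FFA simulation and periodic steady states.

The full individual model is one stiff ODE system (turnover of FFA has a
half-life of seconds while the NiAc action compartments relax over days),
integrated with LSODA at tight tolerances and restarted at every infusion
on/off/step boundary so that rate discontinuities never cross a solver
step.

State layout (columns of a :class:`Trajectory`):

* lean:  ``Asc, Cp, Ct, I, M1I, M2I, RI, F, MF, RF, NF``
* obese: ``Asc, Cp, I, M1I, M2I, RI, NI, F, MF, RF, NF``

Sequential runs (PK first, then insulin driven by the PK interpolant,
then FFA driven by both) mirror how the sub-models are fitted; coupled
runs integrate everything in one state vector.  Both must agree to well
under 0.1 %, which is covered by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import ffa as ffa_mod
from . import insulin as ins_mod
from . import pk as pk_mod
from .parameters import FFAParameters, InsulinParameters, PKParameters
from .protocols import DosingProtocol

__all__ = [
    "Trajectory",
    "integrate_piecewise",
    "simulate_individual",
    "periodic_steady_state",
    "state_columns",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


class SolverError(RuntimeError):
    """Raised when the stiff integrator fails to complete a segment."""


@dataclass
class Trajectory:
    """Dense simulated path: a tidy frame plus piecewise dense interpolants."""

    frame: pd.DataFrame
    dense: Optional[List[Tuple[float, float, Callable]]] = None

    @classmethod
    def from_arrays(cls, times, states, columns, dense=None):
        frame = pd.DataFrame(np.asarray(states), columns=list(columns))
        frame.insert(0, "time", np.asarray(times, dtype=float))
        return cls(frame=frame, dense=dense)

    @property
    def times(self) -> np.ndarray:
        return self.frame["time"].to_numpy()

    def __getitem__(self, column: str) -> np.ndarray:
        return self.frame[column].to_numpy()

    @property
    def columns(self) -> List[str]:
        return [c for c in self.frame.columns if c != "time"]

    def interp(self, t) -> np.ndarray:
        """Evaluate the dense solution at times ``t`` (shape: t x states)."""
        if self.dense is None:
            raise ValueError("trajectory was built without dense output")
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty((t.size, len(self.columns)))
        starts = np.array([a for a, _, _ in self.dense])
        ends = np.array([b for _, b, _ in self.dense])
        idx = np.clip(np.searchsorted(ends, t, side="left"), 0, len(self.dense) - 1)
        for k in range(len(self.dense)):
            mask = idx == k
            if np.any(mask):
                _, _, sol = self.dense[k]
                tk = np.clip(t[mask], starts[k], ends[k])
                out[mask] = sol(tk).T
        return out

    def interpolant(self, column: str) -> Callable:
        """Scalar-capable interpolant of one state column."""
        j = self.columns.index(column)

        def fun(t):
            vals = self.interp(t)[:, j]
            return float(vals[0]) if np.isscalar(t) or np.ndim(t) == 0 else vals

        return fun

    def final_state(self) -> np.ndarray:
        return self.frame.iloc[-1][self.columns].to_numpy(dtype=float)


def state_columns(species: str) -> List[str]:
    if species == "lean":
        return ["Asc", "Cp", "Ct", "I", "M1I", "M2I", "RI", "F", "MF", "RF", "NF"]
    return ["Asc", "Cp", "I", "M1I", "M2I", "RI", "NI", "F", "MF", "RF", "NF"]


def _segment_edges(protocol: DosingProtocol, t_start: float, t_end: float) -> np.ndarray:
    edges = [t_start, t_end]
    for b in protocol.boundaries():
        if t_start < b < t_end:
            edges.append(float(b))
    return np.unique(np.array(edges, dtype=float))


def integrate_piecewise(
    rhs_factory: Callable[[float], Callable],
    y0: np.ndarray,
    protocol: DosingProtocol,
    t_start: float,
    t_end: float,
    t_grid=None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "LSODA",
):
    """Integrate segment-by-segment across the protocol's rate boundaries.

    ``rhs_factory(rate)`` returns the RHS valid for a segment with the
    given programmed rate.  Returns (times, states, dense) where dense is
    a list of ``(a, b, OdeSolution)`` spans suitable for interpolation.
    """
    edges = _segment_edges(protocol, t_start, t_end)
    t_grid = None if t_grid is None else np.asarray(t_grid, dtype=float)
    all_t: List[np.ndarray] = []
    all_y: List[np.ndarray] = []
    dense: List[Tuple[float, float, Callable]] = []
    y = np.asarray(y0, dtype=float)
    for a, b in zip(edges[:-1], edges[1:]):
        rate = protocol.rate_at(0.5 * (a + b))
        rhs = rhs_factory(rate)
        t_eval = None
        if t_grid is not None:
            inside = t_grid[(t_grid >= a) & (t_grid <= b)]
            t_eval = np.unique(np.concatenate([[a], inside, [b]]))
        sol = solve_ivp(rhs, (a, b), y, method=method, rtol=rtol, atol=atol,
                        dense_output=True, t_eval=t_eval)
        if not sol.success:
            raise SolverError(
                f"integration failed on segment [{a}, {b}] (rate={rate}): {sol.message}"
            )
        dense.append((a, b, sol.sol))
        take = slice(0, None) if not all_t else slice(1, None)
        all_t.append(sol.t[take])
        all_y.append(sol.y[:, take])
        y = sol.y[:, -1]
    times = np.concatenate(all_t)
    states = np.concatenate(all_y, axis=1).T
    if t_grid is not None:
        helper = Trajectory.from_arrays(times, states,
                                        [str(i) for i in range(states.shape[1])],
                                        dense=dense)
        times = np.sort(t_grid)
        states = helper.interp(times)
    return times, states, dense


def derive_baseline(pk: PKParameters, ins: InsulinParameters, ffa: FFAParameters):
    """Endogenous baseline and derived turnover rates for one individual."""
    Cp0 = pk_mod.baseline_concentration(pk)
    kinI, kinRI = ins_mod.derive_insulin_baseline_rates(ins, Cp0)
    kinF, kinRF = ffa_mod.derive_ffa_baseline_rates(ffa, ins, Cp0)
    return Cp0, (kinI, kinRI), (kinF, kinRF)


def baseline_state(pk: PKParameters, ins: InsulinParameters, ffa: FFAParameters) -> np.ndarray:
    Cp0 = pk_mod.baseline_concentration(pk)
    return np.concatenate([
        pk_mod.pk_initial_state(pk),
        ins_mod.insulin_initial_state(ins, Cp0),
        ffa_mod.ffa_initial_state(ffa, Cp0),
    ])


def _coupled_rhs_factory(protocol, pk, ins, ffa, rates):
    (kinI, kinRI), (kinF, kinRF) = rates
    n_pk = 3 if pk.two_compartment else 2
    n_ins = 5 if ins.dynamic_efficacy else 4

    def factory(rate):
        def rhs(t, y):
            d_pk = pk_mod._pk_rhs_seg(t, y[:n_pk], pk, protocol.route, rate,
                                      protocol.pump_first_activation)
            Cp = y[1]
            ins_state = y[n_pk:n_pk + n_ins]
            d_ins = ins_mod.insulin_rhs(t, ins_state, ins, Cp, kinI, kinRI)
            I = ins_state[0]
            d_ffa = ffa_mod.ffa_rhs(t, y[n_pk + n_ins:], ffa, Cp, I, kinF, kinRF)
            return np.concatenate([d_pk, d_ins, d_ffa])

        return rhs

    return factory


def _with_actions(frame: pd.DataFrame, ins: InsulinParameters, ffa: FFAParameters) -> pd.DataFrame:
    """Append the per-time action multipliers used in the mechanism plots."""
    Cp = frame["Cp"].to_numpy()
    NI = frame["NI"].to_numpy() if "NI" in frame else Cp  # lean: constant efficacy anyway
    NF = frame["NF"].to_numpy()
    E_i = ins_mod.E_NI(np.maximum(NI, 0.0), ins)
    E_f = ffa_mod.E_NF(np.maximum(NF, 0.0), ffa)
    frame = frame.copy()
    frame["E_NI"] = E_i
    frame["H_NI"] = ins_mod.H_NI(np.maximum(Cp, 0.0), E_i, ins)
    frame["E_NF"] = E_f
    frame["H_NF"] = ffa_mod.H_NF(np.maximum(Cp, 0.0), E_f, ffa)
    frame["moderator_action"] = ffa.F0 / frame["MF"].to_numpy()
    return frame


def simulate_individual(
    protocol: DosingProtocol,
    pk: PKParameters,
    ins: InsulinParameters,
    ffa: FFAParameters,
    t_grid=None,
    mode: str = "coupled",
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    y0: Optional[np.ndarray] = None,
    with_actions: bool = True,
    t_end: Optional[float] = None,
) -> Trajectory:
    """Simulate one individual's full NiAc-insulin-FFA response.

    ``mode="coupled"`` integrates the single 11-state system;
    ``mode="sequential"`` integrates PK, insulin and FFA in turn, each
    driven by exact interpolants of the upstream solution (mirroring the
    sequential fitting scheme).
    """
    if pk.species != ins.species or pk.species != ffa.species:
        raise ValueError("species mismatch between parameter sets")
    Cp0, ins_rates, ffa_rates = derive_baseline(pk, ins, ffa)
    columns = state_columns(pk.species)
    t_start = protocol.start if t_grid is None else min(protocol.start, float(np.min(t_grid)))
    stop = protocol.end if t_grid is None else max(protocol.end, float(np.max(t_grid)))
    if t_end is not None:
        stop = max(stop, t_end)

    if mode == "coupled":
        y_init = baseline_state(pk, ins, ffa) if y0 is None else np.asarray(y0, dtype=float)
        factory = _coupled_rhs_factory(protocol, pk, ins, ffa, (ins_rates, ffa_rates))
        times, states, dense = integrate_piecewise(
            factory, y_init, protocol, t_start, stop, t_grid, rtol=rtol, atol=atol
        )
        traj = Trajectory.from_arrays(times, states, columns, dense=dense)
    elif mode == "sequential":
        if y0 is not None:
            raise ValueError("custom initial states require mode='coupled'")
        traj = _simulate_sequential(protocol, pk, ins, ffa, t_grid, t_start, stop,
                                    Cp0, ins_rates, ffa_rates, rtol, atol)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if with_actions:
        traj.frame = _with_actions(traj.frame, ins, ffa)
    return traj


def _simulate_sequential(protocol, pk, ins, ffa, t_grid, t_start, t_end,
                         Cp0, ins_rates, ffa_rates, rtol, atol):
    kinI, kinRI = ins_rates
    kinF, kinRF = ffa_rates
    pk_traj = pk_mod.simulate_pk(protocol, pk, t_grid=np.array([t_start, t_end]),
                                 rtol=rtol, atol=atol)
    Cp_fun = pk_traj.interpolant("Cp")

    ins_cols = ["I", "M1I", "M2I", "RI"] + (["NI"] if ins.dynamic_efficacy else [])
    y0_ins = ins_mod.insulin_initial_state(ins, Cp0)

    def ins_factory(rate):
        return lambda t, y: ins_mod.insulin_rhs(t, y, ins, Cp_fun(t), kinI, kinRI)

    t_i, y_i, dense_i = integrate_piecewise(ins_factory, y0_ins, protocol,
                                            t_start, t_end, None, rtol=rtol, atol=atol)
    ins_traj = Trajectory.from_arrays(t_i, y_i, ins_cols, dense=dense_i)
    I_fun = ins_traj.interpolant("I")

    def ffa_factory(rate):
        return lambda t, y: ffa_mod.ffa_rhs(t, y, ffa, Cp_fun(t), I_fun(t), kinF, kinRF)

    y0_ffa = ffa_mod.ffa_initial_state(ffa, Cp0)
    t_f, y_f, dense_f = integrate_piecewise(ffa_factory, y0_ffa, protocol,
                                            t_start, t_end, None, rtol=rtol, atol=atol)
    ffa_traj = Trajectory.from_arrays(t_f, y_f, ffa_mod.FFA_STATES, dense=dense_f)

    grid = np.asarray(t_grid, dtype=float) if t_grid is not None else t_f
    parts = [pk_traj.interp(grid), ins_traj.interp(grid), ffa_traj.interp(grid)]
    states = np.hstack(parts)
    columns = pk_traj.columns + ins_cols + list(ffa_mod.FFA_STATES)
    traj = Trajectory.from_arrays(grid, states, columns, dense=None)
    traj._parts = (pk_traj, ins_traj, ffa_traj)  # keep dense sub-solutions alive
    return traj


def periodic_steady_state(
    cycle: DosingProtocol,
    pk: PKParameters,
    ins: InsulinParameters,
    ffa: FFAParameters,
    tol: float = 1e-6,
    max_cycles: int = 500,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    y0: Optional[np.ndarray] = None,
    insulin: str = "dynamic",
    pin_nf: bool = True,
) -> Tuple[Trajectory, int]:
    """Iterate a dosing cycle until the state at the cycle start converges.

    The cycle protocol must be defined on ``[0, P]`` with ``P`` its
    ``acute_window`` end.  Convergence is the maximum relative change of
    all states between successive cycle starts falling below ``tol``.

    ``insulin="set_point"`` clamps insulin at its baseline (regulator at
    1), the convention used for the steady-state regimen predictions; see
    the methods note.  Returns ``(converged cycle trajectory, cycles)``.
    """
    period = cycle.acute_window[1]
    if cycle.segments and (cycle.segments[0][0] < 0 or cycle.segments[-1][1] > period):
        raise ValueError("cycle segments must lie within [0, period]")
    if insulin == "set_point":
        return _periodic_clamped(cycle, pk, ins, ffa, tol, max_cycles, rtol, atol, y0, pin_nf)
    y = baseline_state(pk, ins, ffa) if y0 is None else np.asarray(y0, dtype=float)
    scale = np.maximum(np.abs(y), 1e-3)
    prev_change = None
    for k in range(1, max_cycles + 1):
        traj = simulate_individual(cycle, pk, ins, ffa, mode="coupled", y0=y,
                                   rtol=rtol, atol=atol, with_actions=False,
                                   t_grid=None, t_end=period)
        y_new = traj.final_state()
        change = np.max(np.abs(y_new - y) / np.maximum(scale, np.abs(y_new)))
        y = y_new
        if _cycle_converged(change, prev_change, k, tol):
            traj.frame = _with_actions(traj.frame, ins, ffa)
            return traj, k
        prev_change = change
    raise SolverError(
        f"periodic steady state not reached in {max_cycles} cycles "
        f"(last relative change {change:.3g})"
    )


def _cycle_converged(change, prev_change, k, tol) -> bool:
    """Stopping rule for cycle iteration.

    Accepts either a directly small cycle-to-cycle change, or - since the
    slow states (the NiAc action compartments) approach the periodic
    attractor geometrically - a small *projected remaining* change
    ``change * r / (1 - r)`` with the contraction ratio estimated from
    successive iterates.  The projection matters for short cycles, whose
    per-cycle contraction is weak.
    """
    if change < tol:
        return True
    if prev_change is not None and k >= 3 and prev_change > 0:
        r = change / prev_change
        if r < 0.999 and change * r / (1.0 - r) < tol:
            return True
    return False


def _clamped_rhs_factory(cycle, pk, ffa, kinF, I0):
    """FFA subsystem with insulin held at its set point (RF frozen at 1)."""
    n_pk = 3 if pk.two_compartment else 2

    def factory(rate):
        def rhs(t, y):
            d_pk = pk_mod._pk_rhs_seg(t, y[:n_pk], pk, cycle.route, rate,
                                      cycle.pump_first_activation)
            Cp = y[1]
            F, MF, NF = y[n_pk], y[n_pk + 1], y[n_pk + 2]
            E = ffa_mod.E_NF(max(NF, 0.0), ffa)
            H = ffa_mod.H_NF(max(Cp, 0.0), E, ffa)
            dF = kinF * H * (ffa.F0 / MF) - ffa.koutF * F
            dMF = ffa.ktolF * (F - MF)
            dNF = ffa.kNF * (Cp - NF)
            return np.concatenate([d_pk, [dF, dMF, dNF]])

        return rhs

    return factory


def _periodic_pk_and_nf(cycle, pk, ffa, rtol, atol):
    """Periodic PK cycle state and the exact periodic NF at the cycle start.

    The PK subsystem has no slow memory, so a handful of cycle iterations
    give its periodic orbit.  The NiAc action compartment is a linear
    low-pass of Cp, so its periodic initial value follows in closed form
    from the converged Cp cycle:

        NF*(0) = kNF * e^(-kNF*P) * int_0^P e^(kNF*s) Cp(s) ds / (1 - e^(-kNF*P)).

    Pinning NF at this value removes the days-long transient from the
    cycle iteration, which then only has to relax the moderator.
    """
    from scipy.integrate import quad

    period = cycle.acute_window[1]
    y_pk = pk_mod.pk_initial_state(pk)

    def pk_factory(rate):
        return lambda t, y: pk_mod._pk_rhs_seg(t, y, pk, cycle.route, rate,
                                               cycle.pump_first_activation)

    dense = None
    for _ in range(60):
        _, states, dense = integrate_piecewise(pk_factory, y_pk, cycle, 0.0, period,
                                               None, rtol=rtol, atol=atol)
        y_new = states[-1]
        if np.max(np.abs(y_new - y_pk) / np.maximum(np.abs(y_new), 1e-6)) < 1e-10:
            y_pk = y_new
            break
        y_pk = y_new
    k = ffa.kNF
    integral = 0.0
    for lo, hi, sol in dense:
        val, _ = quad(lambda s: np.exp(k * (s - period)) * sol(s)[1], lo, hi,
                      epsabs=1e-14, epsrel=1e-10, limit=200)
        integral += val
    nf0 = k * integral / (1.0 - np.exp(-k * period))
    return y_pk, nf0


def _periodic_clamped(cycle, pk, ins, ffa, tol, max_cycles, rtol, atol, y0, pin_nf=True):
    Cp0, _, (kinF, kinRF) = derive_baseline(pk, ins, ffa)
    period = cycle.acute_window[1]
    n_pk = 3 if pk.two_compartment else 2
    if pin_nf:
        y_pk, nf0 = _periodic_pk_and_nf(cycle, pk, ffa, rtol, atol)
        if y0 is None:
            y = np.concatenate([y_pk, [ffa.F0, ffa.F0, nf0]])
        else:
            y = np.asarray(y0, dtype=float).copy()
            y[:n_pk] = y_pk
            y[-1] = nf0
    elif y0 is None:
        y = np.concatenate([pk_mod.pk_initial_state(pk), [ffa.F0, ffa.F0, Cp0]])
    else:
        y = np.asarray(y0, dtype=float).copy()
    factory = _clamped_rhs_factory(cycle, pk, ffa, kinF, ins.I0)
    scale = np.maximum(np.abs(y), 1e-3)
    cols = (["Asc", "Cp", "Ct"] if pk.two_compartment else ["Asc", "Cp"]) + ["F", "MF", "NF"]
    prev_change = None
    for k in range(1, max_cycles + 1):
        times, states, dense = integrate_piecewise(factory, y, cycle, 0.0, period,
                                                   None, rtol=rtol, atol=atol)
        y_new = states[-1]
        change = np.max(np.abs(y_new - y) / np.maximum(scale, np.abs(y_new)))
        y = y_new
        if _cycle_converged(change, prev_change, k, tol):
            return Trajectory.from_arrays(times, states, cols, dense=dense), k
        prev_change = change
    raise SolverError(
        f"periodic steady state not reached in {max_cycles} cycles "
        f"(last relative change {change:.3g})"
    )
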
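"""NiAc exposure model: disposition ODEs, endogenous baseline, pump input.

Lean rats: two-compartment disposition with two parallel Michaelis-Menten
elimination pathways.  Obese rats: one-compartment, single pathway.  Both
carry endogenous NiAc synthesis, so the drug-free plasma concentration is
the positive root of synthesis = total saturable elimination.

Subcutaneous dosing feeds a depot compartment through an implanted
mini-pump whose effective output ramps up as erf(t*delta/sqrt(t0)) from
first activation: during the 7 days between implantation and activation,
tissue fluid dilutes the catheter dead volume, so early delivery lags the
programmed rate.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.special import erf

from .parameters import PKParameters
from .protocols import DosingProtocol

__all__ = [
    "pump_rate",
    "pk_rhs",
    "baseline_concentration",
    "elimination_rate",
    "plateau_concentration",
    "simulate_pk",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


def pump_rate(t, inf_rate, delta, t0=168.0):
    """Effective s.c. pump output at time ``t`` since first activation.

    Returns ``inf_rate * erf(t*delta/sqrt(t0))``: zero at activation,
    approaching the programmed rate with the start-up dilution washed out
    on a time scale of sqrt(t0)/delta (about 10 min at the estimated
    delta, with full recovery in roughly 1.5 h).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("pump_rate requires t >= 0 (time since first activation)")
    if delta <= 0 or t0 <= 0:
        raise ValueError("delta and t0 must be positive")
    out = inf_rate * erf(t * delta / math.sqrt(t0))
    return float(out) if out.ndim == 0 else out


def _elimination(params: PKParameters, Cp: float) -> float:
    """Total saturable elimination rate (umol/kg/h) at concentration Cp."""
    rate = params.Vmax1 * Cp / (params.Km1 + Cp)
    if params.two_compartment:
        rate += params.Vmax2 * Cp / (params.Km2 + Cp)
    return rate


def elimination_rate(params: PKParameters, Cp) -> np.ndarray:
    """Vectorized total Michaelis-Menten elimination at concentration Cp."""
    Cp = np.asarray(Cp, dtype=float)
    rate = params.Vmax1 * Cp / (params.Km1 + Cp)
    if params.two_compartment:
        rate = rate + params.Vmax2 * Cp / (params.Km2 + Cp)
    return rate


def baseline_concentration(params: PKParameters) -> float:
    """Drug-free steady-state plasma NiAc concentration Cp0 (uM).

    Solves Synt = sum_i Vmax_i*Cp/(Km_i+Cp).  With a single pathway the
    closed form Cp0 = Synt*Km1/(Vmax1-Synt) is used; with two pathways
    the unique positive root is bracketed and refined numerically.
    """
    total_vmax = params.Vmax1 + (params.Vmax2 or 0.0)
    if params.Synt <= 0:
        return 0.0
    if params.Synt >= total_vmax:
        raise ValueError(
            "no drug-free steady state: endogenous synthesis "
            f"({params.Synt}) >= total elimination capacity ({total_vmax})"
        )
    if not params.two_compartment:
        return params.Synt * params.Km1 / (params.Vmax1 - params.Synt)
    balance = lambda c: _elimination(params, c) - params.Synt
    hi = max(params.Km1, params.Km2) * params.Synt / (total_vmax - params.Synt) + 1.0
    while balance(hi) < 0:
        hi *= 2.0
    root = brentq(balance, 0.0, hi, xtol=1e-16, rtol=8.9e-16)
    residual = abs(_elimination(params, root) - params.Synt)
    assert residual < 1e-12 * params.Synt + 1e-15
    return root


def plateau_concentration(params: PKParameters, iv_rate: float) -> float:
    """Steady-state Cp under a constant i.v. infusion (algebraic MM balance)."""
    total_in = iv_rate + params.Synt
    total_vmax = params.Vmax1 + (params.Vmax2 or 0.0)
    if total_in >= total_vmax:
        raise ValueError("infusion exceeds elimination capacity; no plateau exists")
    balance = lambda c: _elimination(params, c) - total_in
    hi = 1.0
    while balance(hi) < 0:
        hi *= 2.0
    return brentq(balance, 0.0, hi, xtol=1e-15, rtol=8.9e-16)


def rate_for_plateau(params: PKParameters, Cp_target: float) -> float:
    """Constant i.v. rate whose plateau concentration is ``Cp_target``."""
    return _elimination(params, Cp_target) - params.Synt


def pk_rhs(t, state, params: PKParameters, protocol: DosingProtocol):
    """Time derivative of the PK state [Asc, Cp(, Ct)].

    The protocol supplies the programmed rate at ``t``; i.v. rates enter
    plasma directly (the depot is bypassed and dAsc/dt = 0) while s.c.
    rates feed the depot through the diluted pump output.
    """
    rate = protocol.rate_at(t)
    return _pk_rhs_seg(t, np.asarray(state, dtype=float), params, protocol.route,
                       rate, protocol.pump_first_activation)


def _pk_rhs_seg(t, state, params, route, rate, pump_activation):
    """RHS for one constant-programmed-rate segment."""
    if route == "sc_pump":
        Asc = state[0]
        if rate > 0:
            pump = rate * erf((t - pump_activation) * params.delta / math.sqrt(params.t0))
        else:
            pump = 0.0
        dAsc = pump - params.ka * Asc
        inp = params.ka * Asc
    else:
        dAsc = 0.0
        inp = rate
    Cp = state[1]
    if params.two_compartment:
        Ct = state[2]
        dCp = (inp + params.Synt - _elimination(params, Cp)
               - params.Cld * Cp + params.Cld * Ct) / params.Vp
        dCt = (params.Cld * Cp - params.Cld * Ct) / params.Vt
        return np.array([dAsc, dCp, dCt])
    dCp = (inp + params.Synt - _elimination(params, Cp)) / params.Vp
    return np.array([dAsc, dCp])


def pk_initial_state(params: PKParameters) -> np.ndarray:
    """Baseline PK state: empty depot, plasma and tissue at Cp0."""
    Cp0 = baseline_concentration(params)
    if params.two_compartment:
        return np.array([0.0, Cp0, Cp0])
    return np.array([0.0, Cp0])


def simulate_pk(
    protocol: DosingProtocol,
    params: PKParameters,
    t_grid=None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
):
    """Integrate the NiAc disposition model over a protocol.

    Returns a :class:`~niacffa.simulate.Trajectory` restricted to the PK
    states.  Integration restarts at every infusion on/off/step boundary.
    """
    from .simulate import integrate_piecewise, Trajectory

    y0 = pk_initial_state(params)
    t_start = protocol.start if t_grid is None else min(protocol.start, float(np.min(t_grid)))
    t_end = protocol.end if t_grid is None else max(protocol.end, float(np.max(t_grid)))

    def rhs_factory(rate):
        return lambda t, y: _pk_rhs_seg(t, y, params, protocol.route, rate,
                                        protocol.pump_first_activation)

    times, states, dense = integrate_piecewise(
        rhs_factory, y0, protocol, t_start, t_end, t_grid, rtol=rtol, atol=atol
    )
    columns = ["Asc", "Cp", "Ct"] if params.two_compartment else ["Asc", "Cp"]
    return Trajectory.from_arrays(times, states, columns, dense=dense)
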
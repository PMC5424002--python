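"""Insulin turnover model.

Insulin release (rate k_inI) is inhibited by plasma NiAc through a Hill
function whose efficacy is itself down-regulated in obese rats by a slow
"NiAc action" compartment (drug resistance).  Two moderator compartments
in cascade produce tolerance and post-infusion rebound, and an
insulin-driven integral regulator with set point I0 guarantees complete
adaptation: the only equilibrium under any sustained exposure has
insulin back at its baseline.
"""

from __future__ import annotations

import numpy as np

from .parameters import InsulinParameters

__all__ = [
    "H_NI",
    "E_NI",
    "derive_insulin_baseline_rates",
    "insulin_rhs",
    "insulin_initial_state",
    "INSULIN_STATES",
]

#: state layout; the NiAc action compartment NI is present only for obese rats
INSULIN_STATES = ("I", "M1I", "M2I", "RI", "NI")


def E_NI(N, params: InsulinParameters):
    """NiAc efficacy on insulin release at action-compartment level ``N``.

    Constant (``ImaxNI``) in lean rats; in obese rats it is down-regulated
    from ``ImaxNI`` towards ``ImaxNI*(1-SNI)`` as N rises past ``N50I``.
    """
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise ValueError("action-compartment concentration must be >= 0")
    if not params.dynamic_efficacy:
        out = np.full_like(N, params.ImaxNI)
    else:
        Ng = N ** params.gamma
        out = params.ImaxNI * (1.0 - params.SNI * Ng / (params.N50I ** params.gamma + Ng))
    return float(out) if out.ndim == 0 else out


def H_NI(Cp, E, params: InsulinParameters):
    """Inhibition factor on insulin release: 1 - E*Cp^n/(IC50^n + Cp^n)."""
    Cp = np.asarray(Cp, dtype=float)
    if np.any(Cp < 0):
        raise ValueError("plasma concentration must be >= 0")
    Cpn = Cp ** params.n
    out = 1.0 - np.asarray(E) * Cpn / (params.IC50NI ** params.n + Cpn)
    return float(out) if out.ndim == 0 else out


def inhibition_at(Cp, N, params: InsulinParameters):
    """Convenience: H_NI evaluated with the efficacy at action level N."""
    return H_NI(Cp, E_NI(N, params), params)


def derive_insulin_baseline_rates(params: InsulinParameters, Cp0: float):
    """Turnover rates (k_inI, k_inRI) implied by a drug-free steady state.

    At baseline all moderators sit at I0 and the regulator at 1, so
    stationarity of the regulator gives k_inRI = k_outRI*I0 and
    stationarity of insulin gives k_inI = k_outI*I0 / H_NI(Cp0), where
    the inhibition is evaluated at the endogenous NiAc level Cp0.
    """
    H0 = inhibition_at(Cp0, Cp0, params)
    if H0 <= 0:
        raise ValueError("degenerate parameters: full inhibition at baseline exposure")
    kinRI = params.koutRI * params.I0
    kinI = params.koutI * params.I0 / H0
    return kinI, kinRI


def insulin_initial_state(params: InsulinParameters, Cp0: float) -> np.ndarray:
    """Baseline state [I, M1I, M2I, RI(, NI)]: everything at its set point."""
    base = [params.I0, params.I0, params.I0, 1.0]
    if params.dynamic_efficacy:
        base.append(Cp0)
    return np.array(base)


def insulin_rhs(t, state, params: InsulinParameters, Cp, kinI: float, kinRI: float):
    """Time derivative of the insulin state.

    ``Cp`` is the plasma NiAc concentration at ``t`` (scalar), supplied
    either from a PK interpolant (sequential runs) or from the coupled
    state vector.  ``kinI``/``kinRI`` are the derived baseline rates.
    """
    I, M1I, M2I, RI = state[0], state[1], state[2], state[3]
    if M1I <= 0:
        raise FloatingPointError("insulin moderator M1I reached a non-positive value")
    M0I = params.I0
    if params.dynamic_efficacy:
        NI = state[4]
        E = E_NI(max(NI, 0.0), params)
    else:
        E = params.ImaxNI
    H = H_NI(max(Cp, 0.0), E, params)
    dI = kinI * RI * H * (M0I / M1I) - params.koutI * (M2I / M0I) * I
    dM1 = params.ktolI * (I - M1I)
    dM2 = params.ktolI * (M1I - M2I)
    dRI = kinRI - params.koutRI * I
    if params.dynamic_efficacy:
        dNI = params.kNI * (Cp - state[4])
        return np.array([dI, dM1, dM2, dRI, dNI])
    return np.array([dI, dM1, dM2, dRI])
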
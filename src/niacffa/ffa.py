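"""FFA (free fatty acid) turnover model.

FFA release is inhibited by plasma NiAc (Hill function with dynamic
efficacy in both species) and stimulated/suppressed by an insulin-driven
integral regulator whose set point is the *insulin* baseline: when
insulin runs below I0 the regulator rises and pushes FFA release up (the
antilipolytic action of insulin, inverted).  A single moderator
compartment provides acute tolerance and rebound.
"""

from __future__ import annotations

import numpy as np

from .parameters import FFAParameters, InsulinParameters

__all__ = [
    "H_NF",
    "E_NF",
    "derive_ffa_baseline_rates",
    "ffa_rhs",
    "ffa_initial_state",
    "FFA_STATES",
]

FFA_STATES = ("F", "MF", "RF", "NF")


def E_NF(N, params: FFAParameters):
    """NiAc efficacy on FFA release at action-compartment level ``N``."""
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise ValueError("action-compartment concentration must be >= 0")
    Np = N ** params.phi
    out = params.ImaxNF * (1.0 - params.SNF * Np / (params.N50F ** params.phi + Np))
    return float(out) if out.ndim == 0 else out


def H_NF(Cp, E, params: FFAParameters):
    """Inhibition factor on FFA release: 1 - E*Cp^m/(IC50^m + Cp^m)."""
    Cp = np.asarray(Cp, dtype=float)
    if np.any(Cp < 0):
        raise ValueError("plasma concentration must be >= 0")
    Cpm = Cp ** params.m
    out = 1.0 - np.asarray(E) * Cpm / (params.IC50NF ** params.m + Cpm)
    return float(out) if out.ndim == 0 else out


def inhibition_at(Cp, N, params: FFAParameters):
    """Convenience: H_NF evaluated with the efficacy at action level N."""
    return H_NF(Cp, E_NF(N, params), params)


def derive_ffa_baseline_rates(params: FFAParameters, insulin_params: InsulinParameters, Cp0: float):
    """Turnover rates (k_inF, k_inRF) implied by a drug-free steady state.

    The regulator set point is the insulin baseline: k_inRF = k_outRF*I0.
    FFA stationarity at baseline gives k_inF = k_outF*F0 / H_NF(Cp0).
    """
    H0 = inhibition_at(Cp0, Cp0, params)
    if H0 <= 0:
        raise ValueError("degenerate parameters: full inhibition at baseline exposure")
    kinRF = params.koutRF * insulin_params.I0
    kinF = params.koutF * params.F0 / H0
    return kinF, kinRF


def ffa_initial_state(params: FFAParameters, Cp0: float) -> np.ndarray:
    """Baseline state [F, MF, RF, NF]."""
    return np.array([params.F0, params.F0, 1.0, Cp0])


def ffa_rhs(t, state, params: FFAParameters, Cp, I, kinF: float, kinRF: float):
    """Time derivative of the FFA state given plasma NiAc and insulin at t."""
    F, MF, RF, NF = state
    if MF <= 0:
        raise FloatingPointError("FFA moderator reached a non-positive value")
    E = E_NF(max(NF, 0.0), params)
    H = H_NF(max(Cp, 0.0), E, params)
    dF = kinF * RF * H * (params.F0 / MF) - params.koutF * F
    dMF = params.ktolF * (F - MF)
    dRF = kinRF - params.koutRF * I
    dNF = params.kNF * (Cp - NF)
    return np.array([dF, dMF, dRF, dNF])
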
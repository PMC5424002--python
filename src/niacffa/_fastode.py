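"""Compiled right-hand sides for the estimation layer.

FOCE evaluates each subject's trajectory hundreds of times inside nested
optimizations, so the inner integrations run a numba-compiled kernel of
the full coupled system (exposure, optionally insulin, optionally FFA in
one smooth state vector) instead of the reference pure-Python path used
for simulation.  Upstream sub-models enter with their parameters frozen
at the subject's empirical Bayes estimates, so co-integration is exactly
the sequential scheme's "fixed covariate" — without interpolated
covariates that would litter the forcing with kinks and throttle the
step size.  The kernels implement the same equations as the reference
modules; a test pins the two paths together.

numba is optional: without it the kernels run as plain Python (correct,
just slower).
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is normally present
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


# Parameter vector layouts -------------------------------------------------
# pk:      [Vp, Vmax1, Km1, Synt, ka, delta, t0, (Vt, Cld, Vmax2, Km2)]
# insulin: [kinI, kinRI, koutI, ktolI, I0, ImaxNI, IC50NI, n,
#           dyn_flag, kNI, N50I, SNI, gamma]
# ffa:     [kinF, kinRF, koutF, ktolF, F0, ImaxNF, IC50NF, m,
#           kNF, N50F, SNF, phi, koutRF]
#
# State layout: [Asc, Cp(, Ct)] (+ [I, M1I, M2I, RI(, NI)] if level >= 2)
#               (+ [F, MF, RF, NF] if level >= 3)


@njit(cache=True)
def _erf_approx(x):
    # Abramowitz-Stegun 7.1.26 rational approximation (|error| < 1.5e-7)
    s = 1.0 if x >= 0.0 else -1.0
    ax = abs(x)
    u = 1.0 / (1.0 + 0.3275911 * ax)
    poly = u * (0.254829592 + u * (-0.284496736 + u * (1.421413741
               + u * (-1.453152027 + u * 1.061405429))))
    return s * (1.0 - poly * np.exp(-ax * ax))


@njit(cache=True)
def _sys_rhs(t, y, pkv, insv, ffav, two_cmt, sc_route, pump_act,
             seg_start, seg_end, seg_rate, level):
    rate = 0.0
    for k in range(seg_start.size):
        if seg_start[k] <= t < seg_end[k]:
            rate = seg_rate[k]
            break
    out = np.zeros(y.size)
    # --- exposure block ---
    Vp, Vmax1, Km1, Synt, ka = pkv[0], pkv[1], pkv[2], pkv[3], pkv[4]
    if sc_route:
        if rate > 0.0:
            pump = rate * _erf_approx((t - pump_act) * pkv[5] / np.sqrt(pkv[6]))
        else:
            pump = 0.0
        out[0] = pump - ka * y[0]
        inp = ka * y[0]
    else:
        inp = rate
    Cp = y[1]
    Cpc = Cp if Cp > 0.0 else 0.0
    elim = Vmax1 * Cp / (Km1 + Cp)
    if two_cmt:
        Vt, Cld, Vmax2, Km2 = pkv[7], pkv[8], pkv[9], pkv[10]
        elim += Vmax2 * Cp / (Km2 + Cp)
        Ct = y[2]
        out[1] = (inp + Synt - elim - Cld * Cp + Cld * Ct) / Vp
        out[2] = (Cld * Cp - Cld * Ct) / Vt
        i0 = 3
    else:
        out[1] = (inp + Synt - elim) / Vp
        i0 = 2
    if level < 2:
        return out
    # --- insulin block ---
    kinI, kinRI, koutI, ktolI, I0 = insv[0], insv[1], insv[2], insv[3], insv[4]
    ImaxNI, IC50NI, n_hill = insv[5], insv[6], insv[7]
    ins_dyn = insv[8] > 0.5
    if ins_dyn:
        NI = y[i0 + 4]
        NIc = NI if NI > 0.0 else 0.0
        Ng = NIc ** insv[12]  # gamma
        E_i = ImaxNI * (1.0 - insv[11] * Ng / (insv[10] ** insv[12] + Ng))
    else:
        E_i = ImaxNI
    Cpn = Cpc ** n_hill
    H_i = 1.0 - E_i * Cpn / (IC50NI ** n_hill + Cpn)
    I, M1, M2, RI = y[i0], y[i0 + 1], y[i0 + 2], y[i0 + 3]
    out[i0] = kinI * RI * H_i * (I0 / M1) - koutI * (M2 / I0) * I
    out[i0 + 1] = ktolI * (I - M1)
    out[i0 + 2] = ktolI * (M1 - M2)
    out[i0 + 3] = kinRI - (kinRI / I0) * I  # koutRI = kinRI/I0 (set-point relation)
    n_ins = 4
    if ins_dyn:
        out[i0 + 4] = insv[9] * (Cp - NI)
        n_ins = 5
    if level < 3:
        return out
    # --- FFA block ---
    j0 = i0 + n_ins
    kinF, kinRF, koutF, ktolF, F0 = ffav[0], ffav[1], ffav[2], ffav[3], ffav[4]
    ImaxNF, IC50NF, m_hill = ffav[5], ffav[6], ffav[7]
    F, MF, RF, NF = y[j0], y[j0 + 1], y[j0 + 2], y[j0 + 3]
    NFc = NF if NF > 0.0 else 0.0
    Np = NFc ** ffav[11]  # phi
    E_f = ImaxNF * (1.0 - ffav[10] * Np / (ffav[9] ** ffav[11] + Np))
    Cpm = Cpc ** m_hill
    H_f = 1.0 - E_f * Cpm / (IC50NF ** m_hill + Cpm)
    out[j0] = kinF * RF * H_f * (F0 / MF) - koutF * F
    out[j0 + 1] = ktolF * (F - MF)
    out[j0 + 2] = kinRF - ffav[12] * I
    out[j0 + 3] = ffav[8] * (Cp - NF)
    return out


_DUMMY = np.ones(13)


def pk_param_vector(pk) -> np.ndarray:
    base = [pk.Vp, pk.Vmax1, pk.Km1, pk.Synt, pk.ka, pk.delta, pk.t0]
    if pk.two_compartment:
        base += [pk.Vt, pk.Cld, pk.Vmax2, pk.Km2]
    return np.array(base, dtype=float)


def insulin_param_vector(ins, kinI, kinRI) -> np.ndarray:
    dyn = ins.dynamic_efficacy
    return np.array([
        kinI, kinRI, ins.koutI, ins.ktolI, ins.I0,
        ins.ImaxNI, ins.IC50NI, ins.n,
        1.0 if dyn else 0.0,
        ins.kNI or 0.0, ins.N50I or 1.0,
        ins.SNI if ins.SNI is not None else 0.0,
        ins.gamma or 1.0,
    ], dtype=float)


def ffa_param_vector(ffa, kinF, kinRF) -> np.ndarray:
    return np.array([
        kinF, kinRF, ffa.koutF, ffa.ktolF, ffa.F0,
        ffa.ImaxNF, ffa.IC50NF, ffa.m, ffa.kNF, ffa.N50F, ffa.SNF, ffa.phi,
        ffa.koutRF,
    ], dtype=float)


def make_rhs(protocol, pkv, insv=None, ffav=None, two_cmt=False, level=1):
    """Bind a protocol and parameter vectors into a ``fun(t, y)`` RHS."""
    segs = protocol.segments
    seg_start = np.array([s[0] for s in segs] or [0.0])
    seg_end = np.array([s[1] for s in segs] or [0.0])
    seg_rate = np.array([s[2] for s in segs] or [0.0])
    sc = protocol.route == "sc_pump"
    act = protocol.pump_first_activation
    insv = _DUMMY if insv is None else insv
    ffav = _DUMMY if ffav is None else ffav

    def fun(t, y):
        return _sys_rhs(t, y, pkv, insv, ffav, two_cmt, sc, act,
                        seg_start, seg_end, seg_rate, level)

    return fun


def integrate_obs(fun, y0, edges, obs_times, rtol, atol, final_state=False):
    """Piecewise LSODA integration returning states at observation times.

    ``edges`` are the protocol discontinuities (sorted, spanning the full
    range); ``obs_times`` must lie within [edges[0], edges[-1]].
    """
    obs_times = np.asarray(obs_times, dtype=float)
    order = np.argsort(obs_times)
    t_sorted = obs_times[order]
    values = np.empty((obs_times.size, np.asarray(y0).size))
    y = np.asarray(y0, dtype=float)
    pos = 0
    for a, b in zip(edges[:-1], edges[1:]):
        hi = np.searchsorted(t_sorted, b, side="right" if b == edges[-1] else "left")
        t_eval = t_sorted[pos:hi]
        t_all = np.unique(np.concatenate([[a], t_eval, [b]]))
        sol = solve_ivp(fun, (a, b), y, method="LSODA", rtol=rtol, atol=atol,
                        t_eval=t_all)
        if not sol.success:
            raise FloatingPointError(f"fast integration failed on [{a}, {b}]: {sol.message}")
        for tt in t_eval:
            idx = np.searchsorted(sol.t, tt)
            values[pos] = sol.y[:, idx]
            pos += 1
        y = sol.y[:, -1]
    out = np.empty_like(values)
    out[order] = values
    return (out, y) if final_state else out
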
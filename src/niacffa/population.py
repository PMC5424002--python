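"""Nonlinear mixed-effects layer: FOCE likelihood, sequential fitting, VPC.

The population model puts log-normal between-subject variability on a
designated subset of parameters (absorption, elimination capacity and
synthesis for the exposure model; baseline, moderator turnover and
potency for insulin and FFA), optional fixed-study effects (group-wise
multipliers on baselines and moderator turnover), a proportional residual
error on NiAc and additive residual errors on insulin and FFA.

Estimation follows the sequential scheme: the exposure model is fitted
first; its empirical Bayes estimates (EBEs) are then frozen and act as
fixed individual covariates of the insulin fit, whose EBEs in turn drive
the FFA fit (operationally, the frozen upstream sub-models are
co-integrated with the stage being fitted).  The marginal likelihood of
each stage is approximated by FOCE with interaction: per subject the
random-effect mode is found by an inner Gauss-Newton optimization
(warm-started across objective evaluations) and the Laplace correction
uses the Gauss-Newton inner Hessian.  Outer gradients use the envelope
property of the inner optimum: finite differences are taken with the
modes and prediction Jacobians frozen, so each component costs one
trajectory per subject.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import _fastode as fast
from . import ffa as ffa_mod
from . import insulin as ins_mod
from . import pk as pk_mod
from .parameters import (
    FFAParameters,
    InsulinParameters,
    PKParameters,
    default_parameters,
    replace_fields,
)
from .protocols import DosingProtocol, build_protocol, zero_protocol

__all__ = [
    "PopulationModel",
    "ObservationTable",
    "FitResult",
    "default_population_model",
    "individual_nll",
    "foce_nll",
    "fit_sequential",
    "sensitivity_ranking",
    "vpc",
    "turnover_half_lives",
]

LOG2PI = math.log(2.0 * math.pi)

#: estimation-time solver tolerances (simulation defaults are tighter)
FIT_RTOL = 1e-6
FIT_ATOL = 1e-8

OBSERVABLES = ("NiAc", "insulin", "FFA")

STAGES = {
    "pk": {"observable": "NiAc", "error": "proportional", "sigma": "prop_NiAc"},
    "insulin": {"observable": "insulin", "error": "additive", "sigma": "add_insulin"},
    "ffa": {"observable": "FFA", "error": "additive", "sigma": "add_FFA"},
}

#: parameters with log-normal between-subject variability, per stage
ETA_PARAMS = {
    "pk": {"lean": ["ka", "Vmax1", "Synt"], "obese": ["ka", "Vmax1"]},
    "insulin": {"lean": ["I0", "ktolI", "IC50NI"], "obese": ["I0", "ktolI", "IC50NI"]},
    "ffa": {"lean": ["F0", "ktolF", "IC50NF"], "obese": ["F0", "ktolF", "IC50NF"]},
}

#: parameters constrained to (0, 1); everything else is positive (log scale)
_LOGIT_PARAMS = {"ImaxNI", "ImaxNF", "SNI", "SNF"}


# ---------------------------------------------------------------------------
# Containers.

class ObservationTable:
    """Long-format observations: id, group, species, observable, time_h, value, protocol."""

    REQUIRED = ["id", "group", "species", "observable", "time_h", "value", "protocol"]

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise ValueError(f"observation table missing column(s): {missing}")
        bad = set(frame["observable"]) - set(OBSERVABLES)
        if bad:
            raise ValueError(f"unknown observable(s): {sorted(bad)}")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "ObservationTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @property
    def subject_ids(self) -> List:
        return list(dict.fromkeys(self.frame["id"]))

    def subject(self, sid) -> pd.DataFrame:
        return self.frame[self.frame["id"] == sid]

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class PopulationModel:
    """Fixed effects + BSV + residual-error + fixed-study-effect structure.

    ``omega`` maps parameter names to log-scale standard deviations (the
    published BSV CV% equals ``100*omega``).  ``study_effects`` maps a
    parameter name to per-group multipliers on its median.
    """

    species: str
    pk: PKParameters
    insulin: InsulinParameters
    ffa: FFAParameters
    omega: Dict[str, float] = field(default_factory=dict)
    sigma: Dict[str, float] = field(default_factory=dict)
    study_effects: Dict[str, Dict[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        for name, om in self.omega.items():
            if om < 0:
                raise ValueError(f"omega[{name!r}] must be >= 0")

    def copy(self) -> "PopulationModel":
        return copy.deepcopy(self)

    def cv_percent(self) -> Dict[str, float]:
        """Between-subject variability in CV% (100*sqrt(omega^2))."""
        return {k: 100.0 * v for k, v in self.omega.items()}

    def _holder(self, name: str):
        for attr in ("pk", "insulin", "ffa"):
            params = getattr(self, attr)
            if hasattr(params, name):
                return attr, params
        raise KeyError(f"no parameter named {name!r}")

    def get_param(self, name: str) -> float:
        _, params = self._holder(name)
        return getattr(params, name)

    def set_param(self, name: str, value: float) -> None:
        attr, params = self._holder(name)
        setattr(self, attr, replace_fields(params, **{name: value}))

    def individual_parameters(self, eta: Dict[str, float], group: Optional[str] = None):
        """Apply study-effect multipliers and exp(eta) perturbations."""
        updates: Dict[str, Dict[str, float]] = {"pk": {}, "insulin": {}, "ffa": {}}
        names = set(eta) | set(self.study_effects)
        for name in names:
            attr, params = self._holder(name)
            value = getattr(params, name)
            if group is not None and name in self.study_effects:
                value = value * self.study_effects[name].get(group, 1.0)
            value = value * math.exp(eta.get(name, 0.0))
            updates[attr][name] = value
        pk = replace_fields(self.pk, **updates["pk"]) if updates["pk"] else self.pk
        ins = replace_fields(self.insulin, **updates["insulin"]) if updates["insulin"] else self.insulin
        ffa = replace_fields(self.ffa, **updates["ffa"]) if updates["ffa"] else self.ffa
        return pk, ins, ffa


_DEFAULT_OMEGA = {
    "lean": {"ka": 0.801, "Vmax1": 0.935, "Synt": 0.667,
             "I0": 0.493, "ktolI": 0.939, "IC50NI": 1.11,
             "F0": 0.178, "ktolF": 0.584, "IC50NF": 0.418},
    "obese": {"ka": 0.802, "Vmax1": 0.224,
              "I0": 0.103, "ktolI": 3.10, "IC50NI": 1.90,
              "F0": 0.00874, "ktolF": 0.342, "IC50NF": 0.418},
}

_DEFAULT_SIGMA = {
    "lean": {"prop_NiAc": 0.313, "add_insulin": 0.0699, "add_FFA": 0.130},
    "obese": {"prop_NiAc": 0.483, "add_insulin": 0.748, "add_FFA": 0.135},
}


def default_population_model(species: str) -> PopulationModel:
    """Published median fixed effects with the published BSV and sigmas."""
    pk, ins, ffa = default_parameters(species)
    return PopulationModel(
        species=species, pk=pk, insulin=ins, ffa=ffa,
        omega=dict(_DEFAULT_OMEGA[species]),
        sigma=dict(_DEFAULT_SIGMA[species]),
    )


@dataclass
class FitResult:
    """Point estimates, EBEs, objective and (optional) standard errors."""

    estimates: Dict[str, float]
    objective: float
    ebes: Dict[str, Dict]
    stage_objectives: Dict[str, float]
    converged: bool
    rse_percent: Dict[str, float] = field(default_factory=dict)
    bsv_cv_percent: Dict[str, float] = field(default_factory=dict)
    message: str = ""
    model: Optional[PopulationModel] = None
    n_subjects: int = 0

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates,
            "rse_percent": self.rse_percent,
            "bsv_cv_percent": self.bsv_cv_percent,
            "objective": self.objective,
            "stage_objectives": self.stage_objectives,
            "converged": self.converged,
            "message": self.message,
            "n_subjects": self.n_subjects,
            "ebes": self.ebes,
        }


# ---------------------------------------------------------------------------
# Protocol lookup and per-subject prediction machinery.

def _resolve_protocol(label: str, species: str) -> DosingProtocol:
    if label in ("control", "none", "vehicle"):
        return zero_protocol(8.0)
    if label.startswith("control:"):
        base = build_protocol(label.split(":", 1)[1], species)
        return DosingProtocol(route=base.route, segments=(),
                              pretreatment_duration=base.pretreatment_duration,
                              acute_window=base.acute_window, name=label)
    return build_protocol(label, species)


class _Subject:
    def __init__(self, sid, group, species, protocol_label, obs: pd.DataFrame):
        self.id = sid
        self.group = group
        self.species = species
        self.protocol = _resolve_protocol(protocol_label, species)
        self.obs = {
            name: (part["time_h"].to_numpy(float), part["value"].to_numpy(float))
            for name, part in obs.groupby("observable")
        }
        self.is_dosed = self.protocol.total_programmed_amount() > 0
        # frozen upstream sub-models, filled in as stages complete
        self.Cp0: Optional[float] = None
        self.pk_frozen: Optional[PKParameters] = None
        self.pk_vec: Optional[np.ndarray] = None
        self.ins_frozen: Optional[InsulinParameters] = None
        self.ins_vec: Optional[np.ndarray] = None

    def has(self, observable: str) -> bool:
        return observable in self.obs and self.obs[observable][0].size > 0

    def edges(self, times: np.ndarray) -> np.ndarray:
        t0 = min(self.protocol.start, float(np.min(times)))
        t1 = max(float(np.max(times)), t0)
        pts = [t0, t1] + [float(b) for b in self.protocol.boundaries() if t0 < b < t1]
        return np.unique(np.array(pts))


def _build_subjects(dataset: ObservationTable) -> List["_Subject"]:
    subjects = []
    for sid, part in dataset.frame.groupby("id", sort=False):
        subjects.append(_Subject(sid, part["group"].iloc[0], part["species"].iloc[0],
                                 part["protocol"].iloc[0], part))
    return subjects


def _fast_predict_niac(pk_params, subject, times, rtol=FIT_RTOL, atol=FIT_ATOL):
    times = np.asarray(times, float)
    Cp0 = pk_mod.baseline_concentration(pk_params)
    if not subject.is_dosed:
        return np.full(times.size, Cp0)
    fun = fast.make_rhs(subject.protocol, fast.pk_param_vector(pk_params),
                        two_cmt=pk_params.two_compartment, level=1)
    vals = fast.integrate_obs(fun, pk_mod.pk_initial_state(pk_params),
                              subject.edges(times), times, rtol, atol)
    return vals[:, 1]


def _fast_predict_insulin(ins_params, subject, times, rtol=FIT_RTOL, atol=FIT_ATOL):
    times = np.asarray(times, float)
    if not subject.is_dosed:
        return np.full(times.size, ins_params.I0)
    Cp0 = subject.Cp0
    kinI, kinRI = ins_mod.derive_insulin_baseline_rates(ins_params, Cp0)
    insv = fast.insulin_param_vector(ins_params, kinI, kinRI)
    y0 = np.concatenate([pk_mod.pk_initial_state(subject.pk_frozen),
                         ins_mod.insulin_initial_state(ins_params, Cp0)])
    fun = fast.make_rhs(subject.protocol, subject.pk_vec, insv,
                        two_cmt=subject.pk_frozen.two_compartment, level=2)
    vals = fast.integrate_obs(fun, y0, subject.edges(times), times, rtol, atol)
    i_idx = 3 if subject.pk_frozen.two_compartment else 2
    return vals[:, i_idx]


def _fast_predict_ffa(ffa_params, subject, times, rtol=FIT_RTOL, atol=FIT_ATOL):
    times = np.asarray(times, float)
    if not subject.is_dosed:
        return np.full(times.size, ffa_params.F0)
    Cp0 = subject.Cp0
    ins_params = subject.ins_frozen
    kinF, kinRF = ffa_mod.derive_ffa_baseline_rates(ffa_params, ins_params, Cp0)
    ffav = fast.ffa_param_vector(ffa_params, kinF, kinRF)
    y0 = np.concatenate([pk_mod.pk_initial_state(subject.pk_frozen),
                         ins_mod.insulin_initial_state(ins_params, Cp0),
                         ffa_mod.ffa_initial_state(ffa_params, Cp0)])
    fun = fast.make_rhs(subject.protocol, subject.pk_vec, subject.ins_vec, ffav,
                        two_cmt=subject.pk_frozen.two_compartment, level=3)
    vals = fast.integrate_obs(fun, y0, subject.edges(times), times, rtol, atol)
    n_pk = 3 if subject.pk_frozen.two_compartment else 2
    n_ins = 5 if ins_params.dynamic_efficacy else 4
    return vals[:, n_pk + n_ins]


def _freeze_context(subjects, model, ebes_by_stage, upto="ffa"):
    """Fix every subject's upstream sub-models from the given EBEs.

    Subjects without exposure observations keep zero random effects and
    therefore follow the estimated median individual's exposure,
    mirroring how the chronic group without NiAc samples was handled.
    """
    pk_ebes = ebes_by_stage.get("pk", {})
    ins_ebes = ebes_by_stage.get("insulin", {})
    for s in subjects:
        pk_p, _, _ = model.individual_parameters(pk_ebes.get(s.id, {}), s.group)
        s.pk_frozen = pk_p
        s.pk_vec = fast.pk_param_vector(pk_p)
        s.Cp0 = pk_mod.baseline_concentration(pk_p)
        if upto == "ffa":
            _, ins_p, _ = model.individual_parameters(ins_ebes.get(s.id, {}), s.group)
            kinI, kinRI = ins_mod.derive_insulin_baseline_rates(ins_p, s.Cp0)
            s.ins_frozen = ins_p
            s.ins_vec = fast.insulin_param_vector(ins_p, kinI, kinRI)


# ---------------------------------------------------------------------------
# Gaussian likelihood pieces.

def _gaussian_nll(y, pred, kind, sigma):
    """Exact Gaussian NLL; proportional errors scale with the prediction."""
    pred = np.asarray(pred, dtype=float)
    if not np.all(np.isfinite(pred)):
        raise FloatingPointError("non-finite model prediction in likelihood")
    if kind == "proportional":
        sd = np.maximum(sigma * np.abs(pred), 1e-12)
    else:
        sd = np.full_like(pred, max(sigma, 1e-12))
    resid = (np.asarray(y, dtype=float) - pred) / sd
    return float(0.5 * np.sum(resid ** 2) + np.sum(np.log(sd)) + 0.5 * resid.size * LOG2PI)


def individual_nll(obs, params, protocol, sigma: Dict[str, float],
                   rtol=FIT_RTOL, atol=FIT_ATOL) -> float:
    """Exact Gaussian NLL of one subject's observations given its parameters.

    ``params`` is the (pk, insulin, ffa) triple; every observable present
    in ``obs`` contributes (proportional error for NiAc, additive for
    insulin and FFA).  ``protocol`` may be a name or a DosingProtocol.
    """
    pk_params, ins_params, ffa_params = params
    species = pk_params.species
    frame = obs if isinstance(obs, pd.DataFrame) else obs.frame
    subject = _Subject(frame["id"].iloc[0] if "id" in frame else 0,
                       frame["group"].iloc[0] if "group" in frame else "g",
                       species,
                       protocol if isinstance(protocol, str) else "Off_1h",
                       frame)
    if isinstance(protocol, DosingProtocol):
        subject.protocol = protocol
        subject.is_dosed = protocol.total_programmed_amount() > 0
    Cp0 = pk_mod.baseline_concentration(pk_params)
    all_times = np.unique(np.concatenate([t for t, _ in subject.obs.values()]))
    if subject.is_dosed:
        kinI, kinRI = ins_mod.derive_insulin_baseline_rates(ins_params, Cp0)
        kinF, kinRF = ffa_mod.derive_ffa_baseline_rates(ffa_params, ins_params, Cp0)
        y0 = np.concatenate([pk_mod.pk_initial_state(pk_params),
                             ins_mod.insulin_initial_state(ins_params, Cp0),
                             ffa_mod.ffa_initial_state(ffa_params, Cp0)])
        fun = fast.make_rhs(subject.protocol, fast.pk_param_vector(pk_params),
                            fast.insulin_param_vector(ins_params, kinI, kinRI),
                            fast.ffa_param_vector(ffa_params, kinF, kinRF),
                            two_cmt=pk_params.two_compartment, level=3)
        vals = fast.integrate_obs(fun, y0, subject.edges(all_times), all_times, rtol, atol)
    else:
        n_ins = 5 if ins_params.dynamic_efficacy else 4
        n_pk = 3 if pk_params.two_compartment else 2
        base = np.concatenate([pk_mod.pk_initial_state(pk_params),
                               ins_mod.insulin_initial_state(ins_params, Cp0),
                               ffa_mod.ffa_initial_state(ffa_params, Cp0)])
        vals = np.tile(base, (all_times.size, 1))
    n_pk = 3 if pk_params.two_compartment else 2
    n_ins = 5 if ins_params.dynamic_efficacy else 4
    col = {"NiAc": 1, "insulin": n_pk, "FFA": n_pk + n_ins}
    err = {"NiAc": ("proportional", sigma["prop_NiAc"]),
           "insulin": ("additive", sigma["add_insulin"]),
           "FFA": ("additive", sigma["add_FFA"])}
    total = 0.0
    for name, (t, y) in subject.obs.items():
        idx = np.searchsorted(all_times, t)
        kind, sig = err[name]
        total += _gaussian_nll(y, vals[idx, col[name]], kind, sig)
    return total


# ---------------------------------------------------------------------------
# FOCE machinery.

class _StageProblem:
    """One stage's FOCE objective over a dataset with frozen upstream EBEs."""

    def __init__(self, stage: str, subjects: List["_Subject"], popmodel: PopulationModel,
                 rtol=FIT_RTOL, atol=FIT_ATOL):
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        self.stage = stage
        self.cfg = STAGES[stage]
        self.rtol, self.atol = rtol, atol
        observable = self.cfg["observable"]
        self.subjects = [s for s in subjects if s.has(observable)]
        self.eta_names = [n for n in ETA_PARAMS[stage][popmodel.species]
                          if popmodel.omega.get(n, 0.0) > 1e-12]
        self.warm: Dict = {}
        self.frozen: Dict = {}  # subject id -> (eta_hat, J) for envelope gradients

    def predict(self, model: PopulationModel, subject: "_Subject", eta_vec) -> np.ndarray:
        times = subject.obs[self.cfg["observable"]][0]
        eta = dict(zip(self.eta_names, np.atleast_1d(np.asarray(eta_vec, float)))) \
            if len(self.eta_names) else {}
        pk_p, ins_p, ffa_p = model.individual_parameters(eta, subject.group)
        if self.stage == "pk":
            return _fast_predict_niac(pk_p, subject, times, self.rtol, self.atol)
        if self.stage == "insulin":
            return _fast_predict_insulin(ins_p, subject, times, self.rtol, self.atol)
        return _fast_predict_ffa(ffa_p, subject, times, self.rtol, self.atol)

    # -- pieces ---------------------------------------------------------------

    def _sd(self, pred, sigma):
        if self.cfg["error"] == "proportional":
            return np.maximum(sigma * np.abs(pred), 1e-12)
        return np.full_like(np.asarray(pred, float), max(sigma, 1e-12))

    def _laplace(self, g, J, sd, om2):
        H = (J / sd[:, None]).T @ (J / sd[:, None]) + np.diag(1.0 / om2)
        sign, logdet = np.linalg.slogdet(H)
        if sign <= 0:
            raise FloatingPointError("non-positive-definite inner Hessian")
        return g - 0.5 * len(om2) * LOG2PI + 0.5 * logdet, H

    def _inner_fit(self, model, subject):
        """Posterior-mode eta by damped Gauss-Newton with warm starts."""
        times, y = subject.obs[self.cfg["observable"]]
        kind = self.cfg["error"]
        sigma = model.sigma[self.cfg["sigma"]]
        d = len(self.eta_names)
        om2 = np.array([model.omega[n] ** 2 for n in self.eta_names])
        prior_const = 0.5 * float(np.sum(np.log(2.0 * np.pi * om2)))

        def g_of(pred, eta):
            return _gaussian_nll(y, pred, kind, sigma) \
                + 0.5 * float(np.sum(eta ** 2 / om2)) + prior_const

        def try_predict(eta_vec):
            try:
                return self.predict(model, subject, eta_vec)
            except (FloatingPointError, ValueError, RuntimeError):
                return None

        eta = np.asarray(self.warm.get(subject.id, np.zeros(d)), float).copy()
        pred = try_predict(eta)
        if pred is None and np.any(eta != 0.0):
            eta = np.zeros(d)  # stale warm start; retry from the prior mode
            pred = try_predict(eta)
        if pred is None:
            raise FloatingPointError(f"model unevaluable for subject {subject.id}")
        g = g_of(pred, eta)
        J = np.zeros((pred.size, d))
        step = 1e-4
        lam = 0.0  # Levenberg-Marquardt damping, raised when GN steps fail
        for _ in range(60):
            for j in range(d):
                up = eta.copy()
                up[j] += step
                pred_j = try_predict(up)
                if pred_j is None:
                    raise FloatingPointError(f"Jacobian unevaluable for subject {subject.id}")
                J[:, j] = (pred_j - pred) / step
            sd = self._sd(pred, sigma)
            dsd = sigma * np.sign(pred) if kind == "proportional" else np.zeros_like(pred)
            r = y - pred
            dnll_df = -r / sd ** 2 + (1.0 - (r / sd) ** 2) * dsd / sd
            grad = J.T @ dnll_df + eta / om2
            # the envelope-gradient outer scheme requires a sharp mode
            if float(np.max(np.abs(grad))) < 1e-5:
                break
            H = (J / sd[:, None]).T @ (J / sd[:, None]) + np.diag(1.0 / om2)
            improved = False
            for _damp in range(8):
                try:
                    delta = -np.linalg.solve(H + lam * np.diag(np.diag(H)), grad)
                except np.linalg.LinAlgError:
                    raise FloatingPointError(f"singular inner Hessian for subject {subject.id}")
                if not np.all(np.isfinite(delta)):
                    raise FloatingPointError(f"inner step diverged for subject {subject.id}")
                alpha = 1.0
                for _ls in range(4):
                    trial = eta + alpha * delta
                    pred_t = try_predict(trial)
                    g_t = g_of(pred_t, trial) if pred_t is not None else np.inf
                    if g_t <= g - 1e-13:
                        eta, pred, g = trial, pred_t, g_t
                        improved = True
                        break
                    alpha *= 0.25
                if improved:
                    lam = max(lam / 4.0, 0.0)
                    break
                lam = 10.0 * lam if lam > 0 else 1e-3
            if not improved:
                break  # no descent even fully damped: numerically at the mode
        self.warm[subject.id] = eta.copy()
        return eta, pred, g, J

    def subject_nll(self, model: PopulationModel, subject: "_Subject",
                    return_eta: bool = False):
        d = len(self.eta_names)
        sigma = model.sigma[self.cfg["sigma"]]
        if d == 0:
            times, y = subject.obs[self.cfg["observable"]]
            pred = self.predict(model, subject, np.zeros(0))
            val = _gaussian_nll(y, pred, self.cfg["error"], sigma)
            self.frozen[subject.id] = (np.zeros(0), np.zeros((pred.size, 0)), pred)
            return (val, np.zeros(0)) if return_eta else val
        eta_hat, pred, g, J = self._inner_fit(model, subject)
        om2 = np.array([model.omega[n] ** 2 for n in self.eta_names])
        nll, _ = self._laplace(g, J, self._sd(pred, sigma), om2)
        self.frozen[subject.id] = (eta_hat, J, pred)
        return (nll, eta_hat) if return_eta else nll

    def _frozen_from_pred(self, subject, pred, sigma, om2) -> float:
        """Laplace NLL at the frozen mode/Jacobian for a given prediction."""
        _, y = subject.obs[self.cfg["observable"]]
        eta_hat, J, _ = self.frozen[subject.id]
        val = _gaussian_nll(y, pred, self.cfg["error"], sigma)
        if eta_hat.size == 0:
            return val
        g = val + 0.5 * float(np.sum(eta_hat ** 2 / om2)) \
            + 0.5 * float(np.sum(np.log(2.0 * np.pi * om2)))
        nll, _ = self._laplace(g, J, self._sd(pred, sigma), om2)
        return nll

    def subject_nll_frozen(self, model: PopulationModel, subject: "_Subject") -> float:
        """Laplace NLL with the inner mode and Jacobian frozen (envelope)."""
        sigma = model.sigma[self.cfg["sigma"]]
        eta_hat, _, _ = self.frozen[subject.id]
        om2 = np.array([model.omega[n] ** 2 for n in self.eta_names]) \
            if eta_hat.size else np.zeros(0)
        pred = self.predict(model, subject, eta_hat)
        return self._frozen_from_pred(subject, pred, sigma, om2)

    def linearize(self, model: PopulationModel, theta_packs, theta_step: float = 0.05):
        """Secant linearization of every subject's prediction in the
        transformed fixed effects.

        Must follow a full :meth:`nll` refresh (which stores each mode and
        base prediction).  ``theta_packs`` is a list of ``(name, fwd,
        inv)`` transform triples.  Returns per-subject prediction
        Jacobians with one column per free fixed effect; the local
        surrogate ``pred0 + J_theta @ dx_theta`` then makes the
        trust-region subproblem pure linear algebra (no ODE solves).
        """
        out = {subject.id: np.zeros((self.frozen[subject.id][2].size, len(theta_packs)))
               for subject in self.subjects}
        trial = model.copy()
        for j, (name, fwd, inv) in enumerate(theta_packs):
            base_value = model.get_param(name)
            trial.set_param(name, inv(fwd(base_value) + theta_step))
            for subject in self.subjects:
                eta_hat, _, pred0 = self.frozen[subject.id]
                try:
                    pred_j = self.predict(trial, subject, eta_hat)
                except (FloatingPointError, ValueError, RuntimeError):
                    pred_j = pred0
                out[subject.id][:, j] = (pred_j - pred0) / theta_step
            trial.set_param(name, base_value)
        return out

    def nll(self, model: PopulationModel, skip_failures: bool = False,
            frozen: bool = False) -> float:
        total = 0.0
        for subject in self.subjects:
            try:
                if frozen:
                    total += self.subject_nll_frozen(model, subject)
                else:
                    total += self.subject_nll(model, subject)
            except (FloatingPointError, ValueError, RuntimeError, np.linalg.LinAlgError):
                if not skip_failures:
                    raise
                total += 1e6
        return total

    def ebes(self, model: PopulationModel) -> Dict:
        out = {}
        for subject in self.subjects:
            _, eta = self.subject_nll(model, subject, return_eta=True)
            out[subject.id] = dict(zip(self.eta_names, (float(v) for v in eta)))
        return out


def foce_nll(dataset: ObservationTable, popmodel: PopulationModel, stage: str,
             rtol=FIT_RTOL, atol=FIT_ATOL, skip_failures: bool = False,
             _subjects=None) -> float:
    """FOCE(-interaction) approximate population NLL for one stage.

    Upstream sub-models are fixed at the population values with zero
    random effects unless pre-frozen subjects are supplied by
    :func:`fit_sequential`.
    """
    if _subjects is None:
        _subjects = _build_subjects(dataset)
        _freeze_context(_subjects, popmodel, {}, upto=stage)
    problem = _StageProblem(stage, _subjects, popmodel, rtol, atol)
    return problem.nll(popmodel, skip_failures=skip_failures)


# ---------------------------------------------------------------------------
# Sequential fitting.

def _transform(name):
    if name in _LOGIT_PARAMS:
        return (lambda v: math.log(v / (1.0 - v)), lambda x: 1.0 / (1.0 + math.exp(-x)))
    return (math.log, math.exp)


DEFAULT_FREE = {
    "pk": {
        "lean": ["ka", "delta", "Vmax1"],
        "obese": ["ka", "delta", "Vmax1"],
    },
    "insulin": {
        "lean": ["I0", "koutI", "ImaxNI", "IC50NI", "n", "ktolI", "koutRI"],
        "obese": ["I0", "koutI", "IC50NI", "n", "ktolI", "koutRI", "kNI", "N50I", "gamma"],
    },
    "ffa": {
        "lean": ["F0", "koutF", "IC50NF", "m", "ktolF", "koutRF", "kNF", "N50F", "SNF"],
        "obese": ["F0", "koutF", "IC50NF", "m", "ktolF", "koutRF", "kNF", "N50F", "phi"],
    },
}


def fit_sequential(
    dataset: ObservationTable,
    init: PopulationModel,
    stages: Sequence[str] = ("pk", "insulin", "ffa"),
    free: Optional[Dict[str, Dict[str, List[str]]]] = None,
    maxiter: int = 40,
    compute_se: bool = False,
    rtol: float = FIT_RTOL,
    atol: float = FIT_ATOL,
    verbose: bool = False,
) -> FitResult:
    """Maximize the FOCE likelihood stage by stage (PK -> insulin -> FFA).

    After each stage converges, the subjects' random effects are frozen
    at their EBEs and enter the next stage as fixed individual
    sub-models.  Fixed effects are optimized on log (logit for
    efficacies) scale; the stage's omegas and residual sigma are
    estimated on log scale alongside.  The optimizer alternates
    mode-refresh cycles with trust-region minimization of the
    frozen-mode objective (see :func:`_trust_region_em`); ``maxiter``
    caps the number of refresh cycles.

    ``free`` optionally restricts the free quantities per stage, e.g.
    ``{"pk": {"theta": ["ka"], "omega": ["ka"], "sigma": ["prop_NiAc"]}}``;
    by default every parameter the original analysis estimated is free.

    With ``compute_se=True`` standard errors come from a central
    finite-difference Hessian of the objective at the optimum, mapped to
    the natural scale by the delta method; RSE% = 100*SE/estimate.
    """
    model = init.copy()
    subjects = _build_subjects(dataset)
    ebes_by_stage: Dict[str, Dict] = {}
    estimates: Dict[str, float] = {}
    rse: Dict[str, float] = {}
    stage_obj: Dict[str, float] = {}
    converged = True
    messages = []
    eps = 1e-4

    for stage in stages:
        spec = (free or {}).get(stage) or {}
        theta_names = spec.get("theta", DEFAULT_FREE[stage][model.species])
        omega_names = spec.get(
            "omega", [n for n in ETA_PARAMS[stage][model.species] if n in model.omega])
        sigma_names = spec.get("sigma", [STAGES[stage]["sigma"]])

        _freeze_context(subjects, model, ebes_by_stage, upto=stage)
        problem = _StageProblem(stage, subjects, model, rtol, atol)

        packs = []  # (kind, name, fwd, inv)
        x0 = []
        for name in theta_names:
            fwd, inv = _transform(name)
            packs.append(("theta", name, fwd, inv))
            x0.append(fwd(model.get_param(name)))
        for name in omega_names:
            packs.append(("omega", name, math.log, math.exp))
            x0.append(math.log(max(model.omega[name], 1e-6)))
        for name in sigma_names:
            packs.append(("sigma", name, math.log, math.exp))
            x0.append(math.log(model.sigma[name]))
        x0 = np.array(x0)

        def apply(x, m):
            for (kind, name, fwd, inv), xi in zip(packs, x):
                if kind == "theta":
                    m.set_param(name, inv(xi))
                elif kind == "omega":
                    m.omega[name] = inv(xi)
                else:
                    m.sigma[name] = inv(xi)

        trial = model.copy()

        def objective(x, frozen=False):
            apply(x, trial)
            try:
                return problem.nll(trial, skip_failures=True, frozen=frozen)
            except (FloatingPointError, RuntimeError, ValueError):
                return 1e7

        theta_packs = [(name, fwd, inv) for kind, name, fwd, inv in packs
                       if kind == "theta"]
        theta_idx = np.array([i for i, p in enumerate(packs) if p[0] == "theta"],
                             dtype=int)
        omega_pos = {name: i for i, (kind, name, _, _) in enumerate(packs)
                     if kind == "omega"}
        sigma_pos = [i for i, p in enumerate(packs) if p[0] == "sigma"]
        stage_sigma = STAGES[stage]["sigma"]

        def make_local(x):
            """Quadratic-in-data local surrogate around x (frozen modes,
            linearized predictions); exact in the omega/sigma directions."""
            apply(x, trial)
            lin = problem.linearize(trial, theta_packs)
            x_theta0 = x[theta_idx]
            fixed_om = {n: trial.omega[n] for n in problem.eta_names}

            def local(z):
                dtheta = z[theta_idx] - x_theta0
                sigma_val = math.exp(z[sigma_pos[0]]) if sigma_pos \
                    else trial.sigma[stage_sigma]
                om2 = np.array([
                    (math.exp(z[omega_pos[n]]) if n in omega_pos else fixed_om[n]) ** 2
                    for n in problem.eta_names])
                total = 0.0
                for subject in problem.subjects:
                    pred0 = problem.frozen[subject.id][2]
                    pred = pred0 + lin[subject.id] @ dtheta
                    try:
                        total += problem._frozen_from_pred(subject, pred, sigma_val, om2)
                    except (FloatingPointError, np.linalg.LinAlgError):
                        total += 1e6
                return total

            return local

        x_opt, f_opt, n_cycles, stage_converged = _trust_region_em(
            objective, make_local, x0, max_cycles=maxiter, verbose=verbose,
            label=stage)
        apply(x_opt, model)
        stage_obj[stage] = float(f_opt)
        converged = converged and stage_converged
        messages.append(f"{stage}: {'converged' if stage_converged else 'cycle cap'} "
                        f"({n_cycles} refresh cycles)")
        if verbose:
            print(f"[{stage}] obj={f_opt:.3f} cycles={n_cycles} converged={stage_converged}",
                  flush=True)

        ebes_by_stage[stage] = problem.ebes(model)

        for kind, name, _, inv in packs:
            if kind == "theta":
                estimates[name] = model.get_param(name)
            elif kind == "omega":
                estimates[f"omega_{name}"] = model.omega[name]
            else:
                estimates[f"sigma_{name}"] = model.sigma[name]

        if compute_se:
            rse.update(_hessian_rse(objective, x_opt, packs))

    return FitResult(
        estimates=estimates,
        objective=float(sum(stage_obj.values())),
        ebes=ebes_by_stage,
        stage_objectives=stage_obj,
        converged=converged,
        rse_percent=rse,
        bsv_cv_percent=model.cv_percent(),
        message="; ".join(messages),
        model=model,
        n_subjects=len(subjects),
    )


def _trust_region_em(objective, make_local, x0, max_cycles=40, r0=0.3, r_max=0.6,
                     xtol=5e-3, verbose=False, label=""):
    """Alternate mode refreshes with trust-region moves on a local surrogate.

    The exact FOCE objective carries small evaluation noise from the
    warm-started inner optimizations (flat random-effect posteriors make
    the located mode path-dependent at the 0.01-0.1 level), which ruins
    finite differences taken directly on it.  Instead, each cycle (i)
    refreshes every subject's mode, prediction and Jacobians at the
    current fixed effects and (ii) minimizes a smooth deterministic local
    surrogate - the Laplace objective with modes frozen and predictions
    linearized in the transformed fixed effects, exact in the omega and
    sigma directions - within an adaptive trust region, accepting the
    move only if the exact objective improves.  At a fixed point the
    surrogate's gradient vanishes, which by the envelope property of the
    inner optimum is FOCE stationarity.
    """
    x = np.asarray(x0, float).copy()
    f = objective(x)  # refreshes modes/Jacobians at x
    r = r0
    cycles = 0
    for cycles in range(1, max_cycles + 1):
        local = make_local(x)
        bounds = [(xi - r, xi + r) for xi in x]
        res = minimize(local, x, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 80, "ftol": 1e-12, "gtol": 1e-8,
                                "eps": 1e-6})
        x_new = res.x
        step = float(np.max(np.abs(x_new - x)))
        f_new = objective(x_new)  # exact, refreshes modes at the candidate
        if verbose:
            print(f"  [{label}] cycle {cycles}: f={min(f, f_new):.4f} "
                  f"step={step:.4f} r={r:.3f}", flush=True)
        if f_new < f:
            x, f = x_new, f_new
            if step < xtol:
                return x, f, cycles, True
            if step > 0.9 * r:
                r = min(2.0 * r, r_max)
        else:
            if step < xtol:  # rejected a sub-tolerance move: at the noise floor
                return x, f, cycles, True
            r *= 0.25
            if r < 1e-3:
                return x, f, cycles, True
    return x, f, cycles, False


def _hessian_rse(objective, x_opt, packs, step: float = 1e-3) -> Dict[str, float]:
    """RSE% from a central finite-difference Hessian on the transformed scale."""
    p = x_opt.size
    H = np.empty((p, p))
    f0 = objective(x_opt)
    for i in range(p):
        ei = np.zeros(p); ei[i] = step
        H[i, i] = (objective(x_opt + ei) - 2 * f0 + objective(x_opt - ei)) / step ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p); ej[j] = step
            fpp = objective(x_opt + ei + ej)
            fpm = objective(x_opt + ei - ej)
            fmp = objective(x_opt - ei + ej)
            fmm = objective(x_opt - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * step ** 2)
    try:
        cov = np.linalg.inv(H)
        se_t = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        return {}
    out = {}
    for (kind, name, _, inv), xi, se in zip(packs, x_opt, se_t):
        label = name if kind == "theta" else f"{kind}_{name}"
        value = inv(xi)
        deriv = value * (1 - value) if (kind == "theta" and name in _LOGIT_PARAMS) else value
        if value != 0:
            out[label] = 100.0 * abs(se * deriv / value)
    return out


# ---------------------------------------------------------------------------
# Sensitivity ranking, VPC, half-lives.

def sensitivity_ranking(
    popmodel: PopulationModel,
    protocol,
    candidates: Sequence[str],
    observable: str = "FFA",
    t_grid: Optional[np.ndarray] = None,
    rel_step: float = 1e-3,
    rtol: float = FIT_RTOL,
    atol: float = FIT_ATOL,
) -> pd.DataFrame:
    """Rank parameters by integrated output sensitivity at the medians.

    For each candidate the central-difference derivative of the output
    with respect to the log parameter (so scores are comparable across
    parameter magnitudes), normalized by the observable's baseline scale,
    is averaged over the observation grid.  The relative normalization
    makes the ranking invariant to rescaling the output.  Parameters with
    the highest scores are the natural carriers of between-subject
    variability.
    """
    from .simulate import simulate_individual

    if isinstance(protocol, str):
        protocol = _resolve_protocol(protocol, popmodel.species)
    if t_grid is None:
        t_grid = np.linspace(protocol.acute_window[0], protocol.acute_window[1], 40)
    col = {"NiAc": "Cp", "insulin": "I", "FFA": "F"}[observable]
    scale = {"NiAc": pk_mod.baseline_concentration(popmodel.pk),
             "insulin": popmodel.insulin.I0, "FFA": popmodel.ffa.F0}[observable]

    def output(model):
        traj = simulate_individual(protocol, model.pk, model.insulin, model.ffa,
                                   t_grid=t_grid, mode="coupled",
                                   rtol=rtol, atol=atol, with_actions=False)
        return traj[col]

    rows = []
    for name in candidates:
        value = popmodel.get_param(name)
        up, dn = popmodel.copy(), popmodel.copy()
        dn.set_param(name, value * (1 - rel_step))
        try:
            up.set_param(name, value * (1 + rel_step))
            dy = (output(up) - output(dn)) / (2 * rel_step)  # d y / d log p
        except ValueError:  # parameter sits on a bound; one-sided difference
            up.set_param(name, value)
            dy = (output(up) - output(dn)) / rel_step
        rows.append({"parameter": name, "sensitivity": float(np.mean(np.abs(dy)) / scale)})
    frame = pd.DataFrame(rows).sort_values("sensitivity", ascending=False, ignore_index=True)
    frame["rank"] = np.arange(1, len(frame) + 1)
    return frame


def vpc(
    popmodel: PopulationModel,
    protocol,
    n_sim: int = 500,
    seed: int = 0,
    observable: str = "FFA",
    times: Optional[np.ndarray] = None,
    group: Optional[str] = None,
    quantiles: Tuple[float, float, float] = (5.0, 50.0, 95.0),
    rtol: float = FIT_RTOL,
    atol: float = FIT_ATOL,
) -> pd.DataFrame:
    """Monte-Carlo visual-predictive-check bands (default the 90% interval).

    Simulates ``n_sim`` virtual subjects with between-subject variability,
    study effects and residual error, and returns the requested
    percentiles of the simulated observations per time point.
    """
    from .simulate import simulate_individual

    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if isinstance(protocol, str):
        protocol = _resolve_protocol(protocol, popmodel.species)
    if times is None:
        times = np.linspace(protocol.acute_window[0], protocol.acute_window[1], 30)
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    col = {"NiAc": "Cp", "insulin": "I", "FFA": "F"}[observable]
    sigma_key = {"NiAc": "prop_NiAc", "insulin": "add_insulin", "FFA": "add_FFA"}[observable]
    sims = np.empty((n_sim, times.size))
    eta_names = [n for n, om in popmodel.omega.items() if om > 0]
    for i in range(n_sim):
        eta = {n: rng.normal(0.0, popmodel.omega[n]) for n in eta_names}
        pk_p, ins_p, ffa_p = popmodel.individual_parameters(eta, group)
        traj = simulate_individual(protocol, pk_p, ins_p, ffa_p, t_grid=times,
                                   mode="coupled", rtol=rtol, atol=atol,
                                   with_actions=False)
        pred = traj[col]
        sigma = popmodel.sigma[sigma_key]
        if observable == "NiAc":
            sims[i] = pred * (1.0 + rng.normal(0.0, sigma, size=pred.size))
        else:
            sims[i] = pred + rng.normal(0.0, sigma, size=pred.size)
    bands = np.percentile(sims, quantiles, axis=0)
    out = pd.DataFrame({"time_h": times})
    for q, row in zip(quantiles, bands):
        out[f"p{q:g}"] = row
    return out


def turnover_half_lives(
    ins: InsulinParameters,
    ffa: FFAParameters,
    pk: Optional[PKParameters] = None,
) -> pd.DataFrame:
    """Half-life table ln(2)/k for the turnover processes (hours).

    Rows: biomarker (k_out), moderator (k_tol), integral controller
    (k_outR; ln2/k applied to the printed numeric value by convention,
    ignoring its nM^-1 factor) and NiAc action (k_N; undefined for the
    lean insulin model, reported as NaN).  The absorption half-life
    ln(2)/ka is appended when PK parameters are given.
    """
    ln2 = math.log(2.0)

    def hl(k):
        return ln2 / k if k else float("nan")

    frame = pd.DataFrame(
        {
            "insulin": [hl(ins.koutI), hl(ins.ktolI), hl(ins.koutRI), hl(ins.kNI)],
            "FFA": [hl(ffa.koutF), hl(ffa.ktolF), hl(ffa.koutRF), hl(ffa.kNF)],
        },
        index=["biomarker", "moderator", "controller", "NiAc action"],
    )
    if pk is not None:
        frame.loc["absorption"] = [float("nan"), float("nan")]
        frame["NiAc"] = float("nan")
        frame.loc["absorption", "NiAc"] = hl(pk.ka)
    return frame
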
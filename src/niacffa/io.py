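"""Parameter files, trajectory/observation CSV, and result reporting.

The single tabular interchange format is CSV; parameter and protocol
files are YAML.  Parameter files use the published symbol names under
``lean:``/``obese:`` sections, each with ``pk``, ``insulin`` and ``ffa``
blocks; the file shipped with the package reproduces the published
median estimates exactly.
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .parameters import (
    FFAParameters,
    InsulinParameters,
    PKParameters,
    PUMP_INACTIVATION_TIME_H,
)

__all__ = [
    "default_parameter_path",
    "load_parameters",
    "save_parameters",
    "trajectory_to_csv",
    "report",
]

_PK_KEYS = {"Vp", "Vt", "Cld", "Vmax1", "Km1", "Vmax2", "Km2", "Synt", "ka", "delta", "t0"}
_INS_KEYS = {"I0", "koutI", "ImaxNI", "IC50NI", "n", "ktolI", "koutRI", "kNI", "N50I", "gamma", "SNI"}
_FFA_KEYS = {"F0", "koutF", "ImaxNF", "IC50NF", "m", "ktolF", "koutRF", "kNF", "N50F", "phi", "SNF"}


def default_parameter_path() -> Path:
    """Path of the shipped parameter file (published median estimates)."""
    return Path(resources.files("niacffa").joinpath("data/parameters.yaml"))


def _check_keys(block: dict, allowed: set, label: str):
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in {label} block: {sorted(unknown)}")


def load_parameters(path=None, species: str = "obese"
                    ) -> Tuple[PKParameters, InsulinParameters, FFAParameters]:
    """Load one species' (PK, insulin, FFA) parameters from a YAML file.

    Unknown keys and out-of-range values raise a validation error naming
    the offending key.  Without ``path`` the shipped defaults are used.
    """
    path = default_parameter_path() if path is None else Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if species not in data:
        raise ValueError(f"parameter file has no section for species {species!r}")
    section = data[species]
    for block_name in ("pk", "insulin", "ffa"):
        if block_name not in section:
            raise ValueError(f"missing {block_name!r} block for species {species!r}")
    _check_keys(section["pk"], _PK_KEYS, f"{species}/pk")
    _check_keys(section["insulin"], _INS_KEYS, f"{species}/insulin")
    _check_keys(section["ffa"], _FFA_KEYS, f"{species}/ffa")
    pk = PKParameters(species=species, **section["pk"])
    ins = InsulinParameters(species=species, **section["insulin"])
    ffa = FFAParameters(species=species, **section["ffa"])
    return pk, ins, ffa


def _params_to_block(params, keys):
    out = {}
    for f in dataclasses.fields(params):
        if f.name in keys:
            value = getattr(params, f.name)
            if value is not None:
                out[f.name] = float(value)
    return out


def save_parameters(path, *species_sets) -> None:
    """Write one or more (pk, ins, ffa) triples to a YAML parameter file."""
    data = {}
    for pk, ins, ffa in species_sets:
        data[pk.species] = {
            "pk": _params_to_block(pk, _PK_KEYS),
            "insulin": _params_to_block(ins, _INS_KEYS),
            "ffa": _params_to_block(ffa, _FFA_KEYS),
        }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def trajectory_to_csv(traj, path, pk_only: bool = False) -> None:
    """Export a trajectory; PK export uses time_h/Asc/Cp_uM/Ct_uM columns."""
    frame = traj.frame.copy()
    if pk_only:
        out = pd.DataFrame({"time_h": frame["time"], "Asc": frame["Asc"],
                            "Cp_uM": frame["Cp"]})
        out["Ct_uM"] = frame["Ct"] if "Ct" in frame else np.nan
        out.to_csv(path, index=False)
        return
    frame = frame.rename(columns={"time": "time_h"})
    frame.to_csv(path, index=False)


def report(result, format: str = "text") -> str:
    """Render a fit result or a tabular result as JSON or fixed-width text.

    ``result`` may be a :class:`~niacffa.population.FitResult`, a pandas
    DataFrame (e.g. the half-life table or a regimen surface), or any
    mapping; JSON mode is loss-free, text mode mirrors the published
    estimate / RSE% / BSV CV% layout where applicable.
    """
    from .population import FitResult

    if result is None or (isinstance(result, (dict, list)) and not result):
        return ""
    if isinstance(result, FitResult):
        payload = result.to_dict()
        if format == "json":
            return json.dumps(payload, indent=2, default=float)
        lines = [f"{'parameter':<12}{'estimate':>12}{'RSE%':>10}{'BSV CV%':>10}"]
        for name, est in payload["estimates"].items():
            rse = payload["rse_percent"].get(name)
            cv = payload["bsv_cv_percent"].get(name)
            rse_s = "" if rse is None else f"{rse:.3g}"
            cv_s = "" if cv is None else f"{cv:.3g}"
            lines.append(f"{name:<12}{est:>12.4g}{rse_s:>10}{cv_s:>10}")
        lines.append(f"objective (-2LL/2): {payload['objective']:.4f}")
        lines.append(f"converged: {payload['converged']}")
        return "\n".join(lines)
    if isinstance(result, pd.DataFrame):
        if format == "json":
            return result.to_json(orient="records", indent=2)
        return result.to_string(index=False)
    if format == "json":
        return json.dumps(result, indent=2, default=float)
    return "\n".join(f"{k}: {v}" for k, v in dict(result).items())
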
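"""Model parameters for the NiAc-insulin-FFA system.

Units are fixed package-wide: time in hours, NiAc in uM, insulin in nM,
FFA in mM, drug amounts in umol/kg.  The constant-rate infusion used in
the rat studies, 170 nmol/min/kg, is therefore stored as 10.2 umol/kg/h.

Two species variants are supported:

* ``lean`` (Sprague-Dawley): two-compartment NiAc disposition with two
  parallel Michaelis-Menten elimination pathways; constant NiAc efficacy
  on insulin (no insulin action compartment).
* ``obese`` (Zucker, fa/fa): one-compartment disposition, single
  Michaelis-Menten pathway; dynamic NiAc efficacy on both insulin and FFA.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional

__all__ = [
    "PKParameters",
    "InsulinParameters",
    "FFAParameters",
    "default_pk_parameters",
    "default_insulin_parameters",
    "default_ffa_parameters",
    "default_parameters",
    "PUMP_INACTIVATION_TIME_H",
    "BASE_INFUSION_RATE",
]

#: pump inactivation time t0 (h); the mini-pump is implanted 7 days before
#: the acute experiment.
PUMP_INACTIVATION_TIME_H = 168.0

#: 170 nmol/min/kg expressed in umol/kg/h.
BASE_INFUSION_RATE = 10.2


def _require_positive(obj, names):
    for name in names:
        value = getattr(obj, name)
        if value is None:
            raise ValueError(f"{type(obj).__name__}.{name} is required")
        if not value > 0:
            raise ValueError(f"{type(obj).__name__}.{name} must be > 0, got {value}")


def _require_unit_interval(obj, names):
    for name in names:
        value = getattr(obj, name)
        if value is None:
            continue
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{type(obj).__name__}.{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class PKParameters:
    """NiAc disposition constants.

    Lean rats use the full two-compartment model (``Vt``, ``Cld``,
    ``Vmax2``, ``Km2`` set); obese rats use the one-compartment, single
    pathway reduction (those four fields are ``None``).
    """

    species: str
    Vp: float            # plasma volume of distribution (L/kg)
    Vmax1: float         # maximal elimination, pathway 1 (umol/kg/h)
    Km1: float           # Michaelis constant, pathway 1 (uM)
    Synt: float          # endogenous NiAc synthesis (umol/kg/h)
    ka: float            # first-order s.c. absorption rate (h^-1)
    delta: float         # lumped diffusion coefficient of the pump catheter
    t0: float = PUMP_INACTIVATION_TIME_H  # pump inactivation time (h)
    Vt: Optional[float] = None    # tissue volume (L/kg, lean only)
    Cld: Optional[float] = None   # inter-compartmental distribution (L/kg/h, lean only)
    Vmax2: Optional[float] = None  # maximal elimination, pathway 2 (lean only)
    Km2: Optional[float] = None    # Michaelis constant, pathway 2 (lean only)

    def __post_init__(self):
        if self.species not in ("lean", "obese"):
            raise ValueError(f"species must be 'lean' or 'obese', got {self.species!r}")
        _require_positive(self, ["Vp", "Vmax1", "Km1", "Synt", "ka", "delta", "t0"])
        lean_only = ["Vt", "Cld", "Vmax2", "Km2"]
        if self.species == "lean":
            _require_positive(self, lean_only)
        else:
            for name in lean_only:
                if getattr(self, name) is not None:
                    raise ValueError(f"obese PKParameters must not define {name}")

    @property
    def two_compartment(self) -> bool:
        return self.species == "lean"


@dataclass(frozen=True)
class InsulinParameters:
    """Insulin turnover model constants.

    The insulin system carries a two-moderator feedback cascade and an
    insulin-driven integral regulator with set point ``I0``.  For obese
    rats the NiAc efficacy is dynamic, driven by a slow NiAc action
    compartment (``kNI``, ``N50I``, ``gamma``, ``SNI``); lean rats have a
    constant efficacy ``ImaxNI`` and no action compartment.
    """

    species: str
    I0: float          # baseline insulin (nM)
    koutI: float       # fractional turnover rate (h^-1)
    ktolI: float       # moderator fractional turnover rate (h^-1)
    koutRI: float      # integral gain (nM^-1 h^-1)
    ImaxNI: float      # initial drug efficacy, in [0, 1]
    IC50NI: float      # NiAc potency on insulin (uM)
    n: float           # Hill coefficient
    kNI: Optional[float] = None    # NiAc-action turnover rate (h^-1, obese)
    N50I: Optional[float] = None   # action-compartment potency (uM, obese)
    SNI: Optional[float] = None    # long-term efficacy loss, in [0, 1] (obese)
    gamma: Optional[float] = None  # Hill coefficient of efficacy relation (obese)

    def __post_init__(self):
        if self.species not in ("lean", "obese"):
            raise ValueError(f"species must be 'lean' or 'obese', got {self.species!r}")
        _require_positive(self, ["I0", "koutI", "ktolI", "koutRI", "IC50NI", "n"])
        _require_unit_interval(self, ["ImaxNI", "SNI"])
        dyn = ["kNI", "N50I", "SNI", "gamma"]
        if self.species == "obese":
            _require_positive(self, ["kNI", "N50I", "gamma"])
            if self.SNI is None:
                raise ValueError("obese InsulinParameters require SNI")
        else:
            for name in dyn:
                if getattr(self, name) is not None:
                    raise ValueError(f"lean InsulinParameters must not define {name}")

    @property
    def dynamic_efficacy(self) -> bool:
        return self.species == "obese"


@dataclass(frozen=True)
class FFAParameters:
    """FFA turnover model constants.

    Single moderator, insulin-driven integral regulator (set point is the
    *insulin* baseline), and NiAc inhibition with dynamic efficacy in both
    species.
    """

    species: str
    F0: float          # baseline FFA (mM)
    koutF: float       # fractional turnover rate (h^-1)
    ktolF: float       # moderator turnover rate (h^-1)
    koutRF: float      # integral gain (nM^-1 h^-1)
    ImaxNF: float      # efficacy (fixed to 1 in both species)
    IC50NF: float      # NiAc potency on FFA (uM)
    m: float           # Hill coefficient
    kNF: float         # NiAc-action turnover rate (h^-1)
    N50F: float        # action-compartment potency (uM)
    SNF: float         # long-term efficacy loss, in [0, 1]
    phi: float         # Hill coefficient of the efficacy relation

    def __post_init__(self):
        if self.species not in ("lean", "obese"):
            raise ValueError(f"species must be 'lean' or 'obese', got {self.species!r}")
        _require_positive(self, ["F0", "koutF", "ktolF", "koutRF", "IC50NF", "m", "kNF", "N50F", "phi"])
        _require_unit_interval(self, ["ImaxNF", "SNF"])


# ---------------------------------------------------------------------------
# Default (published median) parameter values.

_PK_DEFAULTS = {
    "lean": dict(
        species="lean", Vp=0.393, Vt=0.172, Cld=0.0511,
        Vmax1=2.64, Km1=0.235, Vmax2=425.0, Km2=74.5,
        Synt=0.213, ka=4.27, delta=77.4,
    ),
    "obese": dict(
        species="obese", Vp=0.323,
        Vmax1=164.0, Km1=18.9,
        Synt=0.168, ka=5.54, delta=62.4,
    ),
}

_INSULIN_DEFAULTS = {
    "lean": dict(
        species="lean", I0=0.188, koutI=6.58, ImaxNI=0.793,
        IC50NI=0.338, n=3.54, ktolI=0.646, koutRI=3.94,
    ),
    "obese": dict(
        species="obese", I0=3.26, koutI=10.8, ImaxNI=1.0,
        IC50NI=0.175, n=0.840, ktolI=0.125, koutRI=0.0612,
        kNI=0.0242, N50I=0.897, gamma=18.9, SNI=1.0,
    ),
}

_FFA_DEFAULTS = {
    "lean": dict(
        species="lean", F0=0.707, koutF=428.0, ImaxNF=1.0,
        IC50NF=0.436, m=1.24, ktolF=1.21, koutRF=0.965,
        kNF=0.00654, N50F=3.05, SNF=0.807, phi=1.0,
    ),
    "obese": dict(
        species="obese", F0=1.14, koutF=173.0, ImaxNF=1.0,
        IC50NF=0.456, m=0.731, ktolF=0.708, koutRF=0.0165,
        kNF=0.0377, N50F=0.854, SNF=1.0, phi=8.83,
    ),
}


def default_pk_parameters(species: str) -> PKParameters:
    return PKParameters(**_PK_DEFAULTS[species])


def default_insulin_parameters(species: str) -> InsulinParameters:
    return InsulinParameters(**_INSULIN_DEFAULTS[species])


def default_ffa_parameters(species: str) -> FFAParameters:
    return FFAParameters(**_FFA_DEFAULTS[species])


def default_parameters(species: str):
    """Published median parameters: (PK, insulin, FFA) for one species."""
    return (
        default_pk_parameters(species),
        default_insulin_parameters(species),
        default_ffa_parameters(species),
    )


def replace_fields(params, **updates):
    """Return a copy of a parameter dataclass with selected fields replaced."""
    kwargs = {f.name: getattr(params, f.name) for f in fields(params)}
    kwargs.update(updates)
    return type(params)(**kwargs)
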
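"""Dosing protocols: the published rat study designs and arbitrary regimens.

A protocol is an ordered list of constant-rate infusion segments on a
common time axis where t = 0 h marks the start of the acute experiment.
Pretreated groups carry explicit negative-time segments (the 5-day
history is simulated, not assumed away), and subcutaneous protocols
record when the implanted pump was first activated so that the start-up
dilution clock can be anchored there.

Rates are in umol/kg/h; the studies' base rate of 170 nmol/min/kg is
10.2 umol/kg/h.  The step-down taper ladders are the published rate
sequences, applied as seven equal 0.5 h steps between infusion end and
the final switch-off (1 -> 4.5 h and 12 -> 15.5 h).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
import yaml

__all__ = ["DosingProtocol", "build_protocol", "PROTOCOL_NAMES"]

_NMOL_MIN_TO_UMOL_H = 0.06  # nmol/min/kg -> umol/kg/h

BASE_RATE = 170 * _NMOL_MIN_TO_UMOL_H  # 10.2 umol/kg/h

# Published step-down ladders (nmol/min/kg), 12 h and 1 h variants.
STEP_DOWN_12H = [88.9, 58.3, 43.7, 34.0, 24.3, 17.0, 9.7]
STEP_DOWN_1H = [31.1, 20.4, 15.3, 11.9, 8.50, 5.95, 3.40]

PROTOCOL_NAMES = (
    "NiAc_Naive",
    "Cont_NiAc",
    "Inter_NiAc",
    "Off_1h",
    "StpDwn_1h",
    "Off_12h",
    "StpDwn_12h",
)


@dataclass(frozen=True)
class DosingProtocol:
    """Ordered infusion segments plus observation-window metadata.

    Parameters
    ----------
    route:
        ``"iv"`` (rate enters plasma directly) or ``"sc_pump"`` (rate
        feeds the subcutaneous depot through the implanted pump, subject
        to the start-up dilution factor).
    segments:
        Sorted, non-overlapping ``(start, end, rate)`` tuples in hours
        and umol/kg/h.  Gaps between segments mean zero infusion.
    pretreatment_duration:
        Hours of dosing history before the acute window (0 or 120).
    pump_first_activation:
        Time (h) at which the s.c. pump first turned on; anchors the
        start-up dilution clock.  Ignored for i.v. protocols.
    acute_window:
        ``(start, end)`` of the acute observation window (h).
    """

    route: str
    segments: Tuple[Tuple[float, float, float], ...]
    pretreatment_duration: float = 0.0
    pump_first_activation: float = 0.0
    acute_window: Tuple[float, float] = (0.0, 8.0)
    name: str = ""

    def __post_init__(self):
        if self.route not in ("iv", "sc_pump"):
            raise ValueError(f"route must be 'iv' or 'sc_pump', got {self.route!r}")
        segs = tuple((float(a), float(b), float(r)) for a, b, r in self.segments)
        object.__setattr__(self, "segments", segs)
        last_end = -np.inf
        for start, end, rate in segs:
            if end <= start:
                raise ValueError(f"segment ({start}, {end}) has non-positive duration")
            if start < last_end - 1e-12:
                raise ValueError("segments overlap or are unsorted")
            if rate < 0:
                raise ValueError("infusion rates must be >= 0")
            last_end = end

    @property
    def start(self) -> float:
        """Simulation start: beginning of pretreatment or of the acute window."""
        t0 = -self.pretreatment_duration
        if self.segments:
            t0 = min(t0, self.segments[0][0])
        return min(t0, self.acute_window[0])

    @property
    def end(self) -> float:
        t1 = self.acute_window[1]
        if self.segments:
            t1 = max(t1, self.segments[-1][1])
        return t1

    def rate_at(self, t: float) -> float:
        """Programmed infusion rate at time t (before pump dilution)."""
        for start, end, rate in self.segments:
            if start <= t < end:
                return rate
        return 0.0

    def boundaries(self) -> np.ndarray:
        """All segment on/off/step times; integration restarts here."""
        pts = set()
        for start, end, _ in self.segments:
            pts.add(start)
            pts.add(end)
        return np.array(sorted(pts))

    def total_programmed_amount(self) -> float:
        """Total programmed drug (umol/kg), ignoring the pump dilution."""
        return sum((end - start) * rate for start, end, rate in self.segments)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "route": self.route,
            "segments": [list(s) for s in self.segments],
            "pretreatment_duration": self.pretreatment_duration,
            "pump_first_activation": self.pump_first_activation,
            "acute_window": list(self.acute_window),
            "name": self.name,
        }

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, data: dict) -> "DosingProtocol":
        return cls(
            route=data["route"],
            segments=tuple(tuple(s) for s in data["segments"]),
            pretreatment_duration=float(data.get("pretreatment_duration", 0.0)),
            pump_first_activation=float(data.get("pump_first_activation", 0.0)),
            acute_window=tuple(data.get("acute_window", (0.0, 8.0))),
            name=data.get("name", ""),
        )

    @classmethod
    def from_yaml(cls, path_or_text) -> "DosingProtocol":
        try:
            with open(path_or_text) as fh:
                data = yaml.safe_load(fh)
        except (OSError, TypeError):
            data = yaml.safe_load(path_or_text)
        return cls.from_dict(data)


def zero_protocol(duration: float = 8.0, route: str = "iv") -> DosingProtocol:
    """Vehicle-control protocol: no drug, observation window [0, duration]."""
    return DosingProtocol(route=route, segments=(), acute_window=(0.0, duration), name="control")


def constant_iv(rate: float, duration: float, window: float | None = None) -> DosingProtocol:
    """Single constant-rate i.v. infusion starting at t = 0."""
    window = duration if window is None else window
    return DosingProtocol(
        route="iv", segments=((0.0, duration, rate),),
        acute_window=(0.0, window), name="constant_iv",
    )


def _ladder_segments(t_on_end: float, ladder_nmol_min: Sequence[float]) -> List[Tuple[float, float, float]]:
    segs = []
    t = t_on_end
    for rate in ladder_nmol_min:
        segs.append((t, t + 0.5, rate * _NMOL_MIN_TO_UMOL_H))
        t += 0.5
    return segs


def build_protocol(name: str, species: str = "obese") -> DosingProtocol:
    """Construct one of the published study protocols by name.

    Conscious groups (``NiAc_Naive``, ``Cont_NiAc``, ``Inter_NiAc``) are
    subcutaneous with a 5 h acute window and 2-3 basal samples before
    t = 0; the pretreated groups carry an explicit 120 h history.  The
    anesthetized groups are the 1 h i.v. and 12 h s.c. infusions with
    abrupt stop (``Off``) or the published step-down taper (``StpDwn``).
    The ``species`` argument is kept for interface symmetry; the designs
    are identical for lean and obese animals.
    """
    if species not in ("lean", "obese"):
        raise ValueError(f"unknown species {species!r}")
    if name == "NiAc_Naive":
        return DosingProtocol(
            route="sc_pump", segments=((0.0, 5.0, BASE_RATE),),
            pretreatment_duration=0.0, pump_first_activation=0.0,
            acute_window=(0.0, 5.0), name=name,
        )
    if name == "Cont_NiAc":
        return DosingProtocol(
            route="sc_pump", segments=((-120.0, 5.0, BASE_RATE),),
            pretreatment_duration=120.0, pump_first_activation=-120.0,
            acute_window=(0.0, 5.0), name=name,
        )
    if name == "Inter_NiAc":
        # 12 h on / 12 h off cycles through the 5-day pretreatment, with a
        # fresh on-cycle starting at the acute window.
        segments = [(-120.0 + 24.0 * k, -120.0 + 24.0 * k + 12.0, BASE_RATE) for k in range(5)]
        segments.append((0.0, 5.0, BASE_RATE))
        return DosingProtocol(
            route="sc_pump", segments=tuple(segments),
            pretreatment_duration=120.0, pump_first_activation=-120.0,
            acute_window=(0.0, 5.0), name=name,
        )
    if name == "Off_1h":
        return DosingProtocol(
            route="iv", segments=((0.0, 1.0, BASE_RATE),),
            acute_window=(0.0, 6.0), name=name,
        )
    if name == "StpDwn_1h":
        segments = [(0.0, 1.0, BASE_RATE)] + _ladder_segments(1.0, STEP_DOWN_1H)
        return DosingProtocol(
            route="iv", segments=tuple(segments),
            acute_window=(0.0, 6.0), name=name,
        )
    if name == "Off_12h":
        return DosingProtocol(
            route="sc_pump", segments=((0.0, 12.0, BASE_RATE),),
            pump_first_activation=0.0, acute_window=(11.0, 17.0), name=name,
        )
    if name == "StpDwn_12h":
        segments = [(0.0, 12.0, BASE_RATE)] + _ladder_segments(12.0, STEP_DOWN_12H)
        return DosingProtocol(
            route="sc_pump", segments=tuple(segments),
            pump_first_activation=0.0, acute_window=(11.0, 17.0), name=name,
        )
    raise ValueError(f"unknown protocol name {name!r}; known: {PROTOCOL_NAMES}")
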
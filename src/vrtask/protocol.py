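"""Rotation protocol for the vestibular rotation task.

The task consists of nine trials.  In each trial the examiner rotates the
blindfolded participant through one, two or three chair turns (signed
degrees, clockwise positive when viewed from above) and the participant then
points the tablet back at a remembered reference object.  This module
encodes the fixed nine-trial protocol, the compass geometry of a correct
response, and JSON round-tripping for custom protocols.

Conventions used package-wide: compass headings are degrees in [0, 360),
clockwise-positive; signed turns live in (-180, 180].
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

__all__ = [
    "TrialSpec",
    "ReferencePoint",
    "default_protocol",
    "net_rotation",
    "required_turn_to_reference",
    "wrap_heading",
    "wrap_signed",
    "protocol_to_json",
    "protocol_from_json",
]

# Nine scripted rotation sequences, one per trial, in trial order.
# Positive = clockwise, negative = anticlockwise; multi-turn trials list the
# turns in execution order.
_DEFAULT_ROTATIONS: tuple[tuple[float, ...], ...] = (
    (90,),
    (90, -210),
    (120,),
    (300,),
    (145, -230),
    (230, -130),
    (-225, 290, 60),
    (-290, 265, -70),
    (-200, 310, -190),
)


def wrap_heading(deg: float) -> float:
    """Wrap an angle to a compass heading in [0, 360)."""
    return float(deg) % 360.0


def wrap_signed(deg: float) -> float:
    """Wrap an angle to the signed interval (-180, 180]."""
    wrapped = -((-float(deg) + 180.0) % 360.0 - 180.0)
    # The modulo above maps +180 to +180 and -180 to +180, as required.
    return wrapped if wrapped != -180.0 else 180.0


@dataclass(frozen=True)
class TrialSpec:
    """One trial of the rotation protocol.

    Parameters
    ----------
    trial_id:
        Trial number, 1-9 in the default protocol.
    rotations:
        Ordered chair turns in signed degrees; every turn is nonzero.
    """

    trial_id: int
    rotations: tuple[float, ...]

    def __post_init__(self) -> None:
        if not 1 <= int(self.trial_id):
            raise ValueError(f"trial_id must be >= 1, got {self.trial_id}")
        rotations = tuple(float(r) for r in self.rotations)
        if len(rotations) == 0:
            raise ValueError("rotations must be non-empty")
        if any(r == 0 for r in rotations):
            raise ValueError("every rotation must be nonzero")
        object.__setattr__(self, "rotations", rotations)


@dataclass(frozen=True)
class ReferencePoint:
    """Recorded location of the remembered reference object at trial start.

    Only the compass bearing enters the analysis; ``elevation`` is carried
    as an inert placeholder because the task records x, y, z coordinates
    but the response measure is purely directional.
    """

    heading_deg: float
    elevation: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.heading_deg < 360.0:
            raise ValueError(
                f"heading_deg must be in [0, 360), got {self.heading_deg}"
            )


def default_protocol() -> list[TrialSpec]:
    """Return the fixed nine-trial rotation protocol, in trial order."""
    return [
        TrialSpec(trial_id=i + 1, rotations=rots)
        for i, rots in enumerate(_DEFAULT_ROTATIONS)
    ]


def net_rotation(trial: TrialSpec) -> float:
    """Algebraic sum of a trial's turns in signed degrees (not wrapped).

    This is where the chair leaves the participant's body heading relative
    to where it started, before any wrapping to compass range.
    """
    return float(sum(trial.rotations))


def required_turn_to_reference(
    body_heading_deg: float, reference: ReferencePoint
) -> float:
    """Signed minimal turn, in (-180, 180], from a body heading to the reference.

    A perfect responder facing ``body_heading_deg`` executes exactly this
    turn to point at the reference bearing.
    """
    if not 0.0 <= body_heading_deg < 360.0:
        raise ValueError("body_heading_deg must be in [0, 360)")
    return wrap_signed(reference.heading_deg - body_heading_deg)


def protocol_to_json(protocol: Iterable[TrialSpec], path: str | Path | None = None) -> str:
    """Serialize a protocol to a JSON list of {trial_id, rotations}."""
    doc = [
        {"trial_id": t.trial_id, "rotations": list(t.rotations)} for t in protocol
    ]
    text = json.dumps(doc, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def protocol_from_json(source: str | Path) -> list[TrialSpec]:
    """Load a protocol from a JSON document (path or JSON text)."""
    if isinstance(source, Path) or (isinstance(source, str) and Path(source).exists()):
        text = Path(source).read_text()
    else:
        text = source
    doc = json.loads(text)
    return [
        TrialSpec(trial_id=int(d["trial_id"]), rotations=tuple(d["rotations"]))
        for d in doc
    ]
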
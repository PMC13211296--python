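"""Stimulus protocols: ordered perfusion phases with analyte and duration.

The canonical glucose-stimulated insulin secretion (GSIS) protocol perfuses a
trapped islet with low glucose, steps to high glucose, returns to low glucose,
and finishes with KCl depolarization.  Phases are contiguous from t = 0 and
expressed in minutes; conversion to frame indices happens where a trace's
frame interval is known.
"""

from __future__ import annotations

import dataclasses


class ProtocolError(ValueError):
    """Raised for empty or ill-formed stimulus protocols."""


@dataclasses.dataclass(frozen=True)
class Phase:
    label: str
    analyte: str
    concentration: float
    units: str
    duration_min: float

    def __post_init__(self) -> None:
        if self.duration_min <= 0:
            raise ProtocolError(
                f"phase {self.label!r}: duration must be > 0 min, got {self.duration_min}"
            )


@dataclasses.dataclass(frozen=True)
class StimulusProtocol:
    """Ordered, contiguous perfusion phases starting at t = 0."""

    phases: tuple[Phase, ...]

    def __post_init__(self) -> None:
        if not self.phases:
            raise ProtocolError("protocol must contain at least one phase")

    @property
    def total_duration_min(self) -> float:
        return sum(p.duration_min for p in self.phases)

    def boundaries_min(self) -> list[float]:
        """Phase start times plus the final end time, in minutes."""
        out = [0.0]
        for p in self.phases:
            out.append(out[-1] + p.duration_min)
        return out

    def boundary_frames(self, frame_interval_min: float) -> list[int]:
        """Phase boundaries as frame indices (floor at each start)."""
        return [int(b / frame_interval_min) for b in self.boundaries_min()]

    def n_transitions(self) -> int:
        """Number of stimulus switches (phase-to-phase boundaries)."""
        return len(self.phases) - 1

    def phase_at_frame(self, frame: int, frame_interval_min: float) -> Phase | None:
        bounds = self.boundary_frames(frame_interval_min)
        for phase, lo, hi in zip(self.phases, bounds[:-1], bounds[1:]):
            if lo <= frame < hi:
                return phase
        return None


def standard_gsis_protocol() -> StimulusProtocol:
    """Low glucose 15 min, high glucose 30 min, low glucose 15 min, KCl 15 min.

    At one frame per minute the phase boundaries fall at frames
    0, 15, 45, 60 and 75; the secretion-linked optical step decreases are
    expected at the high-glucose onset (frame 15) and the KCl onset (frame 60).
    """
    return StimulusProtocol(
        phases=(
            Phase("low glucose", "glucose", 2.8, "mM", 15.0),
            Phase("high glucose", "glucose", 20.0, "mM", 30.0),
            Phase("low glucose washout", "glucose", 2.8, "mM", 15.0),
            Phase("KCl", "KCl", 30.0, "mM", 15.0),
        )
    )
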
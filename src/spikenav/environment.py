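"""Open arena, hidden goal zone, and trial bookkeeping.

The agent lives in a square arena centred on the origin.  Moves are clamped
per axis to the walls (the agent slides along a wall rather than bouncing).
A trial ends on goal entry or at the timeout; it counts as *successful* only
if the goal was entered before the (stricter) success threshold — the band
between threshold and timeout is nearly empty in practice and is treated as
failure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ProtocolError",
    "Arena",
    "GoalZone",
    "AgentState",
    "TrialRecord",
    "reset_trial",
    "apply_displacement",
    "in_goal",
    "classify_trial",
]

SUCCESS = "success"
FAILURE = "failure"


class ProtocolError(RuntimeError):
    """A trial violated the task protocol (e.g. ran past the timeout)."""


@dataclass(frozen=True)
class Arena:
    """Square arena of side ``side_length`` metres centred on (0, 0)."""

    side_length: float = 2.4

    def __post_init__(self):
        if self.side_length <= 0:
            raise ValueError("side_length must be positive")

    @property
    def half(self) -> float:
        return self.side_length / 2.0

    def contains(self, position: np.ndarray) -> bool:
        p = np.asarray(position, dtype=float)
        return bool(np.all(np.abs(p) <= self.half + 1e-12))


@dataclass(frozen=True)
class GoalZone:
    """Hidden circular goal: closed disk of radius ``radius`` at ``center``."""

    center: np.ndarray
    radius: float

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.radius <= 0:
            raise ValueError("goal radius must be positive")


@dataclass(frozen=True)
class AgentState:
    position: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))


@dataclass
class TrialRecord:
    """Outcome of one trial of the navigation task."""

    trial_index: int
    duration: float
    outcome: str
    #: (n, 3) array of (t, x, y) samples, subsampled along the trajectory
    trajectory: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    #: time of goal entry (s), or None if the goal was never entered
    reward_time: Optional[float] = None

    @property
    def success(self) -> bool:
        return self.outcome == SUCCESS


def reset_trial(arena: Arena) -> AgentState:
    """Place the agent at the arena centre at t = 0.

    Only the agent's pose is reset; network activity, synaptic traces and
    weights deliberately persist across trials.
    """
    return AgentState(position=np.zeros(2), t=0.0)


def apply_displacement(
    state: AgentState, a: np.ndarray, dt: float, arena: Arena
) -> AgentState:
    """Move the agent by ``a`` (metres), clamping per axis to the walls."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    a = np.asarray(a, dtype=float)
    if not np.all(np.isfinite(a)):
        raise FloatingPointError(f"non-finite displacement {a!r}")
    half = arena.half
    new_pos = np.clip(state.position + a, -half, half)
    return AgentState(position=new_pos, t=state.t + dt)


def in_goal(state: AgentState | np.ndarray, goal: GoalZone) -> bool:
    """True iff the agent is inside the goal disk (boundary inclusive)."""
    pos = state.position if isinstance(state, AgentState) else np.asarray(state, float)
    d = pos - goal.center
    return bool(d @ d <= goal.radius**2)


def classify_trial(
    duration: float,
    goal_entered: bool,
    timeout: float = 5.0,
    success_threshold: float = 4.5,
) -> str:
    """Classify a finished trial as success or failure.

    Success requires goal entry *and* duration strictly below the success
    threshold.  A duration beyond the timeout means the driver loop violated
    the protocol and raises :class:`ProtocolError`.
    """
    if duration < 0:
        raise ProtocolError(f"negative trial duration {duration}")
    if duration > timeout + 1e-9:
        raise ProtocolError(
            f"trial duration {duration} s exceeds the timeout of {timeout} s"
        )
    if goal_entered and duration < success_threshold:
        return SUCCESS
    return FAILURE
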
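"""Reward and health accounting.

Episode reward starts at 0 and decreases by 1/t per step (t = timeLimit;
disabled when t = 0), 10x faster inside a hot zone.  Contacting a valenced
goal adds (or subtracts) its current valence; episode-ending goals
terminate the episode; "Multi", grow/shrink and ripen/decay goals are
collected without terminating.  A death zone costs exactly -1 and ends the
episode.  Health starts at 100, tracks reward at a fixed factor of 100
health points per unit reward (a 0.5-valence goal restores 50 health),
is clamped to [0, 100], and ends the episode in failure at 0.

Valence is proportional to goal size with proportionality constant 1:
a GoodGoal of size v is worth +v reward.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .ontology import kind_info

HEALTH_PER_REWARD = 100.0
HOT_ZONE_FACTOR = 10.0


class TerminationCause(Enum):
    NONE = "none"
    GOAL = "goal"
    DEATHZONE = "deathzone"
    TIMEOUT = "timeout"
    HEALTH_ZERO = "healthZero"


@dataclass
class ValenceState:
    """Cumulative reward and health for one episode."""

    reward: float = 0.0
    health: float = 100.0
    terminated: bool = False
    cause: TerminationCause = TerminationCause.NONE

    def apply_delta(self, delta: float) -> None:
        """Add a reward delta and move health with it (factor 100, clamped)."""
        self.reward += delta
        self.health, failed = update_health(self.health, delta)
        if failed and not self.terminated:
            self.terminated = True
            self.cause = TerminationCause.HEALTH_ZERO

    def terminate(self, cause: TerminationCause) -> None:
        if not self.terminated:
            self.terminated = True
            self.cause = cause


@dataclass(frozen=True)
class GoalSchedule:
    """Time course of a goal's valence (and, for grow/shrink, its size).

    Piecewise linear: the value holds at its starting level for ``delay``
    steps, moves linearly to its terminal level over ``duration`` steps,
    then clamps there.
    """

    mode: str = "static"  # static | decay | ripen | grow | shrink
    fullValence: float = 1.0
    emptyValence: float = 0.0
    delay: int = 0
    duration: int = 1
    startSize: float = 1.0
    endSize: float = 1.0

    def __post_init__(self):
        if self.delay < 0:
            raise ValueError("delay must be >= 0")
        if self.mode != "static" and self.duration < 1:
            raise ValueError("duration must be >= 1 for time-varying modes")


def step_reward_delta(in_hot_zone: bool, t: int) -> float:
    """Per-step reward decrement: 0 if t == 0, else -1/t (-10/t in a hot
    zone — the accelerated rate replaces, not augments, the base rate)."""
    if t < 0:
        raise ValueError("timeLimit must be >= 0")
    if t == 0:
        return 0.0
    return -(HOT_ZONE_FACTOR if in_hot_zone else 1.0) / t


def on_contact(goal_kind: str, valence: float) -> tuple[float, bool, bool]:
    """Effect of agent contact with a valenced object.

    Returns ``(reward delta, terminate, remove-from-world)``.  GoodGoal and
    BadGoal end the episode; Multi/scheduled goals are collected without
    ending it; DecoyGoal is neutral; a DeathZone costs exactly -1,
    terminates, and stays in the world.
    """
    info = kind_info(goal_kind)
    if info.name == "DeathZone":
        return -1.0, True, False
    if info.name == "HotZone":
        return 0.0, False, False
    if not info.collectible:
        raise ValueError(f"{goal_kind} is not a contact-valenced object")
    delta = info.valence_sign * valence
    return delta, info.episode_ending, True


def _interp(start: float, end: float, s: GoalSchedule, step: int) -> float:
    if step <= s.delay:
        return start
    frac = min(1.0, (step - s.delay) / s.duration)
    return start + (end - start) * frac


def scheduled_valence(s: GoalSchedule, steps_since_spawn: int) -> float:
    """Current valence of a goal ``steps_since_spawn`` after it appeared."""
    if steps_since_spawn < 0:
        raise ValueError("steps_since_spawn must be >= 0")
    if s.mode in ("static", "grow", "shrink"):
        if s.mode == "grow":
            return _interp(s.startSize, s.endSize, s, steps_since_spawn)
        if s.mode == "shrink":
            return _interp(s.startSize, s.endSize, s, steps_since_spawn)
        return s.fullValence
    if s.mode == "decay":
        return _interp(s.fullValence, s.emptyValence, s, steps_since_spawn)
    if s.mode == "ripen":
        return _interp(s.emptyValence, s.fullValence, s, steps_since_spawn)
    raise ValueError(f"unknown schedule mode {s.mode!r}")


def scheduled_size(s: GoalSchedule, steps_since_spawn: int,
                   space_free: bool, last_size: float | None = None) -> float:
    """Current diameter of a grow/shrink goal.

    Size follows the same linear schedule as valence.  While the space
    around a growing goal is restricted (``space_free`` False) it stops
    growing and holds ``last_size``; shrinking is never blocked.
    """
    if s.mode not in ("grow", "shrink"):
        raise ValueError("scheduled_size applies to grow/shrink modes only")
    target = _interp(s.startSize, s.endSize, s, steps_since_spawn)
    if s.mode == "grow" and not space_free:
        return last_size if last_size is not None else s.startSize
    return target


def update_health(health: float, reward_delta: float) -> tuple[float, bool]:
    """Move health by 100x the reward delta, clamped to [0, 100]; the
    episode fails when health reaches 0."""
    new = min(100.0, max(0.0, health + HEALTH_PER_REWARD * reward_delta))
    return new, new == 0.0


def episode_outcome(reward: float, pass_mark: float) -> str:
    """'pass' iff the final cumulative reward is >= the pass mark."""
    return "pass" if reward >= pass_mark else "fail"
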
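"""Baseline agent battery: random-action agent, heuristic raycast
navigators (foraging and operant variants), and scripted oracles.

The random agent defines chance performance: it picks one of the nine
actions (optionally weighted, optionally correlated with its recent
choices) and repeats it for a number of steps drawn from a clipped normal
distribution with mean 5 and standard deviation 1, rounded to the nearest
integer and never below 1.

The heuristic forager steers toward the nearest positive goal seen on its
raycasts (45 rays over the frontal 60 degrees), rotates in place when no
goal is visible, and jinks forwards-left or forwards-right with equal
probability when stuck.  The operant variant also homes on buttons and
immovable structure, repeats its previous action when nothing is detected,
and moves forwards-left when stationary; its raycasts carry category
information only, so it cannot tell which side of a button is the front.

Oracles are scripted full-state policies used as near-optimal references.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .observe import Observation
from .ontology import Category
from .physics import Action, heading_vector

_N_ACTIONS = 9


@dataclass
class RandomPolicyParams:
    action_weights: tuple[float, ...] = (1.0,) * _N_ACTIONS
    repeat_distribution: str = "normal"   # normal | fixed | geometric
    repeat_mean: float = 5.0
    repeat_sd: float = 1.0
    correlation: float = 0.0              # recency weighting coefficient

    def __post_init__(self):
        if len(self.action_weights) != _N_ACTIONS:
            raise ValueError("action_weights must have 9 entries")
        if any(w < 0 for w in self.action_weights):
            raise ValueError("action_weights must be non-negative")
        if sum(self.action_weights) <= 0:
            raise ValueError("action_weights must not sum to zero")
        if not (0.0 <= self.correlation < 1.0):
            raise ValueError("correlation must be in [0, 1)")


class RandomPolicy:
    """Chance-performance baseline; repeat counts are always >= 1."""

    def __init__(self, params: RandomPolicyParams | None = None,
                 seed: int = 0):
        self.params = params or RandomPolicyParams()
        self.reset(seed)

    def reset(self, seed: int) -> None:
        self.rng = np.random.default_rng(seed)
        self._current: Action = Action.NO_ACTION
        self._remaining = 0
        self._recency = np.zeros(_N_ACTIONS)

    def draw_repeat(self) -> int:
        p = self.params
        if p.repeat_distribution == "normal":
            return max(1, int(round(self.rng.normal(p.repeat_mean,
                                                    p.repeat_sd))))
        if p.repeat_distribution == "fixed":
            return max(1, int(round(p.repeat_mean)))
        if p.repeat_distribution == "geometric":
            return int(self.rng.geometric(1.0 / max(1.0, p.repeat_mean)))
        raise ValueError(
            f"unknown repeat distribution {p.repeat_distribution!r}")

    def _draw_action(self) -> Action:
        w = np.asarray(self.params.action_weights, dtype=float)
        c = self.params.correlation
        if c > 0 and self._recency.sum() > 0:
            w = (1 - c) * w / w.sum() + c * self._recency / self._recency.sum()
        a = Action(int(self.rng.choice(_N_ACTIONS, p=w / w.sum())))
        self._recency *= 0.9
        self._recency[int(a)] += 1.0
        return a

    def act(self, obs: Observation | None = None, env=None) -> Action:
        if self._remaining <= 0:
            self._current = self._draw_action()
            self._remaining = self.draw_repeat()
        self._remaining -= 1
        return self._current

    __call__ = act


@dataclass
class HeuristicParams:
    ray_count: int = 45
    angle_span: float = 60.0
    stuck_speed: float = 0.01      # units/step, over a 5-step window
    stuck_window: int = 5
    variant: str = "forager"       # forager | operant

    def __post_init__(self):
        if self.ray_count % 2 == 0:
            raise ValueError("ray_count must be odd")


class HeuristicPolicy:
    """Raycast-steering navigator."""

    _TARGETS = {
        "forager": (Category.GOAL_POSITIVE,),
        "operant": (Category.GOAL_POSITIVE, Category.DISPENSER,
                    Category.IMMOVABLE),
    }

    def __init__(self, params: HeuristicParams | None = None, seed: int = 0):
        self.params = params or HeuristicParams()
        if self.params.variant not in self._TARGETS:
            raise ValueError(f"unknown variant {self.params.variant!r}")
        self.reset(seed)

    def reset(self, seed: int) -> None:
        self.rng = np.random.default_rng(seed)
        self._speeds: deque[float] = deque(maxlen=self.params.stuck_window)
        self._unstick: Action | None = None
        self._previous: Action = Action.FORWARDS

    def _stuck(self, speed: float) -> bool:
        self._speeds.append(speed)
        return (len(self._speeds) == self.params.stuck_window
                and max(self._speeds) < self.params.stuck_speed)

    def steer(self, matrix: np.ndarray) -> Action | None:
        """Steer toward the nearest target-category ray, or None if no
        target is visible: centre ray -> Forwards, a ray left of centre ->
        ForwardsLeft, right of centre -> ForwardsRight."""
        p = self.params
        if matrix.shape != (8, p.ray_count):
            raise ValueError(f"expected an 8 x {p.ray_count} raycast matrix, "
                             f"got {matrix.shape}")
        cats = self._TARGETS[p.variant]
        hits = np.zeros(p.ray_count, dtype=bool)
        for cat in cats:
            # earlier categories take priority (goals over structure)
            cat_hits = matrix[cat.value] > 0
            if cat_hits.any():
                hits = cat_hits
                break
        if not hits.any():
            return None
        dist = np.where(hits, matrix[7], np.inf)
        j = int(np.argmin(dist))
        centre = p.ray_count // 2
        if j == centre:
            return Action.FORWARDS
        return Action.FORWARDS_LEFT if j < centre else Action.FORWARDS_RIGHT

    def act(self, obs: Observation, env=None) -> Action:
        speed = 0.0
        if obs.proprio is not None:
            speed = float(np.linalg.norm(obs.proprio.velocity))
        if self._unstick is not None:
            if speed >= self.params.stuck_speed:
                self._unstick = None
            else:
                return self._unstick
        if self._stuck(speed):
            self._unstick = (Action.FORWARDS_LEFT if self.rng.uniform() < 0.5
                             else Action.FORWARDS_RIGHT)
            self._speeds.clear()
            return self._unstick
        action = self.steer(obs.raycast.matrix)
        if action is None:
            if self.params.variant == "operant":
                action = (Action.FORWARDS_LEFT if speed < self.params.stuck_speed
                          else self._previous)
            else:
                action = Action.LEFT
        self._previous = action
        return action

    __call__ = act


# ---------------------------------------------------------------------------
# scripted oracles
# ---------------------------------------------------------------------------

def _yaw_to(src: np.ndarray, dst_x: float, dst_z: float) -> float:
    return math.degrees(math.atan2(dst_x - src[0], dst_z - src[2])) % 360.0


def navigate_action(agent_pos: np.ndarray, agent_yaw: float,
                    target_x: float, target_z: float,
                    velocity: np.ndarray | None = None) -> Action:
    """One steering action toward a ground target: brake-and-turn for
    large bearing errors (so momentum does not carry the agent past the
    target), rotate in place at low speed, otherwise drive forwards with
    small corrections."""
    desired = _yaw_to(agent_pos, target_x, target_z)
    diff = (desired - agent_yaw + 180.0) % 360.0 - 180.0
    if abs(diff) > 30.0:
        turning = Action.RIGHT if diff > 0 else Action.LEFT
        if velocity is not None:
            speed = float(np.hypot(velocity[0], velocity[2]))
            forward = heading_vector(agent_yaw)
            if speed > 0.12 and velocity @ forward > 0:
                # still sliding forwards: thrust against the motion
                return (Action.BACKWARDS_RIGHT if diff > 0
                        else Action.BACKWARDS_LEFT)
        return turning
    if diff > 3.0:
        return Action.FORWARDS_RIGHT
    if diff < -3.0:
        return Action.FORWARDS_LEFT
    return Action.FORWARDS


class OraclePolicy:
    """Full-state scripted policy; near-optimal reference behaviour.

    ``foraging``: greedy pursuit of the nearest live positive goal.
    ``operant``: drive to the front of the spawner button, press it, then
    collect the spawned goal (detouring around the chamber walls).
    """

    def __init__(self, task: str = "foraging"):
        if task not in ("foraging", "operant"):
            raise ValueError(f"unknown oracle task {task!r}")
        self.task = task
        self.reset(0)

    def reset(self, seed: int) -> None:
        self._jam = 0
        self._sidestep = 0
        self._phase = 0

    def act(self, obs: Observation, env) -> Action:
        world = env.world
        agent = world.agent
        if self.task == "foraging":
            target = self._nearest_goal(world)
            if target is None:
                return Action.NO_ACTION
            action = navigate_action(agent.pos, agent.yaw,
                                     target.pos[0], target.pos[2], agent.vel)
            return self._unstick(agent, action)
        return self._operant_act(world, agent)

    def _unstick(self, agent, action: Action) -> Action:
        """Sidestep for a few steps when driving has stopped making
        progress (e.g. jammed against a trunk or wall)."""
        speed = float(np.hypot(agent.vel[0], agent.vel[2]))
        drives = (Action.FORWARDS, Action.FORWARDS_LEFT,
                  Action.FORWARDS_RIGHT)
        if self._sidestep > 0:
            self._sidestep -= 1
            return Action.FORWARDS_LEFT
        if action in drives and speed < 0.02:
            self._jam += 1
            if self._jam >= 5:
                self._jam = 0
                self._sidestep = 20
                return Action.FORWARDS_LEFT
        else:
            self._jam = 0
        return action

    @staticmethod
    def _nearest_goal(world):
        best, best_d = None, math.inf
        for b in world.bodies[1:]:
            if b.alive and b.info.collectible and b.info.valence_sign > 0:
                d = float(np.linalg.norm(b.pos - world.agent.pos))
                if d < best_d:
                    best, best_d = b, d
        return best

    def _operant_act(self, world, agent) -> Action:
        button = next((b for b in world.bodies
                       if b.alive and b.kind == "SpawnerButton"), None)
        goal = self._nearest_goal(world)
        if goal is not None:
            # goal spawned: leave the chamber mouth sideways first (the
            # straight line from the button crosses a chamber wall), then
            # drive directly to the goal
            target = goal.pos
            if button is not None:
                front = heading_vector(button.yaw)
                right = heading_vector(button.yaw + 90.0)
                rel = agent.pos - button.pos
                goal_side = 1.0 if float((goal.pos - button.pos) @ right) >= 0 \
                    else -1.0
                if float(rel @ front) < 3.5 and abs(float(rel @ right)) < 3.0:
                    target = button.pos + front * 4.0 + goal_side * right * 3.5
            return self._unstick(agent, navigate_action(
                agent.pos, agent.yaw, target[0], target[2], agent.vel))
        if button is None:
            return Action.NO_ACTION
        front = heading_vector(button.yaw)
        rel = agent.pos - button.pos
        along = float(rel @ front)
        if along <= 0.5:
            # beside or behind the chamber: route to a point well out in
            # front of the button first
            staging = button.pos + front * 6.0
            return self._unstick(agent, navigate_action(
                agent.pos, agent.yaw, staging[0], staging[2], agent.vel))
        # carrot-point pursuit down the button's axis: aim two units ahead
        # of the agent on the axis so the bearing error stays small and the
        # final contact is frontal
        carrot = button.pos + front * max(0.0, along - 2.0)
        return self._unstick(agent, navigate_action(
            agent.pos, agent.yaw, carrot[0], carrot[2], agent.vel))

    __call__ = act
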
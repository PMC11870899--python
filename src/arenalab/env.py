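"""Episodic environment API: reset/step with seeding, frozen-agent delays,
multi-arena episodes, pass/fail outcomes, and per-step logging.

The interface follows the familiar episodic reset/step contract:
``reset`` returns the first observation; ``step`` returns (observation,
reward delta, terminated, truncated, info).  ``terminated`` is set by an
episode-ending goal, a death zone, or health reaching zero; ``truncated``
by the time limit; never both.

In ``multi-arena-single-episode`` mode, collecting an episode-ending goal
advances the agent to the next arena of the file without resetting
cumulative reward or health; a death zone, health failure, or timeout ends
the whole episode.

Everything is deterministic under (configuration, seed, action sequence).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import interactive, schema
from .ontology import Shape, kind_info
from .physics import (Action, Body, WorldState, body_from_placed,
                      _sphere_box_contact, _solid_obstacles, step_world,
                      heading_vector, BOUNCE_SPEED)
from .observe import (CameraObs, Observation, ProprioObs, RaycastObs,
                      apply_lights_out, raycast_scan, render_camera)
from .valence import (TerminationCause, ValenceState, episode_outcome,
                      on_contact, scheduled_size, scheduled_valence,
                      step_reward_delta)

_SEED_MOD = 2**31 - 1


@dataclass(frozen=True)
class ObservationSpec:
    """Which sensory channels the environment returns."""

    raycast: bool = True
    rays: int = 45
    angle_span: float = 60.0
    camera: bool = False
    camera_k: int = 16
    grayscale: bool = False
    proprio: bool = True

    def __post_init__(self):
        if not (self.raycast or self.camera or self.proprio):
            raise ValueError("at least one observation channel is required")


@dataclass
class EnvConfig:
    config: schema.ConfigFile
    observations: ObservationSpec = field(default_factory=ObservationSpec)
    seed: int = 0


@dataclass
class StepResult:
    observation: Observation
    reward_delta: float
    terminated: bool
    truncated: bool
    info: dict


@dataclass
class EpisodeLog:
    """Per-step record of one episode plus its outcome."""

    rows: list[dict] = field(default_factory=list)
    outcome: str = "fail"
    termination_cause: str = "none"
    final_reward: float = 0.0
    steps: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for row in self.rows:
                fh.write(json.dumps(row) + "\n")
            fh.write(json.dumps({"outcome": self.outcome,
                                 "terminationCause": self.termination_cause,
                                 "finalReward": self.final_reward}) + "\n")


class ArenaEnv:
    """An episodic arena simulator driven by one configuration file."""

    def __init__(self, cfg: EnvConfig):
        self.cfg = cfg
        self.arena_indices = sorted(cfg.config.arenas)
        if not self.arena_indices:
            raise schema.ConfigError("configuration contains no arenas")
        self.multi_arena = (cfg.config.episodeMode
                            == "multi-arena-single-episode")
        self.world: WorldState | None = None
        self._done = True

    # -- episode lifecycle -------------------------------------------------

    def reset(self, arena_index: int | None = None,
              seed: int | None = None) -> Observation:
        """Start a new episode; same seed gives an identical initial state."""
        if seed is not None:
            self.cfg.seed = seed
        self._root_rng = np.random.default_rng(self.cfg.seed)
        self._episode_seed = int(self._root_rng.integers(_SEED_MOD))
        self.valence = ValenceState()
        self.log = EpisodeLog()
        self._done = False
        self._truncated = False
        self._arena_pos = (self.arena_indices.index(arena_index)
                           if arena_index is not None else 0)
        self._load_arena(self.arena_indices[self._arena_pos])
        return self._observe()

    def _load_arena(self, idx: int) -> None:
        spec = self.cfg.config.arenas[idx]
        self.arena_index = idx
        sub = np.random.default_rng((self._episode_seed, idx))
        concrete = schema.resolve_randomness(spec, int(sub.integers(_SEED_MOD)))
        if concrete.agent_index() is None:
            # the agent can spawn anywhere when the file does not place it
            concrete.objects.insert(0, schema.PlacedObject(
                name="Agent",
                position=schema.Vector3(float(sub.uniform(0.5, 39.5)), 0.0,
                                        float(sub.uniform(0.5, 39.5))),
                rotation=float(sub.uniform(0, 360))))
        concrete = schema.place_with_precedence(
            concrete, int(sub.integers(_SEED_MOD)))
        ai = concrete.agent_index()
        ordered = ([concrete.objects[ai]]
                   + [o for i, o in enumerate(concrete.objects) if i != ai])
        bodies = [body_from_placed(o) for o in ordered]
        self.world = WorldState(bodies=bodies)
        self.time_limit = spec.timeLimit
        self.frozen_steps = spec.frozenAgentDelays
        self.lights_out = spec.lightsOut
        self.pass_mark = spec.passMark
        self._rng = np.random.default_rng(
            (self._episode_seed, idx, 0xA11CE))
        self._init_interactive(bodies)
        self._init_bounce(bodies)

    def _init_interactive(self, bodies: list[Body]) -> None:
        self._spawners: dict[int, interactive.SpawnerSpec] = {}
        self._buttons: dict[int, interactive.ButtonSpec] = {}
        self._last_press: dict[int, int] = {}
        kind_map = {"SpawnerTree": "tree",
                    "SpawnerDispenserTall": "dispenserTall",
                    "SpawnerDispenserShort": "dispenserShort"}
        for i, b in enumerate(bodies):
            sp = b.special
            if b.kind in kind_map:
                base_y = b.pos[1] + b.size[1] / 2.0
                self._spawners[i] = interactive.SpawnerSpec(
                    kind=kind_map[b.kind],
                    origin=(float(b.pos[0]), float(base_y), float(b.pos[2])),
                    count=int(sp.get("count", 10)),
                    delay=int(sp.get("delay", 0)),
                    interval=int(sp.get("interval", 10)),
                    goalSize=float(sp.get("goalSize", 1.0)))
            elif b.kind == "SpawnerButton":
                pos = sp.get("spawnPosition",
                             [float(b.pos[0]), 0.0, float(b.pos[2]) + 2.0])
                if isinstance(pos, dict):
                    pos = [pos.get("x", 0), pos.get("y", 0), pos.get("z", 0)]
                self._buttons[i] = interactive.ButtonSpec(
                    spawnProbability=float(sp.get("spawnProbability", 1.0)),
                    weights=dict(sp.get("weights", {"GoodGoal": 1.0,
                                                    "GoodGoalMulti": 1.0,
                                                    "BadGoal": 1.0})),
                    spawnPosition=tuple(float(v) for v in pos),
                    resetSteps=int(sp.get("resetSteps", 0)),
                    goalSize=float(sp.get("goalSize", 1.0)))

    def _init_bounce(self, bodies: list[Body]) -> None:
        for b in bodies:
            if b.info.bounce:
                vel = b.special.get("initialVelocity")
                speed = float(b.special.get("speed", BOUNCE_SPEED))
                if vel is None:
                    direction = heading_vector(float(self._rng.uniform(0, 360)))
                else:
                    if isinstance(vel, dict):
                        vel = [vel.get("x", 0), vel.get("y", 0),
                               vel.get("z", 0)]
                    direction = np.asarray(vel, dtype=float)
                    n = np.linalg.norm(direction)
                    direction = direction / n if n > 0 else direction
                b.vel = direction * speed

    # -- stepping ----------------------------------------------------------

    def step(self, action: Action | int) -> StepResult:
        """Advance one step.  Raises if called after the episode is over."""
        if self._done:
            raise RuntimeError("step() called on a finished episode; "
                               "call reset() first")
        world = self.world
        frozen = world.step < self.frozen_steps
        applied = Action.NO_ACTION if frozen else Action(action)
        reward_before = self.valence.reward

        events = step_world(world, applied)
        self._tick_spawners()
        self._handle_presses(events.button_presses)
        self._update_schedules()
        goal_terminated = self._handle_contacts(events)

        if not frozen and not self.valence.terminated:
            self.valence.apply_delta(
                step_reward_delta(events.in_hot_zone, self.time_limit))

        truncated = False
        if self.time_limit > 0 and world.step >= self.time_limit and (
                not self.valence.terminated
                or self.valence.cause is TerminationCause.HEALTH_ZERO):
            # the health drain from the time decrement reaches zero on the
            # timeout step itself; that is a timeout, not a health failure
            truncated = True
            self.valence.terminated = True
            self.valence.cause = TerminationCause.TIMEOUT

        # multi-arena: a collected episode-ending goal advances the arena
        if (goal_terminated and self.multi_arena
                and self._arena_pos + 1 < len(self.arena_indices)):
            self._arena_pos += 1
            self.valence.terminated = False
            self.valence.cause = TerminationCause.NONE
            self._load_arena(self.arena_indices[self._arena_pos])
            goal_terminated = False

        terminated = self.valence.terminated and not truncated
        delta = self.valence.reward - reward_before
        obs = self._observe()
        info = {
            "position": tuple(float(v) for v in world.agent.pos),
            "velocity": tuple(float(v) for v in world.agent.vel),
            "health": self.valence.health,
            "arenaIndex": self.arena_index,
            "outcome": episode_outcome(self.valence.reward, self.pass_mark),
        }
        self.log.rows.append({
            "step": world.step, "arenaIndex": self.arena_index,
            "action": int(applied),
            "x": round(info["position"][0], 9),
            "y": round(info["position"][1], 9),
            "z": round(info["position"][2], 9),
            "rewardDelta": delta,
            "rewardCumulative": self.valence.reward,
            "health": self.valence.health,
        })
        if terminated or truncated:
            self._done = True
            self.log.outcome = info["outcome"]
            self.log.termination_cause = self.valence.cause.value
            self.log.final_reward = self.valence.reward
            self.log.steps = len(self.log.rows)
        return StepResult(obs, delta, terminated, truncated, info)

    # -- internals ---------------------------------------------------------

    def _spawn_goal(self, ev: interactive.SpawnEvent) -> None:
        placed = schema.PlacedObject(
            name=ev.kind,
            position=schema.Vector3(*ev.position),
            size=schema.Vector3(ev.size, ev.size, ev.size))
        body = body_from_placed(placed, spawn_step=self.world.step)
        self.world.bodies.append(body)

    def _tick_spawners(self) -> None:
        for idx in sorted(self._spawners):
            sp = self._spawners[idx]
            for ev in interactive.tick_spawner(sp, self.world.step, self._rng):
                self._spawn_goal(ev)

    def _handle_presses(self, presses: list[int]) -> None:
        for idx in sorted(set(presses)):
            if idx not in self._buttons:
                continue
            since = self.world.step - self._last_press.get(idx, -10**9)
            ev = interactive.press_button(self._buttons[idx], since, self._rng)
            if ev is not None or since >= self._buttons[idx].resetSteps:
                self._last_press[idx] = self.world.step
            if ev is not None:
                self._spawn_goal(ev)

    def _space_free(self, body: Body, new_radius: float) -> bool:
        for obstacle in _solid_obstacles(self.world, body):
            if _sphere_box_contact(body.pos, new_radius, obstacle):
                return False
        agent = self.world.agent
        gap = float(np.linalg.norm(agent.pos - body.pos))
        return gap > new_radius + agent.radius

    def _update_schedules(self) -> None:
        for b in self.world.bodies:
            if not b.alive or b.schedule is None:
                continue
            age = self.world.step - b.spawn_step
            mode = b.schedule.mode
            if mode in ("decay", "ripen"):
                b.valence = scheduled_valence(b.schedule, age)
            elif mode in ("grow", "shrink"):
                target = scheduled_size(b.schedule, age, True)
                if mode == "grow" and target > b.size[0]:
                    if self._space_free(b, target / 2.0):
                        b.size = np.full(3, target)
                else:
                    b.size = np.full(3, target)
                b.pos[1] = max(b.pos[1], b.radius)
                b.valence = b.size[0]

    def _handle_contacts(self, events) -> bool:
        """Apply goal and zone contact effects; True if an episode-ending
        goal was collected."""
        goal_end = False
        for i in events.goal_contacts:
            b = self.world.bodies[i]
            if not b.alive:
                continue
            delta, terminate, remove = on_contact(b.kind, b.valence)
            if terminate:
                # the terminal contact is the cause, even if the reward
                # swing also drains health to zero
                self.valence.terminate(TerminationCause.GOAL)
                goal_end = True
            self.valence.apply_delta(delta)
            if remove:
                b.alive = False
            if self.valence.terminated and not goal_end:
                break
        if events.in_death_zone and not self.valence.terminated:
            self.valence.terminate(TerminationCause.DEATHZONE)
            delta, _, _ = on_contact("DeathZone", 1.0)
            self.valence.apply_delta(delta)
        return goal_end

    def _observe(self) -> Observation:
        spec = self.cfg.observations
        obs = Observation()
        step = self.world.step
        if spec.raycast:
            rc = raycast_scan(self.world, spec.rays, spec.angle_span)
            obs.raycast = apply_lights_out(rc, self.lights_out, step)
        if spec.camera:
            cam = render_camera(self.world, spec.camera_k, spec.grayscale)
            obs.camera = apply_lights_out(cam, self.lights_out, step)
        if spec.proprio:
            a = self.world.agent
            obs.proprio = ProprioObs(
                health=self.valence.health,
                velocity=tuple(float(v) for v in a.vel),
                position=tuple(float(v) for v in a.pos))
        return obs


def run_episode(policy, cfg: EnvConfig, seed: int | None = None,
                max_steps: int = 5000) -> EpisodeLog:
    """Drive one full episode of ``policy`` on ``cfg`` and return its log.

    ``policy`` is either a callable ``obs -> action`` or an object with
    ``act(obs, env) -> action`` (oracles use ``env`` for full state) and an
    optional ``reset(seed)``.
    """
    env = ArenaEnv(cfg)
    obs = env.reset(seed=seed)
    if hasattr(policy, "reset"):
        policy.reset(seed if seed is not None else cfg.seed)
    for _ in range(max_steps):
        if hasattr(policy, "act"):
            action = policy.act(obs, env)
        else:
            action = policy(obs)
        result = env.step(action)
        obs = result.observation
        if result.terminated or result.truncated:
            break
    else:
        env.log.outcome = episode_outcome(env.valence.reward, env.pass_mark)
        env.log.termination_cause = "none"
        env.log.final_reward = env.valence.reward
        env.log.steps = len(env.log.rows)
    return env.log
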
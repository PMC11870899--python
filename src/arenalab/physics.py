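"""Discrete-time physics: agent actions, the force model, and collision
resolution among spheres, boxes, ramps, tunnels, and the arena walls.

The simulator advances in lock-step with agent actions (one semi-implicit
Euler substep per environment step).  The force model is the qualitative
catalogue of a simple rigid-body world: a constant gravitational pull on y,
an applied impulse when the agent drives forwards/backwards, drag opposing
velocity in proportion to a body's cross-section, ground friction opposing
horizontal motion, reaction impulses shared in proportion to mass on
collision, and normal support from the floor and from climbable ramp
surfaces.

Only translation (plus the agent's yaw) is simulated; blocks do not rotate.
Ramps are walkable inclined planes when their height:length ratio is at
most 4:1 and behave as solid obstacles otherwise.  Hemi-cylindrical tunnels
are approximated by two side walls plus a ceiling slab, leaving the passage
open.  All motion is deterministic given the state and the action.

Calibration (module constants below) targets two behaviours: a forward-
driving agent crosses the 40-unit arena in roughly 150 steps, and ramp
climbability switches exactly at the printed 4:1 ratio.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .ontology import ARENA_SIZE, Shape, kind_info
from .schema import PlacedObject
from .valence import GoalSchedule

# --- calibration constants (one place; see docs/methods.md) ---------------
GRAVITY = 0.05          # units/step^2, applied to -y
DRIVE_FORCE = 0.03      # per-step velocity impulse from Forwards/Backwards
FRICTION_MU = 0.08      # per-step horizontal velocity loss while grounded
DRAG_COEFF = 0.025      # per-step loss x body cross-section
TURN_DEGREES = 6.0      # yaw change per Left/Right component
BOUNCE_RESTITUTION = 1.0  # horizontal restitution of '-Bounce' goals
BOUNCE_SPEED = 0.25     # default initial speed of '-Bounce' goals
MAX_STEP_RISE = 1.5     # max walkable surface rise per step (units)
_EPS = 1e-9


class Action(IntEnum):
    """The nine discrete agent actions (default: NO_ACTION)."""

    NO_ACTION = 0
    FORWARDS = 1
    LEFT = 2
    RIGHT = 3
    FORWARDS_LEFT = 4
    FORWARDS_RIGHT = 5
    BACKWARDS = 6
    BACKWARDS_LEFT = 7
    BACKWARDS_RIGHT = 8


# (drive, turn): drive +1 forwards / -1 backwards; turn -1 left / +1 right
_ACTION_COMPONENTS: dict[Action, tuple[int, int]] = {
    Action.NO_ACTION: (0, 0),
    Action.FORWARDS: (1, 0),
    Action.LEFT: (0, -1),
    Action.RIGHT: (0, 1),
    Action.FORWARDS_LEFT: (1, -1),
    Action.FORWARDS_RIGHT: (1, 1),
    Action.BACKWARDS: (-1, 0),
    Action.BACKWARDS_LEFT: (-1, -1),
    Action.BACKWARDS_RIGHT: (-1, 1),
}


def heading_vector(yaw_degrees: float) -> np.ndarray:
    """Unit heading on the x-z plane; yaw 0 faces +z, positive yaw turns
    rightwards (clockwise from above)."""
    th = math.radians(yaw_degrees)
    return np.array([math.sin(th), 0.0, math.cos(th)])


@dataclass
class Body:
    """One dynamic or static entity in the world.

    ``pos`` is the geometric centre.  Spheres use ``size.x`` as diameter.
    """

    kind: str
    pos: np.ndarray
    yaw: float = 0.0
    vel: np.ndarray = field(default_factory=lambda: np.zeros(3))
    size: np.ndarray = field(default_factory=lambda: np.ones(3))
    color: tuple[int, int, int] = (153, 153, 153)
    special: dict = field(default_factory=dict)
    # valence bookkeeping (goals only)
    valence: float = 0.0
    schedule: GoalSchedule | None = None
    spawn_step: int = 0
    alive: bool = True
    grounded: bool = False

    @property
    def info(self):
        return kind_info(self.kind)

    @property
    def radius(self) -> float:
        return self.size[0] / 2.0

    @property
    def is_sphere(self) -> bool:
        return self.info.shape is Shape.SPHERE

    def snapshot(self) -> dict:
        return {
            "kind": self.kind,
            "pos": [round(float(v), 12) for v in self.pos],
            "yaw": round(float(self.yaw), 12),
            "vel": [round(float(v), 12) for v in self.vel],
            "size": [float(v) for v in self.size],
            "valence": round(float(self.valence), 12),
            "alive": self.alive,
        }


def body_from_placed(obj: PlacedObject, spawn_step: int = 0) -> Body:
    """Build a physics body from a placed configuration object."""
    info = kind_info(obj.name)
    size = np.array([obj.size.x, obj.size.y, obj.size.z], dtype=float)
    if info.shape is Shape.SPHERE:
        centre_y = obj.position.y + size[0] / 2.0
    else:
        centre_y = obj.position.y + size[1] / 2.0
    pos = np.array([obj.position.x, centre_y, obj.position.z])
    body = Body(kind=obj.name, pos=pos, yaw=obj.rotation, size=size,
                color=(obj.color.r, obj.color.g, obj.color.b),
                special=dict(obj.special), spawn_step=spawn_step)
    if info.collectible:
        sched = _schedule_from_special(obj.name, size[0], obj.special)
        body.schedule = sched
        body.valence = sched.fullValence if sched.mode in ("static", "decay") \
            else (sched.emptyValence if sched.mode == "ripen"
                  else sched.startSize)
    return body


def _schedule_from_special(name: str, diameter: float, special: dict
                           ) -> GoalSchedule:
    info = kind_info(name)
    mode = info.schedule_mode
    if mode in ("decay", "ripen"):
        return GoalSchedule(
            mode=mode,
            fullValence=float(special.get("fullValence", diameter)),
            emptyValence=float(special.get("emptyValence", 0.0)),
            delay=int(special.get("delay", 0)),
            duration=int(special.get("duration", 100)),
        )
    if mode in ("grow", "shrink"):
        return GoalSchedule(
            mode=mode,
            delay=int(special.get("delay", 0)),
            duration=int(special.get("duration", 100)),
            startSize=float(special.get("startSize", diameter)),
            endSize=float(special.get("endSize", diameter)),
        )
    return GoalSchedule(mode="static", fullValence=diameter)


@dataclass
class StepEvents:
    """Contacts produced by one physics step, consumed by the env layer."""

    goal_contacts: list[int] = field(default_factory=list)
    in_death_zone: bool = False
    in_hot_zone: bool = False
    button_presses: list[int] = field(default_factory=list)


@dataclass
class WorldState:
    """Complete dynamic state of one arena."""

    bodies: list[Body]            # agent first
    step: int = 0

    @property
    def agent(self) -> Body:
        return self.bodies[0]

    def serialise(self) -> str:
        doc = {"step": self.step,
               "bodies": [b.snapshot() for b in self.bodies if b.alive]}
        return json.dumps(doc, sort_keys=True)


# ---------------------------------------------------------------------------
# actions
# ---------------------------------------------------------------------------

def apply_action(agent: Body, action: Action | int) -> Body:
    """Apply one discrete action to the agent in place (and return it):
    each Left/Right component changes yaw by exactly -6/+6 degrees; each
    Forwards/Backwards component adds a fixed impulse along the heading."""
    try:
        action = Action(action)
    except ValueError:
        raise ValueError(f"unknown action code: {action!r}") from None
    drive, turn = _ACTION_COMPONENTS[action]
    agent.yaw = (agent.yaw + turn * TURN_DEGREES) % 360.0
    if drive:
        agent.vel = agent.vel + drive * DRIVE_FORCE * heading_vector(agent.yaw)
    return agent


def is_ramp_climbable(height: float, length: float) -> bool:
    """A ramp can be ascended iff height/length does not exceed 4:1."""
    if length <= 0:
        raise ValueError("ramp length must be positive")
    if height < 0:
        raise ValueError("ramp height must be >= 0")
    return height / length <= 4.0


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _to_local(body: Body, p: np.ndarray) -> np.ndarray:
    """World point -> body-local frame (translate then un-rotate yaw)."""
    d = p - body.pos
    th = math.radians(body.yaw)
    c, s = math.cos(th), math.sin(th)
    return np.array([c * d[0] - s * d[2], d[1], s * d[0] + c * d[2]])


def _to_world_dir(body: Body, v: np.ndarray) -> np.ndarray:
    th = math.radians(body.yaw)
    c, s = math.cos(th), math.sin(th)
    return np.array([c * v[0] + s * v[2], v[1], -s * v[0] + c * v[2]])


def ramp_surface_height(ramp: Body, p: np.ndarray,
                        extend: float = 0.0) -> float | None:
    """Height of the ramp's inclined surface under world point ``p``,
    or None when ``p`` is outside the ramp footprint.  The ramp ascends
    along its local +z axis from 0 to its full height.  ``extend`` widens
    the footprint past the top edge (sphere-vs-edge contact: a sphere of
    that radius still rests on the top corner just beyond it)."""
    local = _to_local(ramp, p)
    hx, hy, hz = ramp.size / 2.0
    if abs(local[0]) > hx or not (-hz <= local[2] <= hz + extend):
        return None
    frac = min(1.0, (local[2] + hz) / (2.0 * hz))
    base = ramp.pos[1] - hy
    return base + frac * ramp.size[1]


def _point_in_box(body: Body, p: np.ndarray) -> bool:
    local = _to_local(body, p)
    return bool(np.all(np.abs(local) <= body.size / 2.0 + _EPS))


def _tunnel_parts(t: Body) -> list[tuple[np.ndarray, np.ndarray]]:
    """Local-frame (centre, half-size) boxes for a tunnel: two side walls
    and a ceiling slab; passage runs along local z."""
    hx, hy, hz = t.size / 2.0
    wall_t = max(0.1, 0.15 * t.size[0])
    return [
        (np.array([-hx + wall_t / 2, 0.0, 0.0]),
         np.array([wall_t / 2, hy, hz])),
        (np.array([hx - wall_t / 2, 0.0, 0.0]),
         np.array([wall_t / 2, hy, hz])),
        (np.array([0.0, hy - wall_t / 2, 0.0]),
         np.array([hx, wall_t / 2, hz])),
    ]


def _sphere_box_contact(sphere_pos: np.ndarray, radius: float, box: Body,
                        local_centre: np.ndarray | None = None,
                        local_half: np.ndarray | None = None):
    """Closest-point sphere-vs-oriented-box test.

    Returns ``(penetration depth, world-frame outward normal)`` or None.
    """
    local = _to_local(box, sphere_pos)
    centre = local_centre if local_centre is not None else np.zeros(3)
    half = local_half if local_half is not None else box.size / 2.0
    d = local - centre
    clamped = np.clip(d, -half, half)
    diff = d - clamped
    dist2 = float(diff @ diff)
    if dist2 > radius * radius:
        return None
    if dist2 > _EPS:
        dist = math.sqrt(dist2)
        normal_local = diff / dist
        return radius - dist, _to_world_dir(box, normal_local)
    # centre inside the box: push out along the axis of least penetration
    over = half - np.abs(d)
    axis = int(np.argmin(over))
    normal_local = np.zeros(3)
    normal_local[axis] = 1.0 if d[axis] >= 0 else -1.0
    return radius + float(over[axis]), _to_world_dir(box, normal_local)


# ---------------------------------------------------------------------------
# the transition function
# ---------------------------------------------------------------------------

def _cross_section(b: Body) -> float:
    if b.is_sphere:
        return math.pi * b.radius ** 2
    return float(b.size[0] * b.size[1])


def _ground_height(state: WorldState, p: np.ndarray,
                   climbable_ramps: list[Body],
                   extend: float = 0.0) -> float:
    g = 0.0
    for ramp in climbable_ramps:
        h = ramp_surface_height(ramp, p, extend)
        if h is not None:
            g = max(g, h)
    return g


def _solid_obstacles(state: WorldState, mover: Body) -> list[Body]:
    out = []
    for b in state.bodies:
        if b is mover or not b.alive:
            continue
        info = b.info
        if not info.solid:
            continue
        if info.shape is Shape.SPHERE:
            continue  # sphere-sphere handled as goal contact / ignore
        out.append(b)
    return out


def _resolve_sphere_world(state: WorldState, body: Body,
                          climbable: set[int], events: StepEvents,
                          is_agent: bool) -> None:
    """Push a moving sphere out of walls, boxes, ramps and tunnels."""
    restitution = BOUNCE_RESTITUTION if body.info.bounce else 0.0
    for obstacle in _solid_obstacles(state, body):
        shape = obstacle.info.shape
        oid = id(obstacle)
        contacts = []
        if shape is Shape.TUNNEL:
            for centre, half in _tunnel_parts(obstacle):
                c = _sphere_box_contact(body.pos, body.radius, obstacle,
                                        centre, half)
                if c:
                    contacts.append(c)
        elif shape is Shape.RAMP and oid in climbable:
            continue  # walkable surface, handled as ground support
        else:
            c = _sphere_box_contact(body.pos, body.radius, obstacle)
            if c:
                contacts.append(c)
        for depth, normal in contacts:
            if is_agent and obstacle.kind == "SpawnerButton":
                # a press requires contact with the front (local +z) face
                if _to_world_dir(obstacle, np.array([0.0, 0.0, 1.0])) @ \
                        normal > 0.7:
                    events.button_presses.append(
                        state.bodies.index(obstacle))
            if obstacle.info.movable:
                share = body.info.mass / (body.info.mass + obstacle.info.mass)
                obstacle.pos = obstacle.pos - normal * depth * share
                vn = float(body.vel @ normal)
                if vn < 0:
                    obstacle.vel = obstacle.vel + normal * vn * share
                body.pos = body.pos + normal * depth * (1 - share)
                _clamp_to_arena(obstacle)
            else:
                body.pos = body.pos + normal * depth
            vn = float(body.vel @ normal)
            if vn < 0:
                body.vel = body.vel - (1.0 + restitution) * vn * normal


def _clamp_to_arena(body: Body, restitution: float = 0.0) -> None:
    if body.is_sphere:
        half_x = half_z = body.radius
    else:
        th = math.radians(body.yaw)
        c, s = abs(math.cos(th)), abs(math.sin(th))
        half_x = body.size[0] / 2 * c + body.size[2] / 2 * s
        half_z = body.size[0] / 2 * s + body.size[2] / 2 * c
    for axis, half in ((0, half_x), (2, half_z)):
        lo, hi = half, ARENA_SIZE - half
        if body.pos[axis] < lo:
            body.pos[axis] = lo
            if body.vel[axis] < 0:
                body.vel[axis] = -restitution * body.vel[axis]
        elif body.pos[axis] > hi:
            body.pos[axis] = hi
            if body.vel[axis] > 0:
                body.vel[axis] = -restitution * body.vel[axis]


def _integrate_body(state: WorldState, body: Body,
                    climbable_ramps: list[Body]) -> None:
    body.vel = body.vel.copy()
    body.vel[1] -= GRAVITY
    drag = max(0.0, 1.0 - DRAG_COEFF * _cross_section(body))
    body.vel = body.vel * drag
    if body.grounded and not body.info.bounce:
        # '-Bounce' goals roll: drag only, no ground friction
        body.vel[0] *= (1.0 - FRICTION_MU)
        body.vel[2] *= (1.0 - FRICTION_MU)
    body.pos = body.pos + body.vel
    # ground / ramp-surface support
    half_h = body.radius if body.is_sphere else body.size[1] / 2.0
    ground = _ground_height(state, body.pos, climbable_ramps,
                            extend=body.radius if body.is_sphere else 0.0)
    # support only lifts a body by a bounded amount per step (gradual
    # ascent up a slope); a taller rise is a face, not a walkable surface
    if ground - (body.pos[1] - half_h) > MAX_STEP_RISE:
        ground = 0.0
    if body.pos[1] - half_h <= ground + 1e-6:
        body.pos[1] = ground + half_h
        if body.vel[1] < 0:
            body.vel[1] = 0.0
        body.grounded = True
    else:
        body.grounded = False
    restitution = BOUNCE_RESTITUTION if body.info.bounce else 0.0
    _clamp_to_arena(body, restitution)


def step_world(state: WorldState, action: Action | int) -> StepEvents:
    """Advance the world one step in place and return the contact events.

    Order: agent action, then integration (gravity, drag, friction,
    position), then collision resolution, then contact detection.
    Deterministic given (state, action).
    """
    agent = state.agent
    apply_action(agent, action)

    climbable_ramps = [
        b for b in state.bodies
        if b.alive and b.info.shape is Shape.RAMP
        and is_ramp_climbable(b.size[1], b.size[2])
    ]
    climbable_ids = {id(b) for b in climbable_ramps}

    events = StepEvents()
    movers = [b for b in state.bodies
              if b.alive and (b.is_sphere or b.info.movable)]
    for body in movers:
        _integrate_body(state, body, climbable_ramps)
    for body in movers:
        if body.is_sphere:
            _resolve_sphere_world(state, body, climbable_ids, events,
                                  is_agent=body is agent)

    # agent contact with valenced goals (sphere-sphere)
    for i, b in enumerate(state.bodies):
        if b is agent or not b.alive or not b.info.collectible:
            continue
        gap = float(np.linalg.norm(agent.pos - b.pos))
        if gap <= agent.radius + b.radius + 1e-6:
            events.goal_contacts.append(i)

    # zone containment (agent centre inside the zone volume)
    for b in state.bodies:
        if not b.alive or b.info.shape is not Shape.ZONE:
            continue
        if _point_in_box(b, agent.pos):
            if b.kind == "DeathZone":
                events.in_death_zone = True
            elif b.kind == "HotZone":
                events.in_hot_zone = True
    if events.in_death_zone:
        events.in_hot_zone = False  # death zone takes precedence

    state.step += 1
    return events
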
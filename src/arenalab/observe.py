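"""Observation models: raycast scans, flat-shaded ray-grid camera images,
grayscale, lights-out masking, and proprioceptive channels.

Raycasts fan out on the agent's horizontal (x-z) plane: the centre ray
points directly ahead and the remaining rays spread evenly over the
configured angular span, ordered left to right.  Each ray reports the
category of the nearest intersected object as a one-hot code plus its
normalised distance, as an 8 x r matrix (6 category rows, a no-hit row,
and a distance row); r must be odd so a centre ray exists.

The camera is a k x k grid of view rays from the agent's eye with flat
shading (each object's configured colour; constant sky/floor/fence
colours); grayscale collapses it to a k x k luminance matrix.  Transparent
walls and tunnels are invisible to the camera colour pass but do register
on raycasts as immovable obstacles.

Lights-out windows replace every visual value with zero; proprioceptive
channels (health, velocity, position) are unaffected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ontology import ARENA_SIZE, Category, Shape, TRANSPARENT_KINDS, kind_info
from .physics import Body, WorldState, heading_vector
from .schema import LightsOut

RAY_LENGTH = 60.0        # max ray reach; covers the arena diagonal (~56.6)
N_CATEGORIES = 6
SKY_COLOR = (135, 206, 235)
FLOOR_COLOR = (200, 200, 200)
FENCE_COLOR = (245, 245, 245)


@dataclass
class RaycastObs:
    """8 x r ray matrix; column j is the j-th ray from the left."""

    matrix: np.ndarray
    angleSpan: float

    @property
    def r(self) -> int:
        return self.matrix.shape[1]

    def distances(self) -> np.ndarray:
        return self.matrix[7]

    def category_hits(self, category: Category) -> np.ndarray:
        return self.matrix[category.value] > 0


@dataclass
class CameraObs:
    """k x k x 3 RGB image, or k x k when grayscale."""

    image: np.ndarray

    @property
    def k(self) -> int:
        return self.image.shape[0]

    @property
    def grayscale(self) -> bool:
        return self.image.ndim == 2


@dataclass
class ProprioObs:
    health: float
    velocity: tuple[float, float, float]
    position: tuple[float, float, float]


@dataclass
class Observation:
    """Per-step sensory bundle; channels are present per the env config."""

    raycast: RaycastObs | None = None
    camera: CameraObs | None = None
    proprio: ProprioObs | None = None


# ---------------------------------------------------------------------------
# ray-primitive intersections
# ---------------------------------------------------------------------------

def _ray_sphere(origin: np.ndarray, direction: np.ndarray,
                centre: np.ndarray, radius: float) -> float | None:
    oc = origin - centre
    b = float(oc @ direction)
    c = float(oc @ oc) - radius * radius
    disc = b * b - c
    if disc < 0:
        return None
    t = -b - math.sqrt(disc)
    if t < 1e-9:
        return None
    return t


def _ray_obb(origin: np.ndarray, direction: np.ndarray,
             body: Body) -> float | None:
    """Slab test against a y-rotated box; returns entry distance."""
    th = math.radians(body.yaw)
    c, s = math.cos(th), math.sin(th)
    d = origin - body.pos
    o_local = np.array([c * d[0] - s * d[2], d[1], s * d[0] + c * d[2]])
    d_local = np.array([c * direction[0] - s * direction[2], direction[1],
                        s * direction[0] + c * direction[2]])
    half = body.size / 2.0
    t_near, t_far = 0.0, math.inf
    for axis in range(3):
        if abs(d_local[axis]) < 1e-12:
            if abs(o_local[axis]) > half[axis]:
                return None
            continue
        t1 = (-half[axis] - o_local[axis]) / d_local[axis]
        t2 = (half[axis] - o_local[axis]) / d_local[axis]
        if t1 > t2:
            t1, t2 = t2, t1
        t_near, t_far = max(t_near, t1), min(t_far, t2)
        if t_near > t_far:
            return None
    return t_near if t_near > 1e-9 else None


def _ray_body(origin: np.ndarray, direction: np.ndarray,
              body: Body) -> float | None:
    if body.info.shape is Shape.SPHERE:
        return _ray_sphere(origin, direction, body.pos, body.radius)
    return _ray_obb(origin, direction, body)


def _visible_bodies(world: WorldState, *, for_camera: bool) -> list[Body]:
    out = []
    for b in world.bodies[1:]:
        if not b.alive:
            continue
        if b.info.category is None:
            continue
        if for_camera and b.kind in TRANSPARENT_KINDS:
            continue
        out.append(b)
    return out


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def ray_angles(r: int, angle_span: float) -> np.ndarray:
    """Ray offsets in degrees, left to right, centre ray at 0."""
    if r % 2 == 0 or r < 1:
        raise ValueError("ray count must be odd and >= 1")
    if not (0 < angle_span <= 360):
        raise ValueError("angleSpan must be in (0, 360]")
    if r == 1:
        return np.zeros(1)
    half = (r - 1) // 2
    return (np.arange(r) - half) * (angle_span / (r - 1))  # centre exactly 0


def raycast_scan(world: WorldState, r: int, angle_span: float) -> RaycastObs:
    """Scan ``r`` rays over ``angle_span`` degrees about the agent heading.

    Matrix rows: 0-5 category one-hot (positive goal, negative goal/zone,
    immovable, movable, dispenser/button, signboard), 6 no-hit flag,
    7 distance normalised by the 60-unit ray length.
    """
    agent = world.agent
    matrix = np.zeros((8, r))
    bodies = _visible_bodies(world, for_camera=False)
    origin = agent.pos.copy()
    for j, offset in enumerate(ray_angles(r, angle_span)):
        direction = heading_vector(agent.yaw + offset)
        best_t, best_cat = None, None
        for b in bodies:
            t = _ray_body(origin, direction, b)
            if t is not None and t <= RAY_LENGTH and (best_t is None
                                                     or t < best_t):
                best_t, best_cat = t, b.info.category
        if best_t is None:
            matrix[N_CATEGORIES, j] = 1.0
        else:
            matrix[best_cat.value, j] = 1.0
            matrix[7, j] = best_t / RAY_LENGTH
    return RaycastObs(matrix=matrix, angleSpan=angle_span)


def render_camera(world: WorldState, k: int,
                  grayscale: bool = False) -> CameraObs:
    """Flat-shaded first-person image from a k x k grid of view rays."""
    if not (4 <= k <= 512):
        raise ValueError("camera resolution k must satisfy 4 <= k <= 512")
    agent = world.agent
    fov = 60.0
    bodies = _visible_bodies(world, for_camera=True)
    img = np.zeros((k, k, 3), dtype=np.uint8)
    origin = agent.pos.copy()
    half = (k - 1) / 2.0
    for row in range(k):
        pitch = -fov * (row - half) / k       # top rows look up
        for col in range(k):
            yaw_off = fov * (col - half) / k
            d = heading_vector(agent.yaw + yaw_off)
            cp = math.cos(math.radians(pitch))
            direction = np.array([d[0] * cp, math.sin(math.radians(pitch)),
                                  d[2] * cp])
            best_t, color = None, None
            for b in bodies:
                t = _ray_body(origin, direction, b)
                if t is not None and t <= RAY_LENGTH and (best_t is None
                                                         or t < best_t):
                    best_t, color = t, b.color
            # floor / fence / sky background
            if direction[1] < -1e-9:
                t_floor = -origin[1] / direction[1]
                if best_t is None or t_floor < best_t:
                    p = origin + t_floor * direction
                    if 0 <= p[0] <= ARENA_SIZE and 0 <= p[2] <= ARENA_SIZE:
                        color = FLOOR_COLOR
            if color is None:
                t_fence = _fence_distance(origin, direction)
                color = FENCE_COLOR if t_fence is not None else SKY_COLOR
            img[row, col] = color
    if grayscale:
        lum = (0.299 * img[..., 0] + 0.587 * img[..., 1]
               + 0.114 * img[..., 2])
        return CameraObs(image=lum.astype(np.uint8))
    return CameraObs(image=img)


_FENCE_HEIGHT = 2.0


def _fence_distance(origin: np.ndarray, direction: np.ndarray) -> float | None:
    best = None
    for axis, bound in ((0, 0.0), (0, ARENA_SIZE), (2, 0.0), (2, ARENA_SIZE)):
        if abs(direction[axis]) < 1e-12:
            continue
        t = (bound - origin[axis]) / direction[axis]
        if t <= 1e-9:
            continue
        p = origin + t * direction
        other = 2 - axis
        if 0 <= p[other] <= ARENA_SIZE and 0 <= p[1] <= _FENCE_HEIGHT:
            best = t if best is None else min(best, t)
    return best


def apply_lights_out(obs: RaycastObs | CameraObs,
                     schedule: LightsOut | None, step: int):
    """Zero every visual value when ``step`` falls in a lights-out window.

    Idempotent; with no schedule this is the identity.  Proprioceptive
    channels are never masked.
    """
    if schedule is None or not schedule.is_dark(step):
        return obs
    if isinstance(obs, RaycastObs):
        return RaycastObs(matrix=np.zeros_like(obs.matrix),
                          angleSpan=obs.angleSpan)
    return CameraObs(image=np.zeros_like(obs.image))
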
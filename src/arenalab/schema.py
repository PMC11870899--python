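"""Arena configuration: domain types, YAML read/write, validation,
randomness resolution, overlap detection, precedence placement.

A configuration file describes one or more arenas.  Each arena is a 40x40
unit floor with four walls, a time limit, a pass mark, and an ordered list
of object specifications.  Coordinates are (x, y, z) with y vertical.

Positions, rotations, sizes and colours may be randomised: either with the
explicit ``random`` token (canonical) or with the conventional sentinel
value ``-1`` in a coordinate field.  Randomisation is resolved with a seed,
reproducibly, by :func:`resolve_randomness`.

Object order in the file defines placement precedence: the agent is always
placed first, then objects in file order; a later object that overlaps an
already-placed solid is relocated to a free spot.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .ontology import ARENA_SIZE, Shape, is_known_kind, kind_info

__all__ = [
    "Vector3", "ColorRGB", "RandomToken", "LightsOut", "ObjectSpec",
    "ArenaSpec", "ConfigFile", "PlacedObject", "ConcreteArena",
    "ConfigError", "PlacementError",
    "parse_config", "write_config", "resolve_randomness",
    "detect_overlaps", "place_with_precedence",
]


class ConfigError(ValueError):
    """Raised for malformed or invalid configuration input."""


class PlacementError(RuntimeError):
    """Raised when no overlap-free location can be found for an object."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Vector3:
    x: float
    y: float
    z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    def __iter__(self):
        return iter((self.x, self.y, self.z))


@dataclass(frozen=True)
class ColorRGB:
    r: int
    g: int
    b: int

    def __post_init__(self):
        for ch in (self.r, self.g, self.b):
            if not (0 <= ch <= 255):
                raise ConfigError(f"colour channel {ch} outside [0, 255]")


@dataclass(frozen=True)
class RandomToken:
    """A deferred random draw inside a configuration.

    ``kind`` is one of ``random-scalar``, ``random-position``,
    ``random-rotation``, ``random-color``.  ``bounds`` optionally narrows
    the draw; ``fixed`` pins individual axes of a position token.
    """

    kind: str
    bounds: tuple[float, float] | None = None
    fixed: tuple[tuple[str, float], ...] = ()

    def fixed_axes(self) -> dict[str, float]:
        return dict(self.fixed)


@dataclass(frozen=True)
class LightsOut:
    """Lights-out schedule: explicit step intervals or an alternating period.

    With ``intervals``, visual observations are zeroed for steps in any
    half-open interval ``[a, b)``.  With ``period`` p, lights are on for
    steps [0, p), off for [p, 2p), and so on.
    """

    intervals: tuple[tuple[int, int], ...] = ()
    period: int = 0

    def is_dark(self, step: int) -> bool:
        if self.period > 0:
            return (step // self.period) % 2 == 1
        return any(a <= step < b for a, b in self.intervals)


@dataclass
class ObjectSpec:
    """Declarative description of one or more instances of an object kind."""

    name: str
    positions: list[Vector3 | RandomToken] = field(default_factory=list)
    rotations: list[float | RandomToken] = field(default_factory=list)
    sizes: list[Vector3 | RandomToken] = field(default_factory=list)
    colors: list[ColorRGB | RandomToken] = field(default_factory=list)
    special: dict = field(default_factory=dict)

    def instance_count(self) -> int:
        return max(1, len(self.positions), len(self.rotations),
                   len(self.sizes), len(self.colors))


@dataclass
class ArenaSpec:
    timeLimit: int = 250
    passMark: float = 0.0
    frozenAgentDelays: int = 0
    lightsOut: LightsOut | None = None
    objects: list[ObjectSpec] = field(default_factory=list)


@dataclass
class ConfigFile:
    arenas: dict[int, ArenaSpec] = field(default_factory=dict)
    episodeMode: str = "sequential-episodes"
    warnings: list[str] = field(default_factory=list, compare=False)


@dataclass
class PlacedObject:
    """One concrete object instance: every random token resolved."""

    name: str
    position: Vector3
    rotation: float = 0.0
    size: Vector3 | None = None
    color: ColorRGB | None = None
    special: dict = field(default_factory=dict)

    def __post_init__(self):
        info = kind_info(self.name)
        if self.size is None:
            self.size = Vector3(*info.default_size)
        if self.color is None:
            self.color = ColorRGB(*info.default_color)

    def is_sphere(self) -> bool:
        return kind_info(self.name).shape is Shape.SPHERE

    def centre(self) -> np.ndarray:
        half_h = self.size.x / 2 if self.is_sphere() else self.size.y / 2
        return self.position.as_array() + np.array([0.0, half_h, 0.0])

    def y_interval(self) -> tuple[float, float]:
        c = self.centre()
        half_h = self.size.x / 2 if self.is_sphere() else self.size.y / 2
        return c[1] - half_h, c[1] + half_h

    def footprint_corners(self) -> np.ndarray:
        """The four ground-plane corners of the y-rotated footprint."""
        th = math.radians(self.rotation)
        c, s = math.cos(th), math.sin(th)
        hx, hz = self.size.x / 2, self.size.z / 2
        centre = self.centre()
        corners = []
        for sx, sz in ((-1, -1), (1, -1), (1, 1), (-1, 1)):
            lx, lz = sx * hx, sz * hz
            corners.append([centre[0] + c * lx + s * lz,
                            centre[2] - s * lx + c * lz])
        return np.array(corners)

    # conservative footprint: axis-aligned box enclosing the y-rotated box
    def aabb(self) -> tuple[np.ndarray, np.ndarray]:
        info = kind_info(self.name)
        hx, hy, hz = self.size.x / 2, self.size.y / 2, self.size.z / 2
        if info.shape is Shape.SPHERE:
            r = self.size.x / 2
            half = np.array([r, r, r])
        else:
            th = math.radians(self.rotation)
            c, s = abs(math.cos(th)), abs(math.sin(th))
            half = np.array([hx * c + hz * s, hy, hx * s + hz * c])
        return self.centre() - half, self.centre() + half


@dataclass
class ConcreteArena:
    """An :class:`ArenaSpec` with all randomness resolved and instances
    expanded, ready for the physics layer."""

    timeLimit: int = 250
    passMark: float = 0.0
    frozenAgentDelays: int = 0
    lightsOut: LightsOut | None = None
    objects: list[PlacedObject] = field(default_factory=list)

    def agent_index(self) -> int | None:
        for i, o in enumerate(self.objects):
            if o.name == "Agent":
                return i
        return None


# ---------------------------------------------------------------------------
# YAML parsing
# ---------------------------------------------------------------------------

_ARENA_KEYS = {"timeLimit", "passMark", "frozenAgentDelays", "lightsOut",
               "items"}
_ITEM_KEYS = {"name", "positions", "rotations", "sizes", "colors", "special"}

_RANDOM_STRINGS = {"random"}


def _is_random_scalar(v) -> bool:
    return (isinstance(v, str) and v.lower() in _RANDOM_STRINGS) or v == -1


def _parse_component(v, what: str):
    """Scalar field: number, 'random', -1, or {random: [lo, hi]}."""
    if isinstance(v, dict) and set(v) == {"random"}:
        lo, hi = v["random"]
        return RandomToken("random-scalar", bounds=(float(lo), float(hi)))
    if _is_random_scalar(v):
        return RandomToken("random-scalar")
    if isinstance(v, (int, float)):
        return float(v)
    raise ConfigError(f"cannot interpret {what} value {v!r}")


def _parse_position(v):
    if _is_random_scalar(v):
        return RandomToken("random-position")
    if isinstance(v, dict):
        comps = {}
        for ax in ("x", "y", "z"):
            comps[ax] = _parse_component(v.get(ax, 0.0), f"position {ax}")
        if any(isinstance(c, RandomToken) for c in comps.values()):
            fixed = tuple((ax, c) for ax, c in comps.items()
                          if not isinstance(c, RandomToken))
            return RandomToken("random-position", fixed=fixed)
        return Vector3(comps["x"], comps["y"], comps["z"])
    if isinstance(v, (list, tuple)) and len(v) == 3:
        return _parse_position({"x": v[0], "y": v[1], "z": v[2]})
    raise ConfigError(f"cannot interpret position {v!r}")


def _parse_rotation(v):
    if _is_random_scalar(v):
        return RandomToken("random-rotation")
    r = _parse_component(v, "rotation")
    if isinstance(r, RandomToken):
        return RandomToken("random-rotation", bounds=r.bounds)
    return r % 360.0


def _parse_size(v):
    if _is_random_scalar(v):
        return RandomToken("random-scalar")
    if isinstance(v, (int, float)):
        return Vector3(float(v), float(v), float(v))
    if isinstance(v, dict) and set(v) == {"random"}:
        lo, hi = v["random"]
        return RandomToken("random-scalar", bounds=(float(lo), float(hi)))
    p = _parse_position(v)
    if isinstance(p, RandomToken):
        raise ConfigError("per-axis random sizes are not supported; "
                          "use a scalar {random: [lo, hi]} token")
    return p


def _parse_color(v):
    if _is_random_scalar(v):
        return RandomToken("random-color")
    if isinstance(v, dict):
        return ColorRGB(int(v.get("r", 0)), int(v.get("g", 0)),
                        int(v.get("b", 0)))
    if isinstance(v, (list, tuple)) and len(v) == 3:
        return ColorRGB(int(v[0]), int(v[1]), int(v[2]))
    raise ConfigError(f"cannot interpret colour {v!r}")


def _parse_lights_out(v) -> LightsOut:
    if isinstance(v, dict):
        if "period" in v:
            return LightsOut(period=int(v["period"]))
        if "intervals" in v:
            ivs = tuple((int(a), int(b)) for a, b in v["intervals"])
            return LightsOut(intervals=ivs)
    raise ConfigError(f"cannot interpret lightsOut schedule {v!r}")


# per-kind allowed `special` keys
_SPECIAL_KEYS = {
    "SpawnerTree": {"count", "delay", "interval", "goalSize"},
    "SpawnerDispenserTall": {"count", "delay", "interval", "goalSize"},
    "SpawnerDispenserShort": {"count", "delay", "interval", "goalSize"},
    "SpawnerButton": {"spawnProbability", "weights", "spawnPosition",
                      "resetSteps", "goalSize"},
    "SignBoard": {"symbol", "grid"},
    "RipenGoal": {"fullValence", "emptyValence", "delay", "duration"},
    "DecayGoal": {"fullValence", "emptyValence", "delay", "duration"},
    "GrowGoal": {"delay", "duration", "startSize", "endSize"},
    "ShrinkGoal": {"delay", "duration", "startSize", "endSize"},
}
for _k in ("GoodGoalBounce", "GoodGoalMultiBounce", "BadGoalBounce",
           "BadGoalMultiBounce", "DecoyGoalBounce"):
    _SPECIAL_KEYS[_k] = {"initialVelocity", "speed"}


def _parse_item(raw: dict, warnings: list[str]) -> ObjectSpec:
    if "name" not in raw:
        raise ConfigError("object item missing required key 'name'")
    name = str(raw["name"])
    if not is_known_kind(name):
        raise ConfigError(f"unknown object kind: {name!r}")
    for key in raw:
        if key not in _ITEM_KEYS:
            warnings.append(f"unknown key {key!r} on object {name}")
    spec = ObjectSpec(name=name)
    spec.positions = [_parse_position(p) for p in raw.get("positions", [])]
    spec.rotations = [_parse_rotation(r) for r in raw.get("rotations", [])]
    spec.sizes = [_parse_size(s) for s in raw.get("sizes", [])]
    colors = [_parse_color(c) for c in raw.get("colors", [])]
    if colors and kind_info(name).fixed_color:
        warnings.append(f"colours ignored for fixed-colour kind {name}")
        colors = []
    spec.colors = colors
    special = dict(raw.get("special", {}))
    allowed = _SPECIAL_KEYS.get(name, set())
    for key in special:
        if key not in allowed:
            warnings.append(f"unknown special parameter {key!r} for {name}")
    spec.special = special
    lens = [len(v) for v in (spec.positions, spec.rotations, spec.sizes,
                             spec.colors) if v]
    if lens and len(set(lens)) > 1:
        raise ConfigError(
            f"object {name}: non-empty instance lists differ in length {lens}")
    return spec


def parse_config(yaml_text: str) -> ConfigFile:
    """Parse a YAML configuration document into a :class:`ConfigFile`.

    Defaults are filled (timeLimit 250, passMark 0, frozenAgentDelays 0);
    unknown keys are recorded on ``ConfigFile.warnings``.
    """
    try:
        raw = yaml.safe_load(io.StringIO(yaml_text))
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigError(f"malformed YAML{line}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("top level of a configuration must be a mapping")

    warnings: list[str] = []
    cfg = ConfigFile()
    for key in raw:
        if key not in {"arenas", "episodeMode"}:
            warnings.append(f"unknown top-level key {key!r}")
    mode = raw.get("episodeMode", "sequential-episodes")
    if mode not in {"sequential-episodes", "multi-arena-single-episode"}:
        raise ConfigError(f"unknown episodeMode {mode!r}")
    cfg.episodeMode = mode

    arenas_raw = raw.get("arenas", {})
    if isinstance(arenas_raw, list):
        arenas_raw = dict(enumerate(arenas_raw))
    for idx, araw in arenas_raw.items():
        idx = int(idx)
        if idx < 0:
            raise ConfigError(f"arena index {idx} must be non-negative")
        araw = araw or {}
        for key in araw:
            if key not in _ARENA_KEYS:
                warnings.append(f"unknown arena key {key!r} (arena {idx})")
        arena = ArenaSpec(
            timeLimit=int(araw.get("timeLimit", 250)),
            passMark=float(araw.get("passMark", 0.0)),
            frozenAgentDelays=int(araw.get("frozenAgentDelays", 0)),
        )
        if arena.timeLimit < 0 or arena.frozenAgentDelays < 0:
            raise ConfigError("timeLimit and frozenAgentDelays must be >= 0")
        if "lightsOut" in araw and araw["lightsOut"] is not None:
            arena.lightsOut = _parse_lights_out(araw["lightsOut"])
        arena.objects = [_parse_item(item, warnings)
                         for item in (araw.get("items") or [])]
        cfg.arenas[idx] = arena

    cfg.warnings = warnings
    return cfg


# ---------------------------------------------------------------------------
# YAML writing
# ---------------------------------------------------------------------------

def _dump_scalar(v):
    if isinstance(v, RandomToken):
        if v.bounds is not None:
            return {"random": [v.bounds[0], v.bounds[1]]}
        return "random"
    return v


def _dump_position(p):
    if isinstance(p, RandomToken):
        fixed = p.fixed_axes()
        if not fixed and p.bounds is None:
            return "random"
        out = {}
        for ax in ("x", "y", "z"):
            out[ax] = fixed[ax] if ax in fixed else "random"
        return out
    return {"x": p.x, "y": p.y, "z": p.z}


def _dump_size(s):
    if isinstance(s, RandomToken):
        return _dump_scalar(s)
    return {"x": s.x, "y": s.y, "z": s.z}


def _dump_color(c):
    if isinstance(c, RandomToken):
        return "random"
    return {"r": c.r, "g": c.g, "b": c.b}


def write_config(cfg: ConfigFile) -> str:
    """Serialise a :class:`ConfigFile` to YAML; inverse of
    :func:`parse_config` (round-trip safe, tokens preserved)."""
    doc: dict = {"arenas": {}}
    if cfg.episodeMode != "sequential-episodes":
        doc["episodeMode"] = cfg.episodeMode
    for idx in sorted(cfg.arenas):
        arena = cfg.arenas[idx]
        araw: dict = {
            "timeLimit": arena.timeLimit,
            "passMark": arena.passMark,
            "frozenAgentDelays": arena.frozenAgentDelays,
        }
        if arena.lightsOut is not None:
            lo = arena.lightsOut
            araw["lightsOut"] = ({"period": lo.period} if lo.period > 0
                                 else {"intervals": [list(iv)
                                                     for iv in lo.intervals]})
        items = []
        for obj in arena.objects:
            item: dict = {"name": obj.name}
            if obj.positions:
                item["positions"] = [_dump_position(p) for p in obj.positions]
            if obj.rotations:
                item["rotations"] = [_dump_scalar(r) for r in obj.rotations]
            if obj.sizes:
                item["sizes"] = [_dump_size(s) for s in obj.sizes]
            if obj.colors:
                item["colors"] = [_dump_color(c) for c in obj.colors]
            if obj.special:
                item["special"] = obj.special
            items.append(item)
        if items:
            araw["items"] = items
        doc["arenas"][idx] = araw
    return yaml.safe_dump(doc, sort_keys=False, default_flow_style=False)


# ---------------------------------------------------------------------------
# randomness resolution
# ---------------------------------------------------------------------------

def _legal_xz(half: float) -> tuple[float, float]:
    lo, hi = half, ARENA_SIZE - half
    if lo > hi:
        raise ConfigError("object too large for the arena")
    return lo, hi


def _resolve_position(tok: RandomToken, rng: np.random.Generator,
                      half_x: float, half_z: float) -> Vector3:
    fixed = tok.fixed_axes()
    if tok.bounds is not None:
        lo, hi = tok.bounds
        if not (0 <= lo <= hi <= ARENA_SIZE):
            raise ConfigError(f"position bounds {tok.bounds} outside arena")
    out = {}
    for ax, half in (("x", half_x), ("z", half_z)):
        if ax in fixed:
            out[ax] = fixed[ax]
        else:
            lo, hi = tok.bounds if tok.bounds is not None else _legal_xz(half)
            out[ax] = float(rng.uniform(lo, hi))
    out["y"] = fixed.get("y", 0.0)
    return Vector3(out["x"], out["y"], out["z"])


def resolve_randomness(spec: ArenaSpec, seed: int) -> ConcreteArena:
    """Replace every random token with a concrete draw and expand object
    specs into per-instance :class:`PlacedObject` entries.

    Positions are drawn uniformly over the legal arena area, rotations
    uniformly over [0, 360).  The same seed reproduces the same arena.
    """
    rng = np.random.default_rng(seed)
    out = ConcreteArena(timeLimit=spec.timeLimit, passMark=spec.passMark,
                        frozenAgentDelays=spec.frozenAgentDelays,
                        lightsOut=spec.lightsOut)
    for ospec in spec.objects:
        info = kind_info(ospec.name)
        n = ospec.instance_count()
        for i in range(n):
            size_entry = ospec.sizes[i] if i < len(ospec.sizes) else None
            if isinstance(size_entry, RandomToken):
                lo, hi = size_entry.bounds or (0.5, 5.0)
                if not (0 < lo <= hi):
                    raise ConfigError(f"size bounds {size_entry.bounds} invalid")
                s = float(rng.uniform(lo, hi))
                size = Vector3(s, s, s)
            elif size_entry is None:
                size = Vector3(*info.default_size)
            else:
                size = size_entry

            pos_entry = (ospec.positions[i] if i < len(ospec.positions)
                         else RandomToken("random-position"))
            if isinstance(pos_entry, RandomToken):
                pos = _resolve_position(pos_entry, rng, size.x / 2, size.z / 2)
            else:
                pos = pos_entry

            rot_entry = ospec.rotations[i] if i < len(ospec.rotations) else 0.0
            if isinstance(rot_entry, RandomToken):
                lo, hi = rot_entry.bounds or (0.0, 360.0)
                rot = float(rng.uniform(lo, hi)) % 360.0
            else:
                rot = float(rot_entry)

            col_entry = ospec.colors[i] if i < len(ospec.colors) else None
            if isinstance(col_entry, RandomToken):
                color = ColorRGB(*(int(c) for c in rng.integers(0, 256, 3)))
            elif col_entry is None:
                color = ColorRGB(*info.default_color)
            else:
                color = col_entry

            out.objects.append(PlacedObject(
                name=ospec.name, position=pos, rotation=rot, size=size,
                color=color, special=dict(ospec.special)))
    return out


# ---------------------------------------------------------------------------
# overlap detection & precedence placement
# ---------------------------------------------------------------------------

_OVERLAP_EPS = 1e-9


def _circle_rect_overlap(centre: np.ndarray, r: float,
                         rect: PlacedObject) -> bool:
    th = math.radians(rect.rotation)
    c, s = math.cos(th), math.sin(th)
    rc = rect.centre()
    dx, dz = centre[0] - rc[0], centre[2] - rc[2]
    lx, lz = c * dx - s * dz, s * dx + c * dz
    hx, hz = rect.size.x / 2, rect.size.z / 2
    qx = min(max(lx, -hx), hx)
    qz = min(max(lz, -hz), hz)
    return (lx - qx) ** 2 + (lz - qz) ** 2 < (r - _OVERLAP_EPS) ** 2


def _rects_overlap(a: PlacedObject, b: PlacedObject) -> bool:
    """Exact 2D separating-axis test on the y-rotated footprints."""
    ca, cb = a.footprint_corners(), b.footprint_corners()
    for rect in (ca, cb):
        for i in range(2):
            edge = rect[(i + 1) % 4] - rect[i]
            axis = np.array([-edge[1], edge[0]])
            pa = ca @ axis
            pb = cb @ axis
            if pa.max() <= pb.min() + _OVERLAP_EPS or \
                    pb.max() <= pa.min() + _OVERLAP_EPS:
                return False
    return True


def _boxes_overlap(a: PlacedObject, b: PlacedObject) -> bool:
    (alo_y, ahi_y), (blo_y, bhi_y) = a.y_interval(), b.y_interval()
    if ahi_y <= blo_y + _OVERLAP_EPS or bhi_y <= alo_y + _OVERLAP_EPS:
        return False
    sa, sb = a.is_sphere(), b.is_sphere()
    if sa and sb:
        gap = float(np.linalg.norm(a.centre() - b.centre()))
        return gap < (a.size.x + b.size.x) / 2 - _OVERLAP_EPS
    if sa:
        return _circle_rect_overlap(a.centre(), a.size.x / 2, b)
    if sb:
        return _circle_rect_overlap(b.centre(), b.size.x / 2, a)
    return _rects_overlap(a, b)


def detect_overlaps(arena: ConcreteArena) -> list[tuple[int, int]]:
    """Return index pairs of solid objects whose bounding volumes intersect.

    Zones are passable and never conflict.
    """
    solid = [i for i, o in enumerate(arena.objects) if kind_info(o.name).solid
             or o.name == "Agent"]
    pairs = []
    for a_pos, i in enumerate(solid):
        for j in solid[a_pos + 1:]:
            if _boxes_overlap(arena.objects[i], arena.objects[j]):
                pairs.append((i, j))
    return pairs


_MAX_PLACEMENT_ATTEMPTS = 100


def place_with_precedence(arena: ConcreteArena, seed: int) -> ConcreteArena:
    """Resolve overlaps by precedence: the agent is placed first regardless
    of its list position, then objects in file order; a later object that
    overlaps an already-placed solid is re-spawned at a uniformly drawn
    free location (up to 100 attempts, then :class:`PlacementError`).
    """
    rng = np.random.default_rng(seed)
    order = []
    ai = arena.agent_index()
    if ai is not None:
        order.append(ai)
    order.extend(i for i in range(len(arena.objects)) if i != ai)

    placed: list[PlacedObject] = []
    new_objects: list[PlacedObject | None] = [None] * len(arena.objects)
    for idx in order:
        obj = replace(arena.objects[idx])
        solid = kind_info(obj.name).solid or obj.name == "Agent"
        if solid:
            attempts = 0
            while any(_boxes_overlap(obj, p) for p in placed):
                if attempts >= _MAX_PLACEMENT_ATTEMPTS:
                    raise PlacementError(
                        f"no overlap-free location for {obj.name} "
                        f"after {_MAX_PLACEMENT_ATTEMPTS} attempts")
                lo_x, hi_x = _legal_xz(obj.size.x / 2)
                lo_z, hi_z = _legal_xz(obj.size.z / 2)
                obj = replace(obj, position=Vector3(
                    float(rng.uniform(lo_x, hi_x)), obj.position.y,
                    float(rng.uniform(lo_z, hi_z))))
                attempts += 1
            placed.append(obj)
        new_objects[idx] = obj

    out = ConcreteArena(timeLimit=arena.timeLimit, passMark=arena.passMark,
                        frozenAgentDelays=arena.frozenAgentDelays,
                        lightsOut=arena.lightsOut,
                        objects=[o for o in new_objects if o is not None])
    return out
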
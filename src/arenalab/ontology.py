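"""Object ontology: the catalogue of kinds an arena may contain.

Every entity that can appear in a configuration file is one of the kinds
registered here.  Each kind carries the static properties the simulator
needs: whether it is solid (zones are passable volumes), whether the agent
can push it (and with what mass), its default size, its default colour,
whether its colour is user-configurable, and the sensory category it
presents to raycast observations.

Masses follow the block catalogue: light blocks 1, heavy blocks 2, the
U/L/J-shaped blocks and hollow boxes 1.5.  The agent is a sphere of
diameter 1 and mass 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

ARENA_SIZE = 40.0  #: side length of the square arena floor, in arena units
AGENT_DIAMETER = 1.0


class Category(Enum):
    """Sensory category reported by raycast observations (one-hot rows)."""

    GOAL_POSITIVE = 0
    GOAL_NEGATIVE = 1
    IMMOVABLE = 2
    MOVABLE = 3
    DISPENSER = 4
    SIGNBOARD = 5


class Shape(Enum):
    SPHERE = "sphere"
    BOX = "box"
    RAMP = "ramp"
    TUNNEL = "tunnel"
    ZONE = "zone"


@dataclass(frozen=True)
class KindInfo:
    """Static properties of one object kind."""

    name: str
    shape: Shape
    category: Category | None
    solid: bool = True
    movable: bool = False
    mass: float = 1.0
    valence_sign: int = 0          # +1 appetitive, -1 aversive, 0 neutral
    episode_ending: bool = False
    collectible: bool = False      # removed from the world on agent contact
    bounce: bool = False           # spawns with an initial horizontal velocity
    schedule_mode: str = "static"  # static | decay | ripen | grow | shrink
    fixed_color: bool = False
    default_color: tuple[int, int, int] = (153, 153, 153)
    default_size: tuple[float, float, float] = (1.0, 1.0, 1.0)


def _goal(name: str, sign: int, *, ending: bool = False, bounce: bool = False,
          mode: str = "static", color: tuple[int, int, int] = (0, 255, 0)) -> KindInfo:
    cat = Category.GOAL_POSITIVE if sign >= 0 else Category.GOAL_NEGATIVE
    return KindInfo(
        name=name, shape=Shape.SPHERE, category=cat, solid=True,
        valence_sign=sign, episode_ending=ending, collectible=True,
        bounce=bounce, schedule_mode=mode, default_color=color,
    )


_GREY = (120, 120, 120)
_KINDS: tuple[KindInfo, ...] = (
    # --- immovable structures -------------------------------------------
    KindInfo("Wall", Shape.BOX, Category.IMMOVABLE),
    KindInfo("WallTransparent", Shape.BOX, Category.IMMOVABLE, fixed_color=True),
    KindInfo("Ramp", Shape.RAMP, Category.IMMOVABLE,
             default_color=(255, 0, 255)),
    KindInfo("CylinderTunnel", Shape.TUNNEL, Category.IMMOVABLE),
    KindInfo("CylinderTunnelTransparent", Shape.TUNNEL, Category.IMMOVABLE,
             fixed_color=True),
    # --- movable blocks (colour fixed, uniform grey) --------------------
    KindInfo("LightBlock", Shape.BOX, Category.MOVABLE, movable=True,
             mass=1.0, fixed_color=True, default_color=_GREY),
    KindInfo("HeavyBlock", Shape.BOX, Category.MOVABLE, movable=True,
             mass=2.0, fixed_color=True, default_color=_GREY),
    KindInfo("UBlock", Shape.BOX, Category.MOVABLE, movable=True,
             mass=1.5, fixed_color=True, default_color=_GREY),
    KindInfo("LBlock", Shape.BOX, Category.MOVABLE, movable=True,
             mass=1.5, fixed_color=True, default_color=_GREY),
    KindInfo("JBlock", Shape.BOX, Category.MOVABLE, movable=True,
             mass=1.5, fixed_color=True, default_color=_GREY),
    KindInfo("HollowBox", Shape.BOX, Category.MOVABLE, movable=True,
             mass=1.5, fixed_color=True, default_color=_GREY),
    # --- valenced goals -------------------------------------------------
    _goal("GoodGoal", +1, ending=True),
    _goal("GoodGoalMulti", +1),
    _goal("BadGoal", -1, ending=True, color=(255, 0, 0)),
    _goal("BadGoalMulti", -1, color=(255, 0, 0)),
    _goal("DecoyGoal", 0, color=(255, 255, 255)),
    _goal("GoodGoalBounce", +1, ending=True, bounce=True),
    _goal("GoodGoalMultiBounce", +1, bounce=True),
    _goal("BadGoalBounce", -1, ending=True, bounce=True, color=(255, 0, 0)),
    _goal("BadGoalMultiBounce", -1, bounce=True, color=(255, 0, 0)),
    _goal("DecoyGoalBounce", 0, bounce=True, color=(255, 255, 255)),
    _goal("GrowGoal", +1, mode="grow"),
    _goal("ShrinkGoal", +1, mode="shrink"),
    _goal("RipenGoal", +1, mode="ripen", color=(128, 128, 128)),
    _goal("DecayGoal", +1, mode="decay", color=(255, 255, 0)),
    # --- valenced zones (passable volumes) ------------------------------
    KindInfo("DeathZone", Shape.ZONE, Category.GOAL_NEGATIVE, solid=False,
             valence_sign=-1, episode_ending=True, fixed_color=True,
             default_color=(255, 0, 0)),
    KindInfo("HotZone", Shape.ZONE, Category.GOAL_NEGATIVE, solid=False,
             valence_sign=-1, fixed_color=True, default_color=(255, 150, 0)),
    # --- dispensers and sign boards -------------------------------------
    KindInfo("SpawnerTree", Shape.BOX, Category.DISPENSER, fixed_color=True,
             default_color=(90, 60, 30), default_size=(2.0, 4.0, 2.0)),
    KindInfo("SpawnerDispenserTall", Shape.BOX, Category.DISPENSER,
             default_size=(1.0, 3.0, 1.0)),
    KindInfo("SpawnerDispenserShort", Shape.BOX, Category.DISPENSER,
             default_size=(1.0, 1.5, 1.0)),
    KindInfo("SpawnerButton", Shape.BOX, Category.DISPENSER, fixed_color=True,
             default_color=(220, 200, 160), default_size=(1.0, 1.5, 1.0)),
    KindInfo("SignBoard", Shape.BOX, Category.SIGNBOARD,
             default_size=(2.0, 2.0, 0.2)),
    # --- the agent ------------------------------------------------------
    KindInfo("Agent", Shape.SPHERE, None, movable=True, mass=1.0,
             default_size=(AGENT_DIAMETER,) * 3),
)

KINDS: dict[str, KindInfo] = {k.name: k for k in _KINDS}

SPAWNER_KINDS = frozenset(
    {"SpawnerTree", "SpawnerDispenserTall", "SpawnerDispenserShort"})
DISPENSER_KINDS = SPAWNER_KINDS | {"SpawnerButton"}
ZONE_KINDS = frozenset({"DeathZone", "HotZone"})
TRANSPARENT_KINDS = frozenset({"WallTransparent", "CylinderTunnelTransparent"})


def kind_info(name: str) -> KindInfo:
    """Look up a kind by name; raises ``ValueError`` for unknown kinds."""
    try:
        return KINDS[name]
    except KeyError:
        raise ValueError(f"unknown object kind: {name!r}") from None


def is_known_kind(name: str) -> bool:
    return name in KINDS
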
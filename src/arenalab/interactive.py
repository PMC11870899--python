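"""Interactive objects: spawner tree, goal dispensers, spawner button,
and sign boards.

Spawner trees drop a configurable number of GoodGoalMulti goals at random
times and positions within the canopy, in the style of naturally falling
fruit.  Tall/short dispensers emit GoodGoalMulti through a hatch on a
regular schedule after an initial delay.  The spawner button spawns one of
{GoodGoal, GoodGoalMulti, BadGoal} with configurable probability and kind
weights when pressed on its front face, subject to a cooldown.  Sign
boards display either a preset symbol or a user-defined pixel grid in
which ``*`` cells are resolved to 0/1 at spawn time with the episode seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TREE_CANOPY_RADIUS = 2.0   # drop positions fall within this disc
TREE_TRUNK_CLEARANCE = 1.3  # fruit lands clear of the trunk footprint
TREE_DROP_HEIGHT = 3.0     # y above the canopy from which fruit falls


@dataclass(frozen=True)
class SpawnEvent:
    """One goal entering the world: kind, base position, diameter."""

    kind: str
    position: tuple[float, float, float]
    size: float = 1.0


@dataclass
class SpawnerSpec:
    """Tree or dispenser configuration.

    ``count`` goals in total are emitted, the first after ``delay`` steps,
    subsequent ones ``interval`` steps apart (trees jitter drop times
    randomly within each interval window).
    """

    kind: str                      # tree | dispenserTall | dispenserShort
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    count: int = 10
    delay: int = 0
    interval: int = 10
    goalSize: float = 1.0
    spawned: int = field(default=0, compare=False)
    drop_schedule: list[int] | None = field(default=None, compare=False)

    def __post_init__(self):
        if self.count < 0 or self.delay < 0 or self.interval < 0:
            raise ValueError("count, delay and interval must be >= 0")


def tick_spawner(s: SpawnerSpec, step: int,
                 rng: np.random.Generator) -> list[SpawnEvent]:
    """Spawn events due at ``step`` (call once per step, in step order).

    Nothing is emitted before ``delay``; exactly ``count`` goals are
    emitted over an episode.  Trees drop from random canopy positions at
    randomised times; dispensers emit at the hatch on a fixed cadence.
    """
    if step < 0:
        raise ValueError("step must be >= 0")
    if s.spawned >= s.count or step < s.delay:
        return []
    ox, oy, oz = s.origin
    events: list[SpawnEvent] = []
    if s.kind == "tree":
        if s.drop_schedule is None:
            # one drop per interval window, jittered within the window
            windows = [s.delay + i * max(1, s.interval) for i in range(s.count)]
            jitter = rng.integers(0, max(1, s.interval), size=s.count)
            s.drop_schedule = sorted(int(w + j) for w, j in zip(windows, jitter))
        due = [t for t in s.drop_schedule if t == step]
        for _ in due:
            if s.spawned >= s.count:
                break
            angle = rng.uniform(0.0, 2.0 * np.pi)
            lo2 = TREE_TRUNK_CLEARANCE ** 2
            r = float(np.sqrt(rng.uniform(lo2, TREE_CANOPY_RADIUS ** 2)))
            pos = (ox + r * np.cos(angle), oy + TREE_DROP_HEIGHT,
                   oz + r * np.sin(angle))
            events.append(SpawnEvent("GoodGoalMulti", pos, s.goalSize))
            s.spawned += 1
    elif s.kind in ("dispenserTall", "dispenserShort"):
        if (step - s.delay) % max(1, s.interval) == 0:
            events.append(SpawnEvent("GoodGoalMulti", (ox, oy, oz),
                                     s.goalSize))
            s.spawned += 1
    else:
        raise ValueError(f"unknown spawner kind {s.kind!r}")
    return events


@dataclass
class ButtonSpec:
    """Spawner-button configuration."""

    spawnProbability: float = 1.0
    weights: dict[str, float] = field(default_factory=lambda: {
        "GoodGoal": 1.0, "GoodGoalMulti": 1.0, "BadGoal": 1.0})
    spawnPosition: tuple[float, float, float] = (0.0, 0.0, 0.0)
    resetSteps: int = 0
    goalSize: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.spawnProbability <= 1.0):
            raise ValueError("spawnProbability must be in [0, 1]")
        bad = {k for k in self.weights
               if k not in ("GoodGoal", "GoodGoalMulti", "BadGoal")}
        if bad:
            raise ValueError(f"button cannot spawn kinds {sorted(bad)}")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")
        if self.spawnProbability > 0 and sum(self.weights.values()) == 0:
            raise ValueError("weights must not all be zero")


def press_button(b: ButtonSpec, steps_since_last_press: int,
                 rng: np.random.Generator) -> SpawnEvent | None:
    """Resolve one button press.

    During the cooldown (fewer than ``resetSteps`` since the previous
    press) nothing happens.  Otherwise a goal spawns with probability
    ``spawnProbability``, its kind drawn in proportion to ``weights``.
    """
    if steps_since_last_press < b.resetSteps:
        return None
    if rng.uniform() >= b.spawnProbability:
        return None
    kinds = sorted(k for k, w in b.weights.items() if w > 0)
    w = np.array([b.weights[k] for k in kinds], dtype=float)
    kind = kinds[int(rng.choice(len(kinds), p=w / w.sum()))]
    return SpawnEvent(kind, b.spawnPosition, b.goalSize)


# ---------------------------------------------------------------------------
# sign boards
# ---------------------------------------------------------------------------

_GRID = 16


def _preset_bitmaps() -> dict[str, np.ndarray]:
    """Built-in 16x16 monochrome symbol bitmaps, drawn programmatically."""
    n = _GRID
    yy, xx = np.mgrid[0:n, 0:n]
    cx = cy = (n - 1) / 2.0
    rad = np.hypot(xx - cx, yy - cy)

    circle = ((rad >= 4.5) & (rad <= 6.5)).astype(np.uint8)

    tick = np.zeros((n, n), np.uint8)
    for i in range(4):
        tick[9 + i, 3 + i] = tick[10 + i, 3 + i] = 1
    for i in range(9):
        r = 12 - i
        if 0 <= r < n:
            tick[r, 7 + i // 2] = tick[r, 6 + i // 2] = 1

    left_arrow = np.zeros((n, n), np.uint8)
    left_arrow[7:9, 3:13] = 1
    for i in range(4):
        left_arrow[7 - i - 1: 9 + i + 1, 6 - i] = 0
        left_arrow[7 - i, 3 + i] = 1
        left_arrow[8 + i, 3 + i] = 1

    uturn = np.zeros((n, n), np.uint8)
    uturn[3:5, 4:12] = 1       # top bar of the loop
    uturn[3:10, 10:12] = 1     # right descender
    uturn[3:13, 4:6] = 1       # left descender
    uturn[10:13, 9:13] = 0
    uturn[9:11, 8:14] = 1      # arrow head hint

    letter_a = np.zeros((n, n), np.uint8)
    letter_a[3:13, 4:6] = 1
    letter_a[3:13, 10:12] = 1
    letter_a[3:5, 4:12] = 1
    letter_a[8:10, 4:12] = 1

    return {"tick": tick, "u-turn-arrow": uturn, "circle": circle,
            "letter-a": letter_a, "left-arrow": left_arrow}


PRESET_SYMBOLS = _preset_bitmaps()


@dataclass
class SignBoardSpec:
    """Either a preset ``symbol`` or a pixel ``grid``.

    Grids are encoded in YAML as rows joined by '/', cells drawn from
    {'0', '1', '*'}; each '*' resolves independently to 0 or 1 with
    probability one half at spawn time.
    """

    symbol: str | None = None
    grid: str | None = None
    color: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self):
        if (self.symbol is None) == (self.grid is None):
            raise ValueError("specify exactly one of symbol or grid")
        if self.grid is not None:
            rows = self.grid.split("/")
            if len({len(r) for r in rows}) != 1:
                raise ValueError("grid rows must have equal length")
            if set("".join(rows)) - set("01*"):
                raise ValueError("grid cells must be '0', '1' or '*'")


def render_signboard(s: SignBoardSpec,
                     rng: np.random.Generator) -> np.ndarray:
    """Resolve a sign-board spec to a concrete 0/1 pixel grid."""
    if s.symbol is not None:
        try:
            return PRESET_SYMBOLS[s.symbol].copy()
        except KeyError:
            raise ValueError(f"unknown preset symbol {s.symbol!r}") from None
    rows = s.grid.split("/")
    out = np.zeros((len(rows), len(rows[0])), dtype=np.uint8)
    for i, row in enumerate(rows):
        for j, cell in enumerate(row):
            if cell == "*":
                out[i, j] = rng.integers(0, 2)
            else:
                out[i, j] = int(cell)
    return out
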
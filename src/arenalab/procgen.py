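"""Procedural configuration generation: a small template DSL, the built-in
foraging and operant-chamber tasks (with curriculum), and the testbed
manifest.

Templates are YAML documents with a ``template`` section (an ordinary
configuration in which values may reference named choices as ``$name`` or
``{choice: name}``), a ``choices`` section declaring how each name is
drawn (fixed list, numeric range, random colour, or an expression over
previously drawn choices), and optional free-form ``labels``.  Generation
is a pure function of (template, n, seed) and every generated file parses
as a valid configuration with no warnings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import yaml

from . import schema

__all__ = [
    "ChoiceSpec", "Template", "CurriculumStage", "generate",
    "parse_template", "build_foraging_task", "build_operant_task",
    "build_curriculum", "testbed_manifest", "exemplar_config",
    "TESTBED_LEVEL_NAMES",
]


# ---------------------------------------------------------------------------
# template DSL
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChoiceSpec:
    """One named random choice.

    kinds: ``fixed-list`` (uniform over ``options``), ``numeric-range``
    (uniform over ``range``; integer endpoints give integer draws),
    ``random-color`` (uniform RGB), ``conditional`` (``expr`` evaluated
    over previously drawn choices).
    """

    kind: str
    options: tuple = ()
    range: tuple[float, float] | None = None
    expr: str = ""

    def __post_init__(self):
        if self.kind == "fixed-list" and not self.options:
            raise ValueError("fixed-list choice needs non-empty options")
        if self.kind == "numeric-range" and self.range is None:
            raise ValueError("numeric-range choice needs a range")
        if self.kind == "conditional" and not self.expr:
            raise ValueError("conditional choice needs an expression")


@dataclass
class Template:
    base: dict
    choices: dict[str, ChoiceSpec] = field(default_factory=dict)
    labels: list[str] = field(default_factory=list)


def parse_template(yaml_text: str) -> Template:
    raw = yaml.safe_load(yaml_text)
    if not isinstance(raw, dict) or "template" not in raw:
        raise schema.ConfigError("template document needs a 'template' key")
    choices = {}
    for name, craw in (raw.get("choices") or {}).items():
        choices[name] = ChoiceSpec(
            kind=craw["kind"],
            options=tuple(craw.get("options", ())),
            range=tuple(craw["range"]) if "range" in craw else None,
            expr=str(craw.get("expr", "")))
    return Template(base=raw["template"], choices=choices,
                    labels=list(raw.get("labels", [])))


_SAFE_FUNCS = {"min": min, "max": max, "abs": abs, "round": round,
               "int": int, "float": float, "floor": math.floor,
               "ceil": math.ceil}


def _resolve_choices(template: Template,
                     rng: np.random.Generator) -> dict[str, object]:
    """Draw every choice, evaluating conditionals after their dependencies
    (simple fixed-point iteration; cycles and unknown names error)."""
    resolved: dict[str, object] = {}
    pending = dict(template.choices)
    while pending:
        progressed = False
        for name in list(pending):
            spec = pending[name]
            if spec.kind == "fixed-list":
                resolved[name] = spec.options[
                    int(rng.integers(len(spec.options)))]
            elif spec.kind == "numeric-range":
                lo, hi = spec.range
                if isinstance(lo, int) and isinstance(hi, int):
                    resolved[name] = int(rng.integers(lo, hi + 1))
                else:
                    resolved[name] = float(rng.uniform(lo, hi))
            elif spec.kind == "random-color":
                r, g, b = (int(v) for v in rng.integers(0, 256, 3))
                resolved[name] = {"r": r, "g": g, "b": b}
            elif spec.kind == "conditional":
                deps = [n for n in template.choices
                        if n != name and n in spec.expr]
                if any(d in pending for d in deps):
                    continue
                try:
                    resolved[name] = eval(  # noqa: S307 - sandboxed names
                        spec.expr, {"__builtins__": {}},
                        {**_SAFE_FUNCS, **resolved})
                except Exception as exc:
                    raise schema.ConfigError(
                        f"unsatisfiable conditional choice {name!r}: {exc}"
                    ) from exc
            else:
                raise schema.ConfigError(f"unknown choice kind {spec.kind!r}")
            del pending[name]
            progressed = True
        if not progressed:
            raise schema.ConfigError(
                f"circular conditional choices: {sorted(pending)}")
    return resolved


def _substitute(node, resolved: dict[str, object]):
    if isinstance(node, dict):
        if set(node) == {"choice"}:
            name = node["choice"]
            if name not in resolved:
                raise schema.ConfigError(f"undeclared choice {name!r}")
            return resolved[name]
        return {k: _substitute(v, resolved) for k, v in node.items()}
    if isinstance(node, list):
        return [_substitute(v, resolved) for v in node]
    if isinstance(node, str) and node.startswith("$"):
        name = node[1:]
        if name not in resolved:
            raise schema.ConfigError(f"undeclared choice {name!r}")
        return resolved[name]
    return node


def generate(template: Template, n: int, seed: int) -> list[schema.ConfigFile]:
    """Generate ``n`` concrete configurations from a template.

    Deterministic under seed; every output parses without warnings and
    carries the template's labels.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        resolved = _resolve_choices(template, rng)
        doc = _substitute(template.base, resolved)
        cfg = schema.parse_config(yaml.safe_dump(doc))
        if cfg.warnings:
            raise schema.ConfigError(
                f"template produced config warnings: {cfg.warnings}")
        cfg.labels = list(template.labels)
        out.append(cfg)
    return out


# ---------------------------------------------------------------------------
# built-in tasks
# ---------------------------------------------------------------------------

def _arena(time_limit: int, pass_mark: float,
           objects: list[schema.ObjectSpec]) -> schema.ConfigFile:
    arena = schema.ArenaSpec(timeLimit=time_limit, passMark=pass_mark,
                             objects=objects)
    return schema.ConfigFile(arenas={0: arena})


def _obj(name: str, pos=None, rot=None, size=None, special=None
         ) -> schema.ObjectSpec:
    o = schema.ObjectSpec(name=name)
    if pos is not None:
        o.positions = [pos]
    if rot is not None:
        o.rotations = [rot]
    if size is not None:
        o.sizes = [schema.Vector3(size, size, size)
                   if isinstance(size, (int, float)) else size]
    if special:
        o.special = special
    return o


FORAGING_TIME_LIMIT = 500
FORAGING_PASS_MARK = 10.0


def build_foraging_task(seed: int = 0) -> schema.ConfigFile:
    """The foraging task: a spawner tree at the arena centre (20,0,20)
    drops 10 GoodGoalMulti goals of size 2; the agent starts at a random
    x on the near edge, (x,0,5), with a random initial rotation."""
    tree = _obj("SpawnerTree", schema.Vector3(20.0, 0.0, 20.0),
                special={"count": 10, "goalSize": 2, "delay": 10,
                         "interval": 20})
    agent = _obj("Agent",
                 schema.RandomToken("random-position",
                                    fixed=(("y", 0.0), ("z", 5.0))),
                 rot=schema.RandomToken("random-rotation"))
    return _arena(FORAGING_TIME_LIMIT, FORAGING_PASS_MARK, [agent, tree])


OPERANT_TIME_LIMIT = 500
OPERANT_PASS_MARK = 0.5
_BUTTON_POS = (38.5, 0.0, 18.8)
_GOAL_SPAWN = (39.0, 3.0, 22.0)
# the button faces the arena interior (toward the stage-1 spawn point)
_BUTTON_YAW = 296.0

_STAGE_SPAWNS: dict[int, object] = {
    1: schema.Vector3(36.0, 0.0, 20.0),
    2: schema.Vector3(30.0, 0.0, 20.0),
    3: schema.Vector3(20.0, 0.0, 20.0),
    4: schema.RandomToken("random-position", fixed=(("x", 20.0), ("y", 0.0))),
    5: schema.RandomToken("random-position", fixed=(("y", 0.0),)),
    0: schema.RandomToken("random-position", fixed=(("y", 0.0),)),
}


def build_operant_task(stage: int = 0,
                       time_limit: int = OPERANT_TIME_LIMIT
                       ) -> schema.ConfigFile:
    """The operant-chamber task: a SpawnerButton at (38.5,0,18.8) that,
    when pressed, spawns a size-1 GoodGoal at (39,3,22); walls enclose the
    button on three sides so it must be approached from the front.

    ``stage`` 0 is the final task (fully random agent spawn); 1-5 are the
    curriculum stages with progressively farther/random spawns.
    """
    if stage not in _STAGE_SPAWNS:
        raise ValueError(f"invalid curriculum stage {stage!r}")
    bx, by, bz = _BUTTON_POS
    th = math.radians(_BUTTON_YAW)
    fx, fz = math.sin(th), math.cos(th)          # front (unit, x-z)
    rx, rz = math.cos(th), -math.sin(th)         # right (unit, x-z)

    button = _obj("SpawnerButton", schema.Vector3(bx, by, bz),
                  rot=_BUTTON_YAW,
                  special={"spawnProbability": 1.0,
                           "weights": {"GoodGoal": 1.0},
                           "spawnPosition": list(_GOAL_SPAWN),
                           "resetSteps": 50, "goalSize": 1.0})
    rear = _obj("Wall",
                schema.Vector3(bx - 1.6 * fx, 0.0, bz - 1.6 * fz),
                rot=_BUTTON_YAW, size=schema.Vector3(3.4, 2.0, 0.5))
    side_l = _obj("Wall",
                  schema.Vector3(bx - 1.6 * rx - 0.2 * fx, 0.0,
                                 bz - 1.6 * rz - 0.2 * fz),
                  rot=_BUTTON_YAW, size=schema.Vector3(0.5, 2.0, 3.2))
    side_r = _obj("Wall",
                  schema.Vector3(bx + 1.6 * rx - 0.2 * fx, 0.0,
                                 bz + 1.6 * rz - 0.2 * fz),
                  rot=_BUTTON_YAW, size=schema.Vector3(0.5, 2.0, 3.2))
    spawn = _STAGE_SPAWNS[stage]
    agent = _obj("Agent", spawn, rot=schema.RandomToken("random-rotation"))
    return _arena(time_limit, OPERANT_PASS_MARK,
                  [agent, button, rear, side_l, side_r])


# ---------------------------------------------------------------------------
# curricula
# ---------------------------------------------------------------------------

@dataclass
class CurriculumStage:
    index: int
    configs: list[schema.ConfigFile]
    steps: int
    cumulative: bool


_TASK_BUILDERS: dict[str, Callable[[int], schema.ConfigFile]] = {
    "operant": lambda stage: build_operant_task(stage),
    "foraging": lambda stage: build_foraging_task(stage),
}


def build_curriculum(task: str, total_stages: int, cumulative: bool = True,
                     steps_per_stage: int = 400_000,
                     seed: int = 0) -> list[CurriculumStage]:
    """Build an ordered curriculum for a built-in task.

    With ``cumulative`` set, stage i contains the configurations of stages
    1..i interleaved (deterministically under ``seed``).
    """
    if task not in _TASK_BUILDERS:
        raise ValueError(f"unknown curriculum task {task!r}")
    if total_stages < 1:
        raise ValueError("total_stages must be >= 1")
    build = _TASK_BUILDERS[task]
    rng = np.random.default_rng(seed)
    stage_cfgs = {i: build(i if total_stages > 1 else 0)
                  for i in range(1, total_stages + 1)}
    stages = []
    for i in range(1, total_stages + 1):
        if cumulative:
            configs = [stage_cfgs[j] for j in range(1, i + 1)]
            order = rng.permutation(len(configs))
            configs = [configs[j] for j in order]
        else:
            configs = [stage_cfgs[i]]
        stages.append(CurriculumStage(index=i, configs=configs,
                                      steps=steps_per_stage,
                                      cumulative=cumulative))
    return stages


# ---------------------------------------------------------------------------
# testbed manifest
# ---------------------------------------------------------------------------

TESTBED_LEVEL_NAMES: tuple[str, ...] = (
    "Food Retrieval",
    "Preferences",
    "Static Obstacles",
    "Avoidance",
    "Spatial Reasoning and Support",
    "Generalisation",
    "Internal Modelling",
    "Object Permanence and Working Memory",
    "Numerosity and Advanced Preferences",
    "Causal Reasoning",
)

TASKS_PER_LEVEL = 30
VARIANTS_PER_TASK = 3


@dataclass(frozen=True)
class ManifestEntry:
    level: int
    level_name: str
    task: int
    variant: int


def testbed_manifest() -> list[ManifestEntry]:
    """The testbed's level/task/variant structure: ten named levels of 30
    tasks with three variants each (900 entries)."""
    return [ManifestEntry(level=lv, level_name=TESTBED_LEVEL_NAMES[lv - 1],
                          task=t, variant=v)
            for lv in range(1, 11)
            for t in range(1, TASKS_PER_LEVEL + 1)
            for v in range(1, VARIANTS_PER_TASK + 1)]


# ---------------------------------------------------------------------------
# illustrative per-level exemplars (not the original testbed contents)
# ---------------------------------------------------------------------------

def exemplar_config(level: int, seed: int = 0) -> schema.ConfigFile:
    """One simple illustrative task in the spirit of a testbed level.

    These are arenalab-authored exemplars of each level's theme, not
    reproductions of the original task geometry.
    """
    rng = np.random.default_rng((seed, level))
    agent = _obj("Agent", schema.RandomToken("random-position",
                                             fixed=(("y", 0.0),)),
                 rot=schema.RandomToken("random-rotation"))
    goal = _obj("GoodGoal", schema.RandomToken("random-position",
                                               fixed=(("y", 0.0),)), size=2)
    objects = [agent, goal]
    arena = schema.ArenaSpec(timeLimit=250, passMark=1.0, objects=objects)
    if level == 2:
        objects.append(_obj("GoodGoalMulti", schema.Vector3(
            float(rng.uniform(5, 35)), 0.0, float(rng.uniform(5, 35))),
            size=1))
    elif level == 3:
        objects.append(_obj("Wall", schema.Vector3(20.0, 0.0, 20.0),
                            rot=float(rng.integers(0, 180)),
                            size=schema.Vector3(8.0, 2.0, 1.0)))
    elif level == 4:
        objects.append(_obj("DeathZone", schema.Vector3(
            float(rng.uniform(10, 26)), 0.0, float(rng.uniform(10, 26))),
            size=schema.Vector3(6.0, 1.0, 6.0)))
        arena.passMark = 0.5
    elif level == 5:
        objects.append(_obj("Ramp", schema.Vector3(20.0, 0.0, 20.0),
                            rot=0.0, size=schema.Vector3(4.0, 2.0, 6.0)))
    elif level == 6:
        objects.append(_obj("Wall", schema.Vector3(20.0, 0.0, 10.0),
                            rot=0.0, size=schema.Vector3(10.0, 2.0, 1.0)))
        objects[-1].colors = [schema.RandomToken("random-color")]
    elif level == 7:
        arena.lightsOut = schema.LightsOut(intervals=((40, 80),))
    elif level == 8:
        objects.append(_obj("Wall", schema.Vector3(20.0, 0.0, 25.0),
                            rot=0.0, size=schema.Vector3(10.0, 3.0, 1.0)))
        arena.lightsOut = schema.LightsOut(intervals=((20, 60),))
    elif level == 9:
        objects.append(_obj("GoodGoalMulti", schema.RandomToken(
            "random-position", fixed=(("y", 0.0),)), size=0.5))
        objects.append(_obj("GoodGoalMulti", schema.RandomToken(
            "random-position", fixed=(("y", 0.0),)), size=3))
    elif level == 10:
        objects.append(_obj("LightBlock", schema.Vector3(20.0, 0.0, 20.0),
                            rot=0.0, size=schema.Vector3(2.0, 2.0, 2.0)))
    if not (1 <= level <= 10):
        raise ValueError("level must be in 1..10")
    return schema.ConfigFile(arenas={0: arena})
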
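"""Configuration schema: parsing, round-trips, randomness, placement."""

import numpy as np
import pytest

from arenalab import schema
from arenalab.schema import (ArenaSpec, ColorRGB, ConfigError, ConfigFile,
                             LightsOut, ObjectSpec, PlacedObject,
                             PlacementError, RandomToken, Vector3,
                             detect_overlaps, parse_config,
                             place_with_precedence, resolve_randomness,
                             write_config)


class TestParse:
    def test_minimal_arena_with_defaults_filled(self):
        cfg = parse_config("arenas:\n  0:\n    timeLimit: 250\n")
        assert len(cfg.arenas) == 1
        arena = cfg.arenas[0]
        assert arena.timeLimit == 250
        assert arena.passMark == 0.0
        assert arena.frozenAgentDelays == 0
        assert arena.objects == []

    def test_goal_item_parses_position_and_size(self):
        cfg = parse_config("""
arenas:
  0:
    items:
      - name: GoodGoal
        positions: [{x: 20, y: 0, z: 20}]
        sizes: [2]
""")
        obj = cfg.arenas[0].objects[0]
        assert obj.name == "GoodGoal"
        assert obj.positions == [Vector3(20, 0, 20)]
        assert obj.sizes == [Vector3(2, 2, 2)]

    def test_unknown_object_kind_is_rejected_by_name(self):
        with pytest.raises(ConfigError, match="FlyingCarpet"):
            parse_config("""
arenas:
  0:
    items:
      - name: FlyingCarpet
""")

    def test_malformed_yaml_reports_line(self):
        with pytest.raises(ConfigError, match="line"):
            parse_config("arenas:\n  0:\n   - ]bad\n  x")

    def test_unknown_keys_are_reported_as_warnings(self):
        cfg = parse_config("""
arenas:
  0:
    timeLimit: 10
    frobnicate: 3
""")
        assert any("frobnicate" in w for w in cfg.warnings)

    def test_colors_on_fixed_color_kind_warn_and_drop(self):
        cfg = parse_config("""
arenas:
  0:
    items:
      - name: LightBlock
        positions: [{x: 5, y: 0, z: 5}]
        colors: [{r: 10, g: 20, b: 30}]
""")
        assert cfg.arenas[0].objects[0].colors == []
        assert any("fixed-colour" in w for w in cfg.warnings)

    def test_mismatched_instance_lists_rejected(self):
        with pytest.raises(ConfigError, match="length"):
            parse_config("""
arenas:
  0:
    items:
      - name: Wall
        positions: [{x: 5, y: 0, z: 5}, {x: 9, y: 0, z: 9}]
        rotations: [0]
""")

    @pytest.mark.parametrize("encoding", ["random", -1])
    def test_random_position_sentinels(self, encoding):
        cfg = parse_config(f"""
arenas:
  0:
    items:
      - name: Agent
        positions: [{encoding}]
""")
        tok = cfg.arenas[0].objects[0].positions[0]
        assert isinstance(tok, RandomToken)
        assert tok.kind == "random-position"


class TestRoundTrip:
    def _configs(self):
        yield ConfigFile(arenas={0: ArenaSpec()})
        yield ConfigFile(arenas={0: ArenaSpec(
            timeLimit=100, passMark=0.5,
            lightsOut=LightsOut(intervals=((10, 20),)),
            objects=[ObjectSpec(name="GoodGoal",
                                positions=[Vector3(20, 0, 20)],
                                sizes=[Vector3(2, 2, 2)])])})
        yield ConfigFile(arenas={0: ArenaSpec(objects=[
            ObjectSpec(name="Agent",
                       positions=[RandomToken("random-position",
                                              fixed=(("y", 0.0), ("z", 5.0)))],
                       rotations=[RandomToken("random-rotation")]),
            ObjectSpec(name="Wall", positions=[Vector3(5, 0, 5)],
                       rotations=[45.0], sizes=[Vector3(4, 2, 1)],
                       colors=[ColorRGB(10, 20, 30)])])},
            episodeMode="multi-arena-single-episode")

    def test_parse_write_is_identity(self):
        for cfg in self._configs():
            assert parse_config(write_config(cfg)) == cfg

    def test_random_tokens_survive_round_trip(self):
        cfg = ConfigFile(arenas={0: ArenaSpec(objects=[ObjectSpec(
            name="GoodGoal",
            positions=[RandomToken("random-position")],
            sizes=[RandomToken("random-scalar", bounds=(1.0, 3.0))])])})
        assert parse_config(write_config(cfg)) == cfg


class TestResolveRandomness:
    def test_tokenless_spec_is_unchanged(self):
        spec = ArenaSpec(objects=[ObjectSpec(
            name="Wall", positions=[Vector3(5, 0, 5)], rotations=[30.0],
            sizes=[Vector3(2, 2, 2)])])
        out = resolve_randomness(spec, seed=3)
        obj = out.objects[0]
        assert obj.position == Vector3(5, 0, 5)
        assert obj.rotation == 30.0

    def test_same_seed_reproduces_draws(self):
        spec = ArenaSpec(objects=[ObjectSpec(
            name="Agent",
            positions=[RandomToken("random-position",
                                   fixed=(("y", 0.0), ("z", 5.0)))])])
        a = resolve_randomness(spec, seed=7).objects[0].position
        b = resolve_randomness(spec, seed=7).objects[0].position
        assert a == b
        assert a.z == 5.0 and a.y == 0.0

    def test_rotation_draws_follow_uniform_law(self):
        spec = ArenaSpec(objects=[ObjectSpec(
            name="Wall", positions=[Vector3(20, 0, 20)] * 1,
            rotations=[RandomToken("random-rotation")])])
        draws = [resolve_randomness(spec, seed=s).objects[0].rotation
                 for s in range(10_000)]
        draws = np.array(draws)
        assert draws.min() >= 0.0 and draws.max() < 360.0
        assert abs(draws.mean() - 180.0) < 3.0

    def test_positions_respect_arena_bounds(self):
        spec = ArenaSpec(objects=[ObjectSpec(
            name="Wall", positions=[RandomToken("random-position")],
            sizes=[Vector3(4, 2, 4)])])
        for s in range(200):
            p = resolve_randomness(spec, seed=s).objects[0].position
            assert 2.0 <= p.x <= 38.0
            assert 2.0 <= p.z <= 38.0

    def test_out_of_arena_bounds_rejected(self):
        spec = ArenaSpec(objects=[ObjectSpec(
            name="Agent", positions=[RandomToken("random-position",
                                                 bounds=(30.0, 50.0))])])
        with pytest.raises(ConfigError):
            resolve_randomness(spec, seed=0)


def _placed(name, x, z, sx=2.0, sy=2.0, sz=2.0, rot=0.0, y=0.0):
    return PlacedObject(name=name, position=Vector3(x, y, z), rotation=rot,
                        size=Vector3(sx, sy, sz))


class TestOverlaps:
    def test_coincident_walls_conflict(self):
        arena = schema.ConcreteArena(objects=[
            _placed("Wall", 10, 10), _placed("Wall", 10, 10)])
        assert detect_overlaps(arena) == [(0, 1)]

    def test_zones_are_passable_and_never_conflict(self):
        arena = schema.ConcreteArena(objects=[
            _placed("Wall", 10, 10), _placed("DeathZone", 10, 10, 6, 1, 6)])
        assert detect_overlaps(arena) == []

    def test_empty_arena_has_no_conflicts(self):
        assert detect_overlaps(schema.ConcreteArena()) == []

    def test_rotated_flush_boxes_do_not_false_positive(self):
        # two thin walls side by side at 45 degrees: their axis-aligned
        # bounding boxes overlap but the true footprints do not
        a = _placed("Wall", 20.0, 20.0, sx=0.5, sz=6.0, rot=45.0)
        b = _placed("Wall", 21.5, 18.5, sx=0.5, sz=6.0, rot=45.0)
        arena = schema.ConcreteArena(objects=[a, b])
        assert detect_overlaps(arena) == []

    def test_separated_objects_do_not_conflict(self):
        arena = schema.ConcreteArena(objects=[
            _placed("Wall", 5, 5), _placed("Wall", 30, 30)])
        assert detect_overlaps(arena) == []


class TestPrecedencePlacement:
    def test_later_object_is_relocated_earlier_kept(self):
        wall = _placed("Wall", 10, 10)
        ramp = _placed("Ramp", 10, 10)
        arena = schema.ConcreteArena(objects=[wall, ramp])
        out = place_with_precedence(arena, seed=0)
        assert out.objects[0].position == Vector3(10, 0, 10)
        assert out.objects[1].position != Vector3(10, 0, 10)
        assert detect_overlaps(out) == []

    def test_agent_takes_precedence_even_when_listed_last(self):
        block = _placed("LightBlock", 10, 10)
        agent = PlacedObject(name="Agent", position=Vector3(10, 0, 10))
        arena = schema.ConcreteArena(objects=[block, agent])
        out = place_with_precedence(arena, seed=0)
        assert out.objects[1].position == Vector3(10, 0, 10)   # agent kept
        assert out.objects[0].position != Vector3(10, 0, 10)   # block moved

    def test_non_overlapping_config_unchanged(self):
        arena = schema.ConcreteArena(objects=[
            _placed("Wall", 5, 5), _placed("Wall", 30, 30)])
        out = place_with_precedence(arena, seed=0)
        assert [o.position for o in out.objects] == \
            [Vector3(5, 0, 5), Vector3(30, 0, 30)]

    def test_unplaceable_object_raises(self):
        huge = _placed("Wall", 20, 20, sx=39.0, sz=39.0)
        other = _placed("Wall", 20, 20, sx=39.0, sz=39.0)
        arena = schema.ConcreteArena(objects=[huge, other])
        with pytest.raises(PlacementError, match="Wall"):
            place_with_precedence(arena, seed=0)

    def test_placement_is_pure_under_seed(self):
        arena = schema.ConcreteArena(objects=[
            _placed("Wall", 10, 10), _placed("Ramp", 10, 10),
            _placed("LightBlock", 10, 10)])
        a = place_with_precedence(arena, seed=9)
        b = place_with_precedence(arena, seed=9)
        assert [o.position for o in a.objects] == \
            [o.position for o in b.objects]

    def test_placed_solids_stay_inside_footprint(self):
        arena = schema.ConcreteArena(objects=[
            _placed("Wall", 10, 10) for _ in range(6)])
        out = place_with_precedence(arena, seed=2)
        for obj in out.objects:
            lo, hi = obj.aabb()
            assert lo[0] >= -1e-9 and lo[2] >= -1e-9
            assert hi[0] <= 40 + 1e-9 and hi[2] <= 40 + 1e-9
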
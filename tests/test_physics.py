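"""Discrete-time physics: actions, forces, collisions, ramps, determinism."""

import numpy as np
import pytest

from arenalab.physics import (Action, Body, apply_action, is_ramp_climbable,
                              step_world)
from arenalab.env import ArenaEnv, EnvConfig, ObservationSpec
from tests.conftest import make_config, make_env


def _agent(yaw=0.0, x=20.0, z=20.0):
    return Body(kind="Agent", pos=np.array([x, 0.5, z]), yaw=yaw)


class TestApplyAction:
    def test_left_turns_minus_six_degrees(self):
        assert apply_action(_agent(yaw=0), Action.LEFT).yaw == 354.0

    def test_right_turns_plus_six_degrees(self):
        assert apply_action(_agent(yaw=0), Action.RIGHT).yaw == 6.0

    def test_no_action_at_rest_leaves_position_unchanged(self):
        env = make_env("""
arenas:
  0:
    timeLimit: 0
    items:
      - name: Agent
        positions: [{x: 20, y: 0, z: 20}]
        rotations: [0]
""")
        before = env.world.agent.pos.copy()
        for _ in range(10):
            env.step(Action.NO_ACTION)
        assert np.allclose(env.world.agent.pos, before)

    def test_forwards_moves_along_heading(self):
        env = make_env("""
arenas:
  0:
    timeLimit: 0
    items:
      - name: Agent
        positions: [{x: 20, y: 0, z: 20}]
        rotations: [90]
""")
        env.step(Action.FORWARDS)
        assert env.world.agent.pos[0] > 20.0           # +x for yaw 90
        assert env.world.agent.pos[2] == pytest.approx(20.0)

    def test_unknown_action_code_rejected(self):
        with pytest.raises(ValueError, match="action"):
            apply_action(_agent(), 17)


class TestGravityAndDissipation:
    def test_unsupported_goal_falls_monotonically_to_ground(self):
        env = make_env("""
arenas:
  0:
    timeLimit: 0
    items:
      - name: Agent
        positions: [{x: 5, y: 0, z: 5}]
      - name: GoodGoalMulti
        positions: [{x: 30, y: 5, z: 30}]
        sizes: [1]
""")
        goal = env.world.bodies[1]
        ys = []
        for _ in range(60):
            env.step(Action.NO_ACTION)
            ys.append(goal.pos[1])
        assert all(a >= b for a, b in zip(ys, ys[1:]))
        assert ys[-1] == pytest.approx(0.5)            # resting on the floor

    def test_speed_non_increasing_under_no_action(self):
        env = make_env("""
arenas:
  0:
    timeLimit: 0
    items:
      - name: Agent
        positions: [{x: 20, y: 0, z: 20}]
        rotations: [0]
""")
        for _ in range(20):
            env.step(Action.FORWARDS)
        speeds = []
        for _ in range(30):
            env.step(Action.NO_ACTION)
            speeds.append(float(np.linalg.norm(env.world.agent.vel)))
        assert all(a >= b - 1e-12 for a, b in zip(speeds, speeds[1:]))


class TestCollisions:
    def _push_block(self, kind):
        env = make_env(f"""
arenas:
  0:
    timeLimit: 0
    items:
      - name: Agent
        positions: [{{x: 20, y: 0, z: 16}}]
        rotations: [0]
      - name: {kind}
        positions: [{{x: 20, y: 0, z: 18.5}}]
        sizes: [{{x: 2, y: 1, z: 2}}]
""")
        block = env.world.bodies[1]
        start = block.pos[2]
        for _ in range(80):
            env.step(Action.FORWARDS)
        return block.pos[2] - start

    def test_light_block_displaced_at_least_as_far_as_heavy(self):
        light = self._push_block("LightBlock")
        heavy = self._push_block("HeavyBlock")
        assert light > 0 and heavy > 0
        assert light >= heavy

    def test_bounce_goal_reflects_off_arena_wall(self):
        env = make_env("""
arenas:
  0:
    timeLimit: 0
    items:
      - name: Agent
        positions: [{x: 5, y: 0, z: 5}]
      - name: GoodGoalBounce
        positions: [{x: 36, y: 0, z: 20}]
        sizes: [1]
        special: {initialVelocity: {x: 1, y: 0, z: 0}, speed: 0.3}
""")
        goal = env.world.bodies[1]
        assert goal.vel[0] > 0
        for _ in range(30):
            env.step(Action.NO_ACTION)
            if goal.vel[0] < 0:
                break
        assert goal.vel[0] < 0                         # reflected at x = 40

    def test_wall_blocks_agent(self):
        env = make_env("""
arenas:
  0:
    timeLimit: 0
    items:
      - name: Agent
        positions: [{x: 20, y: 0, z: 16}]
        rotations: [0]
      - name: Wall
        positions: [{x: 20, y: 0, z: 20}]
        sizes: [{x: 10, y: 3, z: 1}]
""")
        for _ in range(60):
            env.step(Action.FORWARDS)
        assert env.world.agent.pos[2] < 19.5 - 0.49

    def test_zones_never_impede_motion(self):
        base = """
arenas:
  0:
    timeLimit: 0
    items:
      - name: Agent
        positions: [{x: 20, y: 0, z: 5}]
        rotations: [0]
"""
        zone = """
      - name: HotZone
        positions: [{x: 17, y: 0, z: 15}]
        sizes: [{x: 6, y: 2, z: 6}]
"""
        with_zone = make_env(base + zone)
        without = make_env(base)
        for _ in range(100):
            with_zone.step(Action.FORWARDS)
            without.step(Action.FORWARDS)
        assert np.allclose(with_zone.world.agent.pos, without.world.agent.pos)


class TestContainment:
    def test_agent_footprint_stays_inside_arena(self):
        env = make_env("""
arenas:
  0:
    timeLimit: 0
    items:
      - name: Agent
        positions: [{x: 38, y: 0, z: 38}]
        rotations: [45]
""")
        for _ in range(200):
            env.step(Action.FORWARDS)
            x, _, z = env.world.agent.pos
            assert 0.5 - 1e-9 <= x <= 39.5 + 1e-9
            assert 0.5 - 1e-9 <= z <= 39.5 + 1e-9


class TestRamps:
    @pytest.mark.parametrize("height,length,expected", [
        (4.0, 1.0, True),      # boundary of the 4:1 rule
        (4.5, 1.0, False),
        (0.0, 1.0, True),
        (2.0, 2.0, True),
        (16.0, 2.0, False),
    ])
    def test_climbability_rule(self, height, length, expected):
        assert is_ramp_climbable(height, length) is expected

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            is_ramp_climbable(1.0, 0.0)

    @pytest.mark.parametrize("ratio", [1.0, 2.0, 4.0, 4.5, 8.0])
    def test_forward_drive_ascends_exactly_the_climbable_ramps(self, ratio):
        length = 2.0
        height = ratio * length
        env = make_env(f"""
arenas:
  0:
    timeLimit: 0
    items:
      - name: Agent
        positions: [{{x: 20, y: 0, z: 2}}]
        rotations: [0]
      - name: Ramp
        positions: [{{x: 20, y: 0, z: 10}}]
        rotations: [0]
        sizes: [{{x: 4, y: {height}, z: {length}}}]
""")
        top = 0.0
        for _ in range(200):
            r = env.step(Action.FORWARDS)
            top = max(top, r.info["position"][1] - 0.5)
        reached = top >= height - 1e-6
        assert reached is is_ramp_climbable(height, length)


class TestDeterminism:
    def test_identical_state_and_actions_give_bitwise_identical_states(self):
        yaml_text = """
arenas:
  0:
    timeLimit: 0
    items:
      - name: Agent
        positions: [{x: 10, y: 0, z: 10}]
        rotations: [30]
      - name: LightBlock
        positions: [{x: 14, y: 0, z: 14}]
        sizes: [2]
      - name: GoodGoalBounce
        positions: [{x: 25, y: 0, z: 25}]
        sizes: [1]
        special: {initialVelocity: {x: -1, y: 0, z: 1}}
"""
        actions = [Action.FORWARDS, Action.FORWARDS_LEFT, Action.RIGHT,
                   Action.BACKWARDS, Action.FORWARDS_RIGHT] * 30
        snaps = []
        for _ in range(2):
            env = make_env(yaml_text, seed=11)
            for a in actions:
                env.step(a)
            snaps.append(env.world.serialise())
        assert snaps[0] == snaps[1]
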
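"""Episode lifecycle: reset/step contract, freezing, timeouts, multi-arena
episodes, logging, determinism."""

import numpy as np
import pytest

from arenalab.env import ArenaEnv, EnvConfig, ObservationSpec, run_episode
from arenalab.physics import Action
from arenalab.valence import TerminationCause
from tests.conftest import make_config, make_env

_GOAL_AHEAD = """
arenas:
  0:
    timeLimit: 0
    items:
      - name: Agent
        positions: [{x: 20, y: 0, z: 10}]
        rotations: [0]
      - name: GoodGoal
        positions: [{x: 20, y: 0, z: 14}]
        sizes: [1]
"""


class TestReset:
    def test_health_starts_at_100_and_reward_at_0(self):
        env = make_env(_GOAL_AHEAD)
        assert env.valence.health == 100.0
        assert env.valence.reward == 0.0

    def test_same_seed_gives_identical_initial_observations(self):
        cfg = make_config("""
arenas:
  0:
    timeLimit: 100
    items:
      - name: Agent
        positions: [random]
        rotations: [random]
      - name: GoodGoal
        positions: [random]
        sizes: [1]
""")
        spec = ObservationSpec(raycast=True, rays=15, proprio=True)
        a = ArenaEnv(EnvConfig(config=cfg, observations=spec)).reset(seed=3)
        b = ArenaEnv(EnvConfig(config=cfg, observations=spec)).reset(seed=3)
        assert np.array_equal(a.raycast.matrix, b.raycast.matrix)
        assert a.proprio.position == b.proprio.position

    def test_empty_arena_gives_valid_observation(self):
        env = make_env("arenas:\n  0:\n    timeLimit: 10\n",
                       observations=ObservationSpec(rays=9))
        obs = env.reset(seed=0)
        assert obs.raycast.matrix.shape == (8, 9)


class TestStep:
    def test_goal_contact_terminates_with_goal_cause(self):
        env = make_env(_GOAL_AHEAD)
        for _ in range(50):
            r = env.step(Action.FORWARDS)
            if r.terminated:
                break
        assert r.terminated and not r.truncated
        assert env.valence.cause is TerminationCause.GOAL
        assert env.valence.reward == pytest.approx(1.0)

    def test_timeout_truncates_with_reward_minus_one(self, empty_arena_yaml):
        env = make_env(empty_arena_yaml)
        for _ in range(50):
            r = env.step(Action.NO_ACTION)
        assert r.truncated and not r.terminated
        assert env.valence.reward == pytest.approx(-1.0, abs=1e-9)
        assert env.log.termination_cause == "timeout"

    def test_step_after_termination_raises(self, empty_arena_yaml):
        env = make_env(empty_arena_yaml)
        for _ in range(50):
            env.step(Action.NO_ACTION)
        with pytest.raises(RuntimeError, match="reset"):
            env.step(Action.NO_ACTION)

    def test_terminated_and_truncated_never_both(self, empty_arena_yaml):
        env = make_env(empty_arena_yaml)
        for _ in range(50):
            r = env.step(Action.NO_ACTION)
            assert not (r.terminated and r.truncated)

    def test_death_zone_contact_costs_one_and_ends(self):
        env = make_env("""
arenas:
  0:
    timeLimit: 0
    items:
      - name: Agent
        positions: [{x: 20, y: 0, z: 20}]
      - name: DeathZone
        positions: [{x: 18, y: 0, z: 18}]
        sizes: [{x: 6, y: 2, z: 6}]
""")
        r = env.step(Action.NO_ACTION)
        assert r.terminated
        assert r.reward_delta == pytest.approx(-1.0)
        assert env.valence.cause is TerminationCause.DEATHZONE

    def test_hot_zone_decrements_ten_times_faster(self):
        zone_yaml = """
arenas:
  0:
    timeLimit: 100
    items:
      - name: Agent
        positions: [{x: 20, y: 0, z: 20}]
      - name: HotZone
        positions: [{x: 17, y: 0, z: 17}]
        sizes: [{x: 6, y: 2, z: 6}]
"""
        hot = make_env(zone_yaml).step(Action.NO_ACTION).reward_delta
        cold = make_env("""
arenas:
  0:
    timeLimit: 100
    items:
      - name: Agent
        positions: [{x: 20, y: 0, z: 20}]
""").step(Action.NO_ACTION).reward_delta
        assert hot / cold == pytest.approx(10.0)


class TestFrozenAgent:
    def test_agent_immobile_and_undrained_while_frozen(self):
        env = make_env("""
arenas:
  0:
    timeLimit: 100
    frozenAgentDelays: 10
    items:
      - name: Agent
        positions: [{x: 20, y: 0, z: 20}]
        rotations: [0]
""")
        start = env.world.agent.pos.copy()
        for _ in range(10):
            r = env.step(Action.FORWARDS)
        assert np.allclose(env.world.agent.pos, start)
        assert env.valence.reward == 0.0
        env.step(Action.FORWARDS)
        assert env.valence.reward < 0.0        # decrement resumes

    def test_other_bodies_keep_moving_while_agent_frozen(self):
        env = make_env("""
arenas:
  0:
    timeLimit: 100
    frozenAgentDelays: 20
    items:
      - name: Agent
        positions: [{x: 20, y: 0, z: 20}]
      - name: GoodGoalMulti
        positions: [{x: 30, y: 6, z: 30}]
        sizes: [1]
""")
        goal = env.world.bodies[1]
        y0 = goal.pos[1]
        env.step(Action.FORWARDS)
        assert goal.pos[1] < y0                # still falling


class TestMultiArena:
    _TWO_ARENAS = """
episodeMode: multi-arena-single-episode
arenas:
  0:
    timeLimit: 0
    items:
      - name: Agent
        positions: [{x: 20, y: 0, z: 10}]
        rotations: [0]
      - name: GoodGoal
        positions: [{x: 20, y: 0, z: 14}]
        sizes: [1]
  1:
    timeLimit: 0
    passMark: 1.5
    items:
      - name: Agent
        positions: [{x: 20, y: 0, z: 10}]
        rotations: [0]
      - name: GoodGoal
        positions: [{x: 20, y: 0, z: 14}]
        sizes: [1]
"""

    def test_goal_advances_arena_and_reward_accumulates(self):
        env = make_env(self._TWO_ARENAS)
        rewards = []
        for _ in range(200):
            r = env.step(Action.FORWARDS)
            if r.terminated:
                break
        assert env.valence.reward == pytest.approx(2.0)
        assert env.arena_index == 1
        assert env.log.outcome == "pass"
        # one continuous log spanning both arenas
        indices = {row["arenaIndex"] for row in env.log.rows}
        assert indices == {0, 1}

    def test_single_arena_multi_mode_behaves_sequentially(self):
        env = make_env("""
episodeMode: multi-arena-single-episode
arenas:
  0:
    timeLimit: 0
    items:
      - name: Agent
        positions: [{x: 20, y: 0, z: 10}]
        rotations: [0]
      - name: GoodGoal
        positions: [{x: 20, y: 0, z: 14}]
        sizes: [1]
""")
        for _ in range(100):
            r = env.step(Action.FORWARDS)
            if r.terminated:
                break
        assert r.terminated and env.valence.reward == pytest.approx(1.0)


class TestRunEpisode:
    def test_log_row_count_equals_steps_taken(self, empty_arena_yaml):
        log = run_episode(lambda obs: Action.NO_ACTION,
                          EnvConfig(config=make_config(empty_arena_yaml),
                                    observations=ObservationSpec(
                                        raycast=False)), seed=0)
        assert len(log.rows) == 50
        assert log.outcome == "fail"           # passMark 0 > reward -1

    def test_accounting_identity_on_logged_episode(self):
        from arenalab.agents import OraclePolicy
        from arenalab.procgen import build_foraging_task
        cfg = build_foraging_task()
        log = run_episode(OraclePolicy("foraging"),
                          EnvConfig(config=cfg,
                                    observations=ObservationSpec(
                                        raycast=False)), seed=4)
        total = sum(row["rewardDelta"] for row in log.rows)
        assert total == pytest.approx(log.final_reward, abs=1e-9)
        assert log.rows[-1]["rewardCumulative"] == pytest.approx(
            log.final_reward, abs=1e-12)

    def test_same_seed_gives_identical_logs(self, empty_arena_yaml):
        from arenalab.agents import RandomPolicy
        cfg = EnvConfig(config=make_config(empty_arena_yaml),
                        observations=ObservationSpec(raycast=False))
        a = run_episode(RandomPolicy(), cfg, seed=8)
        b = run_episode(RandomPolicy(), cfg, seed=8)
        assert a.rows == b.rows
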
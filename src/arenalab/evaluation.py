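"""Batch evaluation: agent x configuration sweeps with derived per-episode
seeds, and pass-rate summaries by level."""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .env import ArenaEnv, EnvConfig, ObservationSpec, run_episode
from .schema import ConfigFile

_SEED_MOD = 2**31 - 1


@dataclass
class ConfigEntry:
    """One configuration in a battery, with an id and an optional level."""

    config_id: str
    config: ConfigFile
    level: int | None = None


def run_battery(agents: dict[str, object], configs: list[ConfigEntry],
                episodes_per_config: int, seed: int,
                observations: ObservationSpec | None = None,
                max_steps: int = 5000) -> pd.DataFrame:
    """Run every (agent, config) pair ``episodes_per_config`` times.

    ``agents`` maps a name to a policy object (reset per episode with a
    seed derived from ``seed``, so the sweep is fully reproducible).
    Returns one row per episode: agentName, configId, level, episodeIndex,
    finalReward, outcome, steps, seed.
    """
    obs_spec = observations or ObservationSpec()
    rows = []
    for agent_name in sorted(agents):
        policy = agents[agent_name]
        for entry in configs:
            for ep in range(episodes_per_config):
                ep_seed = int(np.random.default_rng(
                    (seed, zlib.crc32(agent_name.encode()),
                     zlib.crc32(entry.config_id.encode()), ep)
                ).integers(_SEED_MOD))
                cfg = EnvConfig(config=entry.config, observations=obs_spec,
                                seed=ep_seed)
                log = run_episode(policy, cfg, seed=ep_seed,
                                  max_steps=max_steps)
                rows.append({
                    "agentName": agent_name,
                    "configId": entry.config_id,
                    "level": entry.level,
                    "episodeIndex": ep,
                    "finalReward": log.final_reward,
                    "outcome": log.outcome,
                    "steps": len(log.rows),
                    "seed": ep_seed,
                })
    return pd.DataFrame(rows)


def pass_rate_by_level(result: pd.DataFrame) -> pd.DataFrame:
    """Proportion of episodes passed per (agent, level); exact integer
    arithmetic on the episode table."""
    if result.empty:
        raise ValueError("battery result is empty")
    df = result.dropna(subset=["level"])
    grouped = (df.assign(passed=(df["outcome"] == "pass").astype(int))
                 .groupby(["agentName", "level"], as_index=False)
                 .agg(episodes=("passed", "size"), passes=("passed", "sum")))
    grouped["proportionPassed"] = grouped["passes"] / grouped["episodes"]
    return grouped


def chance_summary(result: pd.DataFrame, agent_name: str) -> dict:
    """Median and IQR of one agent's final rewards (the chance reference
    when applied to the random-action agent)."""
    scores = result.loc[result["agentName"] == agent_name, "finalReward"]
    if scores.empty:
        raise ValueError(f"no episodes for agent {agent_name!r}")
    q1, med, q3 = scores.quantile([0.25, 0.5, 0.75])
    return {"median": float(med), "iqr": float(q3 - q1),
            "q1": float(q1), "q3": float(q3), "n": int(scores.size)}
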
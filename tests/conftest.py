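import numpy as np
import pytest

from arenalab import schema
from arenalab.env import ArenaEnv, EnvConfig, ObservationSpec


def make_config(yaml_text: str) -> schema.ConfigFile:
    return schema.parse_config(yaml_text)


def make_env(yaml_text: str, seed: int = 1,
             observations: ObservationSpec | None = None) -> ArenaEnv:
    cfg = EnvConfig(config=make_config(yaml_text),
                    observations=observations
                    or ObservationSpec(raycast=False, proprio=True))
    env = ArenaEnv(cfg)
    env.reset(seed=seed)
    return env


@pytest.fixture
def empty_arena_yaml():
    return """
arenas:
  0:
    timeLimit: 50
    items:
      - name: Agent
        positions: [{x: 20, y: 0, z: 20}]
        rotations: [0]
"""


@pytest.fixture
def rng():
    return np.random.default_rng(0)
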
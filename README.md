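# arenalab

A headless, deterministic arena simulator for building
comparative-cognition-style behavioural experiments on computational
agents. It is aimed at researchers who want to pose classic
animal-cognition problems — foraging, operant conditioning, detour and
avoidance tasks, object permanence — to artificial agents in a controlled,
fully reproducible virtual laboratory, with no game engine or graphics
stack required.

## The model

An episode takes place in a 40×40-unit walled arena containing an agent (a
sphere of diameter 1) and a set of declaratively configured objects: walls,
ramps, tunnels, movable blocks (masses 1, 1.5 and 2), valenced goals and
zones, goal dispensers, a pressable spawner button, and sign boards. The
world advances in discrete time; at each step the agent takes one of nine
actions (combinations of forwards/backwards thrust and ±6° yaw), and a
semi-implicit Euler step applies gravity, drag, friction, collision
impulses shared in proportion to mass, and normal support. Ramps are
climbable exactly when their height:length ratio is at most 4:1.

Reward and health follow exact accounting rules. With time limit *t*,
cumulative reward *R* changes per step as

    ΔR = −1/t          (0 if t = 0; −10/t inside a hot zone)

plus ±v on contact with a valenced goal of size v (valence ≡ size).
GoodGoal/BadGoal end the episode; the "Multi", ripening/decaying and
growing/shrinking variants are collected without ending it; a death zone
costs exactly −1 and terminates. Health starts at 100, moves by
100·ΔR clamped to [0, 100] (a 0.5-valence goal restores 50 points), and
ends the episode in failure at 0. An episode is a *pass* iff the final
reward reaches the arena's `passMark`.

Agents observe the world through any combination of raycasts (an 8×r
matrix: six object-category rows, a no-hit row, and a normalised-distance
row, over r odd rays fanned across a configurable span), a flat-shaded
k×k ray-grid camera (4 ≤ k ≤ 512, optional grayscale), and proprioception
(health, velocity, position). Scheduled lights-out windows zero all visual
values.

## Worked example

Arenas are YAML files; built-in tasks can be emitted and run from the
shell:

```bash
arenalab task foraging -o foraging.yaml
arenalab run foraging.yaml --agent heuristic --episodes 1 --seed 7
```

The foraging task places a spawner tree at the arena centre (20,0,20) that
drops 10 goals of size 2, with the agent starting at a random *x* on the
near edge. Running the three baseline agents on it with seed 7:

```
random    reward -1.000  outcome fail  cause timeout  steps 500
heuristic reward +19.000  outcome pass  cause timeout  steps 500
oracle    reward +19.000  outcome pass  cause timeout  steps 500
```

The random agent (the chance reference: uniform over the nine actions,
action-repeat lengths from a clipped normal with mean 5 and sd 1) collects
nothing and drains the −1/t decrement to exactly −1 at timeout. The
heuristic raycast forager (45 rays over the frontal 60°) and the
full-state oracle collect all ten goals — +20 reward minus 1 lost to the
per-step decrement over the 500-step episode — and pass.

The same machinery drives the operant-chamber task (`arenalab task
operant --stage K`): a button at (38.5,0,18.8), enclosed by walls on three
sides, spawns a size-1 GoodGoal at (39,3,22) when pressed on its front
face, with a five-stage shaping curriculum that moves the agent's spawn
from directly in front of the button to a fully random position. Batch
sweeps over agents × configuration directories are run with `arenalab
battery`, and procedurally generated task variations with `arenalab gen`.

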
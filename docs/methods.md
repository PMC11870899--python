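# Methods

This note documents the models, conventions and numerical choices behind
arenalab, in the spirit of a simulator methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## World model and units

The arena is a 40×40-unit square floor with impassable boundary walls;
coordinates are (x, y, z) with y vertical. One environment step equals one
physics substep and one agent decision. The agent is a sphere of diameter
1 and mass 1; movable blocks have masses 1 (light), 2 (heavy) and 1.5
(U/L/J-shaped and hollow boxes). Object order in a configuration file is
placement precedence: the agent is always placed first, later objects that
overlap an already-placed solid are relocated uniformly at random (at most
100 attempts, then an error). Valenced zones are passable volumes and are
exempt from overlap handling.

Overlap detection uses the exact y-rotated footprints: a 2D
separating-axis test between rotated rectangles (circle-vs-rectangle and
circle-vs-circle for spheres) combined with a vertical-interval test. An
earlier conservative variant — axis-aligned boxes enclosing the rotated
footprints — was rejected because it flags deliberately flush task
geometry (the operant chamber's angled walls around its button) as
overlapping and scatters it; exactness here is what makes tightly built
apparatus constructible at all.

## Physics

The transition is semi-implicit Euler with, in order: the action
(±6°/turn-component yaw change, a fixed velocity impulse of 0.03 units/step
per drive component along the heading), gravity (0.05 units/step² on −y),
drag (per-step velocity loss of 0.025 × cross-section), ground friction
(8% horizontal velocity loss per grounded step), position integration,
ground/ramp support, and collision resolution. Only translation (plus the
agent's yaw) is simulated; blocks do not rotate. These constants are
calibrated to two behavioural targets rather than to any physical system:
a forward-driving agent crosses the arena in ≈150 steps (terminal speed
≈0.27 units/step), and ramp ascent switches exactly at the 4:1
height:length boundary.

Collisions are sphere-vs-oriented-box (closest-point) and
sphere-vs-inclined-plane only. When a sphere strikes a movable block, the
push-out and the velocity transfer are shared in proportion to mass, so a
light block is displaced farther than a heavy one under the same drive.
`-Bounce` goals start with a configurable or random horizontal velocity,
reflect with horizontal restitution 1, and roll without ground friction
(drag only); all other grounded bodies are friction-damped. Tunnels are
approximated by two side walls and a ceiling slab, leaving the passage
open.

Climbable ramps (height/length ≤ 4) act as walkable inclined surfaces:
support height rises linearly along the ramp's local +z axis, extended one
sphere radius past the top edge to model edge contact, and a per-step
support rise is capped at 1.5 units so that walking into a ramp's tall
face does not teleport the body upward. Non-climbable ramps are solid
obstacles; the 4:1 rule is therefore exact by construction, and a scripted
forward drive tops ramps at ratios {1, 2, 4} and fails at {4.5, 8}. A
known limitation: a body approaching a *climbable* ramp's tall rear face
can pass through it, since climbable ramps are excluded from box
collision; task builders should orient ramps with the slope facing
traffic.

## Reward, health, schedules

The per-step decrement is −1/t (0 when t = 0); inside a hot zone the
accelerated −10/t rate *replaces* the base rate ("10× faster than time
alone" is read as a total rate, not an addition). Valence equals goal
diameter with proportionality constant 1, anchored by the health rule:
health moves by 100 × the reward delta, clamped to [0, 100], for
increments and decrements alike (so a 0.5-valence goal restores 50
points). Decaying/ripening valences and growing/shrinking sizes are
piecewise linear: hold for `delay` steps, interpolate over `duration`
steps, clamp thereafter; decay and ripen are exact mirror images. Growth
halts (size frozen at its last value) while surrounding space is
restricted and resumes when cleared. A death zone costs exactly −1 and
terminates with cause `deathzone` even though the same swing drains health
to zero; when the time decrement itself zeroes health on the timeout step,
the episode reports a timeout. Episode pass/fail is `reward ≥ passMark`
(inclusive boundary).

## Interactive objects

Spawner trees drop their configured number of goals from 3 units above
the canopy, at uniformly random angles and radii within an annulus from
1.3 (trunk clearance) to 2.0 (canopy radius); drop times are jittered
uniformly within consecutive `interval` windows after `delay`. The annulus
matters: fruit dropped over the solid trunk would come to rest on top of
it, uncollectable. Dispensers emit at the hatch every `interval` steps.
The button spawns on contact with its front (local +z) face only, gated by
a cooldown of `resetSteps`; kind is drawn in proportion to the configured
weights. The dispenser `delay`/`interval` pair is treated as an
inter-spawn cadence (the one-shot reading is also plausible; the cadence
reading makes `count` > 1 meaningful). Sign-board preset symbols are
package-drawn 16×16 monochrome bitmaps — only the identifiers are
normative — and pixel grids resolve each `*` cell to 0/1 with probability
one half under the episode seed.

## Observations

Raycast rows are, in order: six category one-hots (positive goal, negative
goal/zone, immovable, movable, dispenser/button, signboard), a no-hit
flag, and distance normalised by the 60-unit maximum ray length (covering
the arena diagonal ≈56.6). The row semantics are an arenalab convention,
following common ray-sensor layouts in agent toolkits. The decoy goal is
reported in the positive-goal category (it is visually a goal; that is
what makes it a decoy). Rays are cast in 3D from the agent's eye (its
centre) along the horizontal plane, so a ray meets a sphere's surface, not
its silhouette. The camera is a flat-shaded ray-grid renderer (60° field
of view, constant sky/floor/fence colours, no lighting); grayscale is the
standard Rec. 601 luminance. Transparent walls and tunnels are invisible
to the camera but register on raycasts as immovable — a divergence risk
flagged as such, since the original environment's behaviour here is
unstated. Lights-out windows (explicit `[a, b)` intervals or an
alternating period) zero every visual value and never touch
proprioception.

## Episodes and seeding

`reset(seed)` derives independent sub-seeds for randomness resolution,
placement, and in-episode stochasticity (tree drops, button draws,
sign-board cells), so every episode is a pure function of (configuration,
seed, action sequence); the suite checks this bitwise on serialised world
states. During `frozenAgentDelays` the agent's actions are ignored and the
per-step decrement is suspended while other bodies continue to move. In
multi-arena single-episode mode, collecting an episode-ending goal loads
the next arena without resetting cumulative reward or health; death zones,
health failure and timeouts end the whole episode — the advance rule is an
arenalab convention, chosen so curricula can chain sub-tasks while keeping
failure terminal.

## Built-in tasks and baseline agents

The foraging task uses a 500-step time limit (the health drain from
−1/t reaches zero at exactly t steps, so t is also the unaided survival
horizon), pass mark 10, tree drops starting at step 10 every 20 steps.
The operant chamber uses the printed layout (button at (38.5,0,18.8),
goal spawned at (39,3,22)); the button faces the stage-1 spawn point
(36,0,20) (yaw 296°), with the three enclosing walls flush with its sides
and rear — only the button and goal positions are printed, so the wall
coordinates are package choices. Curriculum stages interleave all earlier
configurations when cumulative, shuffled deterministically under seed.

The random agent draws actions in proportion to its weights (optionally
blended with an exponential recency histogram, coefficient `correlation`,
decay 0.9 — the mechanism behind "correlate with previous actions" is a
package choice) and repeats each for max(1, round(N(5, 1))) steps. The
heuristic navigator steers toward the nearest target-category ray
(forwards / forwards-left / forwards-right by ray position), rotates when
nothing is visible (forager) or repeats its previous action (operant
variant), and jinks forwards-left/right with probability ½ when stuck
(speed < 0.01 units/step over a 5-step window). Its raycasts carry
category information only, so the operant variant cannot tell a button's
front from its back — reproduced deliberately. The scripted oracles use
full world state: greedy nearest-goal pursuit (foraging) and a staged
axis-aligned button approach with carrot-point pursuit plus a wall detour
to the spawned goal (operant); both include a jam-recovery sidestep.

## What the synthetic tasks do and do not show

Every experiment here is synthetic by construction: the tasks are built by
the package's own generators, so passing tests demonstrates internal
consistency of the mechanics (reward arithmetic, the 4:1 rule, placement
precedence, determinism) and the *ordering* of baseline agents (heuristic
above chance on foraging), not fidelity to any particular game engine's
contact dynamics, nor the learnability of these tasks by trained
reinforcement-learning agents — training is out of scope. Problem sizes in
the suite (100-episode medians, 90,000 action draws, 10,000 repeat draws,
30,000 button presses) were chosen as the smallest sizes at which the
Monte-Carlo error is comfortably below the asserted tolerances.

## Known limitations

- No rotational dynamics: blocks translate without torque; U/L/J block
  shapes collide as their bounding boxes, so their pulling affordance is
  not modelled.
- Goal-goal collisions are not resolved (goals may interpenetrate while
  falling); only agent-goal contact has consequences.
- The camera renderer is flat-shaded with no occlusion-free transparency
  model; transparent objects simply do not occlude.
- Sphere-vs-sphere pushing (agent rolling a goal) is not modelled; goals
  move only under gravity, initial velocity, and wall reflection.
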
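# reachsim

A pure-software twin of a head-fixed mouse joystick reaching platform:
closed-loop task engines for four reaching task variants, a synthetic mouse
that generates realistic joystick traces, an offline reach
segmentation/kinematics pipeline, an automated training scheduler, and exact
session-log I/O.

## What it does

- **Task engine** (`reachsim.engine`) — tick-based (default 1 kHz) state
  machines for four tasks: basic center-out reaching (radial displacement past
  an amplitude threshold → reward after a 1-s delay → fixed 3-s ITI),
  variable-amplitude operant (per-trial threshold schedule), cued
  reaction-time (go-cue light; anticipatory reaches draw a 5000-ms timeout
  and a trial restart with a new random ITI), and a bidirectional two-armed
  bandit (reach direction sectors carry different reward probabilities that
  swap between blocks). Every random draw is recorded in the event payload,
  so sessions replay exactly.
- **Synthetic mouse** (`reachsim.synthetic`) — minimum-jerk
  outward-and-back reaches with baseline jitter, sub-threshold postural
  "blips", optional opposite-direction "rev-up" pre-movements, cue-locked
  reaction times, and a win-stay/lose-shift bandit policy. Replaces the
  animal and the hardware; all test inputs are generated, nothing is
  downloaded.
- **Analysis** (`reachsim.analysis`) — threshold-crossing reach detection
  that works forward and backward in time from each crossing to the full
  initiation/termination boundaries, kinematics (amplitude, peak outward
  velocity, duration, direction), inter-reach intervals, reaction times
  (values above 5 s omitted), moving average of the last five RTs, and the
  expert-session criterion (>100 rewarded reaches at a ≥0.9 cm threshold).
- **Auto-trainer** (`reachsim.trainer`) — two 30-min sessions/day for the
  first three days then one; after acquisition the amplitude threshold rises
  at most 1 mm/day from 0.1 to 0.9 cm and the reward delay 50 ms/day from
  500 ms to 1 s, gated on session performance; light-early/light-late go-cue
  regimens with punishment introduced at day 14.
- **Session I/O** (`reachsim.sessionio`) — a CSV session format
  (`# key=value` metadata, then `t_ms,x_cm,y_cm,event,payload` rows) that
  round-trips bit-exactly; headerless `t,x,y` streams are accepted for
  analysis-only use.

## CLI

```sh
# run one closed-loop session (synthetic mouse vs. task engine)
reachsim run --config examples/basic.yml --seed 7 --out session.csv

# segment reaches and summarise
reachsim analyze --in session.csv --detect-cm 0.9 --out reaches.csv,summary.json

# print the summary JSON only
reachsim summarize --in session.csv

# simulate an automated training progression
reachsim train --days 21 --seed 1 --regimen light_early --out progression.csv

# write short canonical seeded fixtures
reachsim fixtures --out-dir fixtures/ --seed 0
```

Config files are YAML with optional `task:`, `agent:` and `trainer:`
sections; every default is overridable (see `TaskConfig`, `AgentParams`,
`TrainerConfig`).

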
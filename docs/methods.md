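# Methods

`lhsched` simulates and schedules the liquid-handling operations of a
48× parallel mL-scale bioreactor system.  One pipetting robot (eight
1000 µL channels) is shared by every process-control task — intermittent
substrate feeding, base titration for pH control, multi-stage sampling,
induction — and becomes the bottleneck whenever several of them fall due
together.  The package implements the dynamic, priority-based dispatcher
that resolves this bottleneck, a digital twin of the robot, a synthetic
fed-batch plant that generates the sensor streams the priorities react
to, and a file-backed time-series store, so complete experiments run and
are verified entirely in silico.

## Priority calculus

Every task owns a baseline priority `p_base` and a critical priority
`p_crit` on a dimensionless, per-experiment scale (defaults 10 and 100).
No computed priority may exceed `p_crit` (the cap `p_max = p_crit`).  A
task that violates a hard constraint on every demand-bearing reactor, or
that requires no execution, has priority 0.

Before any priority calculation the task's constraints are evaluated per
reactor.  A constraint bounds one quantity — requested volume (µL), time
since the task last serviced the reactor (s), absolute experiment clock
(s), or vessel fill level (µL) — from below or above, and is *hard*
(prohibits execution, e.g. the minimum pipettable volume) or *soft*
(violable, escalates priority, e.g. a feed-interval ceiling).  The
evaluation returns boolean vectors over the `n_all` active reactors:
`hard_violated`, `soft_violated`, and `affected` (requires action and
passes every hard constraint, `n_aff` positions in total), plus the
soft-violation extent in native units.

Four algorithms map an evaluation to a priority `p`:

- **step** — 0 if blocked; `p_base` if no constraint violated; `p_crit`
  if a soft constraint is violated.
- **step specific** — the step levels weighted by the affected fraction:
  `p_base · n_aff/n_all`, and under soft violation
  `p_base + (p_crit − p_base) · n_aff/n_all`.  `n_all` shrinks when
  malfunctioning positions are excluded.
- **dynamic volume** —
  `p = p_base + (p_crit − p_base)/n_all · Σᵢ (vᵢ − v_lim,lower,i)/Δv_lim,i`
  summed over the affected positions, where `v_lim,lower` and
  `Δv_lim = v_lim,upper − v_lim,lower` come from the task's volume
  constraints.
- **dynamic time** — the same linear form with the per-position time
  since last execution against the task's time bounds.

Design choices where the calculus is underdetermined: each dynamic
summand is clamped to [0, 1] before summation and the total is capped at
`p_crit`, so a single far-overdue reactor cannot produce unbounded
priorities; a hard violation on a strict subset of reactors removes those
reactors from the sum (via `affected = false`) rather than zeroing the
whole task; soft violations of the dynamic algorithms do not switch to a
separate branch — the linear ramp itself is the escalation, with the soft
upper bound marking the point where the per-reactor term saturates at 1.

## Scheduler

A scheduler instance has three phases: initialization (validate the task
graph, connect the twins, start data acquisition), run, and termination.
The run loop advances an event-driven simulated clock: a fixed evaluation
tick (default 10 s), plus command-completion and sensor-acquisition
events, whichever comes first.  At every event the loop steps the plant,
excludes reactors whose stirrer failed, collects a fresh priority from
every non-executing task (an executing task retains its last report —
execution is non-preemptive), persists all reports, and, if the robot is
idle, dispatches the task with the highest priority as a minimal command
message (method name, ordered volumes, target/source position sequences).

Ties break deterministically: higher priority, then the older earliest
per-reactor last execution (starvation-averse), then declaration order in
the configuration.  Because every priority report is persisted, a
finished run can be verified independently: `replay_run` re-applies the
greedy rule to the stored priority log alone and must reproduce the
dispatch log exactly.

Reactor exclusion is permanent for the run: the position leaves `n_all`,
appears in no later command, but continues to be measured (flagged
inactive).  The termination sequence — stop all task runtimes, close the
availability stream, stop acquisition, park the devices, record the cause
— runs on scheduled aborts, on explicit aborts, and, through a guard
around the run loop, on any unexpected failure.

## Liquid-handler twin

The twin merges the broker that exposes the robot with the simulator
behind it, preserving the broker's message contract.  It validates each
command against the declared deck labware and channel limits (unknown
method or position, length mismatches, per-channel volume outside
[10, 1000] µL, empty commands — all blocking) and against the
experiment's declared intent (a nonzero volume outside the dispatching
task's hard volume bounds is a non-blocking "miscalculated volume"
discrepancy).  All findings go to a structured log file; a correct
end-to-end run leaves it empty.

Execution duration is affine in pipetting cycles:
`overhead(method) + ceil(n_targets / n_channels) · per_cycle_duration`,
optionally scaled by a seeded lognormal jitter factor (off by default).
The real robot's historical timing data is not available, so overhead and
cycle times are profile parameters (defaults 30 s each).  Busy/idle
transitions are published on a subscribable availability stream with
monotone timestamps; mutual exclusion is enforced — executing while busy
raises, as it would indicate a dispatcher bug.

## Synthetic plant

The plant is the simplest kinetic model that reproduces the pH
phenomenology the scheduler must react to, per reactor and uncoupled:

- glucose uptake at a Monod rate `q = q_glc_max · S/(S + K_s)`, with a
  fixed fraction (`overflow_fraction`) of the consumed glucose excreted
  as acetate while glucose is present (overflow metabolism), the rest
  yielding biomass;
- pH falls with acetate formed (`k_pH_acid` per g/L) and with biomass
  formed (`k_pH_growth` per g/L — proton extrusion during growth on
  ammonium, the persistent acid load that keeps one-sided base control
  engaged);
- once glucose is depleted (below 1 mg/L — the Monod tail decays
  geometrically and would otherwise never reach zero) acetate is consumed
  at up to `q_ace_max` and pH rises by the same coupling;
- dissolved oxygen relaxes toward a demand-dependent level at rate `kLa`;
- base addition raises pH by `k_pH_base · volume/fill`; feed adds glucose
  mass at the substrate concentration (300 g/L) with dilution; sampling
  removes broth.

Defaults (µ-scale E. coli fed-batch): `q_glc_max` 1.2 g/(g·h), `K_s`
0.05 g/L, yield 0.5 g/g, overflow fraction 0.2, `q_ace_max` 0.8 g/(g·h),
`k_pH_acid` 0.5, `k_pH_growth` 0.15, `k_pH_base` 0.025 pH·mL/µL, `kLa`
300 1/h, initial state 1 g/L biomass, 3 g/L glucose, pH 7.1, 10 mL fill.
The acetate parameters were fixed so that the famine phase between
30-minute boluses clears the acetate formed during the preceding feast —
the regime in which the described pH interplay (fall under overflow, rise
under acetate consumption, hence a falling titration-task priority)
actually occurs; without the growth-acid term the net-neutral acetate
cycle lets one-sided base control ratchet the pH upward instead.

Sensor reads (default every 60 simulated seconds) emit pH, DO and stirrer
status per reactor, with optional Gaussian noise applied on read only;
the internal state stays noise-free, and a parallel noise-free
`plant_state` series (glucose, acetate) is persisted as ground truth for
verification.  Stirrer malfunctions are a seeded Poisson process flagging
positions permanently.  What the generator does **not** emulate:
inter-reactor coupling, temperature or gassing dynamics, structured
metabolism, sensor drift.  A green closed-loop test therefore establishes
that the scheduler reacts correctly to the modeled phenomenology, not
that the kinetics are quantitatively predictive.

## Reference scenario

`lhsched.presets.fed_batch_config` is the stated world of the test suite:
48 reactors, 8 h, exponential feeding (30 µL/h at t=0 growing at 0.2/h,
hard 1800 s minimum interval, soft 2400 s ceiling, dynamic-volume
priority with `p_base` 50), titration (gain 400 µL/pH, setpoint 7.0,
deadband 0.1, dynamic volume, `p_base` 10), and a five-stage sampling
chain every 7200 s (dynamic time, ramping from 10 toward 100 over 3600 s
of lag).  Feeding's high base priority encodes the design intent that the
feeding interval is the primary controlled quantity; sampling stages fill
the idle gaps and escalate only when seriously overdue.  Titration doses
to `setpoint − deadband` (the demand formula `gain · max(0, setpoint −
deadband − pH)`), so the closed-loop pH rides near the band edge with
famine-phase rebounds above it.

## Numerical and design notes

- Explicit Euler at the scheduler tick for the plant; glucose bookkeeping
  is mass-exact (balance checked to 1e-6 g over full runs).
- One experiment seed fans out via `numpy` `SeedSequence` to independent
  plant and twin streams; identical configuration + seed yields
  byte-identical dispatch logs and datastore files.
- Timestamps are simulated seconds from experiment start (floats); data
  points are unique on (measurement, timestamp, tags) and a duplicate
  write overwrites.
- Demands are clamped to the channel's pipettable ceiling; volumes below
  a task's hard minimum leave the reactor unaffected rather than sending
  an illegal command.
- Sampling stages are gated per reactor on predecessor completion
  (execution counts), which enforces strict stage order without a
  workflow engine.
- A DO-control task is deliberately absent; pH control is one-sided
  (base only).  Runtime task addition/removal goes through an in-process
  request queue; there is no network API or GUI.

## Known limitations

- The greedy dispatcher considers only current priorities — no look-ahead
  to imminent crossings and no preemption; a long command can delay a
  task that becomes critical immediately after dispatch.
- Plate-level sampling stages (transport, measurement, wash) are timed
  with the same per-cycle formula as pipetting steps.
- The replay verifier assumes a clean run (no blocked dispatches); runs
  with deliberately invalid commands verify through the discrepancy log
  instead.
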
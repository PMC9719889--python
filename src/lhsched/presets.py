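"""Reference experiment configurations.

``fed_batch_config`` builds the standard in-silico experiment this package
is developed against: 48 parallel mL-reactors, an intermittent
exponential feeding task and a one-sided pH-control task (both prioritized
by the dynamic-volume algorithm), and a five-stage sampling chain
(withdrawal, preparation, reader transport, measurement, washing)
prioritized by the dynamic-time algorithm — the task mix of a typical
bottleneck scenario on a shared eight-channel pipetting robot.

All numbers are the package's documented stated world (see
docs/methods.md): a 30 uL/h initial exponential feed growing at 0.2/h, a
30-minute minimum feed interval with a 10-minute soft ceiling, pH
setpoint 7.0 with a 0.1 deadband and 400 uL/pH titration gain, and
2-hourly sampling of 200 uL.
"""

from __future__ import annotations

from .config import ExperimentConfig, load_config_dict

SAMPLING_STAGES = (
    # (suffix, method, volume uL, overhead s)
    ("withdraw", "sample_withdraw", 200.0, 30.0),
    ("prepare", "sample_prepare", 50.0, 30.0),
    ("transport", "sample_transport", 0.0, 60.0),
    ("measure", "sample_measure", 0.0, 120.0),
    ("wash", "sample_wash", 0.0, 60.0),
)


def sampling_stage_blocks(
    interval: float = 7200.0,
    chase_span: float = 3600.0,
    p_base: float = 10.0,
    p_crit: float = 100.0,
) -> list[dict]:
    """The five-stage sampling chain as config task blocks.

    Stage 1 becomes eligible every ``interval`` seconds; stages 2-5 are
    gated on per-reactor completion of their predecessor.  Every stage's
    priority ramps from ``p_base`` when it falls due toward ``p_crit`` over
    ``chase_span`` seconds of lag, so a sampling round fills the idle gaps
    between feeds instead of monopolising the robot.
    """
    blocks = []
    prev = None
    for k, (suffix, method, volume, _overhead) in enumerate(SAMPLING_STAGES):
        name = f"sampling_{suffix}"
        # stage 1 must never run early (hard lower bound); later stages may
        # start as soon as their predecessor finishes (soft lower bound)
        lower_kind = "hard" if k == 0 else "soft"
        constraints = [
            {"name": "sampling_interval", "kind": lower_kind,
             "quantity": "elapsed_time", "bound": "lower",
             "limit": interval},
            {"name": "sampling_ceiling", "kind": "soft",
             "quantity": "elapsed_time", "bound": "upper",
             "limit": interval + chase_span},
        ]
        blocks.append({
            "name": name,
            "method_name": method,
            "task_class": "sampling_stage",
            "demand": {"kind": "time_trigger", "parameters": {"volume": volume}},
            "priority": {"algorithm": "dynamic_time",
                         "p_base": p_base, "p_crit": p_crit},
            "constraints": constraints,
            "stage_index": k,
            "predecessor": prev,
        })
        prev = name
    return blocks


def feeding_block(
    min_interval: float = 1800.0,
    soft_ceiling: float = 600.0,
    v0: float = 30.0,
    mu: float = 0.2,
    p_base: float = 50.0,
    p_crit: float = 100.0,
) -> dict:
    """Intermittent exponential feeding, dynamic-volume priority.

    The demand is the substrate volume accrued since the last bolus; the
    hard lower time bound enforces the minimum feeding interval and the
    soft upper bound ``min_interval + soft_ceiling`` marks the tolerated
    delay before the interval constraint counts as violated.  The default
    base priority is deliberately the highest of the reference task mix:
    holding the feeding interval is the primary control objective, so an
    eligible feed outranks titration and mid-ramp sampling stages and
    waits at most for the command currently on the robot.
    """
    return {
        "name": "feed",
        "method_name": "feed_reactors",
        "task_class": "feeding",
        "demand": {"kind": "exponential_feed",
                   "parameters": {"v0": v0, "mu": mu}},
        "priority": {"algorithm": "dynamic_volume",
                     "p_base": p_base, "p_crit": p_crit},
        "constraints": [
            {"name": "min_feed_interval", "kind": "hard",
             "quantity": "elapsed_time", "bound": "lower",
             "limit": min_interval},
            {"name": "max_feed_interval", "kind": "soft",
             "quantity": "elapsed_time", "bound": "upper",
             "limit": min_interval + soft_ceiling},
            {"name": "min_bolus", "kind": "hard", "quantity": "volume",
             "bound": "lower", "limit": 10.0},
            {"name": "max_bolus", "kind": "soft", "quantity": "volume",
             "bound": "upper", "limit": 400.0},
            {"name": "fill_cap", "kind": "hard", "quantity": "fill_level",
             "bound": "upper", "limit": 15000.0},
        ],
    }


def ph_control_block(
    setpoint: float = 7.0,
    deadband: float = 0.1,
    gain: float = 400.0,
    p_base: float = 10.0,
    p_crit: float = 100.0,
) -> dict:
    """One-sided pH control by NaOH addition, dynamic-volume priority."""
    return {
        "name": "ph_control",
        "method_name": "add_base",
        "task_class": "ph_control",
        "demand": {"kind": "proportional_titration",
                   "parameters": {"gain": gain, "setpoint": setpoint,
                                  "deadband": deadband}},
        "priority": {"algorithm": "dynamic_volume",
                     "p_base": p_base, "p_crit": p_crit},
        "constraints": [
            {"name": "min_base_shot", "kind": "hard", "quantity": "volume",
             "bound": "lower", "limit": 10.0},
            {"name": "max_base_shot", "kind": "soft", "quantity": "volume",
             "bound": "upper", "limit": 200.0},
            {"name": "fill_cap", "kind": "hard", "quantity": "fill_level",
             "bound": "upper", "limit": 15000.0},
        ],
    }


def abort_block(t_abort: float) -> dict:
    """Scheduled abort: fires once the experiment clock passes ``t_abort``."""
    return {
        "name": "abort",
        "method_name": "abort",
        "task_class": "abort",
        "demand": {"kind": "time_trigger", "parameters": {"once": True}},
        "priority": {"algorithm": "step", "p_base": 1000.0, "p_crit": 1000.0},
        "constraints": [
            {"name": "abort_at", "kind": "hard", "quantity": "clock_time",
             "bound": "lower", "limit": t_abort},
        ],
    }


def fed_batch_config(
    n_reactors: int = 48,
    t_end: float = 28800.0,
    seed: int = 0,
    tick: float = 10.0,
    with_sampling: bool = True,
    with_ph: bool = True,
    feed_min_interval: float = 1800.0,
    sampling_interval: float = 7200.0,
    malfunction_rate: float = 0.0,
    noise_sd: dict | None = None,
    extra_tasks: list[dict] | None = None,
) -> ExperimentConfig:
    """The standard 8-hour in-silico fed-batch experiment."""
    tasks: list[dict] = [feeding_block(min_interval=feed_min_interval)]
    if with_ph:
        tasks.append(ph_control_block())
    if with_sampling:
        tasks.extend(sampling_stage_blocks(interval=sampling_interval))
    if extra_tasks:
        tasks.extend(extra_tasks)
    overheads = {method: overhead for _, method, _, overhead in SAMPLING_STAGES}
    overheads["feed_reactors"] = 30.0
    overheads["add_base"] = 30.0
    return load_config_dict({
        "experiment": {"name": "insilico_fed_batch", "operator": "sim"},
        "seed": seed,
        "reactors": {"count": n_reactors, "glucose": 3.0, "biomass": 1.0,
                     "pH": 7.1, "fill_volume": 10.0},
        "clock": {"tick": tick, "t_end": t_end, "mode": "event_driven"},
        "lhs_profile": {"per_method_overhead": overheads,
                        "per_cycle_duration": 30.0},
        "plant": {"malfunction_rate": malfunction_rate,
                  "noise_sd": noise_sd or {"pH": 0.0, "DO": 0.0}},
        "sensor_interval": 60.0,
        "tasks": tasks,
    })
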
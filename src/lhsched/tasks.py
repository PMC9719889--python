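"""Schedulable task classes and their runtime state machines.

A task bundles an LHS method with a demand model, a constraint set and
priority parameters.  Concrete classes: intermittent substrate feeding,
one-sided pH control (base titration), a multi-stage sampling chain
(withdrawal, preparation, reader transport, measurement, washing),
one-shot induction inside a fixed clock window, and a scheduled abort.

At every scheduler tick each non-executing task recomputes its demand from
the live per-reactor sensor data, evaluates its constraints and reports a
fresh priority; the reported value and the task state are persisted as
time-series points.  Execution is non-preemptive: once dispatched, a task
reports no new priority until its completion callback runs.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .constraints import (
    Bound,
    ConstraintConfigError,
    ConstraintEvaluation,
    ConstraintKind,
    ConstraintSpec,
    Quantity,
    evaluate_constraints,
)
from .plant import ReactorState
from .priority import (
    Algorithm,
    PriorityParams,
    PriorityResult,
    priority_dynamic_time,
    priority_dynamic_volume,
    priority_step,
    priority_step_specific,
)

logger = logging.getLogger(__name__)

SENSOR_STALENESS_S = 300.0  # demand falls to zero when pH data is older


class TaskClass(str, enum.Enum):
    FEEDING = "feeding"
    PH_CONTROL = "ph_control"
    SAMPLING_STAGE = "sampling_stage"
    INDUCTION = "induction"
    ABORT = "abort"


class DemandKind(str, enum.Enum):
    CONSTANT_VOLUME = "constant_volume"
    EXPONENTIAL_FEED = "exponential_feed"
    PROPORTIONAL_TITRATION = "proportional_titration"
    TIME_TRIGGER = "time_trigger"


class TaskStatus(str, enum.Enum):
    IDLE = "idle"
    AWAITING_DISPATCH = "awaiting_dispatch"
    EXECUTING = "executing"
    STOPPED = "stopped"


@dataclass(frozen=True)
class DemandModel:
    """How a task computes its per-reactor demand.

    constant_volume: params ``volume`` (uL) — fixed bolus per execution.
    exponential_feed: params ``v0`` (uL/h at t=0), ``mu`` (1/h) — the
        demand is the feed volume accrued since the last execution,
        (v0/mu) * (e^(mu t_now) - e^(mu t_last)); volumes in uL, t in h.
    proportional_titration: params ``gain`` (uL per pH unit), ``setpoint``,
        ``deadband`` — base volume gain * max(0, setpoint - deadband - pH).
    time_trigger: params ``volume`` (uL, may be 0 for non-pipetting
        stages), ``once`` (bool) — binary demand gated by constraints
        and, for sampling stages, by predecessor completion.
    """

    kind: DemandKind
    parameters: dict = field(default_factory=dict)

    def p(self, name: str, default: float | None = None) -> float:
        if name in self.parameters:
            return self.parameters[name]
        if default is None:
            raise ConstraintConfigError(
                f"demand model {self.kind.value} missing parameter {name!r}"
            )
        return default


@dataclass(frozen=True)
class TaskSpec:
    name: str
    method_name: str
    task_class: TaskClass
    constraints: tuple[ConstraintSpec, ...]
    priority_params: PriorityParams
    demand_model: DemandModel
    stage_index: int = 0
    predecessor: str | None = None

    def __post_init__(self) -> None:
        if self.stage_index < 0:
            raise ValueError("stage_index must be >= 0")


def _limits_from_constraints(
    constraints: tuple[ConstraintSpec, ...],
    quantity: Quantity,
    n: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Derive per-reactor (lower, span) vectors for the dynamic formulas.

    The lower limit is the tightest declared lower bound on ``quantity``;
    the span runs to the tightest *soft* upper bound (the escalation
    ceiling), falling back to any upper bound if no soft one exists.
    """
    lower = np.full(n, -np.inf)
    upper_soft = np.full(n, np.inf)
    upper_any = np.full(n, np.inf)
    seen_lower = seen_upper = False
    for c in constraints:
        if c.quantity is not quantity:
            continue
        mask = np.fromiter((c.covers(i) for i in range(n)), dtype=bool, count=n)
        if c.bound is Bound.LOWER:
            lower[mask] = np.maximum(lower[mask], c.limit)
            seen_lower = True
        else:
            upper_any[mask] = np.minimum(upper_any[mask], c.limit)
            if c.kind is ConstraintKind.SOFT:
                upper_soft[mask] = np.minimum(upper_soft[mask], c.limit)
            seen_upper = True
    if not (seen_lower and seen_upper):
        raise ConstraintConfigError(
            f"dynamic priority needs lower and upper bounds on "
            f"{quantity.value}, found lower={seen_lower}, upper={seen_upper}"
        )
    upper = np.where(np.isfinite(upper_soft), upper_soft, upper_any)
    span = upper - lower
    return lower, span


class TaskRuntime:
    """Mutable runtime of one task: execution history, demand, status."""

    def __init__(self, spec: TaskSpec, n_positions: int,
                 max_volume: float | None = None):
        self.spec = spec
        self.n_positions = n_positions
        self.max_volume = max_volume  # pipettable ceiling from the LHS profile
        self.last_execution = np.zeros(n_positions, dtype=float)
        self.exec_count = np.zeros(n_positions, dtype=int)
        self.pending_demand = np.zeros(n_positions, dtype=float)
        self.status = TaskStatus.IDLE
        self.current_priority = PriorityResult(0.0)
        self.predecessor_runtime: "TaskRuntime | None" = None

    # -- demand --------------------------------------------------------------
    def compute_demand(
        self,
        reactors: list[ReactorState],
        now: float,
        active: np.ndarray,
        sensor_time: float | None = None,
        sensor_ph: np.ndarray | None = None,
    ) -> np.ndarray:
        """Per-position demand vector (uL, or a 0/1 flag); 0 for inactive.

        Titration reads the last *acquired* pH (``sensor_ph``, which may
        carry sensor noise) when available, falling back to the live plant
        state; data older than the staleness threshold zeroes the demand.
        """
        dm = self.spec.demand_model
        demand = np.zeros(self.n_positions, dtype=float)
        if dm.kind is DemandKind.CONSTANT_VOLUME:
            demand[:] = dm.p("volume")
        elif dm.kind is DemandKind.EXPONENTIAL_FEED:
            v0, mu = dm.p("v0"), dm.p("mu")
            t_now_h = now / 3600.0
            t_last_h = self.last_execution / 3600.0
            if mu > 0:
                demand = (v0 / mu) * (
                    np.exp(mu * t_now_h) - np.exp(mu * t_last_h)
                )
            else:
                demand = v0 * (t_now_h - t_last_h)
        elif dm.kind is DemandKind.PROPORTIONAL_TITRATION:
            if sensor_time is not None and now - sensor_time > SENSOR_STALENESS_S:
                logger.warning(
                    "task %s: pH data stale (%.0f s old), demand set to 0",
                    self.spec.name, now - sensor_time,
                )
                return demand
            gain = dm.p("gain")
            setpoint = dm.p("setpoint")
            deadband = dm.p("deadband")
            if sensor_ph is not None:
                ph = np.asarray(sensor_ph, dtype=float)
            else:
                ph = np.array([r.pH for r in reactors])
            demand = gain * np.maximum(0.0, setpoint - deadband - ph)
        elif dm.kind is DemandKind.TIME_TRIGGER:
            if dm.parameters.get("once", False):
                demand = (self.exec_count == 0).astype(float)
            elif self.predecessor_runtime is not None:
                demand = (
                    self.exec_count < self.predecessor_runtime.exec_count
                ).astype(float)
            else:
                demand[:] = 1.0
        if self.max_volume is not None and dm.kind is not DemandKind.TIME_TRIGGER:
            demand = np.minimum(demand, self.max_volume)
        demand[~active] = 0.0
        return demand

    # -- constraint + priority chain -----------------------------------------
    def evaluate(
        self,
        reactors: list[ReactorState],
        now: float,
        active: np.ndarray,
        sensor_time: float | None = None,
        sensor_ph: np.ndarray | None = None,
    ) -> tuple[ConstraintEvaluation, np.ndarray]:
        """Demand + constraint evaluation over the *active* reactors."""
        self.pending_demand = self.compute_demand(
            reactors, now, active, sensor_time, sensor_ph
        )
        idx = np.flatnonzero(active)
        demand_act = self.pending_demand[idx]
        is_flag = self.spec.demand_model.kind is DemandKind.TIME_TRIGGER
        quantities = {
            Quantity.VOLUME: np.zeros(idx.size) if is_flag else demand_act,
            Quantity.ELAPSED_TIME: now - self.last_execution[idx],
            Quantity.CLOCK_TIME: np.full(idx.size, now),
            Quantity.FILL_LEVEL: np.array(
                [reactors[i].fill_volume * 1000.0 for i in idx]
            ),
        }
        ev = evaluate_constraints(list(self.spec.constraints), quantities, demand_act)
        return ev, idx

    def report_priority(
        self,
        reactors: list[ReactorState],
        now: float,
        active: np.ndarray,
        sensor_time: float | None = None,
        sensor_ph: np.ndarray | None = None,
    ) -> PriorityResult:
        """Recompute and store the task's priority; a non-preemption guard
        returns the last reported value while the task is executing."""
        if self.status is TaskStatus.EXECUTING:
            return self.current_priority
        if self.status is TaskStatus.STOPPED:
            return PriorityResult(0.0, timestamp=now)
        ev, idx = self.evaluate(reactors, now, active, sensor_time, sensor_ph)
        params = self.spec.priority_params
        algo = params.algorithm
        if algo is Algorithm.STEP:
            result = priority_step(ev, params, now)
        elif algo is Algorithm.STEP_SPECIFIC:
            result = priority_step_specific(ev, params, now)
        elif algo is Algorithm.DYNAMIC_VOLUME:
            lower, span = _limits_from_constraints(
                self.spec.constraints, Quantity.VOLUME, self.n_positions
            )
            result = priority_dynamic_volume(
                ev, self.pending_demand[idx], lower[idx], span[idx], params, now
            )
        elif algo is Algorithm.DYNAMIC_TIME:
            lower, span = _limits_from_constraints(
                self.spec.constraints, Quantity.ELAPSED_TIME, self.n_positions
            )
            result = priority_dynamic_time(
                ev, now - self.last_execution[idx], lower[idx], span[idx],
                params, now,
            )
        else:  # pragma: no cover
            raise ConstraintConfigError(f"unknown algorithm {algo}")
        self.current_priority = result
        self._last_eval = ev
        self._last_active_idx = idx
        return result

    # -- selection helpers ---------------------------------------------------
    def serviceable_reactors(self, active: np.ndarray) -> np.ndarray:
        """Positions to address in a dispatch: affected active reactors."""
        ev = getattr(self, "_last_eval", None)
        if ev is None:
            return np.empty(0, dtype=int)
        idx = self._last_active_idx
        return idx[ev.affected]

    def min_last_execution(self, active: np.ndarray) -> float:
        """Oldest last-execution time over active positions (tie-breaking)."""
        if not active.any():
            return math.inf
        return float(self.last_execution[active].min())

    def volume_bounds(self) -> tuple[float, float] | None:
        """Declared hard volume bounds, used by the twin's discrepancy check."""
        lo, hi = None, None
        for c in self.spec.constraints:
            if c.quantity is Quantity.VOLUME and c.kind is ConstraintKind.HARD:
                if c.bound is Bound.LOWER:
                    lo = c.limit if lo is None else max(lo, c.limit)
                else:
                    hi = c.limit if hi is None else min(hi, c.limit)
        if lo is None and hi is None:
            return None
        return (lo if lo is not None else 0.0, hi if hi is not None else math.inf)

    # -- lifecycle -----------------------------------------------------------
    def mark_dispatched(self) -> None:
        if self.status is not TaskStatus.IDLE:
            raise RuntimeError(
                f"task {self.spec.name} dispatched while {self.status.value}"
            )
        self.status = TaskStatus.EXECUTING

    def on_execution_complete(self, serviced: list[int], end_time: float) -> None:
        """Completion callback: update history for the serviced reactors only."""
        for i in serviced:
            if not 0 <= i < self.n_positions:
                raise IndexError(f"record names unknown reactor index {i}")
        for i in serviced:
            self.last_execution[i] = end_time
            self.exec_count[i] += 1
            self.pending_demand[i] = 0.0
        self.status = TaskStatus.IDLE

    def stop(self) -> None:
        self.status = TaskStatus.STOPPED
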
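"""The scheduler core: initialization, greedy run-loop, termination.

One scheduler instance owns the simulated experiment: the synthetic plant,
the liquid-handler twin, the datastore and one runtime per declared task.
Its life cycle has three phases — initialization, run, termination.

During the run phase the loop advances an event-driven simulated clock
(ticks plus command-completion events), steps the plant, acquires sensor
data, collects a fresh priority from every non-executing task and, when
the liquid handler is idle, dispatches the task with the highest priority.
Ties break deterministically: higher priority, then the older earliest
per-reactor last execution, then declaration order.  Reactor positions
whose stirrer malfunctions are excluded permanently: they leave every
subsequent priority calculation (``n_all`` shrinks) and no later command
addresses them.

The termination sequence — stop all task runtimes, close the availability
stream, stop data acquisition, park the device twins — runs on scheduled
aborts, on API aborts and, via a guard in :meth:`Scheduler.run`, on any
unexpected run-loop failure.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datastore import DataStore, TimeSeriesPoint
from .lhs_twin import ExecutionRecord, LHSCommand, LHSProfile, LHSTwin
from .plant import PlantParams, ReactorState, apply_addition, read_sensors, step_plant
from .tasks import DemandKind, TaskClass, TaskRuntime, TaskSpec, TaskStatus

logger = logging.getLogger(__name__)


class Phase(str, enum.Enum):
    INITIALIZATION = "initialization"
    RUN = "run"
    TERMINATION = "termination"
    STOPPED = "stopped"


class Cause(str, enum.Enum):
    API_ABORT = "api_abort"
    SCHEDULED_ABORT = "scheduled_abort"
    UNEXPECTED_EXIT = "unexpected_exit"
    COMPLETED = "completed"  # simulation horizon reached


class ClockMode(str, enum.Enum):
    REALTIME = "realtime"
    ACCELERATED = "accelerated"
    EVENT_DRIVEN = "event_driven"


@dataclass
class SimClock:
    """Simulated seconds since experiment start; never decreases.

    In ``event_driven`` mode the loop advances straight to the next
    scheduled event; ``accelerated``/``realtime`` modes carry a wall-clock
    scale factor but the in-silico loop never sleeps.
    """

    now: float = 0.0
    acceleration: float = 1.0
    mode: ClockMode = ClockMode.EVENT_DRIVEN

    def advance_to(self, t: float) -> None:
        if t < self.now:
            raise ValueError(f"clock cannot go backwards ({t} < {self.now})")
        self.now = t


class ConfigurationError(ValueError):
    pass


_PLANT_EFFECT = {
    TaskClass.FEEDING: "feed",
    TaskClass.PH_CONTROL: "base",
    TaskClass.SAMPLING_STAGE: "sample",
    TaskClass.INDUCTION: "inert",
}


@dataclass
class SchedulerSetup:
    """Everything `initialize` needs, already validated by the config layer."""

    experiment_name: str
    n_reactors: int
    initial_reactor: ReactorState
    profile: LHSProfile
    plant_params: PlantParams
    task_specs: list[TaskSpec]
    tick: float = 10.0
    t_end: float = 28800.0
    sensor_interval: float = 60.0
    clock_mode: ClockMode = ClockMode.EVENT_DRIVEN
    acceleration: float = 1.0
    seed: int = 0


class Scheduler:
    """Greedy, non-preemptive dispatcher over one liquid-handler resource."""

    def __init__(self, setup: SchedulerSetup, run_dir: str | Path):
        self.phase = Phase.INITIALIZATION
        self.setup = setup
        self.run_dir = Path(run_dir)
        self.run_dir.mkdir(parents=True, exist_ok=True)

        ss = np.random.SeedSequence(setup.seed)
        plant_seed, twin_seed = ss.spawn(2)
        self.plant_rng = np.random.default_rng(plant_seed)
        self.twin_rng = np.random.default_rng(twin_seed)

        self.clock = SimClock(
            0.0, setup.acceleration, setup.clock_mode
        )
        self.reactors = [
            ReactorState(**vars(setup.initial_reactor))
            for _ in range(setup.n_reactors)
        ]
        self.active = np.ones(setup.n_reactors, dtype=bool)
        self.store = DataStore(self.run_dir / "datastore.jsonl")
        self.twin = LHSTwin(
            setup.profile,
            discrepancy_log=self.run_dir / "discrepancies.log",
            rng=self.twin_rng if setup.profile.jitter_sigma > 0 else None,
        )
        self.availability = self.twin.subscribe()
        self._dispatch_fh = open(self.run_dir / "dispatch_log.jsonl", "w")

        self._validate_task_graph(setup.task_specs)
        self.tasks: dict[str, TaskRuntime] = {}
        for spec in setup.task_specs:
            self.tasks[spec.name] = TaskRuntime(
                spec, setup.n_reactors,
                max_volume=setup.profile.channel_volume_max,
            )
        for rt in self.tasks.values():
            if rt.spec.predecessor is not None:
                rt.predecessor_runtime = self.tasks[rt.spec.predecessor]

        self.dispatch_log: list[ExecutionRecord] = []
        self.executing: tuple[TaskRuntime, ExecutionRecord] | None = None
        self.cause: Cause | None = None
        self.glucose_added = np.zeros(setup.n_reactors)
        self.glucose_consumed = np.zeros(setup.n_reactors)
        self.glucose_sampled = np.zeros(setup.n_reactors)
        self._last_plant_time = 0.0
        self._next_acq = 0.0
        self._sensor_time: float | None = None
        self._sensor_ph: np.ndarray | None = None
        self._pending_requests: list[tuple[str, object]] = []
        self.phase = Phase.RUN

    # -- initialization helpers ----------------------------------------------
    @staticmethod
    def _validate_task_graph(specs: list[TaskSpec]) -> None:
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate task names")
        by_name = {s.name: s for s in specs}
        for s in specs:
            if s.predecessor is not None:
                if s.predecessor not in by_name:
                    raise ConfigurationError(
                        f"task {s.name!r} references undefined predecessor "
                        f"{s.predecessor!r}"
                    )
                pred = by_name[s.predecessor]
                if s.stage_index <= pred.stage_index:
                    raise ConfigurationError(
                        f"stage_index must increase along predecessor links "
                        f"({s.name}={s.stage_index} after "
                        f"{pred.name}={pred.stage_index})"
                    )
            # cycle check by walking the chain
            seen, cur = {s.name}, s.predecessor
            while cur is not None:
                if cur in seen:
                    raise ConfigurationError(
                        f"cycle in sampling predecessors at {cur!r}"
                    )
                seen.add(cur)
                cur = by_name[cur].predecessor if cur in by_name else None

    # -- runtime task management ---------------------------------------------
    def request_add_task(self, spec: TaskSpec) -> None:
        """Queue a task addition; applied at the start of the next tick."""
        self._pending_requests.append(("add", spec))

    def request_remove_task(self, name: str) -> None:
        self._pending_requests.append(("remove", name))

    def _process_requests(self) -> None:
        for kind, payload in self._pending_requests:
            if kind == "add":
                spec = payload
                if spec.name in self.tasks:
                    raise ConfigurationError(f"task {spec.name!r} already exists")
                # a runtime-added task brings a method the twin has not seen
                self.twin.profile.per_method_overhead.setdefault(
                    spec.method_name, self.twin.profile.default_overhead
                )
                self.tasks[spec.name] = TaskRuntime(
                    spec, self.setup.n_reactors,
                    max_volume=self.setup.profile.channel_volume_max,
                )
                if spec.predecessor is not None:
                    self.tasks[spec.name].predecessor_runtime = \
                        self.tasks[spec.predecessor]
            else:
                rt = self.tasks.pop(payload, None)
                if rt is not None:
                    rt.stop()
        self._pending_requests.clear()

    # -- reactor exclusion ---------------------------------------------------
    def exclude_reactor(self, reactor: int, reason: str) -> None:
        """Permanently remove a position from the run (idempotent)."""
        if not self.active[reactor]:
            logger.warning("reactor %d already excluded", reactor)
            return
        self.active[reactor] = False
        self.reactors[reactor].active = False
        self.store.write_points([TimeSeriesPoint(
            "exclusion", self.clock.now,
            {
                "experiment": self.setup.experiment_name,
                "reactor": str(reactor),
                "reason": reason,
            },
            {"excluded": 1.0},
        )])
        logger.info(
            "t=%.0f excluded reactor %d (%s)", self.clock.now, reactor, reason
        )

    # -- the run loop --------------------------------------------------------
    def run(self) -> Cause:
        """Execute the experiment to its horizon or an abort.

        The guard guarantees the termination sequence runs even when the
        loop body raises unexpectedly.
        """
        if self.phase is not Phase.RUN:
            raise RuntimeError(f"run() called in phase {self.phase.value}")
        try:
            while self.phase is Phase.RUN and self.clock.now <= self.setup.t_end:
                self.run_step()
                if self.phase is not Phase.RUN:
                    break
                nxt = self._next_event_time()
                if nxt > self.setup.t_end:
                    break
                self.clock.advance_to(nxt)
        except Exception:
            self.terminate(Cause.UNEXPECTED_EXIT)
            raise
        if self.phase is Phase.RUN:
            self.terminate(Cause.COMPLETED)
        return self.cause

    def _next_event_time(self) -> float:
        t = self.clock.now
        candidates = [t + self.setup.tick]
        if self.twin.busy_until is not None and self.twin.busy_until > t:
            candidates.append(self.twin.busy_until)
        if self._next_acq > t:
            candidates.append(self._next_acq)
        return min(candidates)

    def run_step(self) -> None:
        """One scheduling event at the current simulated time."""
        now = self.clock.now
        self._process_requests()

        # plant integration up to now
        dt = now - self._last_plant_time
        if dt > 0:
            step_plant(
                self.reactors, self.setup.plant_params, dt, self.plant_rng,
                consumed_out=self.glucose_consumed,
            )
            self._last_plant_time = now

        # malfunction monitoring -> exclusion
        for i, r in enumerate(self.reactors):
            if self.active[i] and not r.stirrer_ok:
                self.exclude_reactor(i, "stirrer_malfunction")

        # sensor acquisition
        if now >= self._next_acq:
            points = read_sensors(
                self.reactors, self.setup.plant_params, self.plant_rng,
                now, self.setup.experiment_name,
            )
            # noise-free ground truth of the twin plant, for verification
            points += [
                TimeSeriesPoint(
                    "plant_state", now,
                    {"experiment": self.setup.experiment_name,
                     "reactor": str(i)},
                    {"glucose": r.glucose, "acetate": r.acetate},
                )
                for i, r in enumerate(self.reactors)
            ]
            self.store.write_points(points)
            self._sensor_time = now
            self._sensor_ph = np.array([
                p.fields["value"] for p in points if p.measurement == "pH"
            ])
            while self._next_acq <= now:
                self._next_acq += self.setup.sensor_interval

        # command completion
        if self.executing is not None and self.twin.busy_until is not None \
                and now >= self.twin.busy_until:
            self._complete_execution()

        # priority collection (executing task retains its last value)
        reports: list[tuple[str, float, float]] = []
        for name, rt in self.tasks.items():
            res = rt.report_priority(
                self.reactors, now, self.active, self._sensor_time,
                self._sensor_ph,
            )
            reports.append((name, res.value, rt.min_last_execution(self.active)))
        self.store.write_points([
            TimeSeriesPoint(
                "priority", now,
                {"experiment": self.setup.experiment_name, "task": name},
                {"value": value, "min_last_exec": mle},
            )
            for name, value, mle in reports
        ])

        # greedy dispatch
        if self.twin.is_idle_at(now) and self.executing is None:
            self._dispatch(reports, now)

    def _dispatch(self, reports: list[tuple[str, float, float]], now: float) -> None:
        order = {name: i for i, name in enumerate(self.tasks)}
        ranked = sorted(
            (r for r in reports if r[0] in self.tasks),
            key=lambda r: (-r[1], r[2], order[r[0]]),
        )
        if not ranked or ranked[0][1] <= 0:
            return
        name = ranked[0][0]
        rt = self.tasks[name]
        if rt.spec.task_class is TaskClass.ABORT:
            logger.info("t=%.0f scheduled abort task fired", now)
            self.terminate(Cause.SCHEDULED_ABORT)
            return
        targets = rt.serviceable_reactors(self.active)
        if targets.size == 0:
            return
        cmd = self._build_command(rt, targets)
        try:
            record = self.twin.execute_command(
                cmd, now,
                task_name=name,
                reactor_indices=list(map(int, targets)),
                volume_limits=rt.volume_bounds(),
            )
        except ValueError as exc:
            logger.error("t=%.0f dispatch of %s rejected: %s", now, name, exc)
            return
        rt.mark_dispatched()
        self.executing = (rt, record)
        # logged at dispatch so an in-flight command at the simulation
        # horizon is still visible to the greedy-replay verification
        self._dispatch_fh.write(json.dumps({
            "task": record.task_name,
            "method": record.command.method_name,
            "start": record.start_time,
            "end": record.end_time,
            "reactors": record.serviced_reactors,
            "volumes": record.delivered_volumes,
            "findings": record.validation_findings,
        }, sort_keys=True) + "\n")

    def _build_command(self, rt: TaskRuntime, targets: np.ndarray) -> LHSCommand:
        spec = rt.spec
        if spec.demand_model.kind is DemandKind.TIME_TRIGGER:
            vol = spec.demand_model.parameters.get("volume", 0.0)
            volumes = tuple(float(vol) for _ in targets)
        else:
            volumes = tuple(float(rt.pending_demand[i]) for i in targets)
        target_seq = tuple(f"R{i:02d}" for i in targets)
        source = {
            TaskClass.FEEDING: "substrate",
            TaskClass.PH_CONTROL: "naoh",
            TaskClass.INDUCTION: "inducer",
        }.get(spec.task_class)
        source_seq = tuple(source for _ in targets) if source else None
        return LHSCommand(spec.method_name, volumes, target_seq, source_seq)

    def _complete_execution(self) -> None:
        rt, record = self.executing
        end = record.end_time
        self.twin.complete(self.clock.now)
        effect = _PLANT_EFFECT.get(rt.spec.task_class)
        points = []
        for i, vol in zip(record.serviced_reactors, record.delivered_volumes):
            if effect is not None and vol > 0:
                if effect == "sample":
                    # glucose leaves with the withdrawn broth
                    self.glucose_sampled[i] += self.reactors[i].glucose * vol * 1e-6
                apply_addition(
                    self.reactors[i], effect, vol, self.setup.plant_params
                )
                if effect == "feed":
                    self.glucose_added[i] += \
                        vol * self.setup.plant_params.feed_glucose_conc * 1e-6
            points.append(TimeSeriesPoint(
                "execution", end,
                {
                    "experiment": self.setup.experiment_name,
                    "task": rt.spec.name,
                    "reactor": str(i),
                },
                {"volume": float(vol), "start": record.start_time},
            ))
        self.store.write_points(points)
        rt.on_execution_complete(record.serviced_reactors, end)
        self.dispatch_log.append(record)
        self.executing = None

    # -- termination ---------------------------------------------------------
    def terminate(self, cause: Cause) -> None:
        """Best-effort termination sequence; safe to call in any phase."""
        if self.phase is Phase.STOPPED:
            return
        self.phase = Phase.TERMINATION
        self.cause = cause
        # an in-flight command is abandoned; its task is stopped with the rest
        if self.executing is not None:
            rt, record = self.executing
            self.twin.busy_until = None
            self.executing = None
        for rt in self.tasks.values():
            try:
                rt.stop()
            except Exception:  # pragma: no cover - best effort
                logger.exception("failed to stop task %s", rt.spec.name)
        try:
            self.twin.close()
        except Exception:  # pragma: no cover
            logger.exception("failed to close availability stream")
        try:
            self.store.write_points([TimeSeriesPoint(
                "run_event", self.clock.now,
                {"experiment": self.setup.experiment_name},
                {"terminated": 1.0},
            )])
            self.store.close()
        except Exception:  # pragma: no cover
            logger.exception("failed to close datastore")
        try:
            self._dispatch_fh.close()
        except Exception:  # pragma: no cover
            pass
        for r in self.reactors:
            r.stirrer_ok = r.stirrer_ok  # stirrers parked; twin has no motion state
        (self.run_dir / "termination.json").write_text(json.dumps(
            {"cause": cause.value, "t": self.clock.now}, sort_keys=True
        ) + "\n")
        self.phase = Phase.STOPPED
        logger.info("terminated at t=%.0f (%s)", self.clock.now, cause.value)


def initialize(setup: SchedulerSetup, run_dir: str | Path) -> Scheduler:
    """Build a scheduler in the run phase from a validated setup."""
    return Scheduler(setup, run_dir)
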
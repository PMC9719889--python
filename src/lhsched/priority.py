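"""Priority calculus for schedulable liquid-handler tasks.

Each task owns a baseline priority ``p_base`` and a critical priority
``p_crit``; no computed priority ever exceeds ``p_crit`` (the critical cap
``p_max = p_crit``).  A task that violates a hard constraint on every
demand-bearing reactor, or that requires no execution at all, has priority
zero.

Four algorithms are provided:

``step``
    Static three-level function of the constraint evaluation alone:
    0 / ``p_base`` / ``p_crit``.

``step_specific``
    The step levels scaled by the fraction of affected reactor positions
    ``n_aff / n_all``; ``n_all`` shrinks when malfunctioning positions are
    excluded from the run.

``dynamic_volume``
    Linear in the requested transfer volumes: each affected position i
    contributes ``(v_i - v_lim_lower_i) / dv_lim_i``, the total scaled by
    ``(p_crit - p_base) / n_all`` on top of ``p_base``.

``dynamic_time``
    Same form with the time since last execution replacing volume.

The per-position summands of the dynamic algorithms are clamped to [0, 1]
before summation, and every algorithm's result is capped at ``p_crit``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .constraints import ConstraintEvaluation


class Algorithm(str, enum.Enum):
    STEP = "step"
    STEP_SPECIFIC = "step_specific"
    DYNAMIC_VOLUME = "dynamic_volume"
    DYNAMIC_TIME = "dynamic_time"


class PriorityConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PriorityParams:
    """Baseline and critical priority plus algorithm choice.

    Priorities are dimensionless and comparable only across the tasks of one
    experiment; the defaults put the baseline at 10 and the cap at 100.
    """

    p_base: float = 10.0
    p_crit: float = 100.0
    algorithm: Algorithm = Algorithm.DYNAMIC_TIME

    def __post_init__(self) -> None:
        if not (0 <= self.p_base <= self.p_crit):
            raise PriorityConfigError(
                f"require 0 <= p_base <= p_crit, got p_base={self.p_base}, "
                f"p_crit={self.p_crit}"
            )


@dataclass(frozen=True)
class PriorityResult:
    """A computed priority with its per-reactor summands (dynamic only)."""

    value: float
    per_reactor_terms: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=float)
    )
    timestamp: float = 0.0


def _soft_among_affected(ev: ConstraintEvaluation) -> bool:
    return bool(np.any(ev.soft_violated & ev.affected))


def priority_step(
    ev: ConstraintEvaluation, params: PriorityParams, now: float = 0.0
) -> PriorityResult:
    """Static priority: 0 (blocked or idle) / p_base / p_crit (soft violated)."""
    if ev.n_aff == 0:
        return PriorityResult(0.0, timestamp=now)
    value = params.p_crit if _soft_among_affected(ev) else params.p_base
    return PriorityResult(min(value, params.p_crit), timestamp=now)


def priority_step_specific(
    ev: ConstraintEvaluation, params: PriorityParams, now: float = 0.0
) -> PriorityResult:
    """Step priority weighted by the affected fraction n_aff / n_all."""
    n_all = ev.n_all
    if n_all == 0 or ev.n_aff == 0:
        return PriorityResult(0.0, timestamp=now)
    frac = ev.n_aff / n_all
    if _soft_among_affected(ev):
        value = params.p_base + (params.p_crit - params.p_base) * frac
    else:
        value = params.p_base * frac
    return PriorityResult(min(value, params.p_crit), timestamp=now)


def _dynamic(
    ev: ConstraintEvaluation,
    values: np.ndarray,
    lim_lower: np.ndarray,
    lim_span: np.ndarray,
    params: PriorityParams,
    now: float,
    what: str,
) -> PriorityResult:
    n_all = ev.n_all
    if n_all == 0 or ev.n_aff == 0:
        return PriorityResult(0.0, timestamp=now)
    aff = ev.affected
    span = np.broadcast_to(np.asarray(lim_span, dtype=float), (n_all,))
    if np.any(span[aff] <= 0):
        raise PriorityConfigError(
            f"non-positive {what} limit span for an affected reactor"
        )
    values = np.broadcast_to(np.asarray(values, dtype=float), (n_all,))
    lower = np.broadcast_to(np.asarray(lim_lower, dtype=float), (n_all,))
    terms = np.zeros(n_all, dtype=float)
    terms[aff] = np.clip((values[aff] - lower[aff]) / span[aff], 0.0, 1.0)
    value = params.p_base + (params.p_crit - params.p_base) / n_all * terms.sum()
    return PriorityResult(
        min(value, params.p_crit), per_reactor_terms=terms, timestamp=now
    )


def priority_dynamic_volume(
    ev: ConstraintEvaluation,
    volumes: np.ndarray,
    v_lim_lower: np.ndarray,
    dv_lim: np.ndarray,
    params: PriorityParams,
    now: float = 0.0,
) -> PriorityResult:
    """Priority linear in requested volumes relative to each position's limits.

    ``volumes`` are the feed or base volumes (uL) of the positions that
    fulfil the constraints; ``v_lim_lower`` and ``dv_lim`` are the lower
    volume limit and the allowed span (upper minus lower) per position.
    """
    return _dynamic(ev, volumes, v_lim_lower, dv_lim, params, now, "volume")


def priority_dynamic_time(
    ev: ConstraintEvaluation,
    elapsed: np.ndarray,
    t_lim_lower: np.ndarray,
    dt_lim: np.ndarray,
    params: PriorityParams,
    now: float = 0.0,
) -> PriorityResult:
    """Priority linear in per-position time since last execution (seconds)."""
    return _dynamic(ev, elapsed, t_lim_lower, dt_lim, params, now, "time")
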
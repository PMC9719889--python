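"""Digital twin of the liquid-handling station (LHS).

The twin plays the role of both the broker that exposes the pipetting
robot to external control and the simulator behind it: it receives minimal
dispatch messages (method name, ordered volume array, target and optional
source position sequences), validates them against the declared deck
labware and the physical limits of the pipetting channels, emulates the
execution duration, publishes busy/idle transitions on a subscribable
availability stream, and writes every discrepancy between a command and
the experiment's declared intent to a structured log file.

Durations follow an affine model in pipetting cycles: a command on ``n``
targets with ``c`` channels takes ``overhead(method) + ceil(n / c) *
per_cycle_duration`` seconds, optionally scaled by a seeded lognormal
jitter factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class LHSProfile:
    """Physical capabilities and deck layout of the pipetting robot.

    The default profile models a station with eight 1000 uL pipetting
    channels.  ``deck_sequences`` maps labware names to ordered position
    lists; a command may only address positions present here.
    ``per_method_overhead`` doubles as the registry of known methods.
    """

    n_channels: int = 8
    channel_volume_max: float = 1000.0
    channel_volume_min: float = 10.0
    per_cycle_duration: float = 60.0
    per_method_overhead: dict = field(default_factory=dict)
    deck_sequences: dict = field(default_factory=dict)
    jitter_sigma: float = 0.0
    default_overhead: float = 30.0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if not self.channel_volume_min < self.channel_volume_max:
            raise ValueError("require channel_volume_min < channel_volume_max")

    def known_positions(self) -> set[str]:
        return {p for seq in self.deck_sequences.values() for p in seq}

    def duration(self, method_name: str, n_targets: int,
                 rng: np.random.Generator | None = None) -> float:
        base = self.per_method_overhead[method_name] + \
            math.ceil(n_targets / self.n_channels) * self.per_cycle_duration
        if self.jitter_sigma > 0 and rng is not None:
            base *= float(np.exp(rng.normal(0.0, self.jitter_sigma)))
        return base


@dataclass(frozen=True)
class LHSCommand:
    """Minimal dispatch message: method, volumes, target/source sequences."""

    method_name: str
    volumes: tuple[float, ...]
    target_sequence: tuple[str, ...]
    source_sequence: tuple[str, ...] | None = None


@dataclass(frozen=True)
class Finding:
    """One validation or discrepancy finding; ``blocking`` findings abort
    execution, non-blocking ones are logged and the command still runs."""

    code: str
    message: str
    blocking: bool = True


@dataclass
class ExecutionRecord:
    command: LHSCommand
    task_name: str
    start_time: float
    end_time: float
    serviced_reactors: list[int]
    delivered_volumes: list[float]
    validation_findings: list[str] = field(default_factory=list)


class TwinBusyError(RuntimeError):
    """Execute was called while a command is still running — the mutual-
    exclusion contract of the scheduler was breached."""


BLOCKING_CODES = {
    "unknown_method", "unknown_position", "length_mismatch",
    "volume_out_of_range", "empty_command",
}


def validate_command(
    cmd: LHSCommand,
    profile: LHSProfile,
    volume_limits: tuple[float, float] | None = None,
) -> list[Finding]:
    """Check a command against the deck and channel limits.

    ``volume_limits`` optionally carries the (lower, upper) volume bounds
    the experiment declares for the dispatching task; a nonzero volume
    outside them is reported as a *miscalculated* volume — a discrepancy
    between scheduler output and user intent.  It is logged but does not
    block execution (the structural channel limits do).
    """
    findings: list[Finding] = []
    if cmd.method_name not in profile.per_method_overhead:
        findings.append(Finding(
            "unknown_method", f"method {cmd.method_name!r} is not declared"
        ))
    if len(cmd.target_sequence) == 0:
        findings.append(Finding("empty_command", "command has zero targets"))
    if len(cmd.volumes) != len(cmd.target_sequence):
        findings.append(Finding(
            "length_mismatch",
            f"{len(cmd.volumes)} volumes vs {len(cmd.target_sequence)} targets",
        ))
    if cmd.source_sequence is not None and \
            len(cmd.source_sequence) != len(cmd.target_sequence):
        findings.append(Finding(
            "length_mismatch",
            f"{len(cmd.source_sequence)} sources vs "
            f"{len(cmd.target_sequence)} targets",
        ))
    known = profile.known_positions()
    seqs = [cmd.target_sequence]
    if cmd.source_sequence is not None:
        seqs.append(cmd.source_sequence)
    for seq in seqs:
        for pos in seq:
            if pos not in known:
                findings.append(Finding(
                    "unknown_position", f"position {pos!r} not on the deck"
                ))
    for v in cmd.volumes:
        if v == 0:
            continue  # non-pipetting step (transport, read)
        if not (profile.channel_volume_min <= v <= profile.channel_volume_max):
            findings.append(Finding(
                "volume_out_of_range",
                f"volume {v} uL outside channel range "
                f"[{profile.channel_volume_min}, {profile.channel_volume_max}]",
            ))
            continue
        if volume_limits is not None:
            lo, hi = volume_limits
            if not (lo <= v <= hi):
                findings.append(Finding(
                    "miscalculated_volume",
                    f"volume {v} uL outside the declared task range "
                    f"[{lo}, {hi}]",
                    blocking=False,
                ))
    return findings


class AvailabilitySubscription:
    def __init__(self) -> None:
        self.events: list[tuple[float, str]] = []
        self.closed = False

    def push(self, timestamp: float, state: str) -> None:
        if self.events and timestamp < self.events[-1][0]:
            raise ValueError("out-of-order availability event")
        self.events.append((timestamp, state))


class LHSTwin:
    """Stateful twin: validates, times and logs commands; publishes
    availability transitions to all subscribers."""

    def __init__(
        self,
        profile: LHSProfile,
        discrepancy_log: str | Path | None = None,
        rng: np.random.Generator | None = None,
    ):
        self.profile = profile
        self.busy_until: float | None = None
        self._subs: list[AvailabilitySubscription] = []
        self._log_path = Path(discrepancy_log) if discrepancy_log else None
        if self._log_path is not None:
            self._log_path.parent.mkdir(parents=True, exist_ok=True)
            self._log_path.write_text("")
        self._rng = rng
        self._closed = False
        self.execution_log: list[ExecutionRecord] = []

    # -- availability stream -------------------------------------------------
    def subscribe(self) -> AvailabilitySubscription:
        if self._closed:
            raise RuntimeError("availability stream is closed")
        sub = AvailabilitySubscription()
        self._subs.append(sub)
        return sub

    def _publish(self, timestamp: float, state: str) -> None:
        for sub in self._subs:
            sub.push(timestamp, state)

    def close(self) -> None:
        for sub in self._subs:
            sub.closed = True
        self._closed = True

    @property
    def idle(self) -> bool:
        return self.busy_until is None

    def is_idle_at(self, now: float) -> bool:
        return self.busy_until is None or now >= self.busy_until

    # -- command execution ---------------------------------------------------
    def log_findings(self, now: float, method: str, findings: list[Finding]) -> None:
        if self._log_path is None or not findings:
            return
        with open(self._log_path, "a") as fh:
            for f in findings:
                fh.write(f"{now:.1f}\t{method}\t{f.code}\t{f.message}\n")

    def execute_command(
        self,
        cmd: LHSCommand,
        now: float,
        task_name: str = "",
        reactor_indices: list[int] | None = None,
        volume_limits: tuple[float, float] | None = None,
    ) -> ExecutionRecord:
        """Validate and run ``cmd`` starting at simulated time ``now``.

        Raises :class:`TwinBusyError` if a command is already running, and
        ``ValueError`` when a blocking finding is present (the scheduler is
        expected to validate first).  Non-blocking findings are logged and
        attached to the record; the transfer still happens.
        """
        if not self.is_idle_at(now):
            raise TwinBusyError(
                f"execute at t={now} while busy until t={self.busy_until}"
            )
        findings = validate_command(cmd, self.profile, volume_limits)
        self.log_findings(now, cmd.method_name, findings)
        if any(f.blocking for f in findings):
            raise ValueError(
                "blocking validation findings: "
                + "; ".join(f.message for f in findings if f.blocking)
            )
        duration = self.profile.duration(
            cmd.method_name, len(cmd.target_sequence), self._rng
        )
        self.busy_until = now + duration
        self._publish(now, "busy")
        record = ExecutionRecord(
            command=cmd,
            task_name=task_name,
            start_time=now,
            end_time=now + duration,
            serviced_reactors=list(reactor_indices or []),
            delivered_volumes=list(cmd.volumes),
            validation_findings=[f.message for f in findings],
        )
        self.execution_log.append(record)
        return record

    def complete(self, now: float) -> None:
        """Mark the running command finished; publishes the idle event."""
        if self.busy_until is None:
            return
        end = self.busy_until
        if now < end:
            raise ValueError(f"completion at t={now} before busy_until={end}")
        self.busy_until = None
        self._publish(end, "idle")
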
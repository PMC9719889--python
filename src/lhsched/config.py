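"""Experiment configuration: the declarative replacement for a user script.

An experiment is described in one YAML (or JSON) document: reactor fleet
and initial broth state, the liquid-handler profile, the plant-model
parameters, the clock, and the task list with constraints, demand models
and priority parameters.  The schema is strict — unknown keys are rejected
so typos surface at load time, and every violation is reported with its
field path.  ``load_config`` returns the resolved configuration with all
defaults filled; the run orchestrator persists that resolved form into the
run directory so a finished run is self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .constraints import Bound, ConstraintKind, ConstraintSpec, Quantity
from .lhs_twin import LHSProfile
from .plant import PlantParams, ReactorState
from .priority import Algorithm, PriorityParams
from .scheduler import ClockMode, SchedulerSetup
from .tasks import DemandKind, DemandModel, TaskClass, TaskSpec


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ExperimentSection(_Strict):
    name: str = "experiment"
    operator: str = "unknown"


class ReactorSection(_Strict):
    count: int = Field(48, ge=1)
    biomass: float = 1.0
    glucose: float = 3.0
    acetate: float = 0.0
    pH: float = 7.1
    DO: float = 100.0
    fill_volume: float = 10.0


class ClockSection(_Strict):
    tick: float = Field(10.0, gt=0)
    t_end: float = Field(28800.0, gt=0)
    mode: Literal["realtime", "accelerated", "event_driven"] = "event_driven"
    acceleration: float = Field(1.0, gt=0)


class ProfileSection(_Strict):
    n_channels: int = Field(8, ge=1)
    channel_volume_max: float = 1000.0
    channel_volume_min: float = 10.0
    per_cycle_duration: float = 30.0
    per_method_overhead: dict[str, float] = Field(default_factory=dict)
    deck_sequences: dict[str, list[str]] = Field(default_factory=dict)
    jitter_sigma: float = Field(0.0, ge=0)
    default_overhead: float = 30.0


class PlantSection(_Strict):
    q_glc_max: float = 1.2
    K_s: float = 0.05
    yield_xs: float = 0.5
    overflow_fraction: float = 0.2
    q_ace_max: float = 0.8
    k_pH_acid: float = 0.5
    k_pH_growth: float = 0.15
    k_pH_base: float = 0.025
    kLa: float = 300.0
    our_coeff: float = 12.0
    noise_sd: dict[str, float] = Field(default_factory=lambda: {"pH": 0.0, "DO": 0.0})
    malfunction_rate: float = Field(0.0, ge=0)
    feed_glucose_conc: float = Field(300.0, gt=0)


class ConstraintSection(_Strict):
    name: str
    kind: Literal["hard", "soft"]
    quantity: Literal["volume", "elapsed_time", "clock_time", "fill_level"]
    bound: Literal["lower", "upper"]
    limit: float
    applies_to: list[int] | Literal["all"] = "all"

    def build(self) -> ConstraintSpec:
        applies = "all" if self.applies_to == "all" else frozenset(self.applies_to)
        return ConstraintSpec(
            self.name, ConstraintKind(self.kind), Quantity(self.quantity),
            Bound(self.bound), self.limit, applies,
        )


class PrioritySection(_Strict):
    algorithm: Literal[
        "step", "step_specific", "dynamic_volume", "dynamic_time"
    ] = "dynamic_time"
    p_base: float = Field(10.0, ge=0)
    p_crit: float = 100.0

    @model_validator(mode="after")
    def _ordered(self) -> "PrioritySection":
        if self.p_crit < self.p_base:
            raise ValueError(
                f"p_crit ({self.p_crit}) must be >= p_base ({self.p_base})"
            )
        return self


class DemandSection(_Strict):
    kind: Literal[
        "constant_volume", "exponential_feed",
        "proportional_titration", "time_trigger",
    ]
    parameters: dict[str, float | bool] = Field(default_factory=dict)


class TaskSection(_Strict):
    name: str
    method_name: str
    task_class: Literal[
        "feeding", "ph_control", "sampling_stage", "induction", "abort"
    ]
    demand: DemandSection
    priority: PrioritySection = Field(default_factory=PrioritySection)
    constraints: list[ConstraintSection] = Field(default_factory=list)
    stage_index: int = Field(0, ge=0)
    predecessor: str | None = None

    def build(self) -> TaskSpec:
        return TaskSpec(
            name=self.name,
            method_name=self.method_name,
            task_class=TaskClass(self.task_class),
            constraints=tuple(c.build() for c in self.constraints),
            priority_params=PriorityParams(
                self.priority.p_base, self.priority.p_crit,
                Algorithm(self.priority.algorithm),
            ),
            demand_model=DemandModel(
                DemandKind(self.demand.kind), dict(self.demand.parameters)
            ),
            stage_index=self.stage_index,
            predecessor=self.predecessor,
        )


class ExperimentConfig(_Strict):
    experiment: ExperimentSection = Field(default_factory=ExperimentSection)
    seed: int = 0
    reactors: ReactorSection = Field(default_factory=ReactorSection)
    clock: ClockSection = Field(default_factory=ClockSection)
    lhs_profile: ProfileSection = Field(default_factory=ProfileSection)
    plant: PlantSection = Field(default_factory=PlantSection)
    sensor_interval: float = Field(60.0, gt=0)
    tasks: list[TaskSection]

    @model_validator(mode="after")
    def _tasks_consistent(self) -> "ExperimentConfig":
        names = [t.name for t in self.tasks]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate task names: {dup}")
        for t in self.tasks:
            if t.predecessor is not None and t.predecessor not in names:
                raise ValueError(
                    f"task {t.name!r}: undefined predecessor {t.predecessor!r}"
                )
        return self

    # -- resolution ----------------------------------------------------------
    def resolved_profile(self) -> LHSProfile:
        """Fill method overheads and a default deck from the task list."""
        overheads = dict(self.lhs_profile.per_method_overhead)
        for t in self.tasks:
            overheads.setdefault(t.method_name, self.lhs_profile.default_overhead)
        deck = {k: list(v) for k, v in self.lhs_profile.deck_sequences.items()}
        if not deck:
            deck = {
                "reactors": [f"R{i:02d}" for i in range(self.reactors.count)],
                "substrate": ["substrate"],
                "naoh": ["naoh"],
                "inducer": ["inducer"],
                "sample_mtp": [f"MTP{i:02d}" for i in range(self.reactors.count)],
                "reader": ["reader"],
                "washer": ["washer"],
            }
        return LHSProfile(
            n_channels=self.lhs_profile.n_channels,
            channel_volume_max=self.lhs_profile.channel_volume_max,
            channel_volume_min=self.lhs_profile.channel_volume_min,
            per_cycle_duration=self.lhs_profile.per_cycle_duration,
            per_method_overhead=overheads,
            deck_sequences=deck,
            jitter_sigma=self.lhs_profile.jitter_sigma,
            default_overhead=self.lhs_profile.default_overhead,
        )

    def build_setup(self, seed: int | None = None) -> SchedulerSetup:
        plant_kwargs = self.plant.model_dump()
        return SchedulerSetup(
            experiment_name=self.experiment.name,
            n_reactors=self.reactors.count,
            initial_reactor=ReactorState(
                biomass=self.reactors.biomass,
                glucose=self.reactors.glucose,
                acetate=self.reactors.acetate,
                pH=self.reactors.pH,
                DO=self.reactors.DO,
                fill_volume=self.reactors.fill_volume,
            ),
            profile=self.resolved_profile(),
            plant_params=PlantParams(**plant_kwargs),
            task_specs=[t.build() for t in self.tasks],
            tick=self.clock.tick,
            t_end=self.clock.t_end,
            sensor_interval=self.sensor_interval,
            clock_mode=ClockMode(self.clock.mode),
            acceleration=self.clock.acceleration,
            seed=self.seed if seed is None else seed,
        )

    def to_json(self) -> str:
        return json.dumps(self.model_dump(), sort_keys=True, indent=1)


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and validate a YAML or JSON experiment configuration file."""
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return ExperimentConfig.model_validate(data)


def load_config_dict(data: dict) -> ExperimentConfig:
    """Validate an in-memory configuration mapping."""
    return ExperimentConfig.model_validate(data)
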
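"""Synthetic fed-batch bioprocess driving the per-reactor sensor streams.

The plant emulates 48 (configurable) parallel mL-scale stirred-tank
reactors running an E. coli-like fed-batch: glucose is taken up at a
Monod-type specific rate, a fixed fraction of the flux overflows to
acetate, and acetate formation acidifies the broth.  Once glucose is
depleted the culture consumes the accumulated acetate, which raises the pH
again — the signature the pH-control task reacts to.  Dissolved oxygen
follows a simple oxygen balance (uptake proportional to substrate flux,
recovery through kLa).  Stirrer malfunctions arrive as a seeded Poisson
process and permanently flag a position.

The kinetics are deliberately the simplest model reproducing this
qualitative pH interplay; parameters are documented in
:class:`PlantParams`.  Sensor reads optionally add Gaussian noise; the
internal state stays noise-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datastore import TimeSeriesPoint


@dataclass
class ReactorState:
    """Per-reactor plant variables.

    biomass, glucose, acetate in g/L; pH dimensionless (clamped to [4, 10]);
    DO in % air saturation (clamped to [0, 100]); fill_volume in mL.
    """

    biomass: float = 1.0
    glucose: float = 3.0
    acetate: float = 0.0
    pH: float = 7.1
    DO: float = 100.0
    fill_volume: float = 10.0
    stirrer_ok: bool = True
    active: bool = True

    def clamp(self) -> None:
        self.biomass = max(0.0, self.biomass)
        self.glucose = max(0.0, self.glucose)
        self.acetate = max(0.0, self.acetate)
        self.fill_volume = max(0.0, self.fill_volume)
        self.pH = float(np.clip(self.pH, 4.0, 10.0))
        self.DO = float(np.clip(self.DO, 0.0, 100.0))


@dataclass(frozen=True)
class PlantParams:
    """Kinetic, coupling and noise parameters of the synthetic plant.

    q_glc_max : g/(g h)
        Maximum specific glucose uptake rate.
    K_s : g/L
        Monod half-saturation constant for glucose.
    yield_xs : g/g
        Biomass yield on the non-overflow glucose flux.
    overflow_fraction : –
        Fraction of glucose flux excreted as acetate while glucose > 0.
    q_ace_max : g/(g h)
        Maximum specific acetate consumption rate after glucose depletion.
    k_pH_acid : pH/(g/L)
        pH drop per g/L net acetate formed (and rise per g/L consumed).
    k_pH_growth : pH/(g/L)
        pH drop per g/L biomass formed (proton extrusion during growth on
        ammonium); the persistent acid load that keeps one-sided base
        control engaged.
    k_pH_base : pH mL/uL
        pH rise per uL of titrant per mL fill volume.
    kLa : 1/h
        Volumetric oxygen transfer coefficient.
    our_coeff : %sat/(g/L)
        DO depression per unit of specific substrate flux times biomass.
    noise_sd : map signal -> sd
        Gaussian sensor noise (applied on read only).
    malfunction_rate : events/h per reactor
        Poisson rate of permanent stirrer failures.
    feed_glucose_conc : g/L
        Glucose concentration of the substrate solution (300 g/L).
    """

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
    noise_sd: dict = field(default_factory=lambda: {"pH": 0.0, "DO": 0.0})
    malfunction_rate: float = 0.0
    feed_glucose_conc: float = 300.0

    def __post_init__(self) -> None:
        for name in ("q_glc_max", "K_s", "yield_xs", "overflow_fraction",
                     "q_ace_max", "k_pH_acid", "k_pH_growth", "k_pH_base", "kLa",
                     "our_coeff", "malfunction_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.feed_glucose_conc <= 0:
            raise ValueError("feed_glucose_conc must be > 0")


# glucose below this concentration (g/L) counts as depleted: the Monod tail
# decays geometrically and would otherwise never reach zero exactly
GLC_DEPLETED = 1e-3


def step_plant(
    states: list[ReactorState],
    params: PlantParams,
    dt: float,
    rng: np.random.Generator,
    consumed_out: np.ndarray | None = None,
) -> list[ReactorState]:
    """Advance every reactor by ``dt`` seconds (explicit Euler), in place.

    While glucose is present it is consumed at a Monod rate with a fixed
    overflow fraction diverted to acetate, lowering pH proportionally to
    the acetate formed; once glucose is (numerically) exhausted, acetate is
    consumed and pH rises.  Stirrer malfunctions are sampled per reactor
    from a Poisson process at ``params.malfunction_rate``.

    If ``consumed_out`` is given (length-n float array) the glucose mass
    consumed this step is added per reactor, enabling mass-balance checks.
    Returns the same list for chaining.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    dt_h = dt / 3600.0
    p_fail = -np.expm1(-params.malfunction_rate * dt_h)
    for i, s in enumerate(states):
        if params.malfunction_rate > 0 and s.stirrer_ok:
            if rng.random() < p_fail:
                s.stirrer_ok = False
        if s.glucose <= GLC_DEPLETED and s.glucose > 0:
            # mop up the Monod tail so the famine branch can engage
            if consumed_out is not None:
                consumed_out[i] += s.glucose * s.fill_volume * 1e-3
            s.glucose = 0.0
        q_glc = params.q_glc_max * s.glucose / (s.glucose + params.K_s) \
            if s.glucose > 0 else 0.0
        d_glc = min(q_glc * s.biomass * dt_h, s.glucose)
        if consumed_out is not None:
            consumed_out[i] += d_glc * s.fill_volume * 1e-3
        if d_glc > 0:
            ace_formed = params.overflow_fraction * d_glc
            d_x = params.yield_xs * (1 - params.overflow_fraction) * d_glc
            s.glucose -= d_glc
            s.acetate += ace_formed
            s.biomass += d_x
            s.pH -= params.k_pH_acid * ace_formed + params.k_pH_growth * d_x
            uptake_flux = q_glc * s.biomass
        elif s.acetate > 0:
            d_ace = min(params.q_ace_max * s.biomass * dt_h, s.acetate)
            s.acetate -= d_ace
            s.pH += params.k_pH_acid * d_ace
            uptake_flux = params.q_ace_max * s.biomass
        else:
            uptake_flux = 0.0
        do_target = 100.0 - params.our_coeff * uptake_flux
        decay = np.exp(-params.kLa * dt_h)
        s.DO = do_target + (s.DO - do_target) * decay
        s.clamp()
    return states


def apply_addition(
    state: ReactorState,
    kind: str,
    volume: float,
    params: PlantParams,
) -> ReactorState:
    """Apply a liquid transfer of ``volume`` uL to one reactor, in place.

    kind ``feed``: adds glucose mass ``volume * feed_glucose_conc * 1e-6`` g
    and dilutes all concentrations into the new fill volume.
    kind ``base``: raises pH by ``k_pH_base * volume / fill`` and dilutes.
    kind ``sample``: removes volume; concentrations unchanged.
    """
    if volume < 0:
        raise ValueError("volume must be >= 0")
    if volume == 0:
        return state
    v_ml = volume * 1e-3
    if kind == "feed":
        old_fill = state.fill_volume
        new_fill = old_fill + v_ml
        glc_mass = state.glucose * old_fill * 1e-3 + volume * params.feed_glucose_conc * 1e-6
        state.glucose = glc_mass / (new_fill * 1e-3)
        for attr in ("biomass", "acetate"):
            setattr(state, attr, getattr(state, attr) * old_fill / new_fill)
        state.fill_volume = new_fill
    elif kind == "base":
        state.pH += params.k_pH_base * volume / state.fill_volume
        old_fill = state.fill_volume
        new_fill = old_fill + v_ml
        for attr in ("biomass", "glucose", "acetate"):
            setattr(state, attr, getattr(state, attr) * old_fill / new_fill)
        state.fill_volume = new_fill
    elif kind == "inert":
        # e.g. inducer: dilutes the broth, no metabolic coupling modeled
        old_fill = state.fill_volume
        new_fill = old_fill + v_ml
        for attr in ("biomass", "glucose", "acetate"):
            setattr(state, attr, getattr(state, attr) * old_fill / new_fill)
        state.fill_volume = new_fill
    elif kind == "sample":
        if v_ml > state.fill_volume:
            raise ValueError(
                f"sample volume {volume} uL exceeds fill {state.fill_volume} mL"
            )
        state.fill_volume -= v_ml
    else:
        raise ValueError(f"unknown addition kind {kind!r}")
    state.clamp()
    return state


def read_sensors(
    states: list[ReactorState],
    params: PlantParams,
    rng: np.random.Generator,
    now: float,
    experiment: str,
) -> list[TimeSeriesPoint]:
    """Emit one data point per reactor per signal (pH, DO, stirrer status).

    Noise (per ``params.noise_sd``) is applied to the emitted values only.
    Excluded reactors are still measured but tagged inactive.
    """
    points: list[TimeSeriesPoint] = []
    sd_ph = params.noise_sd.get("pH", 0.0)
    sd_do = params.noise_sd.get("DO", 0.0)
    for i, s in enumerate(states):
        tags = {
            "experiment": experiment,
            "reactor": str(i),
            "active": "true" if s.active else "false",
        }
        ph = s.pH + (rng.normal(0.0, sd_ph) if sd_ph > 0 else 0.0)
        do = s.DO + (rng.normal(0.0, sd_do) if sd_do > 0 else 0.0)
        points.append(TimeSeriesPoint("pH", now, tags, {"value": ph}))
        points.append(TimeSeriesPoint("DO", now, tags, {"value": do}))
        points.append(TimeSeriesPoint(
            "stirrer", now, tags, {"ok": 1.0 if s.stirrer_ok else 0.0}
        ))
    return points
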
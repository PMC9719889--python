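"""Priority calculus: the four algorithms, the critical cap, and an
independent literal transcription of each piecewise formula as oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import make_evaluation

from lhsched.priority import (
    PriorityConfigError,
    PriorityParams,
    Algorithm,
    priority_dynamic_time,
    priority_dynamic_volume,
    priority_step,
    priority_step_specific,
)

# ---------------------------------------------------------------------------
# Literal transcriptions of the piecewise equations (no shared code with the
# implementation): scalar arithmetic over explicit branch selection.
# ---------------------------------------------------------------------------


def oracle_step(hard_all_blocked, any_soft, n_aff, p_base, p_crit):
    if hard_all_blocked or n_aff == 0:
        return 0.0
    if any_soft:
        return p_crit
    return p_base


def oracle_step_specific(hard_all_blocked, any_soft, n_aff, n_all, p_base, p_crit):
    if hard_all_blocked or n_aff == 0 or n_all == 0:
        return 0.0
    if any_soft:
        val = p_base + (p_crit - p_base) * (n_aff / n_all)
    else:
        val = p_base * (n_aff / n_all)
    return min(val, p_crit)


def oracle_dynamic(hard_all_blocked, n_aff, n_all, xs, lowers, spans,
                   p_base, p_crit):
    """Shared form of the dynamic-volume and dynamic-time equations."""
    if hard_all_blocked or n_aff == 0 or n_all == 0:
        return 0.0
    total = 0.0
    for x, lo, sp in zip(xs, lowers, spans):
        term = (x - lo) / sp
        term = 0.0 if term < 0 else (1.0 if term > 1 else term)
        total += term
    return min(p_base + (p_crit - p_base) / n_all * total, p_crit)


PARAMS = PriorityParams(10.0, 100.0, Algorithm.STEP)


class TestStep:
    def test_hard_violation_blocks_everything(self, make_eval):
        ev = make_eval(4, affected=[], hard=[0, 1, 2, 3])
        assert priority_step(ev, PARAMS).value == 0.0

    def test_no_violation_gives_base(self, make_eval):
        ev = make_eval(4, affected=[0, 1])
        assert priority_step(ev, PARAMS).value == 10.0

    def test_soft_violation_gives_critical(self, make_eval):
        ev = make_eval(4, affected=[0, 1], soft=[1])
        assert priority_step(ev, PARAMS).value == 100.0

    def test_no_demand_gives_zero(self, make_eval):
        ev = make_eval(4)
        assert priority_step(ev, PARAMS).value == 0.0

    def test_soft_violation_on_blocked_reactor_ignored(self, make_eval):
        # the blocked reactor's soft flag must not escalate the task
        ev = make_eval(4, affected=[0], soft=[1], hard=[1])
        assert priority_step(ev, PARAMS).value == 10.0


class TestStepSpecific:
    def test_half_affected_scales_base(self, make_eval):
        ev = make_eval(48, affected=range(24))
        assert priority_step_specific(ev, PARAMS).value == pytest.approx(5.0)

    def test_zero_affected(self, make_eval):
        ev = make_eval(48)
        assert priority_step_specific(ev, PARAMS).value == 0.0

    def test_all_affected_soft_reaches_critical(self, make_eval):
        ev = make_eval(8, affected=range(8), soft=range(8))
        assert priority_step_specific(ev, PARAMS).value == pytest.approx(100.0)

    def test_empty_fleet_signals_zero(self, make_eval):
        ev = make_eval(0)
        assert priority_step_specific(ev, PARAMS).value == 0.0


class TestDynamicVolume:
    def test_all_at_lower_limit_gives_base(self, make_eval):
        ev = make_eval(4, affected=range(4))
        v = np.full(4, 50.0)
        res = priority_dynamic_volume(ev, v, np.full(4, 50.0), np.full(4, 100.0),
                                      PARAMS)
        assert res.value == pytest.approx(10.0)

    def test_midspan_single_affected_of_two(self, make_eval):
        # p_base + (p_crit - p_base)/n_all * 0.5 = 10 + 45*0.5 = 32.5
        ev = make_eval(2, affected=[0])
        res = priority_dynamic_volume(
            ev, np.array([75.0, 0.0]), np.full(2, 50.0), np.full(2, 50.0),
            PARAMS,
        )
        assert res.value == pytest.approx(32.5)

    def test_all_at_upper_limit_reaches_critical(self, make_eval):
        ev = make_eval(6, affected=range(6))
        res = priority_dynamic_volume(
            ev, np.full(6, 150.0), np.full(6, 50.0), np.full(6, 100.0), PARAMS
        )
        assert res.value == pytest.approx(100.0)

    def test_nonpositive_span_is_configuration_error(self, make_eval):
        ev = make_eval(2, affected=[0])
        with pytest.raises(PriorityConfigError):
            priority_dynamic_volume(
                ev, np.array([1.0, 0.0]), np.zeros(2), np.zeros(2), PARAMS
            )

    def test_terms_clamped_to_unit_interval(self, make_eval):
        # volumes far past the upper limit contribute at most 1 each
        ev = make_eval(2, affected=range(2))
        res = priority_dynamic_volume(
            ev, np.full(2, 1e6), np.full(2, 10.0), np.full(2, 10.0), PARAMS
        )
        assert res.value == pytest.approx(100.0)
        assert (res.per_reactor_terms <= 1.0).all()


class TestDynamicTime:
    def test_all_at_lower_limit_gives_base(self, make_eval):
        ev = make_eval(48, affected=range(48))
        res = priority_dynamic_time(
            ev, np.full(48, 1800.0), np.full(48, 1800.0), np.full(48, 600.0),
            PARAMS,
        )
        assert res.value == pytest.approx(10.0)

    def test_full_fleet_midspan(self, make_eval):
        # 10 + 90/48 * 48*0.5 = 55
        ev = make_eval(48, affected=range(48))
        res = priority_dynamic_time(
            ev, np.full(48, 2100.0), np.full(48, 1800.0), np.full(48, 600.0),
            PARAMS,
        )
        assert res.value == pytest.approx(55.0)

    def test_hard_violation_zero(self, make_eval):
        ev = make_eval(48, hard=range(48))
        res = priority_dynamic_time(
            ev, np.full(48, 0.0), np.full(48, 1800.0), np.full(48, 600.0),
            PARAMS,
        )
        assert res.value == 0.0


class TestParams:
    def test_ordering_enforced(self):
        with pytest.raises(PriorityConfigError):
            PriorityParams(p_base=50.0, p_crit=10.0)

    def test_negative_base_rejected(self):
        with pytest.raises(PriorityConfigError):
            PriorityParams(p_base=-1.0, p_crit=10.0)


# ---------------------------------------------------------------------------
# Properties
# ---------------------------------------------------------------------------

params_st = st.tuples(
    st.floats(0, 100), st.floats(0, 100)
).map(lambda ab: PriorityParams(min(ab), max(ab), Algorithm.STEP))


@settings(max_examples=300, deadline=None)
@given(
    n_all=st.integers(1, 48),
    data=st.data(),
    params=params_st,
)
def test_cap_never_exceeded(n_all, data, params):
    """No algorithm ever exceeds the critical priority."""
    n_aff = data.draw(st.integers(0, n_all))
    soft = data.draw(st.booleans())
    ev = make_evaluation(
        n_all, affected=range(n_aff), soft=range(n_aff) if soft else []
    )
    xs = np.array(data.draw(st.lists(
        st.floats(0, 1e5), min_size=n_all, max_size=n_all
    )))
    lowers = np.zeros(n_all)
    spans = np.full(n_all, data.draw(st.floats(1e-3, 1e4)))
    for fn in (priority_step, priority_step_specific):
        v = fn(ev, params).value
        assert 0.0 <= v <= params.p_crit + 1e-12
    for fn in (priority_dynamic_volume, priority_dynamic_time):
        v = fn(ev, xs, lowers, spans, params).value
        assert 0.0 <= v <= params.p_crit + 1e-12


@settings(max_examples=200, deadline=None)
@given(n_all=st.integers(1, 48), data=st.data())
def test_boundary_agreement_dynamic_equals_step_specific(n_all, data):
    """With every affected reactor at its upper limit the dynamic formula
    equals the step-specific soft-violation value for the same n_aff/n_all."""
    n_aff = data.draw(st.integers(1, n_all))
    ev_soft = make_evaluation(n_all, affected=range(n_aff), soft=range(n_aff))
    ev_plain = make_evaluation(n_all, affected=range(n_aff))
    lowers = np.full(n_all, 10.0)
    spans = np.full(n_all, 90.0)
    at_upper = lowers + spans
    dyn = priority_dynamic_volume(ev_plain, at_upper, lowers, spans, PARAMS)
    ss = priority_step_specific(ev_soft, PARAMS)
    assert dyn.value == pytest.approx(ss.value, abs=1e-12)


@settings(max_examples=200, deadline=None)
@given(n_all=st.integers(1, 24), data=st.data())
def test_dynamic_monotone_in_values(n_all, data):
    """Raising any per-reactor value within its span never lowers priority."""
    n_aff = data.draw(st.integers(1, n_all))
    ev = make_evaluation(n_all, affected=range(n_aff))
    lowers = np.zeros(n_all)
    spans = np.full(n_all, 100.0)
    xs = np.array(data.draw(st.lists(
        st.floats(0, 100), min_size=n_all, max_size=n_all
    )))
    base = priority_dynamic_time(ev, xs, lowers, spans, PARAMS).value
    i = data.draw(st.integers(0, n_aff - 1))
    bump = data.draw(st.floats(0, 100))
    xs2 = xs.copy()
    xs2[i] = min(100.0, xs2[i] + bump)
    assert priority_dynamic_time(ev, xs2, lowers, spans, PARAMS).value >= \
        base - 1e-12


@settings(max_examples=200, deadline=None)
@given(n_all=st.integers(1, 48), data=st.data())
def test_step_specific_monotone_in_n_aff(n_all, data):
    n_aff = data.draw(st.integers(0, n_all - 1))
    lo = priority_step_specific(make_evaluation(n_all, affected=range(n_aff)), PARAMS)
    hi = priority_step_specific(
        make_evaluation(n_all, affected=range(n_aff + 1)), PARAMS
    )
    assert hi.value >= lo.value - 1e-12


def test_oracle_equivalence_random_instances(make_eval, rng):
    """1,000 random instances per algorithm match the literal transcription
    of each piecewise equation to 1e-12."""
    for _ in range(1000):
        n_all = int(rng.integers(1, 49))
        n_aff = int(rng.integers(0, n_all + 1))
        any_soft = bool(rng.random() < 0.3)
        all_hard = bool(rng.random() < 0.15)
        p_base = float(rng.uniform(0, 50))
        p_crit = float(rng.uniform(p_base, 200))
        params = PriorityParams(p_base, p_crit, Algorithm.STEP)
        if all_hard:
            ev = make_evaluation(n_all, hard=range(n_all))
            n_aff_eff = 0
        else:
            ev = make_evaluation(
                n_all, affected=range(n_aff),
                soft=range(n_aff) if any_soft else [],
            )
            n_aff_eff = n_aff
        xs = rng.uniform(0, 3000, n_all)
        lowers = rng.uniform(0, 1000, n_all)
        spans = rng.uniform(1e-3, 2000, n_all)

        got = priority_step(ev, params).value
        want = oracle_step(all_hard, any_soft and n_aff_eff > 0,
                           n_aff_eff, p_base, p_crit)
        assert got == pytest.approx(want, abs=1e-12)

        got = priority_step_specific(ev, params).value
        want = oracle_step_specific(all_hard, any_soft and n_aff_eff > 0,
                                    n_aff_eff, n_all, p_base, p_crit)
        assert got == pytest.approx(want, abs=1e-12)

        aff_idx = list(range(n_aff_eff))
        want = oracle_dynamic(
            all_hard, n_aff_eff, n_all,
            xs[aff_idx], lowers[aff_idx], spans[aff_idx], p_base, p_crit,
        )
        got = priority_dynamic_volume(ev, xs, lowers, spans, params).value
        assert got == pytest.approx(want, abs=1e-12)
        got = priority_dynamic_time(ev, xs, lowers, spans, params).value
        assert got == pytest.approx(want, abs=1e-12)
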
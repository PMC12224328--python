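"""Cascade kinetics: rate laws, initial-rate estimation, fits, ODE, steady state."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanocascade.kinetics import (
    AssayTimeCourse,
    CascadeModel,
    HillKinetics,
    MMKinetics,
    PseudoOrderRates,
    RatePoint,
    estimate_initial_rates,
    fit_hill,
    fit_mm,
    hill_rate,
    mm_rate,
    pseudo_order_reduction,
    simulate_cascade,
    steady_state_analytic,
    steady_state_scan,
)

from conftest import GLUCOSE_GRID, H2O2_GRID


# ------------------------------------------------------------- rate laws


class TestRateLaws:
    def test_mm_half_saturation_identity(self, mm_params):
        assert mm_rate(mm_params, mm_params.k_m) == pytest.approx(mm_params.v_max / 2)

    def test_mm_zero_substrate(self, mm_params):
        assert mm_rate(mm_params, 0.0) == 0.0

    def test_mm_worked_value(self):
        p = MMKinetics(v_max=10.0, k_m=2.9)
        assert mm_rate(p, 29.0) == pytest.approx(10.0 * 29.0 / 31.9, rel=1e-12)

    def test_mm_catalyst_scaling_linear(self, mm_params):
        assert mm_rate(mm_params, 5.0, catalyst_conc=0.2) == pytest.approx(
            2.0 * mm_rate(mm_params, 5.0), rel=1e-12
        )

    def test_hill_half_saturation_any_h(self):
        for h in (0.5, 1.0, 2.0, 4.0):
            p = HillKinetics(v_max=5.0, k_half=155.1, hill_h=h)
            assert hill_rate(p, 155.1) == pytest.approx(2.5, rel=1e-12)

    def test_hill_reduces_to_mm_at_h1(self, mm_params):
        hp = HillKinetics(v_max=mm_params.v_max, k_half=mm_params.k_m, hill_h=1.0)
        s = np.random.default_rng(0).uniform(0.01, 100.0, 20)
        np.testing.assert_allclose(hill_rate(hp, s), mm_rate(mm_params, s), rtol=1e-12)

    def test_hill_worked_value(self):
        p = HillKinetics(v_max=8.0, k_half=155.1, hill_h=2.0)
        assert hill_rate(p, 50.0) == pytest.approx(8.0 * 2500.0 / (155.1**2 + 2500.0), rel=1e-12)

    def test_negative_substrate_rejected(self, mm_params, hill_params):
        with pytest.raises(ValueError):
            mm_rate(mm_params, -1.0)
        with pytest.raises(ValueError):
            hill_rate(hill_params, -1.0)

    @pytest.mark.parametrize("bad", [dict(v_max=-1, k_m=2.9), dict(v_max=10, k_m=0)])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            MMKinetics(**bad)

    @given(
        v_max=st.floats(0.1, 100), k=st.floats(0.1, 1000),
        h=st.floats(0.3, 5), seed=st.integers(0, 2**16),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_bounded(self, v_max, k, h, seed):
        """Both saturation laws rise monotonically in S and never exceed v_max."""
        s = np.sort(np.random.default_rng(seed).uniform(0.0, 5000.0, 30))
        for law, params in (
            (mm_rate, MMKinetics(v_max=v_max, k_m=k)),
            (hill_rate, HillKinetics(v_max=v_max, k_half=k, hill_h=h)),
        ):
            v = law(params, s)
            assert np.all(np.diff(v) >= -1e-12)
            assert np.all(v <= v_max + 1e-12)


# ------------------------------------------------- initial-rate estimation


class TestInitialRates:
    def test_linear_consumption(self):
        t = np.array([0.0, 3.0, 6.0, 9.0])
        course = AssayTimeCourse(times=t, glucose=10.0 - 0.2 * t)
        (point,) = estimate_initial_rates([course], "glucose")
        assert point.initial_rate == pytest.approx(0.2, rel=1e-12)
        assert point.substrate_conc == 10.0
        assert not point.increasing_substrate

    def test_zero_consumption(self):
        course = AssayTimeCourse(times=[0, 3, 6, 9], glucose=np.full(4, 5.0))
        (point,) = estimate_initial_rates([course], "glucose")
        assert point.initial_rate == 0.0

    def test_origin_constrained_closed_form(self):
        # consumed (0.55, 1.02, 1.40) mM at (3, 6, 9) min
        course = AssayTimeCourse(
            times=[0, 3, 6, 9], h2o2=[10.0, 9.45, 8.98, 8.60]
        )
        (point,) = estimate_initial_rates([course], "h2o2")
        expected = (3 * 0.55 + 6 * 1.02 + 9 * 1.40) / (9 + 36 + 81)
        assert point.initial_rate == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(0.16166, abs=5e-5)

    def test_rising_substrate_flagged(self):
        course = AssayTimeCourse(times=[0, 3, 6, 9], glucose=[5.0, 5.2, 5.5, 5.9])
        with pytest.warns(UserWarning, match="increases over time"):
            (point,) = estimate_initial_rates([course], "glucose")
        assert point.increasing_substrate

    def test_identical_times_rejected(self):
        with pytest.raises(ValueError):
            AssayTimeCourse(times=[0, 3, 3, 9], glucose=[5, 4, 4, 3])


# ------------------------------------------------------------- NLS fits


class TestSaturationFits:
    def test_mm_noiseless_closure(self, mm_params):
        points = [
            RatePoint(s, mm_rate(mm_params, s)) for s in GLUCOSE_GRID
        ]
        fit = fit_mm(points)
        assert fit.converged
        assert fit.params.v_max == pytest.approx(10.0, rel=1e-6)
        assert fit.params.k_m == pytest.approx(2.9, rel=1e-6)
        assert fit.r_squared > 1 - 1e-10

    def test_mm_underdetermined(self):
        points = [RatePoint(1.0, 0.5), RatePoint(1.0, 0.52), RatePoint(5.0, 2.0)]
        with pytest.raises(ValueError, match="distinct"):
            fit_mm(points)

    def test_hill_noiseless_closure(self, hill_params):
        points = [RatePoint(s, hill_rate(hill_params, s)) for s in H2O2_GRID]
        fit = fit_hill(points)
        assert fit.converged
        assert fit.params.v_max == pytest.approx(5.0, rel=1e-6)
        assert fit.params.k_half == pytest.approx(155.1, rel=1e-6)
        assert fit.params.hill_h == pytest.approx(2.0, rel=1e-6)

    def test_hill_fixed_h_matches_mm(self, mm_params):
        points = [RatePoint(s, mm_rate(mm_params, s)) for s in GLUCOSE_GRID]
        mm_fit = fit_mm(points)
        hill_fit = fit_hill(points, fix_h=1.0)
        assert hill_fit.params.k_half == pytest.approx(mm_fit.params.k_m, rel=1e-6)
        assert hill_fit.params.v_max == pytest.approx(mm_fit.params.v_max, rel=1e-6)


# --------------------------------------------------------------- the ODE


def euler_oracle(model, catalyst, g0, h0, t_end, dt=1e-3, depletion=True):
    """Fixed-step forward-Euler integration, independent of solve_ivp."""
    prod, dec = model.production, model.decomposition
    cp = (catalyst / prod.ref_catalyst_conc) ** model.production_catalyst_exponent
    cd = (catalyst / dec.ref_catalyst_conc) ** model.decomposition_catalyst_exponent
    g, h = g0, h0
    for _ in range(int(round(t_end / dt))):
        p = cp * prod.v_max * g / (prod.k_m + g)
        hh = h**dec.hill_h
        d = cd * dec.v_max * hh / (dec.k_half**dec.hill_h + hh) if h > 0 else 0.0
        if depletion:
            g = max(g - p * dt, 0.0)
        h = max(h + (p - d) * dt, 0.0)
    return g, h


REDUCED_MODEL = CascadeModel(
    # production slow enough that H stays far below K0.5: first-order regime
    production=MMKinetics(v_max=0.05, k_m=2.9),
    decomposition=HillKinetics(v_max=5.0, k_half=155.1, hill_h=1.0),
    decomposition_catalyst_exponent=1.0,
)


class TestCascadeODE:
    def test_decay_only_when_no_glucose(self):
        model = CascadeModel(
            production=MMKinetics(v_max=10, k_m=2.9),
            decomposition=HillKinetics(v_max=5, k_half=155.1, hill_h=2),
        )
        t, g, h = simulate_cascade(model, 0.1, glucose0=0.0, h2o2_0=10.0, t_end=60.0)
        assert np.all(np.diff(h) < 0)
        assert np.all(h >= 0)

    def test_matches_pseudo_first_order_closed_form(self):
        rates = pseudo_order_reduction(REDUCED_MODEL, 0.1, 5.0)
        ss = steady_state_analytic(rates)
        assert ss < 0.01 * 155.1  # genuinely reduced regime
        h0 = 0.5
        t, _, h = simulate_cascade(
            REDUCED_MODEL, 0.1, glucose0=5.0, h2o2_0=h0,
            t_end=10.0 / rates.k2, glucose_depletion=False,
        )
        closed = ss * (1 - np.exp(-rates.k2 * t)) + h0 * np.exp(-rates.k2 * t)
        np.testing.assert_allclose(h, closed, rtol=0.01)

    def test_agrees_with_euler_oracle(self):
        model = CascadeModel(
            production=MMKinetics(v_max=2.0, k_m=2.9),
            decomposition=HillKinetics(v_max=5.0, k_half=155.1, hill_h=2.0),
        )
        for catalyst, g0, h0 in [(0.1, 20.0, 1.0), (0.3, 5.0, 0.0), (0.05, 40.0, 10.0)]:
            ge, he = euler_oracle(model, catalyst, g0, h0, 60.0)
            _, g, h = simulate_cascade(model, catalyst, g0, h0, 60.0)
            assert h[-1] == pytest.approx(he, rel=5e-3, abs=1e-6)
            assert g[-1] == pytest.approx(ge, rel=5e-3, abs=1e-6)

    def test_glucose_mass_balance_under_depletion(self):
        model = CascadeModel(
            production=MMKinetics(v_max=1.0, k_m=2.9),
            decomposition=HillKinetics(v_max=5.0, k_half=155.1, hill_h=1.0),
        )
        t, g, h = simulate_cascade(model, 0.1, 10.0, 0.0, 30.0)
        produced = np.trapezoid(model.production.v_max * g / (model.production.k_m + g), t)
        assert (10.0 - g[-1]) == pytest.approx(produced, rel=1e-4)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            simulate_cascade(REDUCED_MODEL, 0.1, 5.0, 0.0, t_end=0.0)
        with pytest.raises(ValueError):
            simulate_cascade(REDUCED_MODEL, 0.1, -5.0, 0.0, t_end=1.0)


# ------------------------------------------------------ steady-state math


class TestSteadyState:
    def test_analytic_values(self):
        assert steady_state_analytic(PseudoOrderRates(k1=0.0, k2=0.1)) == 0.0
        assert steady_state_analytic(PseudoOrderRates(k1=1.0, k2=0.1)) == pytest.approx(10.0)
        with pytest.raises(ValueError):
            steady_state_analytic(PseudoOrderRates(k1=1.0, k2=0.0))

    def test_reduction_values(self):
        rates = pseudo_order_reduction(REDUCED_MODEL, 0.1, 0.0)
        assert rates.k1 == 0.0
        assert rates.k2 == pytest.approx(5.0 / 155.1, rel=1e-12)

    def test_reduction_warns_for_h_not_1(self):
        model = CascadeModel(
            production=MMKinetics(v_max=1, k_m=2.9),
            decomposition=HillKinetics(v_max=5, k_half=155.1, hill_h=2.0),
        )
        with pytest.warns(UserWarning, match="h=1"):
            rates = pseudo_order_reduction(model, 0.1, 5.0)
        assert not rates.first_order_exact

    def test_ode_converges_to_k1_over_k2(self):
        """Random reduced-regime models settle at k1/k2 within 1% by t = 10/k2."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            k2 = rng.uniform(0.01, 0.5)
            k_half = 1e4
            ss_target = rng.uniform(0.1, 20.0)  # << k_half
            k1 = ss_target * k2
            model = CascadeModel(
                production=MMKinetics(v_max=k1 * (2.9 + 100.0) / 100.0, k_m=2.9),
                decomposition=HillKinetics(v_max=k2 * k_half, k_half=k_half, hill_h=1.0),
                decomposition_catalyst_exponent=1.0,
            )
            _, _, h = simulate_cascade(
                model, 0.1, glucose0=100.0, h2o2_0=0.0,
                t_end=10.0 / k2, glucose_depletion=False,
            )
            assert h[-1] == pytest.approx(k1 / k2, rel=0.01)

    def test_scan_equal_exponents_catalyst_independent(self):
        scan = steady_state_scan(
            REDUCED_MODEL, [0.05, 0.1, 0.2, 0.5], glucose=5.0, t_end=2000.0
        )
        assert scan.converged.all()
        assert np.ptp(scan.steady_h2o2) / scan.steady_h2o2.mean() < 1e-4

    def test_scan_production_only_scaling_is_linear(self):
        model = CascadeModel(
            # production kept tiny so every steady state sits far below K0.5
            production=MMKinetics(v_max=0.005, k_m=2.9),
            decomposition=REDUCED_MODEL.decomposition,
            decomposition_catalyst_exponent=0.0,
        )
        scan = steady_state_scan(model, [0.05, 0.1, 0.2, 0.4], glucose=5.0, t_end=2000.0)
        assert scan.converged.all()
        assert scan.r_squared > 0.999
        # through-origin proportionality to catalyst loading
        ratio = scan.steady_h2o2 / scan.catalyst_concs
        assert np.ptp(ratio) / ratio.mean() < 0.02

    def test_scan_zero_glucose(self):
        scan = steady_state_scan(REDUCED_MODEL, [0.1, 0.5], glucose=0.0, t_end=500.0)
        np.testing.assert_allclose(scan.steady_h2o2, 0.0, atol=1e-9)
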
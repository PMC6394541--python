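"""Structural-model checks against closed forms and an ODE oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from dtmilk.kinetics import (
    Dose,
    InfantPool,
    PairParameters,
    infant_amount,
    infant_volume,
    mother_amount,
    predict_enrichment,
)
from dtmilk.kinetics import InvalidParameterError


def ode_amounts(dose, k_mm, k_mb, k_bo, t_grid):
    """Independent oracle: adaptive integration of the linked two-pool system."""

    def rhs(_t, y):
        return [-k_mm * y[0], k_mb * y[0] - k_bo * y[1]]

    sol = solve_ivp(
        rhs,
        (0.0, float(np.max(t_grid))),
        [dose, 0.0],
        t_eval=np.asarray(t_grid, dtype=float),
        rtol=1e-11,
        atol=1e-14,
        method="LSODA",
    )
    return sol.y[0], sol.y[1]


class TestMotherAmount:
    def test_initial_condition_is_dose(self):
        assert mother_amount(0.030, 0.37, 0.0) == pytest.approx(0.030, abs=0)

    def test_closed_form_value(self):
        assert mother_amount(0.030, 0.10, 7.0) == pytest.approx(0.030 * np.exp(-0.7), rel=1e-14)

    @given(
        k=st.floats(0.01, 1.0),
        t1=st.floats(0.0, 13.0),
        dt=st.floats(0.01, 5.0),
    )
    @settings(max_examples=50, derandomize=True)
    def test_strictly_decreasing(self, k, t1, dt):
        assert mother_amount(0.030, k, t1 + dt) < mother_amount(0.030, k, t1)

    def test_log_linear_slope_is_kmm(self):
        t = np.linspace(0.5, 14, 40)
        pair = PairParameters(k_mm=0.11, V_m=28.0, CL_mb=0.8, CL_bo=0.9, V_b=3.5)
        pool = InfantPool(weight_start=5.0, weight_end=5.0)
        logf = np.log(predict_enrichment(pair, pool, Dose(0.030), "mother", t))
        slopes = np.diff(logf) / np.diff(t)
        assert np.allclose(slopes, -0.11, rtol=1e-10)

    @pytest.mark.parametrize("bad", [{"dose": -1.0}, {"dose": 0.0}, {"k_mm": -0.1}])
    def test_invalid_parameters_raise(self, bad):
        kwargs = {"dose": 0.030, "k_mm": 0.1, "t": 1.0}
        kwargs.update(bad)
        with pytest.raises(InvalidParameterError):
            mother_amount(**kwargs)


class TestInfantAmount:
    def test_zero_at_dose_time(self):
        assert infant_amount(0.030, 0.1, 0.03, 0.25, 0.0) == 0.0

    def test_equal_rate_limit_matches_perturbed_form_and_ode(self):
        dose, k, k_mb, t = 0.030, 0.3, 0.05, 4.0
        limit = infant_amount(dose, k, k_mb, k, t)
        assert limit == pytest.approx(dose * k_mb * t * np.exp(-1.2), rel=1e-12)
        for eps in (1e-6, -1e-6):
            nearby = infant_amount(dose, k, k_mb, k * (1 + eps), t)
            assert nearby == pytest.approx(limit, rel=1e-5)
        _, ab = ode_amounts(dose, k, k_mb, k, [t])
        assert limit == pytest.approx(ab[0], rel=1e-8)

    def test_matches_ode_oracle_on_grid(self):
        t = np.linspace(0.0, 14.0, 57)
        dose, k_mm, k_bo, k_mb = 0.030, 0.12, 0.45, 0.02
        _, ab = ode_amounts(dose, k_mm, k_mb, k_bo, t)
        analytic = infant_amount(dose, k_mm, k_mb, k_bo, t)
        scale = np.max(np.abs(ab))
        assert np.allclose(analytic, ab, rtol=1e-8, atol=1e-8 * scale)

    def test_unimodal_rise_then_decay(self):
        t = np.linspace(0.0, 100.0, 10001)
        a = infant_amount(0.030, 0.1, 0.03, 0.25, t)
        d = np.diff(a)
        sign_changes = np.sum(np.diff(np.sign(d[d != 0])) != 0)
        assert sign_changes == 1
        assert np.all(a >= 0)
        assert a[-1] < 1e-2 * a.max()

    @given(
        k_mm=st.floats(0.02, 0.5),
        k_bo=st.floats(0.05, 1.0),
        k_mb=st.floats(0.001, 0.1),
        t=st.floats(0.0, 14.0),
    )
    @settings(max_examples=60, derandomize=True)
    def test_nonnegative(self, k_mm, k_bo, k_mb, t):
        assert infant_amount(0.030, k_mm, k_mb, k_bo, t) >= 0


class TestInfantVolume:
    def test_constant_weight_gives_three_litres_for_5kg(self):
        pool = InfantPool(weight_start=5.0, weight_end=5.0)
        assert infant_volume(pool, 3.7) == pytest.approx(3.0)

    def test_midpoint_interpolation(self):
        pool = InfantPool(weight_start=5.0, weight_end=6.0)
        assert infant_volume(pool, 7.0) == pytest.approx(0.60 * 5.5)
        assert infant_volume(pool, 0.0) == pytest.approx(0.60 * 5.0)

    def test_out_of_window_rejected(self):
        pool = InfantPool(weight_start=5.0, weight_end=6.0)
        with pytest.raises(ValueError):
            infant_volume(pool, 15.0)
        with pytest.raises(ValueError):
            infant_volume(pool, -0.5)


class TestPredictEnrichment:
    def test_mother_initial_enrichment(self):
        pair = PairParameters(k_mm=0.1, V_m=30.0, CL_mb=0.8, CL_bo=0.9, V_b=3.5)
        pool = InfantPool(weight_start=5.0, weight_end=5.0)
        assert predict_enrichment(pair, pool, Dose(0.030), "mother", 0.0) == pytest.approx(1000.0)
        assert predict_enrichment(pair, pool, Dose(0.030), "infant", 0.0) == 0.0

    def test_infant_composition_with_ode_oracle(self):
        pool = InfantPool(weight_start=5.2, weight_end=5.8)
        pair = PairParameters.from_pool(k_mm=0.11, V_m=27.0, CL_mb=0.75, CL_bo=0.85, pool=pool)
        t = np.linspace(0.5, 14.0, 28)
        _, ab = ode_amounts(0.030, pair.k_mm, pair.k_mb, pair.k_bo, t)
        expected = 1e6 * ab / pool.volume(t)
        got = predict_enrichment(pair, pool, Dose(0.030), "infant", t)
        assert np.allclose(got, expected, rtol=1e-8)

    def test_unknown_role_rejected(self):
        pair = PairParameters(k_mm=0.1, V_m=30.0, CL_mb=0.8, CL_bo=0.9)
        pool = InfantPool(weight_start=5.0, weight_end=5.0)
        with pytest.raises(ValueError):
            predict_enrichment(pair, pool, Dose(0.030), "father", 1.0)


class TestPairParameters:
    def test_derived_rate_constants(self):
        pair = PairParameters(k_mm=0.1, V_m=30.0, CL_mb=0.6, CL_bo=0.9, V_b=3.0)
        assert pair.k_mb == pytest.approx(0.02)
        assert pair.k_bo == pytest.approx(0.3)
        assert pair.CL_mo == pytest.approx(0.1 * 30 - 0.6)

    def test_milk_route_cannot_exceed_total_output(self):
        with pytest.raises(InvalidParameterError):
            PairParameters(k_mm=0.01, V_m=30.0, CL_mb=0.6, CL_bo=0.9)
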
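"""Constitutive law, flow-curve fitting, recovery and regime taxonomy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from airprint.rheology import (
    FlowCurve,
    HerschelBulkleyParams,
    MaterialFormulation,
    TearingTrace,
    classify_regime,
    default_catalog,
    effective_viscosity,
    fit_flow_curve,
    read_flow_curve_csv,
    read_tearing_trace_csv,
    recovery_percent,
    shear_stress,
    synthesize_flow_curve,
    write_flow_curve_csv,
    write_tearing_trace_csv,
    yield_capillary_number,
)


class TestEffectiveViscosity:
    def test_newtonian_limit_is_flat(self):
        hb = HerschelBulkleyParams(tau_y=0.0, K=2.0, n=1.0)
        gd = np.array([0.0, 1e-3, 1.0, 1e3])
        assert np.allclose(effective_viscosity(gd, hb), 2.0)

    def test_yield_term_vanishes_at_high_shear(self):
        hb = HerschelBulkleyParams(tau_y=10.0, K=1.0, n=1.0)
        assert effective_viscosity(1e8, hb) == pytest.approx(1.0, rel=1e-6)

    def test_zero_shear_plateau(self):
        hb = HerschelBulkleyParams(tau_y=10.0, K=1.0, n=1.0, m_reg=100.0)
        assert effective_viscosity(0.0, hb) == pytest.approx(10.0 * 100.0 + 1.0)

    def test_cap_applies_for_shear_thinning_zero_limit(self):
        hb = HerschelBulkleyParams(tau_y=0.0, K=1.0, n=0.5)
        assert effective_viscosity(0.0, hb, mu_max=1e6) == 1e6

    def test_rejects_negative_and_nonfinite_shear(self):
        hb = HerschelBulkleyParams(tau_y=1.0, K=1.0, n=1.0)
        with pytest.raises(ValueError):
            effective_viscosity(-1.0, hb)
        with pytest.raises(ValueError):
            effective_viscosity(np.nan, hb)

    @given(
        tau_y=st.floats(0.0, 500.0),
        K=st.floats(0.01, 100.0),
        n=st.floats(0.2, 1.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_stress_monotone_and_viscosity_thinning(self, tau_y, K, n):
        """Regularization must not create non-monotone stress or thickening."""
        hb = HerschelBulkleyParams(tau_y=tau_y, K=K, n=n)
        gd = np.logspace(-3, 3, 400)
        tau = shear_stress(gd, hb)
        mu = effective_viscosity(gd, hb)
        assert (np.diff(tau) > -1e-12 * tau.max()).all()
        assert (np.diff(mu) <= 1e-12 * mu.max()).all()  # n <= 1: shear thinning

    def test_regularized_converges_to_ideal_hb(self):
        hb_ideal = lambda gd: 30.0 + 5.0 * gd**1.0
        gd = np.logspace(0, 3, 50)
        for m_reg, tol in ((10.0, 1e-2), (1000.0, 1e-6)):
            hb = HerschelBulkleyParams(tau_y=30.0, K=5.0, n=1.0, m_reg=m_reg)
            rel = np.abs(shear_stress(gd, hb) - hb_ideal(gd)) / hb_ideal(gd)
            assert rel[gd * m_reg > 30].max() < tol

    def test_stress_zero_at_origin(self):
        hb = HerschelBulkleyParams(tau_y=50.0, K=3.0, n=0.4)
        assert shear_stress(0.0, hb) == 0.0
        assert shear_stress(1.0, HerschelBulkleyParams(0, 3, 1)) == pytest.approx(3.0)


class TestFlowCurveFitting:
    def test_round_trip_noise_free(self):
        true = HerschelBulkleyParams(tau_y=50.0, K=20.0, n=0.4)
        curve = synthesize_flow_curve(true, np.logspace(-2, 3, 30))
        fit = fit_flow_curve(curve)
        assert fit.converged
        assert fit.params.tau_y == pytest.approx(50.0, rel=0.01)
        assert fit.params.K == pytest.approx(20.0, rel=0.01)
        assert fit.params.n == pytest.approx(0.4, rel=0.01)

    def test_newtonian_degenerate_recovery(self):
        curve = synthesize_flow_curve(
            HerschelBulkleyParams(0.0, 5.0, 1.0), np.logspace(-2, 2, 20)
        )
        fit = fit_flow_curve(curve)
        assert fit.params.tau_y <= 0.01 * curve.stresses.max()

    def test_noisy_recovery_within_15pc(self):
        rng = np.random.default_rng(42)
        true = HerschelBulkleyParams(tau_y=50.0, K=20.0, n=0.4)
        curve = synthesize_flow_curve(
            true, np.logspace(-2, 3, 30), noise_sigma=0.05, rng=rng
        )
        fit = fit_flow_curve(curve)
        assert fit.params.tau_y == pytest.approx(50.0, rel=0.15)
        assert fit.params.K == pytest.approx(20.0, rel=0.15)
        assert fit.params.n == pytest.approx(0.4, rel=0.15)

    def test_viscosity_mode_curve(self):
        gd = np.logspace(-1, 2, 12)
        hb = HerschelBulkleyParams(10.0, 2.0, 0.7)
        tau = 10.0 + 2.0 * gd**0.7
        curve = FlowCurve(gd, tau / gd, kind="viscosity")
        fit = fit_flow_curve(curve)
        assert fit.params.tau_y == pytest.approx(10.0, rel=0.02)

    def test_csv_round_trip(self, tmp_path):
        curve = synthesize_flow_curve(
            HerschelBulkleyParams(5.0, 2.0, 0.5), np.logspace(-1, 2, 10)
        )
        path = tmp_path / "curve.csv"
        write_flow_curve_csv(curve, path)
        back = read_flow_curve_csv(path)
        assert np.allclose(back.stresses, curve.stresses)

    def test_validation(self):
        with pytest.raises(ValueError):
            FlowCurve(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))  # <4 pts
        with pytest.raises(ValueError):
            FlowCurve(np.array([1.0, 2, 2, 3]), np.ones(4))  # not ascending


class TestRecovery:
    def _trace(self, first, second):
        t = np.linspace(0.0, 10.0, first.size)
        return TearingTrace(t, first, t, second)

    def test_identical_passes_give_100(self):
        tq = np.full(100, 3.0)
        assert recovery_percent(self._trace(tq, tq)) == pytest.approx(100.0)

    def test_half_second_pass_gives_50(self):
        tq = np.full(100, 3.0)
        assert recovery_percent(self._trace(tq, 0.5 * tq)) == pytest.approx(50.0)

    def test_exponential_recovery_with_noise(self):
        """Synthetic tearing traces regenerate the programmed recovery level."""
        rng = np.random.default_rng(7)
        t = np.linspace(0.0, 10.0, 400)
        plateau = 2.0
        first = plateau * (1.0 - np.exp(-t / 0.5)) * (
            1.0 + 0.02 * rng.standard_normal(t.size)
        )
        second = 0.95 * plateau * (1.0 - np.exp(-t / 0.5)) * (
            1.0 + 0.02 * rng.standard_normal(t.size)
        )
        trace = TearingTrace(t, np.abs(first), t, np.abs(second))
        assert recovery_percent(trace) == pytest.approx(95.0, abs=1.0)

    def test_zero_first_pass_is_undefined(self):
        t = np.linspace(0, 1, 50)
        trace = TearingTrace(t, np.zeros(50), t, np.ones(50))
        with pytest.raises(ValueError):
            recovery_percent(trace)

    def test_csv_round_trip(self, tmp_path):
        t = np.linspace(0.0, 5.0, 30)
        trace = TearingTrace(t, np.full(30, 2.0), t, np.full(30, 1.5), pass_gap=5.0)
        path = tmp_path / "trace.csv"
        write_tearing_trace_csv(trace, path)
        back = read_tearing_trace_csv(path, pass_gap=5.0)
        assert recovery_percent(back) == pytest.approx(75.0)


class TestRegimeTaxonomy:
    def test_yield_capillary_number_worked_example(self):
        assert yield_capillary_number(100.0, 0.025, 250e-6) == pytest.approx(1.0)

    def test_linearity_in_radius(self):
        y1 = yield_capillary_number(50.0, 0.025, 1e-4)
        y2 = yield_capillary_number(50.0, 0.025, 2e-4)
        assert y2 == pytest.approx(2.0 * y1)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            yield_capillary_number(0.0, 0.025, 1e-4)

    def test_catalog_y_increases_with_yield_stress(self):
        cat = default_catalog()
        order = ["M1", "M1A", "M1B", "M1C", "M1D", "M2"]
        ys = [
            yield_capillary_number(cat[m].hb.tau_y, 0.025, 250e-6) for m in order
        ]
        assert (np.diff(ys) > 0).all()

    @pytest.mark.parametrize(
        "recovery,y_scale,expected",
        [(50.0, 1.0, "M3"), (96.0, 10.0, "M2"), (96.0, 0.01, "M1")],
    )
    def test_regime_rules(self, recovery, y_scale, expected):
        cat = default_catalog()
        mat = cat["M2"]
        # scale the radius so Y = y_scale * Y_crit
        R = y_scale * 0.1 * mat.surface_tension_vs_air / mat.hb.tau_y
        assert classify_regime(mat, R, recovery) == expected

    def test_monotone_never_demotes_m2(self):
        """Raising tau_y at fixed sigma, R, recovery never turns M2 into M1."""
        cat = default_catalog()
        base = cat["M1"]
        R = 250e-6
        seen_m2 = False
        for tau_y in np.logspace(0, 3, 30):
            mat = MaterialFormulation(
                name="x",
                hb=HerschelBulkleyParams(tau_y, base.hb.K, base.hb.n),
                density=base.density,
                surface_tension_vs_air=base.surface_tension_vs_air,
            )
            regime = classify_regime(mat, R, recovery=96.0)
            if seen_m2:
                assert regime == "M2"
            seen_m2 = seen_m2 or regime == "M2"
        assert seen_m2

    def test_reference_viscosity_uses_001_shear_rate(self):
        mat = default_catalog()["M2"]
        expected = effective_viscosity(0.01, mat.hb)
        assert mat.reference_viscosity() == pytest.approx(float(expected))


def test_catalog_yaml_round_trip(tmp_path):
    from airprint.rheology import load_catalog, save_catalog

    cat = default_catalog()
    path = tmp_path / "materials.yaml"
    save_catalog(cat, path)
    back = load_catalog(path)
    assert set(back) == set(cat)
    assert back["M2"].hb.tau_y == cat["M2"].hb.tau_y
    assert back["M3"].storage_modulus == cat["M3"].storage_modulus
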
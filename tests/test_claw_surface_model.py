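import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_force_trace, geometric_penetration_slope
from perchgrip.claw_surface_model import (
    ClawTipModel,
    effective_theta,
    depth_ratio,
    evaluate_penetration,
    fit_exponential_offset,
    fit_penetration_curve,
    fit_sphere_tip,
    penetration_slope,
    sweep_usable_surface,
    trace_surface,
    usable_surface,
)
from perchgrip.surface_metrology import SurfaceProfile
from perchgrip.synthetic_data import (
    ClawGenSpec,
    SurfaceGenSpec,
    gen_claw_profile,
    gen_surface_profile,
)


class TestTraceSurface:
    def test_zero_radius_is_identity(self, rough_surface):
        traced = trace_surface(rough_surface, 0.0)
        np.testing.assert_array_equal(traced.traced_heights_um, rough_surface.heights)

    def test_flat_profile_unchanged(self):
        p = SurfaceProfile(np.arange(0.0, 1.0, 0.005), np.zeros(200))
        traced = trace_surface(p, 50.0)
        np.testing.assert_allclose(traced.traced_heights_um, 0.0, atol=1e-9)

    def test_v_notch_bridged(self):
        # notch narrower than the tip diameter: the traced surface bridges it
        spacing = 0.002  # 2 um
        x = np.arange(0.0, 1.0, spacing)
        h = np.zeros(x.size)
        notch = (x > 0.45) & (x < 0.5)  # 50 um wide, tip radius 50 um
        h[notch] = -200.0 * (1 - np.abs(x[notch] - 0.475) / 0.025)
        p = SurfaceProfile(x, h)
        traced = trace_surface(p, 50.0)
        assert traced.traced_heights_um[(x > 0.46) & (x < 0.49)].min() > h.min() + 50.0
        np.testing.assert_allclose(
            traced.traced_heights_um, brute_force_trace(x, h, 50.0), atol=1e-9
        )

    def test_matches_brute_force_on_rough_surface(self, rough_surface):
        traced = trace_surface(rough_surface, 50.0)
        oracle = brute_force_trace(rough_surface.positions, rough_surface.heights, 50.0)
        np.testing.assert_allclose(traced.traced_heights_um, oracle, atol=1e-9)

    def test_extensive_and_monotone_in_radius(self, rough_surface):
        t20 = trace_surface(rough_surface, 20.0)
        t80 = trace_surface(rough_surface, 80.0)
        assert np.all(t20.traced_heights_um >= rough_surface.heights - 1e-9)
        assert np.all(t80.traced_heights_um >= t20.traced_heights_um - 1e-9)

    def test_resolution_guard_warns(self, rough_surface):
        with pytest.warns(UserWarning, match="coarse"):
            trace_surface(rough_surface, 10.0)  # spacing 5 um > 10/5 um

    def test_resolution_guard_strict_raises(self, rough_surface):
        with pytest.raises(ValueError, match="coarse"):
            trace_surface(rough_surface, 10.0, strict=True)


class TestPenetrationSlope:
    def test_zero_limit(self):
        assert penetration_slope(0.0) == 0.0
        # series expansion: m ~ sqrt(DR)/2 for small DR
        assert penetration_slope(1e-8) == pytest.approx(math.sqrt(1e-8) / 2.0, rel=1e-3)

    def test_dr_005(self):
        # frozen from the geometric-construction oracle
        assert penetration_slope(0.05) == pytest.approx(0.11323701145890609, abs=1e-12)
        assert math.degrees(math.atan(penetration_slope(0.05))) == pytest.approx(6.4606, abs=2e-4)

    def test_dr_099(self):
        assert penetration_slope(0.99) == pytest.approx((1 - 0.1) / math.sqrt(0.99), rel=1e-12)

    def test_invalid_dr(self):
        with pytest.raises(ValueError):
            penetration_slope(1.0)
        with pytest.raises(ValueError):
            penetration_slope(-0.1)

    @given(dr=st.floats(1e-6, 0.99, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_matches_geometric_oracle(self, dr):
        assert penetration_slope(dr) == pytest.approx(geometric_penetration_slope(dr), abs=1e-9)


class TestEffectiveTheta:
    def test_dr_zero_passthrough(self):
        assert effective_theta(10.0, 0.0) == 10.0

    def test_theta10_dr005(self):
        # 10 deg - atan(m(0.05)) = 3.5394 deg, from the slope oracle
        expected = 10.0 - math.degrees(math.atan(geometric_penetration_slope(0.05)))
        assert effective_theta(10.0, 0.05) == pytest.approx(expected, abs=1e-9)
        assert effective_theta(10.0, 0.05) == pytest.approx(3.539, abs=1e-3)

    def test_clamped_at_zero(self):
        assert effective_theta(5.0, 0.05) == 0.0

    def test_depth_ratio_helper(self):
        assert depth_ratio(2.5, 50.0) == pytest.approx(0.05)


class TestUsableSurface:
    def test_flat_surface_zero(self):
        p = SurfaceProfile(np.arange(0.0, 1.0, 0.001), np.zeros(1000))
        traced = trace_surface(p, 50.0)
        tip = ClawTipModel(50.0, 0.0, 10.0)
        assert usable_surface(traced, tip) == 0.0

    def test_sawtooth_half_usable(self, sawtooth_surface):
        # 20 deg faces, 10 deg threshold, tiny tip: only the rising half counts
        traced = trace_surface(sawtooth_surface, 1.0)
        tip = ClawTipModel(1.0, 0.0, 10.0)
        n_a = usable_surface(traced, tip, drag_direction=+1)
        assert n_a == pytest.approx(0.5, abs=0.02)

    def test_sawtooth_threshold_above_face_angle(self, sawtooth_surface):
        traced = trace_surface(sawtooth_surface, 1.0)
        tip = ClawTipModel(1.0, 0.0, 25.0)  # steeper than the 20 deg faces
        assert usable_surface(traced, tip) == pytest.approx(0.0, abs=0.02)

    def test_both_directions_doubles_sawtooth(self, sawtooth_surface):
        traced = trace_surface(sawtooth_surface, 1.0)
        tip = ClawTipModel(1.0, 0.0, 10.0)
        n_both = usable_surface(traced, tip, both_directions=True)
        assert n_both == pytest.approx(1.0, abs=0.04)

    def test_rougher_surface_more_usable(self):
        smooth = gen_surface_profile(
            SurfaceGenSpec(target_rms_um=10.0, length_mm=5.0, spacing_um=5.0, seed=7)
        )
        rough = gen_surface_profile(
            SurfaceGenSpec(target_rms_um=40.0, length_mm=5.0, spacing_um=5.0, seed=7)
        )
        tip = ClawTipModel(50.0, 0.0, 10.0)
        n_smooth = usable_surface(trace_surface(smooth, 50.0), tip)
        n_rough = usable_surface(trace_surface(rough, 50.0), tip)
        assert n_rough >= n_smooth

    def test_penetration_increases_usable(self, rough_surface):
        traced = trace_surface(rough_surface, 50.0)
        n_dr0 = usable_surface(traced, ClawTipModel(50.0, 0.0, 10.0))
        n_dr005 = usable_surface(traced, ClawTipModel(50.0, 0.05, 10.0))
        assert n_dr005 >= n_dr0

    def test_monotone_in_theta(self, rough_surface):
        traced = trace_surface(rough_surface, 50.0)
        values = [
            usable_surface(traced, ClawTipModel(50.0, 0.0, th)) for th in (0.0, 5.0, 10.0, 20.0, 40.0)
        ]
        assert all(a >= b for a, b in zip(values, values[1:]))
        assert all(0.0 <= v <= 1.0 for v in values)

    def test_spectrum_changes_engagement_at_equal_rms(self):
        # long- vs short-wavelength roughness at identical RMS engage a
        # 50 um tip differently; verified against the brute-force tracer
        tip = ClawTipModel(50.0, 0.0, 10.0)
        n_a = {}
        for beta in (1.0, 3.0):
            prof = gen_surface_profile(
                SurfaceGenSpec(target_rms_um=30.0, spectral_exponent=beta, length_mm=3.0, spacing_um=5.0, seed=5)
            )
            traced = trace_surface(prof, 50.0)
            oracle = brute_force_trace(prof.positions, prof.heights, 50.0)
            np.testing.assert_allclose(traced.traced_heights_um, oracle, atol=1e-9)
            n_a[beta] = usable_surface(traced, tip)
        assert n_a[1.0] != n_a[3.0]


class TestSweep:
    def test_zero_policy(self, rough_surface):
        rows = sweep_usable_surface(rough_surface, [30.0, 60.0], [5.0, 10.0], "zero")
        assert all(r["depth_ratio"] == 0.0 for r in rows)

    def test_fixed_equals_isometric_at_reference(self, rough_surface):
        fixed = sweep_usable_surface(
            rough_surface, [50.0], [10.0], "fixed", dr_value=0.05
        )
        iso = sweep_usable_surface(
            rough_surface, [50.0], [10.0], "isometric", dr_reference_radius_um=50.0, dr_reference=0.05
        )
        assert fixed[0]["n_a"] == iso[0]["n_a"]
        assert fixed[0]["depth_ratio"] == iso[0]["depth_ratio"]

    def test_isometric_scales_linearly(self, rough_surface):
        rows = sweep_usable_surface(
            rough_surface, [25.0, 50.0, 100.0], [10.0], "isometric",
            dr_reference_radius_um=50.0, dr_reference=0.05,
        )
        drs = {r["r_a_um"]: r["depth_ratio"] for r in rows}
        assert drs[25.0] == pytest.approx(0.025)
        assert drs[100.0] == pytest.approx(0.10)

    def test_rows_monotone_in_theta(self, rough_surface):
        rows = sweep_usable_surface(rough_surface, [30.0, 80.0], [2.0, 10.0, 25.0], "zero")
        for r_a in (30.0, 80.0):
            vals = [r["n_a"] for r in rows if r["r_a_um"] == r_a]
            assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestExpOffsetFit:
    def test_exact_recovery(self):
        r = np.linspace(5.0, 400.0, 30)
        y = 0.6 * np.exp(-r / 80.0) + 0.1
        fit = fit_exponential_offset(r, y)
        assert fit.amplitude == pytest.approx(0.6, rel=1e-6)
        assert fit.decay_length_um == pytest.approx(80.0, rel=1e-6)
        assert fit.offset == pytest.approx(0.1, rel=1e-6)
        assert fit.residual_rms < 1e-9

    def test_constant_data(self):
        r = np.linspace(5.0, 400.0, 20)
        fit = fit_exponential_offset(r, np.full(20, 0.25))
        assert fit.amplitude == pytest.approx(0.0, abs=1e-6)
        assert fit.offset + fit.amplitude * np.exp(-r[0] / fit.decay_length_um) == pytest.approx(
            0.25, abs=1e-6
        )

    def test_noisy_recovery_within_3se(self):
        rng = np.random.default_rng(11)
        r = np.linspace(5.0, 400.0, 40)
        truth = (0.6, 80.0, 0.1)
        amps, lams, offs = [], [], []
        for _ in range(100):
            y = truth[0] * np.exp(-r / truth[1]) + truth[2] + rng.normal(0, 0.02, r.size)
            fit = fit_exponential_offset(r, y)
            amps.append(fit.amplitude)
            lams.append(fit.decay_length_um)
            offs.append(fit.offset)
        for est, true in zip((amps, lams, offs), truth):
            est = np.asarray(est)
            se = est.std(ddof=1) / 10.0
            assert abs(est.mean() - true) < 3.0 * se


class TestSphereTipFit:
    def test_exact_circle(self):
        claw = gen_claw_profile(ClawGenSpec(tip_radius_um=80.0, opening_halfangle_deg=30.0))
        # tangency at h = R(1 - sin 30) = 0.5 R; stay below it
        assert fit_sphere_tip(claw, height_limit_um=35.0) == pytest.approx(80.0, rel=1e-9)

    def test_parabolic_osculating_limit(self):
        h = np.linspace(0.1, 2.0, 50)
        w = 2.0 * np.sqrt(2.0 * 50.0 * h)
        from perchgrip.claw_surface_model import ClawProfile

        claw = ClawProfile(h, w)
        assert fit_sphere_tip(claw, height_limit_um=2.0) == pytest.approx(50.0, rel=0.03)

    def test_parrotlet_like_claw(self):
        claw = gen_claw_profile(ClawGenSpec(tip_radius_um=50.0, opening_halfangle_deg=25.0))
        fitted = fit_sphere_tip(claw, height_limit_um=20.0)
        assert fitted == pytest.approx(50.0, abs=1.0)


class TestPenetrationCurveFit:
    def test_linear_data(self):
        f = np.array([0.4, 1.0, 1.8, 3.0])
        fit = fit_penetration_curve(f, 4.0 * f)
        assert fit.coeffs[0] == pytest.approx(4.0, abs=1e-9)
        assert fit.coeffs[1] == pytest.approx(0.0, abs=1e-9)
        assert fit.coeffs[2] == pytest.approx(0.0, abs=1e-9)

    def test_origin_constraint(self):
        f = np.array([0.4, 1.0, 1.8, 3.0])
        fit = fit_penetration_curve(f, 2.0 * f + 0.5 * f**3)
        assert evaluate_penetration(fit, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_exact_cubic_recovery_at_test_loads(self):
        # four load levels, three coefficients: consistent data recovers exactly
        f = np.array([0.4, 1.0, 1.8, 3.0])
        c = (1.5, -0.2, 0.05)
        d = c[0] * f + c[1] * f**2 + c[2] * f**3
        fit = fit_penetration_curve(f, d)
        np.testing.assert_allclose(fit.coeffs, c, atol=1e-9)

    def test_extrapolation_warns(self):
        f = np.array([0.4, 1.0, 1.8, 3.0])
        fit = fit_penetration_curve(f, 2.0 * f)
        with pytest.warns(UserWarning, match="extrapolation"):
            evaluate_penetration(fit, 5.0)
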
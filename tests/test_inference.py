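"""Equilibrium-angle inference: M, intensity laws, collapse, estimators."""

import math

import numpy as np
import pandas as pd
import pytest

from tropisim import (
    IntensityLaw,
    M_from_equilibrium,
    OrganShape,
    TropicParams,
    derived_numbers,
    estimate_B_from_dark_shape,
    estimate_D,
    fit_intensity_law,
    intensity_to_M,
    invert_law_for_intensity,
    master_curve_collapse,
    orthogonal_line_fit,
    pgea_phenomenological,
)
from tropisim.inference import (
    REASON_A0_BEYOND_90,
    REASON_OK,
    BelowThresholdWarning,
    EmptyFitError,
    InsufficientDataError,
)
from tropisim.models import DomainError
from tropisim.synth import GeneratorSpec, generate_pgea_dataset


def noiseless_prot1(law=None, A0_deg=(0, 10, 30), **kw):
    law = law or IntensityLaw("stevens_power", a=1.0, b=-0.4)
    spec = GeneratorSpec(
        protocol="PROT1",
        A0_list=tuple(math.radians(a) for a in A0_deg),
        law=law,
        noise_sigma=0.0,
        replicates=1,
        seed=0,
        **kw,
    )
    return generate_pgea_dataset(spec)


class TestMFromEquilibrium:
    def test_half_light_angle_means_balanced_sensitivities(self):
        assert M_from_equilibrium(math.pi / 2, math.pi / 4) == pytest.approx(1.0)

    def test_tip_at_light_direction_means_photo_dominates(self):
        assert M_from_equilibrium(0.8, 0.8) == pytest.approx(0.0)

    def test_vertical_tip_returns_infinite_marker(self):
        assert math.isinf(M_from_equilibrium(0.8, 0.0))


class TestOrthogonalFit:
    def test_exact_line_recovered_with_unit_r2(self):
        x = np.linspace(-3, 5, 20)
        fit = orthogonal_line_fit(x, 2.0 - 0.4 * x)
        assert fit.slope == pytest.approx(-0.4, abs=1e-12)
        assert fit.intercept == pytest.approx(2.0, abs=1e-12)
        assert fit.R_squared == 1.0

    def test_matches_brute_force_perpendicular_minimizer(self):
        rng = np.random.default_rng(7)
        for _ in range(3):
            x = rng.uniform(-2, 2, 20)
            y = 1.0 + 0.7 * x + rng.normal(0, 0.4, 20)
            fit = orthogonal_line_fit(x, y)
            # brute force over line angle; optimal offset is the centroid's
            thetas = np.linspace(-np.pi / 2, np.pi / 2, 4001)[:-1]
            xc, yc = x - x.mean(), y - y.mean()
            # perpendicular distance to line through centroid at angle theta
            ss = [np.sum((-np.sin(t) * xc + np.cos(t) * yc) ** 2) for t in thetas]
            best = thetas[int(np.argmin(ss))]
            assert abs(math.atan(fit.slope) - best) < np.pi / 4000 * 2
            assert fit.residual_ss <= min(ss) + 1e-9

    def test_is_symmetric_in_x_and_y(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, 30)
        y = 0.5 + 1.3 * x + rng.normal(0, 0.2, 30)
        fit_xy = orthogonal_line_fit(x, y)
        fit_yx = orthogonal_line_fit(y, x)
        assert fit_xy.slope == pytest.approx(1.0 / fit_yx.slope, rel=1e-9)


class TestFitIntensityLaw:
    def test_noiseless_power_law_recovered_exactly(self):
        fit = fit_intensity_law(noiseless_prot1(), "stevens_power")
        assert abs(fit.slope - (-0.4)) < 1e-6
        assert fit.R_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.law.a == pytest.approx(1.0, rel=1e-9)

    def test_power_data_prefers_stevens_over_weber(self):
        df = noiseless_prot1()
        power = fit_intensity_law(df, "stevens_power")
        log = fit_intensity_law(df, "weber_fechner_log")
        assert power.residual_ss < log.residual_ss

    def test_log_data_prefers_weber_over_stevens(self):
        law = IntensityLaw("weber_fechner_log", a=6.0, b=-0.45)
        df = noiseless_prot1(law=law)
        power = fit_intensity_law(df, "stevens_power")
        log = fit_intensity_law(df, "weber_fechner_log")
        assert log.residual_ss < power.residual_ss

    def test_single_intensity_is_insufficient(self):
        df = noiseless_prot1(n_intensities=1, decades=0.0)
        with pytest.raises(InsufficientDataError):
            fit_intensity_law(df, "stevens_power")

    def test_all_invalid_records_is_an_empty_fit(self):
        df = noiseless_prot1(A0_deg=(120,))
        with pytest.raises(EmptyFitError):
            fit_intensity_law(df, "stevens_power")

    def test_exclusion_accounting_is_complete(self):
        df = noiseless_prot1(A0_deg=(0, 30, 120))
        fit = fit_intensity_law(df, "stevens_power")
        assert fit.n_used + fit.n_excluded == len(df)
        beyond = fit.validity[df["A0"] > math.pi / 2]
        assert (beyond == REASON_A0_BEYOND_90).all()

    def test_fitted_slope_sign_matches_decreasing_law(self):
        spec = GeneratorSpec(
            protocol="PROT1",
            A0_list=(0.0, math.radians(30)),
            noise_sigma=math.radians(2.0),
            replicates=5,
            seed=11,
        )
        fit = fit_intensity_law(generate_pgea_dataset(spec), "stevens_power")
        assert fit.slope < 0


class TestMasterCurveCollapse:
    def test_noiseless_shared_law_collapses(self):
        report = master_curve_collapse(noiseless_prot1())
        assert report.collapsed
        assert report.slope_dispersion < 1e-9

    def test_groups_with_different_exponents_do_not_collapse(self):
        parts = []
        for a0_deg, b in [(10, -0.2), (30, -0.6)]:
            parts.append(noiseless_prot1(
                law=IntensityLaw("stevens_power", a=1.0, b=b), A0_deg=(a0_deg,)))
        report = master_curve_collapse(pd.concat(parts, ignore_index=True))
        assert not report.collapsed
        assert report.slope_dispersion > 0.3

    def test_steep_tilts_are_excluded_and_listed(self):
        df = noiseless_prot1(A0_deg=(0, 30, 120))
        report = master_curve_collapse(df)
        assert report.collapsed
        assert (report.excluded["A0"] > math.pi / 2).all()
        assert len(report.excluded) == df[df["A0"] > math.pi / 2].shape[0]

    def test_single_group_is_trivially_collapsed(self):
        report = master_curve_collapse(noiseless_prot1(A0_deg=(10,)))
        assert report.collapsed and report.trivially_collapsed


class TestInvertLaw:
    def test_reciprocal_law_inverts(self):
        law = IntensityLaw("stevens_power", a=1.0, b=-1.0)
        assert invert_law_for_intensity(law, 0.5) == pytest.approx(2.0)

    def test_round_trip_identity(self):
        law = IntensityLaw("stevens_power", a=2.3, b=-0.4)
        for m in (0.1, 1.0, 7.5):
            assert intensity_to_M(invert_law_for_intensity(law, m), law) == \
                pytest.approx(m, rel=1e-12)

    def test_prot2_target_number(self):
        # holding a 30-degree tilt under light at 120 degrees needs M = 3
        assert 120.0 / 30.0 - 1.0 == pytest.approx(3.0)
        law = IntensityLaw("stevens_power", a=1.0, b=-0.4)
        I = invert_law_for_intensity(law, 3.0)
        assert intensity_to_M(I, law) == pytest.approx(3.0, rel=1e-12)

    def test_nonpositive_target_rejected(self):
        with pytest.raises(DomainError):
            invert_law_for_intensity(IntensityLaw("stevens_power", a=1.0, b=-0.4), 0.0)


class TestMorphometricEstimators:
    def test_noiseless_dark_shape_recovers_B_exactly(self, s_grid):
        B = 4.0
        shape = OrganShape.from_angles(0.5 * np.exp(-B * s_grid), s_grid)
        est = estimate_B_from_dark_shape(shape)
        assert abs(est.B - B) < 1e-6

    def test_straight_organ_gives_zero_B(self, s_grid):
        shape = OrganShape.straight(0.5, 1.0)
        est = estimate_B_from_dark_shape(shape)
        assert est.B == 0.0 and est.flat_profile

    def test_noisy_recovery_stays_within_tenth(self, s_grid):
        B = 4.0
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noisy = 0.5 * np.exp(-B * s_grid) + rng.normal(0, 0.01, s_grid.size)
            est = estimate_B_from_dark_shape(OrganShape.from_angles(noisy, s_grid))
            hits += abs(est.B - B) <= 0.1
        assert hits >= 19

    def test_D_from_B_and_M(self):
        assert estimate_D(4.0, 1.0) == pytest.approx(4.0)
        assert estimate_D(4.0, math.inf) == 0.0
        assert math.isinf(estimate_D(4.0, 0.0))

    def test_D_closes_the_identity_on_random_parameters(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = TropicParams(beta=rng.uniform(0.1, 5), gamma=rng.uniform(0.1, 5),
                             nu=rng.uniform(0.1, 5))
            d = derived_numbers(p)
            assert estimate_D(d.B, d.M) == pytest.approx(d.D, rel=1e-12)


class TestEquilibriumTip:
    def test_converged_run_uses_the_steady_slice(self):
        from tropisim import equilibrium_tip_angle, simulate

        p = TropicParams(beta=0.0, gamma=1.0, nu=4.0, A0=0.5, A_P=0.0)
        tip, status = equilibrium_tip_angle(simulate("AaC", p, 5.0))
        assert status == "steady"
        assert tip == pytest.approx(0.5 / 5.0, abs=1e-3)

    def test_unconverged_run_falls_back_to_windowed_mean(self):
        from tropisim import equilibrium_tip_angle, simulate

        p = TropicParams(beta=4.0, gamma=0.0, nu=0.0, A0=0.3)
        kin = simulate("AC", p, 5.0, dt=0.002)
        tip, status = equilibrium_tip_angle(kin)
        assert status == "transient"
        assert np.isfinite(tip)


class TestPhenomenologicalBaseline:
    def test_threshold_intensity_leaves_only_the_sine_term(self):
        assert pgea_phenomenological(2.0, 2.0, k=1.3, g=0.7, A0=0.5) == \
            pytest.approx(-0.7 * math.sin(0.5))

    def test_vertical_start_e_fold_gives_k(self):
        assert pgea_phenomenological(2.0 * math.e, 2.0, k=1.3, g=0.7, A0=0.0) == \
            pytest.approx(1.3)

    def test_below_threshold_flagged(self):
        with pytest.warns(BelowThresholdWarning):
            pgea_phenomenological(1.0, 2.0, k=1.0, g=1.0, A0=0.0)

    def test_darkness_limit_diverges_from_set_point_model(self, s_grid):
        """In darkness the baseline still depends on A0; the set-point model
        sends the tip toward vertical for any A0 when B is large."""
        from tropisim import steady_state

        baselines, tips = [], []
        for A0 in (0.2, 0.5, 1.0):
            baselines.append(pgea_phenomenological(1.0, 1.0, k=1.0, g=1.0, A0=A0))
            p = TropicParams(beta=8.0, gamma=1.0, nu=0.0, A0=A0)
            tips.append(steady_state("AC", p, s_grid).tip_angle())
        assert np.ptp(baselines) > 0.5  # baseline varies with initial tilt
        assert np.max(np.abs(tips)) < 1e-3  # set-point model does not
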
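import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phytoquant import io as pio
from phytoquant.synthetic import gen_calibration, gen_precision, gen_recovery
from phytoquant.validation import (
    cochran_c,
    detection_limits_empirical,
    detection_limits_from_calibration,
    fit_calibration,
    horwitz_limits,
    mandel_test,
    precision_summary,
    recovery_stats,
    rsd_r_from_rsd_R,
)


def _exact_line(slope=2.0, intercept=1.0, levels=(1, 2, 4, 8, 16)):
    x = np.array(levels, float)
    return pd.DataFrame({"conc": x, "area": intercept + slope * x})


class TestCalibration:
    def test_exact_line_recovered(self):
        fit = fit_calibration(_exact_line())
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.intercept_ci[0] == pytest.approx(fit.intercept_ci[1])

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration(_exact_line(levels=(1, 2, 3)))
        with pytest.raises(ValueError):
            fit_calibration(pd.DataFrame({"conc": [1.0] * 6, "area": range(6)}))

    def test_intercept_ci_coverage_under_true_zero_intercept(self):
        covered = sum(
            fit_calibration(
                gen_calibration(67.6, 0.0, 5.0, seed=s)
            ).intercept_includes_zero
            for s in range(200)
        )
        assert 0.90 <= covered / 200 <= 0.99

    def test_slope_detected_as_nonzero(self):
        fit = fit_calibration(gen_calibration(67.6, 0.0, 5.0, seed=1))
        assert fit.slope_p < 0.05

    def test_per_level_rsd_reported_with_replicates(self):
        fit = fit_calibration(gen_calibration(67.6, 0.0, 1.0, seed=2))
        assert fit.level_rsd is not None
        assert (fit.level_rsd < 5.0).all()  # homoscedasticity screen


class TestMandel:
    def test_pure_quadratic_detected(self):
        x = np.arange(1.0, 7.0)
        res = mandel_test(pd.DataFrame({"conc": x, "area": x ** 2}))
        assert res.decision == "quadratic"
        assert res.f_statistic == np.inf  # second-order fit is exact

    def test_exactly_linear_data(self):
        res = mandel_test(_exact_line(levels=(1, 2, 4, 8, 16, 32)))
        assert res.decision == "linear"
        assert res.f_statistic == 0.0

    def test_type_one_error_rate_near_alpha(self):
        hits = sum(
            mandel_test(gen_calibration(10.0, 1.0, 2.0, seed=s), alpha=0.01).decision
            == "quadratic"
            for s in range(300)
        )
        # binomial 99% band around 1% of 300
        assert hits <= 9

    def test_affine_rescaling_of_response_preserves_decision(self):
        df = gen_calibration(10.0, 1.0, 2.0, seed=9)
        r0 = mandel_test(df)
        df2 = df.assign(area=3.0 * df["area"] + 100.0)
        r1 = mandel_test(df2)
        assert r0.decision == r1.decision
        assert r1.f_statistic == pytest.approx(r0.f_statistic, rel=1e-9)


class TestCochran:
    @pytest.mark.parametrize(
        "variances,expected", [((1, 1, 1, 1), 0.25), ((3, 1, 1, 1), 0.5)]
    )
    def test_statistic_values(self, variances, expected):
        res = cochran_c(variances, n_per_group=6)
        assert res.c_statistic == pytest.approx(expected)

    def test_all_zero_variances_homogeneous(self):
        res = cochran_c((0.0, 0.0, 0.0), n_per_group=5)
        assert res.homogeneous

    def test_rejection_rate_under_equal_variances(self):
        rng = np.random.default_rng(21)
        rejects = 0
        n_sims = 400
        for _ in range(n_sims):
            groups = rng.normal(0.0, 1.0, size=(6, 6))
            res = cochran_c(groups.var(axis=1, ddof=1), n_per_group=6)
            rejects += not res.homogeneous
        rate = rejects / n_sims
        assert 0.02 <= rate <= 0.08


class TestPrecision:
    def test_identical_determinations(self):
        df = gen_precision({"100": 10.0}, sigma_r=0.0, sigma_day=0.0, seed=0)
        res = precision_summary(df)
        assert res.rsd_r == 0.0
        assert res.rsd_R == 0.0

    def test_within_cell_variation_only(self):
        df = pd.DataFrame(
            {"day": [1, 1, 2, 2], "level": ["L"] * 4, "replicate": [1, 2, 1, 2],
             "determination": [9.0, 11.0, 9.0, 11.0]}
        )
        res = precision_summary(df)
        assert res.rsd_r == pytest.approx(14.14, abs=0.01)
        assert res.s_between2 == 0.0
        assert res.rsd_R == pytest.approx(res.rsd_r)

    def test_between_day_variation_only(self):
        df = pd.DataFrame(
            {"day": [1, 1, 2, 2], "level": ["L"] * 4, "replicate": [1, 2, 1, 2],
             "determination": [9.0, 9.0, 11.0, 11.0]}
        )
        res = precision_summary(df)
        assert res.rsd_r == 0.0
        assert res.s_between2 == pytest.approx(2.0)
        assert res.rsd_R == pytest.approx(14.14, abs=0.01)

    def test_intermediate_at_least_repeatability(self):
        for s in range(20):
            df = gen_precision(
                {"50": 10.0, "100": 20.0, "150": 30.0}, 0.3, 0.2, seed=s
            )
            res = precision_summary(df)
            assert res.rsd_R >= res.rsd_r >= 0.0

    def test_single_replicate_cell_rejected(self):
        df = pd.DataFrame(
            {"day": [1, 2], "level": ["L", "L"], "replicate": [1, 1],
             "determination": [9.0, 11.0]}
        )
        with pytest.raises(ValueError):
            precision_summary(df)

    def test_variance_component_recovery(self):
        # sigma_r/mean = 1%, no day component -> RSD_r ~ 1% within the
        # chi-square sampling band for the pooled dof
        df = gen_precision(
            {"50": 100.0, "100": 100.0, "150": 100.0}, sigma_r=1.0,
            sigma_day=0.0, seed=123,
        )
        res = precision_summary(df)
        dof = 12 * 5  # 4 days x 3 levels, 6 replicates per cell
        lo = np.sqrt(stats.chi2.ppf(0.005, dof) / dof)
        hi = np.sqrt(stats.chi2.ppf(0.995, dof) / dof)
        assert lo <= res.rsd_r <= hi


class TestHorwitz:
    def test_closed_forms(self):
        h = horwitz_limits(1.0)
        assert h.rsd_R_max == pytest.approx(2.0)
        assert h.rsd_r_max == pytest.approx(4.0 / 3.0)
        assert horwitz_limits(1e-3).rsd_R_max == pytest.approx(2 ** 2.5)

    def test_two_thirds_relation_everywhere(self):
        for c in 10.0 ** np.arange(-8, 0):
            h = horwitz_limits(c)
            assert h.rsd_r_max == pytest.approx(h.rsd_R_max * 2 / 3)

    def test_limits_decrease_with_mass_fraction(self):
        values = [horwitz_limits(c).rsd_R_max for c in (1e-6, 1e-4, 1e-2, 1.0)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_published_precision_rows_are_internally_consistent(self):
        table = pio.load_precision_table()
        for analyte in table.index:
            row = table.loc[analyte]
            # 0.01 absorbs the table's own rounding (2.9133 prints as 2.92)
            assert rsd_r_from_rsd_R(row["horwitz_rsd_R"]) == pytest.approx(
                row["horwitz_rsd_r"], abs=0.01
            )

    def test_invalid_mass_fraction(self):
        with pytest.raises(ValueError):
            horwitz_limits(0.0)


class TestRecovery:
    def test_published_level_means_reproduce_headline_means(self):
        table = pio.load_recovery_table()
        for analyte in table.index:
            row = table.loc[analyte]
            res = recovery_stats(
                pd.DataFrame(
                    {"level": [75, 100, 125],
                     "recovery_pct": [row["level_75"], row["level_100"],
                                      row["level_125"]]}
                )
            )
            assert res.mean_recovery == pytest.approx(row["printed_mean"], abs=0.005)

    def test_perfect_recovery_passes_all_criteria(self):
        res = recovery_stats(
            gen_recovery(100.0, 0.0, seed=0), rsd_r_reference=2.0
        )
        assert res.mean_recovery == pytest.approx(100.0)
        assert res.rsd_pct == pytest.approx(0.0)
        assert res.ci_contains_100 and res.mean_in_98_102
        assert res.rsd_within_reference

    def test_small_noise_passes_in_most_seeds(self):
        passing = sum(
            (r := recovery_stats(gen_recovery(100.0, 0.5, seed=s))).ci_contains_100
            and r.mean_in_98_102
            for s in range(100)
        )
        assert passing >= 85


class TestDetectionLimits:
    def test_calibration_formula(self):
        fit = fit_calibration(_exact_line(slope=10.0, intercept=0.0))
        res = detection_limits_from_calibration(fit, sigma=1.0)
        assert res.lod == pytest.approx(0.33)
        assert res.loq == pytest.approx(1.0)
        assert res.loq > res.lod > 0

    def test_negative_slope_rejected(self):
        fit = fit_calibration(_exact_line(slope=-2.0))
        with pytest.raises(ValueError):
            detection_limits_from_calibration(fit)

    def test_empirical_thresholds(self):
        series = pd.DataFrame(
            {"conc": [0.1, 0.2, 0.4, 0.8],
             "sn": [1.0, 3.5, 9.0, 20.0],
             "rsd_pct": [12.0, 8.0, 4.0, 2.0]}
        )
        res = detection_limits_empirical(series)
        assert res.lod == pytest.approx(0.2)
        assert res.loq == pytest.approx(0.4)

    def test_estimated_sigma_tracks_truth(self):
        # sigma_hat(intercept) over seeds should centre near the value
        # implied by the noise level, so LoD ~ 3.3*sigma_eff/slope
        lods = [
            detection_limits_from_calibration(
                fit_calibration(gen_calibration(10.0, 0.0, 1.0, seed=s))
            ).lod
            for s in range(200)
        ]
        # analytic se of the intercept for the default level layout
        df = gen_calibration(10.0, 0.0, 0.0, seed=0)
        x = df["conc"].to_numpy()
        se = np.sqrt(1.0 / len(x) + x.mean() ** 2 / ((x - x.mean()) ** 2).sum())
        assert np.mean(lods) == pytest.approx(3.3 * se / 10.0, rel=0.10)
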
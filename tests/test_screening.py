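import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phytoquant.design import build_fractional_factorial
from phytoquant.screening import (
    EffectTable,
    classify_effects,
    dong_critical,
    estimate_effects,
    screen,
)
from phytoquant.synthetic import gen_screening_study

INTERACTIONS = ["A*B", "A*C", "A*D", "A*E", "A*F", "A*G", "B*D"]


def _effect_table(printed_effects, response):
    return EffectTable(
        list(printed_effects.index), printed_effects[response].to_numpy(), response
    )


class TestEstimateEffects:
    def test_exact_two_factor_plane(self):
        # y = 4 + A + 2B on the full 2x2 -> effects are 2 and 4 exactly
        d = build_fractional_factorial(2, 0)
        d.add_response("y", np.array([1.0, 3.0, 5.0, 7.0]))
        eff = estimate_effects(d, "y")
        assert eff.to_series()["A"] == pytest.approx(2.0)
        assert eff.to_series()["B"] == pytest.approx(4.0)

    def test_constant_response_gives_zero_effects(self):
        d = build_fractional_factorial(7, 3, n_center_replicates=2)
        d.add_response("y", np.full(d.n_runs, 42.0))
        eff = estimate_effects(d, "y", contrasts=list("ABCDEFG") + INTERACTIONS)
        assert np.allclose(eff.effects, 0.0)

    def test_center_points_are_excluded_from_contrasts(self):
        d1 = gen_screening_study({"D": 150.0}, 0.0, seed=1, n_center_replicates=0)
        d2 = gen_screening_study({"D": 150.0}, 0.0, seed=1, n_center_replicates=4)
        e1 = estimate_effects(d1, "y").to_series()
        e2 = estimate_effects(d2, "y").to_series()
        assert e1.equals(e2)

    def test_aliased_contrast_pair_is_rejected(self):
        # with E = ABC, requesting both E and A*B*C asks for the same column
        d = build_fractional_factorial(7, 3)
        d.add_response("y", np.arange(16.0))
        with pytest.raises(ValueError, match="aliased"):
            estimate_effects(d, "y", contrasts=["E", "A*B*C"])

    def test_noisy_recovery_of_true_effects(self):
        # mean estimate over seeds approaches truth; sd of an effect is
        # 2*noise/sqrt(n) = 2*5/4 = 2.5 here
        est = [
            estimate_effects(
                gen_screening_study({"D": 150.0, "A": -93.0}, 5.0, seed=s), "y"
            ).to_series()["D"]
            for s in range(30)
        ]
        assert abs(np.mean(est) - 150.0) < 3 * 2.5 / np.sqrt(30)


class TestDongCritical:
    @pytest.mark.parametrize(
        "response,printed", [("CA", 10.97), ("FL", 0.47)]
    )
    def test_lowest75_reproduces_printed_thresholds(
        self, printed_effects, response, printed
    ):
        d = dong_critical(_effect_table(printed_effects, response), variant="lowest75")
        assert d.critical_effect == pytest.approx(printed, abs=0.01)
        assert len(d.retained_effects) == 10

    def test_classic_trimming_reproduces_tf_threshold(self, printed_effects):
        # the third printed threshold follows the 2.5*s0 trimming rule
        d = dong_critical(_effect_table(printed_effects, "TF"), variant="dong_classic")
        assert d.critical_effect == pytest.approx(84.54, abs=0.05)
        assert len(d.retained_effects) == 13

    def test_identical_effect_magnitudes(self):
        from scipy import stats

        et = EffectTable(list("ABCDEF"), np.full(6, 3.0))
        d = dong_critical(et, alpha=0.05, variant="lowest75")
        assert d.se_effect == pytest.approx(3.0)
        assert d.critical_effect == pytest.approx(stats.t.ppf(0.95, 6) * 3.0)

    def test_all_zero_effects_degenerate(self):
        et = EffectTable(list("ABCD"), np.zeros(4))
        with pytest.warns(UserWarning, match="degenerate"):
            d = dong_critical(et)
        assert d.critical_effect == 0.0

    def test_too_few_effects_rejected(self):
        with pytest.raises(ValueError):
            dong_critical(EffectTable(["A", "B"], np.array([1.0, 2.0])))

    @settings(max_examples=30, derandomize=True)
    @given(scale=st.floats(0.01, 1e4), variant=st.sampled_from(
        ["lowest75", "dong_classic"]))
    def test_threshold_scales_linearly_with_effects(
        self, printed_effects, scale, variant
    ):
        base = _effect_table(printed_effects, "CA")
        scaled = EffectTable(base.effect_names, base.effects * scale)
        d0 = dong_critical(base, variant=variant)
        d1 = dong_critical(scaled, variant=variant)
        assert d1.critical_effect == pytest.approx(
            d0.critical_effect * scale, rel=1e-9
        )
        assert d1.retained_effects == d0.retained_effects

    def test_false_positive_rate_on_pure_noise(self):
        # the threshold is one-sided but applied to |E|, so a two-sided
        # test at level alpha uses the 1 - alpha/2 quantile; pure noise
        # should then flag at most ~alpha*m effects on average
        rng = np.random.default_rng(11)
        flagged = []
        for _ in range(200):
            et = EffectTable([f"e{i}" for i in range(14)], rng.normal(0, 1, 14))
            rep = classify_effects(
                et, dong_critical(et, alpha=0.025, variant="dong_classic")
            )
            flagged.append(len(rep.significant))
        assert np.mean(flagged) <= 0.05 * 14 + 0.15


class TestClassification:
    def test_printed_significance_pattern(self, printed_effects):
        ca = _effect_table(printed_effects, "CA")
        rep = classify_effects(ca, dong_critical(ca, variant="lowest75"))
        assert set(rep.significant) == {"A", "C", "D", "E", "G"}
        tf = _effect_table(printed_effects, "TF")
        rep = classify_effects(tf, dong_critical(tf, variant="dong_classic"))
        assert set(rep.significant) == {"A", "D"}

    def test_report_sorted_by_magnitude(self, printed_effects):
        et = _effect_table(printed_effects, "TF")
        rep = classify_effects(et, dong_critical(et))
        mags = rep.table["abs_estimate"].to_numpy()
        assert np.all(np.diff(mags) <= 0)

    def test_zero_effect_never_significant(self):
        et = EffectTable(list("ABCD"), np.array([0.0, 5.0, 6.0, 7.0]))
        rep = classify_effects(et, dong_critical(et))
        assert "A" not in rep.significant

    def test_screen_convenience_recovers_planted_effects(self):
        d = gen_screening_study({"D": 149.0, "A": -93.0}, 20.0, seed=3)
        hits = sum(
            {"A", "D"}
            <= set(
                screen(
                    gen_screening_study({"D": 149.0, "A": -93.0}, 20.0, seed=s),
                    "y",
                    contrasts=list("ABCDEFG") + INTERACTIONS,
                    variant="dong_classic",
                ).significant
            )
            for s in range(40)
        )
        assert hits >= 36  # >= 90% of seeds
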
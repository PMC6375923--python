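import numpy as np
import pandas as pd
import pytest

from phytoquant.quantification import (
    BELOW_LOQ,
    QUANTIFIED,
    AnalyteSpec,
    SamplePrep,
    aggregate_totals,
    concentration_from_area,
    fixture_composition_matrix,
    quantify_peak_table,
    rollup_categories,
    to_mass_fraction,
)
from phytoquant.synthetic import DEFAULT_PREP, DEFAULT_STANDARD_AREAS, gen_peak_tables
from phytoquant.validation import CalibrationFit, DetectionLimits

CA_SPEC = AnalyteSpec(1, "Chlorogenic acid", "phenolic_acid", "CA", "CA", 340)


class TestConcentration:
    def test_area_equal_to_standard_gives_reference_concentration(self):
        conc = concentration_from_area(1360.0, CA_SPEC, standard_area=1360.0)
        assert conc == pytest.approx(20.12)

    def test_proportionality(self):
        half = concentration_from_area(680.0, CA_SPEC, standard_area=1360.0)
        assert half == pytest.approx(20.12 / 2)

    def test_curve_mode_inverts_calibration(self):
        fit = CalibrationFit(
            slope=2.0, intercept=0.0, r_squared=1.0, intercept_se=0.0,
            slope_se=0.0, intercept_ci=(0, 0), slope_ci=(2, 2),
            intercept_p=1.0, slope_p=0.0, n_points=5,
        )
        assert concentration_from_area(10.0, CA_SPEC, mode="curve", curve=fit) == 5.0

    def test_negative_backcalculation_floored(self):
        fit = CalibrationFit(
            slope=2.0, intercept=10.0, r_squared=1.0, intercept_se=0.0,
            slope_se=0.0, intercept_ci=(10, 10), slope_ci=(2, 2),
            intercept_p=0.0, slope_p=0.0, n_points=5,
        )
        with pytest.warns(UserWarning, match="floored"):
            conc = concentration_from_area(4.0, CA_SPEC, mode="curve", curve=fit)
        assert conc == 0.0


class TestMassFraction:
    def test_worked_conversion(self):
        prep = SamplePrep(sample_mass_g=0.5, final_volume_ml=50.0, dilution_factor=2.0)
        assert to_mass_fraction(10.06, prep) == pytest.approx(2012.0)

    def test_identity_prep(self):
        prep = SamplePrep(1.0, 1.0, 1.0)
        assert to_mass_fraction(7.7, prep) == pytest.approx(7.7)

    def test_linearity_in_dilution(self):
        p1 = SamplePrep(0.5, 50.0, 1.0)
        p2 = SamplePrep(0.5, 50.0, 2.0)
        assert to_mass_fraction(3.0, p2) == pytest.approx(2 * to_mass_fraction(3.0, p1))

    def test_invalid_prep_rejected(self):
        with pytest.raises(ValueError):
            SamplePrep(0.0, 50.0, 2.0)


class TestTotals:
    @pytest.mark.parametrize(
        "sample_id,column,printed",
        [("CH-1", "TF", 14899.2), ("CO-1", "TF", 3890.4),
         ("CO-6", "FL_total", 2367.3)],
    )
    def test_fixture_totals_match_printed_values(
        self, composition, sample_id, column, printed
    ):
        samples, specs = composition
        totals = aggregate_totals(samples[sample_id], specs)
        assert totals[column] == pytest.approx(printed, abs=0.051)

    def test_all_censored_total_is_censored(self, composition):
        samples, specs = composition
        totals = aggregate_totals(samples["CP-1"], specs)  # flavonolignans all <LOQ
        assert np.isnan(totals["FL_total"])

    def test_censored_compounds_never_contribute(self, composition):
        samples, specs = composition
        s = samples["CO-1"]
        is_flavonoid = pd.Series(
            [specs[i].cls == "flavonoid" for i in s.values.index],
            index=s.values.index,
        )
        quantified_sum = s.values.loc[
            (s.values["status"] == QUANTIFIED) & is_flavonoid, "mean"
        ].sum()
        assert aggregate_totals(s, specs)["TF"] == pytest.approx(quantified_sum)


class TestCategories:
    def test_quercetin_category_sums_member_rows(self, composition):
        samples, specs = composition
        m = rollup_categories(list(samples.values()), specs)
        ch1 = samples["CH-1"].values
        qg_ids = [i for i in ch1.index if specs[i].category == "QG"]
        expected = ch1.loc[qg_ids].query("status == @QUANTIFIED")["mean"].sum()
        assert m.loc["CH-1", "QG"] == pytest.approx(expected)
        assert len(ch1.loc[qg_ids].query("status == @QUANTIFIED")) == 7

    def test_single_compound_sample(self):
        from phytoquant.quantification import QuantifiedSample

        vals = pd.DataFrame(
            {"mean": [100.0], "sd": [1.0], "status": [QUANTIFIED]},
            index=pd.Index([1], name="compound_id"),
        )
        m = rollup_categories([QuantifiedSample("S", vals)], {1: CA_SPEC})
        assert m.loc["S", "CA"] == 100.0
        assert m.loc["S"].drop("CA").sum() == 0.0

    def test_unmapped_compound_raises(self):
        from phytoquant.quantification import QuantifiedSample

        vals = pd.DataFrame(
            {"mean": [1.0], "sd": [0.0], "status": [QUANTIFIED]},
            index=pd.Index([99], name="compound_id"),
        )
        with pytest.raises(KeyError, match="99"):
            rollup_categories([QuantifiedSample("S", vals)], {1: CA_SPEC})

    def test_column_totals_conserved_under_sample_split(self, composition):
        samples, specs = composition
        m = rollup_categories([samples["CO-1"], samples["CO-2"]], specs)
        merged = m.sum(axis=0)
        # splitting the same mass across two samples leaves column sums equal
        assert merged["CA"] == pytest.approx(
            m.loc["CO-1", "CA"] + m.loc["CO-2", "CA"]
        )


class TestRoundTrip:
    def test_zero_noise_round_trip_reproduces_fixture(self, composition):
        samples, specs = composition
        peaks, specs2, std_areas, prep = gen_peak_tables(area_noise_cv=0.0, seed=0)
        quantified = {
            s.sample_id: s
            for s in quantify_peak_table(peaks, specs2, std_areas, prep)
        }
        for sid, ref in samples.items():
            got = quantified[sid].values
            ref_q = ref.values[ref.values["status"] == QUANTIFIED]
            assert set(got.index) == set(ref_q.index)
            assert np.allclose(
                got.loc[ref_q.index, "mean"], ref_q["mean"], rtol=1e-9
            )

    def test_small_noise_round_trip_close(self):
        peaks, specs, std_areas, prep = gen_peak_tables(area_noise_cv=0.01, seed=4)
        quantified = quantify_peak_table(peaks, specs, std_areas, prep)
        ref = fixture_composition_matrix()
        got = rollup_categories(quantified, specs)
        rel = (got - ref).abs() / ref.where(ref > 0)
        assert np.nanmax(rel.to_numpy()) < 0.03

    def test_determinism(self):
        a, *_ = gen_peak_tables(area_noise_cv=0.02, seed=9)
        b, *_ = gen_peak_tables(area_noise_cv=0.02, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_censoring_applied_from_limits(self):
        peaks = pd.DataFrame(
            {"sample_id": ["S"] * 2, "compound_id": [1, 1],
             "replicate": [1, 2], "area": [1.0, 1.0]}
        )
        limits = {1: DetectionLimits(lod=10.0, loq=100.0, method="calibration")}
        out = quantify_peak_table(
            peaks, {1: CA_SPEC}, {"CA": 1360.0}, DEFAULT_PREP, limits=limits
        )
        assert out[0].values.loc[1, "status"] == "<LOD"
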
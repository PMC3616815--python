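"""Standard-curve fitting, efficiency, method selection, expression calls,
normalization, replicate summaries, reference stability and ANOVA."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from isoprime.qpcr import (anova, call_expressed, efficiency_from_slope,
                           fit_standard_curve, normalize,
                           quantify_experiment, quantity_from_ct,
                           reference_stability, relative_efficiency_slope,
                           slope_from_efficiency, summarize)
from isoprime.simulate import QpcrSimSpec, simulate_qpcr
from isoprime.records import read_ct_table


class TestStandardCurve:
    def test_perfect_doubling_chemistry_closed_form(self):
        """Ct spacing of log2(10) per 1:10 dilution means E = 1 exactly."""
        q = [1.0, 0.1, 0.01]
        cts = [20.0, 20.0 + np.log2(10), 20.0 + 2 * np.log2(10)]
        curve = fit_standard_curve(q, cts)
        assert curve.slope == pytest.approx(-3.3219, abs=1e-4)
        assert curve.efficiency == pytest.approx(1.0, abs=1e-4)
        assert curve.r2 == pytest.approx(1.0, abs=1e-4)

    def test_slope_minus_3_5_gives_e_0_9307(self):
        assert efficiency_from_slope(-3.5) == pytest.approx(0.9307, abs=1e-4)

    def test_censored_standard_is_an_error(self):
        with pytest.raises(ValueError, match="censored"):
            fit_standard_curve([1, 0.1, 0.01], [20.0, np.nan, 27.0])

    def test_fewer_than_three_levels_is_an_error(self):
        with pytest.raises(ValueError, match="3 distinct"):
            fit_standard_curve([1, 1, 0.1], [20, 20.1, 23.4])

    def test_positive_slope_flags_invalid(self):
        with pytest.warns(UserWarning, match="invalid"):
            curve = fit_standard_curve([1, 0.1, 0.01], [20.0, 18.0, 16.0])
        assert not curve.valid
        assert np.isnan(curve.efficiency)

    def test_noisy_curves_recover_efficiency(self):
        """6 x 1:10 dilutions in duplicate, 0.2-Ct noise: E back within
        +/- 0.05 of truth."""
        rng = np.random.default_rng(77)
        e_true = 0.92
        slope = slope_from_efficiency(e_true)
        q = np.repeat(10.0 ** -np.arange(6), 2)
        for _ in range(10):
            cts = 20.0 + slope * np.log10(q) + rng.normal(0, 0.2, len(q))
            curve = fit_standard_curve(q, cts)
            assert curve.efficiency == pytest.approx(e_true, abs=0.05)

    @given(st.floats(0.51, 1.09))
    @settings(max_examples=60, deadline=None)
    def test_efficiency_and_slope_are_mutual_inverses(self, e):
        assert efficiency_from_slope(slope_from_efficiency(e)) == \
            pytest.approx(e, rel=1e-12)


class TestMethodSelection:
    def test_equal_efficiencies_slope_zero(self):
        x = np.log10([1, 0.1, 0.01, 0.001])
        ct_ref = 20 - 3.32 * x
        slope, rec = relative_efficiency_slope(x, ct_ref + 5.0, ct_ref)
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert rec == "comparative ddCt permissible"

    def test_rule_boundary_at_plus_minus_0_1(self):
        x = np.array([0.0, -1.0, -2.0])
        d_in = -0.079 * x
        d_out = -0.206 * x
        _, rec_in = relative_efficiency_slope(x, d_in, np.zeros(3))
        _, rec_out = relative_efficiency_slope(x, d_out, np.zeros(3))
        assert rec_in == "comparative ddCt permissible"
        assert rec_out == "standard-curve method required"


class TestQuantityAndNormalization:
    def test_ct_at_intercept_is_unit_quantity(self):
        curve = fit_standard_curve([1, 0.1, 0.01], [20.0, 23.4, 26.8])
        assert quantity_from_ct(20.0, curve) == pytest.approx(
            10 ** ((20.0 - curve.intercept) / curve.slope))

    def test_quantity_ct_round_trip(self):
        curve = fit_standard_curve([1, 0.1, 0.01], [20.0, 23.4, 26.8])
        for q in [1.0, 0.05, 3.7]:
            ct = curve.intercept + curve.slope * np.log10(q)
            assert quantity_from_ct(ct, curve) == pytest.approx(q, rel=1e-10)

    def test_censored_ct_propagates(self):
        curve = fit_standard_curve([1, 0.1, 0.01], [20.0, 23.4, 26.8])
        assert np.isnan(quantity_from_ct(float("nan"), curve))

    def test_au_invariant_under_common_rescaling(self):
        assert normalize(4.0, 2.0) == normalize(4.0 * 7.3, 2.0 * 7.3)

    def test_nonpositive_reference_is_an_error(self):
        with pytest.raises(ValueError):
            normalize(1.0, 0.0)


class TestExpressionCall:
    def test_all_censored_not_expressed(self):
        assert not call_expressed([[np.nan] * 3, [np.nan] * 3])

    def test_clean_triplicate_with_censored_ntc_expressed(self):
        assert call_expressed([[24.0, 24.0, 24.0]], ntc_cts=[np.nan, np.nan])

    def test_late_ct_near_ntc_fails_3cycle_guard(self):
        assert not call_expressed([[38.0, 38.0, 38.0]], ntc_cts=[39.0])

    def test_one_clean_biological_replicate_suffices(self):
        assert call_expressed([[np.nan, 30.0, 30.0], [30.0, 30.0, 30.0]],
                              ntc_cts=[np.nan])


class TestReferenceStability:
    def make(self, cts):
        rows = []
        for (tissue, cultivar), vals in cts.items():
            for v in vals:
                rows.append(dict(tissue=tissue, cultivar=cultivar, ct=v))
        return pd.DataFrame(rows)

    def test_constant_candidate_ranks_first(self):
        flat = self.make({("peel", "A"): [20, 20], ("flesh", "A"): [20, 20]})
        noisy = self.make({("peel", "A"): [18, 18], ("flesh", "A"): [24, 24]})
        ranking = reference_stability({"actin": flat, "gapdh": noisy})
        assert ranking[0] == ("actin", 0.0)
        assert ranking[1][0] == "gapdh"

    def test_engineered_sd_ordering(self):
        a = self.make({("peel", "A"): [20.0], ("flesh", "A"): [20.2],
                       ("peel", "B"): [20.1], ("flesh", "B"): [20.3]})
        b = self.make({("peel", "A"): [19.0], ("flesh", "A"): [21.0],
                       ("peel", "B"): [20.0], ("flesh", "B"): [22.0]})
        ranking = reference_stability({"ubc": b, "actin": a})
        assert [name for name, _ in ranking] == ["actin", "ubc"]
        assert ranking[0][1] < ranking[1][1]

    def test_ranking_invariant_under_row_order(self):
        df = self.make({("peel", "A"): [20.0, 21.0], ("flesh", "B"): [22.0]})
        shuffled = df.sample(frac=1, random_state=1)
        r1 = reference_stability({"x": df})
        r2 = reference_stability({"x": shuffled})
        assert r1 == r2


class TestSummariesAndAnova:
    def test_identical_replicates_have_zero_sem(self):
        mean, sem = summarize([3.2, 3.2, 3.2])
        assert mean == pytest.approx(3.2)
        assert sem == pytest.approx(0.0, abs=1e-12)

    def test_sem_formula(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        mean, sem = summarize(vals)
        assert mean == 2.5
        assert sem == pytest.approx(np.std(vals, ddof=1) / 2)

    def test_balanced_two_by_two_matches_textbook_f(self):
        """2x2 balanced design, hand-computed sums of squares."""
        df = pd.DataFrame({
            "gene": ["g1", "g1", "g1", "g1", "g2", "g2", "g2", "g2"],
            "tissue": ["p", "p", "f", "f", "p", "p", "f", "f"],
            "au": [10.0, 12.0, 6.0, 8.0, 5.0, 7.0, 1.0, 3.0]})
        table = anova(df, response="au", factors=("gene", "tissue"))
        # hand computation: SS_gene = 8*(9-5.25... see below)
        grand = df.au.mean()                      # 6.5
        ss_gene = sum(4 * (df[df.gene == g].au.mean() - grand) ** 2
                      for g in ("g1", "g2"))      # 50
        ss_tissue = sum(4 * (df[df.tissue == t].au.mean() - grand) ** 2
                        for t in ("p", "f"))      # 32
        ss_resid = table.loc["Residual", "sum_sq"]
        ms_resid = ss_resid / 5
        assert table.loc["C(gene)", "sum_sq"] == pytest.approx(ss_gene)
        assert table.loc["C(tissue)", "sum_sq"] == pytest.approx(ss_tissue)
        assert table.loc["C(gene)", "F"] == pytest.approx(ss_gene / ms_resid)


class TestPipeline:
    def qspec(self, ratio=4.0, noise=0.15, e_target=0.90, e_ref=1.0, seed=0):
        return QpcrSimSpec(
            efficiency={"target": e_target, "actin": e_ref},
            sample_quantities={
                "b1": {"target": 0.04 * ratio, "actin": 0.04},
                "b2": {"target": 0.04 * ratio, "actin": 0.04}},
            sample_meta={"b1": ("peel", "cv"), "b2": ("peel", "cv")},
            noise_sd=noise, seed=seed)

    def test_noiseless_pipeline_recovers_quantities_exactly(self):
        table = simulate_qpcr(self.qspec(ratio=4.0, noise=0.0))
        results, curves = quantify_experiment(table, "actin")
        (res,) = results
        assert curves["target"].efficiency == pytest.approx(0.90, abs=1e-9)
        assert res.au_mean == pytest.approx(4.0, rel=1e-9)
        assert res.au_sem == pytest.approx(0.0, abs=1e-9)

    def test_standard_curve_equals_ddct_at_equal_100pct_efficiency(self):
        """With both assays at E = 1 and no noise, the standard-curve
        result equals the textbook ddCt computation exactly."""
        table = simulate_qpcr(self.qspec(ratio=3.0, noise=0.0,
                                         e_target=1.0, e_ref=1.0))
        results, _ = quantify_experiment(table, "actin")
        df = table.df
        def mean_ct(assay):
            rows = df[(df.assay_id == assay) & (df.sample_id == "b1")]
            return rows.ct.mean()
        dct = mean_ct("target") - mean_ct("actin")
        # ddCt vs the dilution-1.0 standard (Ct difference 0 there)
        assert results[0].au_mean == pytest.approx(2 ** -dct, rel=1e-9)

    def test_known_ratio_recovered_within_10pct_under_noise(self):
        table = simulate_qpcr(self.qspec(ratio=4.0, noise=0.15, seed=5))
        results, _ = quantify_experiment(table, "actin")
        assert results[0].au_mean / 4.0 == pytest.approx(1.0, abs=0.10)

    def test_expression_ratio_converges_with_vanishing_noise(self):
        errs = []
        for noise in (0.4, 0.1, 0.01):
            table = simulate_qpcr(self.qspec(ratio=2.0, noise=noise, seed=3))
            results, _ = quantify_experiment(table, "actin")
            errs.append(abs(results[0].au_mean - 2.0))
        assert errs[2] < errs[0]
        assert errs[2] < 0.01

    def test_csv_round_trip_preserves_quantification(self):
        from isoprime.records import write_ct_table
        table = simulate_qpcr(self.qspec(seed=8))
        buf = io.StringIO()
        write_ct_table(table, buf)
        back = read_ct_table(io.StringIO(buf.getvalue()))
        r1, _ = quantify_experiment(table, "actin")
        r2, _ = quantify_experiment(back, "actin")
        assert r1[0].au_mean == pytest.approx(r2[0].au_mean, rel=1e-9)
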
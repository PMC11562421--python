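"""EF score derivation, outlier filtering, FIML regressions."""

import numpy as np
import pandas as pd
import pytest

from panelnet import (broadband_aggregates, derive_ef_scores,
                      fit_fiml_regression, hierarchical_compare,
                      zscore_outlier_filter)
from panelnet.cohort import CohortSpec, make_ground_truth, simulate_ef, simulate_panel
from panelnet.ef import EfError, filter_ef_table


def make_task_tables(series_by_person, parts_shift, parts_mem):
    dots = pd.DataFrame([
        {"person_id": pid, "series": s, "mean_rt": rt, "pct_errors": pe}
        for pid, series in series_by_person.items()
        for s, (rt, pe) in enumerate(series)
    ])
    def parts_df(parts):
        return pd.DataFrame([
            {"person_id": pid, "part": part, "mean_rt": rt, "pct_errors": pe}
            for pid, d in parts.items() for part, (rt, pe) in d.items()
        ])
    return dots, parts_df(parts_shift), parts_df(parts_mem)


class TestDeriveEfScores:
    def test_five_person_fixture_matches_hand_recomputation(self):
        rng = np.random.default_rng(0)
        series = {pid: [(float(rng.normal(450, 40)), float(rng.uniform(0, 20)))
                        for _ in range(50)] for pid in range(1, 6)}
        shift = {pid: {1: (400.0 + pid, 5.0), 2: (520.0 + 2 * pid, 9.0),
                       3: (560.0, 11.0 + pid)} for pid in range(1, 6)}
        mem = {pid: {1: (350.0, 4.0), 2: (420.0, 6.0),
                     3: (505.0 + pid, 8.5)} for pid in range(1, 6)}
        dots, shifting, memory = make_task_tables(series, shift, mem)
        scores = derive_ef_scores(dots, shifting, memory).set_index("person_id")
        for pid in range(1, 6):
            rts = np.array([rt for rt, _ in series[pid]])
            errs = np.array([pe for _, pe in series[pid]])
            assert scores.loc[pid, "fluct_tempo"] == pytest.approx(
                rts.std(ddof=1))
            assert scores.loc[pid, "fluct_errors"] == pytest.approx(
                errs.mean())
            assert scores.loc[pid, "resinhib_rt"] == pytest.approx(
                520 + 2 * pid - (400 + pid))
            assert scores.loc[pid, "cogflex_err"] == pytest.approx(
                11 + pid - 5.0)
            assert scores.loc[pid, "wm_rt"] == pytest.approx(505 + pid - 350)

    def test_constant_series_zero_fluctuation(self):
        series = {1: [(500.0, 0.0)] * 50}
        parts = {1: {1: (400.0, 5.0), 2: (520.0, 9.0), 3: (560.0, 11.0)}}
        dots, shifting, memory = make_task_tables(series, parts, parts)
        scores = derive_ef_scores(dots, shifting, memory)
        assert scores["fluct_tempo"].iloc[0] == 0.0
        assert scores["resinhib_rt"].iloc[0] == pytest.approx(120.0)

    def test_alternating_series_sample_sd(self):
        # 25 series at 400 ms and 25 at 500 ms: sample SD 50 * sqrt(50/49)
        series = {1: [(400.0, 0.0), (500.0, 0.0)] * 25}
        parts = {1: {1: (1.0, 1.0), 2: (2.0, 2.0), 3: (3.0, 3.0)}}
        dots, shifting, memory = make_task_tables(series, parts, parts)
        scores = derive_ef_scores(dots, shifting, memory)
        assert scores["fluct_tempo"].iloc[0] == pytest.approx(50.51, abs=0.01)

    def test_single_series_rejected(self):
        series = {1: [(500.0, 0.0)]}
        parts = {1: {1: (1.0, 1.0), 2: (2.0, 2.0), 3: (3.0, 3.0)}}
        dots, shifting, memory = make_task_tables(series, parts, parts)
        with pytest.raises(EfError):
            derive_ef_scores(dots, shifting, memory)


class TestOutlierFilter:
    def test_constructed_outlier_removed(self):
        rng = np.random.default_rng(1)
        vals = rng.standard_normal(100)
        vals = (vals - vals.mean()) / vals.std(ddof=1)
        vals = np.append(vals, 6.0)
        out, n_removed = zscore_outlier_filter(vals, threshold=4.0)
        assert n_removed == 1
        assert np.isnan(out[-1])
        assert not np.isnan(out[:-1]).any()

    def test_all_equal_is_noop_with_warning(self):
        with pytest.warns(UserWarning):
            out, n = zscore_outlier_filter(np.ones(10))
        assert n == 0 and not np.isnan(out).any()

    def test_infinite_threshold_is_identity(self):
        vals = np.array([0.0, 1.0, 100.0])
        out, n = zscore_outlier_filter(vals, threshold=np.inf)
        assert n == 0
        np.testing.assert_array_equal(out, vals)

    def test_single_pass_no_reiteration(self):
        # after removing the big outlier the next value would become extreme,
        # but a single pass must leave it in place
        vals = np.concatenate([np.zeros(50), [1.0, 1000.0]])
        out, n = zscore_outlier_filter(vals)
        assert n == 1 and np.isnan(out[-1]) and out[-2] == 1.0

    def test_table_filter(self):
        rng = np.random.default_rng(2)
        ef = pd.DataFrame({c: rng.standard_normal(50)
                           for c in ("fluct_tempo", "wm_rt")})
        ef.loc[0, "wm_rt"] = 50.0
        out = filter_ef_table(ef)
        assert np.isnan(out.loc[0, "wm_rt"])


class TestFimlRegression:
    def test_complete_data_matches_least_squares(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(200)
        y = 0.5 * x + 0.3 + 0.2 * rng.standard_normal(200)
        df = pd.DataFrame({"y": y, "x": x})
        res = fit_fiml_regression(df, "y", ["x"])
        slope = np.cov(x, y, bias=True)[0, 1] / x.var()
        assert res.coefficients["estimate"].iloc[0] == pytest.approx(
            slope, abs=1e-8)
        assert res.intercept == pytest.approx(y.mean() - slope * x.mean(),
                                              abs=1e-8)

    def test_null_r2_small(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"y": rng.standard_normal(2000),
                           "x1": rng.standard_normal(2000),
                           "x2": rng.standard_normal(2000)})
        res = fit_fiml_regression(df, "y", ["x1", "x2"])
        assert res.r2 < 0.01

    def test_mcar_missingness_consistency(self):
        rng = np.random.default_rng(5)
        n = 2000
        x1 = rng.standard_normal(n)
        x2 = 0.5 * x1 + rng.standard_normal(n)
        y = 0.4 * x1 - 0.3 * x2 + rng.standard_normal(n)
        df_full = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        full = fit_fiml_regression(df_full, "y", ["x1", "x2"])
        df_miss = df_full.copy()
        mask = rng.random(df_miss.shape) < 0.3
        df_miss = df_miss.mask(mask)
        miss = fit_fiml_regression(df_miss, "y", ["x1", "x2"])
        np.testing.assert_allclose(miss.coefficients["estimate"],
                                   full.coefficients["estimate"], atol=0.05)

    def test_collinear_predictors_rejected(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(100)
        df = pd.DataFrame({"y": rng.standard_normal(100), "x1": x,
                           "x2": 2 * x})
        with pytest.raises(EfError):
            fit_fiml_regression(df, "y", ["x1", "x2"])

    def test_standardized_betas_affine_invariant(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(300)
        y = 0.3 * x + rng.standard_normal(300)
        d1 = pd.DataFrame({"y": y, "x": x})
        d2 = pd.DataFrame({"y": y, "x": 100 * x + 5})
        b1 = fit_fiml_regression(d1, "y", ["x"])
        b2 = fit_fiml_regression(d2, "y", ["x"])
        assert b1.coefficients["std_estimate"].iloc[0] == pytest.approx(
            b2.coefficients["std_estimate"].iloc[0], abs=1e-8)


@pytest.fixture(scope="module")
def cohort():
    spec = CohortSpec(n_persons=2000, retention=(1, 1, 1), seed=31)
    truth = make_ground_truth(spec, "trails_like")
    panel = simulate_panel(truth, spec)
    ef = simulate_ef(panel, truth, spec)
    return panel, ef


class TestHierarchicalCompare:
    def test_nested_r2_monotone(self, cohort):
        panel, ef = cohort
        symptoms = broadband_aggregates(panel)
        for target in ("internalizing", "externalizing"):
            for wave in (2, 3):
                comp = hierarchical_compare(symptoms, ef, target, wave)
                assert comp.step2.r2 >= comp.step1.r2 - 1e-10
                assert comp.delta_r2 == pytest.approx(
                    comp.step2.r2 - comp.step1.r2)

    def test_null_ef_gives_negligible_increment(self):
        spec = CohortSpec(n_persons=2000, retention=(1, 1, 1), seed=32,
                          ef_betas={})
        truth = make_ground_truth(spec, "trails_like")
        panel = simulate_panel(truth, spec)
        ef = simulate_ef(panel, truth, spec)
        symptoms = broadband_aggregates(panel)
        comp = hierarchical_compare(symptoms, ef, "internalizing", 2)
        assert comp.delta_r2 < 0.01

    def test_step2_coefficients_in_small_effect_regime(self, cohort):
        panel, ef = cohort
        symptoms = broadband_aggregates(panel)
        comp = hierarchical_compare(symptoms, ef, "internalizing", 2)
        ef_terms = comp.step2.coefficients.set_index("term")
        for m in ("fluct_tempo", "wm_rt", "cogflex_rt"):
            assert abs(ef_terms.loc[m, "std_estimate"]) < 0.10

    def test_predictor_order_matches_model_formula(self, cohort):
        panel, ef = cohort
        symptoms = broadband_aggregates(panel)
        comp = hierarchical_compare(symptoms, ef, "externalizing", 3)
        assert comp.step2.terms[:3] == ["sex", "internalizing_w2",
                                        "externalizing_w2"]
        assert comp.step2.terms[3:] == ["wm_rt", "wm_err", "resinhib_err",
                                        "resinhib_rt", "fluct_tempo",
                                        "fluct_errors", "cogflex_rt",
                                        "cogflex_err"]

    def test_missing_ef_measure_rejected(self, cohort):
        panel, ef = cohort
        symptoms = broadband_aggregates(panel)
        with pytest.raises(EfError):
            hierarchical_compare(symptoms, ef.drop(columns=["wm_rt"]),
                                 "internalizing", 2)
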
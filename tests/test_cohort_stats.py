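"""Cohort statistics: pooling, dichotomization, Spearman, IPW, models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vesselphen.cohort_stats import (
    StatsConfig,
    aggregate_case_metrics,
    backward_eliminate,
    dichotomize,
    estimate_ipw_weights,
    fit_weighted_logistic,
    handle_missing,
    make_model_terms,
    multiplicity_flag,
    run_full_analysis,
    spearman_trend,
)
from vesselphen.phenotyping import CoreRecord, VesselObject
from vesselphen.preprocess import MARKERS
from vesselphen.simulate import CohortSimConfig, generate_cohort


def _core(case_id, n_vessels, area, core_id="c"):
    vessels = [
        VesselObject(
            vessel_id=i, core_id=core_id, rows=np.array([i]), cols=np.array([0]),
            centroid_um=(0, 0), area_px=1,
            marker_flags={m: False for m in MARKERS}, class_label="micro",
        )
        for i in range(n_vessels)
    ]
    return CoreRecord(core_id, case_id, area, 0.0, area, vessels)


class TestAggregate:
    def test_single_core_equals_per_core_density(self):
        table, dropped = aggregate_case_metrics({"a": [_core("a", 32, 0.64)]})
        assert table.loc[0, "density_overall"] == pytest.approx(50.0)
        assert not dropped

    def test_pooling_is_count_over_area(self):
        cores = [_core("a", 10, 0.3, "c1"), _core("a", 20, 0.3, "c2")]
        table, _ = aggregate_case_metrics({"a": cores})
        assert table.loc[0, "density_overall"] == pytest.approx(50.0)

    def test_permutation_invariant(self):
        cores = [_core("a", 10, 0.3, "c1"), _core("a", 20, 0.5, "c2")]
        t1, _ = aggregate_case_metrics({"a": cores})
        t2, _ = aggregate_case_metrics({"a": cores[::-1]})
        pd.testing.assert_frame_equal(t1, t2)

    def test_all_cores_failing_qc_drops_case(self):
        bad = _core("a", 5, 0.3)
        bad.qc_passed = False
        table, dropped = aggregate_case_metrics({"a": [bad]})
        assert dropped == ["a"]
        assert len(table) == 0


class TestDichotomize:
    def test_median_rule_strictly_above(self):
        high, cut = dichotomize(pd.Series([1.0, 2.0, 3.0, 4.0]))
        assert cut == 2.5
        assert list(high) == [0, 0, 1, 1]

    def test_lamb1_nonzero_median_rule(self):
        high, cut = dichotomize(pd.Series([0.0, 0.0, 2.0, 4.0, 6.0]), "nonzero-median")
        assert cut == 4.0
        assert list(high) == [0, 0, 0, 0, 1]

    def test_shift_invariance(self, rng):
        v = pd.Series(rng.random(101))
        h1, _ = dichotomize(v)
        h2, _ = dichotomize(v + 17.3)
        assert (h1 == h2).all()

    def test_counts_preserved(self, rng):
        v = pd.Series(rng.random(50))
        high, _ = dichotomize(v)
        assert int(high.sum() + (1 - high).sum()) == 50

    def test_all_equal_warns_all_low(self):
        with pytest.warns(UserWarning, match="all values equal"):
            high, _ = dichotomize(pd.Series([2.0, 2.0, 2.0]))
        assert (high == 0).all()


class TestSpearman:
    def test_perfect_monotone(self):
        rho, _ = spearman_trend([40, 50, 60, 70, 80], [1, 2, 3, 4, 5])
        assert rho == pytest.approx(1.0)

    def test_tied_example_mid_ranks(self):
        # mid-ranks then Pearson by hand: rho = 4/sqrt(20)
        rho, _ = spearman_trend([40, 50, 60, 70, 80], [1, 1, 2, 2, 3])
        ranks_y = stats.rankdata([1, 1, 2, 2, 3])
        expect = stats.pearsonr(stats.rankdata([40, 50, 60, 70, 80]), ranks_y)[0]
        assert rho == pytest.approx(expect, abs=1e-12)

    def test_symmetry(self, rng):
        x, y = rng.random(30), rng.random(30)
        assert spearman_trend(x, y)[0] == pytest.approx(spearman_trend(y, x)[0])

    def test_matches_rank_then_pearson_oracle_with_ties(self, rng):
        for _ in range(100):
            x = rng.integers(0, 10, 25).astype(float)
            y = rng.integers(0, 6, 25).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            rho, _ = spearman_trend(x, y)
            oracle = stats.pearsonr(stats.rankdata(x), stats.rankdata(y))[0]
            assert rho == pytest.approx(oracle, abs=1e-12)

    def test_constant_vector_flagged(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_trend([1, 2, 3, 4, 5], [2, 2, 2, 2, 2])


def _scaled_config(n, seed=0, **kw):
    """Default design scaled down to n cases (availability ~19%)."""
    by_age = (max(round(n * 52 / 4476), 1), round(n * 400 / 4476), round(n * 391 / 4476))
    return CohortSimConfig(n_total=n, n_by_age=by_age, seed=seed, **kw)


class TestHandleMissing:
    def _cohort(self, n=400, seed=0):
        return generate_cohort(_scaled_config(n, seed))

    def test_no_missing_unchanged(self):
        df = self._cohort()
        df = df.dropna(subset=["msi", "cimp", "kras", "braf", "pik3ca",
                               "family_history", "tumor_location", "line1_cat"])
        out = handle_missing(df)
        assert not any(c.endswith("_missing") for c in out.columns)

    def test_majority_imputation_with_indicator(self):
        df = self._cohort(2000, seed=3)
        n_missing = int(df["cimp"].isna().sum())
        assert n_missing > 0
        out = handle_missing(df)
        assert out["cimp"].notna().all()
        assert int(out["cimp_missing"].sum()) == n_missing
        majority = df["cimp"].mode().iloc[0]
        assert (out.loc[out["cimp_missing"] == 1, "cimp"] == majority).all()

    def test_line1_gets_separate_level_not_majority(self):
        df = self._cohort(2000, seed=4)
        n_missing = int(df["line1_cat"].isna().sum())
        out = handle_missing(df)
        assert int((out["line1_cat"] == "missing").sum()) == n_missing
        assert "line1_cat_missing" not in out.columns


class TestWeightedLogistic:
    def test_two_by_two_closed_form(self):
        # exposed: 10 high/40 low; reference: 50 high/50 low -> OR 0.25
        y = np.r_[np.ones(10), np.zeros(40), np.ones(50), np.zeros(50)]
        x = np.r_[np.ones(50), np.zeros(100)]
        design = pd.DataFrame({"exposed": x})
        fit = fit_weighted_logistic(pd.Series(y), design)
        assert np.exp(fit.params["exposed"]) == pytest.approx(0.25, rel=1e-6)

    def test_weight_scale_invariance(self, rng):
        y = pd.Series((rng.random(200) < 0.4).astype(float))
        design = pd.DataFrame({"x": rng.normal(size=200)})
        w = pd.Series(rng.uniform(0.5, 3.0, 200))
        f1 = fit_weighted_logistic(y, design, w)
        f2 = fit_weighted_logistic(y, design, 2 * w)
        assert np.allclose(f1.params, f2.params, atol=1e-8)

    def test_non_binary_outcome_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            fit_weighted_logistic(
                pd.Series([0.0, 0.5, 1.0]), pd.DataFrame({"x": [1.0, 2.0, 3.0]})
            )

    def test_or_table_ci_brackets_estimate(self, rng):
        y = pd.Series((rng.random(300) < 0.5).astype(float))
        design = pd.DataFrame({"x": rng.normal(size=300)})
        tab = fit_weighted_logistic(y, design).or_table
        assert (tab["ci_low"] <= tab["odds_ratio"]).all()
        assert (tab["odds_ratio"] <= tab["ci_high"]).all()
        assert (tab["odds_ratio"] > 0).all()


class TestIPW:
    def test_all_available_unit_weights(self):
        df = generate_cohort(_scaled_config(300, seed=5))
        df["tissue_available"] = True
        res = estimate_ipw_weights(df)
        assert (res.weights == 1.0).all()

    def test_two_strata_exact_reweighting(self, rng):
        # availability 0.5 for <55, 1.0 approached by a large coefficient
        n = 4000
        young = rng.random(n) < 0.5
        avail = np.where(young, rng.random(n) < 0.5, True)
        df = pd.DataFrame(
            {
                "age_group": pd.Categorical(
                    np.where(young, "<55", ">=70"), categories=["<55", "55-69", ">=70"]
                ),
                "tissue_available": avail,
            }
        )
        cfg = StatsConfig(availability_predictors=("age_group",), weight_truncate_quantile=1.0)
        res = estimate_ipw_weights(df, cfg)
        young_avail = df["tissue_available"] & young
        # weights approximate 1/0.5 = 2 in the young stratum
        assert res.weights[young_avail[young_avail].index].mean() == pytest.approx(
            young.sum() / young_avail.sum(), rel=1e-6
        )
        # weighted stratum total equals the full-cohort stratum count
        assert res.weights[young_avail[young_avail].index].sum() == pytest.approx(
            young.sum(), rel=1e-6
        )

    def test_balance_restored_after_weighting(self):
        df = generate_cohort(CohortSimConfig(), rng=np.random.default_rng(6))
        res = estimate_ipw_weights(df)
        assert (res.balance["smd_weighted"].abs() < 0.05).all()

    def test_separation_fails_loudly(self):
        df = generate_cohort(_scaled_config(400, seed=7))
        df["tissue_available"] = df["age_group"] == "<55"
        cfg = StatsConfig(availability_predictors=("age_group",))
        with pytest.raises(RuntimeError, match="separation"):
            estimate_ipw_weights(df, cfg)


class TestBackwardElimination:
    def _sim(self, rng, n=5000, beta_x=0.0):
        age = rng.choice(["<55", "55-69", ">=70"], n, p=[0.2, 0.4, 0.4])
        x = rng.random(n) < 0.5
        lp = -0.3 * (age == "<55") + beta_x * x
        y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float)
        terms = {
            "age": pd.DataFrame({"age[<55]": (age == "<55").astype(float),
                                 "age[55-69]": (age == "55-69").astype(float)}),
            "x": pd.DataFrame({"x": x.astype(float)}),
        }
        return pd.Series(y), terms

    def test_noise_covariate_eliminated_usually(self):
        # under the null the covariate's p-value is uniform, so the 0.1
        # threshold eliminates it in ~90% of replicates
        rng = np.random.default_rng(10)
        eliminated = 0
        n_reps = 40
        for _ in range(n_reps):
            y, terms = self._sim(rng, beta_x=0.0)
            _, kept, _ = backward_eliminate(y, terms)
            eliminated += "x" not in kept
        expected = 0.9 * n_reps
        assert eliminated >= expected - 3 * np.sqrt(n_reps * 0.9 * 0.1)

    def test_strong_covariate_retained(self):
        rng = np.random.default_rng(11)
        kept_count = 0
        for _ in range(40):
            y, terms = self._sim(rng, beta_x=np.log(2.0))
            _, kept, _ = backward_eliminate(y, terms)
            kept_count += "x" in kept
        assert kept_count >= 38

    def test_age_always_forced_in(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            y, terms = self._sim(rng, n=500)
            _, kept, _ = backward_eliminate(y, terms)
            assert "age" in kept


class TestMultiplicity:
    def test_adjusted_alpha_boundary_cases(self):
        flags = multiplicity_flag([0.012, 0.0030, 1.0])
        assert list(flags) == [False, True, False]

    def test_all_ones_no_flags(self):
        assert not multiplicity_flag(np.ones(9)).any()


@pytest.fixture(scope="module")
def report():
    df = generate_cohort(CohortSimConfig(), rng=np.random.default_rng(21))
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_full_analysis(df)


class TestFullAnalysis:
    def test_structural_contract(self, report):
        keys = set(report.results)
        assert keys == {
            (o, s)
            for o in ("overall_high", "micro_high", "lamb1_high")
            for s in ("all", "non-MSI-high")
        }
        for res in report.results.values():
            assert res.univariable is not None
            assert res.multivariable is not None
            assert res.unweighted is not None
            assert "age" in res.retained_terms

    def test_unit_weights_match_unweighted_path(self):
        df = generate_cohort(CohortSimConfig(n_total=2000, seed=30))
        df["tissue_available"] = True
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = run_full_analysis(df)
        for res in rep.results.values():
            assert np.allclose(
                res.multivariable.params.values, res.unweighted.params.values, atol=1e-8
            )

    def test_spearman_table_covers_densities(self, report):
        assert set(report.spearman["variable"]) >= {
            "density_overall", "density_micro", "density_lamb1"
        }
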
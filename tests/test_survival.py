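import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from radnomics.survival import (
    PUBLISHED_MODEL,
    CoxPH,
    backward_eliminate,
    baseline_table,
    calibration_curve,
    combined_rad_score,
    concordance_index,
    km_logrank,
    split_cohort,
    stratify_by_median,
)

from conftest import simulate_survival


class TestCoxFit:
    def test_null_effect_recovered_near_zero(self):
        df = simulate_survival(2000, [0.0], seed=1)
        res = CoxPH(df, covariates=["x0"]).fit()
        assert abs(res.params_["x0"]) < 0.1

    def test_effect_recovery_mean_over_replicates(self):
        est = []
        for seed in range(20):
            df = simulate_survival(1000, [0.8], seed=seed)
            est.append(CoxPH(df, covariates=["x0"]).fit().params_["x0"])
        assert 0.7 < np.mean(est) < 0.9

    def test_three_patient_partial_likelihood_oracle(self):
        # interior maximum; oracle = direct numerical maximization of the
        # hand-written Breslow partial likelihood
        df = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [1, 1, 1],
                           "x": [1.0, 0.0, 1.0]})

        def neg_log_pl(b):
            # risk sets: {A,B,C} at t=1 (A, x=1), {B,C} at t=2 (B, x=0), {C} at t=3
            import math
            return -(b - math.log(2 * math.exp(b) + 1)
                     + 0.0 - math.log(math.exp(b) + 1)
                     + b - math.log(math.exp(b)))

        oracle = optimize.minimize_scalar(neg_log_pl, bounds=(-5, 5), method="bounded").x
        res = CoxPH(df, covariates=["x"]).fit()
        assert res.params_["x"] == pytest.approx(oracle, abs=1e-4)

    def test_constant_covariate_rejected(self):
        df = simulate_survival(50, [0.5], seed=2)
        df["c"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            CoxPH(df, covariates=["x0", "c"])

    def test_no_events_rejected(self):
        df = pd.DataFrame({"time": [40.0, 50.0], "event": [0, 0], "x": [0.0, 1.0]})
        with pytest.raises(ValueError, match="event"):
            CoxPH(df, covariates=["x"])

    def test_predicted_survival_matches_lifelines(self):
        df = simulate_survival(300, [0.7, -0.3], seed=3)
        model = CoxPH(df, covariates=["x0", "x1"])
        res = model.fit()
        # evaluate at observed event times, where the Breslow step function
        # and lifelines' interpolated lookup coincide
        times = np.sort(df.loc[df["event"] == 1, "time"].to_numpy())[[5, 20, 40]]
        got = res.predict_survival(df, times)
        want = res._fitter.predict_survival_function(df, times=times).to_numpy().T
        np.testing.assert_allclose(got, want, atol=1e-8)
        assert ((got > 0) & (got <= 1)).all()

    def test_summary_has_cis_and_pvalues(self):
        df = simulate_survival(200, [0.5], seed=4)
        res = CoxPH(df, covariates=["x0"]).fit()
        s = res.summary()
        assert {"coef", "p"} <= set(s.columns)
        lo, hi = res.confidence_intervals_.iloc[0]
        assert lo < res.params_["x0"] < hi


class TestRadScore:
    def test_published_coefficient_applied_verbatim(self):
        clin = pd.DataFrame({"gender": [0], "age": [0.0], "hgb": [0.0], "n_stage": [0]})
        s = combined_rad_score([1.0], [0.0], clin)
        assert s[0] == pytest.approx(0.88663, abs=1e-12)

    def test_zero_inputs_zero_score(self):
        clin = pd.DataFrame({"gender": [0], "age": [0.0], "hgb": [0.0], "n_stage": [0]})
        assert combined_rad_score([0.0], [0.0], clin)[0] == 0.0

    def test_hand_summed_covariate_vector(self):
        clin = pd.DataFrame({"gender": [1], "age": [50.0], "hgb": [136.0], "n_stage": [2]})
        s = combined_rad_score([1.0], [1.0], clin)
        by_hand = (0.88663 * 1 + 0.50748 * 1 + 0.02159 * 1 + 0.02012 * 50
                   + 0.00691 * 136 - 0.21954 * 2)
        assert s[0] == pytest.approx(by_hand, abs=1e-9)
        assert s[0] == pytest.approx(2.92238, abs=1e-5)

    def test_missing_covariate_named(self):
        clin = pd.DataFrame({"gender": [1], "age": [50.0]})
        with pytest.raises(KeyError, match="hgb"):
            combined_rad_score([1.0], [1.0], clin)


def _cindex_oracle(scores, time, event):
    """O(n^2) pure-python pair enumeration from the stated definition."""
    usable = concordant = tied = 0
    n = len(scores)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            fails_first = (time[i] < time[j] and event[i]) or (
                time[i] == time[j] and event[i] and not event[j])
            if not fails_first:
                continue
            usable += 1
            if scores[i] > scores[j]:
                concordant += 1
            elif scores[i] == scores[j]:
                tied += 1
    return (concordant + 0.5 * tied) / usable, usable


class TestConcordance:
    def test_perfect_anti_and_tied(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.ones(4, dtype=int)
        assert concordance_index([4, 3, 2, 1], t, e)[0] == 1.0
        assert concordance_index([1, 2, 3, 4], t, e)[0] == 0.0
        assert concordance_index([5, 5, 5, 5], t, e)[0] == 0.5

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_pair_enumeration_oracle_exactly(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 100))
        t = rng.integers(1, 20, size=n).astype(float)  # forces time ties
        e = rng.random(n) < 0.6
        s = np.round(rng.normal(size=n), 1)  # forces score ties
        got_c, got_n = concordance_index(s, t, e)
        want_c, want_n = _cindex_oracle(s, t, e)
        assert got_n == want_n
        assert got_c == want_c

    def test_matches_lifelines_on_tie_free_data(self):
        from lifelines.utils import concordance_index as ll_cindex

        rng = np.random.default_rng(42)
        t = rng.exponential(30, size=200)
        e = rng.random(200) < 0.5
        s = rng.normal(size=200)
        c, _ = concordance_index(s, t, e)
        # lifelines orders by predicted survival time (higher = later failure)
        assert c == pytest.approx(ll_cindex(t, -s, e), abs=1e-12)

    def test_random_scores_near_half(self):
        df = simulate_survival(1000, [1.0], seed=5)
        rng = np.random.default_rng(6)
        c, _ = concordance_index(rng.normal(size=1000), df["time"], df["event"])
        assert abs(c - 0.5) < 0.05

    def test_no_usable_pairs_rejected(self):
        with pytest.raises(ValueError, match="usable"):
            concordance_index([1, 2], [40.0, 50.0], [0, 0])


class TestKMLogrank:
    def test_product_limit_by_hand(self):
        res = km_logrank([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], [1, 1, 1, 1, 1, 1],
                         ["a", "a", "a", "b", "b", "b"])
        surv = res["curves"]["a"].set_index("time")["survival"]
        assert surv[1.0] == pytest.approx(2 / 3)
        assert surv[2.0] == pytest.approx(1 / 3)
        assert surv[3.0] == pytest.approx(0.0)

    def test_identical_groups_null(self):
        t = [2.0, 5.0, 9.0, 12.0]
        e = [1, 0, 1, 1]
        res = km_logrank(t + t, e + e, ["a"] * 4 + ["b"] * 4)
        assert res["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_power_under_strong_separation(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            g = np.repeat(["lo", "hi"], 100)
            lp = np.where(g == "hi", np.log(3.0), 0.0)  # hazard ratio 3
            t_ev = rng.exponential(1.0 / (0.02 * np.exp(lp)))
            t_c = rng.uniform(36, 68, size=200)
            e = t_ev <= t_c
            t = np.where(e, t_ev, t_c)
            hits += km_logrank(t, e.astype(int), g)["p"] < 0.05
        assert hits >= 38

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            km_logrank([1.0, 2.0], [1, 1], ["a", "a"])


class TestStratification:
    def test_even_median_split(self):
        strat = stratify_by_median(np.array([1.0, 2.0, 3.0, 4.0]))
        assert strat["threshold"] == 2.5
        assert strat["group"].tolist() == ["low", "low", "high", "high"]

    def test_all_equal_scores_all_high(self):
        strat = stratify_by_median(np.ones(5))
        assert (strat["group"] == "high").all()

    def test_continuous_scores_split_evenly(self):
        scores = np.random.default_rng(8).normal(size=140)
        strat = stratify_by_median(scores)
        assert (strat["group"] == "low").sum() == 70
        assert (strat["group"] == "high").sum() == 70

    def test_validation_scored_against_training_threshold(self):
        strat = stratify_by_median(np.array([0.0, 10.0, 20.0]), np.array([5.0, 15.0]))
        assert strat["threshold"] == 10.0
        assert strat["group"].tolist() == ["low", "high"]


class TestCalibration:
    def test_well_specified_model_calibrates(self):
        df = simulate_survival(2000, [0.8], seed=9)
        res = CoxPH(df, covariates=["x0"]).fit()
        tab = calibration_curve(res, df, df["time"], df["event"], horizon=24.0,
                                n_boot=50, rng=np.random.default_rng(0))
        assert len(tab) == 4
        assert (tab["predicted"] - tab["observed"]).abs().max() < 0.05

    def test_horizon_zero_everything_survives(self):
        df = simulate_survival(200, [0.5], seed=10)
        res = CoxPH(df, covariates=["x0"]).fit()
        tab = calibration_curve(res, df, df["time"], df["event"], horizon=0.0, n_boot=10)
        np.testing.assert_allclose(tab["predicted"], 1.0)
        np.testing.assert_allclose(tab["observed"], 1.0)

    def test_misspecified_model_calibrates_worse(self):
        # a model carried over from data with a doubled hazard scale is
        # biased for these data; its grouped calibration error must exceed
        # the correctly specified model's on the same evaluation set
        df = simulate_survival(1500, [1.2], seed=11)
        good = CoxPH(df, covariates=["x0"]).fit()
        corrupted = df.copy()
        corrupted["time"] = corrupted["time"] / 2.0
        bad = CoxPH(corrupted, covariates=["x0"]).fit()
        err = {}
        for name, res in (("good", good), ("bad", bad)):
            tab = calibration_curve(res, df, df["time"], df["event"], horizon=24.0,
                                    n_boot=10, rng=np.random.default_rng(1))
            err[name] = (tab["predicted"] - tab["observed"]).abs().max()
        assert err["bad"] > err["good"]

    def test_horizon_beyond_followup_warns_and_truncates(self):
        df = simulate_survival(100, [0.5], seed=12)
        res = CoxPH(df, covariates=["x0"]).fit()
        with pytest.warns(UserWarning, match="truncat"):
            calibration_curve(res, df, df["time"], df["event"],
                              horizon=df["time"].max() + 100, n_boot=5)


class TestSplitAndBaseline:
    def test_140_gives_80_60(self):
        tr, va = split_cohort(140, seed=0)
        assert len(tr) == 80 and len(va) == 60
        assert len(np.intersect1d(tr, va)) == 0
        assert len(np.union1d(tr, va)) == 140

    def test_minimum_cohort_splits_4_3(self):
        tr, va = split_cohort(7, seed=1)
        assert len(tr) == 4 and len(va) == 3

    def test_same_seed_same_partition(self):
        assert (split_cohort(50, seed=5)[0] == split_cohort(50, seed=5)[0]).all()
        assert not (split_cohort(50, seed=5)[0] == split_cohort(50, seed=6)[0]).all()

    def test_identical_tables_give_null_pvalues(self):
        from radnomics.cohort import generate_clinical

        clin = generate_clinical(60, np.random.default_rng(1))
        tab = baseline_table(clin, clin.copy())
        chi2_rows = tab[tab["test"] == "chi2"]
        np.testing.assert_allclose(chi2_rows["statistic"], 0.0, atol=1e-12)
        np.testing.assert_allclose(chi2_rows["p"], 1.0)

    def test_shifted_age_detected(self):
        from radnomics.cohort import generate_clinical

        a = generate_clinical(100, np.random.default_rng(2))
        b = generate_clinical(100, np.random.default_rng(3))
        b["age"] += 10
        assert baseline_table(a, b).loc["age", "p"] < 0.001

    def test_null_pvalues_approximately_uniform(self):
        from radnomics.cohort import generate_clinical
        from scipy.stats import kstest

        ps = []
        for seed in range(150):
            rng = np.random.default_rng(seed)
            a = generate_clinical(2000, rng)
            b = generate_clinical(2000, rng)
            ps.append(baseline_table(a, b).loc["age", "p"])
        assert kstest(ps, "uniform").pvalue > 0.01


class TestBackwardElimination:
    def test_keeps_signal_drops_noise(self):
        rng = np.random.default_rng(13)
        x = np.column_stack([rng.normal(size=800), rng.normal(size=800)])
        df = simulate_survival(800, [1.0, 0.0], x=x, seed=13)
        res = backward_eliminate(df, ["x0", "x1"])
        assert list(res.params_.index) == ["x0"]

    def test_retains_at_least_one_covariate(self):
        df = simulate_survival(100, [0.0, 0.0], seed=14)
        res = backward_eliminate(df, ["x0", "x1"])
        assert len(res.params_) >= 1


class TestPublishedThreshold:
    def test_printed_boundary_classification(self):
        assert PUBLISHED_MODEL.risk_group(5.49) == "low"
        assert PUBLISHED_MODEL.risk_group(5.50) == "high"
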
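"""KM, log-rank, Cox, IPCW time-dependent ROC, cutoffs, frozen validation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from helpers import (
    ipcw_auc_oracle,
    km_oracle,
    logrank_2group_oracle,
    mann_whitney_auc,
    random_survival,
)
from scipy import stats

import pairsig as ps


def _surv(times, events):
    return pd.DataFrame({
        "sample_id": [f"S{i}" for i in range(len(times))],
        "time": np.asarray(times, float),
        "event": np.asarray(events, int),
    })


def _scores(surv, values):
    return pd.DataFrame({"sample_id": surv["sample_id"], "risk_score": values})


class TestKaplanMeier:
    def test_no_censoring_closed_form(self):
        km = ps.km_estimate(_surv([1, 2, 3, 4], [1, 1, 1, 1]))
        np.testing.assert_allclose(km.survival_prob, [0.75, 0.5, 0.25, 0.0])

    def test_all_censored_is_flat_one(self):
        km = ps.km_estimate(_surv([1, 2, 3], [0, 0, 0]))
        assert len(km.event_times) == 0
        assert km.survival_at(2.5) == 1.0

    def test_mixed_six_sample_hand_case(self):
        km = ps.km_estimate(_surv([1, 2, 2, 3, 4, 5], [1, 1, 0, 1, 0, 1]))
        # hand product-limit: S(1)=5/6, S(2)=5/6*4/5=2/3, S(3)=2/3*2/3=4/9, S(5)=0
        np.testing.assert_allclose(km.survival_prob, [5 / 6, 2 / 3, 4 / 9, 0.0])

    def test_exhaustive_small_cases_match_oracle(self):
        """All time/event patterns for n <= 4 over a tie-rich time grid."""
        for n in (1, 2, 3, 4):
            for times in itertools.product([1.0, 2.0, 3.0], repeat=n):
                for events in itertools.product([0, 1], repeat=n):
                    surv = _surv(times, events)
                    km = ps.km_estimate(surv)
                    oracle = km_oracle(times, events)
                    assert len(km.event_times) == len(oracle)
                    for t, s in zip(km.event_times, km.survival_prob):
                        assert s == pytest.approx(oracle[t], abs=1e-12)

    def test_random_cases_match_oracle(self, rng):
        for _ in range(100):
            n = rng.integers(2, 11)
            times = rng.integers(1, 6, size=n).astype(float)
            events = rng.integers(0, 2, size=n)
            if events.sum() == 0:
                continue
            km = ps.km_estimate(_surv(times, events))
            oracle = km_oracle(times, events)
            for t, s in zip(km.event_times, km.survival_prob):
                assert s == pytest.approx(oracle[t], abs=1e-12)


class TestLogRank:
    def test_identical_groups_give_null_statistic(self):
        surv = _surv([1, 2, 3, 4, 1, 2, 3, 4], [1, 1, 0, 1, 1, 1, 0, 1])
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=surv["sample_id"])
        res = ps.log_rank_test(surv, groups)
        assert res.chi_square == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0, abs=1e-10)

    def test_perfect_separation_significant(self):
        times = list(range(1, 21)) + list(range(100, 120))
        surv = _surv(times, [1] * 40)
        groups = pd.Series(["early"] * 20 + ["late"] * 20, index=surv["sample_id"])
        assert ps.log_rank_test(surv, groups).p_value < 0.001

    def test_eight_sample_hand_oracle(self):
        times = [2, 4, 4, 6, 1, 3, 5, 7]
        events = [1, 1, 0, 1, 1, 1, 1, 0]
        labels = ["a"] * 4 + ["b"] * 4
        surv = _surv(times, events)
        res = ps.log_rank_test(surv, pd.Series(labels, index=surv["sample_id"]))
        assert res.chi_square == pytest.approx(
            logrank_2group_oracle(times, events, labels), abs=1e-9)

    def test_matches_squared_standardized_oe_on_random_data(self, rng):
        for _ in range(20):
            n = 40
            surv = random_survival(rng, n, censor_scale=150.0)
            labels = rng.choice(["a", "b"], n)
            res = ps.log_rank_test(surv, pd.Series(labels, index=surv["sample_id"].to_numpy()))
            oracle = logrank_2group_oracle(surv["time"], surv["event"], labels)
            assert res.chi_square == pytest.approx(oracle, abs=1e-8)
            assert res.df == 1

    def test_supports_four_groups(self, rng):
        surv = random_survival(rng, 80)
        labels = rng.choice(list("abcd"), 80)
        res = ps.log_rank_test(surv, pd.Series(labels, index=surv["sample_id"].to_numpy()))
        assert res.df == 3

    def test_single_group_rejected(self, rng):
        surv = random_survival(rng, 10)
        with pytest.raises(ps.FitError):
            ps.log_rank_test(surv, pd.Series(["a"] * 10, index=surv["sample_id"].to_numpy()))


class TestCoxFit:
    def test_planted_hazard_ratio_recovered(self):
        hits = 0
        for seed in range(20):
            lrng = np.random.default_rng(seed)
            n = 1000
            x = lrng.integers(0, 2, n)
            t = lrng.exponential(1.0, n) / np.exp(np.log(2.0) * x)
            cov = pd.DataFrame({"sample_id": [f"S{i}" for i in range(n)], "x": x})
            surv = _surv(t, np.ones(n, int))
            res = ps.cox_fit(cov, surv)
            hr = res.table.loc["x", "hazard_ratio"]
            hits += 1.7 <= hr <= 2.35
        assert hits >= 18

    def test_null_p_values_uniform(self):
        ps_vals = []
        for seed in range(200):
            lrng = np.random.default_rng(10_000 + seed)
            n = 60
            cov = pd.DataFrame({"sample_id": [f"S{i}" for i in range(n)],
                                "x": lrng.normal(size=n)})
            surv = _surv(lrng.exponential(50, n) + 1, np.ones(n, int))
            ps_vals.append(ps.cox_fit(cov, surv).table.loc["x", "p_value"])
        assert stats.kstest(ps_vals, "uniform").pvalue > 0.01

    def test_duplicated_column_rejected(self, rng):
        n = 50
        x = rng.normal(size=n)
        cov = pd.DataFrame({"sample_id": [f"S{i}" for i in range(n)], "x": x, "y": x})
        surv = random_survival(rng, n)
        surv["sample_id"] = [f"S{i}" for i in range(n)]
        with pytest.raises(ps.FitError, match="rank deficient"):
            ps.cox_fit(cov, surv)

    def test_constant_column_rejected(self, rng):
        n = 50
        cov = pd.DataFrame({"sample_id": [f"S{i}" for i in range(n)], "x": 1.0})
        surv = random_survival(rng, n)
        surv["sample_id"] = [f"S{i}" for i in range(n)]
        with pytest.raises(ps.FitError, match="constant"):
            ps.cox_fit(cov, surv)


class TestTimeROC:
    def test_perfect_separation_auc_one(self):
        surv = _surv([1, 2, 3, 10, 11, 12], [1] * 6)
        scores = _scores(surv, [5.0, 4.0, 3.0, 0.2, 0.1, 0.0])
        assert ps.time_dependent_roc(scores, surv, 5.0).auc == pytest.approx(1.0)

    def test_uncensored_equals_mann_whitney(self, rng):
        """Property over 50 random uncensored instances, ties included."""
        for _ in range(50):
            n = int(rng.integers(20, 60))
            surv = _surv(rng.exponential(50, n) + 1, np.ones(n, int))
            s = np.round(rng.normal(size=n), 1)  # coarse scores inject ties
            scores = _scores(surv, s)
            horizon = float(np.median(surv["time"]))
            roc = ps.time_dependent_roc(scores, surv, horizon)
            t = surv["time"].to_numpy()
            mw = mann_whitney_auc(s[t <= horizon], s[t > horizon])
            assert roc.auc == pytest.approx(mw, abs=1e-9)

    def test_censored_matches_pairwise_ipcw_oracle(self, rng):
        for _ in range(10):
            n = 80
            surv = random_survival(rng, n, censor_scale=120.0)
            s = np.round(rng.normal(size=n), 1)
            scores = _scores(surv, s)
            horizon = float(np.median(surv["time"]))
            try:
                roc = ps.time_dependent_roc(scores, surv, horizon)
            except ps.FitError:
                continue
            oracle = ipcw_auc_oracle(s, surv["time"], surv["event"], horizon)
            assert roc.auc == pytest.approx(oracle, abs=1e-9)

    def test_matches_sksurv_cumulative_dynamic_auc(self, rng):
        from sksurv.metrics import cumulative_dynamic_auc
        from sksurv.util import Surv

        n = 150
        surv = random_survival(rng, n, censor_scale=150.0)
        s = rng.normal(size=n)
        scores = _scores(surv, s)
        horizon = float(np.quantile(surv["time"], 0.5))
        mine = ps.time_dependent_roc(scores, surv, horizon).auc
        y = Surv.from_arrays(event=surv["event"].astype(bool), time=surv["time"])
        theirs = cumulative_dynamic_auc(y, y, s, [horizon])[0][0]
        assert mine == pytest.approx(theirs, abs=1e-9)

    def test_random_scores_near_half(self):
        aucs = []
        for seed in range(20):
            lrng = np.random.default_rng(seed)
            surv = random_survival(lrng, 500, censor_scale=200.0)
            scores = _scores(surv, lrng.normal(size=500))
            aucs.append(ps.time_dependent_roc(scores, surv,
                                              float(np.median(surv["time"]))).auc)
        assert 0.45 < float(np.mean(aucs)) < 0.55

    def test_monotone_sensitivity_specificity(self, rng):
        surv = random_survival(rng, 100, censor_scale=100.0)
        scores = _scores(surv, np.round(rng.normal(size=100), 1))
        roc = ps.time_dependent_roc(scores, surv, float(np.median(surv["time"])))
        assert (np.diff(roc.sensitivity) <= 1e-12).all()
        assert (np.diff(roc.specificity) >= -1e-12).all()
        # curve endpoints
        assert roc.sensitivity[0] == pytest.approx(1.0, abs=1e-9)
        assert 1 - roc.specificity[0] == pytest.approx(1.0, abs=1e-9)
        assert roc.sensitivity[-1] == pytest.approx(0.0, abs=1e-9)
        assert 1 - roc.specificity[-1] == pytest.approx(0.0, abs=1e-9)

    def test_no_cases_at_horizon_rejected(self):
        surv = _surv([10, 11, 12], [1, 1, 1])
        scores = _scores(surv, [1.0, 2.0, 3.0])
        with pytest.raises(ps.FitError, match="horizon"):
            ps.time_dependent_roc(scores, surv, 5.0)


class TestOptimalCutoff:
    @staticmethod
    def _clustered(seed, shift=0.0):
        lrng = np.random.default_rng(seed)
        n = 200
        group = lrng.integers(0, 2, n)
        s = np.where(group == 1, lrng.normal(3, 0.25, n), lrng.normal(0, 0.25, n)) + shift
        t = np.where(group == 1, lrng.exponential(15, n), lrng.exponential(300, n)) + 1
        surv = _surv(t, np.ones(n, int))
        return _scores(surv, s), surv, s, group

    @pytest.mark.parametrize("method", ["aic", "youden"])
    def test_cutoff_recovers_planted_dichotomy(self, method):
        """The chosen cutoff reproduces the planted high/low clusters almost
        perfectly; it may sit a sample or two off the exact inter-cluster
        gap when a within-cluster sample's survival crosses over."""
        for seed in range(10):
            scores, surv, s, group = self._clustered(seed)
            cut = ps.optimal_cutoff(scores, surv, float(np.median(surv["time"])),
                                    method=method)
            agreement = np.mean((s > cut) == (group == 1))
            assert agreement >= 0.97

    def test_identical_scores_rejected(self, rng):
        surv = random_survival(rng, 30)
        with pytest.raises(ps.FitError, match="identical"):
            ps.optimal_cutoff(_scores(surv, np.ones(30)), surv, 50.0)

    def test_shift_equivariance(self):
        scores, surv, _, _ = self._clustered(3)
        base = ps.optimal_cutoff(scores, surv, 150.0, method="aic")
        shifted = scores.copy()
        shifted["risk_score"] += 10.0
        assert ps.optimal_cutoff(shifted, surv, 150.0, method="aic") == pytest.approx(
            base + 10.0, abs=1e-9)


class TestAssignGroups:
    def test_documented_boundary(self):
        scores = pd.DataFrame({"sample_id": ["a", "b", "c"],
                               "risk_score": [1.0, 1.5, 2.0]})
        out = ps.assign_groups(scores, 1.471)
        assert out["group"].tolist() == ["low", "high", "high"]
        exact = ps.assign_groups(pd.DataFrame({"sample_id": ["x"], "risk_score": [1.471]}),
                                 1.471)
        assert exact["group"].tolist() == ["low"]

    def test_high_group_mean_exceeds_low(self, rng):
        surv = random_survival(rng, 50)
        scores = _scores(surv, rng.normal(size=50))
        out = ps.assign_groups(scores, float(np.median(scores["risk_score"])))
        means = out.groupby("group")["risk_score"].mean()
        assert means["high"] > means["low"]


class TestFrozenValidation:
    @staticmethod
    def _fitted_model_and_cohorts(seed):
        cfg = ps.SimConfig(n_samples=600, n_genes=12, n_causal_pairs=2,
                           causal_betas=[1.5, -1.2], censor_rate=0.3, seed=seed)
        full = ps.simulate_cohort(cfg)
        train, val = full.split(300)
        pm = ps.pair_indicators(train.expression, [(a, b) for a, b, _ in full.truth])
        model = ps.stepwise_cox(pm, train.survival)
        if not model.pairs:
            return None
        scores = ps.compute_risk_score(model, pm)
        model.cutoff = ps.optimal_cutoff(scores, train.survival,
                                         float(np.median(train.survival["time"])))
        return model, train, val

    def test_signal_carries_to_validation_cohort(self):
        hits, total = 0, 0
        for seed in range(10):
            fitted = self._fitted_model_and_cohorts(seed)
            if fitted is None:
                continue
            model, _, val = fitted
            total += 1
            rep = ps.validate_frozen_signature(model, val.expression, val.survival,
                                               horizons=[365.0])
            if rep.log_rank is not None and rep.log_rank.p_value < 0.01:
                hits += 1
        assert total >= 8 and hits >= 0.9 * total

    def test_training_cohort_reproduces_groups(self):
        model, train, _ = self._fitted_model_and_cohorts(2)
        pm = ps.pair_indicators(train.expression, model.pairs)
        direct = ps.assign_groups(ps.compute_risk_score(model, pm), model.cutoff)
        rep = ps.validate_frozen_signature(model, train.expression, train.survival,
                                           horizons=[365.0])
        assert rep.scores["group"].tolist() == direct["group"].tolist()

    def test_no_signal_gives_chance_auc(self):
        model = ps.SignatureModel(pairs=[("LINC0001", "LINC0002")], betas=[1.0],
                                  cutoff=0.5)
        cfg = ps.SimConfig(n_samples=400, n_genes=6, n_causal_pairs=0, causal_betas=[],
                           censor_rate=0.3, seed=9)
        cohort = ps.simulate_cohort(cfg)
        rep = ps.validate_frozen_signature(model, cohort.expression, cohort.survival,
                                           horizons=[float(np.median(cohort.survival['time']))])
        auc = list(rep.aucs.values())[0]
        assert 0.4 <= auc <= 0.6

    def test_cutoff_required(self):
        model = ps.SignatureModel(pairs=[("a", "b")], betas=[1.0], cutoff=None)
        cfg = ps.SimConfig(n_samples=20, n_genes=4, n_causal_pairs=0, causal_betas=[],
                           seed=1)
        cohort = ps.simulate_cohort(cfg)
        with pytest.raises(ps.FitError, match="cutoff"):
            ps.validate_frozen_signature(model, cohort.expression, cohort.survival, [100.0])

    def test_missing_genes_listed(self):
        model = ps.SignatureModel(pairs=[("NOPE1", "NOPE2")], betas=[1.0], cutoff=0.0)
        cfg = ps.SimConfig(n_samples=20, n_genes=4, n_causal_pairs=0, causal_betas=[],
                           seed=1)
        cohort = ps.simulate_cohort(cfg)
        with pytest.raises(KeyError, match="NOPE1"):
            ps.validate_frozen_signature(model, cohort.expression, cohort.survival, [100.0])
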
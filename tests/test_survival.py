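"""Split / Cox / risk-score / log-rank / permutation survival screen."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from icplnc import (
    PipelineConfig,
    cox_newton,
    cross_cohort_summary,
    fit_cox_pair,
    logrank_by_median,
    logrank_statistic,
    permutation_screen,
    risk_score,
    simulate_tumor_cohort,
    split_cohort,
)
from icplnc.simulate import SimConfig
from icplnc.survival import CoxError, RiskModel, cox_covariance


class TestSplit:
    def test_even_split(self):
        train, held = split_cohort([f"S{i}" for i in range(40)], seed=1)
        assert len(train) == 20 and len(held) == 20
        assert set(train) | set(held) == {f"S{i}" for i in range(40)}
        assert set(train) & set(held) == set()

    def test_odd_n_extra_to_train(self):
        train, held = split_cohort([f"S{i}" for i in range(41)], seed=1)
        assert len(train) == 21 and len(held) == 20

    def test_deterministic(self):
        ids = [f"S{i}" for i in range(30)]
        assert split_cohort(ids, seed=5) == split_cohort(ids, seed=5)
        assert split_cohort(ids, seed=5) != split_cohort(ids, seed=6)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            split_cohort([f"S{i}" for i in range(10)], seed=1)


def _exponential_survival(rng, n, betas, censor_frac=0.0):
    p = len(betas)
    X = rng.normal(size=(n, p))
    lam = np.exp(X @ np.asarray(betas))
    time = rng.exponential(1.0 / lam)
    event = np.ones(n)
    if censor_frac > 0:
        cut = np.quantile(time, 1 - censor_frac)
        event = (time <= cut).astype(float)
        time = np.minimum(time, cut)
    return X, time, event


class TestCoxNewton:
    def test_parameter_recovery_uncensored(self, rng):
        X, time, event = _exponential_survival(rng, 500, [0.7, 0.5])
        beta, converged = cox_newton(X, time, event)
        assert converged
        assert abs(beta[0] - 0.7) < 0.15
        assert abs(beta[1] - 0.5) < 0.15

    def test_low_bias_at_large_n(self, rng):
        X, time, event = _exponential_survival(rng, 2000, [0.6, -0.4])
        beta, _ = cox_newton(X, time, event)
        assert abs(beta[0] - 0.6) < 0.08
        assert abs(beta[1] + 0.4) < 0.08

    def test_null_coverage(self):
        """Under beta=0 the estimate stays within 3 SE almost always."""
        hits = 0
        reps = 100
        for s in range(reps):
            rng = np.random.default_rng(1000 + s)
            X, time, event = _exponential_survival(rng, 120, [0.0, 0.0])
            beta, converged = cox_newton(X, time, event)
            se = np.sqrt(np.diag(cox_covariance(X, time, event, beta)))
            if converged and np.all(np.abs(beta) < 3 * se):
                hits += 1
        assert hits >= 94

    def test_matches_lifelines_with_ties(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(3)
        X, time, event = _exponential_survival(rng, 150, [0.8, -0.3], 0.2)
        time = np.round(time, 1)  # force ties to exercise Efron handling
        beta, converged = cox_newton(X, time, event)
        assert converged
        df = pd.DataFrame({"x0": X[:, 0], "x1": X[:, 1], "t": time, "e": event})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        np.testing.assert_allclose(
            beta, cph.params_[["x0", "x1"]].to_numpy(), atol=1e-4
        )

    def test_constant_covariate_rejected(self, rng):
        X, time, event = _exponential_survival(rng, 50, [0.5])
        X = np.column_stack([X, np.ones(50)])
        with pytest.raises(CoxError, match="constant"):
            cox_newton(X, time, event)

    def test_too_few_events_rejected(self, rng):
        X = rng.normal(size=(30, 2))
        time = rng.exponential(size=30)
        event = np.zeros(30)
        event[0] = 1
        with pytest.raises(CoxError, match="events"):
            cox_newton(X, time, event)


class TestRiskScore:
    @staticmethod
    def _cohort(seed=20, n=150, beta=1.0):
        sim = SimConfig(
            seed=seed, samples_per_cohort=n,
            prognostic_pairs=[(("ICP001", "LNC001"), beta)],
            response_pairs=[],
        )
        return simulate_tumor_cohort(sim, "C"), sim

    def test_zero_betas_zero_scores(self):
        (m, ann, _), _sim = self._cohort()
        train, held = split_cohort(list(m.sample_ids), seed=2)
        fit = fit_cox_pair(m, ann, ("ICP001", "LNC001"), train)
        fit = dataclasses.replace(fit, beta=np.zeros(4))
        scores = risk_score(m, fit, ("ICP001", "LNC001"), held)
        assert (scores == 0).all()

    def test_linear_form(self):
        (m, ann, _), _sim = self._cohort()
        train, held = split_cohort(list(m.sample_ids), seed=2)
        fit = fit_cox_pair(m, ann, ("ICP001", "LNC001"), train)
        fit = dataclasses.replace(fit, beta=np.array([1.0, 0.0, 9.9, 9.9]))
        scores = risk_score(m, fit, ("ICP001", "LNC001"), held)
        z = (m.gene("ICP001") - fit.train_means[0]) / fit.train_sds[0]
        expected = pd.Series(z, index=m.sample_ids).loc[held]
        np.testing.assert_allclose(scores.to_numpy(), expected.to_numpy())

    def test_vectorized_matches_per_sample_loop(self):
        (m, ann, _), _sim = self._cohort()
        train, held = split_cohort(list(m.sample_ids), seed=3)
        fit = fit_cox_pair(m, ann, ("ICP001", "LNC001"), train)
        scores = risk_score(m, fit, ("ICP001", "LNC001"), held)
        for sid in held[:20]:
            xi = float(m.gene("ICP001")[m._sample_index[sid]])
            xl = float(m.gene("LNC001")[m._sample_index[sid]])
            want = fit.beta[0] * (xi - fit.train_means[0]) / fit.train_sds[0] + \
                fit.beta[1] * (xl - fit.train_means[1]) / fit.train_sds[1]
            assert scores[sid] == pytest.approx(want, abs=1e-12)

    def test_high_risk_stratum_has_worse_survival(self):
        (m, ann, _), _sim = self._cohort(beta=1.5, n=300)
        train, held = split_cohort(list(m.sample_ids), seed=4)
        fit = fit_cox_pair(m, ann, ("ICP001", "LNC001"), train)
        scores = risk_score(m, fit, ("ICP001", "LNC001"), held)
        a = ann.set_index("sample_id").loc[held]
        hi = scores.to_numpy() > np.median(scores.to_numpy())
        assert (
            a["os_time"].to_numpy()[hi].mean()
            < a["os_time"].to_numpy()[~hi].mean()
        )


from oracles import logrank_hand_table


class TestLogrank:
    def test_identical_strata_give_zero(self):
        time = [3.0, 5.0, 7.0, 9.0] * 2
        event = [1, 0, 1, 1] * 2
        group = [True] * 4 + [False] * 4
        chi2, p = logrank_statistic(np.array(time), np.array(event), np.array(group))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_worked_table(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0,
                         1.5, 2.5, 3.0, 4.5, 6.0, 7.0])
        event = np.array([1, 1, 0, 1, 1, 0, 1, 1, 1, 0, 1, 1])
        group = np.array([True] * 6 + [False] * 6)
        chi2, _ = logrank_statistic(time, event, group)
        assert chi2 == pytest.approx(
            logrank_hand_table(list(time), list(event), list(group)), abs=1e-9
        )

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(7)
        time = rng.exponential(size=80)
        event = rng.random(80) < 0.8
        group = rng.random(80) < 0.5
        chi2, p = logrank_statistic(time, event, group)
        ref = logrank_test(
            time[group], time[~group], event[group], event[~group]
        )
        assert chi2 == pytest.approx(ref.test_statistic, abs=1e-9)
        assert p == pytest.approx(ref.p_value, abs=1e-9)

    def test_power_under_planted_effect(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(500 + s)
            group = np.r_[np.ones(100, bool), np.zeros(100, bool)]
            lam = np.where(group, 3.0, 1.0)
            time = rng.exponential(1 / lam)
            event = np.ones(200)
            _chi2, p = logrank_statistic(time, event, group)
            if p < 0.01:
                hits += 1
        assert hits >= 19

    def test_degenerate_stratum_rejected(self):
        scores = pd.Series([1.0, 1.0, 1.0], index=["a", "b", "c"])
        ann = pd.DataFrame(
            {"sample_id": ["a", "b", "c"], "os_time": [1.0, 2.0, 3.0],
             "os_event": [1, 1, 1]}
        )
        with pytest.raises(ValueError):
            logrank_by_median(scores, ann)


class TestPermutationScreen:
    @staticmethod
    def _cfg(n_perm):
        return PipelineConfig(rng_seed=0, n_survival_perms=n_perm)

    def test_perm_p_formula_floor(self):
        """With 19 permutations and no exceedances, p = (1+0)/20 = 0.05."""
        sim = SimConfig(
            seed=21, samples_per_cohort=200, censor_rate=0.0,
            prognostic_pairs=[(("ICP001", "LNC001"), 2.0)], response_pairs=[],
        )
        m, ann, _ = simulate_tumor_cohort(sim, "C")
        rm = permutation_screen(
            m, ann, ("ICP001", "LNC001"), self._cfg(19), cohort="C"
        )
        assert rm.perm_p == pytest.approx(0.05)
        assert not rm.prognostic  # 0.05 is not < 0.05

    def test_planted_pair_flagged(self):
        sim = SimConfig(
            seed=22, samples_per_cohort=250,
            prognostic_pairs=[(("ICP001", "LNC001"), 1.0)], response_pairs=[],
        )
        m, ann, _ = simulate_tumor_cohort(sim, "C")
        rm = permutation_screen(
            m, ann, ("ICP001", "LNC001"), self._cfg(99), cohort="C"
        )
        assert rm.prognostic
        assert rm.n_train + rm.n_test == 250

    def test_invariant_to_time_unit(self):
        sim = SimConfig(seed=23, samples_per_cohort=150)
        m, ann, _ = simulate_tumor_cohort(sim, "C")
        rm_days = permutation_screen(
            m, ann, ("ICP001", "LNC001"), self._cfg(49), cohort="C"
        )
        ann_months = ann.copy()
        ann_months["os_time"] = ann_months["os_time"] / 30.4
        rm_months = permutation_screen(
            m, ann_months, ("ICP001", "LNC001"), self._cfg(49), cohort="C"
        )
        assert rm_days.perm_p == rm_months.perm_p
        assert rm_days.logrank_chi2 == pytest.approx(
            rm_months.logrank_chi2, abs=1e-9
        )


class TestCrossCohortSummary:
    @staticmethod
    def _model(pair, cohort, prognostic):
        return RiskModel(
            cohort=cohort, pair=pair, beta_icp=0.5, beta_lnc=0.5,
            beta_age=0.0, beta_sex=0.0,
            heldout_scores=pd.Series(dtype=float),
            logrank_chi2=4.0, logrank_p=0.04, perm_p=0.02 if prognostic else 0.5,
            prognostic=prognostic, n_train=50, n_test=50, n_perm_used=100,
        )

    def test_counts(self):
        models = [
            self._model(("I1", "L1"), c, True) for c in ("A", "B", "C")
        ] + [self._model(("I2", "L2"), "A", True),
             self._model(("I2", "L2"), "B", False)]
        table, hist = cross_cohort_summary(models)
        row = table[table["icp"] == "I1"].iloc[0]
        assert row["n_cohorts"] == 3
        assert table[table["icp"] == "I2"].iloc[0]["n_cohorts"] == 1
        assert hist.loc[1] == 1 and hist.loc[3] == 1

    def test_no_prognostic_pairs_empty_with_header(self):
        models = [self._model(("I1", "L1"), "A", False)]
        table, hist = cross_cohort_summary(models)
        assert len(table) == 0
        assert list(table.columns) == ["icp", "lnc", "cohorts", "n_cohorts"]

    def test_counts_match_flag_recount(self):
        rng = np.random.default_rng(9)
        models = []
        for c in "ABCD":
            for i in range(6):
                models.append(
                    self._model((f"I{i}", f"L{i}"), c, bool(rng.random() < 0.5))
                )
        table, _ = cross_cohort_summary(models)
        for _, row in table.iterrows():
            expect = sum(
                1 for rm in models
                if rm.pair == (row["icp"], row["lnc"]) and rm.prognostic
            )
            assert row["n_cohorts"] == expect
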
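"""Response prediction: pair scores, SVM, LASSO, ROC, Fisher exact."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icplnc import (
    ExpressionMatrix,
    GeneSetCatalog,
    PipelineConfig,
    compare_predictions_to_icr,
    fisher_exact_2x2,
    lasso_select,
    pair_mean_features,
    pair_set_score,
    roc_auc,
    simulate_tumor_cohort,
    ssgsea_score,
    train_svm,
)
from icplnc.infiltration import IcrGrouping
from icplnc.simulate import SimConfig


def _matrix(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(values, genes, samples)


class TestPairSetScore:
    def test_degenerate_range_maps_to_zero(self):
        values = np.tile(np.arange(6.0)[:, None], (1, 4))
        m = _matrix(values)
        cfg = PipelineConfig()
        scores = pair_set_score(m, [("G0", "G1")], cfg)
        assert (scores == 0.0).all()

    def test_top_ranked_genes_score_higher(self, rng):
        n_genes = 30
        base = rng.normal(5, 1, size=(n_genes, 2))
        base[:2, 0] = 12.0   # pair genes at the top in sample 0
        base[:2, 1] = -2.0   # and at the bottom in sample 1
        m = _matrix(base)
        scores = pair_set_score(m, [("G0", "G1")], PipelineConfig())
        assert scores["S0"] > scores["S1"]

    def test_matches_recomputed_ssgsea_plus_minmax(self, rng):
        m = _matrix(rng.normal(size=(40, 8)))
        pairs = [("G0", "G1"), ("G5", "G9")]
        cfg = PipelineConfig()
        got = pair_set_score(m, pairs, cfg)
        raw = ssgsea_score(
            m, GeneSetCatalog({"u": ["G0", "G1", "G5", "G9"]}),
            weight=cfg.ssgsea_weight,
        ).series("u")
        want = (raw - raw.min()) / (raw.max() - raw.min())
        np.testing.assert_allclose(got.to_numpy(), want.to_numpy(), atol=1e-9)

    def test_no_overlap_rejected(self, rng):
        m = _matrix(rng.normal(size=(4, 3)))
        with pytest.raises(ValueError):
            pair_set_score(m, [("ZZ", "YY")], PipelineConfig())


class TestSvm:
    def test_separable_blobs_perfect_training_accuracy(self, rng):
        n = 50
        X = np.r_[rng.normal(0, 1, size=(n, 2)), rng.normal(6, 1, size=(n, 2))]
        y = np.r_[np.zeros(n), np.ones(n)]
        feats = pd.DataFrame(X, columns=["f0", "f1"])
        model = train_svm(feats, y, PipelineConfig())
        pred = model.decision_scores(feats) > 0
        assert (pred.to_numpy() == y.astype(bool)).all()

    def test_shuffled_labels_give_chance_auc(self):
        aucs = []
        for s in range(20):
            rng = np.random.default_rng(300 + s)
            X = rng.normal(size=(120, 3))
            y = rng.integers(0, 2, size=120)
            feats = pd.DataFrame(X, columns=["a", "b", "c"])
            model = train_svm(feats.iloc[:80], y[:80], PipelineConfig())
            scores = model.decision_scores(feats.iloc[80:])
            aucs.append(roc_auc(scores.to_numpy(), y[80:]).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_affine_feature_rescaling_invariance(self, rng):
        X = rng.normal(size=(60, 2))
        y = (X[:, 0] + rng.normal(0, 0.5, 60) > 0).astype(int)
        feats = pd.DataFrame(X, columns=["a", "b"])
        cfg = PipelineConfig()
        m1 = train_svm(feats, y, cfg)
        feats2 = feats.copy()
        feats2["a"] = feats2["a"] * 250.0 - 7.0
        m2 = train_svm(feats2, y, cfg)
        p1 = m1.decision_scores(feats)
        p2 = m2.decision_scores(feats2)
        np.testing.assert_allclose(p1.to_numpy(), p2.to_numpy(), atol=1e-6)

    def test_single_class_rejected(self, rng):
        feats = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        with pytest.raises(ValueError):
            train_svm(feats, np.ones(20), PipelineConfig())

    def test_synthetic_response_cohorts_auc(self):
        """Train on one cohort, test on another; planted weight 2.0."""
        sim = SimConfig(seed=30, samples_per_cohort=250)
        m1, a1, t1 = simulate_tumor_cohort(sim, "TRAIN")
        m2, a2, _ = simulate_tumor_cohort(sim, "TEST")
        resp = [(p.icp, p.lnc) for p in t1.planted_pairs if p.response_weight]
        cfg = PipelineConfig()
        model = train_svm(
            pair_mean_features(m1, resp),
            a1.set_index("sample_id").loc[m1.sample_ids, "ici_response"],
            cfg,
        )
        scores = model.decision_scores(pair_mean_features(m2, resp))
        labels = a2.set_index("sample_id").loc[m2.sample_ids, "ici_response"]
        assert roc_auc(scores.to_numpy(), labels.to_numpy()).auc >= 0.85


class TestLasso:
    @staticmethod
    def _informative_problem(rng, n=300, n_noise=47):
        X_inf = rng.normal(size=(n, 3))
        X_noise = rng.normal(size=(n, n_noise))
        logit = 2.0 * X_inf.sum(axis=1)
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        cols = [f"inf{i}" for i in range(3)] + [f"noise{i}" for i in range(n_noise)]
        return pd.DataFrame(np.c_[X_inf, X_noise], columns=cols), y

    def test_recovers_informative_features(self, rng):
        feats, y = self._informative_problem(rng)
        model = lasso_select(feats, y, PipelineConfig())
        informative = [f for f in model.selected if f.startswith("inf")]
        noise = [f for f in model.selected if f.startswith("noise")]
        assert len(informative) >= 2
        assert len(noise) <= 5

    def test_infinite_penalty_empty_selection(self, rng):
        feats, y = self._informative_problem(rng, n=100, n_noise=5)
        model = lasso_select(feats, y, PipelineConfig(), Cs=[1e-10])
        assert model.empty_selection
        assert model.selected == []

    def test_duplicated_feature_does_not_change_auc(self, rng):
        feats, y = self._informative_problem(rng, n=250, n_noise=10)
        cfg = PipelineConfig()
        m1 = lasso_select(feats.iloc[:150], y[:150], cfg)
        feats_dup = feats.copy()
        feats_dup["inf0_copy"] = feats_dup["inf0"]
        m2 = lasso_select(feats_dup.iloc[:150], y[:150], cfg)
        auc1 = roc_auc(
            m1.decision_scores(feats.iloc[150:]).to_numpy(), y[150:]
        ).auc
        auc2 = roc_auc(
            m2.decision_scores(feats_dup.iloc[150:]).to_numpy(), y[150:]
        ).auc
        assert abs(auc1 - auc2) < 0.02


from oracles import auc_pair_counting, fisher_enumeration


class TestRocAuc:
    def test_perfect_separation(self):
        curve = roc_auc(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1]))
        assert curve.auc == 1.0

    def test_all_ties_give_half(self):
        curve = roc_auc(np.ones(6), np.array([0, 1, 0, 1, 0, 1]))
        assert curve.auc == 0.5

    def test_worked_example(self):
        curve = roc_auc(
            np.array([0.1, 0.4, 0.35, 0.8]), np.array([0, 0, 1, 1])
        )
        assert curve.auc == pytest.approx(0.75)
        assert curve.auc == pytest.approx(
            auc_pair_counting([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        )

    def test_curve_monotone_and_trapezoid_consistent(self, rng):
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, size=50)
        if labels.sum() in (0, 50):
            labels[0] = 1 - labels[0]
        curve = roc_auc(scores, labels)
        assert (np.diff(curve.fpr) >= -1e-12).all()
        assert (np.diff(curve.tpr) >= -1e-12).all()
        trapezoid = np.trapezoid(curve.tpr, curve.fpr)
        assert curve.auc == pytest.approx(trapezoid, abs=1e-12)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.tuples(st.floats(0, 1, allow_nan=False), st.integers(0, 1)),
            min_size=4,
            max_size=20,
        )
    )
    def test_matches_exhaustive_pair_counting(self, data):
        scores = np.array([d[0] for d in data])
        labels = np.array([d[1] for d in data])
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        got = roc_auc(scores, labels).auc
        assert got == pytest.approx(auc_pair_counting(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.9]), np.array([1, 1]))




class TestFisherExact:
    def test_balanced_table_p_one(self):
        _odds, p = fisher_exact_2x2(np.array([[1, 1], [1, 1]]))
        assert p == pytest.approx(1.0)

    def test_extreme_table_matches_enumeration(self):
        table = [[5, 0], [0, 5]]
        _odds, p = fisher_exact_2x2(np.array(table))
        assert p == pytest.approx(fisher_enumeration(table), abs=1e-12)
        assert p == pytest.approx(2 / math.comb(10, 5), abs=1e-9)

    def test_random_tables_match_enumeration(self, rng):
        for _ in range(30):
            t = rng.integers(1, 12, size=(2, 2))
            _odds, p = fisher_exact_2x2(t)
            assert p == pytest.approx(
                fisher_enumeration(t.tolist()), abs=1e-9
            )

    def test_transpose_invariance(self, rng):
        t = np.array([[7, 2], [3, 9]])
        assert fisher_exact_2x2(t)[1] == pytest.approx(
            fisher_exact_2x2(t.T)[1]
        )

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact_2x2(np.array([[0, 0], [3, 4]]))


class TestCompareToIcr:
    @staticmethod
    def _grouping(labels_dict):
        labels = pd.Series(labels_dict)
        n = len(labels)
        return IcrGrouping(
            labels=labels,
            consensus=pd.DataFrame(
                np.eye(n), index=labels.index, columns=labels.index
            ),
        )

    def test_identical_labels_concentrate_diagonal(self):
        samples = [f"S{i}" for i in range(12)]
        icr = {s: ("high" if i < 6 else "low") for i, s in enumerate(samples)}
        preds = pd.Series(
            ["responder" if icr[s] == "high" else "non_responder" for s in samples],
            index=samples,
        )
        table, (odds, p) = compare_predictions_to_icr(preds, self._grouping(icr))
        assert table.loc["responder", "low"] == 0
        assert table.loc["non_responder", "high"] == 0
        assert p < 0.01

    def test_counts_match_recount(self, rng):
        samples = [f"S{i}" for i in range(40)]
        icr = {s: ("high" if rng.random() < 0.5 else "low") for s in samples}
        preds = pd.Series(
            np.where(rng.random(40) < 0.5, "responder", "non_responder"),
            index=samples,
        )
        table, _ = compare_predictions_to_icr(preds, self._grouping(icr))
        for p_lab in ("responder", "non_responder"):
            for g in ("high", "low"):
                want = sum(
                    1 for s in samples if preds[s] == p_lab and icr[s] == g
                )
                assert table.loc[p_lab, g] == want

    def test_no_shared_samples_rejected(self):
        preds = pd.Series(["responder"], index=["X1"])
        with pytest.raises(ValueError):
            compare_predictions_to_icr(preds, self._grouping({"Y1": "high"}))
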
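"""Immunotherapy-response prediction from pair-level scores.

Samples are scored on accepted pair gene sets with the per-sample
enrichment statistic (min-max normalized to [0, 1] across samples), a
linear support-vector machine is trained to separate responders from
non-responders, an L1-penalized logistic regression distils the pair panel
to a few informative pairs, predictions are evaluated by ROC/AUC, and
predicted response is tested against the high/low ICR groups with the
two-sided Fisher exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .data import ExpressionMatrix, GeneSetCatalog, PipelineConfig, substream
from .infiltration import IcrGrouping, ssgsea_score

log = logging.getLogger("icplnc")


def pair_set_score(
    m: ExpressionMatrix,
    pairs: list[tuple[str, str]],
    cfg: PipelineConfig,
) -> pd.Series:
    """Comprehensive per-sample risk score of a pair panel.

    The per-sample enrichment score of the union of the pairs' member
    genes, min-max normalized across samples (a degenerate zero range maps
    every sample to 0).
    """
    if not pairs:
        raise ValueError("need at least one pair")
    union: list[str] = []
    for icp, lnc in pairs:
        for g in (icp, lnc):
            if g in m._gene_index and g not in union:
                union.append(g)
    if not union:
        raise ValueError("pair genes have no overlap with the matrix")
    scores = ssgsea_score(
        m, GeneSetCatalog({"pair_panel": union}), weight=cfg.ssgsea_weight
    ).series("pair_panel")
    if not cfg.normalize_pair_scores:
        return scores
    lo, hi = float(scores.min()), float(scores.max())
    if hi == lo:
        return pd.Series(0.0, index=scores.index)
    return (scores - lo) / (hi - lo)


def pair_mean_features(
    m: ExpressionMatrix, pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Per-pair mean-expression features (samples x pairs)."""
    cols = {}
    for icp, lnc in pairs:
        cols[f"{icp}|{lnc}"] = (m.gene(icp) + m.gene(lnc)) / 2.0
    return pd.DataFrame(cols, index=m.sample_ids)


@dataclass
class ResponseModel:
    """A fitted response classifier with its frozen feature recipe."""

    kind: str  # "svm" | "lasso"
    feature_names: list[str]
    scaler_means: np.ndarray
    scaler_sds: np.ndarray
    estimator: object
    threshold: float = 0.0
    empty_selection: bool = False
    selected: list[str] = field(default_factory=list)

    def _check(self, features: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in features.columns]
        if missing:
            raise ValueError(f"missing features at prediction time: {missing}")
        X = features[self.feature_names].to_numpy(float)
        return (X - self.scaler_means) / self.scaler_sds

    def decision_scores(self, features: pd.DataFrame) -> pd.Series:
        X = self._check(features)
        if self.kind == "svm":
            s = self.estimator.decision_function(X)
        else:
            s = self.estimator.predict_proba(X)[:, 1]
        return pd.Series(s, index=features.index)

    def predict_labels(self, features: pd.DataFrame) -> pd.Series:
        s = self.decision_scores(features)
        cut = self.threshold
        return pd.Series(
            np.where(s > cut, "responder", "non_responder"), index=s.index
        )


def _encode_labels(labels: pd.Series | np.ndarray) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "OUS":
        y = (arr == "responder").astype(int)
    else:
        y = arr.astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both response classes must be present")
    return y


def _frozen_scaler(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    sds[sds == 0] = 1.0
    return means, sds


def train_svm(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    cfg: PipelineConfig,
) -> ResponseModel:
    """Linear soft-margin SVM on standardized features.

    Features are standardized with statistics frozen from the training
    samples; responder calls use the sign of the decision function.
    """
    y = _encode_labels(labels)
    if len(y) < 10:
        raise ValueError("need at least 10 training samples")
    X = features.to_numpy(float)
    means, sds = _frozen_scaler(X)
    clf = SVC(
        kernel="linear",
        C=cfg.svm_c,
        random_state=int(substream(cfg.rng_seed, "svm").integers(2**31 - 1)),
    )
    clf.fit((X - means) / sds, y)
    return ResponseModel(
        kind="svm",
        feature_names=list(features.columns),
        scaler_means=means,
        scaler_sds=sds,
        estimator=clf,
        threshold=0.0,
    )


def lasso_select(
    pair_features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    cfg: PipelineConfig,
    Cs: np.ndarray | list[float] | None = None,
) -> ResponseModel:
    """L1-penalized logistic regression with cross-validated penalty.

    The penalty grid is scored by stratified k-fold cross-validated
    deviance; the chosen penalty follows the one-standard-error rule (the
    strongest penalty whose mean CV deviance is within one standard error
    of the minimum), favouring parsimonious panels.  Selected pairs are
    the features with nonzero coefficients in the full-data refit that
    were also nonzero in every CV training fold at the chosen penalty
    (fold-stability filter: spurious features tend to be fold-specific).
    An all-zero selection is flagged (``empty_selection``), not an error.
    Responder calls use probability 0.5.
    """
    y = _encode_labels(labels)
    if pair_features.shape[1] < 2:
        raise ValueError("need at least 2 candidate pair features")
    X = pair_features.to_numpy(float)
    means, sds = _frozen_scaler(X)
    Z = (X - means) / sds
    seed = int(substream(cfg.rng_seed, "lasso").integers(2**31 - 1))
    grid = np.logspace(-3, 2, 20) if Cs is None else np.asarray(Cs, float)
    grid = np.sort(grid)  # ascending C = descending penalty strength
    splitter = StratifiedKFold(
        cfg.lasso_cv_folds, shuffle=True, random_state=seed
    )
    folds = list(splitter.split(Z, y))
    deviance = np.zeros((len(grid), len(folds)))
    fold_nonzero = np.zeros((len(grid), Z.shape[1]))
    eps = 1e-12
    for j, c in enumerate(grid):
        for f, (tr, te) in enumerate(folds):
            fit = LogisticRegression(
                l1_ratio=1.0, C=c, solver="liblinear", max_iter=2000,
                random_state=seed,
            ).fit(Z[tr], y[tr])
            p = np.clip(fit.predict_proba(Z[te])[:, 1], eps, 1 - eps)
            deviance[j, f] = -2.0 * np.mean(
                y[te] * np.log(p) + (1 - y[te]) * np.log(1 - p)
            )
            fold_nonzero[j] += (fit.coef_.ravel() != 0.0)
    mean_dev = deviance.mean(axis=1)
    se_dev = deviance.std(axis=1, ddof=1) / np.sqrt(len(folds))
    best = int(np.argmin(mean_dev))
    within = np.flatnonzero(mean_dev <= mean_dev[best] + se_dev[best])
    j_chosen = int(within[0])  # smallest C within one SE of the best
    clf = LogisticRegression(
        l1_ratio=1.0, C=grid[j_chosen], solver="liblinear", max_iter=2000,
        random_state=seed,
    ).fit(Z, y)
    coefs = clf.coef_.ravel()
    stable = fold_nonzero[j_chosen] == len(folds)
    selected = [
        f
        for f, c, s in zip(pair_features.columns, coefs, stable)
        if c != 0.0 and s
    ]
    if not selected:
        log.warning("LASSO shrank every coefficient to zero")
    return ResponseModel(
        kind="lasso",
        feature_names=list(pair_features.columns),
        scaler_means=means,
        scaler_sds=sds,
        estimator=clf,
        threshold=0.5,
        empty_selection=not selected,
        selected=selected,
    )


@dataclass
class RocCurve:
    """Threshold-sweep ROC points and the tie-aware AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """ROC curve by threshold sweep; AUC via the Mann–Whitney statistic.

    AUC equals the fraction of (positive, negative) score pairs correctly
    ordered, with ties credited 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    y = _encode_labels(labels)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    order = np.argsort(-scores, kind="stable")
    ys = y[order]
    ss = scores[order]
    tp = np.cumsum(ys)
    fp = np.cumsum(1 - ys)
    # keep one point per distinct threshold (last index of each run)
    keep = np.r_[ss[1:] != ss[:-1], True]
    tpr = np.r_[0.0, tp[keep] / n_pos]
    fpr = np.r_[0.0, fp[keep] / n_neg]
    ranks = stats.rankdata(scores)  # average ranks: 0.5 credit on ties
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return RocCurve(fpr=fpr, tpr=tpr, auc=float(auc))


def fisher_exact_2x2(table: np.ndarray) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 contingency table.

    p sums the hypergeometric probabilities of all tables (at fixed
    margins) no more probable than the observed one.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("table entries must be integers")
        t = np.round(t).astype(int)
    if (t < 0).any():
        raise ValueError("table entries must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("every margin must be positive")
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return float(odds), float(p)


def compare_predictions_to_icr(
    predictions: pd.Series, grouping: IcrGrouping
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Cross-tabulate predicted response against ICR groups; Fisher test."""
    shared = [s for s in predictions.index if s in grouping.labels.index]
    if not shared:
        raise ValueError("no shared samples between predictions and grouping")
    pred = predictions.loc[shared]
    icr = grouping.labels.loc[shared]
    table = pd.DataFrame(
        0,
        index=["responder", "non_responder"],
        columns=["high", "low"],
    )
    for p, g in zip(pred, icr):
        table.loc[p, g] += 1
    return table, fisher_exact_2x2(table.to_numpy())
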
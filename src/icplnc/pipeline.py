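"""End-to-end orchestration of the discovery pipeline on a simulated study.

Runs the full chain the way it would run on real cohorts: immune-cell
panel -> high-expression screen; per tumor cohort: infiltration scoring ->
top-75% selection -> ICR consensus grouping -> differential expression ->
pair screen -> network/hubs -> permutation survival screen; across
cohorts: hub classification, similarity matrices, cross-cohort prognostic
summary; and response prediction trained on the first cohort and evaluated
on the second.  Also computes recovery metrics against the planted truth,
which is what the acceptance checks consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .data import PipelineConfig
from .immune import (
    ImmuneHighSets,
    adjust_batches,
    quantile_normalize,
    rank_by_cell_type,
    select_immune_high,
)
from .infiltration import (
    IcrGrouping,
    consensus_cluster_icr,
    differential_expression,
    select_high_infiltration,
    ssgsea_score,
)
from .network import (
    build_network,
    classify_hubs,
    extract_hubs,
    similarity_matrices,
)
from .pairs import PairTable, coincidence_rate, extract_pairs
from .response import (
    lasso_select,
    pair_mean_features,
    pair_set_score,
    roc_auc,
    train_svm,
)
from .simulate import SimConfig, simulate_immune_panel, simulate_tumor_cohort
from .survival import RiskModel, cross_cohort_summary, permutation_screen

log = logging.getLogger("icplnc")


@dataclass
class CohortResult:
    cohort: str
    kept_samples: list[str]
    grouping: IcrGrouping
    de_icps: list[str]
    de_lncs: list[str]
    pair_table: PairTable
    network: nx.Graph
    hubs: set[str]
    coincidence: float | None
    risk_models: list[RiskModel]


@dataclass
class StudyResult:
    immune_sets: ImmuneHighSets
    cohorts: dict[str, CohortResult]
    hub_classes: pd.DataFrame | None
    similarity: dict[str, pd.DataFrame] | None
    prognostic_summary: pd.DataFrame
    response_auc: float | None
    lasso_selected: list[str]
    icr_fisher_p: float | None
    metrics: dict[str, float] = field(default_factory=dict)


def run_cohort(
    matrix, ann, truth, cfg: PipelineConfig, cohort: str,
    candidate_icps: list[str], candidate_lncs: list[str],
) -> CohortResult:
    """Run the within-cohort chain from infiltration scoring to survival."""
    scores = ssgsea_score(matrix, truth.gene_sets, weight=cfg.ssgsea_weight)
    kept = select_high_infiltration(scores, "IMMUNE_SIGNATURE", cfg)
    sub = matrix.subset(samples=kept)
    grouping = consensus_cluster_icr(
        sub.subset(genes=truth.gene_sets["ICR"]), cfg
    )
    icps = [g for g in candidate_icps if g in sub._gene_index]
    lncs = [g for g in candidate_lncs if g in sub._gene_index]
    de = differential_expression(
        sub.subset(genes=icps + lncs), grouping, cfg
    )
    de_icps = [g for g in de.genes() if g in icps]
    de_lncs = [g for g in de.genes() if g in lncs]
    if not de_icps or not de_lncs:
        raise ValueError(f"cohort {cohort}: no differential candidates")
    pt = extract_pairs(sub, de_icps, de_lncs, cfg, cohort=cohort)
    net = build_network(pt, cohort)
    hubs = extract_hubs(net, cfg) if net.number_of_nodes() else set()
    try:
        coinc = coincidence_rate(pt)
    except ValueError:
        coinc = None
    risk_models = [
        permutation_screen(sub, ann, pair, cfg, cohort=cohort)
        for pair in sorted(pt.accepted_set())
    ]
    return CohortResult(
        cohort=cohort,
        kept_samples=kept,
        grouping=grouping,
        de_icps=de_icps,
        de_lncs=de_lncs,
        pair_table=pt,
        network=net,
        hubs=hubs,
        coincidence=coinc,
        risk_models=risk_models,
    )


def run_study(sim: SimConfig, cfg: PipelineConfig) -> StudyResult:
    """Simulate and analyse a full multi-cohort study; score recovery."""
    panel, panel_ann, panel_truth = simulate_immune_panel(sim)
    panel = adjust_batches(quantile_normalize(panel), panel_ann)
    ranks = rank_by_cell_type(panel, panel_ann, panel_truth.gene_classes)
    immune_sets = select_immune_high(ranks, cfg)
    candidate_icps = immune_sets.high_icps
    candidate_lncs = immune_sets.selected_lncs

    cohort_ids = [f"COHORT{i + 1}" for i in range(sim.n_cohorts)]
    cohorts: dict[str, CohortResult] = {}
    tumor_data = {}
    for cid in cohort_ids:
        matrix, ann, truth = simulate_tumor_cohort(sim, cid)
        tumor_data[cid] = (matrix, ann, truth)
        cohorts[cid] = run_cohort(
            matrix, ann, truth, cfg, cid, candidate_icps, candidate_lncs
        )

    hub_classes = None
    similarity = None
    if len(cohorts) >= 2:
        hub_sets = {c: r.hubs for c, r in cohorts.items()}
        nets = {c: r.network for c, r in cohorts.items()}
        if all(hub_sets.values()):
            hub_classes = classify_hubs(hub_sets, nets, cfg).table
        similarity = similarity_matrices(
            {c: r.pair_table for c, r in cohorts.items()}, cfg
        )

    all_models = [rm for r in cohorts.values() for rm in r.risk_models]
    prognostic_summary, _hist = cross_cohort_summary(all_models)

    response_auc = None
    icr_fisher_p = None
    lasso_selected: list[str] = []
    if len(cohorts) >= 2:
        train_id, test_id = cohort_ids[0], cohort_ids[1]
        response_auc, icr_fisher_p, lasso_selected = _response_stage(
            cohorts, tumor_data, train_id, test_id, cfg
        )

    truth0 = tumor_data[cohort_ids[0]][2]
    metrics = _recovery_metrics(sim, cohorts, truth0, response_auc)
    return StudyResult(
        immune_sets=immune_sets,
        cohorts=cohorts,
        hub_classes=hub_classes,
        similarity=similarity,
        prognostic_summary=prognostic_summary,
        response_auc=response_auc,
        lasso_selected=lasso_selected,
        icr_fisher_p=icr_fisher_p,
        metrics=metrics,
    )


def _response_stage(cohorts, tumor_data, train_id, test_id, cfg):
    """LASSO pair selection + SVM on the training cohort, held-out AUC."""
    train_res = cohorts[train_id]
    m_tr, ann_tr, _ = tumor_data[train_id]
    m_te, ann_te, _ = tumor_data[test_id]
    cand_pairs = sorted(train_res.pair_table.accepted_set())
    if not cand_pairs:
        return None, None, []
    kept_tr = train_res.kept_samples
    sub_tr = m_tr.subset(samples=kept_tr)
    labels_tr = (
        ann_tr.set_index("sample_id").loc[kept_tr, "ici_response"]
    )
    feats_tr = pair_mean_features(sub_tr, cand_pairs)
    lasso = lasso_select(feats_tr, labels_tr, cfg)
    selected = (
        [tuple(f.split("|")) for f in lasso.selected]
        if lasso.selected
        else cand_pairs
    )
    svm_feats_tr = _svm_features(sub_tr, selected, cfg)
    svm = train_svm(svm_feats_tr, labels_tr, cfg)

    kept_te = cohorts[test_id].kept_samples
    sub_te = m_te.subset(samples=kept_te)
    labels_te = ann_te.set_index("sample_id").loc[kept_te, "ici_response"]
    svm_feats_te = _svm_features(sub_te, selected, cfg)
    decision = svm.decision_scores(svm_feats_te)
    auc = roc_auc(decision.to_numpy(), labels_te.to_numpy()).auc

    icr_p = None
    try:
        from .response import compare_predictions_to_icr

        preds = svm.predict_labels(svm_feats_te)
        _tab, (_odds, icr_p) = compare_predictions_to_icr(
            preds, cohorts[test_id].grouping
        )
    except ValueError:
        pass
    return auc, icr_p, lasso.selected


def _svm_features(matrix, pairs, cfg: PipelineConfig) -> pd.DataFrame:
    """Assemble the configured SVM feature recipe on one cohort."""
    frames = []
    if cfg.svm_features in ("aggregate", "both"):
        frames.append(
            pair_set_score(matrix, pairs, cfg).rename("pair_panel_score").to_frame()
        )
    if cfg.svm_features in ("pairs", "both"):
        frames.append(pair_mean_features(matrix, pairs))
    return pd.concat(frames, axis=1)


def _recovery_metrics(sim, cohorts, truth, response_auc):
    planted = {(p.icp, p.lnc) for p in truth.planted_pairs}
    prognostic = {
        (p.icp, p.lnc) for p in truth.planted_pairs if p.hazard_beta != 0
    }
    recalls, null_rates, coincs = [], [], []
    for r in cohorts.values():
        accepted = r.pair_table.accepted_set()
        evaluated = set(
            zip(r.pair_table.table["icp"], r.pair_table.table["lnc"])
        )
        planted_eval = planted & evaluated
        if planted_eval:
            recalls.append(len(accepted & planted_eval) / len(planted))
        null_eval = evaluated - planted
        if null_eval:
            null_rates.append(len(accepted & null_eval) / len(null_eval))
        if r.coincidence is not None:
            coincs.append(r.coincidence)
    flagged = set()
    screened = set()
    for r in cohorts.values():
        for rm in r.risk_models:
            if rm.pair in prognostic:
                screened.add((r.cohort, rm.pair))
                if rm.prognostic:
                    flagged.add((r.cohort, rm.pair))
    metrics: dict[str, float] = {}
    if recalls:
        metrics["planted_pair_recall"] = sum(recalls) / len(recalls)
    if null_rates:
        metrics["null_pair_acceptance"] = sum(null_rates) / len(null_rates)
    if coincs:
        metrics["coincidence_rate"] = sum(coincs) / len(coincs)
    if screened:
        metrics["prognostic_flag_rate"] = len(flagged) / len(screened)
    if response_auc is not None:
        metrics["response_auc"] = response_auc
    return metrics
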
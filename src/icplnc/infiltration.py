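"""Immune-infiltration scoring, ICR grouping and differential expression.

Tumor samples are scored per sample with a rank-based single-sample
gene-set enrichment statistic (ssGSEA), the top 75% by immune score are
retained, and the retained samples are split into high and low immune
groups by consensus clustering of the 20-gene immunologic-constant-of-
rejection (ICR) panel.  Immune-related checkpoints and lncRNAs are then
screened by Welch t-test / fold change between the two ICR groups.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .data import (
    ExpressionMatrix,
    GeneSetCatalog,
    PipelineConfig,
    substream,
)

log = logging.getLogger("icplnc")


# ---------------------------------------------------------------------------
# ssGSEA
# ---------------------------------------------------------------------------


@dataclass
class SsgseaScores:
    """(sample, set) -> enrichment score; samples as rows."""

    scores: pd.DataFrame

    def series(self, set_name: str) -> pd.Series:
        return self.scores[set_name]


def ssgsea_score(
    m: ExpressionMatrix, sets: GeneSetCatalog, weight: float = 0.25
) -> SsgseaScores:
    """Per-sample gene-set enrichment by the weighted rank running sum.

    For each sample, genes are ranked by expression (rank N = highest, ties
    broken by gene id so the score is deterministic).  Walking the gene
    list in decreasing rank order, the score is the sum over all positions
    of the difference between the weighted empirical distribution of in-set
    ranks (weights rank^``weight``, normalized over the set) and the
    unweighted distribution of out-of-set genes.  The score depends on the
    sample's ranks only, so it is invariant under strictly monotone
    transforms of that sample's values.
    """
    n = m.n_genes
    gene_arr = np.array(m.gene_ids)
    masks: dict[str, np.ndarray] = {}
    for name in sets:
        members = set(sets[name])
        mask = np.isin(gene_arr, list(members))
        k = int(mask.sum())
        if k == 0:
            raise ValueError(f"gene set {name!r} has no overlap with the matrix")
        if k == n:
            raise ValueError(
                f"gene set {name!r} covers every gene (empty out-set)"
            )
        masks[name] = mask

    out = np.empty((m.n_samples, len(masks)))
    # order genes descending by value, ties by gene id ascending
    gene_rank_key = np.argsort(gene_arr)  # for deterministic tie-breaks
    tie_rank = np.empty(n)
    tie_rank[gene_rank_key] = np.arange(n)
    for s in range(m.n_samples):
        vals = m.values[:, s]
        order = np.lexsort((tie_rank, -vals))  # descending value
        ranks_desc = np.arange(n, 0, -1, dtype=float)  # rank of gene at walk pos
        for j, name in enumerate(masks):
            in_set = masks[name][order]
            w = np.where(in_set, ranks_desc**weight, 0.0)
            p_in = np.cumsum(w) / w.sum()
            p_out = np.cumsum(~in_set) / (n - in_set.sum())
            out[s, j] = float(np.sum(p_in - p_out))
    return SsgseaScores(
        pd.DataFrame(out, index=m.sample_ids, columns=list(masks))
    )


# ---------------------------------------------------------------------------
# High-infiltration sample selection
# ---------------------------------------------------------------------------


def select_high_infiltration(
    scores: SsgseaScores, set_name: str, cfg: PipelineConfig
) -> list[str]:
    """Retain samples in the top fraction of immune scores (75% default).

    The cut point is the (floor((1-f)*n)+1)-th smallest score (nearest rank,
    lower boundary); ties at the boundary are retained, so all samples are
    kept when every score is equal.
    """
    s = scores.series(set_name)
    n = len(s)
    if n < 4:
        raise ValueError("need at least 4 samples to select by infiltration")
    k = math.floor((1.0 - cfg.immune_score_quantile) * n) + 1
    threshold = np.sort(s.to_numpy())[k - 1]
    kept = [sid for sid, v in s.items() if v >= threshold]
    log.info(
        "infiltration screen: kept %d of %d samples (score >= %.4g)",
        len(kept), n, threshold,
    )
    return kept


# ---------------------------------------------------------------------------
# Consensus clustering on the ICR panel
# ---------------------------------------------------------------------------


@dataclass
class IcrGrouping:
    """High/low immune-activation labels with the consensus matrix."""

    labels: pd.Series  # sample_id -> "high" | "low"
    consensus: pd.DataFrame  # samples x samples in [0, 1]
    k: int = 2

    def samples(self, group: str) -> list[str]:
        return list(self.labels.index[self.labels == group])


def consensus_cluster_icr(
    m: ExpressionMatrix, cfg: PipelineConfig
) -> IcrGrouping:
    """Split samples into high/low ICR groups by resampled k-means.

    Runs ``consensus_resamples`` rounds, each drawing a fraction
    ``consensus_subsample`` of samples without replacement and clustering
    gene-standardized ICR expression with k-means (k=2).  The consensus
    entry for a sample pair is the fraction of co-drawn rounds in which the
    pair co-clustered.  Final labels come from average-linkage hierarchical
    clustering of 1 - consensus cut at two groups; the group with higher
    mean ICR expression is labelled "high".
    """
    if m.n_genes < 2:
        raise ValueError("need at least 2 ICR genes for consensus clustering")
    n = m.n_samples
    if n < 8:
        raise ValueError("need at least 8 samples for consensus clustering")
    rng = substream(cfg.rng_seed, "consensus")
    sd = m.values.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    X = ((m.values - m.values.mean(axis=1, keepdims=True)) / sd[:, None]).T

    co_cluster = np.zeros((n, n))
    co_drawn = np.zeros((n, n))
    size = max(2, int(math.floor(cfg.consensus_subsample * n)))
    for _ in range(cfg.consensus_resamples):
        idx = rng.choice(n, size=size, replace=False)
        km = KMeans(
            n_clusters=2,
            n_init=10,
            random_state=int(rng.integers(2**31 - 1)),
        )
        lab = km.fit_predict(X[idx])
        drawn = np.zeros(n, dtype=bool)
        drawn[idx] = True
        co_drawn += np.outer(drawn, drawn)
        for c in (0, 1):
            members = idx[lab == c]
            sel = np.zeros(n, dtype=bool)
            sel[members] = True
            co_cluster += np.outer(sel, sel)
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(co_drawn > 0, co_cluster / co_drawn, 0.0)
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2.0

    dist = squareform(1.0 - consensus, checks=False)
    labels_num = fcluster(linkage(dist, method="average"), 2, criterion="maxclust")
    if len(np.unique(labels_num)) < 2:
        raise ValueError("consensus clustering produced a single group")
    mean_by_group = {
        c: m.values[:, labels_num == c].mean() for c in np.unique(labels_num)
    }
    high_group = max(mean_by_group, key=mean_by_group.get)
    labels = pd.Series(
        np.where(labels_num == high_group, "high", "low"), index=m.sample_ids
    )
    return IcrGrouping(
        labels=labels,
        consensus=pd.DataFrame(consensus, index=m.sample_ids, columns=m.sample_ids),
    )


# ---------------------------------------------------------------------------
# Differential expression between ICR groups
# ---------------------------------------------------------------------------


@dataclass
class DeTable:
    """Per-gene fold change (linear scale, high/low) and Welch-t p-value."""

    table: pd.DataFrame  # index gene_id; columns fold_change, p, direction

    def genes(self, direction: str | None = None) -> list[str]:
        t = self.table
        if direction is None:
            t = t[t["direction"] != "ns"]
        else:
            t = t[t["direction"] == direction]
        return list(t.index)


def differential_expression(
    m: ExpressionMatrix, grouping: IcrGrouping, cfg: PipelineConfig
) -> DeTable:
    """Welch two-sample t-test per gene between high and low ICR groups.

    Values are log2, so the linear fold change is 2**(mean_high - mean_low).
    Direction is "up" when fold_change > 1 and p < alpha, "down" when
    fold_change < 1 and p < alpha, "ns" otherwise.
    """
    high = [s for s in grouping.samples("high") if s in m._sample_index]
    low = [s for s in grouping.samples("low") if s in m._sample_index]
    if len(high) < 2 or len(low) < 2:
        raise ValueError("both ICR groups need at least 2 samples")
    hi = m.subset(samples=high).values
    lo = m.subset(samples=low).values
    t_stat, p = stats.ttest_ind(hi, lo, axis=1, equal_var=False)
    delta = hi.mean(axis=1) - lo.mean(axis=1)
    fold = np.exp2(delta)
    direction = np.where(
        (p < cfg.alpha) & (fold > 1.0),
        "up",
        np.where((p < cfg.alpha) & (fold < 1.0), "down", "ns"),
    )
    return DeTable(
        pd.DataFrame(
            {"fold_change": fold, "p": p, "direction": direction},
            index=m.gene_ids,
        )
    )
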
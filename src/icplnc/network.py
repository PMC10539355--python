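"""Bipartite checkpoint–lncRNA networks, hubs and cross-cohort similarity.

Accepted pairs in a cohort form a bipartite graph (checkpoints on one
side, lncRNAs on the other).  Degree distributions are summarised by an
ordinary least-squares fit on the log–log degree/frequency points (the
scale-free R^2), hubs are the top 5% of nodes by degree (boundary ties
included), and hubs are classified across cohorts as common (hub in more
than five cohorts), specific (hub in exactly one) or other.  Cohort
similarity matrices count shared checkpoints, lncRNAs and pairs,
normalised by the smaller set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .data import PipelineConfig
from .pairs import PairTable

log = logging.getLogger("icplnc")


def build_network(pt: PairTable, cohort: str) -> nx.Graph:
    """Bipartite graph of one cohort's accepted pairs.

    Nodes carry a ``side`` attribute ("ICP" or "lncRNA"); each accepted
    pair is one edge annotated with its correlation sign.
    """
    g = nx.Graph(cohort=cohort)
    acc = pt.accepted()
    acc = acc[acc["cohort"] == cohort] if "cohort" in acc else acc
    for row in acc.itertuples():
        g.add_node(row.icp, side="ICP")
        g.add_node(row.lnc, side="lncRNA")
        g.add_edge(row.icp, row.lnc, sign=row.sign, r=row.r)
    return g


def powerlaw_fit_r2(net: nx.Graph) -> float:
    """R^2 of the OLS line through log10(frequency) vs log10(degree).

    One point per observed degree value; requires at least three distinct
    degrees.
    """
    degrees = np.array([d for _, d in net.degree()])
    degrees = degrees[degrees > 0]
    values, counts = np.unique(degrees, return_counts=True)
    if len(values) < 3:
        raise ValueError(
            f"power-law fit needs >=3 distinct degrees, got {len(values)}"
        )
    res = stats.linregress(np.log10(values), np.log10(counts))
    return float(res.rvalue**2)


def extract_hubs(net: nx.Graph, cfg: PipelineConfig) -> set[str]:
    """Top 5% of nodes by degree, including boundary ties.

    k = ceil((1 - hub_quantile) * n_nodes); the cut is the k-th largest
    degree and every node at or above it is a hub.
    """
    if net.number_of_nodes() < 1:
        raise ValueError("cannot extract hubs from an empty network")
    deg = dict(net.degree())
    # tiny epsilon guards against float noise in (1 - quantile) * n
    k = max(1, math.ceil((1.0 - cfg.hub_quantile) * len(deg) - 1e-9))
    threshold = sorted(deg.values(), reverse=True)[k - 1]
    return {node for node, d in deg.items() if d >= threshold}


@dataclass
class HubClassification:
    """Common/specific/other labels over the union of per-cohort hub sets."""

    table: pd.DataFrame  # index node; columns side, class, n_cohorts,
    #                      cohorts, max_degree, mean_degree

    def nodes_of(self, cls: str) -> list[str]:
        return list(self.table.index[self.table["class"] == cls])


def classify_hubs(
    hub_sets: dict[str, set[str]],
    networks: dict[str, nx.Graph],
    cfg: PipelineConfig,
) -> HubClassification:
    """Classify hubs across cohorts.

    A node is a common hub when it is a hub in at least
    ``common_hub_min_cancers`` cohorts (more than five by default), a
    specific hub when in exactly one, otherwise "other".  Max and mean
    degree are aggregated over the cohorts where the node is a hub.
    """
    if not hub_sets:
        raise ValueError("need at least one cohort")
    rows = []
    universe = sorted(set().union(*hub_sets.values()))
    for node in universe:
        cohorts = sorted(c for c, hs in hub_sets.items() if node in hs)
        degs = [networks[c].degree(node) for c in cohorts]
        side = next(
            networks[c].nodes[node].get("side", "?") for c in cohorts
        )
        n_c = len(cohorts)
        if n_c >= cfg.common_hub_min_cancers:
            cls = "common"
        elif n_c == 1:
            cls = "specific"
        else:
            cls = "other"
        rows.append(
            {
                "node": node,
                "side": side,
                "class": cls,
                "n_cohorts": n_c,
                "cohorts": ",".join(cohorts),
                "max_degree": max(degs),
                "mean_degree": float(np.mean(degs)),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "node", "side", "class", "n_cohorts",
            "cohorts", "max_degree", "mean_degree",
        ],
    ).set_index("node")
    return HubClassification(table)


def _similarity(a: set, b: set, metric: str) -> float:
    if not a or not b:
        return 0.0
    inter = len(a & b)
    if metric == "jaccard":
        return inter / len(a | b)
    return inter / min(len(a), len(b))


def similarity_matrices(
    pair_tables: dict[str, PairTable], cfg: PipelineConfig
) -> dict[str, pd.DataFrame]:
    """Cohort x cohort shared-entity similarity for ICPs, lncRNAs and pairs.

    S(a, b) = |A n B| / min(|A|, |B|) by default (Jaccard via config);
    diagonal entries are 1 where the cohort's set is non-empty.
    """
    if len(pair_tables) < 2:
        raise ValueError("need at least 2 cohorts for similarity matrices")
    cohorts = sorted(pair_tables)
    entity_sets = {
        "ICP": {c: {i for i, _ in pair_tables[c].accepted_set()} for c in cohorts},
        "lncRNA": {c: {l for _, l in pair_tables[c].accepted_set()} for c in cohorts},
        "pair": {c: pair_tables[c].accepted_set() for c in cohorts},
    }
    out: dict[str, pd.DataFrame] = {}
    for kind, sets in entity_sets.items():
        mat = np.zeros((len(cohorts), len(cohorts)))
        for i, a in enumerate(cohorts):
            for j, b in enumerate(cohorts):
                if i == j:
                    mat[i, j] = 1.0 if sets[a] else 0.0
                else:
                    mat[i, j] = _similarity(sets[a], sets[b], cfg.similarity_metric)
        out[kind] = pd.DataFrame(mat, index=cohorts, columns=cohorts)
    return out


def write_network(net: nx.Graph, edge_path, graphml_path=None) -> None:
    """Write the edge list TSV (cancer, icp, lncrna, r, sign) and GraphML."""
    rows = []
    for u, v, data in net.edges(data=True):
        icp, lnc = (u, v) if net.nodes[u].get("side") == "ICP" else (v, u)
        rows.append(
            {
                "cancer": net.graph.get("cohort", ""),
                "icp": icp,
                "lncrna": lnc,
                "r": data.get("r", float("nan")),
                "sign": data.get("sign", ""),
            }
        )
    pd.DataFrame(rows, columns=["cancer", "icp", "lncrna", "r", "sign"]).to_csv(
        edge_path, sep="\t", index=False
    )
    if graphml_path is not None:
        nx.write_graphml(net, graphml_path)
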
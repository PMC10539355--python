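"""Checkpoint–lncRNA cooperative pair discovery.

Candidate pairs (every differential checkpoint crossed with every
differential lncRNA) are screened by two co-expression criteria and
accepted only when both hold:

* Pearson: |r| > 0.3 (strict) with two-sided P < 0.05; and
* mutual information: permutation P < 0.05, where MI is a plug-in
  estimate on equal-frequency bins (monotone-invariant) and the null is
  obtained by permuting one gene's values.

Accepted pairs carry a sign (positive/negative by the sign of r).  The
coincidence rate — the fraction of Pearson-accepted pairs also accepted by
the MI criterion — summarizes the agreement of the two routes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import ExpressionMatrix, PipelineConfig, substream

log = logging.getLogger("icplnc")

PAIR_COLUMNS = (
    "cohort",
    "icp",
    "lnc",
    "r",
    "r_p",
    "mi",
    "mi_p",
    "sign",
    "in_pcc_set",
    "in_mi_set",
    "accepted",
)


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with the two-sided t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def _equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign ranks to n_bins equal-count bins (stable order on ties)."""
    n = len(x)
    ranks = np.empty(n, dtype=int)
    ranks[np.argsort(x, kind="stable")] = np.arange(n)
    return (ranks * n_bins) // n


def _mi_from_binned(bx: np.ndarray, by: np.ndarray, n_bins: int) -> float:
    counts = np.bincount(bx * n_bins + by, minlength=n_bins * n_bins).astype(float)
    n = counts.sum()
    p = counts / n
    px = p.reshape(n_bins, n_bins).sum(axis=1)
    py = p.reshape(n_bins, n_bins).sum(axis=0)
    outer = np.outer(px, py).ravel()
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / outer[nz])))


def default_bins(n: int) -> int:
    """Bin count rule: floor((n/5)^(1/3)) per axis, at least 2.

    Cube-root growth keeps the plug-in bias, roughly (B-1)^2 / (2 n ln 2)
    bits under independence, below ~0.01 bits at n = 10^4 while still
    giving 3+ bins at typical cohort sizes.
    """
    return max(2, int(math.floor((n / 5.0) ** (1.0 / 3.0))))


def mutual_information(
    x: np.ndarray, y: np.ndarray, n_bins: int | None = None
) -> float:
    """Plug-in mutual information (bits) on equal-frequency bins.

    Rank-based binning makes the estimate invariant under strictly
    monotone transforms of either input and exactly symmetric in (x, y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 observations for binned MI")
    b = n_bins if n_bins is not None else default_bins(n)
    if b < 2 or n < 2 * b:
        raise ValueError(f"too few observations ({n}) for {b} bins")
    return _mi_from_binned(
        _equal_frequency_bins(x, b), _equal_frequency_bins(y, b), b
    )


def mi_permutation_p(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 200,
    seed: int = 0,
    n_bins: int | None = None,
) -> float:
    """Permutation p-value for mutual information (permuting y).

    p = (1 + #{permuted MI >= observed}) / (n_perm + 1).
    """
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19 to resolve p < 0.05")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    b = n_bins if n_bins is not None else default_bins(n)
    bx = _equal_frequency_bins(x, b)
    by = _equal_frequency_bins(y, b)
    observed = _mi_from_binned(bx, by, b)
    rng = substream(seed, "mi-perm")
    exceed = 0
    for _ in range(n_perm):
        if _mi_from_binned(bx, rng.permutation(by), b) >= observed:
            exceed += 1
    return (1 + exceed) / (n_perm + 1)


@dataclass
class PairTable:
    """Candidate/accepted pairs with both criteria's statistics."""

    table: pd.DataFrame

    def accepted(self) -> pd.DataFrame:
        return self.table[self.table["accepted"]]

    def pcc_set(self) -> set[tuple[str, str]]:
        t = self.table[self.table["in_pcc_set"]]
        return set(zip(t["icp"], t["lnc"]))

    def mi_set(self) -> set[tuple[str, str]]:
        t = self.table[self.table["in_mi_set"]]
        return set(zip(t["icp"], t["lnc"]))

    def accepted_set(self) -> set[tuple[str, str]]:
        t = self.accepted()
        return set(zip(t["icp"], t["lnc"]))


def extract_pairs(
    m: ExpressionMatrix,
    de_icps: list[str],
    de_lncs: list[str],
    cfg: PipelineConfig,
    cohort: str = "cohort",
) -> PairTable:
    """Evaluate every checkpoint x lncRNA combination against both criteria.

    Acceptance requires |r| > ``pcc_abs_min`` with r_p < alpha (Pearson
    route) and MI permutation p < alpha (MI route).  The table is sorted by
    cohort then |r| descending.  Raw p-values are used by default; the
    Benjamini–Hochberg toggle (``adjust_pvalues``) adjusts each route's
    p-values across all evaluated combinations before thresholding.
    """
    if not de_icps or not de_lncs:
        raise ValueError("both gene lists must be non-empty")
    n = m.n_samples
    xi = m.values[m.gene_positions(de_icps)]
    xl = m.values[m.gene_positions(de_lncs)]

    def zrows(a: np.ndarray) -> np.ndarray:
        sd = a.std(axis=1, ddof=0)
        if np.any(sd == 0):
            bad = np.flatnonzero(sd == 0)[0]
            raise ValueError("constant expression vector in pair screen")
        return (a - a.mean(axis=1, keepdims=True)) / sd[:, None]

    r = np.clip(zrows(xi) @ zrows(xl).T / n, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
    r_p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)

    b = default_bins(n)
    binned_i = [_equal_frequency_bins(row, b) for row in xi]
    binned_l = [_equal_frequency_bins(row, b) for row in xl]

    rows: list[dict] = []
    for a, icp in enumerate(de_icps):
        for c, lnc in enumerate(de_lncs):
            mi = _mi_from_binned(binned_i[a], binned_l[c], b)
            rng = substream(cfg.rng_seed, "mi-perm", cohort, icp, lnc)
            exceed = 0
            by = binned_l[c]
            for _ in range(cfg.mi_null_perms):
                if _mi_from_binned(binned_i[a], rng.permutation(by), b) >= mi:
                    exceed += 1
            mi_p = (1 + exceed) / (cfg.mi_null_perms + 1)
            rows.append(
                {
                    "cohort": cohort,
                    "icp": icp,
                    "lnc": lnc,
                    "r": float(r[a, c]),
                    "r_p": float(r_p[a, c]),
                    "mi": mi,
                    "mi_p": mi_p,
                }
            )
    table = pd.DataFrame(rows)
    r_pv = table["r_p"].to_numpy()
    mi_pv = table["mi_p"].to_numpy()
    if cfg.adjust_pvalues:
        r_pv = _benjamini_hochberg(r_pv)
        mi_pv = _benjamini_hochberg(mi_pv)
    table["in_pcc_set"] = (np.abs(table["r"]) > cfg.pcc_abs_min) & (
        r_pv < cfg.alpha
    )
    table["in_mi_set"] = mi_pv < cfg.alpha
    table["accepted"] = table["in_pcc_set"] & table["in_mi_set"]
    table["sign"] = np.where(table["r"] > 0, "positive", "negative")
    table = table.sort_values(
        ["cohort", "r"], key=lambda s: -s.abs() if s.name == "r" else s
    ).reset_index(drop=True)
    log.info(
        "pair screen (%s): %d combinations, %d PCC, %d MI, %d accepted",
        cohort, len(table), int(table["in_pcc_set"].sum()),
        int(table["in_mi_set"].sum()), int(table["accepted"].sum()),
    )
    return PairTable(table[list(PAIR_COLUMNS)])


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    adj[order] = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
    return np.clip(adj, 0.0, 1.0)


def coincidence_rate(pt: PairTable) -> float:
    """Fraction of Pearson-accepted pairs also in the MI-accepted set."""
    pcc = pt.pcc_set()
    if not pcc:
        raise ValueError("coincidence rate undefined: empty Pearson set")
    return len(pcc & pt.mi_set()) / len(pcc)


def write_pair_table(pt: PairTable, path) -> None:
    pt.table.to_csv(path, sep="\t", index=False)


def read_pair_table(path) -> PairTable:
    t = pd.read_csv(path, sep="\t")
    return PairTable(t[list(PAIR_COLUMNS)])
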
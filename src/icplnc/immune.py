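"""High-expression screen across immune cell types.

Identifies checkpoint genes and lncRNAs that are highly expressed in
purified immune cells: after quantile normalization and batch adjustment,
genes are ranked within their class in each cell type, and a gene counts as
"high" in a cell type when it sits above the configured expression quantile
(top 50% by default).  Checkpoints high in at least one cell type are kept;
lncRNAs are split into immune-specific (high in exactly one cell type) and
immune-general (high in more than half of the cell types — more than nine
when there are eighteen).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, GeneClassMap, PipelineConfig

log = logging.getLogger("icplnc")


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the common per-rank mean distribution.

    After normalization the sorted value vector of each column equals the
    across-column mean of the input's sorted columns.  Ranks within a
    column are assigned in order of value with ties kept in input gene
    order, so the operation is deterministic.
    """
    if m.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    order = np.argsort(m.values, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(m.values, order, axis=0)
    target = sorted_vals.mean(axis=1)
    out = np.empty_like(m.values)
    np.put_along_axis(out, order, target[:, None], axis=0)
    return ExpressionMatrix(out, list(m.gene_ids), list(m.sample_ids))


def adjust_batches(m: ExpressionMatrix, ann: pd.DataFrame) -> ExpressionMatrix:
    """Remove additive batch effects by per-(gene, cell type) mean-centering.

    Within each cell type, every batch's samples are shifted so the batch
    means coincide with the cell type's (sample-weighted) grand mean; the
    per-gene mean within each cell type is preserved exactly.
    """
    ann = ann.set_index("sample_id").loc[m.sample_ids]
    missing = ann.index[ann["batch"].isna()].tolist()
    if missing:
        raise ValueError(f"samples missing a batch label: {missing}")
    if ann["cell_type"].isna().any():
        bad = ann.index[ann["cell_type"].isna()].tolist()
        raise ValueError(f"samples missing a cell type: {bad}")
    out = m.values.copy()
    cell_types = ann["cell_type"].to_numpy()
    batches = ann["batch"].to_numpy()
    for ct in pd.unique(cell_types):
        ct_cols = np.flatnonzero(cell_types == ct)
        grand = out[:, ct_cols].mean(axis=1)
        for b in pd.unique(batches[ct_cols]):
            cols = ct_cols[batches[ct_cols] == b]
            if len(cols) < 2:
                raise ValueError(
                    f"cell type {ct!r} batch {b!r} has fewer than 2 samples"
                )
            out[:, cols] += (grand - out[:, cols].mean(axis=1))[:, None]
    return ExpressionMatrix(out, list(m.gene_ids), list(m.sample_ids))


@dataclass
class RankTable:
    """Per-(cell type, gene) expression rank quantiles within gene class.

    ``table`` columns: cell_type, gene_id, gene_class, quantile.  Within
    each (cell type, class) the quantiles are the k evenly spaced values
    1/k, 2/k, ..., 1 (1 = highest mean expression).
    """

    table: pd.DataFrame

    def cell_types(self) -> list[str]:
        return sorted(self.table["cell_type"].unique())


def rank_by_cell_type(
    m: ExpressionMatrix, ann: pd.DataFrame, classes: GeneClassMap
) -> RankTable:
    """Rank genes within each class by mean expression per cell type.

    Ties in mean expression are broken by lexicographic gene id (the
    alphabetically earlier gene receives the lower quantile), so the table
    is invariant to sample ordering.
    """
    for g in m.gene_ids:
        if g not in classes:
            raise KeyError(f"gene {g!r} has no class assignment")
    ann = ann.set_index("sample_id").loc[m.sample_ids]
    cell_types = ann["cell_type"].to_numpy()
    uniq = pd.unique(cell_types)
    if len(uniq) < 1:
        raise ValueError("no cell types in annotation")
    gene_class = np.array([classes[g] for g in m.gene_ids])
    gene_arr = np.array(m.gene_ids)
    rows: list[pd.DataFrame] = []
    for ct in uniq:
        cols = np.flatnonzero(cell_types == ct)
        if len(cols) == 0:
            raise ValueError(f"cell type {ct!r} has no samples")
        means = m.values[:, cols].mean(axis=1)
        for cls in np.unique(gene_class):
            idx = np.flatnonzero(gene_class == cls)
            # ascending by (mean, gene id); rank k/k = highest mean
            order = idx[np.lexsort((gene_arr[idx], means[idx]))]
            k = len(order)
            quant = np.empty(k)
            quant[:] = (np.arange(1, k + 1)) / k
            rows.append(
                pd.DataFrame(
                    {
                        "cell_type": ct,
                        "gene_id": gene_arr[order],
                        "gene_class": cls,
                        "quantile": quant,
                    }
                )
            )
    return RankTable(pd.concat(rows, ignore_index=True))


@dataclass
class ImmuneHighSets:
    """Outcome of the high-expression screen."""

    high_icps: list[str]
    immune_specific_lncs: list[str]
    immune_general_lncs: list[str]
    high_counts: dict[str, int] = field(default_factory=dict)

    @property
    def selected_lncs(self) -> list[str]:
        return sorted(self.immune_specific_lncs + self.immune_general_lncs)


def general_threshold(n_cell_types: int) -> int:
    """High-cell-type count a lncRNA must exceed to be immune-general.

    Nine for the 18-cell-type design; ceil(n/2) otherwise.
    """
    return math.ceil(n_cell_types / 2)


def select_immune_high(rt: RankTable, cfg: PipelineConfig) -> ImmuneHighSets:
    """Apply the high-expression class rules to a rank table.

    A gene is high in a cell type when its class-wise rank quantile exceeds
    ``high_expr_quantile``.  Checkpoints are kept when high in >=1 cell
    type; lncRNAs are immune-specific when high in exactly one cell type
    and immune-general when high in more than ``general_threshold`` types.
    """
    t = rt.table
    n_ct = t["cell_type"].nunique()
    if n_ct < 1:
        raise ValueError("rank table covers no cell types")
    high = t[t["quantile"] > cfg.high_expr_quantile]
    counts = high.groupby(["gene_id", "gene_class"]).size()
    high_counts: dict[str, int] = {}
    icps: list[str] = []
    specific: list[str] = []
    general: list[str] = []
    thresh = general_threshold(n_ct)
    for (gene, cls), c in counts.items():
        high_counts[gene] = int(c)
        if cls == "ICP" and c >= 1:
            icps.append(gene)
        elif cls == "lncRNA":
            if c == 1:
                specific.append(gene)
            elif c > thresh:
                general.append(gene)
    log.info(
        "immune screen: %d high ICPs, %d specific + %d general lncRNAs "
        "(threshold >%d of %d cell types)",
        len(icps), len(specific), len(general), thresh, n_ct,
    )
    return ImmuneHighSets(
        high_icps=sorted(icps),
        immune_specific_lncs=sorted(specific),
        immune_general_lncs=sorted(general),
        high_counts=high_counts,
    )
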
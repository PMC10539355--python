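"""Synthetic cohorts with planted ground truth.

Two generators emulate the input data the discovery pipeline expects:

* an immune-cell panel — purified immune-cell expression profiles over a
  configurable number of cell types, with designated immune-high genes and
  additive batch effects, for the high-expression screen; and
* tumor cohorts — bulk expression with a latent immune-infiltration gradient
  driving the rejection-signature genes, planted correlated checkpoint–lncRNA
  pairs, survival times whose hazard depends on designated pairs, and binary
  immunotherapy-response labels driven by pair-level scores.

Expression is generated directly on the log2 scale as Gaussian values
(counts and microarray preprocessing are out of scope: every downstream
statistic operates on normalized log-scale arrays).  The returned
:class:`SimTruth` records everything a test needs to verify recovery.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import (
    ExpressionMatrix,
    FormatError,
    GeneClassMap,
    GeneSetCatalog,
    substream,
    validate_annotations,
)

log = logging.getLogger("icplnc")


class SimConfigError(ValueError):
    """A simulation configuration is internally inconsistent."""


@dataclass
class PlantedPair:
    """A planted checkpoint–lncRNA pair with its effect sizes."""

    icp: str
    lnc: str
    rho: float
    hazard_beta: float = 0.0
    response_weight: float = 0.0


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic cohorts.

    The defaults define the reference study used throughout the test suite:
    two tumor cohorts of 300 samples, a 20 ICP x 20 lncRNA gene grid with 20
    planted pairs at rho=0.6 (one per ICP/lncRNA index), the first five
    pairs prognostic at log-hazard 0.8, three further pairs driving
    immunotherapy response at logit weight 2.0, and an 18-cell-type immune
    panel with 50 samples per type.
    """

    # gene universe
    n_icp: int = 20
    n_lnc: int = 20
    n_background: int = 390
    n_icr: int = 20
    n_immune_sig: int = 50
    # immune-cell panel
    n_cell_types: int = 18
    samples_per_cell_type: int = 50
    n_batches: int = 3
    batch_shift_sd: float = 1.0
    n_high_icp: int = 20
    n_specific_lnc: int = 10
    n_general_lnc: int = 10
    general_breadth: int | None = None  # default: n_cell_types - 1
    high_shift: float = 2.0
    baseline_mean: float = 5.0
    planted_baseline: float = 4.0
    # tumor cohorts
    n_cohorts: int = 2
    samples_per_cohort: int = 300
    planted_pairs: list[tuple[str, str, float]] | None = None
    infiltration_effect: float = 1.0
    target_loading: float = 0.5
    prognostic_pairs: list[tuple[tuple[str, str], float]] | None = None
    censor_rate: float = 0.3
    median_survival_days: float = 1000.0
    response_pairs: list[tuple[tuple[str, str], float]] | None = None
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cell_types < 2 or self.samples_per_cell_type < 2:
            raise SimConfigError(
                "need >=2 cell types and >=2 samples per cell type"
            )
        if min(self.n_icp, self.n_lnc) < 1:
            raise SimConfigError("need at least one ICP and one lncRNA gene")
        if self.n_high_icp > self.n_icp:
            raise SimConfigError(
                f"n_high_icp={self.n_high_icp} exceeds n_icp={self.n_icp}"
            )
        if self.n_specific_lnc + self.n_general_lnc > self.n_lnc:
            raise SimConfigError("more planted lncRNAs than lncRNA genes")
        if self.general_breadth is None:
            self.general_breadth = max(1, self.n_cell_types - 1)
        if self.general_breadth > self.n_cell_types:
            raise SimConfigError("general_breadth exceeds n_cell_types")
        if not (0.0 <= self.censor_rate < 1.0):
            raise SimConfigError("censor_rate must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise SimConfigError("noise_sd must be positive")

        self.icp_ids = [f"ICP{i + 1:03d}" for i in range(self.n_icp)]
        self.lnc_ids = [f"LNC{i + 1:03d}" for i in range(self.n_lnc)]
        self.icr_ids = [f"ICR{i + 1:03d}" for i in range(self.n_icr)]
        self.sig_ids = [f"SIG{i + 1:03d}" for i in range(self.n_immune_sig)]
        self.bg_ids = [f"BG{i + 1:03d}" for i in range(self.n_background)]

        if self.planted_pairs is None:
            k = min(self.n_icp, self.n_lnc)
            self.planted_pairs = [
                (self.icp_ids[i], self.lnc_ids[i], 0.6) for i in range(k)
            ]
        else:
            self.planted_pairs = [
                (str(i), str(l), float(r)) for i, l, r in self.planted_pairs
            ]
        for icp, lnc, rho in self.planted_pairs:
            if icp not in self.icp_ids:
                raise SimConfigError(f"planted pair references unknown ICP {icp!r}")
            if lnc not in self.lnc_ids:
                raise SimConfigError(
                    f"planted pair references unknown lncRNA {lnc!r}"
                )
            if not (-1.0 < rho < 1.0):
                raise SimConfigError(f"planted rho={rho} must lie in (-1, 1)")

        planted = {(i, l) for i, l, _ in self.planted_pairs}
        if self.prognostic_pairs is None:
            self.prognostic_pairs = [
                ((i, l), 0.8) for i, l, _ in self.planted_pairs[:5]
            ]
        if self.response_pairs is None:
            self.response_pairs = [
                ((i, l), 2.0) for i, l, _ in self.planted_pairs[5:8]
            ]
        for name, lst in (
            ("prognostic", self.prognostic_pairs),
            ("response", self.response_pairs),
        ):
            for (icp, lnc), _w in lst:
                if (icp, lnc) not in planted:
                    raise SimConfigError(
                        f"{name} pair ({icp}, {lnc}) is not a planted pair"
                    )

    @property
    def gene_ids(self) -> list[str]:
        return (
            self.icp_ids + self.lnc_ids + self.icr_ids + self.sig_ids + self.bg_ids
        )

    def gene_classes(self) -> GeneClassMap:
        classes = {g: "ICP" for g in self.icp_ids}
        classes.update({g: "lncRNA" for g in self.lnc_ids})
        classes.update(
            {g: "other" for g in self.icr_ids + self.sig_ids + self.bg_ids}
        )
        return GeneClassMap(classes)

    def gene_sets(self) -> GeneSetCatalog:
        return GeneSetCatalog(
            {"ICR": list(self.icr_ids), "IMMUNE_SIGNATURE": list(self.sig_ids)}
        )


@dataclass
class SimTruth:
    """Planted ground truth for one simulated data set."""

    planted_pairs: list[PlantedPair] = field(default_factory=list)
    infiltration: pd.Series | None = None
    log_hazard: pd.Series | None = None
    response_prob: pd.Series | None = None
    immune_high: dict[str, list[str]] = field(default_factory=dict)
    gene_classes: GeneClassMap | None = None
    gene_sets: GeneSetCatalog | None = None


def load_sim_config(path: str | Path) -> SimConfig:
    """Read the ``simulation`` section of a JSON config file."""
    with Path(path).open() as fh:
        raw = json.load(fh)
    section = raw.get("simulation", {})
    if not isinstance(section, dict):
        raise FormatError(f"{path}: 'simulation' must be a JSON object")
    section = dict(section)
    for key in ("planted_pairs", "prognostic_pairs", "response_pairs"):
        if key in section and section[key] is not None:
            if key == "planted_pairs":
                section[key] = [tuple(x) for x in section[key]]
            else:
                section[key] = [
                    ((p[0][0], p[0][1]), p[1]) for p in section[key]
                ]
    return SimConfig(**section)


# ---------------------------------------------------------------------------
# Immune-cell panel
# ---------------------------------------------------------------------------


def _design_immune_high(
    cfg: SimConfig, cell_types: list[str]
) -> dict[str, list[str]]:
    """Deterministic designation of immune-high genes per cell type.

    Checkpoints: gene i high in cell type i mod T (the at-least-one-cell
    rule needs no more).  lncRNAs follow an exact schedule that fills each
    cell type's top-half rank slots with designed-high genes: specific
    lncRNA i is high in cell type i mod T only; each general lncRNA is
    high in ``general_breadth`` cell types dealt greedily onto the least
    loaded types; any remaining planted lncRNAs top columns up to
    floor(n_lnc/2).  When the designed memberships fill every column
    exactly, rank positions are decided by the +2 design shift rather than
    by observation noise, so specific/general status is recoverable.
    """
    T = cfg.n_cell_types
    immune_high: dict[str, list[str]] = {}
    for i, g in enumerate(cfg.icp_ids[: cfg.n_high_icp]):
        immune_high[g] = [cell_types[i % T]]

    n_planted = cfg.n_specific_lnc + cfg.n_general_lnc
    if n_planted == 0:
        return immune_high
    load = np.zeros(T, dtype=int)
    for i, g in enumerate(cfg.lnc_ids[: cfg.n_specific_lnc]):
        c = i % T
        immune_high[g] = [cell_types[c]]
        load[c] += 1
    for g in cfg.lnc_ids[
        cfg.n_specific_lnc : cfg.n_specific_lnc + cfg.n_general_lnc
    ]:
        # the B least-loaded cell types, ties by index
        chosen = np.argsort(load, kind="stable")[: cfg.general_breadth]
        immune_high[g] = sorted(cell_types[c] for c in chosen)
        load[chosen] += 1
    slots = cfg.n_lnc // 2
    if np.any(load > slots):
        log.warning(
            "immune-high design overfills some cell types "
            "(max load %d > %d top-half slots); specific/general recovery "
            "may degrade", int(load.max()), slots,
        )
    elif np.any(load < slots):
        log.warning(
            "immune-high design leaves %d top-half slots to noise; "
            "specific lncRNA recovery may degrade",
            int((slots - load).sum()),
        )
    return immune_high


def simulate_immune_panel(
    cfg: SimConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, SimTruth]:
    """Simulate purified immune-cell expression profiles over cell types.

    Per cell type, designated immune-high genes are mean-shifted by
    ``high_shift`` (log2 units) above their baseline; observation noise is
    Normal(0, ``noise_sd``) around a baseline of ``baseline_mean``; each
    (gene, batch) receives an additive offset Normal(0, ``batch_shift_sd``).

    Planted genes (designated-high checkpoints, cell-type-specific and
    immune-general lncRNAs) carry a below-median baseline
    (``planted_baseline``) so that outside their designated cell types they
    reliably rank in the bottom half of their gene class — this is what
    makes "high in exactly one cell type" recoverable.  Undesignated genes
    keep the plain Normal(baseline_mean, noise_sd) model.
    """
    rng = substream(cfg.seed, "immune-panel")
    genes = cfg.gene_ids
    n_genes = len(genes)
    cell_types = [f"CT{c + 1:02d}" for c in range(cfg.n_cell_types)]

    immune_high = _design_immune_high(cfg, cell_types)

    baseline = np.full(n_genes, cfg.baseline_mean)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g in immune_high:
        baseline[gene_pos[g]] = cfg.planted_baseline

    batch_offsets = rng.normal(0.0, cfg.batch_shift_sd, size=(n_genes, cfg.n_batches))
    if cfg.n_batches > 1:
        # centered per gene: batch effects perturb between-batch location
        # without shifting the gene's overall expression level
        batch_offsets -= batch_offsets.mean(axis=1, keepdims=True)

    sample_ids: list[str] = []
    ann_rows: list[dict] = []
    cols: list[np.ndarray] = []
    for ct in cell_types:
        shift = np.zeros(n_genes)
        for g, cts in immune_high.items():
            if ct in cts:
                shift[gene_pos[g]] = cfg.high_shift
        for j in range(cfg.samples_per_cell_type):
            b = j % cfg.n_batches
            sid = f"{ct}_S{j + 1:03d}"
            sample_ids.append(sid)
            ann_rows.append(
                {
                    "sample_id": sid,
                    "cohort": "immune_panel",
                    "cell_type": ct,
                    "batch": f"B{b + 1}",
                }
            )
            cols.append(
                baseline
                + shift
                + batch_offsets[:, b]
                + rng.normal(0.0, cfg.noise_sd, size=n_genes)
            )

    matrix = ExpressionMatrix(np.column_stack(cols), genes, sample_ids)
    ann = validate_annotations(pd.DataFrame(ann_rows))
    truth = SimTruth(
        immune_high=immune_high,
        gene_classes=cfg.gene_classes(),
        gene_sets=cfg.gene_sets(),
    )
    return matrix, ann, truth


# ---------------------------------------------------------------------------
# Tumor cohorts
# ---------------------------------------------------------------------------


def _pair_residual_cholesky(cfg: SimConfig) -> tuple[list[str], np.ndarray]:
    """Cholesky factor of the residual correlation over pair-member genes."""
    members: list[str] = []
    for icp, lnc, _ in cfg.planted_pairs:
        for g in (icp, lnc):
            if g not in members:
                members.append(g)
    pos = {g: i for i, g in enumerate(members)}
    corr = np.eye(len(members))
    for icp, lnc, rho in cfg.planted_pairs:
        corr[pos[icp], pos[lnc]] = rho
        corr[pos[lnc], pos[icp]] = rho
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        raise SimConfigError(
            "planted pair correlations are jointly infeasible "
            "(residual correlation matrix is not positive definite)"
        ) from None
    return members, chol


def simulate_tumor_cohort(
    cfg: SimConfig, cohort_id: str
) -> tuple[ExpressionMatrix, pd.DataFrame, SimTruth]:
    """Simulate one tumor cohort with a latent infiltration gradient.

    Per sample, a latent infiltration score u ~ Normal(0, 1) loads on the
    rejection-panel and immune-signature genes with ``infiltration_effect``
    and on the checkpoint/lncRNA genes with ``target_loading``.  Planted
    pairs receive bivariate-Normal residuals with the configured correlation
    (the planted rho is therefore the partial correlation given u; the total
    correlation is (loading^2 + rho * sd^2) / (loading^2 + sd^2)).  Survival
    times are Exponential with log-hazard summed over prognostic pairs, with
    administrative censoring at the empirical quantile matching
    ``censor_rate``; response labels are Bernoulli in the pair-score logit.
    """
    if cfg.samples_per_cohort < 20:
        raise SimConfigError("samples_per_cohort must be >= 20")
    rng = substream(cfg.seed, "tumor", cohort_id)
    genes = cfg.gene_ids
    n_genes = len(genes)
    n = cfg.samples_per_cohort
    gene_pos = {g: i for i, g in enumerate(genes)}

    u = rng.normal(0.0, 1.0, size=n)
    loading = np.zeros(n_genes)
    for g in cfg.icr_ids + cfg.sig_ids:
        loading[gene_pos[g]] = cfg.infiltration_effect
    for g in cfg.icp_ids + cfg.lnc_ids:
        loading[gene_pos[g]] = cfg.target_loading

    resid = rng.normal(0.0, 1.0, size=(n_genes, n))
    members, chol = _pair_residual_cholesky(cfg)
    member_pos = [gene_pos[g] for g in members]
    resid[member_pos, :] = chol @ rng.normal(0.0, 1.0, size=(len(members), n))

    values = (
        cfg.baseline_mean
        + loading[:, None] * u[None, :]
        + cfg.noise_sd * resid
    )
    sample_ids = [f"{cohort_id}_S{i + 1:04d}" for i in range(n)]
    matrix = ExpressionMatrix(values, genes, sample_ids)

    def pair_score(icp: str, lnc: str) -> np.ndarray:
        return (values[gene_pos[icp]] + values[gene_pos[lnc]]) / 2.0

    eta = np.zeros(n)
    for (icp, lnc), beta in cfg.prognostic_pairs:
        eta += beta * (pair_score(icp, lnc) - cfg.baseline_mean)
    lam0 = np.log(2.0) / cfg.median_survival_days
    times = rng.exponential(1.0 / (lam0 * np.exp(eta)))
    if cfg.censor_rate > 0:
        cutoff = np.quantile(times, 1.0 - cfg.censor_rate)
        events = (times <= cutoff).astype(int)
        times = np.minimum(times, cutoff)
    else:
        events = np.ones(n, dtype=int)

    logit = np.zeros(n)
    for (icp, lnc), w in cfg.response_pairs:
        logit += w * (pair_score(icp, lnc) - cfg.baseline_mean)
    prob = 1.0 / (1.0 + np.exp(-logit))
    response = np.where(
        rng.random(n) < prob, "responder", "non_responder"
    )

    ann = validate_annotations(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "cohort": cohort_id,
                "age": np.round(rng.normal(60.0, 10.0, size=n), 1),
                "sex": rng.integers(0, 2, size=n),
                "os_time": times,
                "os_event": events,
                "ici_response": response,
            }
        )
    )

    hazard_map = {(i, l): b for (i, l), b in cfg.prognostic_pairs}
    weight_map = {(i, l): w for (i, l), w in cfg.response_pairs}
    planted = [
        PlantedPair(
            icp,
            lnc,
            rho,
            hazard_beta=hazard_map.get((icp, lnc), 0.0),
            response_weight=weight_map.get((icp, lnc), 0.0),
        )
        for icp, lnc, rho in cfg.planted_pairs
    ]
    truth = SimTruth(
        planted_pairs=planted,
        infiltration=pd.Series(u, index=sample_ids),
        log_hazard=pd.Series(eta, index=sample_ids),
        response_prob=pd.Series(prob, index=sample_ids),
        gene_classes=cfg.gene_classes(),
        gene_sets=cfg.gene_sets(),
    )
    return matrix, ann, truth


# ---------------------------------------------------------------------------
# Truth reports
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = (
    "kind",
    "icp",
    "lnc",
    "rho",
    "hazard_beta",
    "response_weight",
    "gene",
    "cell_types",
)


def truth_report(truth: SimTruth) -> pd.DataFrame:
    """Flatten planted entities into a table for test harnesses."""
    rows: list[dict] = []
    for p in truth.planted_pairs:
        rows.append(
            {
                "kind": "pair",
                "icp": p.icp,
                "lnc": p.lnc,
                "rho": p.rho,
                "hazard_beta": p.hazard_beta,
                "response_weight": p.response_weight,
                "gene": "",
                "cell_types": "",
            }
        )
    for g, cts in truth.immune_high.items():
        rows.append(
            {
                "kind": "immune_high",
                "icp": "",
                "lnc": "",
                "rho": "",
                "hazard_beta": "",
                "response_weight": "",
                "gene": g,
                "cell_types": ",".join(cts),
            }
        )
    return pd.DataFrame(rows, columns=list(TRUTH_COLUMNS))


def write_truth_report(truth: SimTruth, path: str | Path) -> None:
    truth_report(truth).to_csv(path, sep="\t", index=False)


def read_truth_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False
    )[list(TRUTH_COLUMNS)]
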
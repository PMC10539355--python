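"""Core data containers, file formats, configuration and logging.

Everything downstream operates on log2-scale gene x sample expression
matrices with gene-class bindings (immune checkpoint / lncRNA / other),
per-sample clinical annotations, and GMT gene-set catalogs (immune
signatures and the 20-gene immunologic-constant-of-rejection panel).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("icplnc")

GENE_CLASSES = ("ICP", "lncRNA", "other")

#: Columns an annotation table may carry.  ``sample_id`` and ``cohort`` are
#: required; the rest are optional and may contain missing values.
ANNOTATION_COLUMNS = (
    "sample_id",
    "cohort",
    "cell_type",
    "batch",
    "age",
    "sex",
    "os_time",
    "os_event",
    "ici_response",
)


def configure_logging(level: str = "INFO") -> None:
    """Attach a stream handler to the package logger (idempotent)."""
    logger = logging.getLogger("icplnc")
    logger.setLevel(level.upper())
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)


def substream(seed: int, *labels: object) -> np.random.Generator:
    """Derive a reproducible per-stage random generator.

    Every stochastic stage of the pipeline draws its generator from the
    single configured seed plus a stage label, so whole-pipeline runs are
    reproducible and stages are insensitive to each other's draw counts.
    """
    words = [int(seed) & 0x7FFFFFFF]
    for lab in labels:
        digest = hashlib.blake2b(str(lab).encode(), digest_size=4).digest()
        words.append(int.from_bytes(digest, "big"))
    return np.random.default_rng(np.random.SeedSequence(words))


class FormatError(ValueError):
    """A file did not satisfy the expected dialect or an invariant."""


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2-scale expression values.

    Invariants: unique gene and sample identifiers, all values finite,
    dimensions consistent with the id lists.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise FormatError("expression values must be a 2-D array")
        n_g, n_s = self.values.shape
        if n_g != len(self.gene_ids) or n_s != len(self.sample_ids):
            raise FormatError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise FormatError(f"duplicate {name} id: {dup!r}")
        if not np.all(np.isfinite(self.values)):
            g, s = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite value at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene(self, gene_id: str) -> np.ndarray:
        """Expression vector of one gene across all samples."""
        try:
            return self.values[self._gene_index[gene_id]]
        except KeyError:
            raise KeyError(f"unknown gene id: {gene_id!r}") from None

    def gene_positions(self, gene_ids: Iterable[str]) -> np.ndarray:
        return np.array([self._gene_index[g] for g in gene_ids], dtype=int)

    def subset(
        self,
        genes: Sequence[str] | None = None,
        samples: Sequence[str] | None = None,
    ) -> "ExpressionMatrix":
        gi = (
            self.gene_positions(genes)
            if genes is not None
            else np.arange(self.n_genes)
        )
        if samples is not None:
            si = np.array([self._sample_index[s] for s in samples], dtype=int)
        else:
            si = np.arange(self.n_samples)
        return ExpressionMatrix(
            self.values[np.ix_(gi, si)],
            [self.gene_ids[i] for i in gi],
            [self.sample_ids[i] for i in si],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.sample_ids
        )


def _first_duplicate(ids: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a tab-separated expression matrix.

    Dialect: header row of sample ids (first header cell ignored), one row
    per gene with the gene id in the first column.  Duplicated ids, ragged
    rows and non-numeric cells are reported with the offending row/column.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise FormatError(f"{path}: empty file")
        sample_ids = header.split("\t")[1:]
        n_s = len(sample_ids)
        gene_ids: list[str] = []
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != n_s + 1:
                raise FormatError(
                    f"{path}: line {lineno} has {len(parts) - 1} values, "
                    f"expected {n_s}"
                )
            gene_ids.append(parts[0])
            try:
                rows.append(np.array(parts[1:], dtype=float))
            except ValueError:
                for j, cell in enumerate(parts[1:]):
                    try:
                        float(cell)
                    except ValueError:
                        raise FormatError(
                            f"{path}: non-numeric value {cell!r} at gene "
                            f"{parts[0]!r}, sample {sample_ids[j]!r}"
                        ) from None
                raise
    values = np.vstack(rows) if rows else np.empty((0, n_s))
    return ExpressionMatrix(values, gene_ids, sample_ids)


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix in the dialect :func:`read_expression` reads.

    Values are written with ``repr`` precision so a round trip is exact.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene_id\t" + "\t".join(m.sample_ids) + "\n")
        for g, row in zip(m.gene_ids, m.values):
            fh.write(g + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Gene classes
# ---------------------------------------------------------------------------


@dataclass
class GeneClassMap:
    """gene_id -> class in {ICP, lncRNA, other}; unknown gene lookups raise."""

    classes: dict[str, str]

    def __post_init__(self) -> None:
        for g, c in self.classes.items():
            if c not in GENE_CLASSES:
                raise FormatError(f"gene {g!r} has unknown class {c!r}")

    def __getitem__(self, gene_id: str) -> str:
        try:
            return self.classes[gene_id]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} has no class assignment") from None

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.classes

    def genes_of(self, cls: str) -> list[str]:
        return [g for g, c in self.classes.items() if c == cls]


def read_gene_classes(path: str | Path) -> GeneClassMap:
    """Read a two-column TSV: gene_id <tab> class."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["gene_id", "class"]:
        raise FormatError(f"{path}: expected columns gene_id, class")
    dup = _first_duplicate(list(df["gene_id"]))
    if dup is not None:
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    return GeneClassMap(dict(zip(df["gene_id"], df["class"])))


def write_gene_classes(cm: GeneClassMap, path: str | Path) -> None:
    pd.DataFrame(
        {"gene_id": list(cm.classes), "class": list(cm.classes.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sample annotations
# ---------------------------------------------------------------------------


def validate_annotations(ann: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-annotation table and normalise its dtypes.

    One row per sample.  ``os_time`` and ``os_event`` must be present or
    absent together per sample; sample ids must be unique within a cohort.
    """
    if "sample_id" not in ann.columns or "cohort" not in ann.columns:
        raise FormatError("annotations need sample_id and cohort columns")
    ann = ann.copy()
    for col in ANNOTATION_COLUMNS:
        if col not in ann.columns:
            ann[col] = np.nan
    dup = ann.duplicated(subset=["cohort", "sample_id"])
    if dup.any():
        bad = ann.loc[dup, "sample_id"].iloc[0]
        raise FormatError(f"duplicate sample id within cohort: {bad!r}")
    for col in ("age", "os_time", "os_event", "sex"):
        ann[col] = pd.to_numeric(ann[col], errors="raise")
    mismatch = ann["os_time"].isna() != ann["os_event"].isna()
    if mismatch.any():
        bad = ann.loc[mismatch, "sample_id"].iloc[0]
        raise FormatError(
            f"sample {bad!r}: os_time and os_event must be present together"
        )
    neg = ann["os_time"] < 0
    if neg.any():
        raise FormatError(
            f"negative survival time for sample "
            f"{ann.loc[neg, 'sample_id'].iloc[0]!r}"
        )
    bad_event = ~ann["os_event"].isin([0, 1]) & ann["os_event"].notna()
    if bad_event.any():
        raise FormatError("os_event must be 0 or 1")
    bad_resp = ~ann["ici_response"].isin(
        ["responder", "non_responder"]
    ) & ann["ici_response"].notna()
    if bad_resp.any():
        raise FormatError("ici_response must be responder/non_responder")
    return ann[list(ANNOTATION_COLUMNS)]


def read_annotations(path: str | Path) -> pd.DataFrame:
    return validate_annotations(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))


def write_annotations(ann: pd.DataFrame, path: str | Path) -> None:
    validate_annotations(ann).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene-set catalogs (GMT)
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCatalog:
    """set_name -> ordered list of member gene ids (non-empty, unique)."""

    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
            if _first_duplicate(members) is not None:
                raise FormatError(f"gene set {name!r} has duplicate members")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCatalog:
    """Read a GMT file (name, description, members per tab-separated line).

    Duplicate members within a set are dropped with a warning; the
    description field is discarded.
    """
    sets: dict[str, list[str]] = {}
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3 or not any(p for p in parts[2:]):
                raise FormatError(
                    f"{path}: set {parts[0]!r} (line {lineno}) has no members"
                )
            name = parts[0]
            members: list[str] = []
            seen: set[str] = set()
            for g in parts[2:]:
                if not g:
                    continue
                if g in seen:
                    log.warning(
                        "gene set %r: dropping duplicate member %r", name, g
                    )
                    continue
                seen.add(g)
                members.append(g)
            sets[name] = members
    return GeneSetCatalog(sets)


def write_gmt(cat: GeneSetCatalog, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name, members in cat.sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Thresholds and knobs for every pipeline stage.

    The defaults encode the screening rules used throughout: genes count as
    highly expressed above the median of their class (``high_expr_quantile``),
    the top 75% of samples by immune score are retained, pairs need
    |r| > 0.3 at P < 0.05, hubs are the top 5% of nodes by degree, common
    hubs are hubs in more than five cohorts, and the survival screen uses a
    1000-permutation empirical null.
    """

    high_expr_quantile: float = 0.5
    immune_score_quantile: float = 0.75
    pcc_abs_min: float = 0.3
    alpha: float = 0.05
    hub_quantile: float = 0.95
    common_hub_min_cancers: int = 6
    n_survival_perms: int = 1000
    mi_null_perms: int = 200
    consensus_resamples: int = 100
    consensus_subsample: float = 0.8
    ssgsea_weight: float = 0.25
    similarity_metric: str = "min"
    adjust_pvalues: bool = False
    svm_c: float = 1.0
    svm_features: str = "pairs"
    lasso_cv_folds: int = 5
    normalize_pair_scores: bool = True
    rng_seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        for name in (
            "high_expr_quantile",
            "immune_score_quantile",
            "hub_quantile",
            "alpha",
            "consensus_subsample",
        ):
            v = getattr(self, name)
            if not (0.0 < v < 1.0) and not (
                name == "consensus_subsample" and v == 1.0
            ):
                raise FormatError(f"{name}={v} must lie in (0, 1)")
        if not (0.0 <= self.pcc_abs_min < 1.0):
            raise FormatError(f"pcc_abs_min={self.pcc_abs_min} out of range")
        for name in ("n_survival_perms", "mi_null_perms", "consensus_resamples"):
            if getattr(self, name) < 1:
                raise FormatError(f"{name} must be >= 1")
        if self.similarity_metric not in ("min", "jaccard"):
            raise FormatError(
                f"similarity_metric={self.similarity_metric!r} "
                "must be 'min' or 'jaccard'"
            )
        if self.svm_features not in ("aggregate", "pairs", "both"):
            raise FormatError(
                f"svm_features={self.svm_features!r} must be "
                "'aggregate', 'pairs' or 'both'"
            )
        if self.lasso_cv_folds < 2:
            raise FormatError("lasso_cv_folds must be >= 2")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a JSON config; absent keys take the documented defaults.

    A ``simulation`` section, if present, is ignored here (the synthetic
    cohort generator reads it).  The fully resolved configuration is logged.
    """
    raw: dict = {}
    if path is not None:
        with Path(path).open() as fh:
            raw = json.load(fh)
        if not isinstance(raw, dict):
            raise FormatError(f"{path}: config must be a JSON object")
    raw = {k: v for k, v in raw.items() if k != "simulation"}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    log.info("resolved config: %s", json.dumps(cfg.to_dict(), sort_keys=True))
    return cfg


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        json.dump(cfg.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
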
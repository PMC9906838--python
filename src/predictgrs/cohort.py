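"""Cohort data model and I/O.

A cohort links a clinical table (one row per patient: tumour characteristics,
treatments received, breast-cancer-specific follow-up) with a per-gene
z-score-normalised expression matrix (genes in rows, samples in columns).
Other-cause deaths are recorded but treated as censoring for
breast-cancer-specific survival throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLINICAL_COLUMNS = [
    "patient_id", "age", "er", "pr", "her2", "ki67", "grade", "size_mm",
    "nodes", "detection", "chemo", "hormone", "radio", "trastuzumab",
    "time_years", "event",
]

EVENT_VALUES = {"bc_death", "other_death", "censored"}
DETECTION_VALUES = {"screen", "symptomatic", "unknown"}
CHEMO_VALUES = {"none", "second", "third"}
STATUS_VALUES = {"pos", "neg"}


class SchemaError(ValueError):
    """A clinical file is missing a mandatory column or holds an illegal value."""


class LinkageError(ValueError):
    """Clinical and expression identifiers share no overlap."""


@dataclass
class ClinicalRecord:
    """One patient's clinical covariates, treatments and follow-up.

    Optional binary statuses (``pr_status``, ``ki67_status``) and ``grade``
    are ``None`` when missing; missingness is explicit, never coded as 0.
    """

    patient_id: str
    age: float
    er_status: str                      # "pos" | "neg"
    her2_status: str                    # "pos" | "neg"
    tumour_size: float                  # mm
    nodes_positive: int
    grade: Optional[int] = None         # 1 | 2 | 3 | None
    pr_status: Optional[str] = None
    ki67_status: Optional[str] = None
    detection_mode: str = "unknown"     # screen | symptomatic | unknown
    chemo_generation: str = "none"      # none | second | third
    hormone_therapy: bool = False
    radiotherapy: bool = False
    trastuzumab: bool = False
    follow_up_time: float = 0.0         # years
    event: str = "censored"             # bc_death | other_death | censored

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise SchemaError(f"{self.patient_id}: age must be > 0, got {self.age}")
        if self.tumour_size is not None and not self.tumour_size > 0:
            raise SchemaError(
                f"{self.patient_id}: tumour_size must be > 0, got {self.tumour_size}")
        if self.nodes_positive < 0:
            raise SchemaError(
                f"{self.patient_id}: nodes_positive must be >= 0, got {self.nodes_positive}")
        if self.follow_up_time < 0:
            raise SchemaError(
                f"{self.patient_id}: follow_up_time must be >= 0, got {self.follow_up_time}")
        if self.event not in EVENT_VALUES:
            raise SchemaError(f"{self.patient_id}: event must be one of {sorted(EVENT_VALUES)}")
        if self.grade is not None and self.grade not in (1, 2, 3):
            raise SchemaError(f"{self.patient_id}: grade must be 1, 2 or 3 or missing")
        for name, value in (("er", self.er_status), ("her2", self.her2_status)):
            if value not in STATUS_VALUES:
                raise SchemaError(f"{self.patient_id}: {name} must be 'pos' or 'neg'")
        for name, value in (("pr", self.pr_status), ("ki67", self.ki67_status)):
            if value is not None and value not in STATUS_VALUES:
                raise SchemaError(f"{self.patient_id}: {name} must be 'pos', 'neg' or missing")
        if self.detection_mode not in DETECTION_VALUES:
            raise SchemaError(f"{self.patient_id}: detection must be one of {sorted(DETECTION_VALUES)}")
        if self.chemo_generation not in CHEMO_VALUES:
            raise SchemaError(f"{self.patient_id}: chemo must be one of {sorted(CHEMO_VALUES)}")

    @property
    def bc_event(self) -> bool:
        """Breast-cancer-death indicator; other-cause deaths count as censoring."""
        return self.event == "bc_death"


class ExpressionMatrix:
    """Genes-by-samples continuous expression values.

    Thin wrapper over a :class:`pandas.DataFrame` (index = gene ids, columns =
    sample ids) carrying a ``normalised`` flag. When the flag is set every
    gene row has mean 0 and sample standard deviation 1 to within 1e-8.
    """

    def __init__(self, values: pd.DataFrame, normalised: bool = False):
        if values.index.duplicated().any():
            dupes = values.index[values.index.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate gene ids: {dupes}")
        if values.columns.duplicated().any():
            dupes = values.columns[values.columns.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate sample ids: {dupes}")
        self.values = values.astype(float)
        self.normalised = bool(normalised)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, sample_ids], normalised=self.normalised)

    def check_normalised(self, atol: float = 1e-8) -> bool:
        means = np.nanmean(self.values.to_numpy(), axis=1)
        sds = np.nanstd(self.values.to_numpy(), axis=1, ddof=1)
        return bool(np.all(np.abs(means) < atol) and np.all(np.abs(sds - 1) < atol))


def zscore_normalise(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score each gene row (sample sd, n-1 denominator) over non-missing entries.

    Zero-variance genes are dropped and logged. Idempotent to 1e-8. Raises on
    a single-sample matrix, where the sample standard deviation is undefined.
    """
    if matrix.shape[1] < 2:
        raise ValueError("z-score normalisation needs at least 2 samples")
    X = matrix.values.to_numpy()
    means = np.nanmean(X, axis=1, keepdims=True)
    sds = np.nanstd(X, axis=1, ddof=1, keepdims=True)
    keep = (sds[:, 0] > 0) & np.isfinite(sds[:, 0])
    dropped = [g for g, k in zip(matrix.gene_ids, keep) if not k]
    if dropped:
        logger.info("dropping %d zero-variance gene(s): %s", len(dropped), dropped[:10])
    Z = (X[keep] - means[keep]) / sds[keep]
    out = pd.DataFrame(Z, index=matrix.values.index[keep], columns=matrix.values.columns)
    return ExpressionMatrix(out, normalised=True)


@dataclass
class Cohort:
    """Linked clinical table and expression matrix.

    After linkage each expression sample id matches exactly one clinical
    patient id and the two are in the same order.
    """

    clinical: pd.DataFrame
    expression: ExpressionMatrix
    er_stratum: Optional[str] = None
    dropped_clinical: int = 0
    dropped_expression: int = 0

    def __post_init__(self) -> None:
        pids = list(self.clinical["patient_id"])
        if len(pids) != len(set(pids)):
            raise SchemaError("duplicate patient ids in clinical table")
        if pids != self.expression.sample_ids:
            raise LinkageError("clinical patient ids and expression sample ids differ")

    def __len__(self) -> int:
        return len(self.clinical)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.clinical["patient_id"])

    @property
    def records(self) -> list[ClinicalRecord]:
        return [record_from_row(row) for _, row in self.clinical.iterrows()]

    def subset(self, mask: np.ndarray, er_stratum: Optional[str] = None) -> "Cohort":
        clin = self.clinical.loc[mask].reset_index(drop=True)
        expr = self.expression.subset_samples(list(clin["patient_id"]))
        return Cohort(clin, expr, er_stratum=er_stratum or self.er_stratum)

    def er_subset(self, stratum: str) -> "Cohort":
        """Restrict to one ER stratum ('positive' or 'negative')."""
        flag = "pos" if stratum == "positive" else "neg"
        return self.subset((self.clinical["er"] == flag).to_numpy(), er_stratum=stratum)

    @property
    def bc_survival(self) -> tuple[np.ndarray, np.ndarray]:
        """(time, event) arrays with other-cause deaths censored."""
        t = self.clinical["time_years"].to_numpy(float)
        e = (self.clinical["event"] == "bc_death").to_numpy()
        return t, e.astype(int)


def record_from_row(row: pd.Series) -> ClinicalRecord:
    def _opt_status(v):
        return None if (v is None or (isinstance(v, float) and np.isnan(v)) or v == "") else v

    grade = row["grade"]
    grade = None if pd.isna(grade) else int(grade)
    return ClinicalRecord(
        patient_id=str(row["patient_id"]),
        age=float(row["age"]),
        er_status=row["er"],
        pr_status=_opt_status(row["pr"]),
        her2_status=row["her2"],
        ki67_status=_opt_status(row["ki67"]),
        grade=grade,
        tumour_size=float(row["size_mm"]),
        nodes_positive=int(row["nodes"]),
        detection_mode=row["detection"],
        chemo_generation=row["chemo"],
        hormone_therapy=bool(int(row["hormone"])),
        radiotherapy=bool(int(row["radio"])),
        trastuzumab=bool(int(row["trastuzumab"])),
        follow_up_time=float(row["time_years"]),
        event=row["event"],
    )


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read and validate the clinical CSV; empty strings become missing flags."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"clinical file missing mandatory column(s): {missing}")
    df = df[CLINICAL_COLUMNS].copy()
    for col in ("age", "size_mm", "time_years"):
        df[col] = pd.to_numeric(df[col].mask(df[col] == ""))
    for col in ("nodes", "grade"):
        df[col] = pd.to_numeric(df[col].mask(df[col] == "")).astype("Int64")
    for col in ("hormone", "radio", "trastuzumab"):
        df[col] = pd.to_numeric(df[col].mask(df[col] == "", "0")).astype(int)
    for col in ("pr", "ki67"):
        df[col] = df[col].mask(df[col] == "", None)
    bad_event = set(df["event"]) - EVENT_VALUES
    if bad_event:
        raise SchemaError(f"illegal event value(s): {sorted(bad_event)}")
    # validate row-wise through the record constructor
    for _, row in df.iterrows():
        record_from_row(row)
    return df


def read_expression(path: str | Path, transpose: bool = False) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix; genes in rows unless transposed."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if transpose:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df)


def read_cohort(clinical_path: str | Path, expression_path: str | Path,
                transpose: bool = False) -> Cohort:
    """Read and link clinical CSV with expression TSV.

    Patients lacking expression (and samples lacking clinical data) are
    dropped, with counts logged and recorded on the returned cohort.
    """
    clinical = read_clinical(clinical_path)
    expression = read_expression(expression_path, transpose=transpose)
    return link(clinical, expression)


def link(clinical: pd.DataFrame, expression: ExpressionMatrix) -> Cohort:
    clin_ids = list(clinical["patient_id"])
    expr_ids = set(expression.sample_ids)
    shared = [pid for pid in clin_ids if pid in expr_ids]
    if not shared:
        raise LinkageError("no overlapping ids between clinical and expression data")
    n_drop_clin = len(clin_ids) - len(shared)
    n_drop_expr = len(expr_ids) - len(shared)
    if n_drop_clin:
        logger.info("dropped %d clinical record(s) without expression", n_drop_clin)
    if n_drop_expr:
        logger.info("dropped %d expression sample(s) without clinical data", n_drop_expr)
    clin = clinical[clinical["patient_id"].isin(shared)].reset_index(drop=True)
    expr = expression.subset_samples(list(clin["patient_id"]))
    return Cohort(clin, expr, dropped_clinical=n_drop_clin, dropped_expression=n_drop_expr)


def write_cohort(cohort: Cohort, clinical_path: str | Path,
                 expression_path: str | Path) -> None:
    """Write the clinical CSV and expression TSV in the dialects read_cohort expects."""
    df = cohort.clinical.copy()
    for col in ("pr", "ki67"):
        df[col] = df[col].fillna("")
    df["grade"] = df["grade"].astype(object).where(df["grade"].notna(), "")
    df.to_csv(clinical_path, index=False)
    out = cohort.expression.values.copy()
    out.index.name = "gene_id"
    out.to_csv(expression_path, sep="\t")
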
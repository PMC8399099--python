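"""Reading, merging, cleaning and dichotomizing clinical + expression cohorts.

The analysis dataset pairs one row of follow-up/clinical data per patient
with a genes x patients expression matrix restricted to the same patients in
the same order.  Clinical features are reduced to the eight binary
confounders used by the multivariate hazard model (male sex, age > 65,
T3-4 tumours, node positivity, distant metastasis, late stage, positive
surgical margin, high tobacco exposure).

Expression values are continuous (log2 scale).  An entry is *null* when it
is missing in the input or, optionally, when it is exactly zero on the
stored scale (a not-expressed sentinel from the upstream quantifier); the
reader records the null mask separately so the continuous values stay
uncontaminated.  Genes null in more than ``max_null_fraction`` of patients
are removed before screening.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import CohortMergeError, ConfigurationError, IncompleteProfileError

__all__ = [
    "SurvivalRecord",
    "ClinicalProfile",
    "BinaryCovariates",
    "ExpressionMatrix",
    "AnalysisDataset",
    "COVARIATE_NAMES",
    "CLINICAL_FIELDS",
    "read_clinical_table",
    "read_expression_matrix",
    "merge_cohort",
    "filter_null_genes",
    "dichotomize",
    "summarize_cohort",
    "percentage",
    "write_dataset",
]

#: Binary covariates of the multivariate model, in fixed reporting order.
COVARIATE_NAMES = (
    "male",
    "age_gt_65",
    "t34",
    "n_positive",
    "m1",
    "late_stage",
    "margin_positive",
    "tobacco_high",
)

#: Clinical profile fields and their admissible levels (None = numeric).
CLINICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "gender": ("female", "male"),
    "clinical_t": ("T1", "T2", "T3", "T4"),
    "clinical_n": ("N0", "N1", "N2", "N3"),
    "clinical_m": ("M0", "M1"),
    "stage": ("I", "II", "III", "IV"),
    "margin": ("negative", "positive"),
}

CLINICAL_FIELDS = (
    "gender",
    "age_years",
    "clinical_t",
    "clinical_n",
    "clinical_m",
    "stage",
    "margin",
    "tobacco_pack_years",
)

#: Canonical input column names; a column_map may rename any of them.
REQUIRED_COLUMNS = ("patient_id", "time", "event")


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's follow-up: time in days and event indicator (1=death)."""

    patient_id: str
    time: float
    event: int

    def __post_init__(self):
        if self.time < 0:
            raise ValueError(f"negative survival time for {self.patient_id}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0/1, got {self.event!r}")


@dataclass(frozen=True)
class ClinicalProfile:
    """Raw clinical features; invalid or absent values are stored as None."""

    gender: str | None = None
    age_years: float | None = None
    clinical_t: str | None = None
    clinical_n: str | None = None
    clinical_m: str | None = None
    stage: str | None = None
    margin: str | None = None
    tobacco_pack_years: float | None = None

    def missing_fields(self, required: Sequence[str] = CLINICAL_FIELDS) -> list[str]:
        return [f for f in required if getattr(self, f) is None]

    @property
    def complete(self) -> bool:
        return not self.missing_fields()


@dataclass(frozen=True)
class BinaryCovariates:
    male: int
    age_gt_65: int
    t34: int
    n_positive: int
    m1: int
    late_stage: int
    margin_positive: int
    tobacco_high: int

    def as_dict(self) -> dict[str, int]:
        return {name: getattr(self, name) for name in COVARIATE_NAMES}


@dataclass
class ExpressionMatrix:
    """Genes x patients continuous values plus a boolean null mask."""

    values: pd.DataFrame
    null_mask: pd.DataFrame

    def __post_init__(self):
        if self.values.index.duplicated().any():
            raise ConfigurationError("duplicated gene symbols in expression matrix")
        if self.values.columns.duplicated().any():
            raise ConfigurationError("duplicated patient ids in expression matrix")
        if not self.null_mask.index.equals(self.values.index) or not self.null_mask.columns.equals(
            self.values.columns
        ):
            raise ValueError("null mask not aligned with values")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def patients(self) -> pd.Index:
        return self.values.columns

    def restrict_patients(self, patient_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[:, list(patient_ids)], self.null_mask.loc[:, list(patient_ids)]
        )

    def null_fractions(self) -> pd.Series:
        return self.null_mask.mean(axis=1)


@dataclass
class AnalysisDataset:
    """Aligned clinical table (time, event, binary covariates) + expression."""

    clinical: pd.DataFrame
    expression: ExpressionMatrix
    profiles: pd.DataFrame | None = None

    def __post_init__(self):
        if list(self.clinical.index) != list(self.expression.patients):
            raise ValueError("clinical and expression patient order differ")

    @property
    def n_patients(self) -> int:
        return len(self.clinical)

    @property
    def patients(self) -> pd.Index:
        return self.clinical.index

    @property
    def genes(self) -> pd.Index:
        return self.expression.genes

    @property
    def times(self) -> np.ndarray:
        return self.clinical["time"].to_numpy(float)

    @property
    def events(self) -> np.ndarray:
        return self.clinical["event"].to_numpy(int)

    def covariate_frame(self) -> pd.DataFrame:
        return self.clinical[list(COVARIATE_NAMES)]

    def gene_values(self, gene: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (values, null_mask) for one gene, aligned with patients."""
        return (
            self.expression.values.loc[gene].to_numpy(float),
            self.expression.null_mask.loc[gene].to_numpy(bool),
        )

    def with_expression(self, expr: ExpressionMatrix) -> "AnalysisDataset":
        return AnalysisDataset(self.clinical, expr, self.profiles)


# ---------------------------------------------------------------------------
# readers


def _read_delimited(path: str | Path, sep: str | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype=str, comment="#")


def _norm_level(field_name: str, raw: object) -> str | None:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    text = str(raw).strip()
    if not text or text.lower() in ("na", "nan", ""):
        return None
    levels = CLINICAL_LEVELS[field_name]
    for level in levels:
        if text.lower() == level.lower():
            return level
    # accept e.g. "Stage III" / "stage iv"
    if field_name == "stage":
        tail = text.split()[-1].upper()
        if tail in levels:
            return tail
    return None


def _norm_number(raw: object, minimum: float | None = None) -> float | None:
    try:
        value = float(raw)
    except (TypeError, ValueError):
        return None
    if not np.isfinite(value):
        return None
    if minimum is not None and value < minimum:
        return None
    return value


def read_clinical_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> tuple[list[tuple[SurvivalRecord, ClinicalProfile]], list[dict]]:
    """Read a delimited clinical table.

    ``column_map`` maps canonical field names (``patient_id``, ``time``,
    ``event``, plus the clinical profile fields) to the file's column names.
    Rows whose time/event cannot be parsed are reported in the second return
    value rather than silently dropped.
    """
    frame = _read_delimited(path, sep)
    column_map = dict(column_map or {})
    colname = {canon: column_map.get(canon, canon) for canon in REQUIRED_COLUMNS + CLINICAL_FIELDS}
    for canon in REQUIRED_COLUMNS:
        if colname[canon] not in frame.columns:
            raise ConfigurationError(
                f"required clinical column {colname[canon]!r} (field {canon!r}) not found in {path}"
            )

    records: list[tuple[SurvivalRecord, ClinicalProfile]] = []
    invalid: list[dict] = []
    seen: set[str] = set()
    for idx, row in frame.iterrows():
        pid = str(row[colname["patient_id"]]).strip()
        time = _norm_number(row.get(colname["time"]), minimum=0.0)
        event_raw = _norm_number(row.get(colname["event"]))
        event = int(event_raw) if event_raw in (0.0, 1.0) else None
        if not pid or pid.lower() == "nan":
            invalid.append({"row": int(idx), "patient_id": pid, "reason": "missing patient id"})
            continue
        if pid in seen:
            invalid.append({"row": int(idx), "patient_id": pid, "reason": "duplicate patient id"})
            continue
        if time is None or event is None:
            invalid.append(
                {"row": int(idx), "patient_id": pid, "reason": "unparseable time or event"}
            )
            continue
        seen.add(pid)
        profile = ClinicalProfile(
            gender=_norm_level("gender", row.get(colname["gender"])),
            age_years=_norm_number(row.get(colname["age_years"]), minimum=0.0),
            clinical_t=_norm_level("clinical_t", row.get(colname["clinical_t"])),
            clinical_n=_norm_level("clinical_n", row.get(colname["clinical_n"])),
            clinical_m=_norm_level("clinical_m", row.get(colname["clinical_m"])),
            stage=_norm_level("stage", row.get(colname["stage"])),
            margin=_norm_level("margin", row.get(colname["margin"])),
            tobacco_pack_years=_norm_number(row.get(colname["tobacco_pack_years"]), minimum=0.0),
        )
        records.append((SurvivalRecord(pid, time, event), profile))
    return records, invalid


def read_expression_matrix(
    path: str | Path, sep: str | None = None, zero_is_null: bool = True
) -> ExpressionMatrix:
    """Read a genes x patients matrix (first column = gene symbol).

    Missing entries and, when ``zero_is_null``, exact zeros (the upstream
    not-expressed sentinel) are recorded in the null mask.  Duplicate gene
    rows or patient columns are dropped keeping the first occurrence.
    """
    frame = _read_delimited(path, sep)
    if frame.shape[1] < 2:
        raise ConfigurationError(f"expression file {path} needs a gene column plus patients")
    gene_col = frame.columns[0]
    frame = frame[~frame[gene_col].duplicated(keep="first")]
    frame = frame.loc[:, ~frame.columns.duplicated(keep="first")]
    frame = frame.set_index(gene_col)
    values = frame.apply(pd.to_numeric, errors="coerce")
    mask = values.isna()
    if zero_is_null:
        mask = mask | (values == 0.0)
    values.index.name = "gene"
    return ExpressionMatrix(values, mask)


# ---------------------------------------------------------------------------
# dichotomization


def dichotomize(profile: ClinicalProfile, tobacco_split: float) -> BinaryCovariates:
    """Reduce a complete clinical profile to the eight binary covariates.

    Reference levels (covariate = 0): female, age <= 65, T1-2, N0, M0,
    stage I-II, negative margin, pack-years <= ``tobacco_split``.
    """
    missing = profile.missing_fields()
    if missing:
        raise IncompleteProfileError(missing[0])
    return BinaryCovariates(
        male=int(profile.gender == "male"),
        age_gt_65=int(profile.age_years > 65),
        t34=int(profile.clinical_t in ("T3", "T4")),
        n_positive=int(profile.clinical_n != "N0"),
        m1=int(profile.clinical_m == "M1"),
        late_stage=int(profile.stage in ("III", "IV")),
        margin_positive=int(profile.margin == "positive"),
        tobacco_high=int(profile.tobacco_pack_years > tobacco_split),
    )


# ---------------------------------------------------------------------------
# merging and cleaning


def merge_cohort(
    clinical: Sequence[tuple[SurvivalRecord, ClinicalProfile]],
    expr: ExpressionMatrix,
    required_fields: Sequence[str] = CLINICAL_FIELDS,
    tobacco_split: float | None = None,
) -> tuple[AnalysisDataset, dict]:
    """Inner-join clinical records and expression columns on patient id.

    Patients missing any required clinical field are dropped and reported.
    ``tobacco_split`` defaults to the median pack-years of the joined,
    otherwise-complete patients.
    """
    if not clinical:
        raise ConfigurationError("empty clinical cohort")
    if expr.values.empty:
        raise ConfigurationError("empty expression matrix")
    by_id = {rec.patient_id: (rec, prof) for rec, prof in clinical}
    joined = [pid for pid in expr.patients if pid in by_id]
    if not joined:
        raise CohortMergeError(
            "no patient id occurs in both the clinical table and the expression matrix; "
            "check the identifier scheme"
        )

    required = [f for f in required_fields]
    complete, dropped = [], []
    for pid in joined:
        _, prof = by_id[pid]
        missing = prof.missing_fields(required)
        if missing:
            dropped.append({"patient_id": pid, "missing": missing})
        else:
            complete.append(pid)
    if not complete:
        raise CohortMergeError("no joined patient has complete clinical information")

    if tobacco_split is None:
        packs = [by_id[p][1].tobacco_pack_years for p in complete]
        packs = [v for v in packs if v is not None]
        tobacco_split = float(np.median(packs)) if packs else 0.0

    rows, profile_rows = [], []
    for pid in complete:
        rec, prof = by_id[pid]
        cov = dichotomize(prof, tobacco_split)
        rows.append({"time": rec.time, "event": rec.event, **cov.as_dict()})
        profile_rows.append({f: getattr(prof, f) for f in CLINICAL_FIELDS})
    clinical_df = pd.DataFrame(rows, index=pd.Index(complete, name="patient_id"))
    profiles_df = pd.DataFrame(profile_rows, index=clinical_df.index)
    dataset = AnalysisDataset(clinical_df, expr.restrict_patients(complete), profiles_df)
    report = {
        "n_clinical": len(clinical),
        "n_expression": int(len(expr.patients)),
        "n_joined": len(joined),
        "n_retained": len(complete),
        "tobacco_split": tobacco_split,
        "dropped_incomplete": dropped,
    }
    return dataset, report


def filter_null_genes(
    expr: ExpressionMatrix, max_null_fraction: float = 0.30
) -> tuple[ExpressionMatrix, dict]:
    """Remove genes whose null fraction strictly exceeds ``max_null_fraction``.

    The comparison is strict ("more than"): a gene null in exactly the
    threshold fraction of patients is retained.
    """
    if not (0 < max_null_fraction < 1):
        raise ConfigurationError("max_null_fraction must be in (0, 1)")
    frac = expr.null_fractions()
    removed = frac.index[frac > max_null_fraction]
    kept = frac.index[~(frac > max_null_fraction)]
    out = ExpressionMatrix(expr.values.loc[kept], expr.null_mask.loc[kept])
    report = {
        "max_null_fraction": max_null_fraction,
        "n_input": int(len(frac)),
        "n_removed": int(len(removed)),
        "removed": [
            {"gene": g, "null_fraction": float(frac[g])} for g in removed
        ],
    }
    return out, report


# ---------------------------------------------------------------------------
# summaries


def percentage(count: int, total: int) -> float:
    """100*count/total rounded half-up to one decimal (presentation rule)."""
    if total <= 0:
        raise ValueError("total must be positive")
    value = Decimal(100 * count) / Decimal(total)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize_cohort(
    records: Iterable[ClinicalProfile | tuple[SurvivalRecord, ClinicalProfile]],
) -> dict[str, list[tuple[str, int, float]]]:
    """Counts and percentages per clinical feature level.

    Accepts profiles or (record, profile) pairs.  Unknown/missing levels are
    tallied under ``"missing"``.  Age is summarized as the <=65 / >65 split.
    """
    profiles = [r[1] if isinstance(r, tuple) else r for r in records]
    if not profiles:
        raise ValueError("empty cohort")
    n = len(profiles)
    summary: dict[str, list[tuple[str, int, float]]] = {}
    for fieldname, levels in CLINICAL_LEVELS.items():
        counts: dict[str, int] = {}
        for p in profiles:
            level = getattr(p, fieldname) or "missing"
            counts[level] = counts.get(level, 0) + 1
        summary[fieldname] = [
            (lv, counts[lv], percentage(counts[lv], n))
            for lv in list(levels) + ["missing"]
            if counts.get(lv)
        ]
    le65 = sum(1 for p in profiles if p.age_years is not None and p.age_years <= 65)
    gt65 = sum(1 for p in profiles if p.age_years is not None and p.age_years > 65)
    summary["age"] = [
        (lv, c, percentage(c, n)) for lv, c in (("<=65", le65), (">65", gt65)) if c
    ]
    return summary


# ---------------------------------------------------------------------------
# serialization


def write_dataset(dataset: AnalysisDataset, outdir: str | Path, report: dict | None = None) -> None:
    """Write the cleaned dataset as two TSVs plus a JSON cleaning report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset.clinical.to_csv(outdir / "clinical_clean.tsv", sep="\t")
    expr = dataset.expression.values.copy()
    expr[dataset.expression.null_mask] = np.nan
    expr.to_csv(outdir / "expression_clean.tsv", sep="\t")
    (outdir / "cleaning_report.json").write_text(json.dumps(report or {}, indent=2) + "\n")
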
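"""Claims-side data model: loading and validation of claim lines, enrollment
spans, patient records and gold-standard subtype labels, plus the cohort
eligibility rules (intake window, adult age, continuous enrollment).

In-memory containers are plain :class:`pandas.DataFrame` objects with the
documented column schemas; dates are held as ``datetime64[ns]`` timestamps.

Schemas
-------
claims      : patient_id, service_date, code_system, code
enrollment  : patient_id, start, end
patients    : patient_id, index_date, age_at_index, gender, bmi, dci_score,
              cancer_stage, insurance, region
labels      : patient_id, subtype
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import RowParseError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

ONE_DAY = pd.Timedelta(days=1)

CODE_SYSTEMS = frozenset(
    {"GPI", "HCPCS", "CPT", "ICD9_PROC", "ICD10_PROC", "ICD9_DX", "ICD10_DX"}
)
SUBTYPES = ("NSCLC", "SCLC")
STAGES = ("0", "IA", "IB", "IIA", "IIB", "IIIA", "IIIB", "IV", "Limited")
GENDERS = ("male", "female")
INSURANCE_TYPES = ("commercial", "medicare_supplemental")
REGIONS = ("Northeast", "Midwest", "South", "West")

CLAIMS_COLUMNS = ("patient_id", "service_date", "code_system", "code")
ENROLLMENT_COLUMNS = ("patient_id", "start", "end")
PATIENT_COLUMNS = (
    "patient_id",
    "index_date",
    "age_at_index",
    "gender",
    "bmi",
    "dci_score",
    "cancer_stage",
    "insurance",
    "region",
)
LABEL_COLUMNS = ("patient_id", "subtype")

#: 3 calendar months are counted as 90 days (30-day months), the usual
#: convention in claims research; override via the days_per_month argument.
DAYS_PER_MONTH = 30


# ---------------------------------------------------------------------------
# file readers
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited (CSV) or columnar (Parquet) table with string cells."""
    path = Path(path)
    if path.suffix.lower() in {".parquet", ".pq"}:
        df = pd.read_parquet(path)
        return df.astype({c: str for c in df.columns if df[c].dtype == object})
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path: str | Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def _parse_date_column(df: pd.DataFrame, column: str, path: str | Path) -> pd.Series:
    """Parse an ISO-8601 date column; report the first bad row by file line."""
    parsed = pd.to_datetime(df[column], format="ISO8601", errors="coerce")
    bad = parsed.isna()
    if bad.any():
        i = int(bad.idxmax())
        # header occupies line 1, data row i sits on line i + 2
        raise RowParseError(
            f"{path} line {i + 2}: unparseable date {df[column].iloc[i]!r} "
            f"in column {column!r}"
        )
    return parsed


def load_claims(path: str | Path) -> pd.DataFrame:
    """Load claim lines; duplicates of (patient_id, service_date, code_system,
    code) are dropped, matching how adjudicated claim extracts are deduplicated."""
    df = _read_table(path)
    _require_columns(df, CLAIMS_COLUMNS, path)
    df = df.loc[:, list(CLAIMS_COLUMNS)].copy()
    df["service_date"] = _parse_date_column(df, "service_date", path)
    unknown = set(df["code_system"]) - CODE_SYSTEMS
    if unknown:
        raise ValidationError(
            f"{path}: unknown code system(s): {', '.join(sorted(unknown))}"
        )
    if (df["code"].astype(str).str.len() == 0).any():
        raise ValidationError(f"{path}: empty claim code encountered")
    n_raw = len(df)
    df = df.drop_duplicates(list(CLAIMS_COLUMNS)).reset_index(drop=True)
    logger.info("claims: %d rows read, %d retained after dedup", n_raw, len(df))
    return df


def merge_spans(spans: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping and abutting enrollment spans per patient.

    Two spans abut when one ends the day before the next starts; coverage is
    continuous across such a boundary, so they are stored as one span.
    """
    if spans.empty:
        return spans.reset_index(drop=True)
    df = spans.sort_values(["patient_id", "start", "end"], kind="stable").reset_index(drop=True)
    cummax_end = df.groupby("patient_id", sort=False)["end"].cummax()
    prev_end = cummax_end.groupby(df["patient_id"], sort=False).shift(1)
    new_block = prev_end.isna() | (df["start"] > prev_end + ONE_DAY)
    block = new_block.cumsum()
    merged = (
        df.groupby(["patient_id", block], sort=False)
        .agg(start=("start", "min"), end=("end", "max"))
        .reset_index(level=0)
        .reset_index(drop=True)
    )
    return merged[["patient_id", "start", "end"]]


def load_enrollment(path: str | Path) -> pd.DataFrame:
    """Load enrollment spans, validating start <= end and merging per patient."""
    df = _read_table(path)
    _require_columns(df, ENROLLMENT_COLUMNS, path)
    df = df.loc[:, list(ENROLLMENT_COLUMNS)].copy()
    df["start"] = _parse_date_column(df, "start", path)
    df["end"] = _parse_date_column(df, "end", path)
    bad = df["start"] > df["end"]
    if bad.any():
        i = int(bad.idxmax())
        raise RowParseError(f"{path} line {i + 2}: enrollment span start after end")
    n_raw = len(df)
    df = merge_spans(df)
    logger.info("enrollment: %d rows read, %d merged spans", n_raw, len(df))
    return df


def load_patients(path: str | Path) -> pd.DataFrame:
    """Load patient records with demographics; enum columns are validated
    against the recognised category sets (blank cells are allowed and kept
    as missing)."""
    df = _read_table(path)
    _require_columns(df, PATIENT_COLUMNS, path)
    df = df.loc[:, list(PATIENT_COLUMNS)].copy()
    df["index_date"] = _parse_date_column(df, "index_date", path)
    for col in ("age_at_index", "bmi", "dci_score"):
        df[col] = pd.to_numeric(df[col].replace("", None), errors="coerce")
    if (df["age_at_index"].dropna() < 0).any():
        raise ValidationError(f"{path}: negative age_at_index")
    if (df["bmi"].dropna() <= 0).any():
        raise ValidationError(f"{path}: non-positive BMI")
    for col, allowed in (
        ("cancer_stage", STAGES),
        ("gender", GENDERS),
        ("insurance", INSURANCE_TYPES),
        ("region", REGIONS),
    ):
        values = set(df[col]) - {""} - set(allowed)
        if values:
            raise ValidationError(
                f"{path}: unknown {col} value(s): {', '.join(sorted(map(str, values)))}"
            )
    dup = df["patient_id"].duplicated()
    if dup.any():
        raise ValidationError(f"{path}: duplicate patient_id {df['patient_id'][dup].iloc[0]!r}")
    logger.info("patients: %d rows read", len(df))
    return df


def load_labels(path: str | Path) -> pd.DataFrame:
    """Load gold-standard subtype labels (exactly one NSCLC/SCLC per patient)."""
    df = _read_table(path)
    _require_columns(df, LABEL_COLUMNS, path)
    df = df.loc[:, list(LABEL_COLUMNS)].copy()
    bad = set(df["subtype"]) - set(SUBTYPES)
    if bad:
        raise ValidationError(
            f"{path}: subtype must be one of {SUBTYPES}, got: {', '.join(sorted(bad))}"
        )
    dup = df["patient_id"].duplicated()
    if dup.any():
        raise ValidationError(
            f"{path}: more than one label for patient {df['patient_id'][dup].iloc[0]!r}"
        )
    logger.info("labels: %d rows read", len(df))
    return df


def load_cohort(
    claims_path: str | Path,
    enrollment_path: str | Path,
    patients_path: str | Path,
    labels_path: str | Path,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Load and validate the four cohort tables.

    Returns ``(claims, spans, patients, labels)`` with claims deduplicated
    and enrollment spans merged per patient.
    """
    claims = load_claims(claims_path)
    spans = load_enrollment(enrollment_path)
    patients = load_patients(patients_path)
    labels = load_labels(labels_path)
    return claims, spans, patients, labels


# ---------------------------------------------------------------------------
# eligibility
# ---------------------------------------------------------------------------

def _as_span_pairs(spans) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    if isinstance(spans, pd.DataFrame):
        return [
            (pd.Timestamp(s), pd.Timestamp(e))
            for s, e in zip(spans["start"], spans["end"])
        ]
    return [(pd.Timestamp(s), pd.Timestamp(e)) for s, e in spans]


def check_continuous_enrollment(
    spans,
    index_date,
    pre_months: int = 3,
    post_months: int = 3,
    gap_tolerance_days: int = 0,
    days_per_month: int = DAYS_PER_MONTH,
) -> bool:
    """Is the patient continuously enrolled around the index date?

    The window is ``[index - pre_months*days_per_month,
    index + post_months*days_per_month]``, inclusive at both ends.  The check
    passes when no single uncovered run inside the window exceeds
    ``gap_tolerance_days`` days.  An empty span set fails (returns False).

    Parameters
    ----------
    spans : DataFrame with start/end columns, or iterable of (start, end)
        Enrollment spans of a single patient.
    """
    if pre_months < 0 or post_months < 0 or gap_tolerance_days < 0:
        raise ValueError("pre/post months and gap tolerance must be non-negative")
    index = pd.Timestamp(index_date)
    win_start = index - pd.Timedelta(days=pre_months * days_per_month)
    win_end = index + pd.Timedelta(days=post_months * days_per_month)
    pairs = sorted(_as_span_pairs(spans))

    max_gap = 0
    cursor = win_start  # first day not yet known to be covered
    for start, end in pairs:
        if end < cursor:
            continue
        if start > cursor:
            gap_end = min(start - ONE_DAY, win_end)
            max_gap = max(max_gap, (gap_end - cursor).days + 1)
        cursor = max(cursor, end + ONE_DAY)
        if cursor > win_end:
            break
    if cursor <= win_end:
        max_gap = max(max_gap, (win_end - cursor).days + 1)
    return max_gap <= gap_tolerance_days


def select_eligible(
    patients: pd.DataFrame,
    spans: pd.DataFrame,
    intake_start,
    intake_end,
    labels: pd.DataFrame | None = None,
    min_age: float = 18,
    pre_months: int = 3,
    post_months: int = 3,
    gap_tolerance_days: int = 0,
    days_per_month: int = DAYS_PER_MONTH,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the cohort eligibility rules and tally exclusions.

    Rules, applied in this fixed order (each patient is tallied under the
    first rule that excludes them):

    1. ``missing_label`` — no gold-standard subtype (only when *labels* given)
    2. ``outside_intake_window`` — index date outside [intake_start, intake_end]
    3. ``under_min_age`` — age at index below *min_age* (or missing)
    4. ``not_continuously_enrolled`` — fails :func:`check_continuous_enrollment`

    Returns the retained patients (same columns, original order) and an
    attrition tally whose counts sum to the input count.
    """
    intake_start = pd.Timestamp(intake_start)
    intake_end = pd.Timestamp(intake_end)
    if intake_start > intake_end:
        raise ValueError("intake_start must not be after intake_end")

    tally: dict[str, int] = {
        "input": len(patients),
        "missing_label": 0,
        "outside_intake_window": 0,
        "under_min_age": 0,
        "not_continuously_enrolled": 0,
        "retained": 0,
    }
    labelled = set(labels["patient_id"]) if labels is not None else None
    spans_by_patient: Mapping[str, pd.DataFrame] = (
        {pid: g for pid, g in spans.groupby("patient_id", sort=False)}
        if len(spans)
        else {}
    )

    keep: list[bool] = []
    for row in patients.itertuples(index=False):
        if labelled is not None and row.patient_id not in labelled:
            tally["missing_label"] += 1
            keep.append(False)
            continue
        if not (intake_start <= row.index_date <= intake_end):
            tally["outside_intake_window"] += 1
            keep.append(False)
            continue
        if pd.isna(row.age_at_index) or row.age_at_index < min_age:
            tally["under_min_age"] += 1
            keep.append(False)
            continue
        patient_spans = spans_by_patient.get(row.patient_id)
        ok = patient_spans is not None and check_continuous_enrollment(
            patient_spans,
            row.index_date,
            pre_months=pre_months,
            post_months=post_months,
            gap_tolerance_days=gap_tolerance_days,
            days_per_month=days_per_month,
        )
        if not ok:
            tally["not_continuously_enrolled"] += 1
            keep.append(False)
            continue
        keep.append(True)

    eligible = patients.loc[keep].reset_index(drop=True)
    tally["retained"] = len(eligible)
    logger.info("eligibility: %s", tally)
    return eligible, tally
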
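"""Cohort CSV schema, readers/writers and report rendering.

The cohort file is a wide CSV with a schema-version header comment on its
first line (``# gestage-cohort v1``). Dates are ISO-8601 only; ambiguous
day/month orderings are refused, never guessed — misrecorded dates are the
very failure mode the pipeline studies. Ultrasound exams are stored wide
(``us1_date,us1_ga_days,…``, K columns sized to the cohort); a long-format
companion file is not needed for the sizes this package targets.

Malformed rows are skipped, not fatal: each skip is logged with the row
number and reason, and :func:`read_cohort` returns the issue list alongside
the records.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from gestage.errors import CohortSchemaError
from gestage.records import PregnancyRecord, Sex, UltrasoundExam

logger = logging.getLogger(__name__)

SCHEMA_HEADER = "# gestage-cohort v1"

_FIXED_COLUMNS = [
    "id",
    "lmp_date",
    "lmp_certain",
    "capurro_ga_days",
    "birth_date",
    "birth_weight_g",
    "sex",
    "city",
    "age_group",
    "ethnicity",
    "schooling",
    "marital",
    "parity",
]
_COVARIATES = ["city", "age_group", "ethnicity", "schooling", "marital", "parity"]


@dataclass(frozen=True)
class RowIssue:
    row: int  # 1-based data-row number
    record_id: str
    reason: str


def _parse_iso_date(value: str, field: str) -> dt.date:
    try:
        return dt.date.fromisoformat(value)
    except ValueError as exc:
        raise ValueError(f"{field}: not an ISO-8601 date: {value!r}") from exc


def write_cohort(records: list[PregnancyRecord], path: str | Path) -> None:
    """Write a cohort in the versioned wide CSV schema."""
    max_exams = max((len(r.us_exams) for r in records), default=0)
    exam_cols = []
    for k in range(1, max_exams + 1):
        exam_cols += [f"us{k}_date", f"us{k}_ga_days"]
    rows = []
    for r in records:
        row: dict = {
            "id": r.id,
            "lmp_date": r.lmp_date.isoformat() if r.lmp_date else "",
            "lmp_certain": ""
            if r.lmp_certain is None
            else int(r.lmp_certain),
            "capurro_ga_days": "" if r.capurro_ga_days is None else r.capurro_ga_days,
            "birth_date": r.birth_date.isoformat(),
            "birth_weight_g": r.birth_weight_g,
            "sex": r.infant_sex.value,
        }
        for cov in _COVARIATES:
            row[cov] = r.covariates.get(cov, "")
        for k, exam in enumerate(r.us_exams, start=1):
            row[f"us{k}_date"] = exam.exam_date.isoformat()
            row[f"us{k}_ga_days"] = str(exam.ga_at_exam_days)
        rows.append(row)
    frame = pd.DataFrame(rows, columns=_FIXED_COLUMNS + exam_cols)
    frame = frame.fillna("").astype(str)
    with open(path, "w", newline="") as fh:
        fh.write(SCHEMA_HEADER + "\n")
        frame.to_csv(fh, index=False)


def read_cohort(path: str | Path) -> tuple[list[PregnancyRecord], list[RowIssue]]:
    """Read a cohort file; well-formed rows become records, malformed rows
    are skipped and reported in the issue list.

    Raises CohortSchemaError for an unreadable file or an unknown schema
    version.
    """
    path = Path(path)
    if not path.exists():
        raise CohortSchemaError(f"cohort file not found: {path}")
    with open(path) as fh:
        first = fh.readline().strip()
        if first != SCHEMA_HEADER:
            raise CohortSchemaError(
                f"{path}: missing or unsupported schema header {first!r} "
                f"(expected {SCHEMA_HEADER!r})"
            )
        frame = pd.read_csv(fh, dtype=str, keep_default_na=False)
    missing_cols = set(_FIXED_COLUMNS) - set(frame.columns)
    if missing_cols:
        raise CohortSchemaError(f"{path}: missing columns {sorted(missing_cols)}")
    exam_indices = sorted(
        int(c[2:-5]) for c in frame.columns if c.startswith("us") and c.endswith("_date")
    )

    records: list[PregnancyRecord] = []
    issues: list[RowIssue] = []
    seen_ids: set[str] = set()
    for row_number, row in enumerate(frame.itertuples(index=False), start=1):
        data = dict(zip(frame.columns, row))
        rid = data["id"]
        try:
            if not rid:
                raise ValueError("id: empty")
            if rid in seen_ids:
                raise ValueError(f"id: duplicate {rid!r}")
            birth_date = _parse_iso_date(data["birth_date"], "birth_date")
            exams = []
            for k in exam_indices:
                date_s = data.get(f"us{k}_date", "")
                ga_s = data.get(f"us{k}_ga_days", "")
                if not date_s and not ga_s:
                    continue
                if not date_s or not ga_s:
                    raise ValueError(f"us{k}: date and ga_days must both be present")
                exams.append(
                    UltrasoundExam(
                        exam_date=_parse_iso_date(date_s, f"us{k}_date"),
                        ga_at_exam_days=int(ga_s),
                    )
                )
            record = PregnancyRecord(
                id=rid,
                birth_date=birth_date,
                birth_weight_g=float(data["birth_weight_g"]),
                infant_sex=Sex(data["sex"]),
                lmp_date=_parse_iso_date(data["lmp_date"], "lmp_date")
                if data["lmp_date"]
                else None,
                lmp_certain=None
                if data["lmp_certain"] == ""
                else bool(int(data["lmp_certain"])),
                us_exams=exams,
                capurro_ga_days=int(data["capurro_ga_days"])
                if data["capurro_ga_days"]
                else None,
                covariates={
                    cov: data[cov] for cov in _COVARIATES if data.get(cov)
                },
            )
        except (ValueError, TypeError) as exc:
            reason = str(exc).splitlines()[0]
            issues.append(RowIssue(row=row_number, record_id=rid, reason=reason))
            logger.warning("row %d (%s) skipped: %s", row_number, rid, reason)
            continue
        seen_ids.add(rid)
        records.append(record)
    logger.info(
        "read %d records from %s (%d rows skipped)", len(records), path, len(issues)
    )
    return records, issues


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"id": str})


# ---------------------------------------------------------------------------
# report rendering


def _fmt(value, decimals: int = 2) -> str:
    """Render a metric: '—' for not-defined, fixed decimals otherwise."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return "—"
    if isinstance(value, float):
        return f"{value:.{decimals}f}"
    return str(value)


def write_report_csv(
    frame: pd.DataFrame, path: str | Path, *, config_hash: str, seed: int
) -> None:
    """Write a report table as CSV with a provenance header comment."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# gestage-report v1 config_hash={config_hash} seed={seed}\n")
        frame.to_csv(fh, index=False)


def render_text_table(
    frame: pd.DataFrame, title: str, *, config_hash: str, seed: int,
    footnotes: list[str] | None = None,
) -> str:
    """Aligned plain-text rendering of a report frame."""
    out = [f"# {title}", f"# config_hash={config_hash} seed={seed}", ""]
    display = frame.copy()
    for col in display.columns:
        display[col] = [_fmt(v) for v in display[col]]
    widths = {
        col: max(len(str(col)), *(len(v) for v in display[col])) if len(display) else len(str(col))
        for col in display.columns
    }
    out.append("  ".join(str(c).ljust(widths[c]) for c in display.columns))
    out.append("  ".join("-" * widths[c] for c in display.columns))
    for _, row in display.iterrows():
        out.append("  ".join(str(row[c]).ljust(widths[c]) for c in display.columns))
    for note in footnotes or []:
        out.append(f"note: {note}")
    return "\n".join(out) + "\n"
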
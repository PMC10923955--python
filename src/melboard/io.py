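"""CSV/JSON round-tripping for case records and cohort reports.

The case table is one row per tumor-board registration, comma-separated,
decimal-point millimeters for Breslow thickness and ISO-8601 dates, so files
are bit-comparable across implementations. Unknowns are explicit: a blank
cell maps to the field's explicit unknown member (never to zero), and
enumerations are closed — an out-of-domain value is a row error, reported
with its line number, not a silent coercion.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
from pydantic import ValidationError

from .records import (
    CaseRecord,
    Ldh,
    MetastaticSite,
    Mutation,
    Origin,
    Presentation,
    SlnbResult,
    RStatus,
    Ulceration,
)

CASE_COLUMNS: tuple[str, ...] = (
    "case_id",
    "age",
    "histotype",
    "ecog",
    "decision_date",
    "origin",
    "presentation",
    "breslow_mm",
    "ulceration",
    "occult_positive_nodes",
    "clinically_detected_nodes",
    "matted_nodes",
    "in_transit_or_satellite",
    "metastatic_sites",
    "ldh",
    "unclear_radiology",
    "slnb",
    "cnd_performed",
    "r_status",
    "mutation",
    "relapse",
    "secondary_cancer",
    "severe_comorbidity",
    "clinical_trial",
    "complex_constellation",
    "mdt_code",
)

_BOOL_COLUMNS = {
    "matted_nodes",
    "in_transit_or_satellite",
    "unclear_radiology",
    "relapse",
    "secondary_cancer",
    "severe_comorbidity",
    "clinical_trial",
    "complex_constellation",
}


@dataclasses.dataclass(frozen=True)
class RowError:
    line: int  # 1-based line number in the file (header is line 1)
    message: str

    def __str__(self) -> str:
        return f"line {self.line}: {self.message}"


def record_to_row(case: CaseRecord) -> dict[str, str]:
    def fmt(value) -> str:
        if value is None:
            return ""
        if isinstance(value, bool):
            return "true" if value else "false"
        if isinstance(value, _dt.date):
            return value.isoformat()
        if hasattr(value, "value"):
            return str(value.value)
        return str(value)

    row = {col: fmt(getattr(case, col)) for col in CASE_COLUMNS if col != "metastatic_sites"}
    sites = sorted(s.value for s in case.metastatic_sites)
    row["metastatic_sites"] = ";".join(sites)
    return row


def _parse_bool(raw: str, column: str) -> bool:
    low = raw.strip().lower()
    if low in ("true", "1", "yes"):
        return True
    if low in ("false", "0", "no", ""):
        return False
    raise ValueError(f"{column}: {raw!r} is not a boolean")


def row_to_record(row: dict[str, str]) -> CaseRecord:
    """Parse one CSV row; blank cells map to explicit unknowns/defaults."""
    get = lambda col: (row.get(col) or "").strip()
    kwargs: dict[str, object] = {"case_id": get("case_id")}
    if not kwargs["case_id"]:
        raise ValueError("case_id is required")
    kwargs["age"] = float(get("age"))
    kwargs["histotype"] = get("histotype") or None
    kwargs["ecog"] = int(get("ecog")) if get("ecog") else None
    kwargs["decision_date"] = (
        _dt.date.fromisoformat(get("decision_date")) if get("decision_date") else None
    )
    kwargs["origin"] = Origin(get("origin") or "cutaneous")
    kwargs["presentation"] = Presentation(get("presentation") or "primary_localized")
    kwargs["breslow_mm"] = float(get("breslow_mm")) if get("breslow_mm") else None
    kwargs["ulceration"] = Ulceration(get("ulceration") or "unknown")
    kwargs["occult_positive_nodes"] = int(get("occult_positive_nodes") or 0)
    kwargs["clinically_detected_nodes"] = int(get("clinically_detected_nodes") or 0)
    sites_raw = get("metastatic_sites")
    if sites_raw:
        kwargs["metastatic_sites"] = frozenset(
            MetastaticSite(s.strip()) for s in sites_raw.split(";") if s.strip()
        )
    kwargs["ldh"] = Ldh(get("ldh") or "unknown")
    kwargs["slnb"] = SlnbResult(get("slnb") or "unknown")
    cnd = get("cnd_performed")
    kwargs["cnd_performed"] = None if not cnd else _parse_bool(cnd, "cnd_performed")
    kwargs["r_status"] = RStatus(get("r_status") or "not_applicable")
    kwargs["mutation"] = Mutation(get("mutation") or "unknown")
    for col in _BOOL_COLUMNS:
        kwargs[col] = _parse_bool(get(col), col)
    kwargs["mdt_code"] = get("mdt_code") or None
    return CaseRecord(**kwargs)


def read_cases(path: Union[str, Path]) -> tuple[list[CaseRecord], list[RowError]]:
    """Read a case table; returns valid records plus line-numbered errors.

    Unknown columns are a file-level error (raised); bad values are row-level
    errors collected alongside the rows that did parse.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    unknown = set(df.columns) - set(CASE_COLUMNS)
    if unknown:
        raise ValueError(f"unknown columns in {path}: {sorted(unknown)}")
    records: list[CaseRecord] = []
    errors: list[RowError] = []
    for i, row in enumerate(df.to_dict(orient="records")):
        line = i + 2  # header occupies line 1
        try:
            records.append(row_to_record(row))
        except (ValueError, ValidationError) as exc:
            errors.append(RowError(line, _short_error(exc)))
    return records, errors


def _short_error(exc: Exception) -> str:
    if isinstance(exc, ValidationError):
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"]) or "record"
        return f"{loc}: {first['msg']}"
    return str(exc)


def write_cases(records: Sequence[CaseRecord], path: Union[str, Path]) -> None:
    df = pd.DataFrame([record_to_row(c) for c in records], columns=list(CASE_COLUMNS))
    df.to_csv(path, index=False)


def write_report(
    report: dict,
    path: Union[str, Path],
    *,
    tool_version: Optional[str] = None,
    kb_version: Optional[str] = None,
) -> dict:
    """Write a JSON report with tool/knowledge-base version stamps.

    Returns the exact structure written, so a read-back equals the return
    value (round-trip stability)."""
    from . import __version__

    payload = {
        "tool": {"name": "melboard", "version": tool_version or __version__},
        "knowledge_base_version": kb_version,
        **report,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return payload


def read_report(path: Union[str, Path]) -> dict:
    return json.loads(Path(path).read_text())
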
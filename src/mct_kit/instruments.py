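"""Instrument scoring, range validation and MADRS severity banding.

Five clinical outcome assessments appear in a two-visit record:

* **QLDS** — Quality of Life in Depression Scale, 34 binary ("true"/"not
  true") items, total 0 (good quality of life) to 34 (very poor).
* **MADRS** — Montgomery–Åsberg Depression Rating Scale, clinician rated,
  total 0–60.  There is no consensus banding of the total into depression
  severity levels, so three published sets of cut-offs are shipped as
  built-in :class:`SeverityCriteria`.
* **CGI-SS-r / CGI-SR-I** — 7-point (0–6) clinician global impressions of
  severity of suicidality and of imminent suicide risk.
* **EQ-VAS** — EuroQol visual analogue self-rating of overall health,
  0 (worst) to 100 (best).

Missing scores are permitted at the record level; downstream analyses apply
complete-case deletion per anchor/target pair.  Nothing here imputes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "INSTRUMENT_RANGES",
    "SCORE_COLUMNS",
    "N_QLDS_ITEMS",
    "QldsResponse",
    "score_qlds",
    "SeverityBand",
    "SeverityCriteria",
    "BUILTIN_CRITERIA",
    "builtin_criteria",
    "categorize_madrs",
    "VisitRecord",
    "ValidationIssue",
    "validate_visit_record",
    "read_visit_records",
    "write_visit_records",
    "InstrumentError",
]

#: Closed integer ranges of each instrument total.
INSTRUMENT_RANGES: dict[str, tuple[int, int]] = {
    "qlds_total": (0, 34),
    "madrs_total": (0, 60),
    "cgi_ss_r": (0, 6),
    "cgi_sr_i": (0, 6),
    "eq_vas": (0, 100),
}

SCORE_COLUMNS: tuple[str, ...] = tuple(INSTRUMENT_RANGES)

N_QLDS_ITEMS = 34

QLDS_ITEM_COLUMNS: tuple[str, ...] = tuple(
    f"qlds_item_{i:02d}" for i in range(1, N_QLDS_ITEMS + 1)
)

CSV_COLUMNS: tuple[str, ...] = ("patient_id", "arm", "visit") + SCORE_COLUMNS


class InstrumentError(ValueError):
    """Raised on invalid instrument data (wrong item count, bad range...)."""


# ---------------------------------------------------------------------------
# QLDS

@dataclass(frozen=True)
class QldsResponse:
    """One patient's 34 binary QLDS item responses.

    ``True`` means the item was endorsed ("true"), which scores 1 point;
    higher totals mean worse quality of life.
    """

    items: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.items) != N_QLDS_ITEMS:
            raise InstrumentError(
                f"QLDS requires exactly {N_QLDS_ITEMS} item responses, "
                f"got {len(self.items)}"
            )
        for i, item in enumerate(self.items):
            if not isinstance(item, (bool, np.bool_)):
                raise InstrumentError(
                    f"QLDS item {i + 1} is not binary: {item!r}"
                )


def score_qlds(response: Union[QldsResponse, Sequence[bool]]) -> int:
    """Total QLDS score: the number of endorsed items, 0–34."""
    if not isinstance(response, QldsResponse):
        response = QldsResponse(tuple(response))
    return int(sum(response.items))


# ---------------------------------------------------------------------------
# MADRS severity criteria

@dataclass(frozen=True)
class SeverityBand:
    label: str
    lower: int  # closed bound
    upper: int  # closed bound
    index: int  # ordinal severity, 0 = no depression


@dataclass(frozen=True)
class SeverityCriteria:
    """An ordered banding of the MADRS total (0–60) into severity levels.

    Bands are closed integer intervals; an exclusive published bound such as
    "> 28–60" is encoded as ``[29, 60]`` since MADRS totals are integers.
    The bands must be contiguous, non-overlapping, jointly cover 0–60, and
    carry strictly increasing severity indices.
    """

    name: str
    bands: tuple[SeverityBand, ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise InstrumentError(f"criteria {self.name!r} has no bands")
        lo, hi = INSTRUMENT_RANGES["madrs_total"]
        expected_lower = lo
        prev_index = -1
        for band in self.bands:
            if band.lower != expected_lower:
                raise InstrumentError(
                    f"criteria {self.name!r}: band {band.label!r} starts at "
                    f"{band.lower}, expected {expected_lower} (gap/overlap)"
                )
            if band.upper < band.lower:
                raise InstrumentError(
                    f"criteria {self.name!r}: band {band.label!r} is empty"
                )
            if band.index <= prev_index:
                raise InstrumentError(
                    f"criteria {self.name!r}: severity index must strictly "
                    f"increase with band order"
                )
            prev_index = band.index
            expected_lower = band.upper + 1
        if expected_lower != hi + 1:
            raise InstrumentError(
                f"criteria {self.name!r}: bands cover up to "
                f"{expected_lower - 1}, expected {hi}"
            )

    @property
    def n_levels(self) -> int:
        return len(self.bands)


def _make_criteria(name: str, edges: Sequence[tuple[str, int, int]]) -> SeverityCriteria:
    return SeverityCriteria(
        name=name,
        bands=tuple(
            SeverityBand(label, lo, hi, idx)
            for idx, (label, lo, hi) in enumerate(edges)
        ),
    )


#: The three published MADRS severity bandings (labels configurable; the
#: ordinal index 0..3 is fixed).  Level-1 is labelled "slight" throughout,
#: matching the banding tables even where prose elsewhere says "mild".
BUILTIN_CRITERIA: dict[str, SeverityCriteria] = {
    "criteria_1": _make_criteria(
        "criteria_1",
        [
            ("no depression", 0, 12),
            ("slight depression", 13, 21),
            ("moderate depression", 22, 28),
            ("severe depression", 29, 60),
        ],
    ),
    "criteria_2": _make_criteria(
        "criteria_2",
        [
            ("no depression", 0, 6),
            ("slight depression", 7, 19),
            ("moderate depression", 20, 34),
            ("severe depression", 35, 60),
        ],
    ),
    "criteria_3": _make_criteria(
        "criteria_3",
        [
            ("no depression", 0, 12),
            ("slight depression", 13, 17),
            ("moderate depression", 18, 34),
            ("severe depression", 35, 60),
        ],
    ),
}


def builtin_criteria(name: str) -> SeverityCriteria:
    """Look up one of the three built-in MADRS severity bandings."""
    try:
        return BUILTIN_CRITERIA[name]
    except KeyError:
        raise InstrumentError(
            f"unknown severity criteria {name!r}; "
            f"available: {sorted(BUILTIN_CRITERIA)}"
        ) from None


def categorize_madrs(
    score: int, criteria: SeverityCriteria
) -> tuple[str, int]:
    """Map a MADRS total to its (severity label, ordinal index) band."""
    lo, hi = INSTRUMENT_RANGES["madrs_total"]
    if not (lo <= score <= hi):
        raise InstrumentError(
            f"MADRS total {score} outside [{lo}, {hi}]"
        )
    for band in criteria.bands:
        if band.lower <= score <= band.upper:
            return band.label, band.index
    raise AssertionError("bands validated exhaustive; unreachable")


# ---------------------------------------------------------------------------
# Visit records

@dataclass
class VisitRecord:
    """One patient × visit row of instrument totals (missing allowed)."""

    patient_id: str
    arm: str
    visit: str
    qlds_total: Optional[int] = None
    madrs_total: Optional[int] = None
    cgi_ss_r: Optional[int] = None
    cgi_sr_i: Optional[int] = None
    eq_vas: Optional[int] = None


@dataclass(frozen=True)
class ValidationIssue:
    field: str
    value: object
    message: str


def validate_visit_record(record: VisitRecord) -> list[ValidationIssue]:
    """Check every present score against its instrument range.

    Returns the full list of issues (empty = valid) rather than raising at
    the first problem, so a data report can name every offending field.
    """
    issues: list[ValidationIssue] = []
    for name, (lo, hi) in INSTRUMENT_RANGES.items():
        value = getattr(record, name)
        if value is None or (isinstance(value, float) and np.isnan(value)):
            continue
        if value != int(value) or not (lo <= value <= hi):
            issues.append(
                ValidationIssue(
                    field=name,
                    value=value,
                    message=f"{name}={value!r} outside allowed "
                    f"integer range [{lo}, {hi}]",
                )
            )
    return issues


# ---------------------------------------------------------------------------
# CSV interface

def _validate_frame(df: pd.DataFrame) -> None:
    for name, (lo, hi) in INSTRUMENT_RANGES.items():
        col = df[name].dropna()
        bad = col[(col < lo) | (col > hi)]
        if len(bad):
            first = bad.index[0]
            raise InstrumentError(
                f"{name}={bad.iloc[0]} (patient {df.loc[first, 'patient_id']!r}, "
                f"visit {df.loc[first, 'visit']!r}) outside [{lo}, {hi}]; "
                f"{len(bad)} offending value(s)"
            )
    dup = df.duplicated(subset=["patient_id", "visit"])
    if dup.any():
        pairs = df.loc[dup, ["patient_id", "visit"]].values.tolist()
        raise InstrumentError(f"duplicate (patient_id, visit) rows: {pairs}")


def _score_item_columns(df: pd.DataFrame) -> pd.DataFrame:
    items = df[list(QLDS_ITEM_COLUMNS)]
    n_present = items.notna().sum(axis=1)
    partial = (n_present > 0) & (n_present < N_QLDS_ITEMS)
    if partial.any():
        row = df.loc[partial].iloc[0]
        raise InstrumentError(
            f"patient {row['patient_id']!r} visit {row['visit']!r} has a "
            f"partial QLDS item set ({int(n_present[partial].iloc[0])} of "
            f"{N_QLDS_ITEMS}); partial item sets are refused, not prorated"
        )
    bad = items.stack().loc[lambda s: ~s.isin([0, 1])]
    if len(bad):
        (row_idx, col) = bad.index[0]
        raise InstrumentError(
            f"non-binary QLDS item {col}={bad.iloc[0]!r} "
            f"(patient {df.loc[row_idx, 'patient_id']!r})"
        )
    complete = n_present == N_QLDS_ITEMS
    totals = items.sum(axis=1).where(complete)
    df = df.drop(columns=list(QLDS_ITEM_COLUMNS))
    df["qlds_total"] = df["qlds_total"].where(df["qlds_total"].notna(), totals)
    return df


def validate_records(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an in-memory visit-record table (ranges, uniqueness).

    Returns the table with score columns cast to nullable integers; raises
    :class:`InstrumentError` on the first offending field or duplicate row.
    """
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise InstrumentError(f"missing required columns: {missing}")
    df = df[list(CSV_COLUMNS)].copy()
    for name in SCORE_COLUMNS:
        df[name] = pd.array(df[name], dtype="Int64")
    _validate_frame(df)
    return df


def read_visit_records(path: Union[str, Path]) -> pd.DataFrame:
    """Read a visit-record CSV into a validated long-format DataFrame.

    Expected header: ``patient_id,arm,visit,qlds_total,madrs_total,
    cgi_ss_r,cgi_sr_i,eq_vas`` with an empty cell meaning missing.  Optional
    extra columns ``qlds_item_01..qlds_item_34`` (values 0/1) are scored into
    ``qlds_total`` where that column is empty; a row with a partial item set
    is rejected.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "arm": str, "visit": str})
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise InstrumentError(f"missing required columns: {missing}")
    has_items = [c for c in QLDS_ITEM_COLUMNS if c in df.columns]
    if has_items:
        if len(has_items) != N_QLDS_ITEMS:
            raise InstrumentError(
                f"expected all {N_QLDS_ITEMS} qlds_item_* columns, "
                f"found {len(has_items)}"
            )
        df = _score_item_columns(df)
    df = df[list(CSV_COLUMNS)].copy()
    for name in SCORE_COLUMNS:
        df[name] = pd.array(df[name], dtype="Int64")
    _validate_frame(df)
    return df


def write_visit_records(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a visit-record table in the canonical CSV layout."""
    df[list(CSV_COLUMNS)].to_csv(path, index=False)


def records_to_frame(records: Iterable[VisitRecord]) -> pd.DataFrame:
    """Build a validated long-format table from :class:`VisitRecord` rows."""
    rows = []
    for rec in records:
        issues = validate_visit_record(rec)
        if issues:
            raise InstrumentError(
                f"invalid record ({rec.patient_id!r}, {rec.visit!r}): "
                + "; ".join(i.message for i in issues)
            )
        rows.append({c: getattr(rec, c) for c in CSV_COLUMNS})
    df = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
    for name in SCORE_COLUMNS:
        df[name] = pd.array(df[name], dtype="Int64")
    _validate_frame(df)
    return df
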
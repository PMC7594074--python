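"""Assemble per-use-case indicator rows into an assessment matrix.

A matrix is use cases (rows) x the 15 indicators in canonical order
(columns). Three distinct "no value" states are preserved end to end,
because the balloon plot draws them differently:

* score 0            — the criterion was checked and failed (smallest mark);
* not assessed       — I2/R1.3 under the canonical rubric (cross);
* missing            — a qualitative cell judged "unclear" (no mark at all).
"""

from __future__ import annotations

import csv
import io
import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .acquisition import RetrievalResult
from .errors import ConfigurationError, ConsistencyError
from .indicators import (
    CANONICAL_ORDER,
    IndicatorId,
    IndicatorScore,
    RetrievalMode,
    not_assessed_scores,
    score_a1_family,
    score_a2,
    score_f1,
    score_f2,
    score_f3,
    score_f4,
    score_i1,
    score_i3,
    score_r1,
    score_r1_1,
    score_r1_2,
)
from .metadata import DatasetMetadata, DatasetQuery
from .registry import RegistryRecord

__all__ = [
    "AssessmentRow",
    "AssessmentMatrix",
    "QUALITATIVE_LABELS",
    "assess_use_case",
    "build_matrix",
    "convert_label",
    "import_qualitative",
    "write_report",
    "read_report",
]


# ---------------------------------------------------------------------------
# Rows and matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssessmentRow:
    """All 15 indicator scores for one use case."""

    use_case: str
    scores: Mapping[IndicatorId, IndicatorScore]

    def __post_init__(self) -> None:
        if set(self.scores) != set(CANONICAL_ORDER):
            missing = {i.code for i in CANONICAL_ORDER} - \
                {i.code for i in self.scores}
            extra = {i.code for i in self.scores} - \
                {i.code for i in CANONICAL_ORDER}
            raise ValueError(
                f"row {self.use_case!r} must cover all 15 indicators "
                f"(missing {sorted(missing)}, extra {sorted(extra)})")
        for indicator, score in self.scores.items():
            if score.indicator is not indicator:
                raise ValueError(
                    f"row {self.use_case!r}: score filed under "
                    f"{indicator.code} belongs to {score.indicator.code}")

    def in_order(self) -> tuple[IndicatorScore, ...]:
        return tuple(self.scores[i] for i in CANONICAL_ORDER)

    def __getitem__(self, indicator: IndicatorId | str) -> IndicatorScore:
        if isinstance(indicator, str):
            indicator = IndicatorId.from_code(indicator)
        return self.scores[indicator]


@dataclass(frozen=True)
class AssessmentMatrix:
    """Ordered rows, rectangular over the canonical 15 columns."""

    rows: tuple[AssessmentRow, ...]

    def __post_init__(self) -> None:
        labels = [row.use_case for row in self.rows]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ConfigurationError(f"duplicate use-case labels: {dupes}")

    @property
    def use_cases(self) -> tuple[str, ...]:
        return tuple(row.use_case for row in self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def __getitem__(self, use_case: str) -> AssessmentRow:
        for row in self.rows:
            if row.use_case == use_case:
                return row
        raise KeyError(use_case)

    def to_dataframe(self) -> pd.DataFrame:
        """Score values as a use-cases x indicators DataFrame (NaN for
        not-assessed/missing cells)."""
        data = {
            row.use_case: [s.value for s in row.in_order()]
            for row in self.rows
        }
        frame = pd.DataFrame.from_dict(
            data, orient="index", columns=[i.code for i in CANONICAL_ORDER])
        frame.index.name = "use_case"
        return frame

    def same_scores(self, other: "AssessmentMatrix") -> bool:
        """Equality of values, modes and missing/not-assessed states
        (evidence strings excluded — the CSV report does not carry them)."""
        if self.use_cases != other.use_cases:
            return False
        for mine, theirs in zip(self.rows, other.rows):
            for a, b in zip(mine.in_order(), theirs.in_order()):
                if (a.value, a.mode) != (b.value, b.mode):
                    return False
        return True


def build_matrix(rows: Sequence[AssessmentRow]) -> AssessmentMatrix:
    """Validate and freeze rows into a matrix, preserving input order."""
    if not rows:
        raise ConfigurationError("a matrix needs at least one row")
    return AssessmentMatrix(tuple(rows))


# ---------------------------------------------------------------------------
# Assessing one use case
# ---------------------------------------------------------------------------

def assess_use_case(query: DatasetQuery,
                    meta: DatasetMetadata,
                    registry: RegistryRecord,
                    retrieval: RetrievalResult,
                    f4_flag: Optional[bool],
                    overrides: Optional[Mapping] = None) -> AssessmentRow:
    """Score all 15 indicators for one use case from its evidence bundle.

    Every scoring rule runs exactly once. ``overrides`` (indicator code or
    :class:`IndicatorId` -> value in [0, 1] or None) replace computed values
    with manual corrections and force the manual retrieval mode.
    """
    _check_same_repository(query, meta, registry)

    a1, a1_1, a1_2 = score_a1_family(retrieval)
    i2, r1_3 = not_assessed_scores()
    scores: dict[IndicatorId, IndicatorScore] = {
        IndicatorId.F1: score_f1(registry),
        IndicatorId.F2: score_f2(query, meta),
        IndicatorId.F3: score_f3(query, meta),
        IndicatorId.F4: score_f4(f4_flag),
        IndicatorId.A1: a1,
        IndicatorId.A1_1: a1_1,
        IndicatorId.A1_2: a1_2,
        IndicatorId.A2: score_a2(registry),
        IndicatorId.I1: score_i1(meta),
        IndicatorId.I2: i2,
        IndicatorId.I3: score_i3(meta),
        IndicatorId.R1: score_r1(query, meta),
        IndicatorId.R1_1: score_r1_1(registry),
        IndicatorId.R1_2: score_r1_2(meta),
        IndicatorId.R1_3: r1_3,
    }

    for key, value in (overrides or {}).items():
        indicator = (key if isinstance(key, IndicatorId)
                     else IndicatorId.from_code(str(key)))
        scores[indicator] = IndicatorScore(
            indicator,
            None if value is None else float(value),
            RetrievalMode.MANUAL,
            "manual override",
        )

    return AssessmentRow(query.use_case, scores)


def _check_same_repository(query: DatasetQuery, meta: DatasetMetadata,
                           registry: RegistryRecord) -> None:
    ids = {
        "query": query.repository_id,
        "metadata": meta.repository_id,
        "registry": registry.repository_id,
    }
    stated = {k: v.lower() for k, v in ids.items() if v}
    if len(set(stated.values())) > 1:
        raise ConsistencyError(
            f"evidence objects disagree on the repository: {ids}")


# ---------------------------------------------------------------------------
# Qualitative (traffic-light) tables
# ---------------------------------------------------------------------------

#: Closed label vocabulary of qualitative FAIR assessments and its
#: numeric conversion; "unclear" converts to a missing cell.
QUALITATIVE_LABELS: Mapping[str, Optional[float]] = {
    "complies completely": 1.0,
    "just about/maybe not": 0.5,
    "fails to comply": 0.0,
    "unclear": None,
}


def convert_label(label: str) -> Optional[float]:
    """Convert one qualitative compliance label to a score (None = missing)."""
    key = label.strip().lower()
    if key not in QUALITATIVE_LABELS:
        raise ConfigurationError(
            f"unknown qualitative label {label!r}; "
            f"expected one of {sorted(QUALITATIVE_LABELS)}")
    return QUALITATIVE_LABELS[key]


def import_qualitative(table: str,
                       label_column: Optional[str] = None) -> AssessmentMatrix:
    """Import a qualitative assessment table (CSV text) as a matrix.

    One row per repository; the first column (or ``label_column``) holds the
    repository name, the remaining headers are indicator codes, cells are
    labels from :data:`QUALITATIVE_LABELS`. Converted scores are tagged
    manual (the source assessments were human judgements); indicators absent
    from the table and "unclear"/empty cells become missing marks.
    """
    reader = csv.DictReader(io.StringIO(table))
    if not reader.fieldnames:
        raise ConfigurationError("qualitative table is empty")
    fieldnames = [name.strip() for name in reader.fieldnames]
    name_col = label_column or fieldnames[0]
    if name_col not in fieldnames:
        raise ConfigurationError(f"no column {name_col!r} in table header")

    columns: dict[str, IndicatorId] = {}
    for name in fieldnames:
        if name == name_col:
            continue
        try:
            columns[name] = IndicatorId.from_code(name)
        except KeyError:
            raise ConfigurationError(
                f"unknown indicator column {name!r} in table header") from None

    rows: list[AssessmentRow] = []
    for row_no, record in enumerate(reader, start=2):
        record = { (k or "").strip(): (v or "") for k, v in record.items() }
        label = record.get(name_col, "").strip()
        if not label:
            raise ConfigurationError(f"row {row_no}: blank repository label")
        scores: dict[IndicatorId, IndicatorScore] = {}
        for col_name, indicator in columns.items():
            cell = record.get(col_name, "").strip()
            if not cell:
                value = None
            else:
                try:
                    value = convert_label(cell)
                except ConfigurationError as exc:
                    raise ConfigurationError(
                        f"row {row_no} ({label!r}), column {col_name}: "
                        f"{exc}") from None
            scores[indicator] = IndicatorScore(
                indicator, value, RetrievalMode.MANUAL,
                f"qualitative label {cell!r}" if cell else "no label")
        for indicator in CANONICAL_ORDER:
            if indicator not in scores:
                scores[indicator] = IndicatorScore(
                    indicator, None, RetrievalMode.MANUAL,
                    "not covered by the qualitative table")
        rows.append(AssessmentRow(label, scores))

    if not rows:
        raise ConfigurationError("qualitative table has no data rows")
    return build_matrix(rows)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def write_report(matrix: AssessmentMatrix, destination: str,
                 format: Optional[str] = None) -> str:
    """Serialize a matrix to CSV (values + modes) or JSON (incl. evidence).

    The format is inferred from the destination suffix unless given.
    Returns the written path.
    """
    fmt = (format or os.path.splitext(destination)[1].lstrip(".")).lower()
    if fmt == "csv":
        text = _to_csv(matrix)
    elif fmt == "json":
        text = _to_json(matrix)
    else:
        raise ConfigurationError(f"unknown report format {fmt!r}")
    try:
        with open(destination, "w", encoding="utf-8", newline="") as fh:
            fh.write(text)
    except OSError as exc:
        raise IOError(f"cannot write report to {destination!r}: {exc}") from exc
    return destination


def read_report(path: str, format: Optional[str] = None) -> AssessmentMatrix:
    """Read a matrix report written by :func:`write_report`."""
    fmt = (format or os.path.splitext(path)[1].lstrip(".")).lower()
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    if fmt == "csv":
        return _from_csv(text)
    if fmt == "json":
        return _from_json(text)
    raise ConfigurationError(f"unknown report format {fmt!r}")


def _format_value(value: Optional[float]) -> str:
    if value is None:
        return ""
    return repr(value)  # shortest exact float representation


def _to_csv(matrix: AssessmentMatrix) -> str:
    buffer = io.StringIO()
    writer = csv.writer(buffer, lineterminator="\n")
    codes = [i.code for i in CANONICAL_ORDER]
    writer.writerow(["use_case"] + codes + [f"{c}__mode" for c in codes])
    for row in matrix.rows:
        ordered = row.in_order()
        writer.writerow(
            [row.use_case]
            + [_format_value(s.value) for s in ordered]
            + [s.mode.value for s in ordered])
    return buffer.getvalue()


def _from_csv(text: str) -> AssessmentMatrix:
    reader = csv.DictReader(io.StringIO(text))
    rows: list[AssessmentRow] = []
    for record in reader:
        scores: dict[IndicatorId, IndicatorScore] = {}
        for indicator in CANONICAL_ORDER:
            raw = (record.get(indicator.code) or "").strip()
            mode = RetrievalMode((record.get(f"{indicator.code}__mode")
                                  or "").strip())
            value = float(raw) if raw else None
            scores[indicator] = IndicatorScore(indicator, value, mode)
        rows.append(AssessmentRow(record["use_case"], scores))
    return build_matrix(rows)


def _to_json(matrix: AssessmentMatrix) -> str:
    payload = {
        "indicators": [i.code for i in CANONICAL_ORDER],
        "rows": [
            {
                "use_case": row.use_case,
                "scores": {
                    s.indicator.code: {
                        "value": s.value,
                        "mode": s.mode.value,
                        "evidence": s.evidence,
                    }
                    for s in row.in_order()
                },
            }
            for row in matrix.rows
        ],
    }
    return json.dumps(payload, indent=2)


def _from_json(text: str) -> AssessmentMatrix:
    payload = json.loads(text)
    rows = []
    for entry in payload["rows"]:
        scores = {}
        for code, cell in entry["scores"].items():
            indicator = IndicatorId.from_code(code)
            scores[indicator] = IndicatorScore(
                indicator, cell["value"], RetrievalMode(cell["mode"]),
                cell.get("evidence", ""))
        rows.append(AssessmentRow(entry["use_case"], scores))
    return build_matrix(rows)
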
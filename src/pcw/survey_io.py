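"""Reading, validating and writing physician survey datasets.

A dataset is a pandas DataFrame with the columns of :mod:`pcw.schema`, wrapped
in :class:`SurveyDataset` together with a provenance string. Reading applies
category normalization and row-level validation; eligibility screening applies
the study inclusion rules (at least 4 months in the outpatient clinic and at
least 1 year of full-time employment in the current institution) and reports
the effective recovery rate.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import schema

__all__ = [
    "SurveyDataset",
    "SchemaError",
    "RowValidationError",
    "EligibilityReport",
    "read_survey",
    "validate_records",
    "validate_eligibility",
    "write_table",
]


class SchemaError(ValueError):
    """The file header does not carry the mandatory columns."""


class RowValidationError(ValueError):
    """One or more data rows failed validation.

    Carries ``problems``: a list of (row_index, column, message) triples so a
    caller can report every malformed row instead of the first one.
    """

    def __init__(self, problems: list[tuple[int, str, str]]):
        self.problems = problems
        lines = "; ".join(f"row {r}, {c}: {m}" for r, c, m in problems[:20])
        more = "" if len(problems) <= 20 else f" (+{len(problems) - 20} more)"
        super().__init__(f"{len(problems)} invalid cell(s): {lines}{more}")


@dataclasses.dataclass
class SurveyDataset:
    """An ordered collection of physician records plus provenance."""

    frame: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = self.frame["respondent_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate respondent_id {dup!r}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n(self) -> int:
        return len(self.frame)


@dataclasses.dataclass
class EligibilityReport:
    """Outcome of the inclusion screen."""

    eligible: SurveyDataset
    rejections: list[tuple[object, str]]  # (respondent_id, failed rule)

    @property
    def n_input(self) -> int:
        return len(self.eligible) + len(self.rejections)

    @property
    def recovery_rate(self) -> float | None:
        """Eligible / input as a percentage (1-decimal precision is applied
        only at presentation time); None for empty input."""
        if self.n_input == 0:
            return None
        return 100.0 * len(self.eligible) / self.n_input


def _require_columns(columns: Iterable[str], required: Sequence[str]) -> None:
    missing = [c for c in required if c not in set(columns)]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")


def read_survey(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> SurveyDataset:
    """Read a survey CSV into a validated :class:`SurveyDataset`.

    Parameters
    ----------
    path
        CSV file with one header row. Empty cells are missing values.
    column_map
        Optional mapping from file column names to canonical schema names,
        for files whose headers differ from the canonical schema.

    Raises
    ------
    SchemaError
        A mandatory column is absent from the header.
    RowValidationError
        Unparseable numerics or out-of-vocabulary categories; the error
        lists every offending (row, column) rather than dropping rows.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    raw = raw.replace("", np.nan)
    if column_map:
        raw = raw.rename(columns=dict(column_map))
    _require_columns(raw.columns, schema.ALL_COLUMNS)
    frame, problems = _parse_frame(raw)
    if problems:
        raise RowValidationError(problems)
    return SurveyDataset(frame, provenance=str(path))


def _parse_frame(raw: pd.DataFrame) -> tuple[pd.DataFrame, list[tuple[int, str, str]]]:
    problems: list[tuple[int, str, str]] = []
    out = pd.DataFrame(index=raw.index)
    out["respondent_id"] = raw["respondent_id"].astype(str)

    for col in schema.CATEGORY_COLUMNS:
        vals = []
        for i, v in raw[col].items():
            if pd.isna(v):
                vals.append(np.nan)
                continue
            canon = schema.canonicalize_category(col, v)
            if canon is None and col in schema.BANDERS:
                # numeric hours accepted and banded on read
                try:
                    canon = schema.BANDERS[col](float(schema.normalize_token(v)))
                except ValueError:
                    canon = None
            if canon is None:
                problems.append((i, col, f"value {v!r} not in vocabulary"))
                vals.append(np.nan)
            else:
                vals.append(canon)
        out[col] = vals

    for col in schema.NUMERIC_COLUMNS:
        parsed = pd.to_numeric(raw[col], errors="coerce")
        bad = raw[col].notna() & parsed.isna()
        for i in raw.index[bad]:
            problems.append((i, col, f"unparseable numeric {raw.at[i, col]!r}"))
        out[col] = parsed.astype(float)

    for group in schema.TASK_GROUPS:
        for k in range(1, schema.N_ITEMS + 1):
            col = schema.item_column(group, k)
            parsed = pd.to_numeric(raw[col], errors="coerce")
            bad = raw[col].notna() & parsed.isna()
            for i in raw.index[bad]:
                problems.append((i, col, f"unparseable rating {raw.at[i, col]!r}"))
            out[col] = parsed.astype(float)
        for pair in schema.DIMENSION_PAIRS:
            col = schema.pick_column(group, pair)
            vals = []
            for i, v in raw[col].items():
                if pd.isna(v):
                    vals.append(np.nan)
                elif str(v).strip() in pair:
                    vals.append(str(v).strip())
                else:
                    problems.append(
                        (i, col, f"pick {v!r} is not a member of pair {pair}")
                    )
                    vals.append(np.nan)
            out[col] = vals

    problems.extend(_check_ranges(out))
    return out, problems


def _check_ranges(frame: pd.DataFrame) -> list[tuple[int, str, str]]:
    problems: list[tuple[int, str, str]] = []

    def flag(mask: pd.Series, col: str, msg: str) -> None:
        for i in frame.index[mask.fillna(False)]:
            problems.append((i, col, msg))

    for col in ("t_comm", "t_noncomm", "n_outpatients_per_day",
                "n_admitted_per_day", "months_in_outpatient_clinic",
                "years_employed_current_institution"):
        flag(frame[col] < 0, col, "negative value")
    flag(~frame["satisfaction"].between(0, 100), "satisfaction", "outside [0,100]")
    flag(
        frame["n_admitted_per_day"] > frame["n_outpatients_per_day"],
        "n_admitted_per_day",
        "admissions exceed outpatients seen",
    )
    for group in schema.TASK_GROUPS:
        for k in range(1, schema.N_ITEMS + 1):
            col = schema.item_column(group, k)
            flag(~frame[col].between(0, 100), col, "rating outside [0,100]")
    return problems


def validate_records(dataset: SurveyDataset) -> None:
    """Re-check invariants on an in-memory dataset (e.g. generator output)."""
    _require_columns(dataset.frame.columns, schema.ALL_COLUMNS)
    problems = _check_ranges(dataset.frame)
    for col in schema.CATEGORY_COLUMNS:
        vocab = set(schema.VOCABULARY[col])
        bad = dataset.frame[col].notna() & ~dataset.frame[col].isin(vocab)
        for i in dataset.frame.index[bad]:
            problems.append((i, col, "value not in vocabulary"))
    if problems:
        raise RowValidationError(problems)


_MANDATORY = ("respondent_id",) + schema.CATEGORY_COLUMNS + schema.NUMERIC_COLUMNS


def validate_eligibility(dataset: SurveyDataset) -> EligibilityReport:
    """Apply the study inclusion rules; complete-case on mandatory fields.

    A record is retained iff months_in_outpatient_clinic >= 4,
    years_employed_current_institution >= 1, and no mandatory field (including
    both full assessments) is missing. The rejection log cites the first
    failed rule per record.
    """
    frame = dataset.frame
    assess_cols = schema.assessment_columns("comm") + schema.assessment_columns("noncomm")
    months = frame["months_in_outpatient_clinic"]
    years = frame["years_employed_current_institution"]
    bad_tenure = (months.isna() | (months < 4)).to_numpy()
    bad_employ = (years.isna() | (years < 1)).to_numpy() & ~bad_tenure
    check_cols = list(_MANDATORY + assess_cols)
    isna = frame[check_cols].isna()
    has_missing = isna.any(axis=1).to_numpy() & ~bad_tenure & ~bad_employ
    first_missing = isna.idxmax(axis=1)

    rejections: list[tuple[object, str]] = []
    keep = ~(bad_tenure | bad_employ | has_missing)
    ids = frame["respondent_id"].to_numpy()
    for pos in np.flatnonzero(~keep):
        if bad_tenure[pos]:
            rule = "tenure<4 months"
        elif bad_employ[pos]:
            rule = "employment<1 year"
        else:
            rule = f"missing {first_missing.iloc[pos]}"
        rejections.append((ids[pos], rule))
    eligible = SurveyDataset(
        frame.iloc[keep].reset_index(drop=True),
        provenance=dataset.provenance,
    )
    return EligibilityReport(eligible=eligible, rejections=rejections)


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write any tabular result as CSV with stable column order.

    Round-trip contract: reading the file back with pandas yields equal
    values for the written columns.
    """
    path = Path(path)
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(table)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path
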
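"""Canonical survey schema: column names, category vocabularies, banding rules.

The survey file is UTF-8, comma-delimited, one header row, one row per
respondent. Category cells hold canonical English tokens (below); numeric
cells hold plain numbers. Weekly-hours fields may alternatively hold raw
numeric hours, which are banded on read (left-open, right-closed).
"""

from __future__ import annotations

import itertools
from typing import Mapping, Sequence

#: Workload dimensions of the hybrid NASA-TLX/SWAT instrument, canonical order:
#: mental demands, physical demands, temporal demands, perceived risk,
#: frustration level, performance.
DIMENSIONS: tuple[str, ...] = ("MD", "PD", "TD", "PR", "FL", "Pe")

#: The C(6,2) = 15 unordered dimension pairs, canonical order.
DIMENSION_PAIRS: tuple[tuple[str, str], ...] = tuple(
    itertools.combinations(DIMENSIONS, 2)
)

#: Task groups assessed separately by the instrument.
TASK_GROUPS: tuple[str, ...] = ("comm", "noncomm")

N_ITEMS = 12
N_COMPARISONS = 15

#: PCW type labels in increasing workload order, and their group names.
PCW_TYPES: tuple[str, ...] = ("I", "II", "III", "IV")
PCW_GROUPS: tuple[str, ...] = ("low", "medium", "high", "very high")
TYPE_TO_GROUP: Mapping[str, str] = dict(zip(PCW_TYPES, PCW_GROUPS))

# ---------------------------------------------------------------------------
# Category vocabularies (respondent characteristics)
# ---------------------------------------------------------------------------

VOCABULARY: Mapping[str, tuple[str, ...]] = {
    "gender": ("Male", "Female"),
    "age_band": ("20-30", "31-40", "41-55", ">55"),
    "marital_status": ("Unmarried", "Married", "Divorced", "Widowed"),
    "education": ("Doctorate", "Master", "Undergraduate", "Junior college", "Others"),
    "income_band": ("<=5000", "5001-10000", "10001-15000", ">15000"),
    "title": ("Senior", "Associate senior", "Intermediate", "Junior", "Others"),
    "tenure_band": ("1-5", "6-10", "11-15", "16-20", ">20"),
    "area": ("Eastern", "Central", "Western"),
    "hospital_level": ("Tertiary A", "Tertiary B", "Secondary", "First-tier"),
    "hospital_nature": (
        "Public general",
        "Public specialized",
        "Private general",
        "Private specialized",
    ),
    "department": (
        "Internal",
        "Surgical",
        "Obstetrics and gynecology",
        "Pediatrics",
        "Others",
    ),
    "hours_per_week_band": ("<=40", "41-60", ">60"),
    "outpatient_hours_band": ("<=8", "~16", "~24", "~40", ">40"),
    "health_status": ("Very poor", "Poor", "Fair", "Good", "Very good"),
}

CATEGORY_COLUMNS: tuple[str, ...] = tuple(VOCABULARY)

NUMERIC_COLUMNS: tuple[str, ...] = (
    "months_in_outpatient_clinic",
    "years_employed_current_institution",
    "t_comm",
    "t_noncomm",
    "n_outpatients_per_day",
    "n_admitted_per_day",
    "satisfaction",
)


def item_column(group: str, item: int) -> str:
    """Column holding rating of item ``item`` (1-based) for a task group."""
    return f"{group}_item_{item:02d}"


def pick_column(group: str, pair: tuple[str, str]) -> str:
    """Column holding the winning dimension of one pairwise comparison."""
    return f"{group}_cmp_{pair[0]}_{pair[1]}"


def assessment_columns(group: str) -> tuple[str, ...]:
    items = tuple(item_column(group, k) for k in range(1, N_ITEMS + 1))
    picks = tuple(pick_column(group, p) for p in DIMENSION_PAIRS)
    return items + picks


ALL_COLUMNS: tuple[str, ...] = (
    ("respondent_id",)
    + CATEGORY_COLUMNS
    + NUMERIC_COLUMNS
    + assessment_columns("comm")
    + assessment_columns("noncomm")
)

# ---------------------------------------------------------------------------
# Normalization and banding
# ---------------------------------------------------------------------------

_DASHES = "‐‑‒–—―−"


def normalize_token(value: str) -> str:
    """Map a raw category cell to a comparable form.

    Strips whitespace, converts unicode dashes to ``-`` and the <=/>= signs
    to ASCII digraphs; comparison against the vocabulary is case-insensitive.
    """
    s = str(value).strip()
    for d in _DASHES:
        s = s.replace(d, "-")
    s = s.replace("≤", "<=").replace("≥", ">=")
    return s


def canonicalize_category(column: str, value: str) -> str | None:
    """Return the canonical vocabulary token for ``value``, or None."""
    tok = normalize_token(value)
    for canonical in VOCABULARY[column]:
        if tok.lower() == canonical.lower():
            return canonical
    return None


def band_hours_per_week(hours: float) -> str:
    """Band raw weekly hours: (0,40] / (40,60] / (60,inf)."""
    if hours <= 40:
        return "<=40"
    if hours <= 60:
        return "41-60"
    return ">60"


def band_outpatient_hours(hours: float) -> str:
    """Band raw weekly outpatient hours: (0,8] / (8,16] / (16,24] / (24,40] / (40,inf)."""
    if hours <= 8:
        return "<=8"
    if hours <= 16:
        return "~16"
    if hours <= 24:
        return "~24"
    if hours <= 40:
        return "~40"
    return ">40"


BANDERS = {
    "hours_per_week_band": band_hours_per_week,
    "outpatient_hours_band": band_outpatient_hours,
}


def default_item_map(items: Sequence[int] | None = None) -> dict[str, str]:
    """Default item -> dimension mapping: two consecutive items per dimension.

    Keys are 1-based item numbers as strings ("1".."12"); values are
    dimension codes. The mapping is configurable because the source scale's
    exact assignment is not public; only the 12-item / 6-dimension structure
    is fixed.
    """
    mapping: dict[str, str] = {}
    for k in range(1, N_ITEMS + 1):
        mapping[str(k)] = DIMENSIONS[(k - 1) // 2]
    return mapping
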
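"""Comprehensive workload: adjustment coefficients, PCW scores, classification.

The integrated score for respondent *i* is

    PCW_i = (PW_comm_i + PW_noncomm_i) * R_ov_i * R_pc_i * R_ps_i

where each task-level workload PW is the task group's mental-workload score
multiplied by the per-visit minutes spent on that task group, and the three
multiplicative coefficients adjust for quantity of work (R_ov, outpatients
served per day), served-patient complexity (R_pc, admitted-to-seen ratio
normalized so that 1 is the reference value) and quality of service
(R_ps, self-rated outpatient satisfaction).

Respondents are then stratified into four relative workload types with cut
points at M-SD, M and M+SD of the sample PCW distribution: I (low,
PCW <= M-SD), II (medium, M-SD < PCW <= M), III (high, M < PCW <= M+SD)
and IV (very high, PCW > M+SD).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from . import schema

__all__ = [
    "CoefficientScheme",
    "AdjustmentError",
    "compute_adjustments",
    "compute_task_workload",
    "compute_pcw",
    "ClassificationScheme",
    "classify_pcw",
    "DistributionTable",
    "distribution_table",
    "DEFAULT_EDGES",
]

#: Normalization options per coefficient.
_NORMALIZATIONS = ("raw", "sample_mean", "scale_max", "minmax_plus1")


class AdjustmentError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class CoefficientScheme:
    """How each adjustment coefficient is normalized.

    Defaults: R_ov divides the daily outpatient count by its sample mean
    (so 1 is an average caseload); R_pc min-max normalizes the
    admitted-to-seen ratio over the analysis sample and adds 1 (so a
    zero-admission physician sits exactly at the reference value 1 and the
    range is [1, 2]); R_ps divides satisfaction by its scale maximum 100.
    Any of ``raw``, ``sample_mean``, ``scale_max``, ``minmax_plus1`` may be
    selected per coefficient; the scheme used is recorded in run metadata.
    """

    ov: str = "sample_mean"
    pc: str = "minmax_plus1"
    ps: str = "scale_max"
    ps_scale_max: float = 100.0

    def __post_init__(self) -> None:
        for name in ("ov", "pc", "ps"):
            if getattr(self, name) not in _NORMALIZATIONS:
                raise ValueError(
                    f"{name} scheme must be one of {_NORMALIZATIONS}"
                )

    def describe(self) -> dict[str, str]:
        return {"r_ov": self.ov, "r_pc": self.pc, "r_ps": self.ps}


def _normalize(values: np.ndarray, how: str, scale_max: float | None = None) -> np.ndarray:
    if how == "raw":
        return values
    if how == "sample_mean":
        mean = np.nanmean(values)
        if mean == 0:
            raise AdjustmentError("sample mean is zero; cannot normalize")
        return values / mean
    if how == "scale_max":
        if not scale_max:
            raise AdjustmentError("scale_max normalization needs a positive maximum")
        return values / scale_max
    if how == "minmax_plus1":
        lo, hi = np.nanmin(values), np.nanmax(values)
        if hi == lo:
            warnings.warn(
                "degenerate min-max range; all coefficients set to the reference value 1",
                stacklevel=3,
            )
            return np.ones_like(values)
        return (values - lo) / (hi - lo) + 1.0
    raise AdjustmentError(f"unknown normalization {how!r}")


def compute_adjustments(
    frame: pd.DataFrame, scheme: CoefficientScheme | None = None
) -> pd.DataFrame:
    """Per-record adjustment coefficients r_ov, r_pc, r_ps.

    ``frame`` needs columns ``n_outpatients_per_day``, ``n_admitted_per_day``
    and ``satisfaction``. Records with zero outpatients are flagged (column
    ``zero_outpatients``) and their admitted-to-seen ratio is treated as 0,
    which the default scheme maps to the reference value 1.
    """
    scheme = scheme or CoefficientScheme()
    n_out = frame["n_outpatients_per_day"].to_numpy(dtype=float)
    n_adm = frame["n_admitted_per_day"].to_numpy(dtype=float)
    sat = frame["satisfaction"].to_numpy(dtype=float)

    zero = n_out == 0
    ratio = np.zeros_like(n_out)
    np.divide(n_adm, n_out, out=ratio, where=~zero)

    r_ov = _normalize(n_out, scheme.ov)
    r_pc = _normalize(ratio, scheme.pc)
    if scheme.pc == "minmax_plus1":
        r_pc = np.maximum(r_pc, 1.0)  # floor at the reference value
    r_ps = _normalize(sat, scheme.ps, scheme.ps_scale_max)

    return pd.DataFrame(
        {"r_ov": r_ov, "r_pc": r_pc, "r_ps": r_ps, "zero_outpatients": zero},
        index=frame.index,
    )


def compute_task_workload(pmw, t):
    """Task-level workload: mental-workload score times minutes per visit."""
    pmw = np.asarray(pmw, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative task time")
    out = pmw * t
    return float(out) if out.ndim == 0 else out


def compute_pcw(pw_comm, pw_noncomm, r_ov, r_pc, r_ps):
    """Integrated comprehensive workload score."""
    pw_comm = np.asarray(pw_comm, dtype=float)
    pw_noncomm = np.asarray(pw_noncomm, dtype=float)
    if np.any(pw_comm < 0) or np.any(pw_noncomm < 0):
        raise ValueError("negative task workload")
    out = (pw_comm + pw_noncomm) * np.asarray(r_ov) * np.asarray(r_pc) * np.asarray(r_ps)
    return float(out) if out.ndim == 0 else out


@dataclasses.dataclass(frozen=True)
class ClassificationScheme:
    """Mean/SD stratification with cuts at M-SD, M and M+SD."""

    mean: float
    sd: float

    @property
    def cut_low(self) -> float:
        return self.mean - self.sd

    @property
    def cut_mid(self) -> float:
        return self.mean

    @property
    def cut_high(self) -> float:
        return self.mean + self.sd

    def assign(self, scores) -> pd.Series:
        """Label scores by the boundary convention with <= on the left of
        each cut: I iff score <= M-SD, II iff M-SD < score <= M,
        III iff M < score <= M+SD, IV iff score > M+SD."""
        s = np.asarray(scores, dtype=float)
        if self.sd == 0:
            warnings.warn("zero SD: degenerate classification, all records II")
            labels = np.full(s.shape, "II", dtype=object)
        else:
            labels = np.empty(s.shape, dtype=object)
            labels[s <= self.cut_low] = "I"
            labels[(s > self.cut_low) & (s <= self.cut_mid)] = "II"
            labels[(s > self.cut_mid) & (s <= self.cut_high)] = "III"
            labels[s > self.cut_high] = "IV"
        return pd.Series(
            pd.Categorical(labels, categories=list(schema.PCW_TYPES), ordered=True)
        )

    def groups(self, scores) -> pd.Series:
        """Same partition with group names low/medium/high/very high."""
        types = self.assign(scores)
        return types.map(schema.TYPE_TO_GROUP).astype(
            pd.CategoricalDtype(list(schema.PCW_GROUPS), ordered=True)
        )


def classify_pcw(scores) -> tuple[ClassificationScheme, pd.Series]:
    """Derive the classification scheme from the sample and label it.

    Uses the sample standard deviation (n-1 denominator).
    """
    s = np.asarray(scores, dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 scores to derive cut points")
    scheme = ClassificationScheme(mean=float(np.mean(s)), sd=float(np.std(s, ddof=1)))
    return scheme, scheme.assign(s)


#: Bin edges of the published score-distribution table: left-open,
#: right-closed 200-point intervals up to 1,800, then one terminal interval.
DEFAULT_EDGES: tuple[float, ...] = tuple(float(x) for x in range(0, 2000, 200)) + (5400.0,)


@dataclasses.dataclass
class DistributionTable:
    """Score-interval distribution with percent and cumulative percent."""

    table: pd.DataFrame  # columns: interval, n, proportion, cumulative

    @property
    def n(self) -> int:
        return int(self.table["n"].sum())


def distribution_table(scores, edges: Sequence[float] | None = None) -> DistributionTable:
    """Count scores into left-open, right-closed intervals.

    Proportions and cumulative proportions are rounded to one decimal
    percent. The default edges follow the published layout (0,200] ...
    (1,800,5,400); a score outside all bins raises with the offending value.
    """
    s = np.asarray(scores, dtype=float)
    edges = np.asarray(DEFAULT_EDGES if edges is None else edges, dtype=float)
    if not np.all(np.diff(edges) > 0):
        raise ValueError("edges must be strictly increasing")
    outside = (s <= edges[0]) | (s > edges[-1])
    if np.any(outside):
        raise ValueError(f"score {s[outside][0]} outside all bins")
    # left-open, right-closed: a score on an interior edge belongs below
    idx = np.searchsorted(edges, s, side="left") - 1
    counts = np.bincount(idx, minlength=len(edges) - 1)
    n = counts.sum()
    prop = np.round(100.0 * counts / n, 1)
    cum = np.round(100.0 * np.cumsum(counts) / n, 1)
    labels = [
        f"({_fmt(lo)},{_fmt(hi)}]" for lo, hi in zip(edges[:-1], edges[1:])
    ]
    return DistributionTable(
        pd.DataFrame(
            {"interval": labels, "n": counts, "proportion": prop, "cumulative": cum}
        )
    )


def _fmt(x: float) -> str:
    return f"{int(x):,}" if float(x).is_integer() else f"{x:,}"
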
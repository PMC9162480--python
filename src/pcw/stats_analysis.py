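"""Inferential stages: chi-square cross-tabs, ln(PCW) OLS with VIF,
multinomial logistic regression with relative risk ratios.

Conventions follow standard survey-analysis practice: Pearson chi-square
without continuity correction and with asymptotic p-values; indicator
(dummy) coding with explicit reference levels; Wald 95% confidence
intervals for relative risk ratios, built on the log scale and
exponentiated. Significance is flagged at p < 0.10 and p < 0.05.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from . import schema

__all__ = [
    "ContingencyTable",
    "ChiSquareResult",
    "crosstab",
    "pearson_chi_square",
    "drop_sparse_levels",
    "DEFAULT_REFERENCES",
    "MULTINOMIAL_REFERENCES",
    "RegressionResult",
    "fit_lnpcw_regression",
    "compute_vif",
    "MultinomialResult",
    "fit_multinomial",
]

_Z95 = scipy.stats.norm.ppf(0.975)

#: Reference levels used by the published regression tables.
DEFAULT_REFERENCES: Mapping[str, str] = {
    "gender": "Male",
    "age_band": "20-30",
    "education": "Master",
    "title": "Junior",
    "tenure_band": "6-10",
    "area": "Central",
    "hospital_level": "Tertiary A",
    "department": "Pediatrics",
    "hours_per_week_band": ">60",
    "outpatient_hours_band": "<=8",
}

#: The multinomial table keys area and weekly hours to different references.
MULTINOMIAL_REFERENCES: Mapping[str, str] = {
    **DEFAULT_REFERENCES,
    "area": "Western",
    "hours_per_week_band": "41-60",
}


@dataclasses.dataclass
class ContingencyTable:
    """Characteristic categories x workload groups with cell counts."""

    counts: pd.DataFrame  # rows: characteristic levels; cols: groups

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative cell count")

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


@dataclasses.dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    min_expected: float


def crosstab(labels: Sequence, characteristic: Sequence) -> ContingencyTable:
    """Cross-tabulate per-record workload groups against a characteristic."""
    labels = pd.Series(labels).reset_index(drop=True)
    characteristic = pd.Series(characteristic).reset_index(drop=True)
    if len(labels) != len(characteristic):
        raise ValueError(
            f"length mismatch: {len(labels)} labels vs {len(characteristic)} values"
        )
    table = pd.crosstab(characteristic, labels, dropna=False)
    # keep declared category order where available, drop all-empty levels
    table = table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0]
    return ContingencyTable(table)


def pearson_chi_square(table: ContingencyTable | pd.DataFrame) -> ChiSquareResult:
    """Pearson chi-square on a contingency table, no continuity correction.

    E = row total * column total / N; statistic = sum (O-E)^2 / E;
    df = (r-1)(c-1); asymptotic p-value. A zero row or column marginal makes
    expected counts undefined and raises; expected cells below 5 trigger a
    warning but the asymptotic p-value is still reported.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else pd.DataFrame(table)
    obs = counts.to_numpy(dtype=float)
    if obs.sum() <= 0:
        raise ValueError("empty table")
    if (obs.sum(axis=1) == 0).any() or (obs.sum(axis=0) == 0).any():
        raise ValueError("zero row or column marginal: expected counts undefined")
    stat, p, df, expected = scipy.stats.chi2_contingency(obs, correction=False)
    min_exp = float(expected.min())
    if min_exp < 5:
        warnings.warn(
            f"minimum expected cell count {min_exp:.2f} < 5; "
            "asymptotic p-value may be inaccurate",
            stacklevel=2,
        )
    return ChiSquareResult(float(stat), int(df), float(p), min_exp)


def drop_sparse_levels(
    table: ContingencyTable, min_expected: float = 5.0
) -> ContingencyTable:
    """Drop characteristic levels whose expected counts fall below a floor.

    Expected counts are computed once on the full table; rows with any
    expected cell below ``min_expected`` are removed. Sparse levels of this
    kind are also the ones reported as not-estimable in the multinomial
    model, so the same reduced tables feed both analyses.
    """
    counts = table.counts
    obs = counts.to_numpy(dtype=float)
    n = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    keep = (expected >= min_expected).all(axis=1)
    return ContingencyTable(counts.loc[keep])


# ---------------------------------------------------------------------------
# ln(PCW) multiple linear regression
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RegressionResult:
    """OLS fit of ln(PCW) on indicator-coded characteristics."""

    terms: pd.DataFrame  # predictor, level, beta, se, t, p_value, vif
    intercept: pd.Series  # beta, se, t, p_value
    references: Mapping[str, str]
    n: int
    df_resid: int
    r_squared: float
    sigma: float

    def summary(self) -> str:
        lines = [
            f"ln(PCW) OLS: n={self.n}, df={self.df_resid}, "
            f"R^2={self.r_squared:.3f}, residual SD={self.sigma:.3f}",
            f"Constant  beta={self.intercept['beta']:.3f} "
            f"(SE {self.intercept['se']:.3f})",
        ]
        for _, row in self.terms.iterrows():
            flag = "**" if row.p_value < 0.05 else ("*" if row.p_value < 0.10 else "")
            lines.append(
                f"{row.predictor} [{row.level} vs {self.references[row.predictor]}]"
                f"  beta={row.beta: .4f}  SE={row.se:.4f}  t={row.t: .2f}"
                f"  p={row.p_value:.3f}  VIF={row.vif:.2f} {flag}"
            )
        return "\n".join(lines)


def _indicator_design(
    frame: pd.DataFrame,
    predictors: Sequence[str],
    references: Mapping[str, str] | None,
) -> tuple[pd.DataFrame, dict[str, str], list[tuple[str, str]]]:
    """Dummy-code ``predictors`` with the given reference levels.

    Returns the design (without constant), the resolved reference levels,
    and the (predictor, level) pair per design column.
    """
    references = dict(references or {})
    cols: dict[str, np.ndarray] = {}
    meta: list[tuple[str, str]] = []
    for pred in predictors:
        values = frame[pred]
        if values.isna().any():
            raise ValueError(f"missing values in predictor {pred!r}")
        declared = schema.VOCABULARY.get(pred)
        levels = [
            lv for lv in (declared or sorted(values.unique()))
            if lv in set(values.unique())
        ]
        ref = references.get(pred, levels[0])
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} absent from {pred!r}")
        references[pred] = ref
        for lv in levels:
            if lv == ref:
                continue
            cols[f"{pred}[{lv}]"] = (values == lv).to_numpy(dtype=float)
            meta.append((pred, lv))
    design = pd.DataFrame(cols, index=frame.index)
    return design, references, meta


def _check_aliasing(design: pd.DataFrame) -> None:
    x = np.column_stack([np.ones(len(design)), design.to_numpy()])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValueError(
            "perfectly collinear design; aliased terms among: "
            + ", ".join(design.columns)
        )


def fit_lnpcw_regression(
    frame: pd.DataFrame,
    predictors: Sequence[str],
    references: Mapping[str, str] | None = None,
    outcome: str = "ln_pcw",
) -> RegressionResult:
    """OLS of ln(PCW) on indicator-coded characteristics.

    Rows with non-finite outcome (e.g. PCW = 0) are excluded with a warning.
    VIFs are computed per non-reference indicator on the fitted design.
    """
    y = frame[outcome].to_numpy(dtype=float)
    ok = np.isfinite(y)
    if not ok.all():
        warnings.warn(
            f"excluding {np.sum(~ok)} record(s) with undefined {outcome}",
            stacklevel=2,
        )
    sub = frame.loc[ok]
    y = y[ok]
    design, references, meta = _indicator_design(sub, predictors, references)
    _check_aliasing(design)
    x = sm.add_constant(design, has_constant="add")
    fit = sm.OLS(y, x).fit()
    vifs = compute_vif(design)
    terms = pd.DataFrame(
        {
            "predictor": [p for p, _ in meta],
            "level": [lv for _, lv in meta],
            "beta": fit.params[design.columns].to_numpy(),
            "se": fit.bse[design.columns].to_numpy(),
            "t": fit.tvalues[design.columns].to_numpy(),
            "p_value": fit.pvalues[design.columns].to_numpy(),
            "vif": vifs[design.columns].to_numpy(),
        }
    )
    intercept = pd.Series(
        {
            "beta": fit.params["const"],
            "se": fit.bse["const"],
            "t": fit.tvalues["const"],
            "p_value": fit.pvalues["const"],
        }
    )
    return RegressionResult(
        terms=terms,
        intercept=intercept,
        references=references,
        n=int(fit.nobs),
        df_resid=int(fit.df_resid),
        r_squared=float(fit.rsquared),
        sigma=float(np.sqrt(fit.mse_resid)),
    )


def compute_vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per design column.

    VIF_j = 1 / (1 - R^2_j) where R^2_j comes from regressing column j on
    the remaining columns plus a constant. Exact collinearity is reported as
    an infinite VIF with an aliasing warning rather than an error.
    """
    x = design.to_numpy(dtype=float)
    out = {}
    for j, name in enumerate(design.columns):
        others = np.column_stack(
            [np.ones(len(design))] + [x[:, k] for k in range(x.shape[1]) if k != j]
        )
        beta, _, _, _ = np.linalg.lstsq(others, x[:, j], rcond=None)
        resid = x[:, j] - others @ beta
        tss = np.sum((x[:, j] - x[:, j].mean()) ** 2)
        if tss == 0:
            out[name] = np.inf
            continue
        r2 = 1.0 - np.sum(resid**2) / tss
        if r2 >= 1.0 - 1e-12:
            warnings.warn(f"term {name} is aliased (R^2 = 1); VIF infinite")
            out[name] = np.inf
        else:
            out[name] = 1.0 / (1.0 - r2)
    return pd.Series(out)


# ---------------------------------------------------------------------------
# Multinomial logistic regression
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MultinomialResult:
    """Multinomial logit with RRR = exp(coefficient) per non-base outcome.

    ``table`` has one row per (outcome, predictor, level): rrr, ci_low,
    ci_high, p_value; not-estimable terms (a predictor level with an empty
    outcome cell) carry NaN and estimable=False.
    """

    table: pd.DataFrame
    base_outcome: str
    references: Mapping[str, str]
    n: int
    converged: bool
    dropped_levels: list[tuple[str, str]]

    def summary(self) -> str:
        lines = [
            f"Multinomial logit (base outcome: {self.base_outcome}), n={self.n}"
        ]
        for _, row in self.table.iterrows():
            ref = self.references[row.predictor]
            if not row.estimable:
                lines.append(
                    f"{row.outcome} | {row.predictor} [{row.level} vs {ref}]  N/A"
                )
                continue
            flag = "**" if row.p_value < 0.05 else ("*" if row.p_value < 0.10 else "")
            lines.append(
                f"{row.outcome} | {row.predictor} [{row.level} vs {ref}]  "
                f"RRR={row.rrr:.3f} ({row.ci_low:.3f},{row.ci_high:.3f})  "
                f"p={row.p_value:.3f} {flag}"
            )
        return "\n".join(lines)


def fit_multinomial(
    frame: pd.DataFrame,
    predictors: Sequence[str],
    references: Mapping[str, str] | None = None,
    outcome: str = "pcw_group",
    base_outcome: str = "very high",
    maxiter: int = 200,
) -> MultinomialResult:
    """Maximum-likelihood multinomial logit with a chosen base outcome.

    Predictor levels with zero count in any outcome category are removed
    from the design (they would separate the likelihood) and reported as
    not-estimable for every outcome contrast, with the remaining model fit
    on the reduced design.
    """
    y_raw = frame[outcome]
    if y_raw.isna().any():
        raise ValueError("missing outcome labels")
    present = [g for g in schema.PCW_GROUPS if g in set(y_raw)]
    if base_outcome not in present:
        raise ValueError(f"base outcome {base_outcome!r} absent from data")
    # order outcomes with the base first so its coefficients are the zeroed ones
    categories = [base_outcome] + [g for g in present if g != base_outcome]
    y = pd.Categorical(y_raw, categories=categories).codes

    design, references, meta = _indicator_design(frame, predictors, references)

    # detect empty (level x outcome) cells -> not estimable
    dropped: list[tuple[str, str]] = []
    for (pred, lv), col in zip(meta, design.columns):
        cell_counts = pd.crosstab(design[col] > 0, y_raw)
        if True not in cell_counts.index:
            dropped.append((pred, lv))
            continue
        row = cell_counts.reindex([True]).reindex(columns=present, fill_value=0)
        if (row.to_numpy() == 0).any():
            dropped.append((pred, lv))
    keep_cols = [c for (m, c) in zip(meta, design.columns) if m not in dropped]
    fit_design = design[keep_cols]
    if not fit_design.empty:
        _check_aliasing(fit_design)
    x = sm.add_constant(fit_design, has_constant="add")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MNLogit(y, x.astype(float))
        fit = model.fit(method="newton", maxiter=maxiter, disp=False)
        if not fit.mle_retvals.get("converged", False):
            # Newton stalls near separation; quasi-Newton usually finishes
            fit = model.fit(method="bfgs", maxiter=10 * maxiter, disp=False)
    if not fit.mle_retvals.get("converged", False):
        raise RuntimeError(
            f"multinomial fit did not converge: {fit.mle_retvals}"
        )

    colnames = list(x.columns)
    rows = []
    for j, out_label in enumerate(categories[1:]):  # non-base outcomes
        params = fit.params.iloc[:, j]
        bse = fit.bse.iloc[:, j]
        pvals = fit.pvalues.iloc[:, j]
        for pred, lv in meta:
            if (pred, lv) in dropped:
                rows.append(
                    dict(outcome=out_label, predictor=pred, level=lv,
                         rrr=np.nan, ci_low=np.nan, ci_high=np.nan,
                         p_value=np.nan, estimable=False)
                )
                continue
            k = colnames.index(f"{pred}[{lv}]")
            b, se = params.iloc[k], bse.iloc[k]
            rows.append(
                dict(
                    outcome=out_label,
                    predictor=pred,
                    level=lv,
                    rrr=float(np.exp(b)),
                    ci_low=float(np.exp(b - _Z95 * se)),
                    ci_high=float(np.exp(b + _Z95 * se)),
                    p_value=float(pvals.iloc[k]),
                    estimable=True,
                )
            )
    return MultinomialResult(
        table=pd.DataFrame(rows),
        base_outcome=base_outcome,
        references=references,
        n=len(frame),
        converged=True,
        dropped_levels=dropped,
    )
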
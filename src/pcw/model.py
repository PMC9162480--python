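"""Model/Results surface tying the pipeline together.

:class:`PCWModel` is built from a survey dataset (or CSV); ``fit()`` scores
both mental-workload assessments, derives the adjustment coefficients over
the sample, computes every respondent's comprehensive workload score and its
log, stratifies the sample into the four relative workload groups, and
returns a :class:`PCWResults` carrying the per-respondent table plus the
downstream analyses (distribution table, cross-tabs with chi-square, ln(PCW)
regression, multinomial logit) as methods.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import mwl_scale, pcw_model, schema, stats_analysis
from .survey_io import SurveyDataset, read_survey

__all__ = ["PCWModel", "PCWResults"]


class PCWModel:
    """Integrated comprehensive-workload model for one survey sample.

    Parameters
    ----------
    data
        A :class:`~pcw.survey_io.SurveyDataset` or a DataFrame with the
        canonical schema columns.
    scale
        Item-to-dimension mapping of the mental-workload instrument
        (defaults to two consecutive items per dimension).
    scheme
        Normalization scheme of the three adjustment coefficients.
    """

    def __init__(
        self,
        data: SurveyDataset | pd.DataFrame,
        scale: mwl_scale.ScaleDefinition | None = None,
        scheme: pcw_model.CoefficientScheme | None = None,
    ):
        if isinstance(data, pd.DataFrame):
            data = SurveyDataset(data.reset_index(drop=True), provenance="<frame>")
        self.data = data
        self.scale = scale or mwl_scale.ScaleDefinition.default()
        self.scheme = scheme or pcw_model.CoefficientScheme()

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "PCWModel":
        return cls(read_survey(path), **kwargs)

    def fit(self) -> "PCWResults":
        frame = self.data.frame
        comm = mwl_scale.score_frame(frame, "comm", self.scale)
        noncomm = mwl_scale.score_frame(frame, "noncomm", self.scale)
        adj = pcw_model.compute_adjustments(frame, self.scheme)

        pw_comm = pcw_model.compute_task_workload(
            comm["pmw"].to_numpy(), frame["t_comm"].to_numpy()
        )
        pw_noncomm = pcw_model.compute_task_workload(
            noncomm["pmw"].to_numpy(), frame["t_noncomm"].to_numpy()
        )
        pcw = pcw_model.compute_pcw(
            pw_comm, pw_noncomm,
            adj["r_ov"].to_numpy(), adj["r_pc"].to_numpy(), adj["r_ps"].to_numpy(),
        )
        ln_pcw = np.full_like(pcw, np.nan)
        positive = pcw > 0
        if not positive.all():
            warnings.warn(
                f"{np.sum(~positive)} record(s) with PCW = 0: ln(PCW) undefined, "
                "excluded from regression stages"
            )
        ln_pcw[positive] = np.log(pcw[positive])

        classification, types = pcw_model.classify_pcw(pcw)
        out = frame[
            ["respondent_id"]
            + list(schema.CATEGORY_COLUMNS)
            + list(schema.NUMERIC_COLUMNS)
        ].copy()
        out["pmw_comm"] = comm["pmw"]
        out["pmw_noncomm"] = noncomm["pmw"]
        out["pw_comm"] = pw_comm
        out["pw_noncomm"] = pw_noncomm
        out["r_ov"] = adj["r_ov"]
        out["r_pc"] = adj["r_pc"]
        out["r_ps"] = adj["r_ps"]
        out["pcw"] = pcw
        out["ln_pcw"] = ln_pcw
        out["pcw_type"] = types.set_axis(out.index)
        out["pcw_group"] = classification.groups(pcw).set_axis(out.index)
        return PCWResults(self, out, classification)


class PCWResults:
    """Fitted comprehensive-workload results for one sample."""

    def __init__(
        self,
        model: PCWModel,
        frame: pd.DataFrame,
        classification: pcw_model.ClassificationScheme,
    ):
        self.model = model
        self.frame = frame
        self.classification = classification

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def pcw(self) -> pd.Series:
        return self.frame["pcw"]

    def group_counts(self) -> pd.Series:
        return (
            self.frame["pcw_group"]
            .value_counts()
            .reindex(list(schema.PCW_GROUPS), fill_value=0)
        )

    def distribution(self, edges: Sequence[float] | None = None) -> pcw_model.DistributionTable:
        """Score-interval distribution of the fitted PCW values."""
        if edges is None:
            upper = max(pcw_model.DEFAULT_EDGES[-1], float(self.pcw.max()) + 1.0)
            edges = pcw_model.DEFAULT_EDGES[:-1] + (upper,)
        return pcw_model.distribution_table(self.pcw.to_numpy(), edges)

    def crosstab_chi2(
        self, characteristic: str, min_expected: float | None = 5.0
    ) -> tuple[stats_analysis.ContingencyTable, stats_analysis.ChiSquareResult]:
        """Group cross-tab for one characteristic plus its Pearson chi-square.

        ``min_expected`` drops characteristic levels whose expected counts
        fall below the floor before testing (pass None to keep all levels).
        """
        table = stats_analysis.crosstab(
            self.frame["pcw_group"], self.frame[characteristic]
        )
        if min_expected is not None:
            table = stats_analysis.drop_sparse_levels(table, min_expected)
        return table, stats_analysis.pearson_chi_square(table)

    def regress_ln_pcw(
        self,
        predictors: Sequence[str],
        references: Mapping[str, str] | None = None,
    ) -> stats_analysis.RegressionResult:
        refs = {
            p: stats_analysis.DEFAULT_REFERENCES[p]
            for p in predictors
            if p in stats_analysis.DEFAULT_REFERENCES
        }
        refs.update(references or {})
        return stats_analysis.fit_lnpcw_regression(self.frame, predictors, refs)

    def multinomial(
        self,
        predictors: Sequence[str],
        references: Mapping[str, str] | None = None,
        base_outcome: str = "very high",
    ) -> stats_analysis.MultinomialResult:
        refs = {
            p: stats_analysis.MULTINOMIAL_REFERENCES[p]
            for p in predictors
            if p in stats_analysis.MULTINOMIAL_REFERENCES
        }
        refs.update(references or {})
        return stats_analysis.fit_multinomial(
            self.frame, predictors, refs, base_outcome=base_outcome
        )

    def summary(self) -> str:
        c = self.classification
        counts = self.group_counts()
        lines = [
            f"Physician comprehensive workload, n = {self.n}",
            f"coefficient scheme: {self.model.scheme.describe()}",
            f"PCW mean = {self.pcw.mean():.2f}, SD = {self.pcw.std(ddof=1):.2f}, "
            f"range [{self.pcw.min():.2f}, {self.pcw.max():.2f}]",
            f"cut points (M-SD, M, M+SD): {c.cut_low:.2f}, {c.cut_mid:.2f}, {c.cut_high:.2f}",
        ]
        for group, cnt in counts.items():
            share = 100.0 * cnt / self.n if self.n else float("nan")
            lines.append(f"  {group:>9s}: {cnt:6d} ({share:.1f}%)")
        return "\n".join(lines)

    def plot_distribution(self, ax=None, bins: int = 30):
        """Histogram of PCW scores (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.pcw.to_numpy(), bins=bins, color="#4878d0", edgecolor="white")
        for cut in (self.classification.cut_low, self.classification.cut_mid,
                    self.classification.cut_high):
            ax.axvline(cut, color="crimson", linestyle="--", linewidth=1)
        ax.set_xlabel("comprehensive workload score")
        ax.set_ylabel("physicians")
        return ax
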
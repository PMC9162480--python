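"""End-to-end pipeline orchestration and report rendering.

``run_pipeline`` drives read/generate -> eligibility screen -> scoring ->
classification -> descriptive and inferential tables; ``render_reports``
writes one CSV per table plus a machine-readable ``summary.json``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import schema
from .model import PCWModel
from .pcw_model import CoefficientScheme
from .survey_io import read_survey, validate_eligibility, write_table
from .synthetic_data import GeneratorConfig, sample_population

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "render_reports"]

log = logging.getLogger("pcw")

DEFAULT_PREDICTORS: tuple[str, ...] = (
    "gender", "area", "hours_per_week_band", "outpatient_hours_band",
)


@dataclasses.dataclass
class PipelineConfig:
    """One of ``input_path`` / ``generator`` must be set, not both."""

    input_path: str | None = None
    generator: GeneratorConfig | None = None
    scheme: CoefficientScheme = dataclasses.field(default_factory=CoefficientScheme)
    predictors: Sequence[str] = DEFAULT_PREDICTORS
    references: Mapping[str, str] | None = None
    multinomial_predictors: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.generator is None):
            raise ValueError("set exactly one of input_path / generator")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        gen = raw.pop("generator", None)
        scheme = raw.pop("scheme", None)
        kwargs = dict(raw)
        if gen is not None:
            kwargs["generator"] = GeneratorConfig(**gen)
        if scheme is not None:
            kwargs["scheme"] = CoefficientScheme(**scheme)
        return cls(**kwargs)


@dataclasses.dataclass
class ReportBundle:
    characteristics: pd.DataFrame
    distribution: pd.DataFrame
    group_tests: pd.DataFrame
    regression: pd.DataFrame
    multinomial: pd.DataFrame
    metadata: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "characteristics": self.characteristics,
            "distribution": self.distribution,
            "group_tests": self.group_tests,
            "regression": self.regression,
            "multinomial": self.multinomial,
        }


def characteristics_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Category frequency table plus mean/SD rows for the measurements."""
    rows = []
    n = len(frame)
    for col in schema.CATEGORY_COLUMNS:
        counts = frame[col].value_counts()
        for level in schema.VOCABULARY[col]:
            if level not in counts:
                continue
            cnt = int(counts[level])
            rows.append(
                dict(characteristic=col, level=level, n=cnt,
                     value=round(100.0 * cnt / n, 1) if n else np.nan,
                     kind="percent")
            )
    for col in ("n_outpatients_per_day", "n_admitted_per_day", "satisfaction",
                "t_comm", "t_noncomm"):
        rows.append(
            dict(characteristic=col, level="mean", n=n,
                 value=round(float(frame[col].mean()), 2) if n else np.nan,
                 kind="mean")
        )
        rows.append(
            dict(characteristic=col, level="sd", n=n,
                 value=round(float(frame[col].std(ddof=1)), 2) if n > 1 else np.nan,
                 kind="sd")
        )
    return pd.DataFrame(rows, columns=["characteristic", "level", "n", "value", "kind"])


def _stage(name: str):
    log.info("stage: %s", name)
    return time.perf_counter()


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    t0 = _stage("load")
    if config.input_path is not None:
        data = read_survey(config.input_path)
    else:
        data = sample_population(config.generator)
    log.info("loaded %d records (%.2fs)", len(data), time.perf_counter() - t0)

    t0 = _stage("eligibility")
    report = validate_eligibility(data)
    eligible = report.eligible
    rate = report.recovery_rate
    log.info(
        "eligible %d / %d (recovery %s)", len(eligible), report.n_input,
        "n/a" if rate is None else f"{rate:.1f}%",
    )

    meta: dict = {
        "n_input": report.n_input,
        "n_eligible": len(eligible),
        "recovery_rate_pct": None if rate is None else round(rate, 1),
        "rejections": [
            {"respondent_id": str(r), "rule": rule} for r, rule in report.rejections
        ],
        "coefficient_scheme": config.scheme.describe(),
        "provenance": data.provenance,
    }
    if config.generator is not None:
        meta["seed"] = config.generator.seed
        meta["config_digest"] = config.generator.digest()

    if len(eligible) == 0:
        empty = pd.DataFrame()
        meta["n"] = 0
        return ReportBundle(
            characteristics_table(eligible.frame), empty, empty, empty, empty, meta
        )

    t0 = _stage("score")
    results = PCWModel(eligible, scheme=config.scheme).fit()
    log.info("scored %d records (%.2fs)", results.n, time.perf_counter() - t0)

    meta.update(
        n=results.n,
        pcw_mean=round(float(results.pcw.mean()), 2),
        pcw_sd=round(float(results.pcw.std(ddof=1)), 2),
        cut_points={
            "low": round(results.classification.cut_low, 2),
            "mid": round(results.classification.cut_mid, 2),
            "high": round(results.classification.cut_high, 2),
        },
        group_counts={k: int(v) for k, v in results.group_counts().items()},
    )

    t0 = _stage("cross-tabs")
    test_rows = []
    for col in schema.CATEGORY_COLUMNS:
        try:
            table, chi = results.crosstab_chi2(col)
        except ValueError:
            continue
        for level, row in table.counts.iterrows():
            rec = dict(characteristic=col, level=level)
            rec.update({str(g): int(row[g]) for g in row.index})
            rec.update(chi2=round(chi.statistic, 3), df=chi.df,
                       p_value=chi.p_value)
            test_rows.append(rec)
    group_tests = pd.DataFrame(test_rows)

    t0 = _stage("regression")
    reg = results.regress_ln_pcw(list(config.predictors), config.references)
    regression = reg.terms.copy()
    regression.insert(
        2, "reference", [reg.references[p] for p in regression["predictor"]]
    )
    const = dict(
        predictor="(constant)", level="", reference="",
        beta=reg.intercept["beta"], se=reg.intercept["se"],
        t=reg.intercept["t"], p_value=reg.intercept["p_value"], vif=np.nan,
    )
    regression = pd.concat([pd.DataFrame([const]), regression], ignore_index=True)

    t0 = _stage("multinomial")
    mpred = list(config.multinomial_predictors or config.predictors)
    mres = results.multinomial(mpred)
    multinomial = mres.table.copy()
    multinomial.insert(
        3, "reference", [mres.references[p] for p in multinomial["predictor"]]
    )
    meta["multinomial_base_outcome"] = mres.base_outcome

    return ReportBundle(
        characteristics=characteristics_table(results.frame),
        distribution=results.distribution().table,
        group_tests=group_tests,
        regression=regression,
        multinomial=multinomial,
        metadata=meta,
    )


def render_reports(bundle: ReportBundle, outdir: str | Path) -> list[Path]:
    """Write each table as CSV plus ``summary.json``; stable filenames."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in bundle.tables().items():
        written.append(write_table(table, outdir / f"{name}.csv"))
    summary = outdir / "summary.json"
    summary.write_text(json.dumps(bundle.metadata, indent=2, sort_keys=True) + "\n")
    written.append(summary)
    return written
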
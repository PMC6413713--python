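"""End-to-end study orchestration: simulate -> ASL fit -> CVR fit -> stats.

``run_study`` is a pure function of (config, seed): it generates the
synthetic cohort, runs the perfusion and reactivity analyses per
subject, applies the exclusion rule, runs the per-region group
statistics, and returns tidy tables plus provenance.  ``render_tables``
formats the group summaries in "mean +/- sd" style with significance
markers.
"""

from __future__ import annotations

import platform
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .asl import asl_pipeline
from .cvr import LATE_WINDOW, STEADY_WINDOW, apply_exclusion, cvr_pipeline
from .datamodel import (
    ASL_REGIONS,
    CVR_REGIONS,
    WHOLE_BRAIN,
    CbfConstants,
    group_factors,
)
from .stats import tukey_hsd, two_way_anova
from .synth import CohortSpec, simulate_cohort


@dataclass
class RunConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    constants: CbfConstants = field(default_factory=CbfConstants)
    steady_window: tuple[int, int] = STEADY_WINDOW
    late_window: tuple[int, int] = LATE_WINDOW
    run_asl: bool = True
    run_cvr: bool = True
    run_stats: bool = True


@dataclass
class StudyReport:
    cbf_subject: pd.DataFrame | None
    cbf_group: pd.DataFrame | None
    cvr_subject: pd.DataFrame | None
    cvr_group: pd.DataFrame | None
    late_group: pd.DataFrame | None
    exclusions: pd.DataFrame | None
    anova: pd.DataFrame | None
    tukey: pd.DataFrame | None
    provenance: dict
    truth_cbf: pd.DataFrame | None = None
    truth_cvr: pd.DataFrame | None = None

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {}
        for name in ("cbf_subject", "cbf_group", "cvr_subject", "cvr_group",
                     "late_group", "exclusions", "anova", "tukey",
                     "truth_cbf", "truth_cvr"):
            t = getattr(self, name)
            if t is not None:
                out[name] = t
        return out


def _group_summary(df: pd.DataFrame, value: str) -> pd.DataFrame:
    g = df.groupby(["region", "group"], observed=True)[value]
    out = g.agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count").reset_index()
    return out


def _stats_tables(long: pd.DataFrame, metric: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-region two-way ANOVA and Tukey tables for one metric."""
    anova_rows, tukey_rows = [], []
    for region, sub in long.groupby("region", observed=True):
        res = two_way_anova(sub, response="value")
        for term, (f, df1, df2, p) in res.terms.items():
            anova_rows.append(
                {"metric": metric, "region": region, "term": term,
                 "F": f, "df1": df1, "df2": df2, "p": p}
            )
        tk = tukey_hsd(sub, response="value", group="group")
        tk.insert(0, "region", region)
        tk.insert(0, "metric", metric)
        tukey_rows.append(tk)
    return pd.DataFrame(anova_rows), pd.concat(tukey_rows, ignore_index=True)


def run_study(config: RunConfig = RunConfig(), seed: int = 0) -> StudyReport:
    """Run the whole synthetic study once.

    Produces per-subject and per-group CBF tables, the reactivity
    slope/intercept/R and late-response tables with the exclusion log,
    and the two-way ANOVA + Tukey statistics per region and metric.
    """
    modalities = tuple(m for m, on in (("asl", config.run_asl), ("cvr", config.run_cvr)) if on)
    try:
        cohort = simulate_cohort(config.cohort, seed=seed, modalities=modalities)
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
    group_of = {s.record.subject_id: s.record.group for s in cohort.subjects}

    cbf_subject = cbf_group = None
    cvr_subject = cvr_group = late_group = exclusions = None
    anova_all: list[pd.DataFrame] = []
    tukey_all: list[pd.DataFrame] = []

    if config.run_asl:
        rows = []
        for s in cohort.subjects:
            try:
                df = asl_pipeline(s.asl, cohort.atlas, config.constants, ASL_REGIONS)
            except Exception as exc:
                raise RuntimeError(
                    f"stage 'asl' failed for subject {s.record.subject_id}: {exc}"
                ) from exc
            rows.append(df)
        cbf_subject = pd.concat(rows, ignore_index=True)
        cbf_subject["group"] = cbf_subject["subject_id"].map(group_of)
        cbf_group = _group_summary(cbf_subject, "cbf_mean")
        if config.run_stats:
            long = cbf_subject.rename(columns={"cbf_mean": "value"})
            long = _attach_factors(long)
            a, t = _stats_tables(long, "cbf")
            anova_all.append(a)
            tukey_all.append(t)

    if config.run_cvr:
        per_subject = {}
        for s in cohort.subjects:
            try:
                per_subject[s.record.subject_id] = cvr_pipeline(
                    s.cvr, cohort.atlas, config.steady_window, config.late_window
                )
            except Exception as exc:
                raise RuntimeError(
                    f"stage 'cvr' failed for subject {s.record.subject_id}: {exc}"
                ) from exc
        retained, exclusions = apply_exclusion(per_subject)
        rows = []
        for sid, results in retained.items():
            for r in results:
                if r.region == WHOLE_BRAIN:
                    continue
                rows.append(
                    {"subject_id": sid, "group": group_of[sid], "region": r.region,
                     "cbv0": r.cbv0, "slope_a": r.slope_a, "intercept_b": r.intercept_b,
                     "corr_r": r.corr_r, "late_dcbv_pct": r.late_dcbv_pct,
                     "n_clipped": r.n_clipped}
                )
        cvr_subject = pd.DataFrame(rows)
        cvr_group = _group_summary(cvr_subject, "slope_a").rename(
            columns={"mean": "slope_mean", "sd": "slope_sd"}
        )
        ib = _group_summary(cvr_subject, "intercept_b")
        cvr_group["intercept_mean"] = ib["mean"]
        cvr_group["intercept_sd"] = ib["sd"]
        rmean = cvr_subject.groupby(["region", "group"], observed=True)["corr_r"].mean().reset_index()
        cvr_group["corr_r_mean"] = rmean["corr_r"]
        late_group = _group_summary(cvr_subject, "late_dcbv_pct")
        if config.run_stats:
            for metric in ("slope_a", "late_dcbv_pct", "cbv0"):
                long = cvr_subject.rename(columns={metric: "value"})[
                    ["subject_id", "group", "region", "value"]
                ]
                long = _attach_factors(long)
                a, t = _stats_tables(long, metric)
                anova_all.append(a)
                tukey_all.append(t)

    provenance = {
        "seed": seed,
        "neuroperf_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
        "modalities": list(modalities),
        "steady_window": list(config.steady_window),
        "late_window": list(config.late_window),
        "constants": {
            "lambda_partition": config.constants.lambda_partition,
            "t1_blood_s": config.constants.t1_blood_s,
            "output_scale": config.constants.output_scale,
        },
        "group_n": dict(config.cohort.group_n),
    }
    return StudyReport(
        cbf_subject=cbf_subject,
        cbf_group=cbf_group,
        cvr_subject=cvr_subject,
        cvr_group=cvr_group,
        late_group=late_group,
        exclusions=exclusions,
        anova=pd.concat(anova_all, ignore_index=True) if anova_all else None,
        tukey=pd.concat(tukey_all, ignore_index=True) if tukey_all else None,
        provenance=provenance,
        truth_cbf=cohort.truth_cbf if config.run_asl else None,
        truth_cvr=cohort.truth_cvr if config.run_cvr else None,
    )


def _attach_factors(long: pd.DataFrame) -> pd.DataFrame:
    factors = long["group"].map(lambda g: group_factors(g))
    long = long.copy()
    long["genotype"] = factors.map(lambda t: t[0])
    long["treatment"] = factors.map(lambda t: t[1])
    return long


def significance_marker(p: float) -> str:
    """Star convention: * p<0.05, ** p<0.01, *** p<0.001."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def format_mean_sd(mean: float, sd: float, decimals: int = 3) -> str:
    return f"{mean:.{decimals}f} ± {sd:.{decimals}f}"


def render_tables(report: StudyReport, decimals: int = 3) -> dict[str, pd.DataFrame]:
    """Paper-style wide tables: one row per region, one column per group,
    cells "mean +/- sd" with significance markers from the Tukey stage."""
    out: dict[str, pd.DataFrame] = {}

    def stars(metric: str, region: str, group: str) -> str:
        if report.tukey is None:
            return ""
        tk = report.tukey
        hit = tk[(tk["metric"] == metric) & (tk["region"] == region)
                 & ((tk["group1"] == group) | (tk["group2"] == group))]
        if hit.empty:
            return ""
        return significance_marker(float(hit["p_adj"].min()))

    specs = []
    if report.cbf_group is not None:
        specs.append(("cbf", report.cbf_group, "mean", "sd"))
    if report.cvr_group is not None:
        specs.append(("slope_a", report.cvr_group, "slope_mean", "slope_sd"))
        specs.append(("intercept", report.cvr_group, "intercept_mean", "intercept_sd"))
    if report.late_group is not None:
        specs.append(("late_dcbv_pct", report.late_group, "mean", "sd"))

    for metric, table, mcol, scol in specs:
        rows = {}
        for _, row in table.iterrows():
            n = row.get("n", np.nan)
            if pd.notna(n) and n == 0:
                cell = ""
            else:
                cell = format_mean_sd(row[mcol], row[scol], decimals)
                mark_metric = "slope_a" if metric == "intercept" else metric
                cell += stars(mark_metric, row["region"], row["group"])
            rows.setdefault(row["region"], {})[row["group"]] = cell
        out[metric] = pd.DataFrame(rows).T.rename_axis("region").reset_index()
    return out


def write_report(report: StudyReport, outdir: str | Path) -> Path:
    """Write all report tables, rendered tables and provenance under outdir."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, table in report.tables().items():
        table.to_csv(outdir / f"{name}.csv", index=False)
    for name, table in render_tables(report).items():
        table.to_csv(outdir / f"table_{name}.csv", index=False)
    (outdir / "provenance.json").write_text(json.dumps(report.provenance, indent=1))
    return outdir
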
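"""Cohort-level statistics for impulse-oscillometry studies.

Reproduces the analysis surface of a two-group longitudinal bronchodilator
design: per-cell (group × visit × condition) means of IOS indices and fitted
circuit constants, growth and bronchodilator percent changes computed on the
cell means, paired t-tests for within-subject contrasts, Welch two-sample
t-tests for the unequal-size between-group contrasts, and ordinary
least-squares correlations between model parameters and IOS indices.

Raw p-values are reported with a significance flag at alpha = 0.05; no
multiple-testing correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortDataset
from .fitting import FitOptions, fit_model
from .indices import compute_indices
from .models import InvalidInputError

__all__ = [
    "ALPHA",
    "TestReport",
    "percent_change",
    "round_half_away",
    "paired_t",
    "two_sample_t",
    "linear_fit",
    "record_table",
    "summarize",
    "percent_change_table",
    "study_report",
    "StudyReport",
    "InsufficientDataError",
    "DegenerateFitError",
]

ALPHA = 0.05

#: canonical visit-condition stages in study order
STAGES = ((2006, "preB"), (2008, "preB"), (2008, "postB"))


class InsufficientDataError(InvalidInputError):
    pass


class DegenerateFitError(InvalidInputError):
    pass


@dataclass(frozen=True)
class TestReport:
    label: str
    t: float
    df: float
    p: float
    significant: bool
    flag: str | None = None


def percent_change(earlier: float, later: float) -> float:
    """Signed percent change 100*(later - earlier)/earlier."""
    if not earlier > 0:
        raise InvalidInputError(f"earlier value must be > 0, got {earlier!r}")
    return 100.0 * (later - earlier) / earlier


def round_half_away(x: float) -> int:
    """Integer rounding with ties away from zero (reporting convention)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def paired_t(before, after, label: str = "paired") -> TestReport:
    """Paired Student t on (after − before) differences, two-sided."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape or before.ndim != 1:
        raise InvalidInputError("before/after must be equal-length 1-D")
    n = len(before)
    if n < 2:
        raise InsufficientDataError(f"paired t needs n >= 2, got {n}")
    d = after - before
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return TestReport(label, 0.0, float(n - 1), 1.0, False, flag="zero-variance")
        # nonzero constant shift: limiting value of the statistic
        t = math.copysign(math.inf, d.mean())
        return TestReport(label, t, float(n - 1), 0.0, True, flag="zero-variance")
    res = stats.ttest_rel(after, before)
    p = float(res.pvalue)
    return TestReport(label, float(res.statistic), float(n - 1), p, p < ALPHA)


def two_sample_t(group_a, group_b, label: str = "two-sample") -> TestReport:
    """Welch two-sample t (unequal variances, Welch–Satterthwaite df)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if min(len(a), len(b)) < 2:
        raise InsufficientDataError("each group needs n >= 2")
    res = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if np.allclose(a.mean(), b.mean()):
            return TestReport(label, 0.0, float(len(a) + len(b) - 2), 1.0, False, flag="zero-variance")
        t = math.copysign(math.inf, a.mean() - b.mean())
        return TestReport(label, t, float(len(a) + len(b) - 2), 0.0, True, flag="zero-variance")
    sa, sb = va / len(a), vb / len(b)
    df = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    p = float(res.pvalue)
    return TestReport(label, float(res.statistic), float(df), p, p < ALPHA)


def linear_fit(x, y) -> tuple[float, float, float]:
    """OLS line y = slope*x + intercept and Pearson r."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise InsufficientDataError("linear fit needs paired n >= 2")
    if np.allclose(x, x[0]):
        raise DegenerateFitError("x is constant; slope undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def record_table(dataset: CohortDataset, models=("eric", "aric"), fit_options: FitOptions | None = None) -> pd.DataFrame:
    """Tidy per-record table: indices plus fitted parameters for each model.

    One row per (record, model); the heavy lifting of downstream summaries.
    """
    base_opts = fit_options or FitOptions()
    rows = []
    for rec in dataset.records:
        ios = compute_indices(rec.spectrum)
        for model in models:
            opts = FitOptions(
                model_kind=model,
                fit_frequencies=base_opts.fit_frequencies,
                bounds=base_opts.bounds,
                n_starts=base_opts.n_starts,
                seed=base_opts.seed,
                tolerance=base_opts.tolerance,
            )
            fit = fit_model(rec.spectrum, opts)
            p = fit.parameters
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "group": rec.group,
                    "visit": rec.visit,
                    "condition": rec.condition,
                    "model": model,
                    "R5": ios.R5,
                    "R20": ios.R20,
                    "fdR": ios.fdR,
                    "X5": ios.X5,
                    "fres": ios.fres,
                    "AX": ios.ax,
                    "Rc": p.Rc,
                    "I": p.I,
                    "Rp": p.Rp,
                    "Cp": p.Cp,
                    "Ce": getattr(p, "Ce", float("nan")),
                    "objective": fit.objective,
                    "converged": fit.converged,
                }
            )
    return pd.DataFrame(rows)


def summarize(records: pd.DataFrame) -> pd.DataFrame:
    """Cell means per (group, visit, condition, model), with cell n.

    Cells with no records are flagged by their absence in the index union;
    an empty input is an error rather than an empty table.
    """
    if records.empty:
        raise InsufficientDataError("no records to summarize")
    value_cols = ["R5", "fdR", "X5", "AX", "Rc", "I", "Rp", "Cp", "Ce"]
    grouped = records.groupby(["group", "visit", "condition", "model"], sort=True)
    out = grouped[value_cols].mean()
    out["n"] = grouped.size()
    return out.reset_index()


def percent_change_table(summary: pd.DataFrame, value_cols=None) -> pd.DataFrame:
    """Growth and bronchodilator percent changes computed on cell means.

    ``summary`` must carry columns group/visit/condition plus the value
    columns (``model`` optional). Growth contrasts 2006 pre-B vs 2008 pre-B;
    bronchodilator contrasts 2008 pre-B vs post-B. Output rows: (group,
    [model,] contrast, parameter, percent, percent_rounded).
    """
    if value_cols is None:
        value_cols = [
            c for c in summary.columns
            if c not in ("group", "visit", "condition", "model", "n")
        ]
    keys = ["group"] + (["model"] if "model" in summary.columns else [])
    rows = []
    for key, cell in summary.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        stage = {}
        for visit, cond in STAGES:
            sel = cell[(cell["visit"] == visit) & (cell["condition"] == cond)]
            if len(sel) == 1:
                stage[(visit, cond)] = sel.iloc[0]
        for contrast, (a, b) in (
            ("growth", ((2006, "preB"), (2008, "preB"))),
            ("bronchodilator", ((2008, "preB"), (2008, "postB"))),
        ):
            if a not in stage or b not in stage:
                continue
            for col in value_cols:
                ea, eb = stage[a][col], stage[b][col]
                if not (pd.notna(ea) and pd.notna(eb) and ea > 0):
                    continue
                pct = percent_change(float(ea), float(eb))
                rows.append(dict(zip(keys, key)) | {
                    "contrast": contrast,
                    "parameter": col,
                    "percent": pct,
                    "percent_rounded": round_half_away(pct),
                })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class StudyReport:
    """Machine-readable bundle of the whole cohort analysis."""

    records: pd.DataFrame
    summary: pd.DataFrame
    percent_changes: pd.DataFrame
    within_group_tests: pd.DataFrame
    between_group_tests: pd.DataFrame
    correlations: pd.DataFrame

    def write(self, directory) -> list[str]:
        """Write the bundle as CSV files with deterministic names."""
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        written = []
        for name in (
            "records", "summary", "percent_changes",
            "within_group_tests", "between_group_tests", "correlations",
        ):
            path = d / f"{name}.csv"
            getattr(self, name).to_csv(path, index=False)
            written.append(str(path))
        return written


def _paired_frames(records: pd.DataFrame, model: str):
    """Wide per-subject frames for the three stages, one model."""
    sub = records[records["model"] == model]
    out = {}
    for visit, cond in STAGES:
        cell = sub[(sub["visit"] == visit) & (sub["condition"] == cond)]
        out[(visit, cond)] = cell.set_index("subject_id")
    return out


def study_report(dataset: CohortDataset, fit_options: FitOptions | None = None) -> StudyReport:
    """Compose the full analysis of a cohort dataset.

    Within-group paired contrasts (growth and bronchodilator) and
    between-group Welch contrasts are run on the IOS indices and on the
    fitted Rp/Cp of each model; correlations pool all visit-conditions
    (Cp vs AX, Rp vs fdR, and eRIC-vs-aRIC parameter agreement).
    """
    if len(dataset) == 0:
        raise InsufficientDataError("empty dataset")
    records = record_table(dataset, fit_options=fit_options)
    summary = summarize(records)
    pct = percent_change_table(summary, value_cols=["R5", "fdR", "AX", "Rp", "Cp"])

    index_cols = ["R5", "fdR", "AX"]
    param_cols = ["Rp", "Cp"]

    within = []
    for model in ("eric", "aric"):
        stages = _paired_frames(records, model)
        for contrast, (a, b) in (
            ("growth", ((2006, "preB"), (2008, "preB"))),
            ("bronchodilator", ((2008, "preB"), (2008, "postB"))),
        ):
            fa, fb = stages[a], stages[b]
            common = fa.index.intersection(fb.index)
            for group in sorted(records["group"].unique()):
                ids = [s for s in common if fa.loc[s, "group"] == group]
                if len(ids) < 2:
                    continue
                cols = index_cols + param_cols if model == "eric" else param_cols
                for col in cols:
                    x, y = fa.loc[ids, col].astype(float), fb.loc[ids, col].astype(float)
                    if x.isna().any() or y.isna().any():
                        continue
                    rep = paired_t(x, y, label=f"{group} {contrast} {model} {col}")
                    within.append(
                        {"group": group, "model": model, "contrast": contrast, "parameter": col,
                         "t": rep.t, "df": rep.df, "p": rep.p, "significant": rep.significant}
                    )

    between = []
    for model in ("eric", "aric"):
        sub = records[records["model"] == model]
        for visit, cond in STAGES:
            cell = sub[(sub["visit"] == visit) & (sub["condition"] == cond)]
            cols = index_cols + param_cols if model == "eric" else param_cols
            for col in cols:
                a = cell[cell["group"] == "SAI"][col].dropna().astype(float)
                b = cell[cell["group"] == "H"][col].dropna().astype(float)
                if len(a) < 2 or len(b) < 2:
                    continue
                rep = two_sample_t(a, b, label=f"SAI vs H {visit} {cond} {model} {col}")
                between.append(
                    {"model": model, "visit": visit, "condition": cond, "parameter": col,
                     "t": rep.t, "df": rep.df, "p": rep.p, "significant": rep.significant}
                )

    corr = []
    eric = records[records["model"] == "eric"].set_index(["subject_id", "visit", "condition"])
    aric = records[records["model"] == "aric"].set_index(["subject_id", "visit", "condition"])
    pairs = [
        ("eric Cp vs AX", eric["AX"], eric["Cp"]),
        ("aric Cp vs AX", aric["AX"], aric["Cp"]),
        ("eric Rp vs fdR", eric["fdR"], eric["Rp"]),
        ("aric Rp vs fdR", aric["fdR"], aric["Rp"]),
        ("aric Cp vs eric Cp", eric["Cp"], aric["Cp"]),
        ("aric Rp vs eric Rp", eric["Rp"], aric["Rp"]),
    ]
    for label, x, y in pairs:
        joined = pd.concat([x.rename("x"), y.rename("y")], axis=1).dropna()
        if len(joined) < 2 or np.allclose(joined["x"], joined["x"].iloc[0]):
            continue
        slope, intercept, r = linear_fit(joined["x"], joined["y"])
        corr.append({"pair": label, "slope": slope, "intercept": intercept, "r": r, "n": len(joined)})

    return StudyReport(
        records=records,
        summary=summary,
        percent_changes=pct,
        within_group_tests=pd.DataFrame(within),
        between_group_tests=pd.DataFrame(between),
        correlations=pd.DataFrame(corr),
    )
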
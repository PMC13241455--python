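"""Scalar-outcome cohort models.

Three model families link the depth-windowed fat metrics to the clinical
covariates:

* chronicity regression — OLS of pain chronicity (years) on a subject-mean
  fat metric (overall or deep15 FI%), mean disc degeneration (average
  Pfirrmann grade over L4L5/L5S1), age, sex and BMI;
* activity regression — OLS of weekly MET-minutes on chronicity, pain
  severity, age, sex and BMI;
* mixed FI model — linear mixed-effects model of a per-level FI metric
  (two rows per subject: L4L5, L5S1) on chronicity, level-specific disc
  degeneration, physical activity, pain, age, sex, BMI and lumbar level,
  with a per-subject random intercept (REML).

Continuous fixed effects in the mixed model are z-scored by default so
coefficients are comparable across predictors with very different native
scales (years vs MET-min/wk); sex is coded with male as the reference level.
Incomplete rows are dropped listwise and the count is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

log = logging.getLogger(__name__)

LEVELS = ("L4L5", "L5S1")


@dataclass
class ModelFit:
    formula: str
    table: pd.DataFrame  # index = term; columns: estimate, se, p
    n_obs: int
    n_subjects: int
    converged: bool = True
    random_intercept_var: float | None = None
    dropped: int = 0

    def ci(self, term: str, level: float = 0.95) -> tuple[float, float]:
        from scipy import stats as _st

        row = self.table.loc[term]
        if "df_resid" in self.table.columns and np.isfinite(row.get("df_resid", np.nan)):
            q = _st.t.ppf(0.5 + level / 2.0, row["df_resid"])
        else:
            q = _st.norm.ppf(0.5 + level / 2.0)
        return float(row["estimate"] - q * row["se"]), float(row["estimate"] + q * row["se"])


def _listwise(df: pd.DataFrame, cols: list[str]) -> tuple[pd.DataFrame, int]:
    complete = df.dropna(subset=cols)
    dropped = len(df) - len(complete)
    if dropped:
        log.info("dropped %d incomplete rows (listwise deletion)", dropped)
    return complete, dropped


def _check_variation(df: pd.DataFrame, cols: list[str]) -> None:
    for c in cols:
        x = df[c]
        if x.dtype.kind in "fiu" and np.nanstd(x.to_numpy(dtype=float)) == 0:
            raise ValueError(f"column {c!r} is constant; model is not identifiable")


def _ols_fit(df: pd.DataFrame, outcome: str, predictors: list[str], formula: str,
             dropped: int) -> ModelFit:
    X = [np.ones(len(df))]
    names = ["Intercept"]
    for p in predictors:
        if p == "sex":
            X.append((df["sex"].to_numpy() == "F").astype(float))
            names.append("SEX: F")
        else:
            X.append(df[p].to_numpy(dtype=float))
            names.append(p)
    X = np.column_stack(X)
    y = df[outcome].to_numpy(dtype=float)
    if y.std() == 0:
        raise ValueError(f"outcome {outcome!r} has zero variance")
    res = sm.OLS(y, X).fit()
    table = pd.DataFrame(
        {
            "estimate": res.params,
            "se": res.bse,
            "p": res.pvalues,
            "df_resid": res.df_resid,
        },
        index=names,
    )
    return ModelFit(formula=formula, table=table, n_obs=len(df),
                    n_subjects=len(df), dropped=dropped)


def chronicity_regression(records: pd.DataFrame, metric: str = "deep15") -> ModelFit:
    """OLS: chronicity ~ mean FI metric + mean disc degeneration + age + sex + BMI.

    ``records`` needs one row per subject with ``mean_{metric}_fi`` (the
    L4L5/L5S1 average of overall or deep15 FI%) and ``mean_ddd`` (average
    Pfirrmann grade) columns alongside the covariates.
    """
    if metric not in ("overall", "deep15"):
        raise ValueError("metric must be 'overall' or 'deep15'")
    fi_col = f"mean_{metric}_fi"
    cols = ["chronicity_yr", fi_col, "mean_ddd", "age", "sex", "bmi"]
    df, dropped = _listwise(records, cols)
    _check_variation(df, [fi_col, "mean_ddd", "age", "bmi"])
    return _ols_fit(
        df, "chronicity_yr", [fi_col, "mean_ddd", "age", "sex", "bmi"],
        f"chronicity_yr ~ {fi_col} + mean_ddd + age + sex + bmi", dropped,
    )


def activity_regression(records: pd.DataFrame) -> ModelFit:
    """OLS: weekly MET-minutes ~ chronicity + pain severity + age + sex + BMI."""
    cols = ["met_min_wk", "chronicity_yr", "pain_nrs", "age", "sex", "bmi"]
    df, dropped = _listwise(records, cols)
    _check_variation(df, ["chronicity_yr", "pain_nrs", "age", "bmi"])
    return _ols_fit(
        df, "met_min_wk", ["chronicity_yr", "pain_nrs", "age", "sex", "bmi"],
        "met_min_wk ~ chronicity_yr + pain_nrs + age + sex + bmi", dropped,
    )


MIXED_CONTINUOUS = ["chronicity_yr", "ddd", "met_min_wk", "pain_nrs", "age", "bmi"]
MIXED_TERMS = ["Intercept", "cLBP Chronicity", "Disc Degeneration", "Physical Activity",
               "Pain Intensity", "Age", "SEX: F", "BMI", "Level: L5S1"]


def build_long_table(metrics: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Join per-level metrics (subject, level, overall_fi, deep15_fi) to the
    cohort table, two rows per subject, with level-specific disc grade ``ddd``."""
    df = metrics.merge(cohort, left_on="subject", right_on="id", how="inner")
    df["ddd"] = np.where(df["level"] == "L4L5", df["pfirrmann_L4L5"], df["pfirrmann_L5S1"])
    return df


def mixed_fi_model(
    long_table: pd.DataFrame,
    outcome: str = "deep15",
    standardize: bool = True,
) -> ModelFit:
    """Linear mixed model of a per-level FI metric with a subject random intercept.

    Fixed effects: chronicity, level-specific disc degeneration, physical
    activity, pain intensity, age, sex (female indicator), BMI, and lumbar
    level (L5S1 indicator); REML estimation. Continuous predictors are
    z-scored when ``standardize``. Falls back to ML with a log entry if the
    REML fit fails to converge.
    """
    out_col = {"deep15": "deep15_fi", "overall": "overall_fi"}[outcome]
    cols = [out_col, "id", "level"] + MIXED_CONTINUOUS[:2] + ["met_min_wk", "pain_nrs", "age", "sex", "bmi"]
    df, dropped = _listwise(long_table, [c for c in cols if c in long_table.columns])
    df = df.sort_values(["id", "level"]).reset_index(drop=True)

    def col(name):
        x = df[name].to_numpy(dtype=float)
        if standardize:
            sd = x.std(ddof=1)
            return (x - x.mean()) / sd if sd > 0 else x - x.mean()
        return x

    X = np.column_stack(
        [
            np.ones(len(df)),
            col("chronicity_yr"),
            col("ddd"),
            col("met_min_wk"),
            col("pain_nrs"),
            col("age"),
            (df["sex"].to_numpy() == "F").astype(float),
            col("bmi"),
            (df["level"].to_numpy() == "L5S1").astype(float),
        ]
    )
    y = df[out_col].to_numpy(dtype=float)
    groups = df["id"].to_numpy()
    model = sm.MixedLM(y, X, groups=groups)
    import warnings as _w

    with np.errstate(all="ignore"), _w.catch_warnings():
        _w.simplefilter("ignore")
        try:
            res = model.fit(reml=True)
            converged = bool(res.converged)
        except Exception:
            converged = False
            res = None
        if res is None or not converged:
            log.warning("REML fit did not converge; refitting with ML")
            res = model.fit(reml=False)
            converged = bool(res.converged)

    k = len(MIXED_TERMS)
    table = pd.DataFrame(
        {
            "estimate": res.params[:k],
            "se": res.bse[:k],
            "p": res.pvalues[:k],
        },
        index=MIXED_TERMS,
    )
    n_sub = df["id"].nunique()
    return ModelFit(
        formula=f"{out_col} ~ chronicity + ddd + activity + pain + age + sex + bmi + level + (1|id)",
        table=table,
        n_obs=len(df),
        n_subjects=n_sub,
        converged=converged,
        random_intercept_var=float(np.asarray(res.cov_re)[0, 0]),
        dropped=dropped,
    )


def subject_mean_metrics(metrics: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-subject predictors for the chronicity models: mean FI metrics over
    L4L5/L5S1 and mean disc degeneration, joined to the covariates."""
    means = (
        metrics.groupby("subject")[["overall_fi", "deep15_fi"]]
        .mean()
        .rename(columns={"overall_fi": "mean_overall_fi", "deep15_fi": "mean_deep15_fi"})
        .reset_index()
    )
    df = means.merge(cohort, left_on="subject", right_on="id", how="inner")
    df["mean_ddd"] = (df["pfirrmann_L4L5"] + df["pfirrmann_L5S1"]) / 2.0
    return df
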
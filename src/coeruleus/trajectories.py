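"""Per-subject LC degeneration slopes and the longitudinal model families.

Three model classes, in the ``Model().fit() -> Results`` style:

``BaselineSlopeModel``
    Cross-sectional OLS of the per-subject degeneration slope on baseline
    LC_RI, correcting for age, sex and education.
``LCTrajectoryModel``
    Mixed model of longitudinal LC_RI: ``lc_ri ~ age_bl * time + sex + edu``
    with a subject random intercept, optionally extended to
    ``age_bl * time * abeta``.  Time enters in months since baseline MRI.
``CognitionTrajectoryModel``
    Mixed model of longitudinal cognition per domain:
    ``score ~ time * bl_lc * abeta + time * dlc * abeta + age + sex + edu``
    with a subject random intercept — both interaction families sit in one
    fit so the baseline-LC and degeneration-rate terms control for each
    other.

All models report standardized coefficients by default: continuous
predictors and the outcome are z-scored before fitting (binary covariates
are left as 0/1) and interaction columns are products of the standardized
mains.  Mixed-model inference uses per-effect Satterthwaite degrees of
freedom (see :mod:`coeruleus.lmm`).

The per-subject degeneration slope dLC_RI is the OLS slope of LC_RI on
time for that subject, reported in units per year (months slope x 12).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .lmm import RandomInterceptFit, fit_random_intercept
from .synthetic import COGNITION_DOMAINS

__all__ = [
    "ModelResult",
    "fit_subject_slope",
    "subject_slopes",
    "standardize",
    "BaselineSlopeModel",
    "LCTrajectoryModel",
    "CognitionTrajectoryModel",
    "build_subject_table",
]

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# results container
# --------------------------------------------------------------------------


@dataclass
class ModelResult:
    """Fitted-model summary: standardized betas, CIs, t, df, p per term."""

    table: pd.DataFrame  # term, beta, se, ci_low, ci_high, t, df, p
    n_obs: int
    n_subjects: int
    converged: bool = True
    df_method: str = "residual"
    standardized: bool = True
    model_name: str = ""

    def __post_init__(self) -> None:
        required = {"term", "beta", "se", "ci_low", "ci_high", "t", "df", "p"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"result table misses columns {sorted(missing)}")

    def term(self, name: str) -> pd.Series:
        match = self.table[self.table["term"] == name]
        if match.empty:
            raise KeyError(
                f"term {name!r} not in model (have {list(self.table['term'])})"
            )
        return match.iloc[0]

    def beta(self, name: str) -> float:
        return float(self.term(name)["beta"])

    def pvalue(self, name: str) -> float:
        return float(self.term(name)["p"])

    def summary(self) -> str:
        head = (
            f"{self.model_name or 'model'}  "
            f"(n_obs={self.n_obs}, n_subjects={self.n_subjects}, "
            f"{'standardized' if self.standardized else 'raw'} scale, "
            f"df: {self.df_method}"
            f"{'' if self.converged else ', NOT CONVERGED'})"
        )
        body = self.table.to_string(
            index=False,
            float_format=lambda v: f"{v: .4f}",
        )
        return head + "\n" + body

    def to_dict(self) -> dict:
        return {
            "model_name": self.model_name,
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
            "converged": self.converged,
            "df_method": self.df_method,
            "standardized": self.standardized,
            "terms": self.table.to_dict(orient="records"),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# --------------------------------------------------------------------------
# subject-level slopes
# --------------------------------------------------------------------------


def fit_subject_slope(sessions) -> float:
    """OLS slope of LC_RI on time for one subject, in units per year.

    ``sessions`` is an iterable of ``(months, lc_ri)`` pairs (or a DataFrame
    with ``months`` and ``lc_ri`` columns).  Needs >= 2 distinct time points.
    """
    if isinstance(sessions, pd.DataFrame):
        months = sessions["months"].to_numpy(float)
        values = sessions["lc_ri"].to_numpy(float)
    else:
        arr = np.asarray(list(sessions), dtype=float)
        months, values = arr[:, 0], arr[:, 1]
    if len(np.unique(months)) < 2:
        raise ValueError("need >= 2 sessions with distinct times")
    slope_per_month = np.polyfit(months, values, 1)[0]
    return float(slope_per_month * 12.0)


def subject_slopes(sessions: pd.DataFrame) -> pd.DataFrame:
    """Per-subject dLC_RI (units/year) and baseline LC_RI from a session table.

    Subjects with fewer than two distinct time points are excluded, with the
    reason logged (mirroring session-level QC exclusions).  Baseline LC_RI is
    the measurement at the earliest session.
    """
    rows = []
    for sid, grp in sessions.groupby("subject_id", sort=False):
        try:
            slope = fit_subject_slope(grp)
        except ValueError as err:
            logger.warning("excluding subject %s: %s", sid, err)
            continue
        bl = grp.sort_values("months")["lc_ri"].iloc[0]
        rows.append({"subject_id": sid, "bl_lc_ri": float(bl), "dlc_ri": slope})
    return pd.DataFrame(rows)


def build_subject_table(
    sessions: pd.DataFrame, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Merge estimated slopes/baselines with subject covariates."""
    slopes = subject_slopes(sessions)
    keep = [
        c
        for c in ("subject_id", "age_bl", "sex", "education", "abeta")
        if c in covariates.columns
    ]
    return slopes.merge(covariates[keep].drop_duplicates("subject_id"), on="subject_id")


# --------------------------------------------------------------------------
# standardization
# --------------------------------------------------------------------------


def _is_binary(x: pd.Series) -> bool:
    vals = set(pd.unique(x.dropna()))
    return vals <= {0, 1, 0.0, 1.0, False, True}


def standardize(
    data: pd.DataFrame, columns, skip_binary: bool = True
) -> pd.DataFrame:
    """Z-score the given columns; binary 0/1 columns are left as-is.

    Interactions must be formed *after* this step so products are products
    of standardized mains.  A zero-variance continuous column is an error.
    """
    out = data.copy()
    for col in columns:
        x = out[col].astype(float)
        if skip_binary and _is_binary(x):
            continue
        sd = x.std(ddof=1)
        if not sd > 0:
            raise ValueError(f"column {col!r} has zero variance; cannot standardize")
        out[col] = (x - x.mean()) / sd
    return out


# --------------------------------------------------------------------------
# models
# --------------------------------------------------------------------------


def _ols_result(
    formula: str, data: pd.DataFrame, model_name: str, standardized: bool
) -> ModelResult:
    fit = sm.OLS.from_formula(formula, data).fit()
    df = float(fit.df_resid)
    tcrit = sps.t.ppf(0.975, df)
    table = pd.DataFrame(
        {
            "term": fit.params.index,
            "beta": fit.params.to_numpy(),
            "se": fit.bse.to_numpy(),
            "ci_low": fit.params.to_numpy() - tcrit * fit.bse.to_numpy(),
            "ci_high": fit.params.to_numpy() + tcrit * fit.bse.to_numpy(),
            "t": fit.tvalues.to_numpy(),
            "df": df,
            "p": fit.pvalues.to_numpy(),
        }
    )
    return ModelResult(
        table=table,
        n_obs=int(fit.nobs),
        n_subjects=int(fit.nobs),
        converged=True,
        df_method="residual",
        standardized=standardized,
        model_name=model_name,
    )


def _mixed_result(
    fit: RandomInterceptFit, model_name: str, standardized: bool
) -> ModelResult:
    tcrit = sps.t.ppf(0.975, fit.df)
    table = pd.DataFrame(
        {
            "term": fit.terms,
            "beta": fit.beta,
            "se": fit.se,
            "ci_low": fit.beta - tcrit * fit.se,
            "ci_high": fit.beta + tcrit * fit.se,
            "t": fit.t,
            "df": fit.df,
            "p": fit.p,
        }
    )
    return ModelResult(
        table=table,
        n_obs=fit.n_obs,
        n_subjects=fit.n_groups,
        converged=fit.converged,
        df_method=fit.df_method,
        standardized=standardized,
        model_name=model_name,
    )


class BaselineSlopeModel:
    """Linear regression of dLC_RI on baseline LC_RI + age, sex, education.

    ``subject_table`` needs columns ``dlc_ri``, ``bl_lc_ri``, ``age_bl``,
    ``sex``, ``education`` (one row per subject).
    """

    def __init__(self, subject_table: pd.DataFrame, min_subjects: int = 10):
        if len(subject_table) < min_subjects:
            raise ValueError(
                f"need >= {min_subjects} subjects, got {len(subject_table)}"
            )
        self.data = subject_table.reset_index(drop=True)

    def fit(self, standardize_scale: bool = True) -> ModelResult:
        data = self.data
        cols = ["dlc_ri", "bl_lc_ri", "age_bl", "sex", "education"]
        if standardize_scale:
            data = standardize(data, cols)
        try:
            return _ols_result(
                "dlc_ri ~ bl_lc_ri + age_bl + sex + education",
                data,
                "baseline_slope_association",
                standardize_scale,
            )
        except np.linalg.LinAlgError as err:  # rank deficiency
            raise ValueError(f"design is rank deficient: {err}") from err


class LCTrajectoryModel:
    """Mixed model of longitudinal LC_RI with a subject random intercept.

    ``sessions`` needs columns ``subject_id``, ``months``, ``lc_ri``,
    ``age_bl``, ``sex``, ``education`` and, when ``include_abeta=True``,
    ``abeta``.  Formula: ``lc_ri ~ age_bl * time + sex + edu`` (time in
    months), extended to ``age_bl * time * abeta`` with the flag; main
    effects of interaction terms are included implicitly.
    """

    def __init__(self, sessions: pd.DataFrame, include_abeta: bool = False):
        per_subj = sessions.groupby("subject_id")["months"].nunique()
        if (per_subj < 2).any():
            bad = list(per_subj[per_subj < 2].index)
            raise ValueError(f"subjects with < 2 sessions: {bad}")
        self.include_abeta = include_abeta
        self.data = sessions.rename(columns={"months": "time"}).reset_index(drop=True)

    @property
    def formula(self) -> str:
        if self.include_abeta:
            return "lc_ri ~ age_bl * time * abeta + sex + education"
        return "lc_ri ~ age_bl * time + sex + education"

    def fit(self, standardize_scale: bool = True) -> ModelResult:
        data = self.data
        cols = ["lc_ri", "age_bl", "time", "education"] + (
            ["abeta"] if self.include_abeta else []
        )
        if standardize_scale:
            data = standardize(data, cols)
        fit = fit_random_intercept(self.formula, data, "subject_id")
        return _mixed_result(
            fit,
            "lc_trajectory" + ("_abeta" if self.include_abeta else ""),
            standardize_scale,
        )

    def plot_spaghetti(self, ax=None):
        """Per-subject LC_RI trajectories with the group trend."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        for _, grp in self.data.groupby("subject_id"):
            ax.plot(grp["time"], grp["lc_ri"], color="0.7", lw=0.6, alpha=0.6)
        coef = np.polyfit(self.data["time"], self.data["lc_ri"], 1)
        tt = np.linspace(self.data["time"].min(), self.data["time"].max(), 20)
        ax.plot(tt, np.polyval(coef, tt), color="crimson", lw=2)
        ax.set_xlabel("months since baseline MRI")
        ax.set_ylabel("LC_RI")
        return ax


class CognitionTrajectoryModel:
    """Mixed model of one cognition domain's longitudinal trajectory.

    ``cognition`` is the long table (``subject_id``, ``months``, ``domain``,
    ``score``); ``subjects`` carries one row per subject with ``bl_lc_ri``,
    ``dlc_ri``, ``abeta``, ``age_bl``, ``sex``, ``education``.  Both
    three-way interaction families (time x bl_lc x abeta and
    time x dlc x abeta) enter a single fit.
    """

    def __init__(self, cognition: pd.DataFrame, subjects: pd.DataFrame, domain: str):
        if domain not in COGNITION_DOMAINS:
            raise ValueError(
                f"unknown domain {domain!r}; choose from {COGNITION_DOMAINS}"
            )
        sub = cognition[cognition["domain"] == domain]
        if sub.empty:
            raise ValueError(f"no rows for domain {domain!r}")
        per_subj = sub.groupby("subject_id")["months"].nunique()
        if (per_subj < 2).any():
            bad = list(per_subj[per_subj < 2].index)
            raise ValueError(f"subjects with < 2 visits: {bad}")
        merged = sub.merge(
            subjects[
                ["subject_id", "bl_lc_ri", "dlc_ri", "abeta", "age_bl", "sex", "education"]
            ],
            on="subject_id",
        )
        self.domain = domain
        self.data = merged.rename(
            columns={"months": "time", "bl_lc_ri": "bl_lc", "dlc_ri": "dlc"}
        ).reset_index(drop=True)

    formula = "score ~ time * bl_lc * abeta + time * dlc * abeta + age_bl + sex + education"

    def fit(self, standardize_scale: bool = True) -> ModelResult:
        data = self.data
        if standardize_scale:
            data = standardize(
                data, ["score", "time", "bl_lc", "dlc", "abeta", "age_bl", "education"]
            )
        fit = fit_random_intercept(self.formula, data, "subject_id")
        return _mixed_result(fit, f"cognition_{self.domain}", standardize_scale)
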
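"""Residualized-change moderation analysis of cognitive change.

Follow-up cognition is regressed on its baseline value (residualized
change), group assignment, a baseline network index (modularity or
flexibility) and the group x index interaction:

    followup ~ baseline + group + index + group:index [+ covariates]

A significant interaction is probed with simple effects: estimated
marginal means (EMMs) per group at low (-1 SD), average, and high
(+1 SD) values of the moderator, with the baseline score (and any
covariates) held at sample means.  The group contrast at moderator
value m is exactly ``beta_group + beta_interaction * m``; its standard
error comes from the coefficient covariance.  Effect size d is the
contrast divided by the fit's root-mean-square error.

Estimation is ordinary least squares through statsmodels with classical
standard errors and two-sided t p-values; complete cases only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.stats.outliers_influence import variance_inflation_factor

__all__ = [
    "ModerationFit",
    "SimpleEffects",
    "fit_moderation",
    "simple_effects",
    "diagnostics",
    "vif_table",
    "write_fit",
]


@dataclass
class ModerationFit:
    """OLS fit of the residualized-change interaction model."""

    terms: list
    params: np.ndarray
    bse: np.ndarray
    conf_int: np.ndarray  # (n_terms, 2), 95%
    pvalues: np.ndarray
    r2: float
    r2_adj: float
    df_resid: int
    n: int
    cov_params: np.ndarray
    mse_resid: float
    index_name: str
    covariates: list
    _results: object = None  # statsmodels RegressionResults
    _exog: np.ndarray = None
    _endog: np.ndarray = None

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.params,
                "se": self.bse,
                "ci_low": self.conf_int[:, 0],
                "ci_high": self.conf_int[:, 1],
                "p": self.pvalues,
            }
        )

    def coef(self, term: str) -> float:
        return float(self.params[self.terms.index(term)])


@dataclass
class SimpleEffects:
    """Group contrasts (music - control) at -1 SD / mean / +1 SD moderator."""

    table: pd.DataFrame  # level, moderator, emm_control, emm_music, contrast, se, t, df, p, d
    moderator_mean: float
    moderator_sd: float


def _design(
    table: pd.DataFrame, index_name: str, covariates: list | None
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, list]:
    covariates = list(covariates or [])
    cols = ["mmse_followup", "mmse_baseline", "group", index_name] + covariates
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table lacks columns: {missing}")
    data = table[cols].dropna().reset_index(drop=True)
    groups = set(data["group"].unique())
    if not groups <= {0, 1}:
        raise ValueError(f"group must be coded 0 (control) / 1 (music), found {sorted(groups)}")
    terms = (
        ["intercept", "mmse_baseline", "group", index_name, f"group:{index_name}"]
        + covariates
    )
    x = np.column_stack(
        [
            np.ones(len(data)),
            data["mmse_baseline"].to_numpy(float),
            data["group"].to_numpy(float),
            data[index_name].to_numpy(float),
            data["group"].to_numpy(float) * data[index_name].to_numpy(float),
        ]
        + [data[c].to_numpy(float) for c in covariates]
    )
    y = data["mmse_followup"].to_numpy(float)
    return data, x, y, terms


def _check_rank(x: np.ndarray, terms: list) -> None:
    if np.linalg.matrix_rank(x) == x.shape[1]:
        return
    # name an offending column: first column linearly dependent on its
    # predecessors
    for j in range(1, x.shape[1]):
        sub = x[:, : j + 1]
        if np.linalg.matrix_rank(sub) < sub.shape[1]:
            raise ValueError(
                f"design matrix is rank deficient: column {terms[j]!r} is "
                "collinear with earlier columns (constant or duplicated predictor?)"
            )
    raise ValueError("design matrix is rank deficient")


def fit_moderation(
    table: pd.DataFrame,
    index_name: str = "flexibility",
    covariates: list | None = None,
) -> ModerationFit:
    """Fit followup ~ baseline + group + index + group:index [+ covariates].

    Complete cases only; requires at least #parameters + 1 rows and a
    full-rank design (a constant index, for instance, is rejected with
    the offending column named).
    """
    data, x, y, terms = _design(table, index_name, covariates)
    if len(data) < x.shape[1] + 1:
        raise ValueError(
            f"need at least {x.shape[1] + 1} complete cases, found {len(data)}"
        )
    _check_rank(x, terms)
    res = sm.OLS(y, x).fit()
    return ModerationFit(
        terms=terms,
        params=np.asarray(res.params),
        bse=np.asarray(res.bse),
        conf_int=np.asarray(res.conf_int(alpha=0.05)),
        pvalues=np.asarray(res.pvalues),
        r2=float(res.rsquared),
        r2_adj=float(res.rsquared_adj),
        df_resid=int(res.df_resid),
        n=len(data),
        cov_params=np.asarray(res.cov_params()),
        mse_resid=float(res.mse_resid),
        index_name=index_name,
        covariates=list(covariates or []),
        _results=res,
        _exog=x,
        _endog=y,
    )


def simple_effects(fit: ModerationFit, table: pd.DataFrame) -> SimpleEffects:
    """EMM group contrasts at moderator mean -1 SD, mean, and mean +1 SD.

    Baseline score and covariates are held at their sample means
    (complete cases of the fitted model).  p-values are unadjusted
    two-sided t tests on the fit's residual df; d = contrast / RMSE.
    """
    cols = ["mmse_baseline", "group", fit.index_name] + fit.covariates
    data = table[["mmse_followup"] + cols].dropna()
    mod = data[fit.index_name].to_numpy(float)
    m_mean, m_sd = float(mod.mean()), float(mod.std(ddof=1))
    base_mean = float(data["mmse_baseline"].mean())
    cov_means = [float(data[c].mean()) for c in fit.covariates]
    rmse = float(np.sqrt(fit.mse_resid))
    rows = []
    for level, m in (
        ("-1 SD", m_mean - m_sd),
        ("mean", m_mean),
        ("+1 SD", m_mean + m_sd),
    ):
        emms = {}
        for g in (0, 1):
            xrow = np.array([1.0, base_mean, g, m, g * m] + cov_means)
            emms[g] = float(xrow @ fit.params)
        c = np.array([0.0, 0.0, 1.0, 0.0, m] + [0.0] * len(fit.covariates))
        contrast = float(c @ fit.params)
        se = float(np.sqrt(c @ fit.cov_params @ c))
        t = contrast / se
        p = 2.0 * stats.t.sf(abs(t), fit.df_resid)
        rows.append(
            {
                "level": level,
                "moderator": m,
                "emm_control": emms[0],
                "emm_music": emms[1],
                "contrast": contrast,
                "se": se,
                "t": t,
                "df": fit.df_resid,
                "p": p,
                "d": contrast / rmse,
            }
        )
    return SimpleEffects(
        table=pd.DataFrame(rows), moderator_mean=m_mean, moderator_sd=m_sd
    )


def vif_table(exog: np.ndarray, terms: list) -> pd.DataFrame:
    """Variance inflation factor per non-intercept predictor.

    Perfectly collinear predictors yield infinite VIF; such designs are
    rejected by :func:`fit_moderation`, but this helper accepts them so
    a pre-fit screen can flag the offending columns.
    """
    exog = np.asarray(exog, dtype=float)
    rows = []
    for j in range(1, exog.shape[1]):
        with np.errstate(divide="ignore"):
            v = variance_inflation_factor(exog, j)
        rows.append({"term": terms[j], "vif": float(v)})
    return pd.DataFrame(rows)


def diagnostics(fit: ModerationFit) -> dict:
    """Regression assumption checks on the fitted model.

    Returns residual-vs-fitted summary (correlation of |residual| with
    fitted values), Shapiro-Wilk normality test on residuals,
    Breusch-Pagan heteroscedasticity test, and per-predictor VIFs.
    """
    res = fit._results
    resid = np.asarray(res.resid)
    fitted = np.asarray(res.fittedvalues)
    sw_stat, sw_p = stats.shapiro(resid)
    bp_lm, bp_p, _, _ = het_breuschpagan(resid, fit._exog)
    vifs = vif_table(fit._exog, fit.terms)
    return {
        "resid_fitted_corr": float(np.corrcoef(fitted, np.abs(resid))[0, 1]),
        "shapiro_w": float(sw_stat),
        "shapiro_p": float(sw_p),
        "breusch_pagan_lm": float(bp_lm),
        "breusch_pagan_p": float(bp_p),
        "heteroscedastic_flag": bool(bp_p < 0.05),
        "vif": vifs,
        "max_vif": float(vifs["vif"].max()),
    }


def write_fit(
    fit: ModerationFit,
    effects: SimpleEffects,
    out_dir: str | Path,
    prefix: str = "moderation",
) -> None:
    """Coefficient CSV, simple-effects CSV and a plain-text model report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fit.coef_table().to_csv(out / f"{prefix}_coefficients.csv", index=False)
    effects.table.to_csv(out / f"{prefix}_simple_effects.csv", index=False)
    with open(out / f"{prefix}_report.txt", "w") as fh:
        fh.write(
            f"Residualized change model: mmse_followup ~ mmse_baseline + group "
            f"+ {fit.index_name} + group:{fit.index_name}"
        )
        if fit.covariates:
            fh.write(" + " + " + ".join(fit.covariates))
        fh.write(
            f"\nn = {fit.n}, residual df = {fit.df_resid}, "
            f"R2 = {fit.r2:.3f}, adj R2 = {fit.r2_adj:.3f}\n\n"
        )
        fh.write(fit.coef_table().to_string(index=False))
        fh.write("\n\nSimple effects (music - control) at moderator levels:\n")
        fh.write(effects.table.to_string(index=False))
        fh.write("\n")
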
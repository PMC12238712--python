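"""Sex-stratified association of high FA with latent covariate dimensions.

High FA (the dichotomized composite) is regressed on the FAMD dimension
scores by maximum-likelihood logistic regression, fitted separately per
sex because the hypothesis of interest is sex-specific buffering.  Model
adequacy is reported through the residual-deviance lack-of-fit p-value
(upper-tail chi-square of the residual deviance at its degrees of
freedom).  The module also carries the small descriptive tests used
around the regression: a 2x2 Pearson chi-square of high-FA counts by sex
(no continuity correction), one-way ANOVA, and the Welch unequal-variance
t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class LogisticFit:
    """One fitted logistic regression: estimates, Wald tests, deviances."""

    params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    null_deviance: float
    null_df: int
    residual_deviance: float
    residual_df: int
    lack_of_fit_p: float
    n: int
    converged: bool
    separation_warning: bool
    label: str = ""

    def summary(self) -> str:
        lines = [f"Logistic regression {('[' + self.label + ']') if self.label else ''} (n = {self.n})"]
        lines.append(f"{'term':<14}{'coef':>10}{'SE':>10}{'z':>9}{'P>|z|':>9}")
        for term in self.params.index:
            lines.append(
                f"{term:<14}{self.params[term]:>10.3f}{self.bse[term]:>10.3f}"
                f"{self.zvalues[term]:>9.2f}{self.pvalues[term]:>9.3f}"
            )
        lines.append(
            f"null deviance {self.null_deviance:.2f} on {self.null_df} df; "
            f"residual deviance {self.residual_deviance:.2f} on {self.residual_df} df"
        )
        lines.append(f"lack-of-fit P = {self.lack_of_fit_p:.2f}")
        if self.separation_warning:
            lines.append("warning: possible (quasi-)separation; coefficients may diverge")
        return "\n".join(lines)


def lack_of_fit(residual_deviance: float, residual_df: int) -> float:
    """Upper-tail chi-square probability of the residual deviance."""
    if residual_df <= 0:
        return float("nan")
    return float(stats.chi2.sf(residual_deviance, residual_df))


def fit_logistic(y: np.ndarray, X: pd.DataFrame, label: str = "") -> LogisticFit:
    """Maximum-likelihood logistic fit of a binary outcome via IRLS.

    An intercept is added.  Requires both outcome classes; perfect or
    quasi-perfect separation is detected and flagged rather than fatal.
    """
    y = np.asarray(y, float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class; logistic fit undefined")
    exog = sm.add_constant(pd.DataFrame(X).astype(float), has_constant="add")
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.GLM(y, exog, family=sm.families.Binomial())
        res = model.fit(maxiter=200, tol=1e-10)
        for w in caught:
            if "separat" in str(w.message).lower():
                separation = True
    if res.params.to_numpy()[1:].size and np.abs(res.params.to_numpy()[1:]).max() > 25:
        separation = True
    resid_df = int(res.df_resid)
    return LogisticFit(
        params=res.params,
        bse=res.bse,
        zvalues=res.tvalues,
        pvalues=res.pvalues,
        null_deviance=float(res.null_deviance),
        null_df=int(res.nobs - 1),
        residual_deviance=float(res.deviance),
        residual_df=resid_df,
        lack_of_fit_p=lack_of_fit(float(res.deviance), resid_df),
        n=int(res.nobs),
        converged=bool(res.converged),
        separation_warning=separation,
        label=label,
    )


def sex_stratified_run(
    fa: "pd.DataFrame | object",
    dims: pd.DataFrame,
    min_ratio: int = 10,
) -> dict[str, LogisticFit]:
    """Fit the high-FA logistic regression separately for each sex.

    Parameters
    ----------
    fa
        An :class:`~odontofa.fa.FAIndexResult` or its table: indexed by
        individual, with ``sex``, ``high_fa`` and ``included`` columns.
    dims
        Individual FAMD coordinates (index aligned on individual id).
    min_ratio
        Events-per-parameter heuristic; a sex with fewer than
        ``min_ratio`` x parameters rows draws a warning.
    """
    table = fa.table if hasattr(fa, "table") else fa
    inc = table[table["included"]] if "included" in table.columns else table
    merged = inc.join(dims, how="inner")
    if merged.empty:
        raise ValueError("no overlap between FA results and dimension scores")
    fits: dict[str, LogisticFit] = {}
    p_params = dims.shape[1] + 1
    for sex in sorted(merged["sex"].unique()):
        sub = merged[merged["sex"] == sex]
        if len(sub) < min_ratio * p_params:
            warnings.warn(f"sex {sex}: only {len(sub)} rows for {p_params} parameters")
        fits[str(sex)] = fit_logistic(
            sub["high_fa"].to_numpy(), sub[dims.columns], label=str(sex)
        )
    return fits


def regression_table(fits: dict[str, LogisticFit]) -> pd.DataFrame:
    """Combined per-sex coefficient table (term x sex: coef, SE, P)."""
    rows = []
    for sex, fit in fits.items():
        for term in fit.params.index:
            rows.append(
                {
                    "sex": sex,
                    "term": term,
                    "coef": fit.params[term],
                    "se": fit.bse[term],
                    "p": fit.pvalues[term],
                }
            )
        rows.append(
            {"sex": sex, "term": "lack_of_fit_p", "coef": fit.lack_of_fit_p, "se": np.nan, "p": np.nan}
        )
    return pd.DataFrame(rows)


def high_fa_sex_chisq(counts: np.ndarray) -> dict[str, float]:
    """Pearson chi-square (no continuity correction) on a 2x2 high-FA-by-sex table.

    The uncorrected statistic is the convention used for this
    comparison; with Yates' correction the same counts give a different
    value.
    """
    counts = np.asarray(counts, float)
    if counts.shape != (2, 2):
        raise ValueError("expects a 2x2 table")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    chi2, p, df, expected = stats.chi2_contingency(counts, correction=False)
    if (expected <= 0).any():
        raise ValueError("expected cell count <= 0")
    return {"X2": float(chi2), "df": int(df), "p": float(p)}


def group_anova(values: np.ndarray, groups: np.ndarray) -> dict[str, float]:
    """One-way fixed-effects ANOVA of values across group labels."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in pd.unique(groups)]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("ANOVA needs >= 2 groups with n >= 2 each")
    f, p = stats.f_oneway(*samples)
    df1 = len(samples) - 1
    df2 = values.size - len(samples)
    return {"F": float(f), "df1": df1, "df2": df2, "p": float(p)}


def welch_t(values: np.ndarray, groups: np.ndarray) -> dict[str, float]:
    """Welch unequal-variance t-test with Welch-Satterthwaite df."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError("Welch t-test needs exactly 2 groups")
    a, b = (values[groups == g] for g in labels)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return {"t": 0.0, "df": float("nan"), "p": 1.0, "degenerate": 1.0}
        return {"t": float("inf"), "df": float("nan"), "p": 0.0, "degenerate": 1.0}
    res = stats.ttest_ind(a, b, equal_var=False)
    return {"t": float(res.statistic), "df": float(res.df), "p": float(res.pvalue)}
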
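"""Mixed-effects association of state expression with age and clinical group.

Per state, a linear mixed model regresses a state-expression response
(occupancy or bout count) on fixed effects (corrected age, birth status,
GM classification, Bayley-III composites) with a participant-level random
intercept for repeated videos, fit by REML.  Singular fits (zero
random-effect variance) fall back to ordinary least squares with
cluster-robust standard errors.  Significance uses Bonferroni control
over the K states (alpha / K).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

AGE_CENTRE = 15.0  # weeks; centring age keeps the intercept interpretable

_TERM_COLUMNS = {
    "age": "age_c",
    "birth": "preterm",
    "gma": "gm_abnormal",
    "bayley_motor": "bayley_motor",
    "bayley_cognitive": "bayley_cognitive",
    "bayley_language": "bayley_language",
}


def prepare_analysis_table(
    summaries: pd.DataFrame, cohort: pd.DataFrame
) -> pd.DataFrame:
    """Join per-video summaries with cohort covariates and derive regressors.

    Adds centred age (``age_c``), a preterm indicator and an abnormal-GM
    indicator.  Where a participant has two videos, the GM classification
    of the later video (by corrected age) is used for both, mirroring
    outcome assessment at the later timepoint.
    """
    df = summaries.merge(cohort, on="video_id", how="inner")
    if df.empty:
        raise ValueError("joined summary/cohort table is empty")
    df = df.copy()
    df["age_c"] = df["corrected_age"] - AGE_CENTRE
    df["preterm"] = (df["birth_status"] == "preterm").astype(float)

    later = (
        df.dropna(subset=["gm_class"])
        .sort_values("corrected_age")
        .groupby("participant_id")["gm_class"]
        .last()
    )
    df["gm_later"] = df["participant_id"].map(later)
    df["gm_abnormal"] = (df["gm_later"] == "abnormal_or_absent").astype(float)
    df.loc[df["gm_later"].isna(), "gm_abnormal"] = np.nan
    return df


def fit_state_lme(
    summaries: pd.DataFrame,
    cohort: pd.DataFrame,
    response: str = "occupancy",
    fixed_terms: tuple[str, ...] = ("age",),
    K: int | None = None,
) -> pd.DataFrame:
    """Fit one mixed model per state and return a tidy result table.

    ``response`` is 'occupancy' or 'bout_count'; ``fixed_terms`` draw from
    age, birth, gma and the Bayley domains.  Columns of the result: state,
    response, term, beta, se, p, method ('lme' or 'ols_cluster').
    """
    df = prepare_analysis_table(summaries, cohort)
    cols = []
    for t in fixed_terms:
        if t not in _TERM_COLUMNS:
            raise ValueError(f"unknown fixed term {t!r}")
        cols.append(_TERM_COLUMNS[t])
    if K is None:
        K = sum(1 for c in df.columns if c.startswith(f"{response}_"))
    if K < 1:
        raise ValueError(f"no {response}_k columns found")

    rows = []
    for k in range(K):
        ycol = f"{response}_{k}"
        sub = df[["participant_id", ycol, *cols]].dropna()
        formula = f"{ycol} ~ " + " + ".join(cols)
        method = "lme"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", UserWarning)
            try:
                res = smf.mixedlm(
                    formula, sub, groups=sub["participant_id"]
                ).fit(reml=True)
                singular = (
                    not np.all(np.isfinite(res.bse_fe))
                    or float(np.asarray(res.cov_re).ravel()[0]) < 1e-8
                )
            except (np.linalg.LinAlgError, ValueError):
                singular = True
                res = None
        if singular:
            method = "ols_cluster"
            res = smf.ols(formula, sub).fit(
                cov_type="cluster", cov_kwds={"groups": sub["participant_id"]}
            )
        for term, col in zip(fixed_terms, cols):
            rows.append(
                {
                    "state": k,
                    "response": response,
                    "term": term,
                    "beta": float(res.params[col]),
                    "se": float(res.bse[col]),
                    "p": float(res.pvalues[col]),
                    "method": method,
                }
            )
    return pd.DataFrame(rows)


def bonferroni(
    results: pd.DataFrame, alpha: float = 0.05, K: int = 8
) -> pd.DataFrame:
    """Flag results significant at the Bonferroni-corrected level alpha/K."""
    if K < 1:
        raise ValueError("K must be >= 1")
    out = results.copy()
    out["bonferroni_significant"] = out["p"] < alpha / K
    return out
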
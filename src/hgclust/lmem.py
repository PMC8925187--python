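"""Longitudinal mixed-effects analysis of yearly hair mercury.

The estimand is the difference in hair Hg, over the whole sampling period,
between participants scoring above vs below the median of a symptom-cluster
composite.  Hair Hg is modelled on the log10 scale (it is right-skewed):

    log10(hair Hg)_it = b0 + b_g * group_i + b_a * age_it + b_s * sex_i
                        + b_y * year_t + u_i + e_it

with a participant random intercept u_i by default.  Only participants with at
least ``min_measurements`` yearly values enter (default 10).  The group contrast
is also back-transformed to the ug/g scale as a marginal contrast, with a
participant-bootstrap confidence interval.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class LmemFit:
    fixed_effects: pd.DataFrame      # term, estimate, ci_low, ci_high, p
    random_variances: dict[str, float]
    aic: float
    bic: float
    loglike: float
    group_diff_log10: float
    group_diff_ci: tuple[float, float]
    group_p: float
    group_diff_ugg: float            # back-transformed marginal contrast
    group_diff_ugg_ci: tuple[float, float] | None
    n_participants: int
    n_observations: int
    converged: bool
    result: object = field(repr=False, default=None)
    lr_vs_ols: dict | None = None


def median_split(scores: pd.Series) -> pd.Series:
    """Label participants above (>) the median as 'above', ties and below as 'below'."""
    scores = scores.dropna()
    if len(scores) < 2:
        raise ValueError("need at least 2 participants")
    if scores.nunique() == 1:
        raise ValueError("all scores equal: median split undefined")
    med = scores.median()
    return pd.Series(np.where(scores > med, "above", "below"), index=scores.index)


def build_long(series: dict[str, dict[int, float]], scores: pd.Series,
               covariates: pd.DataFrame, min_measurements: int = 10
               ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Long-format dataset of persons with >= min_measurements yearly values.

    ``covariates`` is indexed by participant and must carry birth_year and sex.
    Returns (data, counts) where counts reports inclusion/exclusion bookkeeping.
    """
    groups = median_split(scores)
    rows = []
    counts = {"total": len(series), "included": 0,
              "excluded_few_measurements": 0, "excluded_no_score": 0}
    for person, yearly in series.items():
        if len(yearly) < min_measurements:
            counts["excluded_few_measurements"] += 1
            continue
        if person not in groups.index or person not in covariates.index:
            counts["excluded_no_score"] += 1
            logger.info("participant %s dropped: no composite score", person)
            continue
        cov = covariates.loc[person]
        counts["included"] += 1
        for year, value in sorted(yearly.items()):
            rows.append({
                "participant_id": person, "year": int(year),
                "hair_hg": float(value),
                "log10_hair": float(np.log10(value)),
                "age_at_sampling": int(year) - int(cov["birth_year"]),
                "sex": cov["sex"],
                "group": groups.loc[person],
            })
    data = pd.DataFrame(rows)
    return data, counts


def fit_lmem(data: pd.DataFrame, random_structure: str = "participant",
             n_boot: int = 200, seed: int = 0,
             min_participants_warn: int = 29) -> LmemFit:
    """REML fit of log10 hair Hg on score group, age, sex and sampling year.

    ``random_structure``: 'participant' (random intercept per person, default)
    or 'year_nested_age' (random intercepts per sampling year with an
    age-at-sampling variance component within year).  A likelihood-ratio test
    against the no-random-effect OLS model and AIC/BIC are reported for model
    selection.  The back-transformed ug/g contrast gets a participant-level
    bootstrap CI (n_boot resamples; 0 disables).
    """
    n_part = data["participant_id"].nunique()
    if n_part < min_participants_warn:
        logger.warning("only %d participants; below the longitudinal "
                       "power-analysis minimum of %d", n_part, min_participants_warn)
    df = data.copy()
    df["group_above"] = (df["group"] == "above").astype(float)
    df["sex_f"] = (df["sex"] == "F").astype(float)
    df["year_c"] = df["year"] - df["year"].mean()
    df["age_c"] = df["age_at_sampling"] - df["age_at_sampling"].mean()
    formula = "log10_hair ~ group_above + age_c + sex_f + year_c"
    if random_structure == "participant":
        model = smf.mixedlm(formula, df, groups=df["participant_id"])
    elif random_structure == "year_nested_age":
        model = smf.mixedlm(formula, df, groups=df["year"].astype(str),
                            re_formula="1", vc_formula={"age": "0 + age_c"})
    else:
        raise ValueError(f"unknown random_structure {random_structure!r}")
    try:
        res = model.fit(reml=True, method="lbfgs", maxiter=200)
    except np.linalg.LinAlgError:
        logger.warning("singular random-effects covariance; refitting with "
                       "a diagonal structure")
        res = model.fit(reml=True, method="powell", maxiter=200)

    params = res.params
    ci = res.conf_int()
    terms = []
    for term in ("Intercept", "group_above", "age_c", "sex_f", "year_c"):
        terms.append({"term": term, "estimate": float(params[term]),
                      "ci_low": float(ci.loc[term, 0]),
                      "ci_high": float(ci.loc[term, 1]),
                      "p": float(res.pvalues[term])})
    fixed = pd.DataFrame(terms)
    gd = float(params["group_above"])
    gd_ci = (float(ci.loc["group_above", 0]), float(ci.loc["group_above", 1]))
    gp = float(res.pvalues["group_above"])

    # marginal ug/g contrast: predict every row under both group labels
    X = df.copy()
    X["group_above"] = 1.0
    above = 10 ** res.predict(exog=X)
    X["group_above"] = 0.0
    below = 10 ** res.predict(exog=X)
    diff_ugg = float(above.mean() - below.mean())

    boot_ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        persons = df["participant_id"].unique()
        by_person = dict(tuple(df.groupby("participant_id")))
        diffs = []
        for _ in range(n_boot):
            pick = rng.choice(persons, size=len(persons), replace=True)
            bdf = pd.concat(
                [by_person[p].assign(participant_id=f"{p}_{i}")
                 for i, p in enumerate(pick)], ignore_index=True)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")   # resamples may be singular
                    bres = smf.mixedlm(formula, bdf, groups=bdf["participant_id"]
                                       ).fit(reml=True, method="lbfgs", maxiter=100)
            except (np.linalg.LinAlgError, ValueError):
                continue
            Xb = bdf.copy()
            Xb["group_above"] = 1.0
            a = 10 ** bres.predict(exog=Xb)
            Xb["group_above"] = 0.0
            b = 10 ** bres.predict(exog=Xb)
            diffs.append(float(a.mean() - b.mean()))
        if len(diffs) >= 20:
            boot_ci = (float(np.percentile(diffs, 2.5)),
                       float(np.percentile(diffs, 97.5)))

    # LR test against plain OLS (no random effect), both by ML
    ols = smf.ols(formula, df).fit()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ml = model.fit(reml=False, method="powell", maxiter=300)
        lr = 2 * (ml.llf - ols.llf)
        # variance component on the boundary: 50:50 mixture of chi2_0 / chi2_1
        lr_test = {"lr": float(lr), "p": float(0.5 * stats.chi2.sf(max(lr, 0.0), 1)),
                   "aic_mixed": float(ml.aic), "aic_ols": float(ols.aic),
                   "bic_mixed": float(ml.bic), "bic_ols": float(ols.bic)}
    except np.linalg.LinAlgError:
        logger.warning("ML refit singular; LR comparison unavailable")
        lr_test = {"lr": np.nan, "p": np.nan, "aic_mixed": np.nan,
                   "aic_ols": float(ols.aic), "bic_mixed": np.nan,
                   "bic_ols": float(ols.bic)}

    rand = {"group_var": float(res.cov_re.iloc[0, 0]) if res.cov_re.size else 0.0,
            "residual_var": float(res.scale)}
    return LmemFit(
        fixed_effects=fixed, random_variances=rand,
        aic=float(res.aic) if res.aic is not None else np.nan,
        bic=float(res.bic) if res.bic is not None else np.nan,
        loglike=float(res.llf),
        group_diff_log10=gd, group_diff_ci=gd_ci, group_p=gp,
        group_diff_ugg=diff_ugg, group_diff_ugg_ci=boot_ci,
        n_participants=n_part, n_observations=len(df),
        converged=bool(res.converged), result=res, lr_vs_ols=lr_test)


def qq_residuals(fit: LmemFit) -> dict:
    """Normal q-q diagnostics of the within-person residuals."""
    resid = np.sort(np.asarray(fit.result.resid))
    n = len(resid)
    if np.allclose(resid, resid[0]):
        raise ValueError("constant residuals: q-q diagnostics undefined")
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    slope, intercept = np.polyfit(theo, resid, 1)
    # standardise so a well-behaved fit has slope ~1
    slope_std = slope / resid.std(ddof=1)
    W, p = stats.shapiro(resid) if n <= 5000 else stats.shapiro(resid[:5000])
    return {"table": pd.DataFrame({"theoretical": theo, "observed": resid}),
            "slope": float(slope), "slope_standardized": float(slope_std),
            "shapiro_W": float(W), "shapiro_p": float(p),
            "flag_nonnormal": bool(p < 0.05)}
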
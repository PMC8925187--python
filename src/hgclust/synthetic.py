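"""Synthetic cohort generator.

Emulates the joint structure the downstream analyses assume: a participant-by-symptom
5-level Likert battery driven by a small number of latent symptom factors, a
piecewise log-linear decline of umbilical-cord blood mercury between anchor years,
sparse yearly hair-mercury series with person-level heterogeneity, a binary
diagnosed nervous-system-disorder mediator, and survey covariates.  Ground-truth
parameters (planted partition, factor scores, effect sizes) travel with the cohort
so every downstream stage can be tested as a parameter-recovery problem.

Ordinal items follow a graded-response-style threshold model: a continuous score
``lambda * factor + noise`` cut at four fixed thresholds, which matches the
polychoric assumptions of the CFA/SEM layer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

SURVEY_YEAR = 2017

#: default piecewise log10-linear anchors for cord blood Hg (ug/L).  The end-point
#: values are the published era means (65.7 ug/L in 1970, 4.48 ug/L in 1992); the
#: interior anchors at the 1976/1987 period breaks reproduce the documented shape
#: (sharp decline to 1976-77, slower decline to 1987, then a plateau).
DEFAULT_CORD_ANCHORS: dict[int, float] = {1970: 65.7, 1976: 12.0, 1987: 5.0, 1992: 4.48}

#: default anchors for the population hair-Hg trend (ug/g); 0.81 ug/g is the
#: plateau value attributed to children after 1990.
DEFAULT_HAIR_ANCHORS: dict[int, float] = {1970: 6.6, 1976: 2.4, 1987: 1.0, 1992: 0.81}

#: background hair Hg before the 1962 discharge (ug/g).
BACKGROUND_HAIR = 0.1


def piecewise_loglinear(year, anchors: dict[int, float]) -> np.ndarray:
    """Evaluate a piecewise log10-linear trend at ``year`` (scalar or array).

    Between consecutive anchor years the log10 value is linearly interpolated;
    outside the anchor range the trend is held flat at the nearest anchor.
    """
    years = np.asarray(sorted(anchors))
    vals = np.log10([anchors[y] for y in years])
    y = np.asarray(year, dtype=float)
    return np.power(10.0, np.interp(y, years, vals))


def hair_trend(year, anchors: dict[int, float] | None = None) -> np.ndarray:
    """Population-level hair Hg trend (ug/g) for any calendar year.

    Background before the 1962 discharge, a log-linear rise 1962->first anchor,
    the anchored decline afterwards, flat after the last anchor.
    """
    anchors = dict(anchors or DEFAULT_HAIR_ANCHORS)
    first = min(anchors)
    y = np.atleast_1d(np.asarray(year, dtype=float))
    out = np.empty_like(y)
    pre = y <= 1961
    rise = (y > 1961) & (y < first)
    post = y >= first
    out[pre] = BACKGROUND_HAIR
    # log-linear ramp from background in 1961 up to the first anchor
    frac = (y[rise] - 1961) / (first - 1961)
    out[rise] = 10 ** (np.log10(BACKGROUND_HAIR)
                       + frac * (np.log10(anchors[first]) - np.log10(BACKGROUND_HAIR)))
    out[post] = piecewise_loglinear(y[post], anchors)
    return out if np.ndim(year) else float(out[0])


@dataclass
class SyntheticParams:
    """Generator configuration; defaults are the study conditions emulated.

    ``cluster_sizes`` plants the informative symptom clusters (default 6 clusters,
    37 symptoms) and ``n_noise_symptoms`` adds unstructured columns (default 22,
    for a 59-item battery).  ``beta_hg`` is the standardized effect of childhood
    exposure on each latent factor; ``beta_mediator`` is the log-odds effect of a
    1-SD increase in log10 childhood Hg on the diagnosed-disorder mediator.
    """

    n_participants: int = 391
    birth_year_range: tuple[int, int] = (1940, 1999)
    cluster_sizes: tuple[int, ...] = (9, 7, 6, 5, 5, 5)
    n_noise_symptoms: int = 22
    loading_range: tuple[float, float] = (0.8, 0.9)
    thresholds: tuple[float, float, float, float] = (-1.2, -0.4, 0.4, 1.2)
    cord_anchors: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_CORD_ANCHORS))
    hair_anchors: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_HAIR_ANCHORS))
    period_breaks: tuple[int, ...] = (1970, 1976, 1987, 1992)
    cord_person_sd: float = 0.45   # log10 ug/L; matches the wide within-year
    # spread of measured cord values (two orders of magnitude across a cohort)
    cord_obs_prob: float = 0.5
    hair_person_sd: float = 0.30   # log10 ug/g
    hair_obs_sd: float = 0.20      # log10 ug/g
    hair_ar1_rho: float = 0.3
    sampling_prob_per_year: float = 0.25
    blood_record_prob: float = 0.15
    blood_to_hair: float = 0.25    # ug/g equivalent hair per ug/L blood
    monitoring_years: tuple[int, int] = (1970, 1997)
    beta_hg: tuple[float, ...] = (0.3, 0.3, 0.3, 0.3, 0.3, 0.3)
    beta_mediator: float = 1.0
    mediator_intercept: float = -1.2
    beta_disorder: float = 0.3     # effect of the mediator on each latent factor
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age_z": 0.25, "sex_female": 0.15})
    fish_effect_log10: float = 0.25
    school_effect_log10: float = -0.15
    missing_rate: float = 0.05
    seed: int = 0

    @property
    def n_symptoms(self) -> int:
        return int(sum(self.cluster_sizes)) + self.n_noise_symptoms

    def validate(self) -> None:
        if any(c < 2 for c in self.cluster_sizes):
            raise ValueError("every cluster must contain at least 2 symptoms")
        if not all(np.diff(self.thresholds) > 0):
            raise ValueError("thresholds must be strictly increasing")
        lo, hi = self.loading_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("loading_range must be within [0, 1]")
        for name in ("cord_person_sd", "hair_person_sd", "hair_obs_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if len(self.beta_hg) != len(self.cluster_sizes):
            raise ValueError("beta_hg must give one effect per cluster")
        if not 0 <= self.sampling_prob_per_year <= 1:
            raise ValueError("sampling_prob_per_year must be in [0, 1]")


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground truth."""

    survey: pd.DataFrame          # participant_id, covariates, sym_### columns
    cord_table: pd.DataFrame      # participant_id, birth_year, cord_hg_ugL
    biomarker_table: pd.DataFrame  # participant_id, year, medium, value
    truth: dict

    @property
    def symptom_columns(self) -> list[str]:
        return [c for c in self.survey.columns if c.startswith("sym_")]


def _symptom_labels(n: int) -> list[str]:
    return [f"sym_{i + 1:03d}" for i in range(n)]


def generate_cohort(params: SyntheticParams) -> SyntheticCohort:
    """Generate a cohort deterministically from ``params.seed``."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_participants
    pid = np.array([f"P{i + 1:04d}" for i in range(n)])

    by_lo, by_hi = params.birth_year_range
    birth_year = rng.integers(by_lo, by_hi + 1, size=n)
    sex = np.where(rng.random(n) < 0.54, "F", "M")
    region = np.where(rng.random(n) < 0.9, "region", "elsewhere")
    age = SURVEY_YEAR - birth_year
    age_category = pd.cut(age, bins=[17, 29, 49, 200],
                          labels=["18-29", "30-49", "50+"]).astype(str)

    # --- true childhood exposure: mean log10 hair Hg over ages 5-15 ------------
    person_u = rng.normal(0.0, params.hair_person_sd, size=n)
    # older cohorts ate fish more often as children
    p_fish = np.clip(0.85 - 0.01 * (birth_year - by_lo), 0.15, 0.9)
    fish_childhood = (rng.random(n) < p_fish).astype(int)
    school_eligible = birth_year <= 1978
    residential_school = (school_eligible & (rng.random(n) < 0.5)).astype(int)
    exposure_shift = (person_u
                      + params.fish_effect_log10 * fish_childhood
                      + params.school_effect_log10 * residential_school)

    ages = np.arange(5, 16)
    child_years = birth_year[:, None] + ages[None, :]
    log10_child = (np.log10(hair_trend(child_years, params.hair_anchors)).mean(axis=1)
                   + exposure_shift)
    z_child = (log10_child - log10_child.mean()) / log10_child.std(ddof=0)

    # --- mediator: diagnosed nervous-system disorder ---------------------------
    logit = params.mediator_intercept + params.beta_mediator * z_child
    nervous_disorder = (rng.random(n) < 1.0 / (1.0 + np.exp(-logit))).astype(int)

    # --- latent symptom factors ------------------------------------------------
    age_sd = age.std(ddof=0)
    age_z = (age - age.mean()) / age_sd if age_sd > 0 else np.zeros(n)
    cov_part = np.zeros(n)
    for name, eff in params.covariate_effects.items():
        if name == "age_z":
            cov_part += eff * age_z
        elif name == "sex_female":
            cov_part += eff * (sex == "F")
        else:
            raise ValueError(f"unknown covariate effect {name!r}")
    K = len(params.cluster_sizes)
    factors = np.empty((n, K))
    disorder_c = nervous_disorder - nervous_disorder.mean()
    for k in range(K):
        systematic = (params.beta_hg[k] * z_child + cov_part
                      + params.beta_disorder * disorder_c)
        resid_var = max(1.0 - np.var(systematic), 0.05)
        factors[:, k] = systematic + rng.normal(0.0, np.sqrt(resid_var), size=n)

    # --- ordinal symptoms ------------------------------------------------------
    labels = _symptom_labels(params.n_symptoms)
    loadings, partition = {}, {}
    cols = {}
    idx = 0
    thr = np.asarray(params.thresholds)
    for k, size in enumerate(params.cluster_sizes):
        for _ in range(size):
            lam = rng.uniform(*params.loading_range)
            cont = lam * factors[:, k] + rng.normal(0.0, np.sqrt(1 - lam ** 2), size=n)
            cols[labels[idx]] = 1 + np.searchsorted(thr, cont).astype(float)
            loadings[labels[idx]] = lam
            partition[labels[idx]] = k
            idx += 1
    for _ in range(params.n_noise_symptoms):
        cont = rng.normal(0.0, 1.0, size=n)
        cols[labels[idx]] = 1 + np.searchsorted(thr, cont).astype(float)
        loadings[labels[idx]] = 0.0
        partition[labels[idx]] = -1   # noise: not part of any planted cluster
        idx += 1
    symptoms = pd.DataFrame(cols, index=pid)
    if params.missing_rate > 0:
        mask = rng.random(symptoms.shape) < params.missing_rate
        symptoms = symptoms.mask(mask)

    # --- umbilical cord Hg -----------------------------------------------------
    in_window = (birth_year >= min(params.cord_anchors)) & \
                (birth_year <= max(params.cord_anchors)) & (region == "region")
    measured = in_window & (rng.random(n) < params.cord_obs_prob)
    log10_cord = (np.log10(piecewise_loglinear(birth_year, params.cord_anchors))
                  + rng.normal(0.0, params.cord_person_sd, size=n))
    cord_val = np.where(measured, 10 ** log10_cord, np.nan)
    cord_table = pd.DataFrame({
        "participant_id": pid, "birth_year": birth_year,
        "cord_hg_ugL": cord_val,
    })

    # --- yearly hair / blood biomarker records ---------------------------------
    y0, y1 = params.monitoring_years
    years = np.arange(y0, y1 + 1)
    trend = np.log10(hair_trend(years, params.hair_anchors))
    rows = []
    for i in range(n):
        alive = years >= birth_year[i] + 2   # no hair sampling of infants
        sampled = alive & (rng.random(len(years)) < params.sampling_prob_per_year)
        # AR(1) observation noise across the person's yearly series
        e = np.empty(len(years))
        e[0] = rng.normal(0.0, params.hair_obs_sd)
        sd_innov = params.hair_obs_sd * np.sqrt(1 - params.hair_ar1_rho ** 2)
        for t in range(1, len(years)):
            e[t] = params.hair_ar1_rho * e[t - 1] + rng.normal(0.0, sd_innov)
        log10_val = trend + exposure_shift[i] + e
        for t in np.flatnonzero(sampled):
            hair_val = 10 ** log10_val[t]
            if rng.random() < params.blood_record_prob:
                rows.append((pid[i], years[t], "blood", hair_val / params.blood_to_hair))
            else:
                rows.append((pid[i], years[t], "hair", hair_val))
    biomarkers = pd.DataFrame(rows, columns=["participant_id", "year", "medium", "value"])

    # --- survey table ----------------------------------------------------------
    survey = pd.DataFrame({
        "participant_id": pid,
        "sex": sex,
        "birth_year": birth_year,
        "age_category": age_category,
        "obesity": (rng.random(n) < 0.47).astype(float),
        "chronic_condition": (rng.random(n) < np.clip(0.35 + 0.006 * age, 0, 0.95)).astype(float),
        "nervous_disorder": nervous_disorder.astype(float),
        "fish_childhood": fish_childhood.astype(float),
        "residential_school": residential_school.astype(float),
        "region_pregnancy": region,
    }).set_index("participant_id")
    # sprinkle covariate missingness so imputation has work to do
    for col in ("obesity", "chronic_condition", "fish_childhood"):
        miss = rng.random(n) < params.missing_rate
        survey.loc[miss, col] = np.nan
    survey = survey.join(symptoms).reset_index()

    truth = {
        "partition": partition,
        "loadings": loadings,
        "factor_scores": pd.DataFrame(
            factors, index=pid, columns=[f"factor_{k + 1}" for k in range(K)]),
        "log10_childhood": pd.Series(log10_child, index=pid),
        "z_childhood": pd.Series(z_child, index=pid),
        "beta_hg": tuple(params.beta_hg),
        "beta_mediator": params.beta_mediator,
        "beta_disorder": params.beta_disorder,
        "params": params,
    }
    return SyntheticCohort(survey=survey, cord_table=cord_table,
                           biomarker_table=biomarkers, truth=truth)


# ---------------------------------------------------------------------------
# I/O


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write survey.csv / cord.csv / biomarkers.csv; missing cells become empty fields."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "survey": directory / "survey.csv",
        "cord": directory / "cord.csv",
        "biomarkers": directory / "biomarkers.csv",
    }
    cohort.survey.to_csv(paths["survey"], index=False)
    cohort.cord_table.to_csv(paths["cord"], index=False)
    cohort.biomarker_table.to_csv(paths["biomarkers"], index=False)
    truth_path = directory / "truth.json"
    serializable = {
        "partition": cohort.truth["partition"],
        "loadings": cohort.truth["loadings"],
        "beta_hg": list(cohort.truth["beta_hg"]),
        "beta_mediator": cohort.truth["beta_mediator"],
        "beta_disorder": cohort.truth["beta_disorder"],
        "params": {k: v for k, v in asdict(cohort.truth["params"]).items()
                   if not isinstance(v, dict)},
    }
    truth_path.write_text(json.dumps(serializable, indent=1, default=str))
    paths["truth"] = truth_path
    return paths


def generate_longitudinal(n_persons: int = 40, n_years: int = 12,
                          delta_log10: float = 0.15,
                          person_sd: float = 0.3, obs_sd: float = 0.15,
                          year_slope: float = -0.02, seed: int = 0,
                          heavy_tails: bool = False) -> pd.DataFrame:
    """Balanced two-group longitudinal hair-Hg panel for mixed-model tests.

    Half the persons are labelled 'above' and shifted by ``delta_log10`` on the
    log10 scale; each person has a random intercept (``person_sd``) and yearly
    observation noise (``obs_sd``), with a common linear year trend.  Columns
    match :func:`hgclust.lmem.build_long` output.
    """
    rng = np.random.default_rng(seed)
    years = np.arange(1975, 1975 + n_years)
    rows = []
    for i in range(n_persons):
        group = "above" if i < n_persons // 2 else "below"
        u = rng.normal(0.0, person_sd)
        birth = int(rng.integers(1935, 1960))
        sex = "F" if rng.random() < 0.5 else "M"
        noise = (rng.standard_t(3, size=n_years) * obs_sd if heavy_tails
                 else rng.normal(0.0, obs_sd, size=n_years))
        base = 0.3 + (delta_log10 if group == "above" else 0.0)
        for t, year in enumerate(years):
            log10v = base + u + year_slope * t + noise[t]
            rows.append({"participant_id": f"L{i:03d}", "year": int(year),
                         "hair_hg": float(10 ** log10v),
                         "log10_hair": float(log10v),
                         "age_at_sampling": int(year) - birth,
                         "sex": sex, "group": group})
    return pd.DataFrame(rows)


def read_cohort(directory: str | Path) -> SyntheticCohort:
    """Read back a cohort written by :func:`write_cohort` (truth partially restored)."""
    directory = Path(directory)
    survey = pd.read_csv(directory / "survey.csv")
    cord = pd.read_csv(directory / "cord.csv")
    biomarkers = pd.read_csv(directory / "biomarkers.csv")
    truth = {}
    tp = directory / "truth.json"
    if tp.exists():
        truth = json.loads(tp.read_text())
    return SyntheticCohort(survey=survey, cord_table=cord,
                           biomarker_table=biomarkers, truth=truth)
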
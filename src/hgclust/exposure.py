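"""Rule-based reconstruction of prenatal and childhood mercury exposure.

Historic biomarker records (blood or hair Hg, 1970-1997) are reduced to one
equivalent-hair value per person-year (blood converted by a fixed hair:blood
ratio, the yearly maximum kept).  Prenatal exposure is the umbilical-cord blood
Hg at birth and childhood exposure the mean hair Hg at ages 5-15; where a person
has no measurement the value is attributed through a measurement-first cascade:

cord (ug/L)           born <= 1961: 1.0 | born 1962-1969: 65.7 (the 1970 era mean)
                      born 1970-1992: the region-year mean, else a period
                      regression prediction | born >= 1993: 4.48 (the 1992 mean)
                      mother elsewhere: 1.0
childhood (ug/g)      >= 10 years old in 1962 (born <= 1952): 0.1 background
                      turned 10 in 1963-1970: mean measured child hair in 1970
                      turned 10 in 1971-1990: cohort mean for that year
                      turned 10 after 1990: 0.81 plateau
Post-1962 childhood attributions are adjusted multiplicatively on reported
childhood fish consumption and residential-school attendance, with stratum
factors derived from the measured data.  The provenance of every value is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

# era attribution constants
CORD_PRE_DISCHARGE_UGL = 1.0     # born before the 1962 discharge
CORD_1970_MEAN_UGL = 65.7        # born 1962-1969
CORD_1992_MEAN_UGL = 4.48        # born after 1992
CORD_ELSEWHERE_UGL = 1.0         # mother spent pregnancy / delivered elsewhere
CHILDHOOD_PRE_DISCHARGE_UGG = 0.1   # >= 10 years old in 1962
CHILDHOOD_POST1990_UGG = 0.81       # 10 years old after 1990

DEFAULT_BLOOD_TO_HAIR = 0.25     # ug/g equivalent hair per ug/L blood (250:1)
DEFAULT_THRESHOLD_UGG = 5.0
MONITORING_WINDOW = (1970, 1997)
CORD_PERIODS = ((1970, 1976), (1977, 1987), (1988, 1992))


@dataclass
class PeriodRegression:
    period: tuple[int, int]
    slope: float        # on log10(cord ug/L) per birth year
    intercept: float
    n: int
    fallback: bool = False   # True when too few points; year means used instead

    def predict(self, birth_year: int) -> float:
        return 10 ** (self.intercept + self.slope * birth_year)


@dataclass
class ExposureProfile:
    participant_id: str
    cord_hg: float | None
    cord_source: str | None
    childhood_hg: float | None
    childhood_source: str | None
    adjusted: bool
    ever_ge5: bool | None
    threshold: float = DEFAULT_THRESHOLD_UGG


# ---------------------------------------------------------------------------
# yearly equivalent-hair series


def build_yearly_hair(records: pd.DataFrame,
                      blood_to_hair: float = DEFAULT_BLOOD_TO_HAIR,
                      window: tuple[int, int] = MONITORING_WINDOW,
                      ) -> dict[str, dict[int, float]]:
    """One equivalent-hair Hg value (ug/g) per person-year: the yearly maximum.

    ``records`` needs columns participant_id, year, medium in {blood, hair},
    value (> 0).  Blood (ug/L) is converted with ``blood_to_hair``; records with
    an unknown medium or outside the monitoring window are rejected and counted.
    """
    df = records.copy()
    known = df["medium"].isin(["blood", "hair"])
    in_window = df["year"].between(*window)
    positive = df["value"] > 0
    rejected = int((~(known & in_window & positive)).sum())
    if rejected:
        logger.warning("build_yearly_hair: %d record(s) rejected", rejected)
    df = df[known & in_window & positive].copy()
    df["equiv_hair"] = np.where(df["medium"] == "blood",
                                df["value"] * blood_to_hair, df["value"])
    best = df.groupby(["participant_id", "year"])["equiv_hair"].max()
    series: dict[str, dict[int, float]] = {}
    for (person, year), val in best.items():
        series.setdefault(person, {})[int(year)] = float(val)
    return series


def childhood_mean_hair(series: dict[int, float], birth_year: int) -> float | None:
    """Arithmetic mean of yearly values at ages 5-15 inclusive; None if no data."""
    vals = [v for y, v in series.items() if 5 <= y - birth_year <= 15]
    return float(np.mean(vals)) if vals else None


def ever_ge5(series: dict[int, float],
             threshold: float = DEFAULT_THRESHOLD_UGG) -> bool | None:
    """True iff any yearly equivalent-hair value reaches the threshold; None if empty."""
    if not series:
        return None
    return bool(any(v >= threshold for v in series.values()))


# ---------------------------------------------------------------------------
# cord regressions and the attribution cascades


def fit_cord_regressions(cord_table: pd.DataFrame,
                         log_scale: bool = True) -> list[PeriodRegression]:
    """OLS of log10 cord Hg on birth year within each exposure period."""
    out = []
    df = cord_table.dropna(subset=["cord_hg_ugL"])
    for start, end in CORD_PERIODS:
        sub = df[df["birth_year"].between(start, end)]
        if len(sub) < 3:
            logger.warning("period %s-%s has %d cord observations; falling back "
                           "to year means", start, end, len(sub))
            out.append(PeriodRegression((start, end), np.nan, np.nan,
                                        len(sub), fallback=True))
            continue
        y = np.log10(sub["cord_hg_ugL"]) if log_scale else sub["cord_hg_ugL"]
        X = sm.add_constant(sub["birth_year"].astype(float))
        fit = sm.OLS(y, X).fit()
        out.append(PeriodRegression((start, end),
                                    slope=float(fit.params["birth_year"]),
                                    intercept=float(fit.params["const"]),
                                    n=len(sub)))
    return out


def _year_means(cord_table: pd.DataFrame, min_n: int = 3) -> dict[int, float]:
    df = cord_table.dropna(subset=["cord_hg_ugL"])
    g = df.groupby("birth_year")["cord_hg_ugL"]
    return {int(y): float(m) for (y, m), c in zip(g.mean().items(), g.count())
            if c >= min_n}


def estimate_cord(participant_id: str, cord_table: pd.DataFrame,
                  regressions: list[PeriodRegression],
                  region_flag: str, birth_year: int | None,
                  year_mean_min_n: int = 3) -> tuple[float | None, str | None]:
    """Measurement-first cascade for prenatal (cord blood) Hg, ug/L."""
    row = cord_table[cord_table["participant_id"] == participant_id]
    if not row.empty and not np.isnan(row["cord_hg_ugL"].iloc[0]):
        return float(row["cord_hg_ugL"].iloc[0]), "measured"
    if birth_year is None or (isinstance(birth_year, float) and np.isnan(birth_year)):
        return None, None
    birth_year = int(birth_year)
    if region_flag == "elsewhere":
        return CORD_ELSEWHERE_UGL, "elsewhere_floor"
    if birth_year <= 1961:
        return CORD_PRE_DISCHARGE_UGL, "era_constant"
    if birth_year <= 1969:
        return CORD_1970_MEAN_UGL, "era_constant"
    if birth_year >= 1993:
        return CORD_1992_MEAN_UGL, "era_constant"
    means = _year_means(cord_table, min_n=year_mean_min_n)
    if birth_year in means:
        return means[birth_year], "region_year_mean"
    for reg in regressions:
        if reg.period[0] <= birth_year <= reg.period[1] and not reg.fallback:
            return reg.predict(birth_year), "regression"
    # regression unavailable (sparse period): fall back to the nearest era mean
    return (CORD_1970_MEAN_UGL if birth_year < 1981 else CORD_1992_MEAN_UGL,
            "era_constant")


def _cohort_year_means(yearly_db: dict[str, dict[int, float]],
                       birth_years: dict[str, int]) -> dict[int, float]:
    """Mean hair Hg among all measured persons, per calendar year."""
    per_year: dict[int, list[float]] = {}
    for person, series in yearly_db.items():
        for y, v in series.items():
            per_year.setdefault(y, []).append(v)
    return {y: float(np.mean(vs)) for y, vs in per_year.items()}


def _child_mean_1970(yearly_db: dict[str, dict[int, float]],
                     birth_years: dict[str, int]) -> float | None:
    """Mean measured hair Hg in children (age <= 15) in 1970."""
    vals = [series[1970] for person, series in yearly_db.items()
            if 1970 in series and person in birth_years
            and 0 <= 1970 - birth_years[person] <= 15]
    return float(np.mean(vals)) if vals else None


def adjustment_factors(yearly_db: dict[str, dict[int, float]],
                       birth_years: dict[str, int],
                       survey: pd.DataFrame) -> dict[tuple[int, int], float]:
    """Multiplicative stratum factors from measured childhood means.

    Factor for a (fish_childhood, residential_school) stratum is the ratio of the
    stratum's mean measured childhood hair Hg to the overall mean, so frequent
    fish eaters scale up and residential-school attendees scale down, matching
    the measured contrast.  Strata without data get factor 1.
    """
    cov = survey.set_index("participant_id")
    rows = []
    for person, series in yearly_db.items():
        if person not in birth_years or person not in cov.index:
            continue
        m = childhood_mean_hair(series, birth_years[person])
        if m is None:
            continue
        fish = cov.loc[person, "fish_childhood"]
        school = cov.loc[person, "residential_school"]
        if np.isnan(fish) or np.isnan(school):
            continue
        rows.append((int(fish), int(school), m))
    factors = {(f, s): 1.0 for f in (0, 1) for s in (0, 1)}
    if not rows:
        return factors
    df = pd.DataFrame(rows, columns=["fish", "school", "hg"])
    overall = np.exp(np.mean(np.log(df["hg"])))   # geometric mean, Hg is log-scaled
    for (f, s), grp in df.groupby(["fish", "school"]):
        if len(grp) >= 3:
            factors[(int(f), int(s))] = float(
                np.exp(np.mean(np.log(grp["hg"]))) / overall)
    return factors


def estimate_childhood(participant_id: str,
                       yearly_db: dict[str, dict[int, float]],
                       birth_years: dict[str, int],
                       fish_childhood: float | None,
                       residential_school: float | None,
                       factors: dict[tuple[int, int], float] | None = None,
                       ) -> tuple[float | None, str | None, bool]:
    """Measurement-first cascade for childhood hair Hg, ug/g.

    Returns (value, source, adjusted).  Undefined (None) when the person has no
    ages-5-15 measurement and did not answer the fish-consumption question.
    """
    birth_year = birth_years.get(participant_id)
    if birth_year is None:
        return None, None, False
    series = yearly_db.get(participant_id, {})
    measured = childhood_mean_hair(series, birth_year)
    if measured is not None:
        return measured, "measured", False
    if birth_year <= 1952:   # at least 10 years old at the 1962 discharge
        return CHILDHOOD_PRE_DISCHARGE_UGG, "era_constant", False
    fish_missing = fish_childhood is None or np.isnan(fish_childhood)
    if fish_missing:
        return None, None, False
    school = 0 if residential_school is None or np.isnan(residential_school) \
        else int(residential_school)
    factor = 1.0
    if factors is not None:
        factor = factors.get((int(fish_childhood), school), 1.0)
    year_at_10 = birth_year + 10
    if year_at_10 <= 1970:
        base = _child_mean_1970(yearly_db, birth_years)
        if base is None:
            base = CHILDHOOD_POST1990_UGG   # degenerate db; keep cascade total
        return base * factor, "era_constant", True
    if year_at_10 >= 1991:
        return CHILDHOOD_POST1990_UGG * factor, "era_constant", True
    means = _cohort_year_means(yearly_db, birth_years)
    if year_at_10 in means:
        return means[year_at_10] * factor, "cohort_year_mean", True
    nearest = min(means, key=lambda y: abs(y - year_at_10)) if means else None
    if nearest is not None:
        return means[nearest] * factor, "cohort_year_mean", True
    return None, None, False


# ---------------------------------------------------------------------------
# cohort-level driver


def build_exposure_table(survey: pd.DataFrame, cord_table: pd.DataFrame,
                         biomarkers: pd.DataFrame,
                         blood_to_hair: float = DEFAULT_BLOOD_TO_HAIR,
                         threshold: float = DEFAULT_THRESHOLD_UGG) -> pd.DataFrame:
    """Apply both cascades to every survey participant; one row each."""
    yearly = build_yearly_hair(biomarkers, blood_to_hair=blood_to_hair)
    birth_years = {r.participant_id: int(r.birth_year)
                   for r in survey.itertuples() if not pd.isna(r.birth_year)}
    regs = fit_cord_regressions(cord_table)
    factors = adjustment_factors(yearly, birth_years, survey)
    rows = []
    for r in survey.itertuples():
        pid = r.participant_id
        by = birth_years.get(pid)
        cord, cord_src = estimate_cord(pid, cord_table, regs,
                                       getattr(r, "region_pregnancy", "region"), by)
        if cord is not None and cord_src != "measured":
            cord = max(cord, CORD_PRE_DISCHARGE_UGL)   # 1.0 ug/L attribution floor
        child, child_src, adjusted = estimate_childhood(
            pid, yearly, birth_years,
            getattr(r, "fish_childhood", None),
            getattr(r, "residential_school", None), factors)
        series = yearly.get(pid, {})
        rows.append({
            "participant_id": pid,
            "cord_hg": cord, "cord_source": cord_src,
            "childhood_hg": child, "childhood_source": child_src,
            "adjusted": adjusted,
            "ever_ge5": ever_ge5(series, threshold),
            "n_hair_years": len(series),
        })
    return pd.DataFrame(rows)


def validate_estimates(measured, estimated) -> tuple[float, float]:
    """Spearman rank correlation between measured and estimated exposures."""
    measured = np.asarray(measured, dtype=float)
    estimated = np.asarray(estimated, dtype=float)
    if len(measured) != len(estimated) or len(measured) < 5:
        raise ValueError("need >= 5 paired values")
    if np.all(measured == measured[0]) or np.all(estimated == estimated[0]):
        raise ValueError("constant input: rank correlation undefined")
    rho, p = stats.spearmanr(measured, estimated)
    return float(rho), float(p)
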
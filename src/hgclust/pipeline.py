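"""End-to-end orchestration: clustering -> exposure -> SEM -> LMEM.

Stage subsets mirror the study's selection logic: variable clustering uses all
survey participants; SEM uses the subset with at least one biomarker
measurement; the longitudinal model uses the subset with at least
``min_measurements`` yearly hair values.  All randomized stages consume named
sub-seeds derived from a single master seed, and every output table is
traceable to the config hash recorded in the run log.

The pipeline-wide significance threshold is p <= 0.05 and no multiple-testing
correction is applied — a deliberate property of the reproduced analysis plan,
stated here prominently rather than buried in defaults.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml

from . import exposure as expo
from . import lmem as lmm
from . import power as pwr
from . import sem as sem_mod
from . import varclust as vc

logger = logging.getLogger(__name__)

SIGNIFICANCE_LEVEL = 0.05


@dataclass
class PipelineConfig:
    survey: str = "survey.csv"
    cord: str = "cord.csv"
    biomarkers: str = "biomarkers.csv"
    output_dir: str = "hgclust_out"
    k_min: int = 4
    k_max: int = 8
    bootstrap_B: int = 60
    min_explained: float = 0.5
    min_sq_corr: float = 0.6
    blood_to_hair: float = expo.DEFAULT_BLOOD_TO_HAIR
    threshold_ugg: float = expo.DEFAULT_THRESHOLD_UGG
    sem_modes: tuple[str, ...] = ("latent_hg", "separate")
    sem_covariates: tuple[str, ...] = ("age_z", "sex_f", "obesity")
    min_measurements: int = 10
    lmem_random_structure: str = "participant"
    lmem_bootstrap: int = 100
    mice_m: int = 5
    stages: tuple[str, ...] = ("varclust", "exposure", "sem", "lmem", "power")
    seed: int = 17

    # era constants (defaults are the published attribution values)
    cord_pre_discharge: float = expo.CORD_PRE_DISCHARGE_UGL
    cord_1970_mean: float = expo.CORD_1970_MEAN_UGL
    cord_1992_mean: float = expo.CORD_1992_MEAN_UGL
    childhood_pre_discharge: float = expo.CHILDHOOD_PRE_DISCHARGE_UGG
    childhood_post1990: float = expo.CHILDHOOD_POST1990_UGG

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        for key in ("sem_modes", "sem_covariates", "stages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def subseed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2 ** 31)


@dataclass
class ReportBundle:
    clusters: pd.DataFrame | None = None
    stability: pd.DataFrame | None = None
    scores: pd.DataFrame | None = None
    exposure: pd.DataFrame | None = None
    sem_paths: pd.DataFrame | None = None
    sem_fit: pd.DataFrame | None = None
    sem_effects: pd.DataFrame | None = None
    lmem: pd.DataFrame | None = None
    power: pd.DataFrame | None = None
    run_log: dict = field(default_factory=dict)
    partial: bool = False

    def tables(self) -> dict[str, pd.DataFrame]:
        named = {"clusters": self.clusters, "stability": self.stability,
                 "scores": self.scores, "exposure": self.exposure,
                 "sem_paths": self.sem_paths, "sem_fit": self.sem_fit,
                 "sem_effects": self.sem_effects, "lmem": self.lmem,
                 "power": self.power}
        return {k: v for k, v in named.items() if v is not None}


# ---------------------------------------------------------------------------
# MICE imputation of survey covariates


def mice_impute(table: pd.DataFrame, m: int = 5, seed: int = 0,
                n_sweeps: int = 5, binary_cols: list[str] | None = None,
                ) -> list[pd.DataFrame]:
    """Chained-equations imputation; returns m completed copies.

    Numeric (including ordinal-as-numeric) columns are imputed by predictive
    mean matching against an OLS fit on the other columns; binary columns by
    draws from a logistic fit.  Observed cells are never altered.
    """
    df = table.copy()
    num_cols = [c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])]
    missing_cols = [c for c in num_cols if df[c].isna().any()]
    for c in missing_cols:
        if df[c].notna().sum() == 0:
            raise ValueError(f"column {c!r} has no observed values")
        frac = df[c].isna().mean()
        if frac >= 0.5:
            raise ValueError(f"column {c!r} is {frac:.0%} missing (>= 50%)")
    if binary_cols is None:
        binary_cols = [c for c in missing_cols
                       if set(df[c].dropna().unique()) <= {0.0, 1.0}]
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(max(m, 1)):
        work = df.copy()
        # initialise missing cells with draws from the observed values
        for c in missing_cols:
            obs = work[c].dropna().to_numpy()
            idx = work[c].isna()
            work.loc[idx, c] = rng.choice(obs, size=int(idx.sum()))
        for _ in range(n_sweeps):
            for c in missing_cols:
                others = [o for o in num_cols if o != c]
                miss = df[c].isna()
                if not others or miss.sum() == 0:
                    continue
                X = work[others].to_numpy(dtype=float)
                Xc = sm.add_constant(X, has_constant="add")
                y = df[c].to_numpy(dtype=float)
                obs_i = ~np.isnan(y)
                if c in binary_cols:
                    try:
                        fit = sm.Logit(y[obs_i], Xc[obs_i]).fit(disp=0, maxiter=50)
                        p = fit.predict(Xc[miss.to_numpy()])
                    except Exception:   # separation: fall back to the base rate
                        p = np.full(int(miss.sum()), np.nanmean(y))
                    work.loc[miss, c] = (rng.random(int(miss.sum())) < p).astype(float)
                else:
                    fit = sm.OLS(y[obs_i], Xc[obs_i]).fit()
                    pred_obs = fit.predict(Xc[obs_i])
                    pred_mis = fit.predict(Xc[miss.to_numpy()])
                    # PMM: draw one of the 5 nearest observed donors
                    donors = y[obs_i]
                    for row, pm in zip(np.flatnonzero(miss.to_numpy()), pred_mis):
                        near = np.argsort(np.abs(pred_obs - pm))[:5]
                        work.iloc[row, work.columns.get_loc(c)] = \
                            donors[rng.choice(near)]
        out.append(work)
    return out


def pool_means(tables: list[pd.DataFrame], column: str) -> dict:
    """Rubin's rules for the mean of a column across imputations."""
    means = np.array([t[column].mean() for t in tables])
    variances = np.array([t[column].var(ddof=1) / len(t) for t in tables])
    m = len(tables)
    qbar = means.mean()
    ubar = variances.mean()
    b = means.var(ddof=1) if m > 1 else 0.0
    total = ubar + (1 + 1 / m) * b
    return {"estimate": float(qbar), "se": float(np.sqrt(total)), "m": m}


# ---------------------------------------------------------------------------
# SEM model construction for a cluster


def _prepare_sem_data(survey: pd.DataFrame, scores: pd.DataFrame,
                      exposure_table: pd.DataFrame, symptoms: list[str],
                      covariates: tuple[str, ...], mice_m: int,
                      seed: int) -> pd.DataFrame:
    df = survey.set_index("participant_id").copy()
    df["age"] = pd.Series(
        {i: a for i, a in zip(df.index, 2017 - df["birth_year"])})
    df["age_z"] = (df["age"] - df["age"].mean()) / df["age"].std(ddof=0)
    df["sex_f"] = (df["sex"] == "F").astype(float)
    exp_idx = exposure_table.set_index("participant_id")
    df["log10_cord"] = np.log10(exp_idx["cord_hg"].astype(float))
    df["log10_childhood"] = np.log10(exp_idx["childhood_hg"].astype(float))
    df["ever_ge5"] = exp_idx["ever_ge5"].map({True: 1.0, False: 0.0})
    keep = symptoms + ["nervous_disorder", "log10_cord", "log10_childhood",
                       "ever_ge5", *covariates]
    data = df[keep].copy()
    impute_cols = [c for c in covariates if data[c].isna().any()] + \
        (["nervous_disorder"] if data["nervous_disorder"].isna().any() else [])
    if impute_cols:
        completed = mice_impute(data[list(dict.fromkeys(impute_cols))],
                                m=1, seed=seed)[0]
        for c in completed.columns:
            data[c] = completed[c]
    return data


def build_cluster_sem_spec(symptoms: list[str], mode: str,
                           covariates: tuple[str, ...]) -> sem_mod.SemModelSpec:
    """Latent-Hg or separate-exposure SEM for one symptom cluster.

    Both variants include the mediation chain through the diagnosed
    nervous-system disorder; the separate variant additionally mediates
    prenatal exposure through childhood exposure.
    """
    ordinal = list(symptoms) + ["nervous_disorder", "ever_ge5"]
    regressions = [("cluster", c) for c in covariates]
    regressions += [("cluster", "nervous_disorder")]
    if mode == "latent_hg":
        latents = {"cluster": list(symptoms),
                   "hg": ["log10_cord", "log10_childhood", "ever_ge5"]}
        regressions += [("cluster", "hg"), ("nervous_disorder", "hg")]
    elif mode == "separate":
        latents = {"cluster": list(symptoms)}
        regressions += [("log10_childhood", "log10_cord"),
                        ("nervous_disorder", "log10_childhood"),
                        ("cluster", "log10_childhood"),
                        ("cluster", "log10_cord"),
                        ("cluster", "ever_ge5")]
    else:
        raise ValueError(f"unknown SEM mode {mode!r}")
    return sem_mod.SemModelSpec(latents=latents, regressions=regressions,
                                ordinal=ordinal)


# ---------------------------------------------------------------------------
# the pipeline


def run_pipeline(config: PipelineConfig,
                 write: bool = True) -> ReportBundle:
    """Execute the configured stages; on stage failure return a partial bundle."""
    bundle = ReportBundle()
    log = {"config_hash": config.hash(), "seed": config.seed, "stages": {}}
    bundle.run_log = log
    out_dir = Path(config.output_dir)

    survey = pd.read_csv(config.survey)
    cord = pd.read_csv(config.cord)
    biomarkers = pd.read_csv(config.biomarkers)
    symptom_cols = sorted(c for c in survey.columns if c.startswith("sym_"))

    solution = None
    exposure_table = None
    scores = None

    try:
        if "varclust" in config.stages:
            data = vc.LikertMatrix(
                survey.set_index("participant_id")[symptom_cols])
            tree = vc.build_tree(data)
            stability = vc.bootstrap_stability(
                data, range(config.k_min, config.k_max + 1),
                B=config.bootstrap_B, seed=config.subseed("varclust"))
            K, diag = vc.select_k(tree, stability)
            partition = vc.cut_tree(tree, K)
            solution = vc.prune_clusters(
                data, vc.composite_scores(data, partition),
                min_explained=config.min_explained,
                min_sq_corr=config.min_sq_corr)
            bundle.stability = diag
            bundle.clusters = pd.DataFrame(
                [{"symptom_id": s, "cluster": k + 1,
                  "squared_loading": solution.squared_loadings.get(s, np.nan),
                  "retained": solution.retained.get(k, False)}
                 for s, k in solution.partition.items()])
            scores = solution.composite_scores.copy()
            scores.index = data.values.index
            bundle.scores = scores.reset_index(names="participant_id")
            log["stages"]["varclust"] = {
                "K": K, "n_participants": len(survey),
                "n_retained_symptoms": sum(
                    solution.retained.get(k, False)
                    for s, k in solution.partition.items()),
                "dropped": solution.dropped_symptoms}

        if "exposure" in config.stages:
            exposure_table = expo.build_exposure_table(
                survey, cord, biomarkers,
                blood_to_hair=config.blood_to_hair,
                threshold=config.threshold_ugg)
            bundle.exposure = exposure_table
            log["stages"]["exposure"] = {
                "source_counts": exposure_table["cord_source"].value_counts(
                    dropna=False).to_dict()}

        if "sem" in config.stages and solution is not None \
                and exposure_table is not None:
            # flow-chart subset: participants with at least one biomarker
            has_bio = exposure_table[
                (exposure_table["n_hair_years"] > 0)
                | (exposure_table["cord_source"] == "measured")
            ]["participant_id"]
            sem_survey = survey[survey["participant_id"].isin(has_bio)]
            log["stages"]["sem"] = {"n": len(sem_survey), "models": []}
            paths_rows, fit_rows, eff_rows = [], [], []
            retained_clusters = [k for k, keep in solution.retained.items() if keep]
            # construct validity: correlated-factors CFA of the retained solution
            measurement = {f"cluster{k + 1}": sorted(solution.members(k))
                           for k in retained_clusters
                           if len(solution.members(k)) >= 3}
            if measurement:
                cfa_cols = [s for inds in measurement.values() for s in inds]
                cfa = sem_mod.fit_cfa(
                    measurement,
                    survey.set_index("participant_id")[cfa_cols])
                fit_rows.append({"cluster": 0, "mode": "cfa",
                                 **cfa.fit_indices,
                                 "converged": cfa.converged, "N": cfa.N})
                log["stages"]["sem"]["cfa"] = {
                    k: round(v, 4) for k, v in cfa.fit_indices.items()}
            for k in retained_clusters:
                symptoms = sorted(solution.members(k))
                if len(symptoms) < 3:
                    continue
                sem_data = _prepare_sem_data(
                    sem_survey, scores, exposure_table, symptoms,
                    config.sem_covariates, config.mice_m,
                    config.subseed(f"sem_impute_{k}"))
                rename = {s: s for s in symptoms}
                for mode in config.sem_modes:
                    spec = build_cluster_sem_spec(symptoms, mode,
                                                  config.sem_covariates)
                    fit = sem_mod.fit_sem(spec, sem_data.dropna(
                        subset=["log10_cord", "log10_childhood"]))
                    exposure_name = "hg" if mode == "latent_hg" else "log10_childhood"
                    eff = sem_mod.decompose_effects(fit, exposure_name, "cluster")
                    for r in fit.estimates.itertuples():
                        paths_rows.append({
                            "cluster": k + 1, "mode": mode, "edge": r.parameter,
                            "std_est": r.est, "se": r.se, "p": r.p})
                    fit_rows.append({"cluster": k + 1, "mode": mode,
                                     **fit.fit_indices,
                                     "converged": fit.converged, "N": fit.N})
                    eff_rows.append({
                        "cluster": k + 1, "mode": mode,
                        "source": exposure_name, "direct": eff.direct,
                        "indirect": eff.indirect, "total": eff.total})
                    log["stages"]["sem"]["models"].append(
                        {"cluster": k + 1, "mode": mode,
                         "converged": fit.converged})
            bundle.sem_paths = pd.DataFrame(paths_rows)
            bundle.sem_fit = pd.DataFrame(fit_rows)
            bundle.sem_effects = pd.DataFrame(eff_rows)

        if "lmem" in config.stages and scores is not None:
            yearly = expo.build_yearly_hair(
                biomarkers, blood_to_hair=config.blood_to_hair)
            covs = survey.set_index("participant_id")[["birth_year", "sex"]]
            lmem_rows = []
            for col in scores.columns:
                cluster_id = int(col.replace("score_cluster", ""))
                if solution is not None and \
                        not solution.retained.get(cluster_id - 1, True):
                    continue
                long, counts = lmm.build_long(
                    yearly, scores[col], covs,
                    min_measurements=config.min_measurements)
                if counts["included"] < 5:
                    logger.warning("cluster %d: only %d longitudinal "
                                   "participants; skipped", cluster_id,
                                   counts["included"])
                    continue
                fit = lmm.fit_lmem(long,
                                   random_structure=config.lmem_random_structure,
                                   n_boot=config.lmem_bootstrap,
                                   seed=config.subseed(f"lmem_{cluster_id}"))
                lmem_rows.append({
                    "cluster": cluster_id,
                    "estimate_ugg": fit.group_diff_ugg,
                    "ci_low": (fit.group_diff_ugg_ci or (np.nan, np.nan))[0],
                    "ci_high": (fit.group_diff_ugg_ci or (np.nan, np.nan))[1],
                    "estimate_log10": fit.group_diff_log10,
                    "p": fit.group_p,
                    "n_participants": fit.n_participants,
                    "n_measurements": fit.n_observations})
            bundle.lmem = pd.DataFrame(lmem_rows)
            log["stages"]["lmem"] = {"clusters": len(lmem_rows)}

        if "power" in config.stages:
            bundle.power = pwr.power_grid()
            log["stages"]["power"] = {"rows": len(bundle.power)}
    except Exception as exc:   # stage failure: mark partial, keep what we have
        bundle.partial = True
        log["failure"] = f"{type(exc).__name__}: {exc}"
        logger.exception("pipeline stage failed")

    # flow-chart ordering check: n_clustering >= n_SEM >= n_LMEM
    ns = [log["stages"].get(s, {}).get(key) for s, key in
          (("varclust", "n_participants"), ("sem", "n"))]
    if all(x is not None for x in ns):
        assert ns[0] >= ns[1], "subset sizes violate the flow-chart ordering"

    if write:
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, tab in bundle.tables().items():
            tab.to_csv(out_dir / f"{name}.csv", index=False,
                       float_format="%.10g")
        (out_dir / "run_log.json").write_text(
            json.dumps(log, indent=1, default=str, sort_keys=True))
    return bundle
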
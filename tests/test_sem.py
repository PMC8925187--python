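"""Ordinal SEM layer: correlations, DWLS fits, mediation, MI, moderation, power."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hgclust.sem import (SemModelSpec, _Model, SemFit, bvn_cdf, decompose_effects,
                         fit_cfa, fit_sem, modification_indices, polychoric,
                         polychoric_matrix, polyserial, sem_power,
                         simulate_target_model, target_effect_power,
                         moderation_test)


def _discretize(x, thr=(-1.2, -0.4, 0.4, 1.2)):
    return (1 + np.searchsorted(np.asarray(thr), x)).astype(float)


# ---------------------------------------------------------------------------
# bivariate normal and the correlation layer


@pytest.mark.parametrize("r", [-0.99, -0.6, 0.0, 0.5, 0.95])
def test_bvn_cdf_matches_scipy(r):
    rng = np.random.default_rng(1)
    h = rng.uniform(-3, 3, 15)
    k = rng.uniform(-3, 3, 15)
    oracle = [stats.multivariate_normal(cov=[[1, r], [r, 1]]).cdf([a, b])
              for a, b in zip(h, k)]
    np.testing.assert_allclose(bvn_cdf(h, k, r), oracle, atol=5e-7)


def test_polychoric_recovers_latent_correlation():
    rng = np.random.default_rng(2)
    z = rng.multivariate_normal([0, 0], [[1, .5], [.5, 1]], size=2000)
    rho, var = polychoric(_discretize(z[:, 0]), _discretize(z[:, 1]))
    assert rho == pytest.approx(0.5, abs=0.05)
    assert 0 < var < 0.01


def test_polychoric_independent_and_identical():
    rng = np.random.default_rng(3)
    a = _discretize(rng.normal(size=1500))
    b = _discretize(rng.normal(size=1500))
    rho, _ = polychoric(a, b)
    assert abs(rho) < 0.06
    rho_same, _ = polychoric(a, a)
    assert rho_same > 0.99


def test_polyserial_recovers_latent_correlation():
    rng = np.random.default_rng(4)
    z = rng.multivariate_normal([0, 0], [[1, .6], [.6, 1]], size=2000)
    rho, _ = polyserial(z[:, 0], _discretize(z[:, 1]))
    assert rho == pytest.approx(0.6, abs=0.05)


def test_polychoric_matrix_mixed_types_psd():
    rng = np.random.default_rng(5)
    f = rng.normal(size=600)
    data = pd.DataFrame({
        "o1": _discretize(0.8 * f + rng.normal(scale=0.6, size=600)),
        "o2": _discretize(0.7 * f + rng.normal(scale=0.7, size=600)),
        "cont": 0.5 * f + rng.normal(scale=0.86, size=600),
        "bin": (0.6 * f + rng.normal(scale=0.8, size=600) > 0).astype(float),
    })
    R, V, n = polychoric_matrix(data, ordinal=["o1", "o2", "bin"])
    assert n == 600
    assert np.linalg.eigvalsh(R.to_numpy()).min() > 0
    assert ((V.to_numpy()[~np.eye(4, dtype=bool)]) > 0).all()
    assert R.loc["o1", "o2"] == pytest.approx(0.56, abs=0.08)


# ---------------------------------------------------------------------------
# CFA


def test_cfa_saturated_model_conventions():
    rng = np.random.default_rng(6)
    f = rng.normal(size=400)
    data = pd.DataFrame({f"y{j}": _discretize(0.8 * f + rng.normal(
        scale=0.6, size=400)) for j in (1, 2, 3)})
    fit = fit_cfa({"eta": ["y1", "y2", "y3"]}, data)
    assert fit.fit_indices["df"] == 0
    assert fit.fit_indices["cfi"] == 1.0
    assert fit.fit_indices["rmsea"] == 0.0


def test_cfa_correct_model_fits_well_and_recovers_loadings():
    chis, rmseas, load_err = [], [], []
    spec_loading = 0.8
    for seed in range(15):
        rng = np.random.default_rng(100 + seed)
        n = 400
        f = rng.multivariate_normal([0, 0], [[1, .4], [.4, 1]], size=n)
        cols = {}
        for k in range(2):
            for j in range(4):
                lam = spec_loading
                cols[f"c{k}y{j}"] = _discretize(
                    lam * f[:, k] + rng.normal(scale=np.sqrt(1 - lam ** 2), size=n))
        data = pd.DataFrame(cols)
        fit = fit_cfa({"eta1": [f"c0y{j}" for j in range(4)],
                       "eta2": [f"c1y{j}" for j in range(4)]}, data)
        chis.append(fit.fit_indices["chi2"])
        rmseas.append(fit.fit_indices["rmsea"])
        est = fit.estimates.set_index("parameter")["est"]
        load_err.append(np.median([abs(est[f"c{k}y{j}~eta{k + 1}"] - spec_loading)
                                   for k in range(2) for j in range(4)]))
    df = fit.fit_indices["df"]
    assert np.mean(chis) == pytest.approx(df, rel=0.5)
    assert np.median(rmseas) < 0.05
    assert np.median(load_err) < 0.07
    assert fit.fit_indices["cfi"] > 0.95


def test_fit_index_closed_forms():
    """CFI/TLI/RMSEA recomputed from the reported chi2, df and N."""
    rng = np.random.default_rng(7)
    data = simulate_target_model(0.3, 300, rng)
    fit = fit_sem(SemModelSpec(latents={"eta": ["y1", "y2", "y3", "y4"]},
                               regressions=[("eta", "exposure")],
                               ordinal=["y1", "y2", "y3", "y4"]), data)
    fi = fit.fit_indices
    T, df, N = fi["chi2"], fi["df"], fit.N
    assert fi["rmsea"] == pytest.approx(
        np.sqrt(max(T - df, 0) / (df * (N - 1))), abs=1e-10)
    assert fi["chi2_df"] == pytest.approx(T / df, abs=1e-10)
    assert 0 <= fi["cfi"] <= 1 and fi["tli"] <= 1
    assert fi["rmsea_lo"] <= fi["rmsea"] <= fi["rmsea_hi"]
    assert fi["srmr"] >= 0
    assert fi["aic"] == pytest.approx(T + 2 * fit.model.n_free)
    assert fi["bic"] == pytest.approx(T + np.log(N) * fit.model.n_free)


# ---------------------------------------------------------------------------
# structural fits


def test_sem_not_identified_raises():
    spec = SemModelSpec(latents={"eta": ["y1", "y2"]},
                        regressions=[("eta", "exposure")],
                        residual_covariances=[("y1", "y2")],
                        ordinal=["y1", "y2"])
    rng = np.random.default_rng(8)
    data = simulate_target_model(0.3, 200, rng, n_indicators=2)
    with pytest.raises(ValueError, match="identified"):
        fit_sem(spec, data)


def test_sem_recovers_planted_path():
    rng = np.random.default_rng(9)
    spec = SemModelSpec(latents={"eta": ["y1", "y2", "y3", "y4"]},
                        regressions=[("eta", "exposure")],
                        ordinal=["y1", "y2", "y3", "y4"])
    ests = [fit_sem(spec, simulate_target_model(0.3, 250, rng)
                    ).estimate("eta~exposure") for _ in range(30)]
    assert np.mean(ests) == pytest.approx(0.3, abs=0.10)


def test_standardized_solution_invariant_to_exposure_rescaling():
    rng = np.random.default_rng(10)
    data = simulate_target_model(0.3, 400, rng)
    spec = SemModelSpec(latents={"eta": ["y1", "y2", "y3", "y4"]},
                        regressions=[("eta", "exposure")],
                        ordinal=["y1", "y2", "y3", "y4"])
    fit1 = fit_sem(spec, data)
    data10 = data.assign(exposure=data["exposure"] * 10)
    fit2 = fit_sem(spec, data10)
    assert fit1.estimate("eta~exposure") == pytest.approx(
        fit2.estimate("eta~exposure"), abs=1e-6)


def test_latent_hg_loading_order_follows_generating_strengths():
    """When childhood Hg and the binary threshold indicator dominate the latent
    exposure construct, their standardized loadings exceed the cord loading."""
    rng = np.random.default_rng(11)
    n = 500
    hg = rng.normal(size=n)
    cord = 0.4 * hg + rng.normal(scale=np.sqrt(1 - 0.4 ** 2), size=n)
    child = 0.85 * hg + rng.normal(scale=np.sqrt(1 - 0.85 ** 2), size=n)
    ever5 = (0.8 * hg + rng.normal(scale=0.6, size=n) > 0.5).astype(float)
    f = 0.4 * hg + rng.normal(scale=np.sqrt(1 - 0.4 ** 2), size=n)
    data = pd.DataFrame({
        "cord": cord, "child": child, "ever5": ever5,
        **{f"y{j}": _discretize(0.8 * f + rng.normal(scale=0.6, size=n))
           for j in range(4)}})
    spec = SemModelSpec(
        latents={"hg": ["cord", "child", "ever5"],
                 "eta": [f"y{j}" for j in range(4)]},
        regressions=[("eta", "hg")],
        ordinal=[f"y{j}" for j in range(4)] + ["ever5"])
    fit = fit_sem(spec, data)
    est = fit.estimates.set_index("parameter")["est"]
    assert est["child~hg"] > est["cord~hg"]
    assert est["ever5~hg"] > est["cord~hg"]


# ---------------------------------------------------------------------------
# mediation decomposition


def _manual_fit(spec: SemModelSpec, theta: np.ndarray) -> SemFit:
    model = _Model(spec)
    assert len(theta) == model.n_free
    return SemFit(spec=spec, estimates=pd.DataFrame(), fit_indices={}, N=0,
                  converged=True, residual_variances={}, heywood=[],
                  R=pd.DataFrame(), V=pd.DataFrame(), model=model,
                  theta=theta, weights=np.empty(0), pairs=[],
                  sample_vec=np.empty(0))


def test_decompose_chain_product_rule():
    spec = SemModelSpec(regressions=[("b", "a"), ("c", "b")])
    model = _Model(spec)
    theta = np.array([{"b~a": 0.5, "c~b": 0.4}[n] for n in model.param_names])
    eff = decompose_effects(_manual_fit(spec, theta), "a", "c")
    assert eff.direct == 0.0
    assert eff.indirect == pytest.approx(0.20)
    assert eff.total == pytest.approx(0.20)


def test_decompose_direct_plus_indirect():
    spec = SemModelSpec(regressions=[("c", "a"), ("b", "a"), ("c", "b")])
    model = _Model(spec)
    vals = {"c~a": 0.3, "b~a": 0.5, "c~b": 0.4}
    theta = np.array([vals[n] for n in model.param_names])
    eff = decompose_effects(_manual_fit(spec, theta), "a", "c")
    assert eff.direct == pytest.approx(0.3)
    assert eff.indirect == pytest.approx(0.2)
    assert eff.total == pytest.approx(0.5, abs=1e-10)


def test_decompose_matches_networkx_enumeration_on_random_dags():
    import networkx as nx

    rng = np.random.default_rng(12)
    for trial in range(20):
        n_nodes = int(rng.integers(3, 6))
        names = [f"v{i}" for i in range(n_nodes)]
        edges = [(names[j], names[i])     # child v_j <- parent v_i, i < j
                 for i in range(n_nodes) for j in range(i + 1, n_nodes)
                 if rng.random() < 0.6]
        if not edges:
            continue
        spec = SemModelSpec(regressions=edges)
        model = _Model(spec)
        rng2 = np.random.default_rng(trial)
        theta = rng2.uniform(-0.8, 0.8, model.n_free)
        fit = _manual_fit(spec, theta)
        coef = {(p, c): t for (kind, c, p), t in
                zip(model.param_kind, theta) if kind == "edge"}
        G = nx.DiGraph(list(coef))
        src, out = names[0], names[-1]
        eff = decompose_effects(fit, src, out)
        total_oracle = 0.0
        if G.has_node(src) and G.has_node(out):
            for path in nx.all_simple_paths(G, src, out):
                prod = np.prod([coef[(a, b)] for a, b in zip(path, path[1:])])
                total_oracle += prod
        assert eff.total == pytest.approx(total_oracle, abs=1e-12)
        assert eff.total == pytest.approx(eff.direct + eff.indirect, abs=1e-12)


# ---------------------------------------------------------------------------
# modification indices


def test_mi_flags_omitted_cross_loading():
    rng = np.random.default_rng(13)
    n = 500
    f = rng.multivariate_normal([0, 0], [[1, .3], [.3, 1]], size=n)
    cols = {}
    for k in range(2):
        for j in range(3):
            cols[f"c{k}y{j}"] = _discretize(
                0.8 * f[:, k] + rng.normal(scale=0.6, size=n))
    # one extra indicator of factor 0 that also loads 0.5 on factor 1
    cols["c0y3"] = _discretize(0.55 * f[:, 0] + 0.5 * f[:, 1]
                               + rng.normal(scale=0.55, size=n))
    data = pd.DataFrame(cols)
    fit = fit_cfa({"eta1": ["c0y0", "c0y1", "c0y2", "c0y3"],
                   "eta2": ["c1y0", "c1y1", "c1y2"]}, data)
    mi = modification_indices(fit)
    assert mi.iloc[0]["parameter"] == "c0y3~eta2"


def test_mi_calibrated_under_correct_specification():
    """With no misspecification each MI is approximately chi2(1): unit-scale
    mean and a modest tail.  (The maximum over ~10 candidates exceeds 3.84
    regularly even for an exactly calibrated score test, so calibration is
    asserted per candidate.)"""
    all_mi = []
    for seed in range(8):
        rng = np.random.default_rng(200 + seed)
        data = simulate_target_model(0.3, 400, rng, n_indicators=5)
        fit = fit_sem(SemModelSpec(
            latents={"eta": [f"y{j + 1}" for j in range(5)]},
            regressions=[("eta", "exposure")],
            ordinal=[f"y{j + 1}" for j in range(5)]), data)
        all_mi.extend(modification_indices(fit)["mi"].tolist())
    all_mi = np.asarray(all_mi)
    assert all_mi.mean() < 2.0          # chi2(1) mean is 1
    assert np.mean(all_mi > 3.84) < 0.2
    assert all_mi.max() < 25


def test_freeing_top_mi_drops_chi2_by_about_mi():
    rng = np.random.default_rng(14)
    n = 600
    f = rng.multivariate_normal([0, 0], [[1, .3], [.3, 1]], size=n)
    cols = {}
    for k in range(2):
        for j in range(3):
            cols[f"c{k}y{j}"] = _discretize(
                0.8 * f[:, k] + rng.normal(scale=0.6, size=n))
    cols["c0y3"] = _discretize(0.5 * f[:, 0] + 0.55 * f[:, 1]
                               + rng.normal(scale=0.55, size=n))
    data = pd.DataFrame(cols)
    base_meas = {"eta1": ["c0y0", "c0y1", "c0y2", "c0y3"],
                 "eta2": ["c1y0", "c1y1", "c1y2"]}
    fit = fit_cfa(base_meas, data)
    mi = modification_indices(fit)
    top = mi.iloc[0]
    assert top["parameter"] == "c0y3~eta2"
    freed = {"eta1": base_meas["eta1"], "eta2": base_meas["eta2"] + ["c0y3"]}
    refit = fit_cfa(freed, data)
    drop = fit.fit_indices["chi2"] - refit.fit_indices["chi2"]
    assert drop >= 0.5 * top["mi"]   # asymptotic score-test contract, loose


# ---------------------------------------------------------------------------
# moderation


def _two_group_data(n_per, effect_a, effect_b, seed):
    rng = np.random.default_rng(seed)
    da = simulate_target_model(effect_a, n_per, rng)
    db = simulate_target_model(effect_b, n_per, rng)
    da["sex"] = 0.0
    db["sex"] = 1.0
    return pd.concat([da, db], ignore_index=True)


MOD_SPEC = SemModelSpec(latents={"eta": ["y1", "y2", "y3", "y4"]},
                        regressions=[("eta", "exposure")],
                        ordinal=["y1", "y2", "y3", "y4"])


def test_moderation_df_bookkeeping_and_null():
    nonsig = 0
    for seed in range(8):
        data = _two_group_data(300, 0.3, 0.3, 300 + seed)
        res = moderation_test(MOD_SPEC, data, "sex", [("eta", "exposure")])
        assert res["df_constrained"] == res["df_free"] + 1
        nonsig += res["p"] > 0.05
    assert nonsig >= 6


def test_moderation_detects_planted_group_difference():
    detected = 0
    for seed in range(8):
        data = _two_group_data(300, 0.3, 0.0, 400 + seed)
        res = moderation_test(MOD_SPEC, data, "sex", [("eta", "exposure")])
        detected += res["p"] <= 0.05
    assert detected >= 0.7 * 8


# ---------------------------------------------------------------------------
# power


def test_sem_power_degenerate_and_monotone():
    res = sem_power(10, 242, 0.05, 0.05)
    assert res["power"] == pytest.approx(0.05)
    p_nota = sem_power(10, 242, 0.05, 0.10)["power"]
    p_notb = sem_power(10, 400, 0.05, 0.10)["power"]
    assert p_notb > p_nota > 0.05
    p_wide = sem_power(10, 242, 0.05, 0.14)["power"]
    assert p_wide > p_nota
    close = sem_power(10, 242, 0.05, 0.01)["power"]
    assert 0 < close <= 1
    with pytest.raises(ValueError):
        sem_power(0, 242, 0.05, 0.1)


def test_target_effect_power_detects_and_calibrates():
    strong = target_effect_power(0.5, 250, reps=30, seed=1)
    assert strong["power"] >= 0.8
    null = target_effect_power(0.0, 250, reps=60, seed=2)
    assert null["power"] <= 0.15
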
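"""Variable clustering: homogeneity criterion, hierarchy, pruning, stability."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from hgclust.synthetic import SyntheticParams, generate_cohort
from hgclust.varclust import (LikertMatrix, adjusted_rand, bootstrap_stability,
                              build_tree, cluster_homogeneity, composite_scores,
                              cronbach_alpha, cut_tree, prune_clusters, select_k,
                              driving_symptoms, StabilityProfile)

from conftest import exact_corr_columns, likert_of


# ---------------------------------------------------------------------------
# homogeneity


def test_homogeneity_single_column_is_one():
    col = pd.DataFrame({"a": np.random.default_rng(0).normal(size=50)})
    assert cluster_homogeneity(col) == pytest.approx(1.0)


@pytest.mark.parametrize("rho", [0.0, 0.3, 0.8, -0.5])
def test_homogeneity_pair_closed_form(rho):
    cols = exact_corr_columns(100, abs(rho), p=2, seed=1)
    if rho < 0:
        cols["v1"] = -cols["v1"]
    assert cluster_homogeneity(cols) == pytest.approx(1 + abs(rho), abs=1e-10)


@pytest.mark.parametrize("p", [3, 4, 7, 12])
def test_homogeneity_matches_eigen_oracle(p):
    rng = np.random.default_rng(p)
    X = pd.DataFrame(rng.normal(size=(200, p)) @ rng.normal(size=(p, p)))
    h = cluster_homogeneity(X)
    oracle = np.linalg.eigvalsh(np.corrcoef(X.to_numpy(), rowvar=False))[-1]
    assert h == pytest.approx(oracle, abs=1e-10)
    # and H equals the sum of squared correlations with the first PC
    corr = np.corrcoef(X.to_numpy(), rowvar=False)
    w = np.linalg.eigh(corr)[1][:, -1]
    Z = (X - X.mean()) / X.std(ddof=1)
    pc1 = Z.to_numpy() @ w
    ssq = sum(np.corrcoef(X.iloc[:, j], pc1)[0, 1] ** 2 for j in range(p))
    assert h == pytest.approx(ssq, abs=1e-8)


def test_homogeneity_zero_variance_column_named():
    X = pd.DataFrame({"ok": [1.0, 2, 3, 4], "flat": [2.0, 2, 2, 2]})
    with pytest.raises(ValueError, match="flat"):
        cluster_homogeneity(X)


# ---------------------------------------------------------------------------
# hierarchy


def _random_likert(n, p, seed):
    rng = np.random.default_rng(seed)
    return LikertMatrix(pd.DataFrame(
        rng.integers(1, 6, size=(n, p)).astype(float),
        columns=[f"s{i:02d}" for i in range(p)]))


def test_first_merge_joins_perfectly_correlated_pair():
    rng = np.random.default_rng(2)
    base = rng.integers(1, 6, size=200).astype(float)
    data = LikertMatrix(pd.DataFrame({
        "a": base, "b": base,
        "c": rng.integers(1, 6, size=200).astype(float)}))
    tree = build_tree(data)
    first_a, first_b, d = tree.merges[0]
    assert first_a | first_b == frozenset({"a", "b"})
    assert d == pytest.approx(0.0, abs=1e-10)


@pytest.mark.parametrize("seed", range(5))
def test_first_merge_equals_exhaustive_pair_search(seed):
    data = _random_likert(100, 6, seed)
    tree = build_tree(data)
    corr = data.correlation()
    # oracle: evaluate d = 2 - (1 + |r|) over all 15 pairs
    best = min(((1.0 - abs(corr.loc[a, b]), tuple(sorted((a, b))))
                for a, b in combinations(data.symptom_ids, 2)))
    a, b, d = tree.merges[0]
    assert tuple(sorted(a | b)) == best[1]
    assert d == pytest.approx(best[0], abs=1e-10)


def test_total_homogeneity_path_nonincreasing_and_ends_at_lambda1(default_cohort):
    data = likert_of(default_cohort)
    tree = build_tree(data)
    assert len(tree.merges) == len(data.symptom_ids) - 1
    assert all(d >= 0 for _, _, d in tree.merges)
    path = np.asarray(tree.homogeneity_path)
    assert (np.diff(path) <= 1e-9).all()
    lam1 = np.linalg.eigvalsh(data.correlation().to_numpy())[-1]
    assert path[-1] == pytest.approx(lam1, abs=1e-8)


def test_cut_tree_limits_and_errors(two_cluster_likert):
    tree = build_tree(two_cluster_likert)
    p = len(tree.labels)
    singles = cut_tree(tree, p)
    assert len(set(singles.values())) == p
    everyone = cut_tree(tree, 1)
    assert set(everyone.values()) == {0}
    with pytest.raises(ValueError):
        cut_tree(tree, 0)
    with pytest.raises(ValueError):
        cut_tree(tree, p + 1)


def test_planted_two_clusters_recovered():
    hits = 0
    for seed in range(20):
        c = generate_cohort(SyntheticParams(
            n_participants=400, cluster_sizes=(5, 5), n_noise_symptoms=0,
            beta_hg=(0.3, 0.3), loading_range=(0.8, 0.9),
            missing_rate=0.0, seed=seed))
        data = likert_of(c)
        part = cut_tree(build_tree(data), 2)
        hits += adjusted_rand(part, c.truth["partition"]) == 1.0
    assert hits >= 19   # >= 95% of seeds


# ---------------------------------------------------------------------------
# composites and pruning


def test_composite_single_variable_cluster(two_cluster_likert):
    ids = two_cluster_likert.symptom_ids
    partition = {ids[0]: 0}
    sol = composite_scores(
        LikertMatrix(two_cluster_likert.values[[ids[0]]]), partition)
    z = two_cluster_likert.standardized()[ids[0]]
    np.testing.assert_allclose(sol.composite_scores.iloc[:, 0], z, atol=1e-10)
    assert sol.squared_loadings[ids[0]] == pytest.approx(1.0)


def test_composite_pair_explained_prop_closed_form():
    rho = 0.6
    cols = exact_corr_columns(300, rho, p=2, seed=4)
    lik = (1 + np.searchsorted(np.array([-1.2, -0.4, 0.4, 1.2]),
                               cols.to_numpy())).astype(float)
    data = LikertMatrix(pd.DataFrame(lik, columns=["a", "b"]))
    sol = composite_scores(data, {"a": 0, "b": 0})
    r = data.correlation().loc["a", "b"]
    assert sol.explained_prop[0] == pytest.approx((1 + r) / 2, abs=1e-10)


def test_composite_orientation_and_loading_vs_eigen_oracle(clean_two_cluster):
    data = likert_of(clean_two_cluster)
    sol = composite_scores(data, clean_two_cluster.truth["partition"])
    for k in (0, 1):
        members = sol.members(k)
        score = sol.composite_scores[f"score_cluster{k + 1}"]
        item_mean = data.values[members].mean(axis=1)
        assert score.corr(item_mean) >= 0
        corr = data.correlation().loc[members, members].to_numpy()
        lam1 = np.linalg.eigvalsh(corr)[-1]
        mean_sq = np.mean([sol.squared_loadings[m] for m in members])
        assert mean_sq == pytest.approx(lam1 / len(members), abs=0.05)


def test_prune_is_fixpoint_when_all_strong():
    # loadings 0.85+ keep every item's squared loading clear of the 0.6 cut
    c = generate_cohort(SyntheticParams(
        n_participants=400, cluster_sizes=(5, 5), n_noise_symptoms=0,
        beta_hg=(0.3, 0.3), loading_range=(0.85, 0.92),
        missing_rate=0.0, seed=3))
    data = likert_of(c)
    sol = composite_scores(data, c.truth["partition"])
    assert all(r2 >= 0.6 for r2 in sol.squared_loadings.values())
    pruned = prune_clusters(data, sol)
    assert pruned.partition == sol.partition
    assert pruned.dropped_symptoms == []
    assert all(pruned.retained.values())


def test_prune_is_fixpoint_when_all_strong_fixture(clean_two_cluster):
    data = likert_of(clean_two_cluster)
    sol = composite_scores(data, clean_two_cluster.truth["partition"])
    pruned = prune_clusters(data, sol, min_sq_corr=0.3)
    assert pruned.partition == sol.partition
    assert pruned.dropped_symptoms == []


def test_prune_removes_planted_noise_symptom():
    c = generate_cohort(SyntheticParams(
        n_participants=400, cluster_sizes=(6,), n_noise_symptoms=1,
        beta_hg=(0.3,), loading_range=(0.85, 0.9), missing_rate=0.0, seed=6))
    data = likert_of(c)
    noise = [s for s, k in c.truth["partition"].items() if k == -1]
    partition = {s: 0 for s in data.symptom_ids}
    pruned = prune_clusters(data, composite_scores(data, partition))
    assert set(pruned.dropped_symptoms) == set(noise)
    assert set(pruned.partition) == set(data.symptom_ids) - set(noise)


def test_prune_flags_degenerate_cluster():
    rng = np.random.default_rng(9)
    cols = pd.DataFrame(rng.integers(1, 6, size=(150, 2)).astype(float),
                        columns=["a", "b"])
    data = LikertMatrix(cols)
    pruned = prune_clusters(data, composite_scores(data, {"a": 0, "b": 0}),
                            min_sq_corr=0.99)
    assert any(pruned.degenerate.values())


def test_driving_symptom_is_max_loading(clean_two_cluster):
    data = likert_of(clean_two_cluster)
    sol = composite_scores(data, clean_two_cluster.truth["partition"])
    for k, s in driving_symptoms(sol).items():
        assert sol.squared_loadings[s] == max(
            sol.squared_loadings[m] for m in sol.members(k))


# ---------------------------------------------------------------------------
# reliability


def test_cronbach_closed_forms():
    # two parallel items with correlation 0.5: Spearman-Brown 2r/(1+r)
    cols = exact_corr_columns(200, 0.5, p=2, seed=7)
    assert cronbach_alpha(cols) == pytest.approx(2 * 0.5 / 1.5, abs=1e-10)
    # nine items, equicorrelation 0.5: p r / (1 + (p-1) r) = 0.9
    cols9 = exact_corr_columns(200, 0.5, p=9, seed=8)
    assert cronbach_alpha(cols9) == pytest.approx(0.9, abs=1e-10)
    # uncorrelated items: alpha ~ 0
    cols0 = exact_corr_columns(200, 0.0, p=4, seed=9)
    assert cronbach_alpha(cols0) == pytest.approx(0.0, abs=1e-10)
    with pytest.raises(ValueError):
        cronbach_alpha(cols[["v0"]])


# ---------------------------------------------------------------------------
# adjusted Rand


def test_ari_identity_and_label_invariance():
    p1 = {"a": 0, "b": 0, "c": 1, "d": 1}
    assert adjusted_rand(p1, p1) == pytest.approx(1.0)
    relabeled = {k: {0: 7, 1: 3}[v] for k, v in p1.items()}
    assert adjusted_rand(p1, relabeled) == pytest.approx(1.0)


def test_ari_crossed_quartet_is_minus_half():
    p1 = {"a": 0, "b": 0, "c": 1, "d": 1}
    p2 = {"a": 0, "b": 1, "c": 0, "d": 1}
    assert adjusted_rand(p1, p2) == pytest.approx(-0.5)


def test_ari_matches_sklearn_on_random_partitions():
    rng = np.random.default_rng(10)
    items = [f"i{j}" for j in range(30)]
    for _ in range(25):
        p1 = {i: int(rng.integers(0, 4)) for i in items}
        p2 = {i: int(rng.integers(0, 4)) for i in items}
        mine = adjusted_rand(p1, p2)
        ref = adjusted_rand_score([p1[i] for i in items], [p2[i] for i in items])
        assert mine == pytest.approx(ref, abs=1e-12)
        assert mine == pytest.approx(adjusted_rand(p2, p1), abs=1e-12)


def test_ari_label_mismatch_raises():
    with pytest.raises(ValueError):
        adjusted_rand({"a": 0}, {"b": 0})


# ---------------------------------------------------------------------------
# stability and K selection


def test_bootstrap_stability_deterministic(two_cluster_likert):
    a = bootstrap_stability(two_cluster_likert, [2, 3], B=8, seed=42)
    b = bootstrap_stability(two_cluster_likert, [2, 3], B=8, seed=42)
    pd.testing.assert_frame_equal(a.table, b.table)


def test_bootstrap_stability_separated_clusters(two_cluster_likert):
    prof = bootstrap_stability(two_cluster_likert, [2], B=20, seed=1)
    assert prof.table.loc[0, "mean_ari"] >= 0.9


def test_bootstrap_stability_pure_noise_near_zero():
    data = _random_likert(200, 10, seed=13)
    prof = bootstrap_stability(data, [3], B=20, seed=2)
    assert abs(prof.table.loc[0, "mean_ari"]) < 0.2


def test_select_k_recovers_planted_six():
    hits = 0
    for seed in range(8):
        c = generate_cohort(SyntheticParams(seed=seed, n_noise_symptoms=0,
                                            missing_rate=0.0))
        data = likert_of(c)
        stab = bootstrap_stability(data, range(4, 9), B=15, seed=seed)
        K, diag = select_k(build_tree(data), stab)
        hits += K == 6
        assert {"K", "mean_ari", "aggregation_gap"} <= set(diag.columns)
    assert hits >= 7   # >= 90% of seeds


def test_select_k_tie_breaks_on_aggregation_gap(two_cluster_likert):
    tree = build_tree(two_cluster_likert)
    tied = StabilityProfile(table=pd.DataFrame(
        {"K": [2, 5], "mean_ari": [0.8, 0.8], "sd_ari": [0.1, 0.1],
         "B_effective": [10, 10]}), B=10, seed=0)
    K, diag = select_k(tree, tied)
    gaps = diag.set_index("K")["aggregation_gap"]
    assert K == int(gaps.idxmax())


# ---------------------------------------------------------------------------
# LikertMatrix validation


# hypothesis property checks: ARI bounds/symmetry and subadditivity of the
# homogeneity criterion under merging


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.lists(st.integers(0, 3), min_size=4, max_size=20),
       st.lists(st.integers(0, 3), min_size=4, max_size=20))
def test_ari_bounds_and_symmetry_property(l1, l2):
    n = min(len(l1), len(l2))
    items = [f"i{j}" for j in range(n)]
    p1 = dict(zip(items, l1))
    p2 = dict(zip(items, l2))
    a = adjusted_rand(p1, p2)
    assert -1.0 - 1e-12 <= a <= 1.0 + 1e-12
    assert a == pytest.approx(adjusted_rand(p2, p1), abs=1e-12)
    assert adjusted_rand(p1, p1) == pytest.approx(1.0)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.integers(0, 10_000), st.integers(2, 5), st.integers(2, 5))
def test_merging_never_increases_total_homogeneity_property(seed, pa, pb):
    """H(A u B) <= H(A) + H(B): the leading eigenvalue of a union cannot beat
    the sum of the parts' leading eigenvalues."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(60, pa + pb)) @ rng.normal(size=(pa + pb, pa + pb))
    df = pd.DataFrame(X)
    ha = cluster_homogeneity(df.iloc[:, :pa])
    hb = cluster_homogeneity(df.iloc[:, pa:])
    hu = cluster_homogeneity(df)
    assert hu <= ha + hb + 1e-9


def test_likert_matrix_rejects_bad_values():
    with pytest.raises(ValueError, match="non-Likert"):
        LikertMatrix(pd.DataFrame({"a": [1.0, 6.0, 2.0]}))
    with pytest.raises(ValueError, match="distinct"):
        LikertMatrix(pd.DataFrame({"a": [2.0, 2.0, 2.0], "b": [1.0, 2.0, 3.0]}))
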
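"""Variable clustering of ordinal symptom batteries.

Symptoms are clustered by hierarchically maximising a homogeneity criterion:
the homogeneity H of a set of variables is the leading eigenvalue of their
correlation matrix, i.e. the sum of squared correlations of the members with
the set's first principal component.  Agglomeration starts from singletons and
at each step merges the pair of clusters with the smallest homogeneity loss
d(A, B) = H(A) + H(B) - H(A u B) >= 0.  Each cluster is then represented by a
composite variable (its first-principal-component score, oriented so that
higher scores mean more frequent symptoms), clusters are pruned on explained
variance and item-composite squared correlation, and partition stability is
assessed with a bootstrapped mean adjusted Rand index.

Likert items are treated as numeric 1-5 scores and standardised, under which
the mixed-data PCA criterion reduces to ordinary standardized PCA.  Missing
cells enter correlation matrices through pairwise-complete observations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import comb

logger = logging.getLogger(__name__)

LIKERT_LEVELS = frozenset({1.0, 2.0, 3.0, 4.0, 5.0})


@dataclass
class LikertMatrix:
    """Participants x symptoms ordinal matrix (1-5; NaN allowed)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        obs = self.values.stack()
        bad = set(np.unique(obs)) - set(LIKERT_LEVELS)
        if bad:
            raise ValueError(f"non-Likert values present: {sorted(bad)}")
        nuniq = self.values.nunique(dropna=True)
        flat = nuniq[nuniq < 2].index.tolist()
        if flat:
            raise ValueError(f"columns with <2 distinct observed values: {flat}")

    @property
    def symptom_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def participant_ids(self) -> list:
        return list(self.values.index)

    def standardized(self) -> pd.DataFrame:
        z = self.values.astype(float)
        return (z - z.mean()) / z.std(ddof=1)

    def correlation(self) -> pd.DataFrame:
        return self.values.astype(float).corr(min_periods=2)


@dataclass
class VarTree:
    """Hierarchy of merges; ``merges[t] = (cluster_a, cluster_b, d)``."""

    merges: list[tuple[frozenset, frozenset, float]]
    homogeneity_path: list[float]
    labels: list[str]


@dataclass
class ClusterSolution:
    K: int
    partition: dict[str, int]
    composite_scores: pd.DataFrame
    squared_loadings: dict[str, float]
    explained_prop: dict[int, float]
    cronbach: dict[int, float]
    retained: dict[int, bool]
    degenerate: dict[int, bool] = field(default_factory=dict)
    dropped_symptoms: list[str] = field(default_factory=list)

    def members(self, k: int) -> list[str]:
        return [s for s, c in self.partition.items() if c == k]


@dataclass
class StabilityProfile:
    table: pd.DataFrame   # columns K, mean_ari, sd_ari, B_effective
    B: int
    seed: int


# ---------------------------------------------------------------------------
# homogeneity and the hierarchy


def cluster_homogeneity(columns: pd.DataFrame | np.ndarray) -> float:
    """Leading eigenvalue of the columns' correlation matrix.

    Equals the sum of squared correlations of the members with their first
    principal component; 1.0 for a single column, 1 + |r| for a pair.
    """
    df = pd.DataFrame(columns).astype(float)
    sd = df.std(ddof=1)
    dead = sd[(sd == 0) | sd.isna()].index.tolist()
    if dead:
        raise ValueError(f"zero-variance column(s): {dead}")
    if df.shape[1] == 1:
        return 1.0
    corr = df.corr(min_periods=2).to_numpy()
    return float(np.linalg.eigvalsh(corr)[-1])


def _h_from_corr(corr: np.ndarray, idx: tuple[int, ...]) -> float:
    if len(idx) == 1:
        return 1.0
    if len(idx) == 2:
        return 1.0 + abs(corr[idx[0], idx[1]])
    sub = corr[np.ix_(idx, idx)]
    return float(np.linalg.eigvalsh(sub)[-1])


def build_tree(data: LikertMatrix) -> VarTree:
    """Agglomerate singleton variables by minimal homogeneity loss.

    Ties are broken toward the merge whose lexicographically smallest member
    label is smallest (then the second cluster's).
    """
    labels = data.symptom_ids
    p = len(labels)
    if p < 2:
        raise ValueError("need at least 2 columns to build a hierarchy")
    corr = data.correlation().to_numpy()
    if np.isnan(corr).any():
        raise ValueError("correlation matrix has missing entries "
                         "(a column pair with <2 joint observations)")

    clusters: dict[frozenset, tuple[int, ...]] = {
        frozenset([lab]): (i,) for i, lab in enumerate(labels)}
    h: dict[frozenset, float] = {c: 1.0 for c in clusters}
    merges: list[tuple[frozenset, frozenset, float]] = []
    path: list[float] = []

    def sort_key(c: frozenset) -> str:
        return min(c)

    # pairwise d cache
    d: dict[tuple[frozenset, frozenset], float] = {}

    def dis(a: frozenset, b: frozenset) -> float:
        key = (a, b) if sort_key(a) <= sort_key(b) else (b, a)
        if key not in d:
            union = tuple(sorted(clusters[a] + clusters[b]))
            d[key] = h[a] + h[b] - _h_from_corr(corr, union)
        return d[key]

    total = float(p)
    while len(clusters) > 1:
        items = sorted(clusters, key=sort_key)
        best = None
        for a, b in combinations(items, 2):
            cand = (dis(a, b), sort_key(a), sort_key(b))
            if best is None or cand < best[0:3]:
                best = (*cand, a, b)
        dd, _, _, a, b = best
        union = a | b
        union_idx = tuple(sorted(clusters[a] + clusters[b]))
        h_union = _h_from_corr(corr, union_idx)
        assert h_union <= h[a] + h[b] + 1e-9, "merge increased total homogeneity"
        for key in list(d):
            if a in key or b in key:
                del d[key]
        del clusters[a], clusters[b], h[a], h[b]
        clusters[union] = union_idx
        h[union] = h_union
        total = total - dd
        merges.append((a, b, float(max(dd, 0.0))))
        path.append(total)
    return VarTree(merges=merges, homogeneity_path=path, labels=labels)


def cut_tree(tree: VarTree, K: int) -> dict[str, int]:
    """Partition with exactly K clusters: replay the first p-K merges."""
    p = len(tree.labels)
    if not 1 <= K <= p:
        raise ValueError(f"K={K} outside [1, {p}]")
    groups: dict[frozenset, None] = {frozenset([lab]): None for lab in tree.labels}
    for a, b, _ in tree.merges[: p - K]:
        del groups[a], groups[b]
        groups[a | b] = None
    ordered = sorted(groups, key=min)
    return {lab: k for k, g in enumerate(ordered) for lab in sorted(g)}


# ---------------------------------------------------------------------------
# composites, pruning, reliability


def _pc1_scores(z: pd.DataFrame, corr: np.ndarray) -> tuple[pd.Series, float]:
    """First-PC scores of standardized members; available-item mean imputation
    when at least half the items are observed, else missing."""
    w = np.linalg.eigh(corr)[1][:, -1]
    lam1 = float(np.linalg.eigvalsh(corr)[-1])
    zz = z.to_numpy()
    observed = ~np.isnan(zz)
    row_mean = np.nanmean(np.where(observed, zz, np.nan), axis=1)
    filled = np.where(observed, zz, row_mean[:, None])
    enough = observed.sum(axis=1) * 2 >= zz.shape[1]
    scores = filled @ w
    scores[~enough] = np.nan
    s = pd.Series(scores, index=z.index)
    # orient: composite must correlate non-negatively with the item mean
    item_mean = pd.Series(row_mean, index=z.index)
    c = s.corr(item_mean)
    if c is not None and not np.isnan(c) and c < 0:
        s = -s
    return s, lam1


def composite_scores(data: LikertMatrix, partition: dict[str, int]) -> ClusterSolution:
    """Composite (first-PC) score per cluster plus loadings and reliability."""
    missing = set(partition) - set(data.symptom_ids)
    if missing:
        raise ValueError(f"partition names unknown symptoms: {sorted(missing)}")
    z = data.standardized()
    ks = sorted(set(partition.values()))
    scores, sq, expl, cron = {}, {}, {}, {}
    for k in ks:
        members = sorted(s for s, c in partition.items() if c == k)
        zk = z[members]
        if len(members) == 1:
            s = zk.iloc[:, 0]
            scores[k] = s
            sq[members[0]] = 1.0
            expl[k] = 1.0
            cron[k] = np.nan
            continue
        corr = zk.corr(min_periods=2).to_numpy()
        s, lam1 = _pc1_scores(zk, corr)
        scores[k] = s
        expl[k] = lam1 / len(members)
        for m in members:
            r = z[m].corr(s)
            sq[m] = float(r ** 2) if not np.isnan(r) else np.nan
        cron[k] = cronbach_alpha(data.values[members])
    comp = pd.DataFrame({f"score_cluster{k + 1}": v for k, v in scores.items()})
    return ClusterSolution(
        K=len(ks), partition=dict(partition), composite_scores=comp,
        squared_loadings=sq, explained_prop=expl, cronbach=cron,
        retained={k: True for k in ks})


def prune_clusters(data: LikertMatrix, solution: ClusterSolution,
                   min_explained: float = 0.5,
                   min_sq_corr: float = 0.6,
                   max_iter: int = 20) -> ClusterSolution:
    """Iteratively drop weak symptoms and flag weak clusters.

    Symptoms with squared item-composite correlation below ``min_sq_corr`` are
    removed and composites recomputed until a fixpoint; clusters whose explained
    proportion stays below ``min_explained`` are marked not retained.  Clusters
    reduced below 2 members are flagged degenerate rather than silently dropped.
    """
    partition = dict(solution.partition)
    dropped: list[str] = []
    degenerate_flags: set[int] = set()
    current = solution
    for _ in range(max_iter):
        weak_by_cluster: dict[int, list[str]] = {}
        for s, r2 in current.squared_loadings.items():
            if not np.isnan(r2) and r2 < min_sq_corr:
                weak_by_cluster.setdefault(current.partition[s], []).append(s)
        to_drop: list[str] = []
        for k, weak in weak_by_cluster.items():
            members = current.members(k)
            if len(members) - len(weak) < 2:
                # dropping would leave fewer than 2 members: flag, keep intact
                degenerate_flags.add(k)
                logger.warning("cluster %d degenerate after pruning; kept intact", k)
                continue
            to_drop.extend(weak)
        if not to_drop:
            break
        for s in to_drop:
            partition.pop(s)
            dropped.append(s)
        current = composite_scores(data, partition)
    degenerate = {k: (k in degenerate_flags or len(current.members(k)) < 2)
                  for k in current.explained_prop}
    retained = {k: (current.explained_prop[k] >= min_explained and not degenerate[k])
                for k in current.explained_prop}
    return ClusterSolution(
        K=current.K, partition=current.partition,
        composite_scores=current.composite_scores,
        squared_loadings=current.squared_loadings,
        explained_prop=current.explained_prop, cronbach=current.cronbach,
        retained=retained, degenerate=degenerate, dropped_symptoms=dropped)


def cronbach_alpha(columns: pd.DataFrame) -> float:
    """Cronbach's alpha, complete-case: (p/(p-1)) * (1 - sum(var_i)/var(sum))."""
    df = pd.DataFrame(columns).dropna().astype(float)
    p = df.shape[1]
    if p < 2:
        raise ValueError("Cronbach alpha needs at least 2 columns")
    item_var = df.var(ddof=1).sum()
    total_var = df.sum(axis=1).var(ddof=1)
    return float(p / (p - 1) * (1.0 - item_var / total_var))


# ---------------------------------------------------------------------------
# partition agreement and stability


def adjusted_rand(p1: dict[str, int], p2: dict[str, int]) -> float:
    """Hubert-Arabie adjusted Rand index from the contingency table."""
    if set(p1) != set(p2):
        raise ValueError("partitions must cover the same items")
    items = sorted(p1)
    a = pd.Categorical([p1[i] for i in items]).codes
    b = pd.Categorical([p2[i] for i in items]).codes
    ct = pd.crosstab(a, b).to_numpy()
    nij = comb(ct, 2).sum()
    ai = comb(ct.sum(axis=1), 2).sum()
    bj = comb(ct.sum(axis=0), 2).sum()
    n2 = comb(len(items), 2)
    expected = ai * bj / n2
    max_index = (ai + bj) / 2.0
    if max_index == expected:   # both partitions trivial
        return 1.0
    return float((nij - expected) / (max_index - expected))


def bootstrap_stability(data: LikertMatrix, K_range, B: int = 60,
                        seed: int = 0) -> StabilityProfile:
    """Mean adjusted Rand index between bootstrap and full-data partitions.

    Participants (rows) are resampled with replacement B times; each bootstrap
    sample is re-clustered once and its hierarchy cut at every K in ``K_range``.
    Replicates where a column collapses to a constant are dropped and counted.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    K_range = sorted(K_range)
    rng = np.random.default_rng(seed)
    full_tree = build_tree(data)
    reference = {K: cut_tree(full_tree, K) for K in K_range}
    ari: dict[int, list[float]] = {K: [] for K in K_range}
    dropped = 0
    n = data.values.shape[0]
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        sample = data.values.iloc[idx]
        try:
            boot = LikertMatrix(sample.reset_index(drop=True))
            tree = build_tree(boot)
        except ValueError:
            dropped += 1
            logger.warning("bootstrap replicate dropped (degenerate column)")
            continue
        for K in K_range:
            ari[K].append(adjusted_rand(cut_tree(tree, K), reference[K]))
    rows = [{"K": K,
             "mean_ari": float(np.mean(ari[K])) if ari[K] else np.nan,
             "sd_ari": float(np.std(ari[K], ddof=1)) if len(ari[K]) > 1 else np.nan,
             "B_effective": len(ari[K])}
            for K in K_range]
    return StabilityProfile(table=pd.DataFrame(rows), B=B, seed=seed)


def select_k(tree: VarTree, stability: StabilityProfile,
             K_range=None) -> tuple[int, pd.DataFrame]:
    """Pick K maximising mean bootstrap ARI; ties go to the larger aggregation gap.

    The aggregation gap at K is the jump in merge dissimilarity between the merge
    that reduces K+1 clusters to K and the one that reduces K to K-1 — a large gap
    means the hierarchy resists merging below K.  Returns (K, diagnostics table).
    """
    tab = stability.table.copy()
    if K_range is not None:
        tab = tab[tab["K"].isin(list(K_range))]
    if tab.empty:
        raise ValueError("empty K range")
    p = len(tree.labels)
    dvals = [m[2] for m in tree.merges]

    def gap(K: int) -> float:
        nxt = dvals[p - K] if 0 <= p - K < len(dvals) else np.nan   # K -> K-1
        prv = dvals[p - K - 1] if 0 <= p - K - 1 < len(dvals) else 0.0
        return float(nxt - prv) if not np.isnan(nxt) else -np.inf

    tab = tab.assign(aggregation_gap=[gap(int(k)) for k in tab["K"]])
    best_ari = tab["mean_ari"].max()
    tied = tab[np.isclose(tab["mean_ari"], best_ari)]
    if len(tied) > 1:
        logger.info("select_k tie on mean ARI among K=%s; using aggregation gap",
                    tied["K"].tolist())
    chosen = int(tied.sort_values(["aggregation_gap", "K"],
                                  ascending=[False, True])["K"].iloc[0])
    return chosen, tab


def driving_symptoms(solution: ClusterSolution) -> dict[int, str]:
    """Max squared-loading member per cluster (an interpretive summary only)."""
    out = {}
    for k in solution.explained_prop:
        members = solution.members(k)
        out[k] = max(members, key=lambda s: solution.squared_loadings.get(s, -1))
    return out
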
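"""Structural equation models for ordinal symptom indicators.

The measurement layer estimates a heterogeneous correlation matrix — polychoric
for ordinal pairs, polyserial for ordinal-continuous, Pearson for continuous —
under the usual underlying-bivariate-normal model with two-step ML (thresholds
from the margins, then one-dimensional ML for each correlation).

The structural layer fits an acyclic system of standardized linear equations to
that matrix by diagonally weighted least squares (DWLS): every variable, latent
or observed, is scaled to unit variance, so estimated loadings and path
coefficients are directly the standardized solution and the model-implied
matrix is itself a correlation matrix.  Residual variances are the implicit
complements 1 - explained and are not free parameters.

Inference uses a sandwich covariance with a Pearson-Filon-structured asymptotic
covariance of the correlation estimates, rescaled to the per-element two-step ML
variances.  Fit statistics (chi2/df, CFI, TLI, RMSEA with 90% CI, SRMR, AIC,
BIC) are recomputed from the discrepancy, the model df and N; modification
indices are score tests on candidate fixed parameters; mediation is decomposed
by path enumeration; moderation is a multi-group equality-constraint test; and
power follows the noncentral-chi2 RMSEA framework plus Monte-Carlo rejection
rates for a target path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

_SQRT_TINY = 1e-12


# ---------------------------------------------------------------------------
# bivariate normal CDF (Genz quadrature, vectorised over (h, k) for scalar r)

_GL_NODES = {
    6: (np.array([0.9324695142031522, 0.6612093864662647, 0.2386191860831970]),
        np.array([0.1713244923791705, 0.3607615730481384, 0.4679139345726904])),
    12: (np.array([0.9815606342467191, 0.9041172563704750, 0.7699026741943050,
                   0.5873179542866171, 0.3678314989981802, 0.1252334085114692]),
         np.array([0.04717533638651177, 0.1069393259953183, 0.1600783285433464,
                   0.2031674267230659, 0.2334925365383547, 0.2491470458134029])),
    20: (np.array([0.9931285991850949, 0.9639719272779138, 0.9122344282513259,
                   0.8391169718222188, 0.7463319064601508, 0.6360536807265150,
                   0.5108670019508271, 0.3737060887154196, 0.2277858511416451,
                   0.07652652113349733]),
         np.array([0.01761400713915212, 0.04060142980038694, 0.06267204833410906,
                   0.08327674157670475, 0.1019301198172404, 0.1181945319615184,
                   0.1316886384491766, 0.1420961093183821, 0.1491729864726037,
                   0.1527533871307259])),
}


def _gl_rule(r: float):
    a = abs(r)
    if a < 0.3:
        return _GL_NODES[6]
    if a < 0.75:
        return _GL_NODES[12]
    return _GL_NODES[20]


def _phi(x):
    return stats.norm.cdf(x)


def bvn_upper(h, k, r: float) -> np.ndarray:
    """P(X > h, Y > k) for standard bivariate normal with correlation r."""
    h = np.atleast_1d(np.asarray(h, dtype=float))
    k = np.atleast_1d(np.asarray(k, dtype=float))
    x, w = _gl_rule(r)
    nodes = np.concatenate([(1 - x) / 2, (1 + x) / 2])
    wts = np.concatenate([w, w]) / 2
    if abs(r) < 0.925:
        hk = h * k
        hs = (h * h + k * k) / 2
        asr = np.arcsin(r)
        sn = np.sin(asr * nodes)                        # quadrature points
        ex = np.exp((hk[:, None] * sn[None, :] - hs[:, None]) / (1 - sn ** 2)[None, :])
        bvn = (ex @ wts) * asr / (2 * np.pi) + _phi(-h) * _phi(-k)
        return np.clip(bvn, 0.0, 1.0)
    # high-correlation branch (Genz): work with sgn(r) * k
    sgn = np.sign(r)
    k2 = sgn * k
    hk = h * k2
    bvn = np.zeros_like(h)
    if abs(r) < 1:
        ass = (1 - r) * (1 + r)
        a = np.sqrt(ass)
        bs = (h - k2) ** 2
        c = (4 - hk) / 8
        d = (12 - hk) / 16
        asr = -(bs / ass + hk) / 2
        m = asr > -100
        bvn[m] = (a * np.exp(asr[m])
                  * (1 - c[m] * (bs[m] - ass) * (1 - d[m] * bs[m] / 5) / 3
                     + c[m] * d[m] * ass * ass / 5))
        m2 = -hk < 100
        b = np.sqrt(bs)
        bvn[m2] -= (np.exp(-hk[m2] / 2) * np.sqrt(2 * np.pi) * _phi(-b[m2] / a)
                    * b[m2] * (1 - c[m2] * bs[m2] * (1 - d[m2] * bs[m2] / 5) / 3))
        a2 = a / 2
        for xi, wi in zip(nodes, wts):
            xs = (a2 * 2 * xi) ** 2
            rs = np.sqrt(1 - xs)
            asr1 = -(bs / xs + hk) / 2
            m3 = asr1 > -100
            bvn[m3] += (a2 * 2 * wi * np.exp(asr1[m3])
                        * (np.exp(-hk[m3] * (1 - rs) / (2 * (1 + rs))) / rs
                           - (1 + c[m3] * xs * (1 + d[m3] * xs))))
        bvn = -bvn / (2 * np.pi)
    if sgn > 0:
        bvn = bvn + _phi(-np.maximum(h, k2))
    else:
        bvn = -bvn + np.maximum(0.0, _phi(k2) - _phi(h))
    return np.clip(bvn, 0.0, 1.0)


def bvn_cdf(h, k, r: float) -> np.ndarray:
    """P(X <= h, Y <= k) for a standard bivariate normal with correlation r."""
    return bvn_upper(-np.asarray(h, dtype=float), -np.asarray(k, dtype=float), r)


# ---------------------------------------------------------------------------
# polychoric / polyserial layer


def _thresholds(col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Category codes (0..K-1) and ML thresholds from marginal proportions."""
    vals = np.unique(col[~np.isnan(col)])
    codes = np.searchsorted(vals, col).astype(float)
    codes[np.isnan(col)] = np.nan
    cum = np.array([(col <= v).sum() for v in vals[:-1]]) / np.sum(~np.isnan(col))
    return codes, stats.norm.ppf(cum)


def _cell_probs(tau_a: np.ndarray, tau_b: np.ndarray, r: float) -> np.ndarray:
    a = np.concatenate([[-np.inf], tau_a, [np.inf]])
    b = np.concatenate([[-np.inf], tau_b, [np.inf]])
    A, B = np.meshgrid(a, b, indexing="ij")
    # cumulative probabilities on the grid; infinite bounds via marginals
    G = np.zeros_like(A)
    finite = np.isfinite(A) & np.isfinite(B)
    G[finite] = bvn_cdf(A[finite], B[finite], r)
    G[np.isposinf(A) & np.isfinite(B)] = _phi(B[np.isposinf(A) & np.isfinite(B)])
    G[np.isfinite(A) & np.isposinf(B)] = _phi(A[np.isfinite(A) & np.isposinf(B)])
    G[np.isposinf(A) & np.isposinf(B)] = 1.0
    P = G[1:, 1:] - G[:-1, 1:] - G[1:, :-1] + G[:-1, :-1]
    return np.clip(P, 1e-12, 1.0)


def polychoric(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-step ML polychoric correlation and its asymptotic variance.

    Thresholds are fixed at their marginal estimates; the correlation maximises
    the bivariate contingency likelihood.  Empty cells are handled by the
    probability floor inside the likelihood.
    """
    m = ~(np.isnan(x) | np.isnan(y))
    x, y = x[m], y[m]
    cx, ta = _thresholds(x)
    cy, tb = _thresholds(y)
    table = np.zeros((len(ta) + 1, len(tb) + 1))
    for i, j in zip(cx.astype(int), cy.astype(int)):
        table[i, j] += 1

    def nll(r):
        return -np.sum(table * np.log(_cell_probs(ta, tb, r)))

    res = optimize.minimize_scalar(nll, bounds=(-0.999, 0.999), method="bounded",
                                   options={"xatol": 1e-6})
    rho = float(res.x)
    h = 1e-4
    d2 = (nll(rho + h) - 2 * nll(rho) + nll(rho - h)) / h ** 2
    var = 1.0 / d2 if d2 > 0 else (1 - rho ** 2) ** 2 / len(x)
    return rho, float(var)


def polyserial(x_cont: np.ndarray, y_ord: np.ndarray) -> tuple[float, float]:
    """Two-step ML polyserial correlation (continuous x, ordinal y) and variance."""
    m = ~(np.isnan(x_cont) | np.isnan(y_ord))
    x, y = x_cont[m], y_ord[m]
    z = (x - x.mean()) / x.std(ddof=0)
    cy, tau = _thresholds(y)
    cy = cy.astype(int)
    edges_hi = np.concatenate([tau, [np.inf]])[cy]
    edges_lo = np.concatenate([[-np.inf], tau])[cy]

    def nll(r):
        s = np.sqrt(1 - r ** 2)
        p = _phi((edges_hi - r * z) / s) - _phi((edges_lo - r * z) / s)
        return -np.sum(np.log(np.clip(p, 1e-12, 1.0)))

    res = optimize.minimize_scalar(nll, bounds=(-0.999, 0.999), method="bounded",
                                   options={"xatol": 1e-6})
    rho = float(res.x)
    h = 1e-4
    d2 = (nll(rho + h) - 2 * nll(rho) + nll(rho - h)) / h ** 2
    var = 1.0 / d2 if d2 > 0 else (1 - rho ** 2) ** 2 / len(x)
    return rho, float(var)


def _smooth_psd(R: np.ndarray, floor: float = 1e-6) -> tuple[np.ndarray, bool]:
    w, v = np.linalg.eigh(R)
    if w.min() >= floor:
        return R, False
    w = np.clip(w, floor, None)
    S = v @ np.diag(w) @ v.T
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d), True


def polychoric_matrix(data: pd.DataFrame, ordinal: list[str],
                      ) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Heterogeneous correlation matrix with per-element asymptotic variances.

    Returns (R, V, n) where R mixes polychoric / polyserial / Pearson entries,
    V holds each entry's estimated sampling variance and n is the median pairwise
    sample size.  R is smoothed to positive semi-definite if needed (logged).
    """
    cols = list(data.columns)
    p = len(cols)
    R = np.eye(p)
    V = np.full((p, p), np.nan)
    ns = []
    X = data.to_numpy(dtype=float)
    is_ord = [c in ordinal for c in cols]
    for i, j in combinations(range(p), 2):
        xi, xj = X[:, i], X[:, j]
        m = ~(np.isnan(xi) | np.isnan(xj))
        n_ij = int(m.sum())
        if n_ij < 10:
            raise ValueError(f"too few joint observations for {cols[i]},{cols[j]}")
        ns.append(n_ij)
        if is_ord[i] and is_ord[j]:
            r, v = polychoric(xi, xj)
        elif is_ord[i]:
            r, v = polyserial(xj, xi)
        elif is_ord[j]:
            r, v = polyserial(xi, xj)
        else:
            r = float(np.corrcoef(xi[m], xj[m])[0, 1])
            v = (1 - r ** 2) ** 2 / n_ij
        R[i, j] = R[j, i] = r
        V[i, j] = V[j, i] = max(v, _SQRT_TINY)
    R, smoothed = _smooth_psd(R)
    if smoothed:
        logger.warning("polychoric matrix smoothed to positive semi-definite")
    return (pd.DataFrame(R, index=cols, columns=cols),
            pd.DataFrame(V, index=cols, columns=cols),
            int(np.median(ns)))


def pearson_filon_gamma(R: np.ndarray, V: np.ndarray, n: int,
                        pairs: list[tuple[int, int]]) -> np.ndarray:
    """Asymptotic covariance of the correlation vector.

    Off-diagonal structure follows the Pearson-Filon normal-theory formula,
    rescaled so each element's variance equals the two-step ML estimate in V.
    """
    q = len(pairs)
    G = np.empty((q, q))

    def pf(i, j, k, l):
        return (0.5 * R[i, j] * R[k, l]
                * (R[i, k] ** 2 + R[i, l] ** 2 + R[j, k] ** 2 + R[j, l] ** 2)
                + R[i, k] * R[j, l] + R[i, l] * R[j, k]
                - (R[i, j] * R[i, k] * R[i, l] + R[i, j] * R[j, k] * R[j, l]
                   + R[k, l] * R[i, k] * R[j, k] + R[k, l] * R[i, l] * R[j, l]))

    pf_var = np.array([max(pf(i, j, i, j), _SQRT_TINY) for i, j in pairs])
    v = np.array([V[i, j] for i, j in pairs])
    scale = np.sqrt(v / (pf_var / n))
    for a, (i, j) in enumerate(pairs):
        for b, (k, l) in enumerate(pairs[a:], start=a):
            c = pf(i, j, k, l) / n * scale[a] * scale[b]
            G[a, b] = G[b, a] = c
    np.fill_diagonal(G, v)
    return G


# ---------------------------------------------------------------------------
# model specification and the implied correlation structure


@dataclass
class SemModelSpec:
    """An acyclic standardized SEM.

    ``latents`` maps each latent to its indicator columns; ``regressions`` are
    directed (outcome, predictor) edges among latents and observed variables;
    ``residual_covariances`` are free error correlations between indicator
    pairs; ``ordinal`` names the ordinal observed columns.  All exogenous
    variables covary freely.
    """

    latents: dict[str, list[str]] = field(default_factory=dict)
    regressions: list[tuple[str, str]] = field(default_factory=list)
    residual_covariances: list[tuple[str, str]] = field(default_factory=list)
    ordinal: list[str] = field(default_factory=list)

    @property
    def observed(self) -> list[str]:
        seen: dict[str, None] = {}
        for inds in self.latents.values():
            for i in inds:
                seen[i] = None
        for out, pred in self.regressions:
            for v in (out, pred):
                if v not in self.latents:
                    seen[v] = None
        return list(seen)

    @property
    def variables(self) -> list[str]:
        return self.observed + list(self.latents)

    def edges(self) -> list[tuple[str, str]]:
        """(child, parent) pairs: loadings then regressions."""
        e = [(ind, lat) for lat, inds in self.latents.items() for ind in inds]
        e += [(out, pred) for out, pred in self.regressions]
        return e

    def validate(self) -> None:
        edges = self.edges()
        # acyclicity via Kahn on (parent -> child)
        children: dict[str, list[str]] = {}
        indeg = {v: 0 for v in self.variables}
        for child, parent in edges:
            children.setdefault(parent, []).append(child)
            indeg[child] += 1
        queue = [v for v, d in indeg.items() if d == 0]
        seen = 0
        while queue:
            v = queue.pop()
            seen += 1
            for c in children.get(v, []):
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if seen != len(self.variables):
            raise ValueError("model graph contains a cycle")
        for lat, inds in self.latents.items():
            if len(inds) < 1:
                raise ValueError(f"latent {lat} has no indicators")


class _Model:
    """Parameter bookkeeping and the implied correlation matrix."""

    def __init__(self, spec: SemModelSpec):
        spec.validate()
        self.spec = spec
        self.obs = spec.observed
        self.nodes = spec.variables
        self.index = {v: i for i, v in enumerate(self.nodes)}
        self.edges = spec.edges()              # (child, parent)
        parents: dict[str, list[str]] = {}
        for child, parent in self.edges:
            parents.setdefault(child, []).append(parent)
        self.parents = parents
        self.exo = [v for v in self.nodes if v not in parents]
        self.topo = self._toposort()
        # free parameters: edges, exogenous covariances, residual covariances
        self.param_names: list[str] = []
        self.param_kind: list[tuple] = []
        for child, parent in self.edges:
            self.param_names.append(f"{child}~{parent}")
            self.param_kind.append(("edge", child, parent))
        for a, b in combinations(self.exo, 2):
            self.param_names.append(f"{a}~~{b}")
            self.param_kind.append(("exocov", a, b))
        for a, b in spec.residual_covariances:
            self.param_names.append(f"{a}~~{b}")
            self.param_kind.append(("rescov", a, b))
        self.n_free = len(self.param_names)

    def _toposort(self) -> list[str]:
        order, seen = [], set()

        def visit(v):
            if v in seen:
                return
            for p in self.parents.get(v, []):
                visit(p)
            seen.add(v)
            order.append(v)

        for v in self.nodes:
            visit(v)
        return order

    def start_values(self, R: pd.DataFrame) -> np.ndarray:
        theta = np.zeros(self.n_free)
        for i, kind in enumerate(self.param_kind):
            tag = kind[0]
            if tag == "edge":
                child, parent = kind[1], kind[2]
                if parent in self.spec.latents:
                    theta[i] = 0.6
                else:
                    theta[i] = 0.1
            elif tag == "exocov":
                a, b = kind[1], kind[2]
                if a in R.index and b in R.index:
                    theta[i] = R.loc[a, b]
        return theta

    def implied(self, theta: np.ndarray) -> tuple[np.ndarray, float, dict[str, float]]:
        """Implied correlation among observed variables.

        Returns (Sigma_obs, penalty, residual variances).  The penalty grows when
        an endogenous variable's systematic variance reaches 1 (Heywood region),
        keeping the optimiser inside the admissible set smoothly.
        """
        nv = len(self.nodes)
        C = np.zeros((nv, nv))
        coefs: dict[str, dict[str, float]] = {}
        exocov: dict[tuple[str, str], float] = {}
        rescov: list[tuple[str, str, float]] = []
        for val, kind in zip(theta, self.param_kind):
            if kind[0] == "edge":
                coefs.setdefault(kind[1], {})[kind[2]] = val
            elif kind[0] == "exocov":
                exocov[(kind[1], kind[2])] = val
            else:
                rescov.append((kind[1], kind[2], val))
        for v in self.exo:
            C[self.index[v], self.index[v]] = 1.0
        for (a, b), val in exocov.items():
            C[self.index[a], self.index[b]] = C[self.index[b], self.index[a]] = val
        penalty = 0.0
        resid: dict[str, float] = {}
        done = list(self.exo)
        done_set = set(done)
        for v in self.topo:
            if v in done_set:
                continue
            iv = self.index[v]
            P = self.parents[v]
            b = np.array([coefs[v][p] for p in P])
            ip = [self.index[p] for p in P]
            cov_pp = C[np.ix_(ip, ip)]
            sys_var = float(b @ cov_pp @ b)
            if sys_var > 0.98:
                penalty += (sys_var - 0.98) ** 2 * 1e3
                shrink = np.sqrt(0.98 / sys_var)
                b = b * shrink
                sys_var = 0.98
            iu = [self.index[u] for u in done]
            cv = b @ C[np.ix_(ip, iu)]
            C[iv, iu] = cv
            C[iu, iv] = cv
            resid[v] = 1.0 - sys_var
            C[iv, iv] = 1.0
            done.append(v)
            done_set.add(v)
        for a, b_, val in rescov:
            ia, ib = self.index[a], self.index[b_]
            C[ia, ib] += val
            C[ib, ia] += val
        iobs = [self.index[v] for v in self.obs]
        return C[np.ix_(iobs, iobs)], penalty, resid


# ---------------------------------------------------------------------------
# fitting


@dataclass
class SemFit:
    spec: SemModelSpec
    estimates: pd.DataFrame        # parameter, est, se, z, p (standardized)
    fit_indices: dict[str, float]
    N: int
    converged: bool
    residual_variances: dict[str, float]
    heywood: list[str]
    R: pd.DataFrame
    V: pd.DataFrame
    model: _Model
    theta: np.ndarray
    weights: np.ndarray
    pairs: list[tuple[int, int]]
    sample_vec: np.ndarray
    scale_a: float = 1.0           # scaled-shifted chi2 multiplier

    def estimate(self, name: str) -> float:
        return float(self.estimates.set_index("parameter").loc[name, "est"])

    def pvalue(self, name: str) -> float:
        return float(self.estimates.set_index("parameter").loc[name, "p"])


def _fit_indices(T: float, df: int, Tb: float, dfb: int, N: int,
                 srmr: float, npar: int) -> dict[str, float]:
    out = {"chi2": T, "df": float(df), "chi2_df": T / df if df > 0 else np.nan,
           "srmr": srmr, "aic": T + 2 * npar, "bic": T + np.log(N) * npar}
    if df == 0:
        out.update(cfi=1.0, tli=1.0, rmsea=0.0, rmsea_lo=0.0, rmsea_hi=0.0)
        return out
    num = max(T - df, 0.0)
    den = max(Tb - dfb, T - df, 0.0)
    out["cfi"] = 1.0 - (num / den if den > 0 else 0.0)
    if dfb > 0 and Tb / dfb > 1:
        out["tli"] = min(((Tb / dfb) - (T / df)) / ((Tb / dfb) - 1.0), 1.0)
    else:
        out["tli"] = 1.0
    out["rmsea"] = float(np.sqrt(num / (df * (N - 1))))

    def rmsea_ci(alpha=0.10):
        # invert the noncentral chi2 cdf in the noncentrality parameter
        def lam_for(prob):
            if stats.chi2.cdf(T, df) < prob:
                return 0.0
            lo, hi = 0.0, max(10.0, 2 * T)
            while stats.ncx2.cdf(T, df, hi) > prob:
                hi *= 2
                if hi > 1e7:
                    break
            for _ in range(200):
                mid = (lo + hi) / 2
                if stats.ncx2.cdf(T, df, mid) > prob:
                    lo = mid
                else:
                    hi = mid
            return (lo + hi) / 2

        lam_hi = lam_for(alpha / 2)
        lam_lo = lam_for(1 - alpha / 2)
        return (np.sqrt(lam_lo / (df * (N - 1))), np.sqrt(lam_hi / (df * (N - 1))))

    out["rmsea_lo"], out["rmsea_hi"] = rmsea_ci()
    return out


def fit_sem(spec: SemModelSpec, data: pd.DataFrame | None = None, *,
            matrix: tuple[pd.DataFrame, pd.DataFrame, int] | None = None,
            se: str = "sandwich") -> SemFit:
    """DWLS fit of ``spec``; pass raw ``data`` or a precomputed (R, V, n) triple.

    Raises on under-identification (df < 0) before optimisation.  Heywood cases
    (residual variance pinned at the boundary) are flagged, not silenced.
    """
    model = _Model(spec)
    if matrix is None:
        if data is None:
            raise ValueError("provide data or a correlation matrix triple")
        cols = model.obs
        R, V, N = polychoric_matrix(data[cols], spec.ordinal)
    else:
        R, V, N = matrix
        R = R.loc[model.obs, model.obs]
        V = V.loc[model.obs, model.obs]
    p = len(model.obs)
    pairs = list(combinations(range(p), 2))
    q = len(pairs)
    df = q - model.n_free
    if df < 0:
        raise ValueError(f"model not identified: {model.n_free} free parameters "
                         f"for {q} sample correlations")
    Rm = R.to_numpy()
    s = np.array([Rm[i, j] for i, j in pairs])
    v = np.array([V.to_numpy()[i, j] for i, j in pairs])
    w = 1.0 / v

    def discrepancy(theta):
        Sigma, penalty, _ = model.implied(theta)
        sig = np.array([Sigma[i, j] for i, j in pairs])
        return float(np.sum(w * (s - sig) ** 2)) + penalty

    theta0 = model.start_values(R)
    res = optimize.minimize(discrepancy, theta0, method="L-BFGS-B",
                            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
    theta = res.x
    Sigma, penalty, resid = model.implied(theta)
    heywood = [vn for vn, rv in resid.items() if rv <= 0.02 + 1e-9]
    if heywood:
        logger.warning("Heywood case(s): %s", heywood)
    sig = np.array([Sigma[i, j] for i, j in pairs])
    F = float(np.sum(w * (s - sig) ** 2))
    Fb = float(np.sum(w * s ** 2))
    srmr = float(np.sqrt(np.mean((s - sig) ** 2)))

    # mean-and-variance (scaled-shifted) adjustment of the DWLS statistic:
    # F_hat ~ sum(lambda_i chi2_1) with lambda = eig(U Gamma); rescale so the
    # reported chi2 has mean df and variance 2 df under a correct model.
    Delta = _jacobian(model, theta, pairs)
    W = np.diag(w)
    Gamma = pearson_filon_gamma(Rm, V.to_numpy(), N, pairs)
    bread = Delta.T @ W @ Delta
    scale_a = 1.0
    se_vec = np.full(model.n_free, np.nan)
    try:
        bread_inv = np.linalg.inv(bread)
        U = W - W @ Delta @ bread_inv @ Delta.T @ W
        UG = U @ Gamma
        c1, c2 = float(np.trace(UG)), float(np.trace(UG @ UG))
        if df > 0 and c2 > 0:
            scale_a = float(np.sqrt(df / c2))
            T = max(scale_a * (F - c1) + df, 0.0)
        else:
            T = 0.0
        WG = w[:, None] * Gamma
        c1b, c2b = float(np.trace(WG)), float(np.trace(WG @ WG))
        Tb = max(np.sqrt(q / c2b) * (Fb - c1b) + q, 0.0) if c2b > 0 else 0.0
        if se == "sandwich":
            meat = Delta.T @ W @ Gamma @ W @ Delta
            cov = bread_inv @ meat @ bread_inv
            se_vec = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        logger.warning("singular information matrix; falling back to the "
                       "unadjusted statistic, SEs unavailable")
        T = (N - 1) * F
        Tb = (N - 1) * Fb
    indices = _fit_indices(T, df, Tb, q, N, srmr, model.n_free)
    z = np.where(se_vec > 0, theta / se_vec, np.nan)
    pvals = 2 * stats.norm.sf(np.abs(z))
    est = pd.DataFrame({"parameter": model.param_names, "est": theta,
                        "se": se_vec, "z": z, "p": pvals})
    return SemFit(spec=spec, estimates=est, fit_indices=indices, N=N,
                  converged=bool(res.success) and penalty < 1e-6,
                  residual_variances=resid, heywood=heywood, R=R, V=V,
                  model=model, theta=theta, weights=w, pairs=pairs,
                  sample_vec=s, scale_a=scale_a)


def _jacobian(model: _Model, theta: np.ndarray,
              pairs: list[tuple[int, int]], h: float = 1e-6) -> np.ndarray:
    q = len(pairs)
    J = np.empty((q, len(theta)))
    for j in range(len(theta)):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        Sp = model.implied(tp)[0]
        Sm = model.implied(tm)[0]
        J[:, j] = [(Sp[i, k] - Sm[i, k]) / (2 * h) for i, k in pairs]
    return J


def fit_cfa(measurement: dict[str, list[str]], data: pd.DataFrame | None = None,
            ordinal: list[str] | None = None, *,
            matrix=None) -> SemFit:
    """Correlated-factors CFA of the clustering solution (construct validity)."""
    all_inds = [i for inds in measurement.values() for i in inds]
    spec = SemModelSpec(latents=dict(measurement),
                        ordinal=list(ordinal or all_inds))
    return fit_sem(spec, data, matrix=matrix)


# ---------------------------------------------------------------------------
# mediation decomposition


@dataclass
class EffectDecomposition:
    source: str
    outcome: str
    direct: float
    indirect_paths: dict[tuple[str, ...], float]
    total: float

    @property
    def indirect(self) -> float:
        return float(sum(self.indirect_paths.values()))


def decompose_effects(fit: SemFit, source: str, outcome: str) -> EffectDecomposition:
    """Direct, indirect (per mediating chain) and total standardized effects.

    Enumerates every directed path source -> outcome in the model graph; each
    indirect effect is the product of standardized coefficients along the chain.
    """
    coef: dict[tuple[str, str], float] = {}
    for kind, est in zip(fit.model.param_kind, fit.theta):
        if kind[0] == "edge":
            coef[(kind[2], kind[1])] = est   # parent -> child
    children: dict[str, list[str]] = {}
    for (parent, child) in coef:
        children.setdefault(parent, []).append(child)

    paths: dict[tuple[str, ...], float] = {}

    def dfs(node, acc, prod):
        if node == outcome:
            paths[tuple(acc)] = prod
            return
        for ch in children.get(node, []):
            if ch not in acc:
                dfs(ch, acc + [ch], prod * coef[(node, ch)])

    dfs(source, [source], 1.0)
    direct = paths.pop((source, outcome), 0.0)
    total = direct + sum(paths.values())
    return EffectDecomposition(source=source, outcome=outcome, direct=direct,
                               indirect_paths=paths, total=total)


# ---------------------------------------------------------------------------
# modification indices


def modification_indices(fit: SemFit, max_candidates: int | None = None
                         ) -> pd.DataFrame:
    """Score-test (1-df) expected chi2 drop for candidate fixed parameters.

    Candidates are omitted cross-loadings and omitted indicator residual
    correlations.  Rows where the information matrix is singular get NaN.
    """
    model = fit.model
    spec = fit.spec
    existing = set(model.param_names)
    candidates: list[tuple] = []
    for lat in spec.latents:
        for ind in model.obs:
            if ind in spec.latents:
                continue
            if f"{ind}~{lat}" not in existing and ind not in spec.latents.get(lat, []):
                if any(ind in inds for inds in spec.latents.values()):
                    candidates.append(("edge", ind, lat))
    indicators = [i for inds in spec.latents.values() for i in inds]
    for a, b in combinations(indicators, 2):
        if f"{a}~~{b}" not in existing and f"{b}~~{a}" not in existing:
            candidates.append(("rescov", a, b))
    if max_candidates:
        candidates = candidates[:max_candidates]

    s, w, pairs, N = fit.sample_vec, fit.weights, fit.pairs, fit.N
    rows = []
    for cand in candidates:
        ext_spec = SemModelSpec(
            latents={k: list(v) for k, v in spec.latents.items()},
            regressions=list(spec.regressions),
            residual_covariances=list(spec.residual_covariances),
            ordinal=list(spec.ordinal))
        if cand[0] == "edge":
            ext_spec.latents[cand[2]] = ext_spec.latents[cand[2]] + [cand[1]]
            # keep indicator order of the base model
        else:
            ext_spec.residual_covariances.append((cand[1], cand[2]))
        try:
            ext = _Model(ext_spec)
        except ValueError:
            continue
        # map base estimates into the extended parameterisation; candidate at 0
        theta_ext = np.zeros(ext.n_free)
        base = dict(zip(model.param_names, fit.theta))
        for i, name in enumerate(ext.param_names):
            theta_ext[i] = base.get(name, 0.0)
        ext_pairs = pairs   # same observed set, same order

        def Fstat(th):
            Sigma, penalty, _ = ext.implied(th)
            sig = np.array([Sigma[i, j] for i, j in ext_pairs])
            return float(np.sum(w * (s - sig) ** 2)) + penalty

        g = optimize.approx_fprime(theta_ext, Fstat, 1e-6)
        try:
            J = _jacobian(ext, theta_ext, ext_pairs)
            H = 2 * (J.T @ np.diag(w) @ J)   # Gauss-Newton Hessian of F
            Hinv = np.linalg.inv(H)
            # expected drop in F from freeing the candidate, on the
            # scaled-shifted chi2 metric of the base fit
            mi = fit.scale_a * 0.5 * float(g @ Hinv @ g)
        except np.linalg.LinAlgError:
            mi = np.nan
        label = (f"{cand[1]}~{cand[2]}" if cand[0] == "edge"
                 else f"{cand[1]}~~{cand[2]}")
        rows.append({"parameter": label, "kind": cand[0], "mi": mi})
    out = pd.DataFrame(rows)
    return out.sort_values("mi", ascending=False).reset_index(drop=True)


# ---------------------------------------------------------------------------
# moderation (multi-group equality constraint)


def moderation_test(spec: SemModelSpec, data: pd.DataFrame, moderator: str,
                    constrained_paths: list[tuple[str, str]],
                    min_group_n: int = 50) -> dict:
    """Multi-group test of whether ``moderator`` changes the constrained paths.

    Fits the model in each moderator group with the listed paths free, then with
    them constrained equal; reports the chi2 difference, its df, p-value and the
    CFI change.  The moderator must be binary.
    """
    groups = data[moderator].dropna().unique()
    if len(groups) != 2:
        raise ValueError("moderator must be binary")
    sub = {g: data[data[moderator] == g].drop(columns=[moderator]) for g in groups}
    for g, d in sub.items():
        if len(d) < min_group_n:
            logger.warning("moderator group %s has n=%d < %d", g, len(d), min_group_n)
    mats, fits = {}, {}
    for g, d in sub.items():
        model = _Model(spec)
        mats[g] = polychoric_matrix(d[model.obs], spec.ordinal)
        fits[g] = fit_sem(spec, matrix=mats[g])
    T_free = sum(f.fit_indices["chi2"] for f in fits.values())
    df_free = sum(int(f.fit_indices["df"]) for f in fits.values())

    # constrained joint fit: shared values for the listed paths
    model = _Model(spec)
    con_names = [f"{out}~{pred}" for out, pred in constrained_paths]
    con_idx = [model.param_names.index(nm) for nm in con_names]
    other_idx = [i for i in range(model.n_free) if i not in con_idx]
    glist = list(groups)

    def pack(theta_joint):
        shared = theta_joint[:len(con_idx)]
        out = []
        off = len(con_idx)
        for _ in glist:
            th = np.empty(model.n_free)
            th[con_idx] = shared
            th[other_idx] = theta_joint[off:off + len(other_idx)]
            off += len(other_idx)
            out.append(th)
        return out

    prep = {}
    for g in glist:
        R, V, N = mats[g]
        Rm = R.to_numpy()
        pairs = list(combinations(range(len(model.obs)), 2))
        sg = np.array([Rm[i, j] for i, j in pairs])
        wg = 1.0 / np.array([V.to_numpy()[i, j] for i, j in pairs])
        prep[g] = (sg, wg, pairs, N)

    def T_joint(theta_joint):
        tot = 0.0
        for th, g in zip(pack(theta_joint), glist):
            sg, wg, pairs, N = prep[g]
            Sigma, penalty, _ = model.implied(th)
            sig = np.array([Sigma[i, j] for i, j in pairs])
            tot += (N - 1) * (float(np.sum(wg * (sg - sig) ** 2)) + penalty)
        return tot

    x0 = np.concatenate(
        [np.mean([fits[g].theta[con_idx] for g in glist], axis=0)]
        + [fits[g].theta[other_idx] for g in glist])
    res = optimize.minimize(T_joint, x0, method="L-BFGS-B",
                            options={"maxiter": 500, "ftol": 1e-12})
    T_con = float(res.fun)
    df_con = df_free + len(con_idx)
    d_df = df_con - df_free
    # calibrated equality test: Wald statistic on the group difference of each
    # constrained path, using the sandwich SEs (the raw DWLS chi2 difference is
    # not chi2-scaled under diagonal weights)
    g1, g2 = glist
    d_chi2 = 0.0
    for nm in con_names:
        e1, e2 = fits[g1].estimate(nm), fits[g2].estimate(nm)
        s1 = float(fits[g1].estimates.set_index("parameter").loc[nm, "se"])
        s2 = float(fits[g2].estimates.set_index("parameter").loc[nm, "se"])
        d_chi2 += (e1 - e2) ** 2 / (s1 ** 2 + s2 ** 2)
    p = float(stats.chi2.sf(d_chi2, d_df)) if d_df > 0 else np.nan
    cfi_free = np.mean([fits[g].fit_indices["cfi"] for g in glist])
    # constrained CFI from pooled chi2 against the pooled baseline
    Tb = sum((prep[g][3] - 1) * float(np.sum(prep[g][1] * prep[g][0] ** 2))
             for g in glist)
    qb = sum(len(prep[g][2]) for g in glist)
    num = max(T_con - df_con, 0.0)
    den = max(Tb - qb, num, _SQRT_TINY)
    cfi_con = 1.0 - num / den
    return {"delta_chi2": d_chi2, "delta_df": d_df, "p": p,
            "delta_cfi": float(cfi_free - cfi_con),
            "chi2_free": T_free, "df_free": df_free,
            "chi2_constrained": T_con, "df_constrained": df_con,
            "group_fits": fits}


# ---------------------------------------------------------------------------
# power


def sem_power(model_df: int, N: int, rmsea_null: float, rmsea_alt: float,
              alpha: float = 0.05) -> dict:
    """Power of the RMSEA-based misspecification test (noncentral chi2).

    Noncentrality lambda = (N - 1) * df * epsilon^2 on each side.  With
    rmsea_null == rmsea_alt the test has power alpha by construction (noted).
    """
    if model_df < 1 or N < 10:
        raise ValueError("need df >= 1 and N >= 10")
    lam0 = (N - 1) * model_df * rmsea_null ** 2
    lam1 = (N - 1) * model_df * rmsea_alt ** 2
    crit = stats.ncx2.ppf(1 - alpha, model_df, lam0) if lam0 > 0 else \
        stats.chi2.ppf(1 - alpha, model_df)
    if np.isclose(rmsea_null, rmsea_alt):
        return {"power": alpha, "note": "rmsea_null == rmsea_alt: power equals alpha"}
    if rmsea_alt > rmsea_null:   # not-close-fit alternative
        power = float(stats.ncx2.sf(crit, model_df, lam1))
    else:                        # test of close fit with a better alternative
        crit_lo = stats.ncx2.ppf(alpha, model_df, lam0) if lam0 > 0 else \
            stats.chi2.ppf(alpha, model_df)
        power = float(stats.ncx2.cdf(crit_lo, model_df, lam1)) if lam1 > 0 else \
            float(stats.chi2.cdf(crit_lo, model_df))
    return {"power": power, "lambda_null": lam0, "lambda_alt": lam1,
            "critical_value": float(crit)}


def simulate_target_model(effect: float, n: int, rng: np.random.Generator,
                          n_indicators: int = 4, loading: float = 0.8
                          ) -> pd.DataFrame:
    """One latent outcome with ordinal indicators regressed on a continuous
    exposure with standardized effect ``effect`` (the target-path test bed)."""
    x = rng.normal(size=n)
    eta = effect * x + rng.normal(scale=np.sqrt(1 - effect ** 2), size=n)
    thr = np.array([-1.2, -0.4, 0.4, 1.2])
    cols = {"exposure": x}
    for j in range(n_indicators):
        cont = loading * eta + rng.normal(scale=np.sqrt(1 - loading ** 2), size=n)
        cols[f"y{j + 1}"] = 1 + np.searchsorted(thr, cont)
    return pd.DataFrame(cols)


def target_effect_power(effect: float, N: int, reps: int = 200, seed: int = 0,
                        alpha: float = 0.05, n_indicators: int = 4) -> dict:
    """Monte-Carlo power for detecting the exposure -> latent outcome path."""
    rng = np.random.default_rng(seed)
    spec = SemModelSpec(
        latents={"eta": [f"y{j + 1}" for j in range(n_indicators)]},
        regressions=[("eta", "exposure")],
        ordinal=[f"y{j + 1}" for j in range(n_indicators)])
    hits = 0
    used = 0
    for _ in range(reps):
        data = simulate_target_model(effect, N, rng, n_indicators)
        try:
            fit = fit_sem(spec, data)
        except (ValueError, np.linalg.LinAlgError):
            continue
        used += 1
        if fit.pvalue("eta~exposure") <= alpha:
            hits += 1
    power = hits / used if used else np.nan
    half = 1.96 * np.sqrt(power * (1 - power) / used) if used else np.nan
    return {"power": power, "reps": used, "ci95": (power - half, power + half)}
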
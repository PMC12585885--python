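"""Genome-wide PCA, admixture-proportion EM, and ternary ancestry classes.

``GenotypePCA`` and ``AdmixtureEM`` are scikit-learn style estimators
operating on dosage matrices (rows = individuals, columns = biallelic
sites, ``-1`` = missing). ``AdmixtureEM`` maximizes the standard binomial
admixture likelihood

    L(Q, P) = prod_ij C(2, g_ij) theta_ij^g_ij (1 - theta_ij)^(2 - g_ij),
    theta_ij = sum_k q_ik p_kj

by expectation-maximization with multiplicative (frappe-style) updates,
which are monotone in the log-likelihood. The ternary classifier turns a
K=3 ancestry vector into one of seven classes (C, S, M, CS, SM, MC, MCS)
using the published threshold rules: a parental class needs one ancestry
strictly above 0.80; a two-way class needs the third ancestry at or below
0.10; everything else is the balanced three-way class.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans

from .matrix import GenotypeMatrix

log = logging.getLogger(__name__)

PARENTAL = ("C", "S", "M")
TWO_WAY = {frozenset(("C", "S")): "CS", frozenset(("S", "M")): "SM", frozenset(("M", "C")): "MC"}


def _as_dosage(X):
    if isinstance(X, GenotypeMatrix):
        return X.dosage
    return np.asarray(X)


class GenotypePCA(BaseEstimator, TransformerMixin):
    """PCA of centred (optionally scaled) dosages with mean imputation.

    Missing dosages are replaced by the per-site mean for the
    decomposition only. Scaling ``patterson`` divides each site by
    sqrt(p(1-p)) with p the alt-allele frequency; ``unit`` divides by the
    site standard deviation; ``none`` leaves centred dosages. Axis signs
    follow a deterministic convention: the sample score of largest
    magnitude on each axis is made positive.

    Attributes
    ----------
    mean_, scale_ : per-site centring and scaling vectors
    components_ : (n_axes, n_sites) loadings
    explained_variance_ratio_ : per-axis fraction of total variance
    coords_ : (n_samples, n_axes) scores of the fitted samples
    """

    def __init__(self, n_axes: int = 10, scaling: str = "patterson"):
        self.n_axes = n_axes
        self.scaling = scaling

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def fit_transform(self, X, y=None):
        D = _as_dosage(X).astype(np.float64)
        if D.ndim != 2 or D.shape[0] < 2:
            raise ValueError("need at least 2 samples")
        miss = D < 0
        D[miss] = np.nan
        mean = np.nanmean(D, axis=0)
        poly = np.nanstd(D, axis=0) > 0
        if poly.sum() < 2:
            raise ValueError("need at least 2 polymorphic sites")
        if self.scaling == "patterson":
            p = mean / 2.0
            scale = np.sqrt(np.maximum(p * (1 - p), 1e-12))
        elif self.scaling == "unit":
            scale = np.maximum(np.nanstd(D, axis=0), 1e-12)
        elif self.scaling == "none":
            scale = np.ones(D.shape[1])
        else:
            raise ValueError(f"unknown scaling {self.scaling!r}")
        Z = (np.where(np.isnan(D), mean[None, :], D) - mean[None, :]) / scale[None, :]
        Z[:, ~poly] = 0.0
        k = min(self.n_axes, min(Z.shape) - 1) or 1
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        coords = U[:, :k] * s[:k]
        # deterministic sign: largest-|score| coordinate positive per axis
        for a in range(coords.shape[1]):
            j = int(np.argmax(np.abs(coords[:, a])))
            if coords[j, a] < 0:
                coords[:, a] *= -1
                Vt[a] *= -1
        var = s**2
        self.mean_, self.scale_, self.poly_ = mean, scale, poly
        self.components_ = Vt[:k]
        self.explained_variance_ratio_ = (var[:k] / var.sum()) if var.sum() > 0 else var[:k]
        self.coords_ = coords
        return coords

    def transform(self, X):
        D = _as_dosage(X).astype(np.float64)
        D[D < 0] = np.nan
        Z = (np.where(np.isnan(D), self.mean_[None, :], D) - self.mean_[None, :]) / self.scale_[None, :]
        Z[:, ~self.poly_] = 0.0
        return Z @ self.components_.T


def pca(gm: GenotypeMatrix, n_axes: int = 10, scaling: str = "patterson") -> dict:
    """Functional wrapper over :class:`GenotypePCA` returning a result dict."""
    est = GenotypePCA(n_axes=n_axes, scaling=scaling)
    coords = est.fit_transform(gm)
    return {
        "coords": coords,
        "explained_var": est.explained_variance_ratio_,
        "loadings": est.components_,
        "samples": list(gm.samples),
    }


class AdmixtureEM(BaseEstimator):
    """Binomial admixture model fitted by EM.

    ``n_init`` short EM runs (``warm_iter`` iterations each; the first is
    seeded from k-means on PCA scores, the rest randomly) are scored and
    the best continued to convergence (``abs(delta loglik) < tol``). The
    refinement phase uses SQUAREM extrapolation with a monotonicity
    safeguard: an accelerated step is kept only when it does not lower
    the log-likelihood relative to the plain double EM step, so the
    recorded log-likelihood path is non-decreasing by construction.

    Attributes
    ----------
    Q_ : (n_samples, K) ancestry proportions, rows summing to 1
    P_ : (K, n_sites) cluster allele frequencies
    loglik_ : final log-likelihood (binomial kernel, constants dropped)
    loglik_path_ : per-iteration log-likelihood of the final run
    converged_ : whether the tolerance was reached before max_iter
    """

    _EPS = 1e-9

    def __init__(self, K: int = 3, n_init: int = 10, warm_iter: int = 20,
                 max_iter: int = 1000, tol: float = 1e-3, seed: int = 0,
                 accelerate: bool = True):
        self.K = K
        self.n_init = n_init
        self.warm_iter = warm_iter
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed
        self.accelerate = accelerate

    # -- internals ------------------------------------------------------
    def _loglik(self, G, M, Q, P):
        theta = np.clip(Q @ P, self._EPS, 1 - self._EPS)
        ll = np.where(M, G * np.log(theta) + (2 - G) * np.log1p(-theta), 0.0)
        return float(ll.sum())

    def _em_step(self, G, M, Q, P, J_i):
        theta = np.clip(Q @ P, self._EPS, 1 - self._EPS)
        U = np.where(M, G / theta, 0.0)
        V = np.where(M, (2 - G) / (1 - theta), 0.0)
        E_alt = P * (Q.T @ U)
        E_ref = (1 - P) * (Q.T @ V)
        P_new = np.clip(E_alt / np.maximum(E_alt + E_ref, self._EPS), self._EPS, 1 - self._EPS)
        Q_new = Q * (U @ P.T + V @ (1 - P).T)
        Q_new /= np.maximum(2 * J_i[:, None], 1)
        Q_new = np.maximum(Q_new, self._EPS)
        Q_new /= Q_new.sum(axis=1, keepdims=True)
        return Q_new, P_new

    def _squarem_cycle(self, G, M, Q, P, J_i):
        """One SQUAREM extrapolation cycle, safeguarded to be monotone."""
        Q1, P1 = self._em_step(G, M, Q, P, J_i)
        Q2, P2 = self._em_step(G, M, Q1, P1, J_i)
        rQ, rP = Q1 - Q, P1 - P
        vQ, vP = Q2 - Q1 - rQ, P2 - P1 - rP
        nv = np.sqrt((vQ**2).sum() + (vP**2).sum())
        if nv <= 0:
            return Q2, P2
        nr = np.sqrt((rQ**2).sum() + (rP**2).sum())
        alpha = -max(nr / nv, 1.0)
        Qa = Q - 2 * alpha * rQ + alpha**2 * vQ
        Pa = P - 2 * alpha * rP + alpha**2 * vP
        Qa = np.maximum(Qa, self._EPS)
        Qa /= Qa.sum(axis=1, keepdims=True)
        Pa = np.clip(Pa, self._EPS, 1 - self._EPS)
        Qa, Pa = self._em_step(G, M, Qa, Pa, J_i)  # stabilizing EM step
        if self._loglik(G, M, Qa, Pa) >= self._loglik(G, M, Q2, P2):
            return Qa, Pa
        return Q2, P2

    def _init_state(self, G, M, rng, kind):
        n, m = G.shape
        K = self.K
        if kind == "kmeans":
            try:
                coords = GenotypePCA(n_axes=min(8, n - 1)).fit_transform(np.where(M, G, -1))
                km = KMeans(n_clusters=K, n_init=4, random_state=int(rng.integers(2**31)))
                lab = km.fit_predict(coords)
                P = np.empty((K, m))
                for k in range(K):
                    sel = lab == k
                    if sel.sum() == 0:
                        P[k] = rng.uniform(0.05, 0.95, size=m)
                        continue
                    with np.errstate(invalid="ignore", divide="ignore"):
                        num = np.where(M[sel], G[sel], 0).sum(axis=0)
                        den = 2 * M[sel].sum(axis=0)
                        P[k] = np.where(den > 0, num / np.maximum(den, 1), 0.5)
                P = np.clip(P, 0.01, 0.99)
            except Exception:  # degenerate inputs: fall back to random
                P = rng.uniform(0.05, 0.95, size=(K, m))
        else:
            P = rng.uniform(0.05, 0.95, size=(K, m))
        Q = rng.dirichlet(np.ones(K), size=n)
        Q = np.maximum(Q, self._EPS)
        Q /= Q.sum(axis=1, keepdims=True)
        return Q, P

    # -- API ------------------------------------------------------------
    def fit(self, X, y=None):
        G = _as_dosage(X).astype(np.float64)
        M = G >= 0
        G = np.where(M, G, 0.0)
        if self.K < 2:
            raise ValueError("K must be >= 2")
        J_i = M.sum(axis=1).astype(np.float64)
        rng = np.random.default_rng(self.seed)

        best = None
        for r in range(max(1, self.n_init)):
            kind = "kmeans" if r == 0 else "random"
            Q, P = self._init_state(G, M, rng, kind)
            for _ in range(self.warm_iter):
                Q, P = self._em_step(G, M, Q, P, J_i)
            ll = self._loglik(G, M, Q, P)
            if best is None or ll > best[0]:
                best = (ll, Q, P)

        ll, Q, P = best
        path = [self._loglik(G, M, Q, P)]
        converged = False
        for _ in range(self.max_iter):
            if self.accelerate:
                Q, P = self._squarem_cycle(G, M, Q, P, J_i)
            else:
                Q, P = self._em_step(G, M, Q, P, J_i)
            path.append(self._loglik(G, M, Q, P))
            if abs(path[-1] - path[-2]) < self.tol:
                converged = True
                break
        if not converged:
            log.warning("AdmixtureEM: not converged after %d iterations", self.max_iter)
        self.Q_, self.P_ = Q, P
        self.loglik_ = path[-1]
        self.loglik_path_ = np.array(path)
        self.n_iter_ = len(path) - 1
        self.converged_ = converged
        return self

    def predict_proba(self, X=None):
        return self.Q_


def admixture_em(gm: GenotypeMatrix, K: int = 3, seed: int = 0,
                 max_iter: int = 2000, tol: float = 1e-4, n_init: int = 10):
    """Functional wrapper: returns (Q, P, loglik)."""
    est = AdmixtureEM(K=K, seed=seed, max_iter=max_iter, tol=tol, n_init=n_init).fit(gm)
    return est.Q_, est.P_, est.loglik_


def align_q_to_groups(Q: np.ndarray, labels, parental=PARENTAL) -> np.ndarray:
    """Permute ancestry components to match reference parental groups.

    Greedy matching of per-group mean Q: for each parental label (in the
    order given) pick the unused component with the highest mean
    proportion among samples carrying that label. Returns the column
    permutation such that ``Q[:, perm]`` has columns ordered as
    ``parental``.
    """
    labels = np.asarray(labels)
    K = Q.shape[1]
    perm = []
    used = set()
    for g in parental:
        sel = labels == g
        means = Q[sel].mean(axis=0) if sel.any() else np.zeros(K)
        order = np.argsort(-means)
        pick = next((k for k in order if k not in used), None)
        perm.append(pick)
        used.add(pick)
    return np.array(perm)


def classify_ternary(q, major: float = 0.80, minor: float = 0.10) -> str:
    """Seven-way ternary ancestry class from a K=3 proportion vector.

    Strictly more than ``major`` of one ancestry gives the parental class;
    otherwise, if the smallest ancestry does not exceed ``minor``, the
    class is named by the two largest components; otherwise the balanced
    three-way class. Ties for the smallest component are resolved by
    keeping the higher-priority ancestry (C > S > M) in the class name.
    """
    q = np.asarray(q, dtype=float)
    if q.shape != (3,) or np.any(np.isnan(q)) or abs(q.sum() - 1.0) > 1e-6:
        return "unclassified"
    if np.max(q) > major:
        return PARENTAL[int(np.argmax(q))]
    if np.min(q) <= minor:
        mn = np.min(q)
        tied = [i for i in range(3) if q[i] == mn]
        drop = tied[-1]  # last in C > S > M priority order
        if len(tied) > 1:
            log.debug("ternary tie among minima %s; dropping %s", tied, PARENTAL[drop])
        pair = frozenset(PARENTAL[i] for i in range(3) if i != drop)
        return TWO_WAY[pair]
    return "MCS"


def classify_profiles(Q: np.ndarray, samples, major: float = 0.80,
                      minor: float = 0.10) -> pd.DataFrame:
    """Per-sample ancestry profile table: q vector plus ternary class."""
    rows = [
        (s, *Q[i], classify_ternary(Q[i], major=major, minor=minor))
        for i, s in enumerate(samples)
    ]
    return pd.DataFrame(rows, columns=["sample", "q_C", "q_S", "q_M", "ternary_class"])


def class_composition_report(profiles: pd.DataFrame, sample_sheet) -> pd.DataFrame:
    """Contingency table location x ternary class (counts)."""
    loc = sample_sheet.location_of()
    df = profiles.copy()
    df["location"] = df["sample"].map(loc)
    tab = pd.crosstab(df["location"], df["ternary_class"])
    return tab
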
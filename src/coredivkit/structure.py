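"""Population structure: admixture-model ancestry, Evanno K selection,
cluster assignment, genotype PCA, and Hudson Fst.

The admixture model treats each genotype g_ij (copies of allele A1) as
Binomial(2, sum_k q_ik f_jk): Q holds per-sample ancestry fractions over K
subpopulations and F per-variant subpopulation allele frequencies.  The
likelihood is maximised by EM block updates of Q and F, which is the model
the original quasi-Newton tool optimises; the EM log-likelihood is
monotone non-decreasing, which the fit asserts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import MISSING, GenotypeMatrix

_F_EPS = 1e-6


class AdmixtureEM(BaseEstimator):
    """Maximum-likelihood admixture ancestry estimation by EM.

    Parameters
    ----------
    K : int
        Number of ancestral subpopulations.
    tol : float
        Relative log-likelihood change below which EM stops.
    max_iter : int
        Iteration cap.
    random_state : int or None
        Seeds the Dirichlet initialisation of Q and the jitter on F.

    Attributes (after ``fit``)
    --------------------------
    Q_ : (n_samples, K) ancestry fractions, rows summing to 1.
    F_ : (n_variants, K) subpopulation frequencies of allele A1.
    loglik_ : final log-likelihood.
    loglik_path_ : per-iteration log-likelihood (non-decreasing).
    n_iter_, converged_ : stopping diagnostics.
    """

    def __init__(self, K: int = 2, tol: float = 1e-4, max_iter: int = 2000,
                 random_state: int | None = None):
        self.K = K
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def _loglik(self, G, W, P):
        P = np.clip(P, _F_EPS, 1 - _F_EPS)
        return float(np.sum(W * (G * np.log(P) + (2 - G) * np.log1p(-P))))

    def fit(self, X, y=None):
        """Fit on a samples x variants dosage matrix (MISSING allowed)."""
        if self.K < 1:
            raise ValueError("K must be >= 1")
        G = np.asarray(X, dtype=np.float64)
        W = (G != MISSING).astype(np.float64)  # 1 where called
        G = np.where(W > 0, G, 0.0)
        n, m = G.shape
        K = self.K
        rng = np.random.default_rng(self.random_state)

        # init: F from observed frequencies jittered, Q from Dirichlet
        called = W.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_hat = np.where(called > 0, G.sum(axis=0) / (2 * called), 0.5)
        F = np.clip(
            p_hat[:, None] + rng.normal(0, 0.05 if K > 1 else 0.0, size=(m, K)),
            _F_EPS, 1 - _F_EPS,
        )
        Q = rng.dirichlet(np.ones(K), size=n) if K > 1 else np.ones((n, 1))
        Q = np.clip(Q, 1e-8, None)
        Q /= Q.sum(axis=1, keepdims=True)

        path = []
        prev = -np.inf
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            P = np.clip(Q @ F.T, _F_EPS, 1 - _F_EPS)
            A_sum_q = np.zeros_like(Q)
            A_sum_f_num = np.zeros_like(F)
            A_sum_f_den = np.zeros_like(F)
            R1 = W * G / P          # weight for the A1-allele expectation
            R0 = W * (2 - G) / (1 - P)
            for k in range(K):
                qf = Q[:, k][:, None] * F[:, k][None, :]
                q1f = Q[:, k][:, None] * (1 - F[:, k])[None, :]
                Ak = R1 * qf
                Bk = R0 * q1f
                A_sum_q[:, k] = Ak.sum(axis=1) + Bk.sum(axis=1)
                A_sum_f_num[:, k] = Ak.sum(axis=0)
                A_sum_f_den[:, k] = Ak.sum(axis=0) + Bk.sum(axis=0)
            denom = 2 * W.sum(axis=1, keepdims=True)
            Q = A_sum_q / np.maximum(denom, 1e-12)
            Q = np.clip(Q, 1e-12, None)
            Q /= Q.sum(axis=1, keepdims=True)
            with np.errstate(divide="ignore", invalid="ignore"):
                F = np.where(
                    A_sum_f_den > 0, A_sum_f_num / A_sum_f_den, F
                )
            F = np.clip(F, _F_EPS, 1 - _F_EPS)

            ll = self._loglik(G, W, Q @ F.T)
            path.append(ll)
            if np.isfinite(prev) and abs(ll - prev) < self.tol * abs(prev):
                converged = True
                break
            prev = ll

        self.Q_ = Q
        self.F_ = F
        self.loglik_ = path[-1]
        self.loglik_path_ = np.asarray(path)
        self.n_iter_ = it
        self.converged_ = converged
        return self


@dataclass
class AncestryModel:
    K: int
    Q: np.ndarray
    F: np.ndarray
    loglik: float
    n_iterations: int
    converged: bool
    seed: int | None = None


def fit_admixture(
    g: GenotypeMatrix | np.ndarray,
    K: int,
    seed: int | None = None,
    tol: float = 1e-4,
    max_iter: int = 2000,
) -> AncestryModel:
    """Functional wrapper over :class:`AdmixtureEM` on a genotype matrix."""
    X = g.dosages if isinstance(g, GenotypeMatrix) else np.asarray(g)
    est = AdmixtureEM(K=K, tol=tol, max_iter=max_iter, random_state=seed).fit(X)
    return AncestryModel(
        K=K, Q=est.Q_, F=est.F_, loglik=est.loglik_,
        n_iterations=est.n_iter_, converged=est.converged_, seed=seed,
    )


def evanno_best_k(logliks_by_k: dict[int, list[float]]) -> pd.DataFrame:
    """Evanno ΔK table from replicated log-likelihoods per K.

    ΔK(K) = mean over replicates of |L(K+1) - 2 L(K) + L(K-1)| divided by
    the standard deviation of L(K) across replicates; defined for interior
    K only.  The returned frame has one row per K and an attribute
    ``best_k`` (the ΔK argmax; ties broken toward the smallest K).
    """
    import warnings

    ks = sorted(logliks_by_k)
    if len(ks) < 3:
        raise ValueError("need at least 3 consecutive K values")
    reps = {k: np.asarray(logliks_by_k[k], dtype=float) for k in ks}
    if min(len(v) for v in reps.values()) < 2:
        raise ValueError("need >= 2 replicates per K")
    rows = []
    for k in ks:
        L = reps[k]
        row = {
            "K": k,
            "mean_L": L.mean(),
            "sd_L": L.std(ddof=1),
            "Lprime": np.nan,
            "Ldoubleprime": np.nan,
            "deltaK": np.nan,
        }
        if k - 1 in reps:
            row["Lprime"] = reps[k].mean() - reps[k - 1].mean()
        if k - 1 in reps and k + 1 in reps:
            r = min(len(reps[k - 1]), len(reps[k]), len(reps[k + 1]))
            l2 = np.abs(reps[k + 1][:r] - 2 * reps[k][:r] + reps[k - 1][:r])
            row["Ldoubleprime"] = l2.mean()
            sd = row["sd_L"]
            if sd > 0:
                row["deltaK"] = l2.mean() / sd
            else:
                warnings.warn(f"sd of L(K) is zero at K={k}; ΔK undefined there")
        rows.append(row)
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["deltaK"])
    if valid.empty:
        raise ValueError("ΔK undefined at every interior K")
    best = int(valid.loc[valid["deltaK"].idxmax(), "K"])
    table.attrs["best_k"] = best
    return table


def run_replicated_admixture(
    g: GenotypeMatrix | np.ndarray,
    k_min: int = 1,
    k_max: int = 10,
    n_replicates: int = 10,
    seed: int | None = None,
    tol: float = 1e-4,
    max_iter: int = 2000,
) -> dict[int, list[AncestryModel]]:
    """Fit the admixture model for K = k_min..k_max with replicates.

    Replicate seeds are fanned out deterministically from ``seed``.
    """
    rng = np.random.default_rng(seed)
    out: dict[int, list[AncestryModel]] = {}
    for K in range(k_min, k_max + 1):
        out[K] = [
            fit_admixture(g, K, seed=int(rng.integers(2**31 - 1)),
                          tol=tol, max_iter=max_iter)
            for _ in range(n_replicates)
        ]
    return out


def assign_clusters(model: AncestryModel, threshold: float = 0.70) -> np.ndarray:
    """Assign each sample to its majority-ancestry cluster.

    Returns an integer array: cluster index (0-based) where the maximum
    ancestry fraction is >= ``threshold`` (boundary inclusive), else -1
    ("unassigned").
    """
    if not (0.5 < threshold <= 1.0):
        raise ValueError("threshold must be in (0.5, 1]")
    q = np.asarray(model.Q)
    best = q.argmax(axis=1)
    return np.where(q.max(axis=1) >= threshold, best, -1)


class GenotypePCA(BaseEstimator):
    """PCA of mean-imputed, column-centered genotype dosages.

    Missing dosages are replaced by the variant's mean dosage; columns are
    centered (not scaled by default).  ``explained_variance_ratio_`` is
    taken against the total dosage variance, so the ratios over all
    possible components sum to 1.
    """

    def __init__(self, n_components: int = 10, scale: bool = False):
        self.n_components = n_components
        self.scale = scale

    def fit_transform(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        n, m = X.shape
        if self.n_components > min(n, m):
            raise ValueError("n_components exceeds min(n_samples, n_variants)")
        X = X.copy()
        X[X == MISSING] = np.nan
        mu = np.nanmean(X, axis=0)
        mu = np.where(np.isnan(mu), 0.0, mu)
        inds = np.where(np.isnan(X))
        X[inds] = np.take(mu, inds[1])
        X -= X.mean(axis=0)
        if self.scale:
            sd = X.std(axis=0)
            sd[sd == 0] = 1.0
            X /= sd
        u, s, _ = np.linalg.svd(X, full_matrices=False)
        total_var = (s**2).sum()
        k = self.n_components
        self.explained_variance_ratio_ = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
        self.singular_values_ = s[:k]
        coords = u[:, :k] * s[:k]
        self.coordinates_ = coords
        return coords

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self


def pca_genotypes(
    g: GenotypeMatrix | np.ndarray, n_components: int = 10, scale: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Sample PC coordinates and per-PC variance fractions."""
    X = g.dosages if isinstance(g, GenotypeMatrix) else np.asarray(g)
    est = GenotypePCA(n_components=n_components, scale=scale)
    coords = est.fit_transform(X)
    return coords, est.explained_variance_ratio_


def hudson_fst(
    g: GenotypeMatrix | np.ndarray, group_a, group_b
) -> float:
    """Hudson Fst between two sample sets, ratio-of-averages over sites.

    Per site j: N_j = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1) and
    D_j = p1(1-p2) + p2(1-p1), with n the number of called alleles in each
    group; Fst = sum N_j / sum D_j over sites where both groups have >= 2
    called alleles and D_j > 0.
    """
    X = g.dosages if isinstance(g, GenotypeMatrix) else np.asarray(g)
    a = np.asarray(group_a, dtype=int)
    b = np.asarray(group_b, dtype=int)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 samples")

    def freqs(idx):
        sub = X[idx, :].astype(np.float64)
        called = 2.0 * (sub != MISSING).sum(axis=0)
        tot = np.where(sub == MISSING, 0, sub).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(called > 0, tot / called, np.nan)
        return p, called

    p1, n1 = freqs(a)
    p2, n2 = freqs(b)
    ok = (n1 >= 2) & (n2 >= 2) & ~np.isnan(p1) & ~np.isnan(p2)
    if not ok.any():
        raise ValueError("no site with >= 2 called alleles in both groups")
    p1, p2, n1, n2 = p1[ok], p2[ok], n1[ok], n2[ok]
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    use = den > 0
    if not use.any():
        raise ValueError("Fst undefined: all sites monomorphic across both groups")
    return float(num[use].sum() / den[use].sum())
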
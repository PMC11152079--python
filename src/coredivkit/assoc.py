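"""Mixed-model association scans, Bonferroni control, peak calling, and
cluster-vs-phenotype tests.

The per-variant model is y = W a + x b + u + e with u ~ N(0, sg^2 K) for a
centered genomic relatedness matrix K and e ~ N(0, se^2 I).  K is
eigendecomposed once; the variance ratio lambda = sg^2/se^2 is estimated by
REML under the no-SNP model and reused across variants (an exact
per-variant option exists), after which every variant reduces to a 2x2
weighted least-squares solve and a Wald t test of b = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .io import MISSING, GenotypeMatrix, PhenotypeTable


def centered_kinship(g: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """K = (1/m) sum_j (x_j - mean_j)(x_j - mean_j)^T over dosage columns.

    Missing dosages are mean-imputed per variant for this computation only.
    """
    X = (g.dosages if isinstance(g, GenotypeMatrix) else np.asarray(g)).astype(np.float64)
    if X.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    X = X.copy()
    X[X == MISSING] = np.nan
    mu = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(mu, inds[1])
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        raise ValueError("all variants monomorphic; kinship is degenerate")
    return (Xc @ Xc.T) / X.shape[1]


def encode_phenotype(
    table: PhenotypeTable, trait: str, min_observations: int = 20
) -> tuple[pd.Series, dict]:
    """Response vector for one trait, per the scan's encoding rules.

    Quantitative traits are natural-log transformed; non-positive values
    are dropped (their count is reported).  Qualitative indicator traits
    pass through as 0/1.  Missing stays missing.
    """
    if trait not in table.data.columns:
        raise KeyError(f"trait {trait!r} not present")
    col = table.data[trait]
    info = {"trait": trait, "kind": table.kinds.get(trait), "n_dropped_nonpositive": 0}
    if table.kinds.get(trait) == "quantitative":
        y = col.copy().astype(float)
        nonpos = y.notna() & (y <= 0)
        info["n_dropped_nonpositive"] = int(nonpos.sum())
        y[nonpos] = np.nan
        y = np.log(y)
        info["transform"] = "ln"
    else:
        y = col.astype(float)
        info["transform"] = "identity"
    if y.notna().sum() < min_observations:
        raise ValueError(
            f"trait {trait!r} has only {int(y.notna().sum())} observations "
            f"(< {min_observations}); refusing to scan"
        )
    return y, info


def _reml_neg_loglik(log_lam: float, s: np.ndarray, Uty: np.ndarray,
                     UtW: np.ndarray) -> float:
    lam = np.exp(log_lam)
    w = 1.0 / (lam * s + 1.0)
    WtHW = UtW.T @ (w[:, None] * UtW)
    WtHy = UtW.T @ (w * Uty)
    sign, logdet_WtHW = np.linalg.slogdet(WtHW)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(WtHW, WtHy)
    rss = float(Uty @ (w * Uty) - WtHy @ beta)
    n, c = len(Uty), UtW.shape[1]
    if rss <= 0:
        return np.inf
    logdet_H = float(np.sum(np.log(lam * s + 1.0)))
    return 0.5 * (logdet_H + logdet_WtHW + (n - c) * np.log(rss))


@dataclass
class AssociationScan:
    """Per-variant effects, standard errors and Wald p-values for one trait."""

    results: pd.DataFrame  # id, chrom, pos, maf, n_used, beta, se, p
    trait: str
    transform: str
    n_tests: int
    lambda_: float
    bonferroni_alpha: float = 0.05

    @property
    def bonferroni_cutoff(self) -> float:
        return bonferroni_threshold(self.n_tests, self.bonferroni_alpha)

    def significant(self) -> pd.DataFrame:
        return self.results[self.results["p"] <= self.bonferroni_cutoff]


class LinearMixedGWAS(BaseEstimator):
    """Univariate linear-mixed-model association scan.

    Parameters
    ----------
    min_maf, max_missing : variant filters applied before testing (strict
        inequalities: MAF > min_maf, missingness < max_missing).
    per_variant_lambda : re-optimise the variance ratio for every variant
        instead of reusing the null-model estimate.
    """

    def __init__(self, min_maf: float = 0.01, max_missing: float = 0.05,
                 per_variant_lambda: bool = False, alpha: float = 0.05):
        self.min_maf = min_maf
        self.max_missing = max_missing
        self.per_variant_lambda = per_variant_lambda
        self.alpha = alpha

    def fit(self, X, y, kinship=None, variants: pd.DataFrame | None = None):
        """Scan dosage matrix ``X`` (samples x variants) against ``y``.

        Samples with missing ``y`` are dropped; ``kinship`` defaults to the
        centered kinship of ``X`` computed on the retained samples.
        """
        X = np.asarray(X)
        y = np.asarray(y, dtype=float)
        keep = ~np.isnan(y)
        X = X[keep, :]
        y = y[keep]
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite response values")
        n = len(y)
        K = centered_kinship(X) if kinship is None else np.asarray(kinship)[np.ix_(keep, keep)]
        if not np.allclose(K, K.T, atol=1e-8):
            raise ValueError("kinship matrix not symmetric")
        s, U = np.linalg.eigh(K)
        if s.min() < -1e-6 * max(1.0, abs(s.max())):
            raise ValueError("kinship matrix not positive semi-definite")
        s = np.clip(s, 0.0, None)

        # variant filters
        miss = X == MISSING
        called = (~miss).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p1 = np.where(called > 0, np.where(miss, 0, X).sum(axis=0) / (2.0 * called), np.nan)
        maf = np.minimum(p1, 1 - p1)
        miss_frac = miss.mean(axis=0)
        tested = (maf > self.min_maf) & (miss_frac < self.max_missing) & ~np.isnan(maf)
        idx = np.flatnonzero(tested)
        if len(idx) == 0:
            raise ValueError("no variant passes the MAF/missingness filters")

        Xs = X[:, idx].astype(np.float64)
        Xs[Xs == MISSING] = np.nan
        mu = np.nanmean(Xs, axis=0)
        nan_at = np.where(np.isnan(Xs))
        Xs[nan_at] = np.take(mu, nan_at[1])

        ones = np.ones(n)
        Uty = U.T @ y
        Ut1 = U.T @ ones
        res = optimize.minimize_scalar(
            _reml_neg_loglik, bounds=(-10.0, 10.0), method="bounded",
            args=(s, Uty, Ut1[:, None]),
        )
        lam = float(np.exp(res.x))
        self.lambda_ = lam

        w = 1.0 / (lam * s + 1.0)
        UtX = U.T @ Xs
        if self.per_variant_lambda:
            beta = np.empty(len(idx))
            se = np.empty(len(idx))
            pvals = np.empty(len(idx))
            for jj in range(len(idx)):
                W2 = np.column_stack([Ut1, UtX[:, jj]])
                r = optimize.minimize_scalar(
                    _reml_neg_loglik, bounds=(-10.0, 10.0), method="bounded",
                    args=(s, Uty, W2),
                )
                lj = float(np.exp(r.x))
                wj = 1.0 / (lj * s + 1.0)
                beta[jj], se[jj], pvals[jj] = _wald_one(wj, Ut1, UtX[:, jj], Uty, n)
        else:
            a11 = float(np.sum(w * Ut1 * Ut1))
            a12 = (w * Ut1) @ UtX
            a22 = np.einsum("i,ij,ij->j", w, UtX, UtX)
            b1 = float(np.sum(w * Ut1 * Uty))
            b2 = (w * Uty) @ UtX
            det = a11 * a22 - a12**2
            det = np.where(det <= 0, np.nan, det)
            beta = (a11 * b2 - a12 * b1) / det
            alpha_hat = (a22 * b1 - a12 * b2) / det
            yy = float(np.sum(w * Uty * Uty))
            rss = yy - (alpha_hat * b1 + beta * b2)
            rss = np.clip(rss, 1e-300, None)
            sigma2 = rss / (n - 2)
            se = np.sqrt(sigma2 * a11 / det)
            with np.errstate(divide="ignore", invalid="ignore"):
                tstat = beta / se
            pvals = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
        pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)

        if variants is not None:
            vsub = variants.iloc[idx]
            out = pd.DataFrame(
                {
                    "id": vsub["id"].to_numpy(),
                    "chrom": vsub["chrom"].to_numpy(),
                    "pos": vsub["pos"].to_numpy(),
                }
            )
        else:
            out = pd.DataFrame({"id": idx.astype(str), "chrom": "0", "pos": idx})
        out["maf"] = maf[idx]
        out["n_used"] = n
        out["beta"] = beta
        out["se"] = se
        out["p"] = pvals
        self.results_ = out
        self.n_tests_ = len(idx)
        self.tested_index_ = idx
        return self


def _wald_one(w, Ut1, Utx, Uty, n):
    a11 = float(np.sum(w * Ut1 * Ut1))
    a12 = float(np.sum(w * Ut1 * Utx))
    a22 = float(np.sum(w * Utx * Utx))
    b1 = float(np.sum(w * Ut1 * Uty))
    b2 = float(np.sum(w * Utx * Uty))
    det = a11 * a22 - a12**2
    if det <= 0:
        return np.nan, np.nan, 1.0
    beta = (a11 * b2 - a12 * b1) / det
    alpha_hat = (a22 * b1 - a12 * b2) / det
    rss = float(np.sum(w * Uty * Uty)) - (alpha_hat * b1 + beta * b2)
    sigma2 = max(rss, 1e-300) / (n - 2)
    se = float(np.sqrt(sigma2 * a11 / det))
    t = beta / se
    return beta, se, 2.0 * stats.t.sf(abs(t), df=n - 2)


def lmm_scan(
    g: GenotypeMatrix,
    y,
    kinship: np.ndarray | None = None,
    trait: str = "trait",
    transform: str = "identity",
    min_maf: float = 0.01,
    max_missing: float = 0.05,
    per_variant_lambda: bool = False,
) -> AssociationScan:
    """Functional wrapper over :class:`LinearMixedGWAS` on a genotype matrix."""
    est = LinearMixedGWAS(
        min_maf=min_maf, max_missing=max_missing, per_variant_lambda=per_variant_lambda
    ).fit(g.dosages, np.asarray(y, dtype=float), kinship=kinship, variants=g.variants)
    return AssociationScan(
        results=est.results_,
        trait=trait,
        transform=transform,
        n_tests=est.n_tests_,
        lambda_=est.lambda_,
    )


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise cutoff alpha / n_tests; significance is p <= cutoff."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


@dataclass
class Peak:
    chrom: str
    start: int
    end: int
    member_ids: list
    tag_snp: str
    tag_p: float


def call_peaks(
    scan: AssociationScan,
    g: GenotypeMatrix,
    r2_link: float = 0.20,
    max_gap: int = 1_000_000,
) -> list[Peak]:
    """Merge significant variants into peaks.

    Two significant variants are linked when they share a chromosome, lie
    within ``max_gap`` bp, and have pairwise r2 > ``r2_link``; peaks are the
    connected components.  The tag SNP is the member with the minimum
    p-value (ties: smaller position, then id).
    """
    sig = scan.significant()
    if sig.empty:
        return []
    sig = sig.sort_values(["chrom", "pos"]).reset_index(drop=True)
    id_to_col = {v: j for j, v in enumerate(g.variants["id"])}
    cols = [id_to_col[v] for v in sig["id"]]
    X = g.dosages[:, cols].astype(np.float64)
    X[X == MISSING] = np.nan
    mu = np.nanmean(X, axis=0)
    nan_at = np.where(np.isnan(X))
    X[nan_at] = np.take(mu, nan_at[1])
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    sd[sd == 0] = np.nan
    Z = Xc / sd
    r2 = np.nan_to_num((Z.T @ Z) / X.shape[0], nan=0.0) ** 2

    k = len(sig)
    parent = list(range(k))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    chrom = sig["chrom"].to_numpy()
    pos = sig["pos"].to_numpy()
    for i in range(k):
        for j in range(i + 1, k):
            if chrom[i] != chrom[j]:
                continue
            if abs(int(pos[j]) - int(pos[i])) > max_gap:
                continue
            if r2[i, j] > r2_link:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri

    comps: dict[int, list[int]] = {}
    for i in range(k):
        comps.setdefault(find(i), []).append(i)
    peaks = []
    for members in comps.values():
        sub = sig.iloc[members].sort_values(["p", "pos", "id"])
        tag = sub.iloc[0]
        peaks.append(
            Peak(
                chrom=str(tag["chrom"]),
                start=int(sub["pos"].min()),
                end=int(sub["pos"].max()),
                member_ids=sorted(sub["id"].tolist()),
                tag_snp=str(tag["id"]),
                tag_p=float(tag["p"]),
            )
        )
    peaks.sort(key=lambda p: (p.chrom, p.start))
    return peaks


def cluster_phenotype_tests(
    table: PhenotypeTable,
    assignment: np.ndarray,
    sample_ids,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Compare trait distributions between two ancestry clusters.

    Quantitative traits: two-sided Mann-Whitney-Wilcoxon.  Qualitative
    (0/1 indicator) traits: two-sided Fisher exact test on the 2x2
    presence table.  Unassigned samples (-1) are excluded.  Bonferroni
    correction is applied within each trait family separately.
    """
    assignment = np.asarray(assignment)
    clusters = sorted(set(assignment[assignment >= 0].tolist()))
    if len(clusters) != 2:
        raise ValueError("exactly two assigned clusters required")
    id_pos = {s: i for i, s in enumerate(sample_ids)}
    rows = []
    for trait in table.traits():
        vals = table.data[trait]
        v = np.full(len(sample_ids), np.nan)
        for s, x in vals.items():
            if s in id_pos:
                v[id_pos[s]] = x
        in_a = (assignment == clusters[0]) & ~np.isnan(v)
        in_b = (assignment == clusters[1]) & ~np.isnan(v)
        kind = table.kinds.get(trait, "quantitative")
        flag = ""
        if in_a.sum() == 0 or in_b.sum() == 0:
            p = np.nan
            flag = "no data in one cluster"
        elif kind == "quantitative":
            va, vb = v[in_a], v[in_b]
            if np.ptp(va) == 0 and np.ptp(vb) == 0 and va[0] == vb[0]:
                p, flag = 1.0, "zero variance in both clusters"
            else:
                p = float(stats.mannwhitneyu(va, vb, alternative="two-sided").pvalue)
        else:
            a1 = int(np.nansum(v[in_a]))
            b1 = int(np.nansum(v[in_b]))
            tab = [[a1, int(in_a.sum()) - a1], [b1, int(in_b.sum()) - b1]]
            p = float(stats.fisher_exact(tab, alternative="two-sided")[1])
        rows.append({"trait": trait, "kind": kind, "p": p, "flag": flag,
                     "n_a": int(in_a.sum()), "n_b": int(in_b.sum())})
    out = pd.DataFrame(rows)
    for kind in ("quantitative", "qualitative"):
        fam = out["kind"] == kind
        n_fam = int((fam & out["p"].notna()).sum())
        if n_fam:
            out.loc[fam, "p_cutoff"] = alpha / n_fam
            out.loc[fam, "significant"] = out.loc[fam, "p"] <= alpha / n_fam
    return out


def regional_enrichment(
    categories, assignment: np.ndarray, alpha: float = 0.05
) -> pd.DataFrame:
    """Chi-squared test of cluster membership per category level.

    For each level (e.g. geographic region) builds the 2x2 table
    (in level vs not) x (cluster a vs cluster b) among assigned samples.
    """
    assignment = np.asarray(assignment)
    categories = np.asarray(categories, dtype=object)
    assigned = assignment >= 0
    clusters = sorted(set(assignment[assigned].tolist()))
    if len(clusters) != 2:
        raise ValueError("exactly two assigned clusters required")
    rows = []
    for level in sorted({c for c in categories[assigned] if c is not None and c == c}, key=str):
        in_level = assigned & (categories == level)
        out_level = assigned & (categories != level)
        tab = np.array(
            [
                [(in_level & (assignment == c)).sum() for c in clusters],
                [(out_level & (assignment == c)).sum() for c in clusters],
            ]
        )
        if (tab.sum(axis=1) == 0).any() or (tab.sum(axis=0) == 0).any():
            p = np.nan
        else:
            p = float(stats.chi2_contingency(tab, correction=False)[1])
        rows.append({"category": level, "n": int(in_level.sum()), "p": p})
    return pd.DataFrame(rows)
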
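"""Site/sample quality filters, near-duplicate accession collapse, LD pruning.

The filtering order is fixed: sites by missingness, then samples by
missingness and heterozygosity, then duplicate-accession collapse on the
allelic Hamming distance, then MAF/missingness selection plus windowed LD
pruning to produce the marker set used for structure analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import MISSING, GenotypeMatrix


@dataclass
class QCReport:
    """Counts and thresholds from one filtering step."""

    step: str
    thresholds: dict
    n_sites_removed: int = 0
    n_samples_removed: int = 0
    removed_samples: pd.DataFrame | None = None  # columns: id, reason


@dataclass
class DuplicateClustering:
    """Groups of near-identical accessions and their chosen representatives.

    ``distance_matrix`` is the symmetric allelic-mismatch count matrix the
    clustering was computed on; ``clusters`` maps a cluster label to the
    member sample ids (every cluster has >= 2 members); ``representatives``
    maps the same labels to the member retained downstream.
    """

    distance_matrix: np.ndarray
    sample_ids: list
    clusters: dict = field(default_factory=dict)
    representatives: dict = field(default_factory=dict)
    cut_height: float = 500.0
    rng_seed: int | None = None


def filter_sites_by_missingness(
    g: GenotypeMatrix, max_missing_fraction: float = 0.95
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop variants whose missing-call fraction exceeds the threshold."""
    if not (0 < max_missing_fraction <= 1):
        raise ValueError("max_missing_fraction must be in (0, 1]")
    miss_frac = g.missing_mask().mean(axis=0)
    keep = miss_frac <= max_missing_fraction
    report = QCReport(
        step="filter_sites_by_missingness",
        thresholds={"max_missing_fraction": max_missing_fraction},
        n_sites_removed=int((~keep).sum()),
    )
    return g.take_variants(np.flatnonzero(keep)), report


def filter_samples(
    g: GenotypeMatrix, max_missing: float = 0.50, max_het: float = 0.20
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop samples with > ``max_missing`` missing calls or a heterozygous
    fraction (hets / non-missing calls) > ``max_het``.  Both inequalities
    are strict: a sample at exactly the threshold is retained."""
    if g.n_variants == 0 or g.n_samples == 0:
        raise ValueError("empty genotype matrix")
    miss = g.missing_mask()
    miss_frac = miss.mean(axis=1)
    n_called = (~miss).sum(axis=1)
    het_frac = np.divide(
        (g.dosages == 1).sum(axis=1),
        n_called,
        out=np.zeros(g.n_samples),
        where=n_called > 0,
    )
    drop_miss = miss_frac > max_missing
    drop_het = het_frac > max_het
    keep = ~(drop_miss | drop_het)
    removed = pd.DataFrame(
        {
            "id": g.samples["id"][~keep],
            "reason": np.where(drop_miss[~keep], "missingness", "heterozygosity"),
        }
    ).reset_index(drop=True)
    report = QCReport(
        step="filter_samples",
        thresholds={"max_missing": max_missing, "max_het": max_het},
        n_samples_removed=int((~keep).sum()),
        removed_samples=removed,
    )
    return g.take_samples(np.flatnonzero(keep)), report


def pairwise_hamming(g: GenotypeMatrix) -> np.ndarray:
    """Allelic mismatch counts between all sample pairs.

    distance(i, j) = sum over variants called in both of |dosage_i -
    dosage_j| (so opposite homozygotes count 2), rescaled by
    total_variants / shared_called_variants and rounded to the nearest
    integer -- the flat-missing behaviour of plink 1.9 --distance.  Pairs
    with zero shared called variants get NaN.
    """
    if g.n_samples < 2:
        raise ValueError("need >= 2 samples")
    d = g.dosages.astype(np.float64)
    called = ~g.missing_mask()
    d[~called] = 0.0
    m_total = g.n_variants
    n = g.n_samples
    out = np.zeros((n, n))
    shared = called.astype(np.float64) @ called.T.astype(np.float64)
    for i in range(n):
        both = called[i] & called
        diff = np.abs(d[i] - d) * both
        out[i] = diff.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(shared > 0, np.rint(out * (m_total / shared)), np.nan)
    np.fill_diagonal(out, 0.0)
    return out


def cluster_near_identical(
    distance_matrix: np.ndarray,
    sample_ids,
    cut_height: float = 500.0,
    seed: int | None = None,
    method: str = "average",
) -> DuplicateClustering:
    """Agglomerative clustering of the distance matrix with a static tree cut.

    Groups whose merge height stays below ``cut_height`` form clusters;
    singletons are dropped.  One representative per cluster is drawn
    uniformly at random under ``seed``.
    """
    if cut_height <= 0:
        raise ValueError("cut_height must be positive")
    if method not in {"single", "complete", "average"}:
        raise ValueError(f"unsupported linkage method {method!r}")
    dm = np.asarray(distance_matrix, dtype=float)
    if np.isnan(dm).any():
        raise ValueError("distance matrix contains undefined (NaN) entries")
    z = linkage(squareform(dm, checks=False), method=method)
    labels = fcluster(z, t=cut_height, criterion="distance")
    rng = np.random.default_rng(seed)
    ids = list(sample_ids)
    clusters: dict = {}
    reps: dict = {}
    for lab in np.unique(labels):
        members = [ids[i] for i in np.flatnonzero(labels == lab)]
        if len(members) >= 2:
            key = len(clusters) + 1
            clusters[key] = members
            reps[key] = members[rng.integers(len(members))]
    return DuplicateClustering(
        distance_matrix=dm,
        sample_ids=ids,
        clusters=clusters,
        representatives=reps,
        cut_height=cut_height,
        rng_seed=seed,
    )


def drop_duplicates(g: GenotypeMatrix, clustering: DuplicateClustering) -> GenotypeMatrix:
    """Retain all unclustered samples plus one representative per cluster."""
    clustered = {s for members in clustering.clusters.values() for s in members}
    reps = set(clustering.representatives.values())
    if not reps <= set(g.samples["id"]):
        raise ValueError("representative sample not present in matrix")
    keep = [
        i
        for i, s in enumerate(g.samples["id"])
        if s not in clustered or s in reps
    ]
    return g.take_samples(np.asarray(keep, dtype=int))


def _maf_and_missing(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    miss = g.missing_mask()
    called = (~miss).sum(axis=0)
    d = np.where(miss, 0, g.dosages).astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(called > 0, d.sum(axis=0) / (2.0 * called), np.nan)
    maf = np.minimum(p1, 1.0 - p1)
    return maf, miss.mean(axis=0)


def _r2_mean_imputed(x: np.ndarray) -> np.ndarray:
    """Pairwise squared dosage correlation with missing set to column mean."""
    x = x.astype(np.float64)
    miss = x == MISSING
    x[miss] = np.nan
    mu = np.nanmean(x, axis=0)
    x = np.where(np.isnan(x), mu, x)
    x -= x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = np.nan
    xn = x / sd
    r = (xn.T @ xn) / x.shape[0]
    return np.nan_to_num(r**2, nan=0.0)


def ld_prune(
    g: GenotypeMatrix,
    window: int = 50,
    step: int = 10,
    r2_threshold: float = 0.20,
    min_maf: float = 0.01,
    max_missing: float = 0.05,
) -> list:
    """Greedy windowed LD pruning; returns retained variant ids in order.

    Variants are first restricted to MAF >= ``min_maf`` and missingness
    <= ``max_missing``; then, per chromosome, within each ``window``-SNP
    window sliding by ``step``, while any retained pair exceeds the r2
    threshold, the member with the lower MAF (tie: later position) is
    removed -- the plink 1.9 --indep-pairwise scheme.
    """
    if window < step:
        raise ValueError("window must be >= step")
    maf, miss = _maf_and_missing(g)
    eligible = (maf >= min_maf) & (miss <= max_missing) & ~np.isnan(maf)
    kept_ids: list = []
    for chrom in pd.unique(g.variants["chrom"]):
        on_chrom = np.flatnonzero((g.variants["chrom"] == chrom).to_numpy() & eligible)
        if len(on_chrom) == 0:
            continue
        alive = np.ones(len(on_chrom), dtype=bool)
        pos = g.variants["pos"].to_numpy()[on_chrom]
        sub_maf = maf[on_chrom]
        # windows slide over the currently retained list; passes repeat until
        # stable so that no surviving pair inside any window exceeds the
        # threshold (removals compact the list, bringing new pairs together)
        changed = True
        while changed:
            changed = False
            live_all = np.flatnonzero(alive)
            start = 0
            while start < len(live_all):
                live = live_all[start: start + window]
                live = live[alive[live]]
                if len(live) > 1:
                    r2 = _r2_mean_imputed(g.dosages[:, on_chrom[live]].copy())
                    np.fill_diagonal(r2, 0.0)
                    while True:
                        i, j = np.unravel_index(np.argmax(r2), r2.shape)
                        if r2[i, j] <= r2_threshold:
                            break
                        # drop the lower-MAF member; tie -> later position
                        mi, mj = sub_maf[live[i]], sub_maf[live[j]]
                        if mi < mj:
                            drop = i
                        elif mj < mi:
                            drop = j
                        else:
                            drop = (i, j)[int(pos[live[j]] > pos[live[i]])]
                        alive[live[drop]] = False
                        changed = True
                        r2[drop, :] = 0.0
                        r2[:, drop] = 0.0
                if start + window >= len(live_all):
                    break
                start += step
        kept_ids.extend(g.variants["id"].to_numpy()[on_chrom[alive]].tolist())
    return kept_ids
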
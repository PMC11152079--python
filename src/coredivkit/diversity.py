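"""Allele-frequency diversity statistics and the minimal core-subset search.

Expected heterozygosity is the biallelic gene diversity
He = (1/N) * sum_sites (1 - (p^2 + q^2)) with p, q the major/minor allele
frequencies computed over non-missing calls.  The core-subset search adds
accessions one at a time in random order and records, per cohort size, the
fraction of the full panel's segregating sites (and He) captured; the
minimal core size for a target is the smallest size whose mean captured
fraction across iterations reaches the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix


def allele_frequencies(g: GenotypeMatrix, sample_index=None) -> pd.DataFrame:
    """Per-variant allele frequencies over non-missing calls.

    Returns a frame with columns p (major), q (minor), maf, p_a1 (frequency
    of allele A1), n_called.  Variants with zero calls in the subset have
    NaN frequencies.
    """
    d = g.dosages
    if sample_index is not None:
        sample_index = np.asarray(sample_index)
        if len(sample_index) == 0:
            raise ValueError("empty sample subset")
        d = d[sample_index, :]
    miss = d == MISSING
    called = (~miss).sum(axis=0)
    a1 = np.where(miss, 0, d).sum(axis=0).astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_a1 = np.where(called > 0, a1 / (2.0 * called), np.nan)
    maf = np.minimum(p_a1, 1.0 - p_a1)
    return pd.DataFrame(
        {
            "id": g.variants["id"].to_numpy(),
            "p": np.maximum(p_a1, 1.0 - p_a1),
            "q": maf,
            "maf": maf,
            "p_a1": p_a1,
            "n_called": called,
        }
    )


def expected_heterozygosity(freqs: pd.DataFrame) -> float:
    """He = mean over defined sites of 1 - (p^2 + q^2)."""
    p = freqs["p"].to_numpy(dtype=float)
    q = freqs["q"].to_numpy(dtype=float)
    ok = ~np.isnan(p)
    if not ok.any():
        raise ValueError("no sites with defined allele frequencies")
    return float(np.mean(1.0 - (p[ok] ** 2 + q[ok] ** 2)))


@dataclass
class DiversitySummary:
    group: str
    n_samples: int
    n_segregating: int
    he: float
    folded_afs: pd.DataFrame  # columns: bin_low, bin_high, n_sites
    median_maf_segregating: float


def folded_afs(maf: np.ndarray, bin_width: float = 0.05) -> pd.DataFrame:
    """Histogram of segregating-site counts by minor allele frequency.

    Bins cover (0, 0.5] with half-open intervals (low, high]; monomorphic
    and undefined sites are excluded.
    """
    maf = maf[~np.isnan(maf) & (maf > 0)]
    edges = np.arange(0.0, 0.5 + bin_width / 2, bin_width)
    # right-closed bins so maf = 0.5 lands in the last bin
    idx = np.clip(np.ceil(maf / bin_width).astype(int) - 1, 0, len(edges) - 2)
    counts = np.bincount(idx, minlength=len(edges) - 1)
    return pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "n_sites": counts}
    )


def diversity_summary(
    g: GenotypeMatrix, grouping: dict, bin_width: float = 0.05
) -> list[DiversitySummary]:
    """Per-group segregating sites, He, folded AFS and median segregating MAF.

    ``grouping`` maps sample id -> group label; samples without a label are
    ignored.  Empty groups are skipped with a warning.
    """
    import warnings

    ids = g.samples["id"].to_numpy()
    out = []
    for group in sorted(set(grouping.values()), key=str):
        idx = np.flatnonzero([grouping.get(s) == group for s in ids])
        if len(idx) == 0:
            warnings.warn(f"group {group!r} has no samples; skipped")
            continue
        freqs = allele_frequencies(g, idx)
        maf = freqs["maf"].to_numpy(dtype=float)
        seg = ~np.isnan(maf) & (maf > 0)
        he = expected_heterozygosity(freqs)
        out.append(
            DiversitySummary(
                group=str(group),
                n_samples=len(idx),
                n_segregating=int(seg.sum()),
                he=he,
                folded_afs=folded_afs(maf, bin_width),
                median_maf_segregating=float(np.median(maf[seg])) if seg.any() else float("nan"),
            )
        )
    return out


@dataclass
class CoreSubsetResult:
    target_fraction: float
    minimal_n: int
    representative_subset: list
    n_iterations: int
    capture_curve: pd.DataFrame  # size, mean_seg_fraction, mean_he_fraction
    rng_seed: int | None = None


def _segregating_mask(d: np.ndarray) -> np.ndarray:
    """Sites where both alleles are observed among non-missing calls."""
    has_a1 = ((d == 1) | (d == 2)).any(axis=0)
    has_a2 = ((d == 1) | (d == 0)).any(axis=0)
    return has_a1 & has_a2


def minimal_core_subset(
    g: GenotypeMatrix,
    target_fraction: float,
    n_iterations: int = 1000,
    seed: int | None = None,
    track_he: bool = True,
) -> CoreSubsetResult:
    """Smallest cohort capturing ``target_fraction`` of the panel's diversity.

    Diversity capture is measured as the fraction of the full panel's
    segregating sites present in the cohort (He capture is tracked
    alongside for inspection).  Accessions are added one at a time in a
    random order per iteration; the minimal n is the smallest cohort size
    whose mean captured fraction across iterations reaches the target.
    """
    if not (0 < target_fraction <= 1):
        raise ValueError("target_fraction must be in (0, 1]")
    n, m = g.shape
    d = g.dosages
    baseline_seg = _segregating_mask(d)
    n_base = int(baseline_seg.sum())
    if n_base == 0:
        raise ValueError("panel is monomorphic; target unreachable")
    freqs_all = allele_frequencies(g)
    he_base = expected_heterozygosity(freqs_all)

    rng = np.random.default_rng(seed)
    seg_frac = np.zeros((n_iterations, n))
    he_frac = np.zeros((n_iterations, n)) if track_he else None
    orders = np.empty((n_iterations, n), dtype=int)
    miss = d == MISSING
    dz = np.where(miss, 0, d).astype(np.int64)
    for it in range(n_iterations):
        order = rng.permutation(n)
        orders[it] = order
        seen_a1 = np.zeros(m, dtype=bool)
        seen_a2 = np.zeros(m, dtype=bool)
        if track_he:
            a1_count = np.zeros(m, dtype=np.int64)
            called2 = np.zeros(m, dtype=np.int64)
        for k, i in enumerate(order):
            row = d[i]
            seen_a1 |= (row == 1) | (row == 2)
            seen_a2 |= (row == 1) | (row == 0)
            seg_frac[it, k] = (seen_a1 & seen_a2 & baseline_seg).sum() / n_base
            if track_he:
                a1_count += dz[i]
                called2 += 2 * (~miss[i])
                with np.errstate(divide="ignore", invalid="ignore"):
                    p1 = a1_count / called2
                ok = called2 > 0
                he_k = np.mean(2.0 * p1[ok] * (1.0 - p1[ok])) if ok.any() else 0.0
                he_frac[it, k] = he_k / he_base

    mean_seg = seg_frac.mean(axis=0)
    curve = pd.DataFrame(
        {
            "size": np.arange(1, n + 1),
            "mean_seg_fraction": mean_seg,
            "mean_he_fraction": he_frac.mean(axis=0) if track_he else np.nan,
        }
    )
    meeting = np.flatnonzero(mean_seg >= target_fraction)
    if len(meeting) == 0:
        raise ValueError("target fraction never reached (increase iterations?)")
    minimal_n = int(meeting[0] + 1)
    # representative subset: iteration whose capture at minimal_n is the
    # closest above the target
    at_size = seg_frac[:, minimal_n - 1]
    above = at_size >= target_fraction
    cand = np.flatnonzero(above) if above.any() else np.array([int(np.argmax(at_size))])
    best_it = cand[np.argmin(at_size[cand] - target_fraction)]
    ids = g.samples["id"].to_numpy()
    subset = ids[orders[best_it][:minimal_n]].tolist()
    return CoreSubsetResult(
        target_fraction=target_fraction,
        minimal_n=minimal_n,
        representative_subset=subset,
        n_iterations=n_iterations,
        capture_curve=curve,
        rng_seed=seed,
    )
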
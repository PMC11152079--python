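"""Linkage-disequilibrium profiles, background level, and decay distances.

r2 between two sites is the squared Pearson correlation of their dosage
vectors over pairwise-complete samples (composite LD on unphased array
data).  Pairs are only formed within a chromosome and within a distance
cap; decay profiles average r2 in fixed-width distance bins and take the
median of the occupied-bin means as the background level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, chromosome_sort_key


def pairwise_r2_within(
    g: GenotypeMatrix, max_distance: int = 10_000_000
) -> pd.DataFrame:
    """All same-chromosome variant pairs within ``max_distance`` bp.

    Returns columns (id_a, id_b, chrom, distance, r2).  r2 is computed on
    pairwise-complete samples; pairs monomorphic in the complete subset
    (undefined correlation) are omitted.
    """
    if not g.is_sorted():
        raise ValueError("variants must be sorted by (chromosome, position)")
    X = g.dosages.astype(np.float64)
    X[g.dosages == MISSING] = np.nan
    chroms = g.variants["chrom"].to_numpy()
    pos = g.variants["pos"].to_numpy()
    ids = g.variants["id"].to_numpy()
    rows = []
    for chrom in sorted(pd.unique(chroms), key=chromosome_sort_key):
        idx = np.flatnonzero(chroms == chrom)
        cp = pos[idx]
        for a_i, j in enumerate(idx):
            upper = np.searchsorted(cp, cp[a_i] + max_distance, side="right")
            partners = idx[a_i + 1: upper]
            if len(partners) == 0:
                continue
            x = X[:, j]
            y = X[:, partners]
            both = ~np.isnan(x)[:, None] & ~np.isnan(y)
            nb = both.sum(axis=0).astype(np.float64)
            xm = np.where(both, x[:, None], 0.0)
            ym = np.where(both, y, 0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                sx = xm.sum(axis=0) / nb
                sy = ym.sum(axis=0) / nb
                sxx = (xm**2).sum(axis=0) / nb - sx**2
                syy = (ym**2).sum(axis=0) / nb - sy**2
                sxy = (xm * ym).sum(axis=0) / nb - sx * sy
                r2 = np.where((sxx > 0) & (syy > 0), sxy**2 / (sxx * syy), np.nan)
            dist = pos[partners] - cp[a_i]
            ok = ~np.isnan(r2) & (nb >= 2)
            for pj, dd, rr in zip(partners[ok], dist[ok], r2[ok]):
                rows.append((ids[j], ids[pj], chrom, int(dd), float(min(rr, 1.0))))
    return pd.DataFrame(rows, columns=["id_a", "id_b", "chrom", "distance", "r2"])


@dataclass
class LDProfile:
    """Distance-binned LD decay profile."""

    scope: str
    bin_width: int
    bins: pd.DataFrame  # bin_start, bin_end, n_pairs, mean_r2 (occupied only)
    background: float

    def occupied(self) -> pd.DataFrame:
        return self.bins


def ld_decay_profile(
    pairs: pd.DataFrame, bin_width: int = 500, scope: str = "genome-wide"
) -> LDProfile:
    """Mean r2 per distance bin [k*w, (k+1)*w); background = median of
    occupied-bin means (empty bins are skipped, not zero-filled)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if len(pairs) == 0:
        raise ValueError("empty pair list")
    b = (pairs["distance"].to_numpy() // bin_width).astype(int)
    grp = pd.DataFrame({"bin": b, "r2": pairs["r2"].to_numpy()}).groupby("bin")["r2"]
    means = grp.mean()
    counts = grp.size()
    bins = pd.DataFrame(
        {
            "bin_start": means.index * bin_width,
            "bin_end": (means.index + 1) * bin_width,
            "n_pairs": counts.to_numpy(),
            "mean_r2": means.to_numpy(),
        }
    ).reset_index(drop=True)
    return LDProfile(
        scope=scope,
        bin_width=bin_width,
        bins=bins,
        background=float(np.median(bins["mean_r2"])),
    )


def decay_distances(
    profile: LDProfile,
    threshold: float = 0.20,
    persistence: int = 3,
) -> tuple[float | None, float | None]:
    """Distances (bp) at which LD decays to ``threshold`` and to background.

    The crossing is the lower edge of the first occupied bin whose mean r2
    is <= the level and whose next ``persistence - 1`` occupied bins also
    satisfy it (guards against single-bin noise; set persistence=1 for
    first-crossing).  A level never reached persistently yields None.
    """
    if len(profile.bins) < 2:
        raise ValueError("need >= 2 occupied bins")

    def crossing(level: float) -> float | None:
        vals = profile.bins["mean_r2"].to_numpy()
        starts = profile.bins["bin_start"].to_numpy()
        below = vals <= level
        for i in range(len(vals)):
            j = min(i + persistence, len(vals))
            if below[i:j].all():
                return float(starts[i])
        return None

    return crossing(threshold), crossing(profile.background)


def locus_content_estimate(
    window_bp: float,
    mean_intergenic_bp: float = 5611,
    mean_gene_len_bp: float = 3843,
    mean_snp_spacing_bp: float = 3997,
) -> tuple[int, int]:
    """Expected gene and array-SNP counts in a genomic window.

    A gene "footprint" is the mean intergenic distance plus the mean gene
    length; counts are floored to integers.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be non-negative")
    if min(mean_intergenic_bp, mean_gene_len_bp, mean_snp_spacing_bp) <= 0:
        raise ValueError("spacing/length parameters must be positive")
    expected_genes = int(window_bp // (mean_intergenic_bp + mean_gene_len_bp))
    expected_snps = int(window_bp // mean_snp_spacing_bp)
    return expected_genes, expected_snps
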
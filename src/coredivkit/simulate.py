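"""Synthetic genotype/phenotype cohorts with the structure the pipeline assumes.

The generator emulates an inbred crop core collection genotyped on a SNP
array: two (or more) diverged subpopulations with Balding-Nichols
frequency divergence plus a fraction of admixed individuals; linkage
disequilibrium injected by a haplotype copying process whose mean r2 decays
approximately as exp(-d / scale) with distance; uniform missingness; a low
rate of heterozygous calls; planted near-duplicate accessions; the
six-locus seed-pigmentation model planted at its tag-SNP minor allele
frequencies inside LD blocks; and quantitative traits with planted QTLs
confounded by structure.

Defaults describe a collection of ~2,000 accessions typed at ~48,000 SNPs
on 11 chromosomes with divergence 0.3 between the two principal
subpopulations; tests run the same generator at smaller sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, PhenotypeTable, encode_trait_table
from . import pigment as pig


@dataclass
class DuplicateSpec:
    n_groups: int = 130
    n_copies: int = 2          # copies appended per founder (group size = n_copies + 1)
    mutation_rate: float = 0.004  # per-allele flip probability per copy


@dataclass
class PigmentSpec:
    """Where and at what frequency the six pigmentation loci are planted.

    MAFs for the four tag SNPs with array-reported frequencies; the two
    remaining loci default to array-typical intermediate frequencies.
    ``block_width_bp`` controls the LD block induced around each locus.
    """

    mafs: dict = field(
        default_factory=lambda: {
            "Pat9.1": 0.146,
            "Pat10.1": 0.221,
            "Pat10.2": 0.15,
            "Col3.1": 0.102,
            "Col5.1": 0.463,
            "Col6.1": 0.30,
        }
    )
    block_width_bp: int = 200_000
    #: allele letter counted by the planted dosage (the minor allele)
    minor_allele: dict = field(
        default_factory=lambda: {
            "Pat9.1": "A",
            "Pat10.1": "C",
            "Pat10.2": "T",
            "Col3.1": "T",
            "Col5.1": "C",
            "Col6.1": "C",
        }
    )
    pattern_priority: tuple = ("full coat", "small eye", "Watson", "large eye", "Holstein")
    color_priority: tuple = ("black", "red", "tan", "blue", "white")


@dataclass
class TraitSpec:
    n_qtl: int = 1
    qtl_share: float = 0.2
    structure_share: float = 0.3
    polygenic_share: float = 0.1
    n_polygenic: int = 100


@dataclass
class SimulationConfig:
    n_samples: int = 2000
    n_variants: int = 48000
    n_chromosomes: int = 11
    chromosome_length_bp: int = 45_000_000
    k_true: int = 2
    f_divergence: float = 0.3
    admixed_fraction: float = 0.10
    missing_rate: float = 0.02
    het_excess_rate: float = 0.01
    inbreeding: float = 0.95   # within-individual allele correlation (selfing crop)
    ld_decay_scale_bp: float = 75_000.0
    # optional per-haplotype flip when a variant copies its neighbor; leave 0
    # so that mean r2 stays a pure function of distance (nonzero values
    # attenuate r2 per copied variant, i.e. per marker-density step)
    copy_flip_rate: float = 0.0
    duplicate_spec: DuplicateSpec = field(default_factory=DuplicateSpec)
    pigment_spec: PigmentSpec = field(default_factory=PigmentSpec)
    trait_spec: TraitSpec = field(default_factory=TraitSpec)
    seed: int | None = None

    def __post_init__(self):
        # allow plain dicts (e.g. from JSON configs) for the nested specs
        if isinstance(self.duplicate_spec, dict):
            self.duplicate_spec = DuplicateSpec(**self.duplicate_spec)
        if isinstance(self.pigment_spec, dict):
            self.pigment_spec = PigmentSpec(**self.pigment_spec)
        if isinstance(self.trait_spec, dict):
            self.trait_spec = TraitSpec(**self.trait_spec)
        for name in ("admixed_fraction", "missing_rate", "het_excess_rate", "inbreeding"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (0 < self.f_divergence < 1):
            raise ValueError("f_divergence must be in (0, 1)")
        if self.n_variants < 2 * self.n_chromosomes:
            raise ValueError("need >= 2 variants per chromosome")


def _draw_true_q(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    n, K = cfg.n_samples, cfg.k_true
    Q = np.zeros((n, K))
    n_adm = int(round(cfg.admixed_fraction * n))
    pops = np.arange(n - n_adm) % K
    for i, p in enumerate(pops):
        Q[i, p] = 1.0
    for i in range(n - n_adm, n):
        if K == 2:
            q0 = rng.uniform(0.35, 0.65)
            Q[i] = [q0, 1 - q0]
        else:
            Q[i] = rng.dirichlet(np.full(K, 5.0))
    return Q


def simulate_structured_genotypes(
    cfg: SimulationConfig, seed: int | None = None
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Generate a structured genotype matrix and the true ancestry Q.

    Subpopulation allele frequencies follow the Balding-Nichols model
    around ancestral frequencies uniform on [0.05, 0.5]; haplotype alleles
    copy their left neighbor with probability exp(-d / scale) (with a small
    flip rate), injecting distance-decaying LD.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n, m, K = cfg.n_samples, cfg.n_variants, cfg.k_true
    F_div = cfg.f_divergence
    Q = _draw_true_q(cfg, rng)

    per_chrom = np.full(cfg.n_chromosomes, m // cfg.n_chromosomes)
    per_chrom[: m % cfg.n_chromosomes] += 1
    dosage = np.empty((n, m), dtype=np.int8)
    chroms, positions = [], []
    F_all = np.empty((m, K))
    j0 = 0
    for c in range(cfg.n_chromosomes):
        mc = int(per_chrom[c])
        pos = np.sort(rng.choice(np.arange(1, cfg.chromosome_length_bp), size=mc, replace=False))
        chrom_name = f"Vu{c + 1:02d}"
        H = np.zeros((n, 2), dtype=np.int8)
        for jj in range(mc):
            j = j0 + jj
            if jj == 0:
                copy = False
            else:
                d = pos[jj] - pos[jj - 1]
                copy = rng.random() < np.exp(-d / cfg.ld_decay_scale_bp)
            if copy:
                F_all[j] = F_all[j - 1]
                flip = rng.random((n, 2)) < cfg.copy_flip_rate
                H = np.where(flip, 1 - H, H)
            else:
                p_anc = rng.uniform(0.05, 0.5)
                a = p_anc * (1 - F_div) / F_div
                b = (1 - p_anc) * (1 - F_div) / F_div
                F_all[j] = rng.beta(a, b, size=K)
                p_i = Q @ F_all[j]
                H = (rng.random((n, 2)) < p_i[:, None]).astype(np.int8)
                # selfing: the second haplotype mirrors the first for most
                # individuals, keeping heterozygosity realistically low
                selfed = rng.random(n) < cfg.inbreeding
                H[selfed, 1] = H[selfed, 0]
            dosage[:, j] = H.sum(axis=1)
        chroms.extend([chrom_name] * mc)
        positions.extend(pos.tolist())
        j0 += mc

    if cfg.het_excess_rate > 0:
        het_mask = rng.random(dosage.shape) < cfg.het_excess_rate
        dosage[het_mask] = 1
    if cfg.missing_rate > 0:
        miss_mask = rng.random(dosage.shape) < cfg.missing_rate
        dosage[miss_mask] = MISSING

    variants = pd.DataFrame(
        {
            "id": [f"snp_{k:06d}" for k in range(m)],
            "chrom": chroms,
            "pos": np.asarray(positions, dtype=np.int64),
            "a1": "A",
            "a2": "G",
        }
    )
    samples = pd.DataFrame(
        {
            "id": [f"acc_{i:05d}" for i in range(n)],
            "region": np.where(Q[:, 0] >= 0.5, "Eastern Africa", "Western Africa"),
            "germplasm_status": "traditional cultivar",
        }
    )
    return GenotypeMatrix(dosage, variants, samples), Q


def plant_duplicates(
    g: GenotypeMatrix, spec: DuplicateSpec, seed: int | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Append near-identical copies of founder samples.

    Each of ``n_groups`` founders gets ``n_copies`` appended copies; each
    copy flips alleles at a Binomial(2m, mutation_rate) number of sites
    (each flip moves the dosage by one allele).  Returns the augmented
    matrix and a truth table (group, founder_id, member_id).
    """
    rng = np.random.default_rng(seed)
    n, m = g.shape
    if spec.n_groups > n:
        raise ValueError("more founder groups than samples")
    founders = rng.choice(n, size=spec.n_groups, replace=False)
    new_rows, truth = [], []
    new_ids = []
    counter = 0
    for gi, f in enumerate(founders):
        fid = g.samples["id"].iat[int(f)]
        truth.append({"group": gi, "founder_id": fid, "member_id": fid})
        for _ in range(spec.n_copies):
            row = g.dosages[int(f)].copy()
            n_mut = rng.binomial(2 * m, spec.mutation_rate)
            sites = rng.choice(m, size=min(n_mut, m), replace=False)
            for s in sites:
                v = row[s]
                if v == MISSING:
                    continue
                row[s] = v + 1 if v == 0 else (v - 1 if v == 2 else v + rng.choice([-1, 1]))
            dup_id = f"dup_{counter:05d}"
            counter += 1
            new_rows.append(row)
            new_ids.append(dup_id)
            truth.append({"group": gi, "founder_id": fid, "member_id": dup_id})
    dosages = np.vstack([g.dosages] + [r[None, :] for r in new_rows])
    samples = pd.concat(
        [
            g.samples,
            pd.DataFrame(
                {
                    "id": new_ids,
                    "region": "unknown",
                    "germplasm_status": "traditional cultivar",
                }
            ),
        ],
        ignore_index=True,
    )
    return GenotypeMatrix(dosages, g.variants.copy(), samples), pd.DataFrame(truth)


def plant_pigment_loci(
    g: GenotypeMatrix, spec: PigmentSpec, seed: int | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Plant the six pigmentation loci at their tag-SNP MAFs in LD blocks.

    The planted column gets homozygous dosages only (inbred assumption):
    dosage 2 = homozygous minor with probability MAF, else dosage 0.
    Variants within ``block_width_bp`` copy the planted dosage with a
    per-sample probability decaying with distance, creating the local LD
    block.  Variant ids at planted positions are renamed to the tag SNPs.
    Returns the modified matrix and a truth table per locus.
    """
    rng = np.random.default_rng(seed)
    n = g.n_samples
    variants = g.variants.copy()
    dosage = g.dosages.copy()
    truth_rows = []
    block_scale = float(spec.block_width_bp)
    # loci sharing a chromosome (Pat10.1 / Pat10.2 on Vu10) go to distinct,
    # well-separated positions so their LD blocks do not merge
    rel_pos = {"Pat10.1": 0.30, "Pat10.2": 0.75}
    for locus in pig.PATTERN_LOCI + pig.COLOR_LOCI:
        chrom = pig.LOCUS_CHROM[locus]
        on_chrom = np.flatnonzero((variants["chrom"] == chrom).to_numpy())
        if len(on_chrom) == 0:
            raise ValueError(f"no variants on {chrom} to plant {locus}")
        frac = rel_pos.get(locus, 0.5)
        mid = on_chrom[min(int(frac * len(on_chrom)), len(on_chrom) - 1)]
        maf = spec.mafs[locus]
        if not (0 < maf <= 0.5):
            raise ValueError(f"planted MAF for {locus} must be in (0, 0.5]")
        col = np.where(rng.random(n) < maf, 2, 0).astype(np.int8)
        dosage[:, mid] = col
        variants.loc[mid, "id"] = pig.TAG_SNPS[locus]
        minor = spec.minor_allele[locus]
        major = [a for a in pig.ALLELES[locus] if a != minor][0]
        variants.loc[mid, "a1"] = minor
        variants.loc[mid, "a2"] = major
        pos0 = variants["pos"].iat[mid]
        block = []
        for j in on_chrom:
            if j == mid:
                continue
            d = abs(int(variants["pos"].iat[j]) - int(pos0))
            if d <= spec.block_width_bp:
                copy_p = np.exp(-d / block_scale)
                take = rng.random(n) < copy_p
                dosage[take, j] = col[take]
                block.append(variants["id"].iat[j])
        truth_rows.append(
            {
                "locus": locus,
                "tag_snp": pig.TAG_SNPS[locus],
                "chrom": chrom,
                "pos": int(pos0),
                "maf": maf,
                "block_ids": tuple(block),
            }
        )
    return GenotypeMatrix(dosage, variants, g.samples.copy()), pd.DataFrame(truth_rows)


def simulate_pigment_phenotypes(
    g: GenotypeMatrix,
    spec: PigmentSpec,
    truth: pd.DataFrame,
) -> PhenotypeTable:
    """Pattern and color phenotypes from the planted pigmentation genotypes.

    Reads the six planted columns, translates dosages to homozygous allele
    letters, applies the genotype->phenotype map, resolves ambiguous label
    sets by the configured priority, and emits case/control indicator
    traits per pattern and color level.
    """
    id_to_col = {v: j for j, v in enumerate(g.variants["id"])}
    letters = {}
    for _, row in truth.iterrows():
        locus = row["locus"]
        j = id_to_col[row["tag_snp"]]
        minor = spec.minor_allele[locus]
        major = [a for a in pig.ALLELES[locus] if a != minor][0]
        d = g.dosages[:, j]
        lt = np.where(d >= 1, minor, major)  # planted data is homozygous 0/2
        letters[locus] = lt
    loci = pig.PATTERN_LOCI + pig.COLOR_LOCI
    patterns, colors = [], []
    for i in range(g.n_samples):
        geno = pig.PigmentGenotype(*[str(letters[l][i]) for l in loci])
        p, p_hits = pig.pattern_from_genotype(geno)
        c, c_hits = pig.color_from_genotype(geno)
        if p == pig.AMBIGUOUS:
            p = pig.resolve_label(p_hits, list(spec.pattern_priority))
        if c == pig.AMBIGUOUS:
            c = pig.resolve_label(c_hits, list(spec.color_priority))
        patterns.append(p)
        colors.append(c)
    raw = pd.DataFrame(
        {"pattern": patterns, "color": colors}, index=g.samples["id"].to_numpy()
    )
    return encode_trait_table(raw, {"pattern": "qualitative", "color": "qualitative"})


def simulate_quantitative_trait(
    g: GenotypeMatrix,
    spec: TraitSpec,
    true_q: np.ndarray | None = None,
    seed: int | None = None,
) -> tuple[pd.Series, dict]:
    """One quantitative trait with planted QTLs, structure confounding,
    a polygenic term, and Gaussian noise at configured variance shares."""
    shares = spec.qtl_share + spec.structure_share + spec.polygenic_share
    if shares > 1:
        raise ValueError("variance shares sum to more than 1")
    noise_share = 1.0 - shares
    rng = np.random.default_rng(seed)
    n, m = g.shape
    X = g.dosages.astype(np.float64)
    X[X == MISSING] = np.nan
    mu = np.nanmean(X, axis=0)
    nan_at = np.where(np.isnan(X))
    X[nan_at] = np.take(mu, nan_at[1])
    sd = X.std(axis=0)
    informative = np.flatnonzero(sd > 0.3)
    if len(informative) < spec.n_qtl:
        raise ValueError("not enough polymorphic variants to plant QTLs")

    def standardize(v):
        s = v.std()
        return (v - v.mean()) / s if s > 0 else np.zeros_like(v)

    qtl_idx = rng.choice(informative, size=spec.n_qtl, replace=False)
    y = np.zeros(n)
    if spec.qtl_share > 0:
        comp = X[:, qtl_idx].sum(axis=1)
        y += np.sqrt(spec.qtl_share) * standardize(comp)
    if spec.structure_share > 0:
        if true_q is None:
            raise ValueError("structure_share > 0 requires true_q")
        y += np.sqrt(spec.structure_share) * standardize(true_q[:, 0].astype(float))
    if spec.polygenic_share > 0:
        poly_idx = rng.choice(informative, size=min(spec.n_polygenic, len(informative)), replace=False)
        betas = rng.normal(0, 1, size=len(poly_idx))
        y += np.sqrt(spec.polygenic_share) * standardize(X[:, poly_idx] @ betas)
    y += np.sqrt(noise_share) * rng.normal(0, 1, size=n)
    truth = {
        "qtl_ids": g.variants["id"].to_numpy()[qtl_idx].tolist(),
        "qtl_index": qtl_idx.tolist(),
        "shares": {
            "qtl": spec.qtl_share,
            "structure": spec.structure_share,
            "polygenic": spec.polygenic_share,
            "noise": noise_share,
        },
    }
    return pd.Series(y, index=g.samples["id"].to_numpy(), name="trait"), truth
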
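# coredivkit

Genotype diversity, population structure, linkage disequilibrium and
mixed-model GWAS analysis for crop core collections typed on SNP arrays —
with a matched synthetic-cohort generator so the whole pipeline can be
validated end to end without external data.

The package targets genebank and crop-genomics workflows of the kind used
to characterise the IITA cowpea (*Vigna unguiculata*) core collection:
~2,000 inbred accessions genotyped at ~48,000 biallelic SNPs across 11
chromosomes, with strong two-subpopulation structure, many near-duplicate
accessions, slow LD decay, and highly heritable Mendelian traits such as
seed-coat pigmentation.

## What it computes

- **QC and deduplication** — site filtering by missingness (>95%
  removed), sample filtering by missingness (>50%) and heterozygosity
  (>20%), pairwise allelic Hamming distances with flat-missing rescaling,
  average-linkage clustering with a static tree cut (500 allelic
  mismatches ≈ 0.5% of sites at array scale) and random representative
  selection, and windowed LD pruning (50-SNP windows, step 10, r² > 0.20,
  MAF ≥ 0.01, missingness ≤ 5%).
- **Diversity** — expected heterozygosity
  `He = (1/N) Σ (1 − (p² + q²))` over sites, segregating-site counts,
  folded allele-frequency spectra per group, and an iterative
  minimal-core-subset search: accessions are added in random order, and the
  smallest cohort whose mean captured fraction of segregating sites
  reaches a target (90%, 95%) over 1,000 randomised iterations is reported.
- **Population structure** — the admixture model
  `g_ij ~ Binomial(2, Σ_k q_ik f_jk)` fitted by EM (monotone
  log-likelihood, Q on the simplex), replicated over K = 1..10, model
  selection by Evanno's ΔK = mean|L″(K)| / sd L(K), cluster assignment at
  the 70% ancestry threshold, genotype PCA with mean imputation, and
  Hudson's Fst estimator (ratio of averages).
- **LD decay** — pairwise dosage r² within 10 Mbp, 500-bp distance bins,
  background = median of bin means, decay distances to r² = 0.20 and to
  background with a persistence rule, and expected gene/SNP content of an
  association window from reference-genome spacing constants.
- **GWAS** — univariate linear mixed model `y = Wα + xβ + u + ε`,
  `u ~ N(0, σ_g² K)` with a centered genomic relatedness matrix K,
  eigendecomposition plus 1-D REML for the variance ratio, Wald tests,
  per-trait Bonferroni control, and peak calling (significant SNPs linked
  at r² > 0.20 within 1 Mbp form one peak, tagged by the minimum p).
- **Seed pigmentation model** — an executable six-locus genotype→phenotype
  map for seed-coat pattern (full coat, small eye, large eye, Holstein,
  Watson) and color (black, red, tan, blue, white), with the tag SNPs and
  allele states of the underlying patterning/color QTLs, including
  exhaustive enumeration of all 2⁶ homozygous genotypes.
- **Synthetic cohorts** — Balding–Nichols subpopulation divergence,
  haplotype-copying LD with a configurable decay scale, selfing-level
  heterozygosity, missingness, planted near-duplicates, the six
  pigmentation loci planted at their tag-SNP minor allele frequencies
  inside LD blocks, and quantitative traits with structure confounding.

## Worked example

```python
import numpy as np
from coredivkit import *
from coredivkit.simulate import PigmentSpec

cfg = SimulationConfig(n_samples=300, n_variants=2200, n_chromosomes=11,
                       chromosome_length_bp=8_000_000, f_divergence=0.3,
                       admixed_fraction=0.10, seed=42)
g, true_q = simulate_structured_genotypes(cfg)
spec = PigmentSpec(block_width_bp=300_000)
g, truth = plant_pigment_loci(g, spec, seed=43)

pruned = g.subset_variant_ids(ld_prune(g))
runs = run_replicated_admixture(pruned, 1, 6, 4, seed=0, max_iter=800, tol=1e-5)
table = evanno_best_k({k: [m.loglik for m in v] for k, v in runs.items()})
best = max(runs[2], key=lambda m: m.loglik)
asg = assign_clusters(best, threshold=0.70)
a, b = np.flatnonzero(asg == 0), np.flatnonzero(asg == 1)

pairs = pairwise_r2_within(g, max_distance=2_000_000)
prof = ld_decay_profile(pairs, bin_width=25_000)
d20, _ = decay_distances(prof)

pheno = simulate_pigment_phenotypes(g, spec, truth)
scan = lmm_scan(g, pheno.data["color.black"].to_numpy(dtype=float),
                kinship=centered_kinship(g), trait="color.black")
peaks = call_peaks(scan, g)
```

prints (via the surrounding report statements):

```
pruned marker set: 683 SNPs
Evanno best K = 2
cluster sizes: [135, 135], unassigned: 30
Hudson Fst between clusters = 0.277
LD background r2 = 0.016; decay to r2 = 0.20 by 125 kb
peak Vu05:3739636-4040221  tag 2_19309  p = 1.04e-28
peak Vu06:3707436-3880351  tag snp_001099  p = 2.95e-08
```

Reading this: ΔK model selection recovers the two planted subpopulations;
the 70% ancestry rule assigns 270 of 300 accessions and leaves the planted
admixed ones unassigned; the between-cluster Fst (0.277) sits near the
simulated divergence (0.3, diluted slightly by admixed individuals and
genotyping noise); the LD profile decays to r² = 0.20 near the configured
scale; and the GWAS for black seed coat peaks at tag SNP `2_19309` — the
planted color locus on Vu05 — plus a secondary peak in the planted Col6.1
block on Vu06, which also distinguishes black from blue seed coats in the
six-locus model.

A command-line interface mirrors the library
(`coredivkit simulate|validate|convert|qc|dedup|prune|diversity|coreset|structure|pca|fst|ld|gwas|pigment|run`);
every analysis writes plain TSV/JSON.

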
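# Methods

This note documents the statistical models implemented in coredivkit, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions a maintainer should know
about.

## Data model

Genotypes are held as a samples × variants matrix of dosages counting
copies of allele A1 (0, 1, 2) with a single missing sentinel (−1).  A1 is
taken exactly as written in the PLINK BIM; allele frequencies are always
recomputed from the data, never trusted from file, because externally
produced files differ in whether A1 is the minor or the reference allele.
Variants are kept sorted by (chromosome, position) with chromosome labels
treated as opaque strings ordered by alphabetic prefix then numeric suffix
("Vu01" … "Vu11").  Positions are 1-based; all genomic distances are
`pos_b − pos_a` on the same chromosome.  Missing calls survive every I/O
round trip; mean imputation happens only inside PCA and kinship, in local
working copies.

## QC

Filter order is fixed: sites → samples → duplicate collapse → LD pruning.

- Sites with a missing-call fraction above 0.95 are removed first.
- Samples are then removed when missingness exceeds 0.50 or the
  heterozygous fraction exceeds 0.20.  The heterozygosity denominator is
  the number of non-missing calls — standard QC practice for call-rate
  heterogeneity.  Both comparisons are strict (a sample at exactly the
  threshold survives).
- Pairwise distance is the allelic mismatch count Σ|Δdosage| over calls
  present in both samples (opposite homozygotes count 2), rescaled by
  `total_variants / shared_called_variants` and rounded — the
  flat-missing behaviour of plink 1.9 `--distance`.  Pairs with no
  overlap are undefined (NaN) and rejected by the clustering step.
- Near-duplicates: average-linkage (UPGMA) agglomerative clustering on the
  distance matrix with a static cut.  The default cut of 500 allelic
  mismatches corresponds to ~0.5% of sites on a ~48k-SNP array
  (500 / 96,000 alleles); at other panel sizes the cut should be scaled to
  0.5% of 2m alleles, which is what the test suite does.  The linkage
  method is configurable ({single, complete, average}); average is the
  default because the cut height then approximates a mean within-cluster
  difference rate.  One representative per cluster is drawn uniformly at
  random under a recorded seed.
- LD pruning restricts to MAF ≥ 0.01 and missingness ≤ 5%, then removes
  the lower-MAF member (tie: later position) of any pair with r² > 0.20
  inside 50-SNP windows sliding by 10, per chromosome.  Unlike a single
  plink-style pass, the windowed pass is iterated to a fixed point over
  the retained list, which guarantees that no surviving pair within any
  50-SNP window of the *pruned* set exceeds the threshold (a single pass
  cannot, because removals bring originally distant variants together).
  Pruning r² uses mean-imputed dosage correlation for speed; the LD-decay
  module uses pairwise-complete correlation (see below).

## Diversity

Expected heterozygosity is `He = (1/N) Σ_sites (1 − (p² + q²))` with p, q
the major/minor allele frequencies over non-missing calls; sites with no
calls are excluded from N.  This is the biallelic gene-diversity form,
bounded by 0.5 and zero at monomorphic sites.  A site "segregates" in a
group when both alleles are observed there (a single heterozygote
suffices).  The folded AFS uses right-closed bins of width 0.05 over
(0, 0.5].

The minimal core subset is found by resampling: in each of 1,000
iterations the accessions are permuted and added one at a time; per cohort
size the fraction of the full panel's segregating sites captured is
recorded (He capture is tracked alongside for inspection).  The minimal
core size for a target is the smallest size whose *mean* captured
fraction across iterations reaches the target; the reported subset is the
prefix of the iteration whose capture at that size is closest above the
target.  Segregating-site capture is used as the criterion because it is
monotone under sample addition (sites only accumulate), which makes the
curve and the minimum well defined; mean aggregation is the default and a
quantile alternative would be a one-line change at the aggregation step.
Note a consequence of mean aggregation: a panel in which one accession
alone carries all diversity still has minimal n > 1, because the mean at
size 1 averages over all possible first draws.

## Admixture model

Each genotype is modeled as `g_ij ~ Binomial(2, π_ij)` with
`π_ij = Σ_k q_ik f_jk`; Q rows are ancestry fractions on the simplex and F
columns subpopulation allele frequencies.  The log-likelihood
`Σ_ij [g_ij log π_ij + (2 − g_ij) log(1 − π_ij)]` (missing entries
skipped) is maximised by the classic EM block update of Q and F, which is
monotone — the fit records the per-iteration log-likelihood and the test
suite asserts monotonicity on every fit.  Q is initialised from a
symmetric Dirichlet and F from observed frequencies with N(0, 0.05²)
jitter; F is clipped to [1e−6, 1 − 1e−6].  Convergence: relative
log-likelihood change < 1e−4 (configurable), max 2,000 iterations.  EM
rather than the accelerated quasi-Newton of the reference tool keeps the
implementation dependency-free and exactly testable; it needs more
iterations but each is a handful of vectorised matrix products.

K selection uses Evanno's ΔK: with replicated fits per K,
`ΔK = mean_r |L_r(K+1) − 2 L_r(K) + L_r(K−1)| / sd_r L_r(K)`, defined for
interior K with positive sd; replicates are paired by index (the scheme
assumes equal replicate counts per K).  Ties break toward the smallest K.
ΔK is known to be biased toward K = 2; that is a property of the method,
not of this implementation.  Samples are assigned to their majority
cluster when the maximum ancestry fraction is ≥ 0.70 (boundary
inclusive), else left unassigned.

PCA mean-imputes missing dosages per variant, centers columns, and takes
the SVD; variance fractions are relative to the total dosage variance so
they sum to 1 over all components.  Columns are not scaled by default
(allele-frequency PCA); unit-variance scaling is an option.

Fst uses Hudson's estimator as a ratio of sums across sites:
`N_j = (p1 − p2)² − p1(1 − p1)/(n1 − 1) − p2(1 − p2)/(n2 − 1)`,
`D_j = p1(1 − p2) + p2(1 − p1)`, with n the called allele counts.  Ratio
of averages (not average of ratios) avoids the small-D_j instability.
With identical groups the estimate sits at the finite-sample floor
≈ −1/(n_alleles − 1), not exactly zero.  Weir–Cockerham would be a
straightforward alternative behind the same signature; Hudson was chosen
for its insensitivity to unequal sample sizes.

## LD

r² is the squared Pearson correlation of dosage vectors over
pairwise-complete samples — composite LD, appropriate for unphased array
data.  Pairs are formed within chromosomes up to 10 Mbp.  Decay profiles
average r² in 500-bp bins `[k·500, (k+1)·500)`; the background is the
median over occupied bins (empty far-distance bins are skipped, not
zero-filled, because zero-filling would drag the median toward sparse
long-range bins).  The decay distance to a level is the lower edge of the
first occupied bin at or below the level whose next two occupied bins
also stay below it; the 3-bin persistence rule suppresses single-bin
noise and is configurable down to first-crossing.  Reporting the lower
edge biases the crossing downward by about half a bin on average, which
the calibration test accounts for.

Locus content of an association window divides the window width by the
per-gene footprint (mean adjacent-gene distance 5,611 bp + mean gene
length 3,843 bp) or by the mean adjacent-SNP spacing (3,997 bp) and
floors the result; for a window of twice the 121.5-kb half-decay distance
this gives 25 genes and 60 SNPs.

## Mixed-model GWAS

Per trait: quantitative phenotypes are natural-log transformed
(non-positive values dropped and counted — an offset would distort effect
scales); qualitative phenotypes enter as 0/1 indicators analysed with the
same linear model.  Traits with fewer than 20 observations are refused.

The model is `y = Wα + xβ + u + ε`, `u ~ N(0, σ_g² K)`,
`ε ~ N(0, σ_e² I)`, with W an intercept and K the centered relatedness
matrix `K = (1/m) Σ_j (x_j − x̄_j)(x_j − x̄_j)ᵀ` (missing dosages
mean-imputed for K only).  K is eigendecomposed once; in the rotated
basis the variance ratio λ = σ_g²/σ_e² has a 1-D REML profile that is
optimised by bounded search on log λ ∈ [−10, 10].  By default λ is
estimated once under the null (no-SNP) model and reused for every variant
— the standard "population parameters previously determined"
approximation, whose bias is small when no single SNP moves the variance
components much; `per_variant_lambda=True` re-optimises per variant.
Each variant then reduces to a 2 × 2 weighted least-squares solve; the
Wald statistic β̂/se(β̂) is referred to a t distribution with n − 2
degrees of freedom.  Variants with MAF ≤ 0.01 or missingness ≥ 5% are not
tested; per-variant missing dosages are mean-imputed.  Bonferroni control
uses α = 0.05 over the number of variants actually tested for that trait.

Peaks: significant variants are nodes; edges join same-chromosome pairs
within 1 Mbp with r² > 0.20 (mean-imputed correlation on the scan
samples); peaks are connected components; the tag SNP is the member with
the smallest p (ties: smaller position, then id).  Calibration checks in
the test suite: with a vanishing kinship the scan reproduces OLS p-values
to 1e−6; under a null trait the type-I error at 0.05 stays in
[0.035, 0.065] and the genomic inflation factor in [0.9, 1.1]; a planted
QTL explaining 20% of variance tops the scan; and on
structure-confounded traits the mixed model yields no more Bonferroni
false positives than an uncorrected scan.

Cluster-phenotype comparisons use two-sided Mann–Whitney–Wilcoxon tests
for quantitative traits and two-sided Fisher exact tests on 2 × 2
presence tables for binary traits, Bonferroni-corrected within each trait
family separately; per-category chi-squared tests handle regional
enrichment between clusters.

## Seed-pigmentation model

Three patterning loci (Pat9.1/Vu09, Pat10.1/Vu10, Pat10.2/Vu10; tag SNPs
2_01960, 2_31919, 2_15395) and three color loci (Col3.1/Vu03, Col5.1/Vu05,
Col6.1/Vu06; tag SNPs 2_20787, 2_19309, 2_22603) determine seed-coat
pattern and color.  Only homozygous states are modeled, matching the
selfing biology of the accession panels this map describes; each locus is
summarised by one allele letter.  The map returns the *set* of phenotype
rows a genotype satisfies.  Two ambiguities are intrinsic to the model
table and deliberately surfaced rather than resolved: the large-eye and
Holstein rows require the same alleles (A, T, C), and the white row
(which additionally requires the patterning allele Pat10.1ᶜ) overlaps
black or tan on its color alleles.  Callers needing a single label — the
simulator — resolve via an explicit priority list (default order:
full coat, small eye, Watson, large eye, Holstein; black, red, tan, blue,
white), i.e. large eye is preferred over Holstein because nothing in the
allele table distinguishes them.  Of the 64 homozygous genotypes, 40 give
a unique pattern, 8 an ambiguous pattern and 16 match no pattern row;
32/8/24 for color.

## Synthetic cohorts

The generator emulates an array-genotyped inbred core collection:

- **Structure**: ancestral allele frequencies uniform on [0.05, 0.5]
  (mimicking array ascertainment against rare variants); subpopulation
  frequencies Balding–Nichols, `Beta(p(1−F)/F, (1−p)(1−F)/F)` with
  divergence F (default 0.3, two subpopulations); a configurable fraction
  (default 10%) of admixed individuals with ancestry drawn uniform on
  [0.35, 0.65].
- **LD**: each haplotype allele copies its left neighbour with
  probability `exp(−d/scale)` (default scale 75 kb), else redraws from
  the variant's frequency; mean r² therefore decays approximately as
  `exp(−d/scale)` and crosses 0.20 near `scale · ln 5`.  A per-copy flip
  rate exists but defaults to 0 because flips attenuate r² per *marker
  step*, which would make decay depend on marker density rather than
  distance.
- **Inbreeding**: the second haplotype mirrors the first with probability
  0.95, giving the few-percent heterozygosity of a selfing crop (plus a
  1% heterozygous-call noise rate); without this, half the simulated
  samples would fail the 20% heterozygosity QC filter.
- **Missingness**: uniform at 2% by default (the 1–5% range typical of
  array data).
- **Duplicates**: founder rows are copied with per-allele flips at a
  configurable rate (≤ 0.005 so planted groups stay below the dedup cut).
- **Pigmentation**: the six loci are planted as homozygous columns at
  their tag-SNP minor allele frequencies (0.146, 0.221, 0.463, 0.102 for
  the four array-reported tags; 0.15 and 0.30 chosen as array-typical
  intermediate frequencies for the two tags whose MAFs are not reported),
  each inside an LD block where neighbours copy the planted dosage with
  probability `exp(−d/block_width)`.  Pigment loci are planted *before*
  duplicate copies so copies inherit them.  Phenotypes come from the
  pigment map applied to the planted genotypes, ambiguities resolved by
  the configured priority, emitted as case/control indicators.
- **Quantitative traits**: y is a variance-share-weighted sum of
  standardised components — planted QTL dosages, the first true-ancestry
  axis (structure confounding), a polygenic term over random variants,
  and Gaussian noise.

What the generator does **not** emulate: realistic demographic history or
coalescent genealogies (Balding–Nichols is a frequency-level
approximation), genotyping-array ascertainment beyond the frequency
floor, linked selection, batch effects, or heterozygous pigment
genotypes.  Passing tests therefore demonstrate the correctness and
calibration of the estimators under a controlled generative model, not
their behaviour under every pathology of real array data.

## Problem sizes used in the test suite

Tests run the same code paths as a full-scale analysis at reduced sizes,
chosen to keep each statistical check well-powered: duplicate recovery on
30 + 8 samples × 2,000 SNPs over 20 seeds; K-selection on 150 × 900
(pruned to ~300) with K = 1..6 × 4 replicates; Fst consistency at
2 × 200 × 5,000 (the estimator-consistency runs disable the
heterozygous-noise layer, since the Balding–Nichols expectation applies
to the pure model); LMM calibration at 200 × 1,000 and power at
300 × 800, 20 seeds each (power runs use an LD-free configuration so the
planted QTL is the unique optimum — under copied-haplotype LD a perfect
proxy SNP can tie it); pigment-locus recovery at 320 × 1,100 over 20
seeds.  The generator defaults themselves describe the full-scale
collection (2,000 × 48,000, 11 chromosomes).

## Known limitations

- The admixture EM can need many iterations near flat likelihood regions;
  replicate fits with different seeds (as the pipeline does) are the
  guard against local optima.
- λ reuse across variants is an approximation; exact per-variant REML is
  available but linear-factor slower.
- Binary traits use the linear mixed model, not a logistic one; p-values
  are well calibrated but effect sizes are on the observed 0/1 scale.
- The dedup cut height is an absolute allelic-mismatch count and must be
  scaled when the marker panel is much smaller than ~48k SNPs.
- Evanno's ΔK cannot select K = 1 and is biased toward K = 2.
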
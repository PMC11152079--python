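import numpy as np
import pytest

from coredivkit.io import MISSING, read_plink, write_plink
from coredivkit.simulate import (
    DuplicateSpec,
    PigmentSpec,
    SimulationConfig,
    TraitSpec,
    plant_duplicates,
    plant_pigment_loci,
    simulate_pigment_phenotypes,
    simulate_quantitative_trait,
    simulate_structured_genotypes,
)
from coredivkit import pigment as pig


def _small_cfg(**kw):
    base = dict(
        n_samples=60, n_variants=400, n_chromosomes=2,
        chromosome_length_bp=5_000_000, seed=0,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestStructuredGenotypes:
    def test_shapes_and_value_set(self):
        g, q = simulate_structured_genotypes(_small_cfg())
        assert g.shape == (60, 400)
        assert set(np.unique(g.dosages)) <= {0, 1, 2, MISSING}
        assert np.allclose(q.sum(axis=1), 1.0)

    def test_missingness_near_target(self):
        g, _ = simulate_structured_genotypes(_small_cfg(n_samples=200, missing_rate=0.03))
        assert abs(g.missing_mask().mean() - 0.03) < 0.01

    def test_heterozygosity_is_low(self):
        """Selfing biology: only a few percent heterozygous calls."""
        g, _ = simulate_structured_genotypes(_small_cfg(n_samples=200))
        assert (g.dosages == 1).mean() < 0.10

    def test_round_trip_through_plink(self, tmp_path):
        g, _ = simulate_structured_genotypes(_small_cfg())
        write_plink(g, tmp_path / "sim")
        assert g.equals(read_plink(tmp_path / "sim"))

    def test_seed_reproducibility(self):
        a, qa = simulate_structured_genotypes(_small_cfg(seed=5))
        b, qb = simulate_structured_genotypes(_small_cfg(seed=5))
        assert a.equals(b)
        assert np.array_equal(qa, qb)

    def test_fst_monotone_in_divergence(self):
        from coredivkit.structure import hudson_fst

        fsts = []
        for fd in (0.05, 0.1, 0.2, 0.3):
            g, q = simulate_structured_genotypes(
                _small_cfg(n_samples=200, n_variants=1500, f_divergence=fd,
                           admixed_fraction=0.0, seed=31)
            )
            a = np.flatnonzero(q[:, 0] == 1)
            b = np.flatnonzero(q[:, 1] == 1)
            fsts.append(hudson_fst(g, a, b))
        assert fsts == sorted(fsts)

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_variants=10, n_chromosomes=11)


class TestPlantDuplicates:
    def test_zero_mutation_rate_exact_copies(self):
        from coredivkit.qc import pairwise_hamming

        g, _ = simulate_structured_genotypes(_small_cfg(missing_rate=0.0))
        spec = DuplicateSpec(n_groups=2, n_copies=1, mutation_rate=0.0)
        g2, truth = plant_duplicates(g, spec, seed=1)
        dist = pairwise_hamming(g2)
        ids = g2.samples["id"].tolist()
        for _, grp in truth.groupby("group"):
            members = [ids.index(m) for m in grp["member_id"]]
            assert dist[members[0], members[1]] == 0

    def test_expected_allelic_distance(self):
        from coredivkit.qc import pairwise_hamming

        g, _ = simulate_structured_genotypes(
            _small_cfg(n_variants=2000, missing_rate=0.0)
        )
        spec = DuplicateSpec(n_groups=8, n_copies=1, mutation_rate=0.004)
        g2, truth = plant_duplicates(g, spec, seed=2)
        dist = pairwise_hamming(g2)
        ids = g2.samples["id"].tolist()
        ds = []
        for _, grp in truth.groupby("group"):
            members = [ids.index(m) for m in grp["member_id"]]
            ds.append(dist[members[0], members[1]])
        # expected ~ rate x 2m = 16 alleles; binomial spread around it
        assert 8 <= np.mean(ds) <= 24

    def test_truth_table_lists_all_members(self):
        g, _ = simulate_structured_genotypes(_small_cfg())
        spec = DuplicateSpec(n_groups=3, n_copies=2, mutation_rate=0.001)
        g2, truth = plant_duplicates(g, spec, seed=3)
        assert g2.n_samples == g.n_samples + 6
        assert truth.groupby("group").size().tolist() == [3, 3, 3]


@pytest.fixture(scope="module")
def planted():
    cfg = SimulationConfig(
        n_samples=400, n_variants=2200, n_chromosomes=11,
        chromosome_length_bp=8_000_000, seed=17,
    )
    g, _ = simulate_structured_genotypes(cfg)
    spec = PigmentSpec()
    g2, truth = plant_pigment_loci(g, spec, seed=4)
    return g2, spec, truth


class TestPigmentPlanting:

    def test_tag_snps_present_with_target_mafs(self, planted):
        g2, spec, truth = planted
        from coredivkit.diversity import allele_frequencies

        freqs = allele_frequencies(g2).set_index("id")
        for _, row in truth.iterrows():
            maf = freqs.loc[row["tag_snp"], "maf"]
            target = spec.mafs[row["locus"]]
            assert abs(maf - target) < 3 * np.sqrt(target * (1 - target) / 400)

    def test_planted_columns_homozygous(self, planted):
        g2, _, truth = planted
        cols = [list(g2.variants["id"]).index(t) for t in truth["tag_snp"]]
        assert set(np.unique(g2.dosages[:, cols])) <= {0, 2}

    def test_block_neighbors_in_ld(self, planted):
        g2, _, truth = planted
        ids = list(g2.variants["id"])
        d = g2.dosages.astype(float)
        for _, row in truth.iterrows():
            if not row["block_ids"]:
                continue
            tag = d[:, ids.index(row["tag_snp"])]
            best = max(
                np.corrcoef(tag, d[:, ids.index(b)])[0, 1] ** 2
                for b in row["block_ids"]
            )
            assert best > 0.2

    def test_all_full_coat_when_forced(self):
        cfg = SimulationConfig(
            n_samples=50, n_variants=660, n_chromosomes=11,
            chromosome_length_bp=5_000_000, seed=6,
        )
        g, _ = simulate_structured_genotypes(cfg)
        # MAF -> 0 at pattern loci means everyone carries the major alleles
        # (G, T, C): the full-coat combination
        spec = PigmentSpec(mafs={**PigmentSpec().mafs,
                                 "Pat9.1": 1e-9, "Pat10.1": 1e-9, "Pat10.2": 1e-9})
        g2, truth = plant_pigment_loci(g, spec, seed=7)
        pheno = simulate_pigment_phenotypes(g2, spec, truth)
        assert pheno.data["pattern.full coat"].mean() == 1.0

    def test_phenotype_frequencies_match_mendelian_expectation(self, planted):
        """Realized trait frequencies match the product-of-loci expectation."""
        g2, spec, truth = planted
        pheno = simulate_pigment_phenotypes(g2, spec, truth)

        def allele_p(locus, letter):
            maf = spec.mafs[locus]
            return maf if letter == spec.minor_allele[locus] else 1 - maf

        # expectation for the unambiguous full-coat row: P(G) P(T) P(C)
        expect = (
            allele_p("Pat9.1", "G") * allele_p("Pat10.1", "T") * allele_p("Pat10.2", "C")
        )
        got = pheno.data["pattern.full coat"].mean()
        se = np.sqrt(expect * (1 - expect) / 400)
        assert abs(got - expect) < 4 * se

    def test_phenotypes_agree_with_pigment_map(self, planted):
        """Round trip: emitted labels equal the map applied to planted calls."""
        g2, spec, truth = planted
        pheno = simulate_pigment_phenotypes(g2, spec, truth)
        ids = list(g2.variants["id"])
        loci = pig.PATTERN_LOCI + pig.COLOR_LOCI
        cols = {row["locus"]: ids.index(row["tag_snp"]) for _, row in truth.iterrows()}
        rng = np.random.default_rng(0)
        for i in rng.choice(g2.n_samples, size=25, replace=False):
            letters = []
            for l in loci:
                dos = g2.dosages[i, cols[l]]
                minor = spec.minor_allele[l]
                major = [a for a in pig.ALLELES[l] if a != minor][0]
                letters.append(minor if dos >= 1 else major)
            pg = pig.PigmentGenotype(*letters)
            label, hits = pig.pattern_from_genotype(pg)
            if label != pig.AMBIGUOUS:
                assert pheno.data.iloc[i][f"pattern.{label}"] == 1.0


class TestQuantitativeTrait:
    def test_pure_noise_independent_of_genotype(self):
        g, q = simulate_structured_genotypes(_small_cfg(n_samples=200))
        spec = TraitSpec(qtl_share=0.0, structure_share=0.0, polygenic_share=0.0)
        y, truth = simulate_quantitative_trait(g, spec, q, seed=8)
        assert truth["shares"]["noise"] == 1.0
        assert abs(np.corrcoef(y, g.dosages[:, truth["qtl_index"][0]].astype(float))[0, 1]) < 0.2

    def test_zero_noise_single_qtl_dominates(self):
        from coredivkit.assoc import LinearMixedGWAS

        g, q = simulate_structured_genotypes(
            _small_cfg(n_samples=150, n_variants=500, ld_decay_scale_bp=1.0)
        )
        spec = TraitSpec(qtl_share=1.0, structure_share=0.0, polygenic_share=0.0)
        y, truth = simulate_quantitative_trait(g, spec, q, seed=9)
        est = LinearMixedGWAS().fit(g.dosages, y.to_numpy(), variants=g.variants)
        cutoff = 0.05 / est.n_tests_
        top = est.results_.loc[est.results_["p"].idxmin()]
        assert top["id"] in truth["qtl_ids"]
        assert top["p"] < cutoff

    def test_bad_shares_rejected(self):
        g, q = simulate_structured_genotypes(_small_cfg())
        with pytest.raises(ValueError):
            simulate_quantitative_trait(
                g, TraitSpec(qtl_share=0.6, structure_share=0.6), q, seed=0
            )
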
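import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coredivkit.assoc import (
    AssociationScan,
    LinearMixedGWAS,
    bonferroni_threshold,
    call_peaks,
    centered_kinship,
    cluster_phenotype_tests,
    encode_phenotype,
    lmm_scan,
    regional_enrichment,
)
from coredivkit.io import MISSING, PhenotypeTable
from conftest import make_matrix


class TestKinship:
    def test_hand_computed_4x3(self):
        X = np.array([[0, 1, 2], [2, 1, 0], [1, 1, 1], [1, 1, 1]], dtype=np.int8)
        K = centered_kinship(X)
        Xc = X - X.mean(axis=0)
        expect = (Xc @ Xc.T) / 3
        assert np.allclose(K, expect)

    def test_duplicated_samples_equal_rows(self):
        rng = np.random.default_rng(0)
        X = rng.choice([0, 1, 2], size=(6, 30)).astype(np.int8)
        X[2] = X[1]
        K = centered_kinship(X)
        assert np.allclose(K[1], K[2])

    def test_column_sums_zero(self):
        rng = np.random.default_rng(1)
        K = centered_kinship(rng.choice([0, 1, 2], size=(8, 40)).astype(np.int8))
        assert np.allclose(K.sum(axis=0), 0.0, atol=1e-10)

    def test_monomorphic_raises(self):
        with pytest.raises(ValueError):
            centered_kinship(np.ones((4, 5), dtype=np.int8) * 2)


class TestEncodePhenotype:
    def _table(self, values, kind="quantitative", name="t"):
        df = pd.DataFrame({name: values}, index=[f"s{i}" for i in range(len(values))])
        return PhenotypeTable(df, {name: kind}, {name: name})

    def test_log_transform(self):
        vals = [np.e] * 10 + [1.0, 10.0, 100.0] + [2.0] * 10
        y, info = encode_phenotype(self._table(vals), "t")
        assert y.iloc[0] == pytest.approx(1.0)
        assert y.iloc[10:13].tolist() == pytest.approx([0.0, np.log(10), np.log(100)])
        assert info["transform"] == "ln"

    def test_nonpositive_dropped_and_counted(self):
        vals = [1.0] * 22 + [-3.0, 0.0]
        y, info = encode_phenotype(self._table(vals), "t")
        assert info["n_dropped_nonpositive"] == 2
        assert y.isna().iloc[-2:].all()

    def test_binary_passthrough(self):
        vals = [1.0, 0.0] * 12
        y, info = encode_phenotype(self._table(vals, kind="qualitative"), "t")
        assert set(y.unique()) == {0.0, 1.0}
        assert info["transform"] == "identity"

    def test_power_guard(self):
        with pytest.raises(ValueError, match="refusing"):
            encode_phenotype(self._table([1.0] * 5), "t")


class TestLMMScan:
    def test_matches_ols_when_no_genetic_variance(self):
        """With a vanishing kinship the LMM must reduce to plain OLS."""
        rng = np.random.default_rng(0)
        n = 50
        X = rng.choice([0, 1, 2], size=(n, 30)).astype(np.int8)
        y = rng.normal(size=n)
        est = LinearMixedGWAS(min_maf=0.0, max_missing=1.0).fit(
            X, y, kinship=np.eye(n) * 1e-10
        )
        for jj, j in enumerate(est.tested_index_):
            Xd = np.column_stack([np.ones(n), X[:, j]])
            beta = np.linalg.lstsq(Xd, y, rcond=None)[0]
            rss = ((y - Xd @ beta) ** 2).sum()
            cov = rss / (n - 2) * np.linalg.inv(Xd.T @ Xd)
            t = beta[1] / np.sqrt(cov[1, 1])
            p = 2 * stats.t.sf(abs(t), n - 2)
            assert est.results_["p"].iloc[jj] == pytest.approx(p, abs=1e-6)
            assert est.results_["beta"].iloc[jj] == pytest.approx(beta[1], abs=1e-8)

    def test_invariance_to_affine_y_and_allele_swap(self):
        rng = np.random.default_rng(1)
        n = 60
        X = rng.choice([0, 1, 2], size=(n, 20)).astype(np.int8)
        y = rng.normal(size=n)
        base = LinearMixedGWAS(min_maf=0.0, max_missing=1.0).fit(X, y)
        scaled = LinearMixedGWAS(min_maf=0.0, max_missing=1.0).fit(X, 3.0 * y + 7.0)
        assert np.allclose(base.results_["p"], scaled.results_["p"], atol=1e-8)
        swapped = (2 - X).astype(np.int8)
        flip = LinearMixedGWAS(min_maf=0.0, max_missing=1.0).fit(swapped, y)
        assert np.allclose(base.results_["p"], flip.results_["p"], atol=1e-8)
        assert np.allclose(base.results_["beta"], -flip.results_["beta"], atol=1e-10)

    def test_maf_and_missingness_filters(self):
        rng = np.random.default_rng(2)
        n = 200
        X = rng.choice([0, 1, 2], size=(n, 3)).astype(np.int8)
        X[1:, 0] = 0  # MAF 1/400 -> excluded
        X[: int(n * 0.06), 1] = MISSING  # 6% missing -> excluded
        est = LinearMixedGWAS().fit(X, rng.normal(size=n))
        assert est.n_tests_ == 1

    def test_per_variant_lambda_close_to_shared(self, two_pop_cohort):
        g, q, _ = two_pop_cohort
        rng = np.random.default_rng(3)
        y = q[:, 0] + rng.normal(0, 1, size=g.n_samples)
        sub = g.dosages[:, :40]
        kin = centered_kinship(g.dosages)
        a = LinearMixedGWAS(min_maf=0.0, max_missing=1.0).fit(sub, y, kinship=kin)
        b = LinearMixedGWAS(min_maf=0.0, max_missing=1.0, per_variant_lambda=True).fit(
            sub, y, kinship=kin
        )
        # log-p agreement within a small relative band
        assert np.allclose(
            np.log10(a.results_["p"]), np.log10(b.results_["p"]), atol=0.3
        )

    def test_structure_correction_reduces_false_positives(self):
        """On a structure-confounded trait with no true QTL, the mixed model
        must produce no more Bonferroni hits than a naive OLS scan."""
        from coredivkit.simulate import (
            SimulationConfig,
            TraitSpec,
            simulate_quantitative_trait,
            simulate_structured_genotypes,
        )

        lmm_fp = ols_fp = 0
        for seed in range(5):
            cfg = SimulationConfig(
                n_samples=200, n_variants=800, n_chromosomes=4,
                chromosome_length_bp=10_000_000, f_divergence=0.3,
                seed=seed,
            )
            g, q = simulate_structured_genotypes(cfg)
            spec = TraitSpec(qtl_share=0.0, structure_share=0.5, polygenic_share=0.0)
            y, _ = simulate_quantitative_trait(g, spec, q, seed=seed + 50)
            est = LinearMixedGWAS().fit(g.dosages, y.to_numpy(), variants=g.variants)
            cutoff = 0.05 / est.n_tests_
            lmm_fp += int((est.results_["p"] <= cutoff).sum())
            # naive scan: same machinery with a vanishing kinship = plain OLS
            naive = LinearMixedGWAS().fit(
                g.dosages, y.to_numpy(),
                kinship=np.eye(200) * 1e-10, variants=g.variants,
            )
            ols_fp += int((naive.results_["p"] <= 0.05 / naive.n_tests_).sum())
        assert lmm_fp <= ols_fp
        assert ols_fp > 0  # confounding does fool the uncorrected scan

    def test_nonfinite_y_raises(self):
        X = np.zeros((30, 4), dtype=np.int8)
        y = np.full(30, np.inf)
        with pytest.raises(ValueError):
            LinearMixedGWAS().fit(X, y)


class TestBonferroni:
    def test_reported_denominator(self):
        assert bonferroni_threshold(48_004) == pytest.approx(1.0416e-6, rel=1e-3)

    def test_single_test(self):
        assert bonferroni_threshold(1) == 0.05

    def test_halves_when_doubling(self):
        assert bonferroni_threshold(200) == bonferroni_threshold(100) / 2


def _scan_from(results, n_tests):
    return AssociationScan(results=results, trait="t", transform="identity",
                           n_tests=n_tests, lambda_=0.0)


class TestCallPeaks:
    def _matrix_with_columns(self, cols, chrom, pos):
        d = np.column_stack(cols).astype(np.int8)
        return make_matrix(d, chrom=chrom, pos=pos)

    def test_single_snp_single_peak(self):
        rng = np.random.default_rng(0)
        g = self._matrix_with_columns(
            [rng.choice([0, 2], size=50)], ["Vu01"], [1000]
        )
        res = pd.DataFrame(
            {"id": ["v0"], "chrom": ["Vu01"], "pos": [1000], "p": [1e-9]}
        )
        peaks = call_peaks(_scan_from(res, 1), g)
        assert len(peaks) == 1
        assert peaks[0].tag_snp == "v0"
        assert peaks[0].start == peaks[0].end == 1000

    def test_distance_rule_dominates_high_r2(self):
        rng = np.random.default_rng(1)
        col = rng.choice([0, 2], size=50)
        g = self._matrix_with_columns([col, col], ["Vu01", "Vu01"], [1000, 2_100_000])
        res = pd.DataFrame(
            {"id": ["v0", "v1"], "chrom": "Vu01", "pos": [1000, 2_100_000],
             "p": [1e-9, 1e-8]}
        )
        peaks = call_peaks(_scan_from(res, 2), g)
        assert len(peaks) == 2  # r2 = 1 but 2.1 Mbp apart

    def test_linkage_components(self):
        rng = np.random.default_rng(2)
        a = rng.choice([0, 2], size=300)
        b = a.copy()
        b[:60] = 2 - b[:60]  # r ~ 0.6 with a, so r2 ~ 0.36 > 0.2
        c = rng.choice([0, 2], size=300)  # independent
        g = self._matrix_with_columns(
            [a, b, c], ["Vu01"] * 3, [100_000, 300_000, 800_000]
        )
        res = pd.DataFrame(
            {"id": ["v0", "v1", "v2"], "chrom": "Vu01",
             "pos": [100_000, 300_000, 800_000], "p": [1e-9, 1e-7, 1e-8]}
        )
        peaks = call_peaks(_scan_from(res, 3), g)
        assert len(peaks) == 2
        ab = next(p for p in peaks if len(p.member_ids) == 2)
        assert ab.member_ids == ["v0", "v1"]
        assert ab.tag_snp == "v0"  # the smaller p tags the peak

    def test_partition_matches_component_oracle(self, two_pop_cohort):
        """Peak membership equals a brute-force connected-components oracle."""
        g, _, _ = two_pop_cohort
        rng = np.random.default_rng(5)
        # declare a random subset of variants "significant"
        take = np.sort(rng.choice(g.n_variants, size=60, replace=False))
        sub = g.variants.iloc[take]
        res = pd.DataFrame(
            {"id": sub["id"].to_numpy(), "chrom": sub["chrom"].to_numpy(),
             "pos": sub["pos"].to_numpy(),
             "p": rng.uniform(1e-12, 1e-8, size=60)}
        )
        scan = _scan_from(res, 60)
        peaks = call_peaks(scan, g, r2_link=0.2, max_gap=1_000_000)
        # oracle: explicit adjacency + DFS
        d = g.dosages.astype(float)
        d[g.dosages == MISSING] = np.nan
        def r2(i, j):
            ok = ~np.isnan(d[:, i]) & ~np.isnan(d[:, j])
            x, y = d[ok, i], d[ok, j]
            # peaks use mean-imputed r2; recompute the same way
            xi, yj = d[:, i].copy(), d[:, j].copy()
            xi[np.isnan(xi)] = np.nanmean(xi)
            yj[np.isnan(yj)] = np.nanmean(yj)
            if xi.std() == 0 or yj.std() == 0:
                return 0.0
            return np.corrcoef(xi, yj)[0, 1] ** 2
        adj = {i: set() for i in range(60)}
        for ii in range(60):
            for jj in range(ii + 1, 60):
                vi, vj = take[ii], take[jj]
                if g.variants["chrom"].iat[vi] != g.variants["chrom"].iat[vj]:
                    continue
                if abs(int(g.variants["pos"].iat[vi]) - int(g.variants["pos"].iat[vj])) > 1_000_000:
                    continue
                if r2(vi, vj) > 0.2:
                    adj[ii].add(jj)
                    adj[jj].add(ii)
        seen, comps = set(), []
        for i in range(60):
            if i in seen:
                continue
            stack, comp = [i], set()
            while stack:
                k = stack.pop()
                if k in comp:
                    continue
                comp.add(k)
                stack.extend(adj[k] - comp)
            seen |= comp
            comps.append(frozenset(sub["id"].iloc[sorted(comp)]))
        got = {frozenset(p.member_ids) for p in peaks}
        assert got == set(comps)
        # every significant variant in exactly one peak
        all_members = [m for p in peaks for m in p.member_ids]
        assert sorted(all_members) == sorted(res["id"])

    def test_empty_significant_set(self):
        g = make_matrix(np.zeros((10, 2), dtype=np.int8))
        res = pd.DataFrame({"id": [], "chrom": [], "pos": [], "p": []})
        assert call_peaks(_scan_from(res, 100), g) == []


class TestClusterPhenotypeTests:
    def _pheno(self, data, kinds):
        return PhenotypeTable(pd.DataFrame(data), kinds,
                              {k: k for k in kinds})

    def test_identical_distributions_p_one(self):
        ids = [f"s{i}" for i in range(20)]
        vals = list(range(10)) * 2
        t = self._pheno(pd.DataFrame({"q": vals}, index=ids), {"q": "quantitative"})
        assignment = np.array([0] * 10 + [1] * 10)
        out = cluster_phenotype_tests(t, assignment, ids)
        assert out["p"].iloc[0] > 0.9

    def test_fisher_perfect_separation(self):
        ids = [f"s{i}" for i in range(20)]
        vals = [1.0] * 10 + [0.0] * 10
        t = self._pheno(pd.DataFrame({"b": vals}, index=ids), {"b": "qualitative"})
        assignment = np.array([0] * 10 + [1] * 10)
        out = cluster_phenotype_tests(t, assignment, ids)
        # [[10,0],[0,10]]: two-sided exact p = 2 / C(20,10)
        assert out["p"].iloc[0] == pytest.approx(2 / 184_756, rel=1e-6)

    def test_balanced_trait_p_one(self):
        ids = [f"s{i}" for i in range(80)]
        vals = ([1.0] * 20 + [0.0] * 20) * 2
        t = self._pheno(pd.DataFrame({"b": vals}, index=ids), {"b": "qualitative"})
        assignment = np.array([0] * 40 + [1] * 40)
        out = cluster_phenotype_tests(t, assignment, ids)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_unassigned_excluded(self):
        ids = [f"s{i}" for i in range(12)]
        vals = [0.0] * 4 + [1.0] * 4 + [0.5] * 4
        t = self._pheno(pd.DataFrame({"q": vals}, index=ids), {"q": "quantitative"})
        assignment = np.array([0] * 4 + [1] * 4 + [-1] * 4)
        out = cluster_phenotype_tests(t, assignment, ids)
        assert out["n_a"].iloc[0] == 4
        assert out["n_b"].iloc[0] == 4

    def test_regional_enrichment_detects_skew(self):
        regions = np.array(["W"] * 30 + ["E"] * 30, dtype=object)
        assignment = np.concatenate([np.zeros(28), np.ones(2), np.ones(28), np.zeros(2)]).astype(int)
        out = regional_enrichment(regions, assignment)
        assert (out["p"] < 0.001).all()
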
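import numpy as np
import pandas as pd
import pytest
from scipy import stats

import connmed
from connmed import genetics as gen
from connmed.genetics import GenotypeMatrix

from conftest import bh_brute_force, ols_normal_equations


def gm(dosages, **kw):
    d = np.asarray(dosages, dtype=float)
    return GenotypeMatrix(
        d,
        snp_ids=kw.get("snp_ids", [f"s{j}" for j in range(d.shape[1])]),
        subject_ids=kw.get("subject_ids", [f"i{i}" for i in range(d.shape[0])]),
        minor_alleles=kw.get("minor_alleles", []),
        major_alleles=kw.get("major_alleles", []),
    )


class TestRecodeMinorAllele:
    def test_low_frequency_column_unchanged(self):
        G = gm([[0], [0], [1]])
        out = gen.recode_minor_allele(G)
        np.testing.assert_array_equal(out.dosages[:, 0], [0, 0, 1])

    def test_high_frequency_column_flipped(self):
        G = gm([[2], [2], [1]], minor_alleles=["A"], major_alleles=["G"])
        out = gen.recode_minor_allele(G)
        np.testing.assert_array_equal(out.dosages[:, 0], [0, 0, 1])
        assert out.minor_alleles == ["G"] and out.major_alleles == ["A"]

    def test_exact_half_left_unflipped(self):
        G = gm([[0], [2]])
        np.testing.assert_array_equal(gen.recode_minor_allele(G).dosages[:, 0], [0, 2])

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        d = rng.integers(0, 3, (40, 8)).astype(float)
        d[rng.random((40, 8)) < 0.1] = np.nan
        once = gen.recode_minor_allele(gm(d))
        twice = gen.recode_minor_allele(once)
        np.testing.assert_array_equal(once.dosages, twice.dosages)

    def test_all_missing_snp_rejected(self):
        with pytest.raises(ValueError):
            gen.recode_minor_allele(gm([[np.nan], [np.nan]]))


class TestHweTest:
    def test_perfect_hwe_proportions(self):
        assert gen.hwe_test(25, 50, 25) == pytest.approx(1.0)

    def test_planted_violation_matches_chi_square_tail(self):
        # counts 50/0/50: statistic is exactly 100
        p = gen.hwe_test(50, 0, 50)
        assert p == pytest.approx(stats.chi2.sf(100, 1))
        assert p == pytest.approx(1.5e-23, rel=0.05)

    def test_monomorphic_convention(self):
        assert gen.hwe_test(30, 0, 0) == 1.0
        assert gen.hwe_test(0, 0, 30) == 1.0


class TestQcFilter:
    def test_clean_data_untouched(self):
        G = gm(np.tile([0.0, 1.0, 1.0, 2.0], (6, 1)).T)
        out, report = gen.qc_filter(G)
        np.testing.assert_array_equal(out.dosages, G.dosages)
        assert report.n_subjects_removed == 0
        assert report.n_variants_missing_removed == 0
        assert report.n_variants_hwe_removed == 0

    def test_high_missingness_subject_removed(self):
        d = np.tile([0.0, 1.0, 2.0, 1.0], (10, 1)).T  # 4 subjects x 10 SNPs
        d[0, :5] = np.nan  # subject 0 at 50% missing
        out, report = gen.qc_filter(gm(d))
        assert report.n_subjects_removed == 1
        assert out.n_subjects == 3

    def test_toy_matrix_with_planted_violations(self):
        """Two HWE violations + one 20%-missing variant -> 3 variants removed."""
        rng = np.random.default_rng(7)
        n = 100
        d = rng.binomial(2, 0.4, (n, 20)).astype(float)
        # SNPs 1 and 4: perfect heterozygote deficits, counts 50/0/50
        for j in (1, 4):
            d[:, j] = np.repeat([2.0, 0.0], 50)
        d[:20, 2] = np.nan  # SNP 2 at 20% missingness (5% per subject: kept)
        out, report = gen.qc_filter(gm(d))
        assert report.n_subjects_removed == 0
        assert report.n_variants_missing_removed == 1
        assert report.n_variants_hwe_removed == 2
        assert out.n_snps == 17

    def test_everything_removed_is_an_error(self):
        d = np.full((3, 2), np.nan)
        d[0, 0] = 1.0
        with pytest.raises(gen.EmptyDataError):
            gen.qc_filter(gm(d))


class TestGenotypePca:
    def test_two_subpopulations_separate_on_pc1(self):
        rng = np.random.default_rng(11)
        n_half, n_snps = 60, 200
        f1, f2 = 0.1, 0.5
        d = np.vstack(
            [
                rng.binomial(2, f1, (n_half, n_snps)),
                rng.binomial(2, f2, (n_half, n_snps)),
            ]
        ).astype(float)
        scores = gen.genotype_pca(gm(d), n_components=2)
        pc1 = scores[:, 0]
        g1, g2 = pc1[:n_half], pc1[n_half:]
        assert max(g1.min(), g2.min()) > min(g1.max(), g2.max()) or max(
            g2.min(), g1.min()
        ) > min(g2.max(), g1.max())  # zero overlap between groups

    def test_identical_subjects_give_zero_scores(self):
        d = np.tile([1.0, 0.0, 2.0], (6, 1))  # 6 identical subjects
        scores = gen.genotype_pca(gm(d), n_components=2)
        np.testing.assert_allclose(scores, 0.0, atol=1e-12)

    def test_components_orthogonal(self):
        rng = np.random.default_rng(12)
        d = rng.binomial(2, 0.3, (50, 80)).astype(float)
        scores = gen.genotype_pca(gm(d), n_components=3)
        assert abs(scores[:, 0] @ scores[:, 1]) < 1e-8 * np.linalg.norm(scores[:, 0]) * np.linalg.norm(scores[:, 1]) + 1e-8

    def test_rank_overflow_rejected(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0], [0.0, 1.0]])
        with pytest.raises(ValueError):
            gen.genotype_pca(gm(d), n_components=3)


class TestClusterGwas:
    def test_noiseless_planted_slope_recovered_exactly(self):
        rng = np.random.default_rng(3)
        n = 60
        x = rng.integers(0, 3, n).astype(float)
        w1 = 0.1 + 0.05 * x
        W = np.column_stack([w1, 1 - w1])
        Z = pd.DataFrame({"age": np.zeros(n), "sex": np.zeros(n)})
        assoc = gen.cluster_gwas(W, gm(x[:, None]), Z)
        row = assoc[(assoc.cluster == 0)].iloc[0]
        assert row.beta_hat == pytest.approx(0.05, abs=1e-12)
        assert row.p < 1e-200 or row.p == 0.0

    def test_matches_normal_equations_with_missing_dosages(self, rng):
        n = 30
        x = rng.integers(0, 3, n).astype(float)
        x[[2, 9, 17]] = np.nan
        W = rng.dirichlet(np.ones(3), n)
        Z = pd.DataFrame({"age": rng.normal(30, 5, n), "sex": rng.integers(0, 2, n)})
        assoc = gen.cluster_gwas(W, gm(x[:, None]), Z)
        mask = ~np.isnan(x)
        X = np.column_stack(
            [np.ones(mask.sum()), x[mask], Z.age[mask], Z.sex[mask]]
        )
        for k in range(3):
            beta = ols_normal_equations(X, W[mask, k])[1]
            got = assoc[(assoc.cluster == k)].iloc[0].beta_hat
            assert got == pytest.approx(beta, rel=1e-8)

    def test_monomorphic_snp_flagged(self):
        n = 20
        W = np.tile([0.5, 0.5], (n, 1))
        Z = pd.DataFrame({"age": np.arange(n), "sex": np.zeros(n)})
        assoc = gen.cluster_gwas(W, gm(np.ones((n, 1))), Z)
        assert assoc.degenerate.all()
        assert (assoc.p == 1.0).all()

    def test_null_permutation_calibration(self, rng):
        """Permuted genotypes: raw p<0.05 rate over 1000 pairs in [0.035, 0.065]."""
        n, n_snps, K = 100, 100, 10
        b = connmed.scenario("null", n, seed=17, n_snps=n_snps, K=K)
        perm = rng.permutation(n)
        G = gm(b.genotypes.dosages[perm])
        Z = pd.DataFrame(
            {"age": b.covariates.age.to_numpy(), "sex": b.covariates.sex.to_numpy()}
        )
        assoc = gen.cluster_gwas(b.proportions, G, Z)
        rate = (assoc.p < 0.05).mean()
        assert 0.035 <= rate <= 0.065


class TestFdrSelect:
    def test_bh_worked_example(self):
        p = [0.001, 0.01, 0.03, 0.04, 0.2]
        assoc = pd.DataFrame(
            {"snp": [f"s{i}" for i in range(5)], "cluster": 0, "p": p, "degenerate": False}
        )
        out = gen.fdr_select(assoc, q=0.05)
        assert out.selected.tolist() == [True, True, True, True, False]

    def test_all_ones_select_nothing(self):
        assoc = pd.DataFrame(
            {"snp": list("abc"), "cluster": 0, "p": [1.0, 1.0, 1.0], "degenerate": False}
        )
        assert not gen.fdr_select(assoc).selected.any()

    def test_monotone_in_q(self, rng):
        assoc = pd.DataFrame(
            {
                "snp": [f"s{i}" for i in range(50)],
                "cluster": rng.integers(0, 3, 50),
                "p": rng.random(50),
                "degenerate": False,
            }
        )
        prev = set()
        for q in (0.01, 0.05, 0.1, 0.3):
            cur = set(
                gen.fdr_select(assoc, q=q).query("selected").apply(
                    lambda r: (r.snp, r.cluster), axis=1
                )
            )
            assert prev <= cur
            prev = cur

    def test_per_cluster_application_on_block_input(self):
        """Identical p-vector in two clusters is adjusted independently, so
        selections match the single-cluster run in each block."""
        p = [0.001, 0.04, 0.5]
        assoc = pd.DataFrame(
            {
                "snp": ["a", "b", "c", "a", "b", "c"],
                "cluster": [0, 0, 0, 1, 1, 1],
                "p": p + p,
                "degenerate": False,
            }
        )
        out = gen.fdr_select(assoc, q=0.05)
        reject, adj = bh_brute_force(np.array(p), 0.05)
        for k in (0, 1):
            blk = out[out.cluster == k]
            np.testing.assert_array_equal(blk.selected.to_numpy(), reject)
            np.testing.assert_allclose(blk.fdr_p.to_numpy(), adj)


class TestLdR2:
    def test_identity_and_allele_flip(self, rng):
        g1 = rng.integers(0, 3, 100).astype(float)
        assert gen.ld_r2(g1, g1) == pytest.approx(1.0)
        assert gen.ld_r2(g1, 2 - g1) == pytest.approx(1.0)
        assert gen.ld_r2(g1, 2 - g1) == pytest.approx(gen.ld_r2(2 - g1, g1))

    def test_independent_snps_near_zero(self):
        rng = np.random.default_rng(23)
        g1 = rng.binomial(2, 0.3, 10_000).astype(float)
        g2 = rng.binomial(2, 0.3, 10_000).astype(float)
        assert gen.ld_r2(g1, g2) < 0.01

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            gen.ld_r2(np.ones(10), np.arange(10) % 3)
        with pytest.raises(ValueError):
            gen.ld_r2(np.array([1.0, np.nan]), np.array([np.nan, 1.0]))


class TestLeadSnps:
    def _assoc(self, snps, ps):
        return pd.DataFrame(
            {
                "snp": snps,
                "cluster": 0,
                "p": ps,
                "degenerate": False,
                "selected": True,
            }
        )

    def test_correlated_pair_keeps_best_p(self, rng):
        g = rng.integers(0, 3, 50).astype(float)
        G = gm(np.column_stack([g, g]), snp_ids=["a", "b"])
        out = gen.lead_snps(self._assoc(["a", "b"], [1e-6, 1e-8]), G)
        assert out == ["b"]

    def test_independent_snps_all_kept(self):
        rng = np.random.default_rng(31)
        G = gm(rng.binomial(2, 0.4, (2000, 4)).astype(float))
        out = gen.lead_snps(self._assoc(list(G.snp_ids), [1e-8, 1e-7, 1e-6, 1e-5]), G)
        assert out == list(G.snp_ids)

    def test_matches_brute_force_on_block_structure(self):
        rng = np.random.default_rng(37)
        n = 400
        base = [rng.binomial(2, 0.5, n).astype(float) for _ in range(3)]
        cols, owner = [], []
        for bi, g in enumerate(base):
            for _ in range(3 if bi < 2 else 4):
                cols.append(g)  # perfect LD inside each block
                owner.append(bi)
        G = gm(np.column_stack(cols))
        ps = rng.random(10) * 1e-4
        assoc = self._assoc(list(G.snp_ids), ps)
        got = gen.lead_snps(assoc, G, r2_max=0.1)
        # brute-force re-application of the greedy rule
        order = sorted(range(10), key=lambda j: (ps[j], G.snp_ids[j]))
        expected, taken_blocks = [], set()
        for j in order:
            r2s = [gen.ld_r2(G.dosages[:, j], G.dosages[:, G.snp_ids.index(a)]) for a in expected]
            if all(r <= 0.1 for r in r2s):
                expected.append(G.snp_ids[j])
        assert got == expected

    def test_empty_selection_rejected(self):
        G = gm(np.zeros((5, 1)) + np.array([[0.0], [1], [2], [1], [0]]))
        assoc = self._assoc(["s0"], [0.5])
        assoc["selected"] = False
        with pytest.raises(ValueError):
            gen.lead_snps(assoc, G)


class TestActiveSets:
    def test_inversion_of_selected_pairs(self):
        assoc = pd.DataFrame(
            {
                "snp": ["g1", "g1", "g2", "g3"],
                "cluster": [0, 2, 0, 1],
                "p": [1e-8] * 4,
                "degenerate": False,
                "selected": [True, True, True, False],
            }
        )
        out = gen.active_sets(assoc)
        assert out == {"g1": [0, 2], "g2": [0]}

    def test_empty_selection_gives_empty_map(self):
        assoc = pd.DataFrame(
            {"snp": ["a"], "cluster": [0], "p": [0.9], "degenerate": False, "selected": [False]}
        )
        assert gen.active_sets(assoc) == {}

    def test_sizes_sum_to_selected_pairs(self, rng):
        n = 40
        assoc = pd.DataFrame(
            {
                "snp": rng.choice(list("abcdef"), n),
                "cluster": rng.integers(0, 5, n),
                "p": rng.random(n),
                "degenerate": False,
            }
        )
        assoc = assoc.drop_duplicates(["snp", "cluster"])
        assoc["selected"] = rng.random(len(assoc)) < 0.5
        out = gen.active_sets(assoc)
        assert sum(len(v) for v in out.values()) == int(assoc.selected.sum())


def test_planted_pair_selected_with_high_power():
    """Screen power sanity: the planted (SNP, cluster) pair survives
    per-cluster FDR in >=80% of replicates at n=2000."""
    from connmed.validate import mediation_recovery

    df = mediation_recovery(
        "full_mediation", n_reps=25, n_subjects=2000, n_snps=200, seed=41
    )
    assert df.planted_selected.mean() >= 0.8
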
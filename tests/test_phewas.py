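import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nrhap.phewas import (
    DosageMatrix,
    GRMEigen,
    bh_fdr,
    compute_grm,
    encode_haplotype,
    fisher_one_sided,
    genomic_control_lambda,
    grm_snp_filters,
    hwe_exact_test,
    inverse_normal_transform,
    linear_association,
    mlma_test,
    preprocess_phenotype,
    read_dosage_tsv,
    reml_variance_components,
    write_dosage_tsv,
    _reml_neg_ll,
)
from nrhap.haplotyping import ALT_GROUP, REF_GROUP, UNASSIGNED
from nrhap.simulate import simulate_autosomal_dosages

from oracles import bh_oracle, fisher_one_sided_oracle, hwe_exact_oracle


class TestHweExact:
    def test_monomorphic_single_outcome(self):
        assert hwe_exact_test(1, 0, 0) == 1.0

    def test_two_het_enumeration(self):
        # 2 individuals, 2 A and 2 a alleles: het counts {0, 2} possible
        assert hwe_exact_test(0, 2, 0) == pytest.approx(
            hwe_exact_oracle(0, 2, 0)
        )

    def test_matches_exact_enumeration_all_small_tables(self):
        for n in range(1, 21):
            for n_AA in range(n + 1):
                for n_Aa in range(n - n_AA + 1):
                    n_aa = n - n_AA - n_Aa
                    got = hwe_exact_test(n_AA, n_Aa, n_aa)
                    want = hwe_exact_oracle(n_AA, n_Aa, n_aa)
                    assert got == pytest.approx(want, abs=1e-10), (
                        n_AA, n_Aa, n_aa
                    )

    def test_input_validation(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 1, 0)


class TestGrmSnpFilters:
    def _dm(self, cols):
        cols = np.asarray(cols, dtype=float).T
        return DosageMatrix(
            sample_ids=[f"s{i}" for i in range(cols.shape[0])],
            snp_ids=[f"snp{j}" for j in range(cols.shape[1])],
            dosages=cols,
        )

    def test_hwe_balanced_snp_retained_monomorphic_removed(self):
        balanced = [0] * 25 + [1] * 50 + [2] * 25
        mono = [0] * 100
        dm = self._dm([balanced, mono])
        out = grm_snp_filters(dm)
        assert out.snp_ids == ["snp0"]

    def test_missingness_threshold_strict(self):
        ok = [np.nan] * 10 + [1] * 45 + [0, 2] * 22 + [1]  # 10% missing
        bad = [np.nan] * 11 + [1] * 45 + [0, 2] * 22  # 11% missing
        dm = self._dm([ok, bad])
        out = grm_snp_filters(dm, hwe_p_min=0.0, maf_min=0.0)
        assert out.snp_ids == ["snp0"]

    def test_female_only_hwe_subset(self):
        # males all (spuriously) het at an X SNP wreck the pooled HWE test;
        # the female subset is in equilibrium and keeps the SNP
        col = [1] * 50 + [0] * 12 + [1] * 26 + [2] * 12
        dm = self._dm([col])
        females = np.array([False] * 50 + [True] * 50)
        out = grm_snp_filters(dm, hwe_sample_subset=females, hwe_p_min=1e-3)
        assert out.snp_ids == ["snp0"]
        with pytest.raises(ValueError, match="all SNPs removed"):
            grm_snp_filters(dm, hwe_p_min=1e-3)


class TestComputeGrm:
    def test_identical_samples(self):
        rng = np.random.default_rng(0)
        row = rng.integers(0, 3, size=200).astype(float)
        other = 2.0 - row  # keeps every SNP polymorphic across the samples
        dm = DosageMatrix(["a", "b", "c"], [f"s{j}" for j in range(200)],
                          np.stack([row, row, other]))
        grm, counts = compute_grm(dm)
        assert grm[0, 1] == pytest.approx(grm[0, 0])
        assert (counts == 200).all()

    def test_unrelated_off_diagonal_near_zero(self):
        # sample-frequency centering makes E[off-diagonal] = -1/(n-1),
        # so n must be large enough for the +-0.01 band
        dm, _ = simulate_autosomal_dosages(500, 5000, sibship_size=1, seed=3)
        grm, _ = compute_grm(dm)
        off = grm[~np.eye(500, dtype=bool)]
        assert abs(off.mean()) < 0.01
        assert np.diag(grm).mean() == pytest.approx(1.0, abs=0.05)

    def test_full_sib_kinship(self):
        dm, sibs = simulate_autosomal_dosages(200, 4000, sibship_size=4, seed=4)
        grm, _ = compute_grm(dm)
        same = sibs[:, None] == sibs[None, :]
        off = ~np.eye(200, dtype=bool)
        within = grm[same & off].mean()
        between = grm[~same].mean()
        assert within == pytest.approx(0.5, abs=0.05)
        assert within > between

    def test_monomorphic_rejected(self):
        dm = DosageMatrix(["a", "b"], ["s0"], np.array([[0.0], [0.0]]))
        with pytest.raises(ValueError, match="monomorphic"):
            compute_grm(dm)

    def test_sample_order_invariance(self):
        dm, _ = simulate_autosomal_dosages(30, 500, seed=5)
        grm, _ = compute_grm(dm)
        perm = np.random.default_rng(1).permutation(30)
        dm2 = DosageMatrix(
            [dm.sample_ids[i] for i in perm], dm.snp_ids, dm.dosages[perm]
        )
        grm2, _ = compute_grm(dm2)
        np.testing.assert_allclose(grm2, grm[np.ix_(perm, perm)], atol=1e-12)

    def test_dosage_tsv_round_trip(self, tmp_path):
        dm, _ = simulate_autosomal_dosages(10, 20, seed=6)
        write_dosage_tsv(dm, tmp_path / "d.tsv")
        back = read_dosage_tsv(tmp_path / "d.tsv")
        assert back.sample_ids == dm.sample_ids
        np.testing.assert_array_equal(back.dosages, dm.dosages)


class TestPreprocessPhenotype:
    def test_middle_of_three_is_zero(self):
        out = preprocess_phenotype(np.array([3.0, 1.0, 2.0]))
        assert out[2] == pytest.approx(0.0, abs=1e-12)

    def test_rank_preserving(self):
        rng = np.random.default_rng(7)
        raw = rng.gamma(2, size=200)
        out = preprocess_phenotype(raw)
        rho = stats.spearmanr(raw, out).statistic
        assert rho == pytest.approx(1.0)

    def test_standard_normal_nearly_identity(self):
        """Quantile map converges to the identity on already-normal data.

        Extreme order statistics fluctuate at O(1) scale even at n = 10^4,
        so the tight bound applies to the central mass and a looser one to
        the tails."""
        rng = np.random.default_rng(8)
        raw = rng.standard_normal(10_000)
        out = preprocess_phenotype(raw)
        dev = np.abs(out - (raw - raw.mean()))
        interior = (raw > np.quantile(raw, 0.01)) & (raw < np.quantile(raw, 0.99))
        assert np.median(dev) < 0.01
        assert dev[interior].max() < 0.1
        assert dev.max() < 0.5

    def test_covariate_residualisation(self):
        rng = np.random.default_rng(9)
        cov = rng.standard_normal(500)
        raw = 3 * cov + rng.standard_normal(500)
        out = preprocess_phenotype(raw, covariates=cov)
        # residualised trait is uncorrelated with the covariate
        assert abs(np.corrcoef(out, cov)[0, 1]) < 0.1

    def test_missing_propagation_and_errors(self):
        raw = np.array([1.0, np.nan, 2.0, 3.0])
        out = preprocess_phenotype(raw)
        assert np.isnan(out[1]) and np.isfinite(out[[0, 2, 3]]).all()
        with pytest.raises(ValueError, match="constant"):
            preprocess_phenotype(np.array([1.0, 1.0, 1.0]))
        with pytest.raises(ValueError, match="non-missing"):
            preprocess_phenotype(np.array([1.0, np.nan, np.nan]))

    def test_int_is_permutation_of_quantiles(self):
        rng = np.random.default_rng(10)
        raw = rng.uniform(size=51)
        out = inverse_normal_transform(raw)
        expected = stats.norm.ppf((np.arange(1, 52) - 3 / 8) / (51 + 1 / 4))
        np.testing.assert_allclose(np.sort(out), expected, atol=1e-12)


class TestEncodeHaplotype:
    def test_mapping(self):
        asg = pd.DataFrame(
            {
                "sample_id": ["a", "b", "c"],
                "label": [REF_GROUP, ALT_GROUP, UNASSIGNED],
            }
        )
        enc = encode_haplotype(asg, REF_GROUP)
        assert enc["a"] == 0.0 and enc["b"] == 2.0 and np.isnan(enc["c"])
        flipped = encode_haplotype(asg, ALT_GROUP)
        assert flipped["a"] == 2.0 and flipped["b"] == 0.0

    def test_bad_reference_group(self):
        asg = pd.DataFrame({"sample_id": ["a"], "label": [REF_GROUP]})
        with pytest.raises(ValueError):
            encode_haplotype(asg, "Y1")


@pytest.fixture(scope="module")
def sib_grm():
    dm, sibs = simulate_autosomal_dosages(400, 2000, sibship_size=4, seed=20)
    grm, _ = compute_grm(dm)
    return grm, GRMEigen.from_grm(grm), sibs


class TestReml:
    def test_null_heritability_near_zero(self, sib_grm):
        grm, eig, _ = sib_grm
        rng = np.random.default_rng(30)
        ests = []
        for _ in range(20):
            y = rng.standard_normal(400)
            sg2, se2 = reml_variance_components(y, np.ones((400, 1)), eig)
            ests.append(sg2 / (sg2 + se2))
        assert np.median(ests) < 0.02

    def test_h2_recovery(self, sib_grm):
        grm, eig, _ = sib_grm
        rng = np.random.default_rng(31)
        chol = np.linalg.cholesky(grm + 1e-8 * np.eye(400))
        ests = []
        for _ in range(20):
            g = chol @ rng.standard_normal(400) * np.sqrt(0.5)
            y = g + rng.standard_normal(400) * np.sqrt(0.5)
            sg2, se2 = reml_variance_components(y, np.ones((400, 1)), eig)
            ests.append(sg2 / (sg2 + se2))
        assert np.median(ests) == pytest.approx(0.5, abs=0.1)

    def test_optimum_beats_grid(self, sib_grm):
        grm, eig, _ = sib_grm
        rng = np.random.default_rng(32)
        y = rng.standard_normal(400)
        X = np.ones((400, 1))
        sg2, se2 = reml_variance_components(y, X, eig)
        if sg2 == 0:
            return  # boundary optimum; grid comparison below needs interior
        best = np.log(se2 / sg2)
        s = np.maximum(eig.eigenvalues, 0)
        yr = eig.eigenvectors.T @ y
        Xr = eig.eigenvectors.T @ X
        f_best = _reml_neg_ll(best, s, yr, Xr)[0]
        for ld in np.linspace(-10, 10, 21):
            assert f_best <= _reml_neg_ll(ld, s, yr, Xr)[0] + 1e-6

    def test_identity_grm_not_identifiable(self):
        with pytest.raises(ValueError, match="identifiable"):
            GRMEigen.from_grm(np.eye(50))


class TestMlma:
    def test_reduces_to_ols_with_identity_covariance(self):
        """With V proportional to I (fixed components), MLMA equals OLS."""
        rng = np.random.default_rng(40)
        n = 120
        x = rng.choice([0.0, 2.0], size=n)
        y = 0.1 * x + rng.standard_normal(n)
        eig = GRMEigen(eigenvalues=np.ones(n), eigenvectors=np.eye(n))
        # closed-form OLS with the residual variance as the fixed V scale
        X = np.column_stack([np.ones(n), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        sigma2 = float(resid @ resid) / (n - 2)
        res = mlma_test(y, x, eig, variance_components=(0.0, sigma2))
        cov = sigma2 * np.linalg.inv(X.T @ X)
        z2 = beta[1] ** 2 / cov[1, 1]
        from scipy.stats import chi2

        assert res.beta == pytest.approx(beta[1], abs=1e-10)
        assert res.wald == pytest.approx(z2, rel=1e-10)
        assert res.p == pytest.approx(chi2.sf(z2, 1), rel=1e-10)

    def test_constant_genotype_flagged(self, sib_grm):
        _, eig, _ = sib_grm
        y = np.random.default_rng(41).standard_normal(400)
        res = mlma_test(y, np.zeros(400), eig)
        assert res.flagged == "constant genotype"
        assert np.isnan(res.p)

    def test_power_under_true_effect(self, sib_grm):
        grm, eig, sibs = sib_grm
        rng = np.random.default_rng(42)
        x = np.where(rng.random(400) < 0.5, 0.0, 2.0)
        y = 0.3 * x + rng.standard_normal(400)
        res = mlma_test(y, x, eig)
        assert res.p < 1e-6 and res.beta == pytest.approx(0.3, abs=0.15)


class TestBhFdr:
    def test_hand_worked_example(self):
        q = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_trivial_cases(self):
        assert bh_fdr(np.array([0.2]))[0] == pytest.approx(0.2)
        np.testing.assert_allclose(bh_fdr(np.ones(5)), 1.0)
        assert bh_fdr(np.array([])).size == 0

    def test_matches_oracle_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(50)
        p = rng.uniform(size=37)
        q = bh_fdr(p)
        np.testing.assert_allclose(q, bh_oracle(p), atol=1e-12)
        np.testing.assert_allclose(
            q, multipletests(p, method="fdr_bh")[1], atol=1e-12
        )

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(51)
        p = rng.uniform(size=100)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
        assert (q <= 1).all() and (q >= p - 1e-15).all()


class TestFisherOneSided:
    def test_hand_enumerated_table(self):
        p, flagged = fisher_one_sided(np.array([[3, 1], [1, 3]]), "greater")
        assert p == pytest.approx(17 / 70)
        assert not flagged

    def test_identical_rows_not_enriched(self):
        p, _ = fisher_one_sided(np.array([[5, 5], [5, 5]]), "greater")
        assert p >= 0.5

    def test_zero_margin_convention(self):
        p, flagged = fisher_one_sided(np.array([[0, 0], [3, 4]]), "greater")
        assert p == 1.0 and flagged

    def test_matches_enumeration_all_small_tables(self):
        for n in range(1, 13):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        if (a + b == 0 or c + d == 0
                                or a + c == 0 or b + d == 0):
                            continue
                        got, _ = fisher_one_sided(
                            np.array([[a, b], [c, d]]), "greater"
                        )
                        want = fisher_one_sided_oracle(a, b, c, d)
                        assert got == pytest.approx(want, abs=1e-10), (a, b, c, d)


def test_genomic_control_lambda_null_uniform():
    rng = np.random.default_rng(60)
    p = rng.uniform(size=20_000)
    assert genomic_control_lambda(p) == pytest.approx(1.0, abs=0.05)
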
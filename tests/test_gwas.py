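"""Backsolved SNP effects, variances, p-values, and diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ssgwas import gwas, relmat
from ssgwas.apy import ApyPartition, build_gapy_inverse
from ssgwas.gwas import (
    backsolve_snp_effects,
    bonferroni_threshold,
    compare_methods,
    genomic_control,
    make_result,
    qq_slope,
    snp_pvalues,
    snp_variance_apy,
    snp_variance_exact,
)
from ssgwas.pev import PevMatrix
from ssgwas.relmat import BlendedG, GenotypeMatrix


@pytest.fixture(scope="module")
def toy_geno():
    # external (non-data) allele frequencies keep ZZ' full rank: centering
    # by observed frequencies would put the all-ones vector in its null space
    rng = np.random.default_rng(12)
    counts = rng.integers(0, 3, size=(30, 80)).astype(float)
    return GenotypeMatrix(
        [f"a{i}" for i in range(30)], [f"m{j}" for j in range(80)], counts,
        allele_freq=np.full(80, 0.45),
    )


@pytest.fixture(scope="module")
def raw_blended(toy_geno):
    """Blending/tuning switched off: G is exactly ZZ'/k (plus a ridge-free
    full-rank check)."""
    G = relmat.build_G_raw(toy_geno)
    # 30 animals x 80 markers: ZZ'/k is almost surely full rank
    return BlendedG(matrix=G, beta=0.0, b_tune=1.0, alpha_tune=0.0)


class TestBacksolve:
    def test_zero_gebv_gives_zero_effects(self, raw_blended, toy_geno):
        a = backsolve_snp_effects(np.zeros(toy_geno.n_animals), raw_blended, toy_geno)
        np.testing.assert_allclose(a, 0.0)

    def test_reconstructs_gebv_without_blending(self, raw_blended, toy_geno):
        """With G = ZZ'/k exactly, Z a_hat = u_hat."""
        rng = np.random.default_rng(5)
        u = rng.normal(size=toy_geno.n_animals)
        a = backsolve_snp_effects(u, raw_blended, toy_geno)
        np.testing.assert_allclose(toy_geno.Z @ a, u, atol=1e-8)

    def test_apy_operator_matches_exact_at_full_core(self, raw_blended, toy_geno):
        rng = np.random.default_rng(6)
        u = rng.normal(size=toy_geno.n_animals)
        part = build_gapy_inverse(
            raw_blended, ApyPartition(toy_geno.animal_ids, []), toy_geno.animal_ids
        )
        a_exact = backsolve_snp_effects(u, raw_blended, toy_geno)
        a_apy = backsolve_snp_effects(u, raw_blended, toy_geno, apy_partition=part)
        np.testing.assert_allclose(a_apy, a_exact, atol=1e-8)

    def test_planted_qtn_have_largest_effects(self, family_pop, tmp_path):
        """Backsolved effects recover the planted signal by rank."""
        from ssgwas import io as io_mod
        from ssgwas import pipeline

        cfg = io_mod.RunConfig(
            pedigree="", genotypes="", snp_map="", phenotypes="",
            sigma_u2=0.3, sigma_e2=0.7, method="exact_ginv",
            seed=1, out_dir=str(tmp_path / "out_rank"),
        )
        res = pipeline.run_pipeline(
            cfg, inputs=(family_pop.pedigree, family_pop.genotypes,
                         family_pop.phenotypes)
        )
        qtn_markers = {
            family_pop.genotypes.marker_ids[j] for j in family_pop.qtn_indices
        }
        tab = res.table.assign(absr=lambda t: np.abs(t["effect"])).sort_values(
            "absr", ascending=False
        )
        is_qtn = tab["marker"].isin(qtn_markers).to_numpy()
        qtn_ranks = np.nonzero(is_qtn)[0]
        m = len(tab)
        # planted QTN sit far above the median rank of null markers
        assert np.median(qtn_ranks) < m / 10


class TestVariances:
    def test_no_information_pev_zeroes_variances(self, raw_blended, toy_geno):
        C = PevMatrix(
            matrix=raw_blended.matrix * 0.3,
            animal_set=list(toy_geno.animal_ids), method="exact-full",
        )
        var = snp_variance_exact(raw_blended, C, toy_geno, sigma_u2=0.3)
        assert np.max(var) < 1e-12

    def test_two_animal_hand_computation(self):
        geno = GenotypeMatrix(["a", "b"], ["m1", "m2"],
                              np.array([[0.0, 1.0], [2.0, 2.0]]))
        G = relmat.build_G_raw(geno) + 0.1 * np.eye(2)
        bg = BlendedG(matrix=G, beta=0.0, b_tune=1.0, alpha_tune=0.0)
        sigma_u2, sigma_e2 = 0.5, 1.0
        C = PevMatrix(matrix=0.2 * np.eye(2), animal_set=["a", "b"],
                      method="exact-full")
        var = snp_variance_exact(bg, C, geno, sigma_u2)
        k = geno.scale_k
        Ginv = np.linalg.inv(G)
        mid = Ginv @ (G * sigma_u2 - 0.2 * np.eye(2)) @ Ginv
        for i in range(2):
            z = geno.Z[:, i]
            assert var[i] == pytest.approx((1 / k) ** 2 * z @ mid @ z, rel=1e-10)

    def test_core_route_degenerates_to_exact(self, raw_blended, toy_geno):
        """Full core + exact-core PEV reproduces the all-animal variances."""
        rng = np.random.default_rng(7)
        S = rng.normal(size=(toy_geno.n_animals, toy_geno.n_animals + 3))
        C = 0.05 * S @ S.T / (toy_geno.n_animals + 3)
        # keep C below the prior variance so variances stay positive
        Cm = PevMatrix(matrix=C, animal_set=list(toy_geno.animal_ids),
                       method="exact-full")
        var_exact = snp_variance_exact(raw_blended, Cm, toy_geno, sigma_u2=0.5)
        part = build_gapy_inverse(
            raw_blended, ApyPartition(toy_geno.animal_ids, []), toy_geno.animal_ids
        )
        Cc = PevMatrix(matrix=C, animal_set=list(part.core_ids), method="exact-core")
        var_apy = snp_variance_apy(
            part, Cc, toy_geno, beta=0.0, b_tune=1.0,
            scale_k=toy_geno.scale_k, sigma_u2=0.5,
        )
        np.testing.assert_allclose(var_apy, var_exact, rtol=1e-8)

    def test_negative_variance_beyond_roundoff_raises(self, raw_blended, toy_geno):
        C = PevMatrix(
            matrix=raw_blended.matrix * 10.0,  # far above the prior variance
            animal_set=list(toy_geno.animal_ids), method="exact-full",
        )
        with pytest.raises(FloatingPointError):
            snp_variance_exact(raw_blended, C, toy_geno, sigma_u2=0.3)


class TestPvalues:
    def test_zero_effect_gives_one(self):
        p, nlp = snp_pvalues(np.array([0.0]), np.array([1.0]))
        assert p[0] == pytest.approx(1.0)
        assert nlp[0] == pytest.approx(0.0, abs=1e-12)

    def test_normal_quantile(self):
        p, _ = snp_pvalues(np.array([1.959964]), np.array([1.0]))
        assert p[0] == pytest.approx(0.05, abs=1e-4)

    def test_extreme_statistic_no_underflow(self):
        p, nlp = snp_pvalues(np.array([10.0]), np.array([1.0]))
        assert nlp[0] > 20
        # oracle: asymptotic log tail of the normal distribution
        t = 10.0
        approx = -(np.log(2) + stats.norm.logsf(t)) / np.log(10)
        assert nlp[0] == pytest.approx(approx, rel=1e-12)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            snp_pvalues(np.array([1.0]), np.array([0.0]))

    @settings(deadline=None, max_examples=30)
    @given(
        st.lists(
            st.floats(min_value=0.01, max_value=8.0), min_size=2, max_size=20
        )
    )
    def test_pvalues_strictly_decrease_in_statistic(self, ts):
        ts = np.unique(np.asarray(ts))
        p, _ = snp_pvalues(ts, np.ones_like(ts))
        assert (np.diff(p) < 0).all()


class TestDiagnostics:
    def test_bonferroni_values(self):
        assert bonferroni_threshold(1, 0.05) == pytest.approx(1.301, abs=1e-3)
        assert bonferroni_threshold(39744, 0.05) == pytest.approx(5.900, abs=1e-3)
        assert bonferroni_threshold(100, 1.0) == pytest.approx(2.0)

    def test_bonferroni_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0, 0.05)
        with pytest.raises(ValueError):
            bonferroni_threshold(10, 0.0)

    def test_genomic_control_null_calibration(self):
        p = (np.arange(1, 10001) - 0.5) / 10000
        lam, corrected = genomic_control(p)
        assert lam == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(corrected, p, atol=1e-6)

    def test_genomic_control_scale_equivariance(self):
        p = (np.arange(1, 1001) - 0.5) / 1000
        chi2 = stats.chi2.isf(p, 1)
        lam1, _ = genomic_control(p)
        lam2, _ = genomic_control(stats.chi2.sf(2 * chi2, 1))
        assert lam2 == pytest.approx(2 * lam1, rel=1e-6)

    def test_genomic_control_monte_carlo_null(self):
        rng = np.random.default_rng(23)
        z = rng.normal(size=10000)
        p = 2 * stats.norm.sf(np.abs(z))
        lam, _ = genomic_control(p)
        assert lam == pytest.approx(1.0, abs=0.05)

    def test_qq_slope_identity_and_doubling(self):
        m = 500
        exp_q = (np.arange(1, m + 1) - 0.5) / m
        assert qq_slope(exp_q) == pytest.approx(1.0, rel=1e-9)
        assert qq_slope(exp_q**2) == pytest.approx(2.0, rel=1e-9)


class TestResultAndComparison:
    def test_pvalue_invariant_reevaluates(self, raw_blended, toy_geno):
        rng = np.random.default_rng(3)
        eff = rng.normal(size=toy_geno.n_markers) * 0.01
        var = np.full(toy_geno.n_markers, 1e-4)
        res = make_result(toy_geno, eff, var, "Exact_Ginv")
        t = np.abs(res.effects) / np.sqrt(res.variances)
        np.testing.assert_allclose(
            res.pvalues, 2 * (1 - stats.norm.cdf(t)), atol=1e-12
        )

    def test_self_comparison_is_unity(self, raw_blended, toy_geno):
        rng = np.random.default_rng(3)
        eff = rng.normal(size=toy_geno.n_markers)
        var = np.abs(rng.normal(size=toy_geno.n_markers)) + 0.1
        r1 = make_result(toy_geno, eff, var, "Exact_Ginv")
        r2 = make_result(toy_geno, eff, var, "Exact_GinvAPY")
        table = compare_methods([r1, r2])
        assert table["pvalue_all"].iloc[0] == pytest.approx(1.0)
        assert table["effect_all"].iloc[0] == pytest.approx(1.0)
        assert table["variance_all"].iloc[0] == pytest.approx(1.0)

    def test_marker_mismatch_rejected(self, toy_geno):
        rng = np.random.default_rng(3)
        eff = rng.normal(size=toy_geno.n_markers)
        var = np.ones(toy_geno.n_markers)
        r1 = make_result(toy_geno, eff, var, "A")
        sub = GenotypeMatrix(
            toy_geno.animal_ids, toy_geno.marker_ids[:-1],
            toy_geno.counts[:, :-1],
        )
        r2 = make_result(sub, eff[:-1], var[:-1], "B")
        with pytest.raises(ValueError):
            compare_methods([r1, r2])
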
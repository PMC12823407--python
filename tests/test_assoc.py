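"""Simulated GWAS and burden summary statistics."""

import numpy as np
import pytest
import scipy.stats as st
from scipy.integrate import quad

from specdrift.assoc import (
    pvalues_and_hits,
    realized_heritability_experiment,
    sample_gwas_frequency,
    simulate_burden_panel,
    simulate_burden_test,
    simulate_gwas_estimates,
    subsample_summary,
)
from specdrift.effects import EffectMatrix, GeneModel


def _effects(values: np.ndarray) -> EffectMatrix:
    return EffectMatrix(np.asarray(values, dtype=float), f=0.33, p=0.5)


def _gene(gamma_sq, expected_lofs, gene_id="G0"):
    return GeneModel(
        gene_id=gene_id,
        gamma_sq=np.asarray(gamma_sq, dtype=float),
        expected_lofs=expected_lofs,
        chrom="chr1",
        start=0,
        end=1000,
    )


class TestSampleFrequency:
    def test_boundary_frequencies_exact(self):
        assert sample_gwas_frequency(0.0, seed=0) == 0.0
        assert sample_gwas_frequency(1.0, seed=0) == 1.0

    def test_binomial_variance(self, rng):
        f = 0.01
        n = 600_000
        draws = sample_gwas_frequency(np.full(100_000, f), n_alleles=n, seed=rng)
        assert draws.var() == pytest.approx(f * (1 - f) / n, rel=0.05)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sample_gwas_frequency(1.5)


class TestGwasEstimates:
    def test_noiseless_limit_recovers_squared_effects(self):
        sq = np.array([[1e-4, 4e-4], [9e-4, 1e-6]])
        summ = simulate_gwas_estimates(
            _effects(sq), np.array([0.3, 0.2]), n_eff=1e18, seed=0
        )
        assert np.allclose(summ.alpha_hat**2, sq, rtol=1e-4)

    def test_null_z2_is_chi_squared(self, rng):
        sq = np.full((100_000, 1), 1e-30)
        maf = np.full(100_000, 0.25)
        summ = pvalues_and_hits(
            simulate_gwas_estimates(_effects(sq), maf, n_eff=1e7, seed=rng)
        )
        assert summ.z2.mean() == pytest.approx(1.0, rel=0.02)
        # null calibration: fraction of P below q matches q to binomial error
        for q in [0.05, 0.01]:
            frac = (summ.log10p < np.log10(q)).mean()
            se = np.sqrt(q * (1 - q) / 100_000)
            assert abs(frac - q) < 3 * se

    def test_noncentral_mean(self, rng):
        sq = np.full((200_000, 1), 2e-6)
        maf = np.full(200_000, 0.1)
        summ = pvalues_and_hits(
            simulate_gwas_estimates(_effects(sq), maf, n_eff=1e7, seed=rng)
        )
        expected = 1.0 + 2 * 1e7 * 0.1 * 0.9 * 2e-6
        assert summ.z2.mean() == pytest.approx(expected, rel=0.02)

    def test_zero_maf_rejected(self):
        with pytest.raises(ValueError, match="infinite"):
            simulate_gwas_estimates(_effects([[1e-4]]), np.array([0.0]))


class TestPvalues:
    def test_chi2_examples(self):
        summ = simulate_gwas_estimates(
            _effects([[1e-30]]), np.array([0.5]), n_eff=1e7, seed=0
        )
        summ.alpha_hat = np.array([[0.0]])
        out = pvalues_and_hits(summ)
        assert out.log10p[0, 0] == pytest.approx(0.0)
        summ.alpha_hat = np.array([[np.sqrt(3.841459) * summ.se[0]]])
        out = pvalues_and_hits(summ)
        assert 10 ** out.log10p[0, 0] == pytest.approx(0.05, rel=1e-4)

    def test_matches_quadrature_of_chi2_density(self, rng):
        z2 = rng.uniform(0.1, 30.0, size=20)
        from specdrift.assoc import log10_sf_chi2

        for v in z2:
            tail, _ = quad(st.chi2(1).pdf, v, v + 250.0, epsabs=1e-300, epsrel=1e-12)
            assert 10 ** log10_sf_chi2(np.array([v]))[0] == pytest.approx(
                tail, rel=1e-8
            )


class TestBurden:
    def test_zero_sites_untestable(self, study_grid):
        g = _gene([1e-3], expected_lofs=0.0)
        assert simulate_burden_test(g, study_grid, seed=0) is None

    def test_length_drives_standard_error(self, study_grid, rng):
        # ten-fold more LoF opportunities -> ~sqrt(10) smaller SE
        g1 = _gene([1e-3, 1e-3], expected_lofs=2e-6, gene_id="short")
        g10 = _gene([1e-3, 1e-3], expected_lofs=2e-5, gene_id="long")
        se1, se10 = [], []
        for _ in range(300):
            r1 = simulate_burden_test(g1, study_grid, seed=rng)
            r10 = simulate_burden_test(g10, study_grid, seed=rng)
            if r1 is not None:
                se1.append(r1["se"])
            if r10 is not None:
                se10.append(r10["se"])
        # SE ~ 1/sqrt(p_lof) and p_lof ~ sum of site frequencies
        ratio = np.mean(se10) / np.mean(se1)
        assert ratio == pytest.approx(1 / np.sqrt(10), rel=0.25)

    def test_expected_z2_proportional_to_importance(self, study_grid, rng):
        # at (approximately) fixed aggregate frequency, mean z2 - 1 scales
        # with the squared burden effect
        gammas = np.array([1e-4, 4e-4, 1.6e-3])
        means = []
        for g2 in gammas:
            vals = []
            for _ in range(400):
                res = simulate_burden_test(
                    _gene([g2], expected_lofs=2e-5), study_grid, seed=rng
                )
                if res is not None:
                    vals.append(res["z2"][0])
            means.append(np.mean(vals) - 1.0)
        means = np.array(means)
        ratios = means / means[0]
        # noncentrality is proportional to gamma^2 while p_lof barely moves
        assert ratios[1] == pytest.approx(4.0, rel=0.35)
        assert ratios[2] == pytest.approx(16.0, rel=0.35)

    def test_panel_aggregation_reduces_frequency_noise(self, study_grid, rng):
        # burden aggregation averages drift: the aggregate carrier frequency
        # varies far less across replicate genes than single-site frequency
        sp = study_grid.spectra[study_grid.nearest_index(1e-3)]
        # single-site frequency draws, monomorphic draws included: a site is
        # usually monomorphic, which is exactly the stochasticity the burden
        # genotype averages away
        single = sp.sample_counts(300_000, rng) / sp.model.two_N
        genes = [
            _gene([1e-3], expected_lofs=100 * 1.25e-8, gene_id=f"g{i}")
            for i in range(400)
        ]
        panel = simulate_burden_panel(genes, study_grid, seed=rng)
        p_lof = panel.table["p_lof"].to_numpy()
        cv_single = single.std() / single.mean()
        cv_agg = p_lof.std() / p_lof.mean()
        assert cv_agg < cv_single / np.sqrt(50)

    def test_untestable_panel_genes_flagged_not_raised(self, study_grid):
        genes = [_gene([1e-3], expected_lofs=1.25e-8, gene_id=f"g{i}") for i in range(30)]
        panel = simulate_burden_panel(genes, study_grid, seed=5)
        assert len(panel.table) + len(panel.untestable) == 30


class TestSubsample:
    def test_full_sample_is_identity(self):
        a = np.array([0.1, -0.2])
        se = np.array([0.01, 0.02])
        a2, se2 = subsample_summary(a, se, n_sub=100, n_full=100, seed=0)
        assert np.array_equal(a2, a)
        assert np.allclose(se2, se)

    def test_conditional_variance_at_half_sample(self, rng):
        se = np.full(100_000, 0.03)
        a = np.zeros(100_000)
        a2, _ = subsample_summary(a, se, n_sub=50, n_full=100, seed=rng)
        # (N - n)/n = 1 at n = N/2, so Var(alpha_sub - alpha_full) = SE^2
        assert (a2 - a).var() == pytest.approx(0.03**2, rel=0.05)

    def test_se_scaling(self):
        _, se2 = subsample_summary(np.zeros(3), np.ones(3), n_sub=25, n_full=100, seed=0)
        assert np.allclose(se2**2, 4.0)
        _, se_lit = subsample_summary(
            np.zeros(3), np.ones(3), n_sub=25, n_full=100, seed=0, se_mode="literal"
        )
        assert np.allclose(se_lit, 4.0)

    def test_oversized_subsample_rejected(self):
        with pytest.raises(ValueError):
            subsample_summary(np.zeros(2), np.ones(2), n_sub=101, n_full=100)


class TestRealizedHeritability:
    def test_scaling_and_lost_variants(self, study_grid):
        tab = realized_heritability_experiment(
            study_grid, n_shet=50, variants_per_shet=10, seed=0
        )
        lost = tab.sample_freq == 0
        assert np.all(tab.scaled_realized_h2[lost] == 0)
        for arr in (tab.scaled_sq_effect, tab.scaled_realized_h2):
            assert arr.min() >= 0 and arr.max() == pytest.approx(1.0)
        assert (tab.scaled_sq_effect == 1).sum() >= 1
        assert (tab.scaled_realized_h2 == 1).sum() == 1

    def test_drift_decouples_ranking_among_important_variants(self, study_grid):
        # among the most trait-important variants, realized heritability is
        # nearly uncorrelated with importance: frequency luck dominates
        tab = realized_heritability_experiment(study_grid, seed=11)
        sel = (tab.scaled_sq_effect > 0.25) & (tab.sample_freq > 0)
        rho = st.spearmanr(
            tab.scaled_sq_effect[sel], tab.scaled_realized_h2[sel]
        ).statistic
        assert abs(rho) < 0.15
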
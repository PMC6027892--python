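import numpy as np
import pytest

from gblupgwas import (
    GenotypePanel,
    ModelSpec,
    VarianceComponents,
    backsolve_from_gblup,
    center_genotypes,
    fit_snpblup,
    marker_variance_from_h2,
)
from conftest import gls_blup_oracle, random_panel


def make_panel(dosages):
    dosages = np.asarray(dosages, dtype=float)
    m = dosages.shape[1]
    return GenotypePanel(
        dosages=dosages,
        marker_ids=[f"s{j}" for j in range(m)],
        chromosome=["1"] * m,
        position_bp=np.arange(1, m + 1),
    )


class TestGenotypePanel:
    def test_allele_freq_is_half_column_mean(self):
        panel = make_panel([[0, 2], [1, 2], [2, 2]])
        np.testing.assert_allclose(panel.allele_freq, [0.5, 1.0])
        assert panel.monomorphic.tolist() == [False, True]

    def test_rejects_non_dosage_values(self):
        with pytest.raises(ValueError, match="0, 1, 2"):
            make_panel([[0, 3], [1, 1]])

    def test_rejects_zero_based_positions(self):
        with pytest.raises(ValueError, match="1-based"):
            GenotypePanel(
                np.zeros((2, 1)), ["s0"], ["1"], [0]
            )

    def test_map_length_must_match(self):
        with pytest.raises(ValueError, match="map length"):
            GenotypePanel(np.zeros((2, 2)), ["s0"], ["1", "1"], [1, 2])


class TestCenterGenotypes:
    def test_all_zero_column_centers_to_zero_and_flags_monomorphic(self):
        panel = make_panel([[0, 1], [0, 2], [0, 1]])
        Z = center_genotypes(panel)
        np.testing.assert_array_equal(Z[:, 0], 0.0)
        assert panel.monomorphic[0]

    def test_symmetric_column_centers_to_plus_minus_one(self):
        panel = make_panel([[0], [1], [2]])
        np.testing.assert_allclose(center_genotypes(panel)[:, 0], [-1, 0, 1])

    def test_column_means_zero_and_missing_imputed_to_zero(self):
        rng = np.random.default_rng(5)
        dos = rng.integers(0, 3, size=(5, 3)).astype(float)
        dos[2, 1] = np.nan
        panel = make_panel(dos)
        Z = center_genotypes(panel)
        assert Z[2, 1] == 0.0
        # non-missing entries of each column average to zero
        for j in range(3):
            obs = ~np.isnan(panel.dosages[:, j])
            np.testing.assert_allclose(Z[obs, j].mean(), 0.0, atol=1e-12)

    def test_all_missing_column_errors_with_marker_name(self):
        dos = np.array([[0.0, np.nan], [1.0, np.nan]])
        panel = make_panel(dos)
        with pytest.raises(ValueError, match="s1"):
            center_genotypes(panel)


class TestFitSnpBlup:
    def test_zero_phenotype_gives_zero_solutions(self):
        rng = np.random.default_rng(1)
        panel = random_panel(rng, 8, 4)
        vc = VarianceComponents(0.2, 0.8)
        fit = fit_snpblup(panel, np.zeros(8), None, vc)
        np.testing.assert_allclose(fit.a_hat, 0.0, atol=1e-14)
        np.testing.assert_allclose(fit.b_hat, 0.0, atol=1e-14)

    def test_infinite_shrinkage_drives_effects_to_zero(self):
        rng = np.random.default_rng(2)
        panel = random_panel(rng, 10, 4)
        y = rng.normal(size=10)
        loose = fit_snpblup(panel, y, None, VarianceComponents(1.0, 1.0))
        tight = fit_snpblup(panel, y, None, VarianceComponents(1e-10, 1.0))
        assert np.linalg.norm(tight.a_hat) < 1e-6 * np.linalg.norm(loose.a_hat)

    def test_matches_dense_gls_blup_oracle(self):
        rng = np.random.default_rng(7)
        panel = random_panel(rng, 6, 3)
        y = rng.normal(size=6)
        vc = VarianceComponents(0.4, 0.6)
        fit = fit_snpblup(panel, y, ModelSpec(), vc)
        a_oracle, keep = gls_blup_oracle(panel, y, vc)
        np.testing.assert_allclose(fit.a_hat[keep], a_oracle, atol=1e-10)

    @pytest.mark.parametrize("seed", range(8))
    def test_mme_vs_gls_equivalence_random_instances(self, seed):
        """MME solve equals the V-matrix closed form on n<=30, m<=10 draws."""
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(8, 31))
        m = int(rng.integers(2, 11))
        panel = random_panel(rng, n, m)
        y = rng.normal(size=n)
        vc = VarianceComponents(float(rng.uniform(0.05, 1.0)), float(rng.uniform(0.2, 2.0)))
        fit = fit_snpblup(panel, y, ModelSpec(), vc)
        a_oracle, keep = gls_blup_oracle(panel, y, vc)
        np.testing.assert_allclose(fit.a_hat[keep], a_oracle, atol=1e-8)

    def test_solutions_satisfy_mixed_model_equations(self, small_fit):
        panel, y, vc, fit = small_fit
        keep = ~fit.dropped
        Z = center_genotypes(panel)[:, keep]
        W = np.ones((panel.n_individuals, 1))
        lam = vc.sigma2_e / vc.sigma2_a
        C = np.block([
            [W.T @ W, W.T @ Z],
            [Z.T @ W, Z.T @ Z + lam * np.eye(Z.shape[1])],
        ])
        rhs = np.concatenate([W.T @ y, Z.T @ y])
        sol = np.concatenate([fit.b_hat, fit.a_hat[keep]])
        assert np.linalg.norm(C @ sol - rhs) <= 1e-8 * np.linalg.norm(rhs)

    def test_posterior_variance_bounded_by_prior(self, small_fit):
        _, _, vc, fit = small_fit
        diag = np.diag(fit.caa_matrix)
        assert np.all(diag > 0.0)
        assert np.all(diag <= vc.sigma2_a + 1e-12)

    def test_caa_blocks_symmetric_positive_definite(self, small_fit):
        _, _, _, fit = small_fit
        block = fit.caa([0, 2, 4])
        np.testing.assert_allclose(block, block.T, atol=1e-12)
        assert np.linalg.eigvalsh(block).min() > 0.0

    def test_singular_fixed_block_raises(self):
        rng = np.random.default_rng(9)
        panel = random_panel(rng, 10, 3)
        spec = ModelSpec(covariates=np.ones((10, 1)))  # duplicates the intercept
        with pytest.raises(np.linalg.LinAlgError):
            fit_snpblup(panel, rng.normal(size=10), spec, VarianceComponents(0.2, 0.8))

    def test_nonpositive_variances_rejected(self):
        with pytest.raises(ValueError):
            VarianceComponents(0.0, 1.0)
        with pytest.raises(ValueError):
            VarianceComponents(1.0, -0.5)

    def test_phenotype_length_mismatch(self):
        rng = np.random.default_rng(4)
        panel = random_panel(rng, 6, 2)
        with pytest.raises(ValueError, match="individuals"):
            fit_snpblup(panel, np.zeros(5), None, VarianceComponents(0.1, 0.9))

    def test_dropped_monomorphic_markers_carry_prior_posterior(self):
        dos = np.array([[0.0, 0, 1], [0, 1, 2], [0, 2, 0], [0, 1, 1]])
        panel = make_panel(dos)
        vc = VarianceComponents(0.25, 0.75)
        fit = fit_snpblup(panel, np.array([0.1, -0.2, 0.3, 0.0]), None, vc)
        assert fit.dropped.tolist() == [True, False, False]
        assert fit.a_hat[0] == 0.0
        assert fit.caa([0])[0, 0] == vc.sigma2_a
        assert fit.caa([0, 1])[0, 1] == 0.0


class TestBacksolveFromGblup:
    def test_zero_breeding_values_give_zero_effects(self):
        rng = np.random.default_rng(21)
        panel = random_panel(rng, 4, 8)
        vc = VarianceComponents(0.3, 0.7)
        np.testing.assert_allclose(backsolve_from_gblup(np.zeros(4), panel, vc), 0.0)

    def test_round_trip_recovers_fitted_effects(self):
        # full-rank G requires at least as many markers as individuals
        rng = np.random.default_rng(22)
        panel = random_panel(rng, 5, 12)
        y = rng.normal(size=5)
        vc = VarianceComponents(0.3, 0.7)
        fit = fit_snpblup(panel, y, ModelSpec(include_intercept=False), vc)
        keep = ~fit.dropped
        Z = center_genotypes(panel)[:, keep]
        u = Z @ fit.a_hat[keep]
        recovered = backsolve_from_gblup(u, panel, vc)
        np.testing.assert_allclose(recovered[keep], fit.a_hat[keep], atol=1e-8)

    def test_hand_case_two_individuals_three_markers(self):
        # Z rows: (-1, 0.5, -0.5) and (1, -0.5, 0.5) after 2p-centering.
        # Column centering puts the ones vector in G's null space, so take
        # u in the range of G and compare with the explicit pseudo-inverse.
        panel = make_panel([[0, 2, 1], [2, 1, 2]])
        vc = VarianceComponents(0.5, 1.0)
        Z = center_genotypes(panel)
        G = Z @ Z.T * vc.sigma2_a
        u = np.array([0.3, -0.3])  # proportional to Z's first row pattern
        expected = vc.sigma2_a * Z.T @ np.linalg.pinv(G) @ u
        np.testing.assert_allclose(
            backsolve_from_gblup(u, panel, vc), expected, atol=1e-12
        )

    def test_breeding_values_outside_range_of_g_raise(self):
        rng = np.random.default_rng(23)
        panel = random_panel(rng, 12, 3)  # n >> m: G is rank deficient
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            backsolve_from_gblup(rng.normal(size=12), panel, VarianceComponents(0.2, 0.8))


class TestMarkerVarianceFromH2:
    def test_heritability_0_56_splits_unit_phenotypic_variance(self):
        vc = marker_variance_from_h2(0.56, 1.0, [0.3, 0.4])
        het = 2 * (0.3 * 0.7 + 0.4 * 0.6)
        assert vc.sigma2_e == pytest.approx(0.44)
        assert vc.sigma2_a == pytest.approx(0.56 / het)

    def test_single_marker_at_half_frequency(self):
        vc = marker_variance_from_h2(0.4, 2.0, [0.5])
        assert vc.sigma2_a == pytest.approx(2 * 0.4 * 2.0)  # sigma2_u / 0.5

    def test_algebraic_round_trip(self):
        rng = np.random.default_rng(31)
        p = rng.uniform(0.05, 0.5, size=10)
        vc = marker_variance_from_h2(0.3, 1.5, p)
        assert vc.sigma2_a * 2 * np.sum(p * (1 - p)) == pytest.approx(0.3 * 1.5)

    def test_monomorphic_only_panel_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            marker_variance_from_h2(0.5, 1.0, [0.0, 1.0])

    @pytest.mark.parametrize("h2", [0.0, 1.0, -0.1, 1.5])
    def test_h2_outside_open_interval_rejected(self, h2):
        with pytest.raises(ValueError):
            marker_variance_from_h2(h2, 1.0, [0.5])
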
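import numpy as np
import pytest

from xcmax4 import (
    CaseControlData,
    DegenerateStatisticError,
    SimulationConfig,
    XCI_R,
    XciCoding,
    component_statistics,
    correlation_matrix,
    fit_null,
    genotypic_score,
    pairwise_covariance,
    score_U,
    score_variance,
    simulate_dataset,
)
from xcmax4.data import CANONICAL_CODINGS


def dense_information_oracle(Gcols, fit, X):
    """Brute-force covariance of score functions: build the full joint
    information matrix of [G..., X] row by row in a Python loop and take the
    Schur complement of the covariate block."""
    n, p = X.shape
    m = len(Gcols)
    Z = np.column_stack(list(Gcols) + [X])
    info = np.zeros((m + p, m + p))
    for i in range(n):
        w = fit.p_hat[i] * (1 - fit.p_hat[i])
        info += w * np.outer(Z[i], Z[i])
    A = info[:m, :m]
    B = info[:m, m:]
    Dm = info[m:, m:]
    return A - B @ np.linalg.inv(Dm) @ B.T


class TestGenotypicScore:
    @pytest.mark.parametrize(
        "coding,sex,geno,expected",
        [
            (XCI_R, 1, 1, 1.0),  # heterozygous female under random XCI
            (XCI_R, 0, 1, 2.0),  # hemizygous male, dosage compensated
            (XciCoding(1, 1, "XCI-E"), 0, 1, 1.0),  # escape: male counts one copy
            (XciCoding(0, 2, "XCI-SN"), 1, 1, 0.0),
            (XciCoding(2, 2, "XCI-SR"), 1, 1, 2.0),
        ],
    )
    def test_table_of_scores(self, coding, sex, geno, expected):
        d = CaseControlData(
            genotype=[geno, 0],
            sex=[sex, 1],
            phenotype=[1, 0],
            covariates=np.ones((2, 1)),
        )
        assert genotypic_score(d, coding)[0] == expected

    def test_female_homozygotes_fixed(self, sim_small):
        for coding in CANONICAL_CODINGS:
            G = genotypic_score(sim_small, coding)
            fem = sim_small.sex == 1
            assert np.all(G[fem & (sim_small.genotype == 0)] == 0)
            assert np.all(G[fem & (sim_small.genotype == 2)] == 2)


class TestScoreU:
    def test_zero_score_vector(self, stage1, stage1_fit):
        assert score_U(np.zeros(stage1.n), stage1_fit, stage1.phenotype) == 0.0

    def test_constant_score_is_absorbed_by_intercept(self, stage1, stage1_fit):
        U = score_U(np.full(stage1.n, 3.0), stage1_fit, stage1.phenotype)
        assert U == pytest.approx(0.0, abs=1e-6)

    def test_matches_naive_loop(self, stage1, stage1_fit):
        G = genotypic_score(stage1, XCI_R)
        naive = sum(
            G[i] * (stage1.phenotype[i] - stage1_fit.p_hat[i]) for i in range(stage1.n)
        )
        assert score_U(G, stage1_fit, stage1.phenotype) == pytest.approx(naive, rel=1e-12)


class TestScoreVariance:
    def test_zero_vector(self, stage1, stage1_fit):
        assert score_variance(np.zeros(stage1.n), stage1_fit, stage1.covariates) == 0.0

    def test_covariate_column_fully_projected_out(self, stage1, stage1_fit):
        V = score_variance(stage1.covariates[:, 1], stage1_fit, stage1.covariates)
        assert V == pytest.approx(0.0, abs=1e-6)

    def test_matches_dense_oracle(self, stage1, stage1_fit):
        G = genotypic_score(stage1, XCI_R)
        V = score_variance(G, stage1_fit, stage1.covariates)
        Vo = dense_information_oracle([G], stage1_fit, stage1.covariates)[0, 0]
        assert V == pytest.approx(Vo, rel=1e-8)


class TestPairwiseCovariance:
    def test_identical_codings_give_correlation_one(self, stage1, stage1_fit):
        G = genotypic_score(stage1, XCI_R)
        C = pairwise_covariance(G, G, stage1_fit, stage1.covariates)
        assert C[0, 0] == pytest.approx(C[0, 1], rel=1e-12)
        assert C[0, 1] / np.sqrt(C[0, 0] * C[1, 1]) == pytest.approx(1.0, abs=1e-12)

    def test_matches_dense_oracle(self, stage1, stage1_fit):
        G1 = genotypic_score(stage1, CANONICAL_CODINGS[0])
        G2 = genotypic_score(stage1, CANONICAL_CODINGS[2])
        C = pairwise_covariance(G1, G2, stage1_fit, stage1.covariates)
        Co = dense_information_oracle([G1, G2], stage1_fit, stage1.covariates)
        assert np.allclose(C, Co, rtol=1e-8)

    def test_diagonal_consistent_with_score_variance(self, stage1, stage1_fit):
        for ca, cb in [(0, 1), (1, 3), (2, 3)]:
            G1 = genotypic_score(stage1, CANONICAL_CODINGS[ca])
            G2 = genotypic_score(stage1, CANONICAL_CODINGS[cb])
            C = pairwise_covariance(G1, G2, stage1_fit, stage1.covariates)
            assert C[0, 0] == pytest.approx(
                score_variance(G1, stage1_fit, stage1.covariates), rel=1e-10
            )
            assert C[1, 1] == pytest.approx(
                score_variance(G2, stage1_fit, stage1.covariates), rel=1e-10
            )


class TestComponentStatistics:
    def test_fixed_component_order(self, stage1, stage1_fit):
        comps = component_statistics(stage1, stage1_fit)
        assert [(c.coding.z1, c.coding.z2) for c in comps] == [(0, 2), (1, 2), (2, 2), (1, 1)]
        for c in comps:
            assert not c.degenerate
            assert c.W == pytest.approx(c.S**2, abs=1e-12)

    def test_max_component_exceeds_final_pvalue_tail(self, stage1, stage1_fit):
        from scipy.stats import norm

        from xcmax4 import run_xcmax4

        comps = component_statistics(stage1, stage1_fit)
        zmax = max(abs(c.S) for c in comps)
        res = run_xcmax4(stage1, fit=stage1_fit)
        assert 2 * norm.sf(zmax) < res.p_value

    def test_no_males_no_heterozygotes_collapses_components(self):
        rng = np.random.default_rng(3)
        n = 200
        geno = rng.choice([0, 2], size=n)
        pheno = rng.integers(0, 2, n)
        pheno[:2] = [0, 1]
        d = CaseControlData(geno, np.ones(n, dtype=int), pheno, np.ones((n, 1)))
        comps = component_statistics(d, fit_null(d))
        S = [c.S for c in comps]
        assert np.allclose(S, S[0], atol=1e-10)


class TestCorrelationMatrix:
    def test_stage1_sigma_properties(self, stage1, stage1_fit):
        sig = correlation_matrix(stage1, stage1_fit).sigma
        assert np.allclose(sig, sig.T)
        assert np.allclose(np.diag(sig), 1.0)
        off = sig[np.triu_indices(4, 1)]
        assert np.all(off > 0) and np.all(off <= 1)
        assert np.linalg.eigvalsh(sig).min() >= -1e-8

    def test_monomorphic_genotype_raises(self):
        rng = np.random.default_rng(3)
        n = 200
        sex = np.tile([0, 1], n // 2)
        pheno = rng.integers(0, 2, n)
        pheno[:2] = [0, 1]
        d = CaseControlData(
            np.zeros(n, dtype=int), sex, pheno,
            np.column_stack([np.ones(n), sex.astype(float)]),
        )
        with pytest.raises(DegenerateStatisticError):
            correlation_matrix(d, fit_null(d))

    def test_no_males_no_heterozygotes_gives_all_rho_one(self):
        rng = np.random.default_rng(3)
        n = 200
        geno = rng.choice([0, 2], size=n)
        pheno = rng.integers(0, 2, n)
        pheno[:2] = [0, 1]
        d = CaseControlData(geno, np.ones(n, dtype=int), pheno, np.ones((n, 1)))
        sig = correlation_matrix(d, fit_null(d)).sigma
        assert np.allclose(sig, 1.0, atol=1e-10)

    def test_sigma_matches_permutation_monte_carlo(self, stage1, stage1_fit,
                                                   permutation_scores):
        """Empirical correlations of the four standardized scores under
        phenotype permutation (null refitted per permutation, since
        estimating the nuisance coefficients is what induces the covariate
        projection) agree with the analytic Sigma."""
        sig = correlation_matrix(stage1, stage1_fit).sigma
        S = permutation_scores(stage1, n_perm=1500, seed=42)
        emp = np.corrcoef(S.T)
        # Monte-Carlo resolution at 1500 permutations; the tighter 0.02
        # check at 10^4 permutations lives in the acceptance suite
        assert np.max(np.abs(emp - sig)) < 0.05


class TestInvariances:
    def test_affine_covariate_invariance(self, stage1, stage1_fit):
        M = np.array([[1.0, -0.7], [0.0, 0.5]])
        d2 = CaseControlData(
            stage1.genotype, stage1.sex, stage1.phenotype, stage1.covariates @ M
        )
        f2 = fit_null(d2)
        c1 = component_statistics(stage1, stage1_fit)
        c2 = component_statistics(d2, f2)
        for a, b in zip(c1, c2):
            assert b.U == pytest.approx(a.U, rel=1e-8)
            assert b.V == pytest.approx(a.V, rel=1e-8)
            assert b.S == pytest.approx(a.S, rel=1e-8)

    def test_intercept_only_reduces_to_trend_chi_square(self):
        """With no covariates beyond the intercept, S^2 for a coding equals
        the classical trend chi-square computed directly from the genotype
        table."""
        data = simulate_dataset(
            SimulationConfig(n_cases=400, n_controls=400, beta=0.1116), seed=9
        )
        d0 = CaseControlData(
            data.genotype, data.sex, data.phenotype, np.ones((data.n, 1))
        )
        fit = fit_null(d0)
        G = genotypic_score(d0, XCI_R)
        comps = component_statistics(d0, fit)
        S12 = comps[1].S
        # algebraic trend statistic: U = sum G (D - dbar);
        # V = dbar(1-dbar) * (sum G^2 - (sum G)^2 / n)
        dbar = d0.phenotype.mean()
        U = float(G @ (d0.phenotype - dbar))
        V = dbar * (1 - dbar) * (np.sum(G**2) - np.sum(G) ** 2 / d0.n)
        assert S12**2 == pytest.approx(U**2 / V, rel=1e-10)
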
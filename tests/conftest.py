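import numpy as np
import pytest

from xcmax4 import (
    CaseControlData,
    SimulationConfig,
    expand_counts,
    fit_null,
    load_fixture,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def stage1():
    """Graves' disease stage I data expanded to individual level."""
    return expand_counts(load_fixture("chu_stage1"))


@pytest.fixture(scope="session")
def stage1_fit(stage1):
    return fit_null(stage1)


@pytest.fixture(scope="session")
def sim_small():
    """One mid-size simulated dataset under the null."""
    return simulate_dataset(SimulationConfig(n_cases=300, n_controls=300), seed=11)


@pytest.fixture(scope="session")
def permutation_scores():
    """Factory: matrix of the four standardized scores across phenotype
    permutations, refitting the null model for each permutation (the refit
    is what makes the permutation distribution reproduce the covariate-
    projected covariance)."""
    from xcmax4 import component_statistics

    def _run(data, n_perm, seed):
        rng = np.random.default_rng(seed)
        out = np.empty((n_perm, 4))
        base = data.phenotype.copy()
        for r in range(n_perm):
            perm = CaseControlData(
                data.genotype, data.sex, rng.permutation(base), data.covariates
            )
            comps = component_statistics(perm, fit_null(perm))
            out[r] = [c.S for c in comps]
        return out

    return _run


@pytest.fixture()
def balanced_intercept_only():
    """50 cases / 50 controls, intercept-only covariates, alternating genotypes."""
    rng = np.random.default_rng(5)
    n = 100
    sex = np.tile([0, 1], n // 2)
    geno = np.where(sex == 1, rng.integers(0, 3, n), rng.integers(0, 2, n))
    pheno = np.repeat([1, 0], n // 2)
    X = np.ones((n, 1))
    return CaseControlData(geno, sex, pheno, X)
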
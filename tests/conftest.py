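import numpy as np
import pytest

from gblupgwas import (
    GenotypePanel,
    ModelSpec,
    SnpBlupFit,
    VarianceComponents,
    center_genotypes,
    fit_snpblup,
)


def random_panel(rng, n, m, n_chrom=1, maf_range=(0.1, 0.5)):
    """Small random dosage panel drawn marker-by-marker from binomial(2, p)."""
    p = rng.uniform(*maf_range, size=m)
    dosages = rng.binomial(2, p, size=(n, m)).astype(float)
    chrom = np.repeat(
        [str(c + 1) for c in range(n_chrom)],
        [len(a) for a in np.array_split(np.arange(m), n_chrom)],
    )
    return GenotypePanel(
        dosages=dosages,
        marker_ids=[f"s{j}" for j in range(m)],
        chromosome=chrom,
        position_bp=(np.arange(m) + 1) * 1000,
        individual_ids=[f"i{k}" for k in range(n)],
    )


def gls_blup_oracle(panel, y, vc, intercept=True):
    """Direct dense GLS/BLUP closed form: a = sigma2_a Z'V^{-1}(y - W b_GLS)."""
    keep = ~panel.monomorphic
    Z = center_genotypes(panel)[:, keep]
    n = panel.n_individuals
    V = Z @ Z.T * vc.sigma2_a + np.eye(n) * vc.sigma2_e
    Vi = np.linalg.inv(V)
    if intercept:
        W = np.ones((n, 1))
        b = np.linalg.solve(W.T @ Vi @ W, W.T @ Vi @ y)
        resid = y - W @ b
    else:
        resid = y
    return vc.sigma2_a * Z.T @ Vi @ resid, keep


@pytest.fixture
def worked_example_single():
    """Fit summary from the published single-marker example:
    sigma2_a = 0.2, a_hat = 0.5, posterior sd = 0.05."""
    return SnpBlupFit.from_posterior([0.5], [[0.05**2]], sigma2_a=0.2)


@pytest.fixture
def worked_example_pair():
    """Fit summary from the published two-marker example:
    a_hat = (0.5, 0.4), Caa = [[0.05, -0.02], [-0.02, 0.08]], sigma2_a = 0.2."""
    return SnpBlupFit.from_posterior(
        [0.5, 0.4], [[0.05, -0.02], [-0.02, 0.08]], sigma2_a=0.2
    )


@pytest.fixture
def small_fit():
    """A genuinely fitted small model (n=20, m=5) plus its ingredients."""
    rng = np.random.default_rng(11)
    panel = random_panel(rng, 20, 5)
    y = rng.normal(size=20)
    vc = VarianceComponents(sigma2_a=0.3, sigma2_e=0.7)
    fit = fit_snpblup(panel, y, ModelSpec(), vc)
    return panel, y, vc, fit
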
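import numpy as np
import pytest

from cpgevo.simulate import SimulationConfig, simulate_bundle


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_bundle():
    """Fully realized (FASTA/GTF) two-organism bundle, 300 genes."""
    return simulate_bundle(SimulationConfig(seed=7, n_genes=300), sequences=True)


@pytest.fixture(scope="session")
def values_bundle():
    """Values-only bundle at analysis scale (5000 genes)."""
    return simulate_bundle(SimulationConfig(seed=11, n_genes=5000), sequences=False)


def mixture_draws(rng, n, w1=0.557, m1=0.120, s1=0.083, m2=0.631, s2=0.242):
    """Draws from the two-component promoter nCpG mixture, truncated at 0."""
    pick = rng.random(n) < w1
    out = np.where(pick, rng.normal(m1, s1, n), rng.normal(m2, s2, n))
    bad = out < 0
    while bad.any():
        k = int(bad.sum())
        pick = rng.random(k) < w1
        out[bad] = np.where(pick, rng.normal(m1, s1, k), rng.normal(m2, s2, k))
        bad = out < 0
    return out


def analytic_valley(w1=0.557, m1=0.120, s1=0.083, m2=0.631, s2=0.242):
    """Numerically located minimum of the mixture pdf between the component means.

    Truncation at 0 rescales the density by a constant above 0, so the
    valley location of the truncated and untruncated mixtures coincide.
    """
    from scipy import optimize, stats

    pdf = lambda x: w1 * stats.norm.pdf(x, m1, s1) + (1 - w1) * stats.norm.pdf(x, m2, s2)
    res = optimize.minimize_scalar(pdf, bounds=(m1, m2), method="bounded")
    return float(res.x)
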
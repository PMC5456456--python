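import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gwasmix.core_model import DesignContext, MixtureParams, posterior_mean, posterior_variance
from gwasmix.resampling import BinnedMoments

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture])
settings.load_profile("suite")


@pytest.fixture
def cd_like_theta() -> MixtureParams:
    """Sparse large effects over a weak replicating background."""
    return MixtureParams.from_sd(pi2=0.01, sigma0=1.0, sigma1=0.001, sigma2=0.05)


@pytest.fixture
def design() -> DesignContext:
    return DesignContext(n_eff=12_000, p_bar=0.275)


def random_triples(n: int, seed: int = 0):
    """Seeded random (theta, design, z) triples covering the parameter space."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        theta = MixtureParams(
            pi1=rng.uniform(0.5, 0.999),
            sigma0_sq=rng.uniform(0.8, 1.3),
            sigma1_sq=10 ** rng.uniform(-7, -4),
            sigma2_sq=10 ** rng.uniform(-4, -2),
        )
        d = DesignContext(n_eff=10 ** rng.uniform(3, 4.5), p_bar=rng.uniform(0.1, 0.5))
        z = rng.uniform(-8.0, 8.0)
        out.append((theta, d, z))
    return out


def analytic_moments(theta: MixtureParams, design: DesignContext, rho: float = 1.0,
                     c: float = 10.0, m_bins: int = 201,
                     counts: np.ndarray | None = None) -> BinnedMoments:
    """Noise-free binned moments exactly matching the model's own predictions."""
    from gwasmix.core_model import marginal_density

    edges = np.linspace(-c, c, m_bins + 1)
    mid = 0.5 * (edges[:-1] + edges[1:])
    mu = posterior_mean(mid, theta, design)
    sig2 = posterior_variance(mid, theta, design)
    mean = np.sqrt(rho) * mu
    var = rho * sig2 + theta.sigma0_sq
    if counts is None:
        counts = np.maximum(
            marginal_density(mid, theta, design) * 1e5 * (edges[1] - edges[0]), 1.0)
    return BinnedMoments(bin_edges=edges, count=counts, mean_rep=mean,
                         meansq_rep=var + mean**2, rho=rho,
                         n_train=design.n_eff, n_rep=rho * design.n_eff)
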
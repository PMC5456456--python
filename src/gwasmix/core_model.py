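"""Closed-form mathematics of the scale mixture of two normals model.

The model describes per-SNP GWAS z-scores through the measurement equation

    z_i = sqrt(n) * delta_i + omega_i,        omega_i ~ N(0, sigma0^2),

where the standardized effect size ``delta_i = sqrt(2 p_i (1 - p_i)) b_i / sigma_i``
is a random draw from a two-component scale mixture of centered normals,

    g(delta) = pi1 * N(0, sigma1^2) + pi2 * N(0, sigma1^2 + sigma2^2),

with ``pi2 = 1 - pi1`` the prior proportion of "large" (non-null) effects.
Substituting the mean effect-allele frequency ``p_bar`` for per-SNP
frequencies, the heterozygosity-sample-size scale ``X = 2 p_bar (1 - p_bar) n``
converts effect-size variances to z-score variances, giving the marginal

    f(z) = pi1 * N(z; 0, v1) + pi2 * N(z; 0, v2),
    v1 = sigma0^2 + X sigma1^2,   v2 = sigma0^2 + X (sigma1^2 + sigma2^2).

All downstream quantities — the local false discovery rate, posterior moments
of ``sqrt(n) delta``, and the finite-sample replication probability — follow in
closed form from conjugate-normal algebra and are implemented here.  Densities
and mixture weights are computed in log space throughout, so the formulas stay
accurate far into the tails (|z| > 8).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp, ndtr

_LOG_2PI = math.log(2.0 * math.pi)

__all__ = [
    "MixtureParams",
    "DesignContext",
    "ComponentDecomposition",
    "decompose",
    "marginal_density",
    "marginal_log_density",
    "local_fdr",
    "posterior_mean",
    "posterior_variance",
    "posterior_second_moment",
    "replication_probability",
    "tweedie_posterior",
]


@dataclass(frozen=True)
class MixtureParams:
    """Parameters theta = {pi1, sigma0^2, sigma1^2, sigma2^2} of the mixture.

    Attributes
    ----------
    pi1
        Weight of the small-effect component, in [0, 1].  The large-effect
        weight is ``pi2 = 1 - pi1``.
    sigma0_sq
        Variance of the z-score noise (theoretical value 1; may exceed 1
        under population substructure).
    sigma1_sq
        Prior variance of small effects on the delta scale (>= 0; 0 recovers
        the sharp-null two-groups model).
    sigma2_sq
        Incremental prior variance of large effects; the large-effect prior
        variance is ``sigma1_sq + sigma2_sq``.
    """

    pi1: float
    sigma0_sq: float
    sigma1_sq: float
    sigma2_sq: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi1 <= 1.0:
            raise ValueError(f"pi1 must be in [0, 1], got {self.pi1}")
        if not self.sigma0_sq > 0.0:
            raise ValueError(f"sigma0_sq must be > 0, got {self.sigma0_sq}")
        if self.sigma1_sq < 0.0 or self.sigma2_sq < 0.0:
            raise ValueError("sigma1_sq and sigma2_sq must be >= 0")
        for name in ("pi1", "sigma0_sq", "sigma1_sq", "sigma2_sq"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def pi2(self) -> float:
        return 1.0 - self.pi1

    @property
    def sigma0(self) -> float:
        return math.sqrt(self.sigma0_sq)

    def to_dict(self) -> dict:
        return {
            "pi1": self.pi1,
            "sigma0_sq": self.sigma0_sq,
            "sigma1_sq": self.sigma1_sq,
            "sigma2_sq": self.sigma2_sq,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureParams":
        return cls(
            pi1=float(d["pi1"]),
            sigma0_sq=float(d["sigma0_sq"]),
            sigma1_sq=float(d["sigma1_sq"]),
            sigma2_sq=float(d["sigma2_sq"]),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "MixtureParams":
        return cls.from_dict(json.loads(s))

    @classmethod
    def from_sd(cls, pi2: float, sigma0: float, sigma1: float, sigma2: float) -> "MixtureParams":
        """Build from the standard-deviation parametrization used in reports."""
        return cls(
            pi1=1.0 - pi2,
            sigma0_sq=sigma0 * sigma0,
            sigma1_sq=sigma1 * sigma1,
            sigma2_sq=sigma2 * sigma2,
        )


@dataclass(frozen=True)
class DesignContext:
    """Study design: effective sample size and mean effect-allele frequency.

    ``het_scale`` (X = 2 p_bar (1 - p_bar) n_eff) is the factor that converts
    an effect-size variance on the delta scale into a z-score variance.
    """

    n_eff: float
    p_bar: float

    def __post_init__(self) -> None:
        if not self.n_eff > 0:
            raise ValueError(f"n_eff must be > 0, got {self.n_eff}")
        if not 0.0 < self.p_bar <= 0.5:
            raise ValueError(f"p_bar must be in (0, 0.5], got {self.p_bar}")

    @property
    def het_scale(self) -> float:
        return 2.0 * self.p_bar * (1.0 - self.p_bar) * self.n_eff

    def scaled(self, multiple: float) -> "DesignContext":
        """Design with effective sample size scaled by ``multiple`` (p_bar fixed)."""
        return DesignContext(n_eff=self.n_eff * multiple, p_bar=self.p_bar)

    @classmethod
    def from_case_control(cls, n_cases: float, n_controls: float, p_bar: float) -> "DesignContext":
        # effective sample size of a balanced study with the same information
        n_eff = 4.0 / (1.0 / n_cases + 1.0 / n_controls)
        return cls(n_eff=n_eff, p_bar=p_bar)

    @classmethod
    def from_het_scale(cls, het_scale: float, p_bar: float = 0.25) -> "DesignContext":
        """Design with a directly specified heterozygosity-sample-size scale X."""
        return cls(n_eff=het_scale / (2.0 * p_bar * (1.0 - p_bar)), p_bar=p_bar)

    def to_dict(self) -> dict:
        return {"n_eff": self.n_eff, "p_bar": self.p_bar}


@dataclass(frozen=True)
class ComponentDecomposition:
    """Marginal (v_j) and signal (s_j = v_j - sigma0^2) variances per component."""

    marginal_var_small: float
    marginal_var_large: float
    signal_var_small: float
    signal_var_large: float

    @property
    def v(self) -> np.ndarray:
        return np.array([self.marginal_var_small, self.marginal_var_large])

    @property
    def s(self) -> np.ndarray:
        return np.array([self.signal_var_small, self.signal_var_large])


def decompose(theta: MixtureParams, design: DesignContext) -> ComponentDecomposition:
    X = design.het_scale
    s1 = X * theta.sigma1_sq
    s2 = X * (theta.sigma1_sq + theta.sigma2_sq)
    return ComponentDecomposition(
        marginal_var_small=theta.sigma0_sq + s1,
        marginal_var_large=theta.sigma0_sq + s2,
        signal_var_small=s1,
        signal_var_large=s2,
    )


def _check_z(z) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z-scores must be finite")
    return z


def _norm_logpdf(z: np.ndarray, var: float) -> np.ndarray:
    return -0.5 * (_LOG_2PI + math.log(var) + z * z / var)


def _component_logpdfs(z: np.ndarray, theta: MixtureParams, design: DesignContext):
    """Log of the weighted component densities log(pi_j * phi(z; 0, v_j))."""
    comp = decompose(theta, design)
    with np.errstate(divide="ignore"):
        lw = np.array([np.log(theta.pi1), np.log(theta.pi2)])
    lp = np.stack([_norm_logpdf(z, comp.marginal_var_small) + lw[0],
                   _norm_logpdf(z, comp.marginal_var_large) + lw[1]])
    return lp, comp


def marginal_log_density(z, theta: MixtureParams, design: DesignContext) -> np.ndarray:
    """log f(z) of the two-component marginal mixture of the z-scores."""
    z = _check_z(z)
    lp, _ = _component_logpdfs(z, theta, design)
    return logsumexp(lp, axis=0)


def marginal_density(z, theta: MixtureParams, design: DesignContext) -> np.ndarray:
    """Marginal density f(z) = pi1 N(z;0,v1) + pi2 N(z;0,v2)."""
    return np.exp(marginal_log_density(z, theta, design))


def local_fdr(z, theta: MixtureParams, design: DesignContext) -> np.ndarray:
    """Local false discovery rate: posterior probability of the small-effect class.

    fdr(z) = pi1 phi(z; 0, v1) / f(z), evaluated on the log scale so that the
    ratio never degenerates to 0/0 in the far tails.
    """
    z = _check_z(z)
    lp, _ = _component_logpdfs(z, theta, design)
    out = np.exp(lp[0] - logsumexp(lp, axis=0))
    return np.clip(out, 0.0, 1.0)


def _posterior_weights(z: np.ndarray, theta: MixtureParams, design: DesignContext):
    lp, comp = _component_logpdfs(z, theta, design)
    lse = logsumexp(lp, axis=0)
    w = np.exp(lp - lse)  # (2, ...) rows: fdr, tdr
    return w, comp


def posterior_mean(z, theta: MixtureParams, design: DesignContext) -> np.ndarray:
    """Posterior mean of sqrt(n)*delta given z.

    mu(z) = z * [ (s1/v1) fdr(z) + (s2/v2) tdr(z) ] — the conjugate-normal
    shrinkage factor of each component weighted by its posterior probability.
    """
    z = _check_z(z)
    w, comp = _posterior_weights(z, theta, design)
    shrink = (comp.s / comp.v)  # per-component s_j / v_j
    return z * (w[0] * shrink[0] + w[1] * shrink[1])


def _component_posterior_moments(z: np.ndarray, theta: MixtureParams, design: DesignContext):
    """Per-component posterior mean m_j = z s_j/v_j and variance c_j = sigma0^2 s_j/v_j."""
    w, comp = _posterior_weights(z, theta, design)
    ratio = comp.s / comp.v
    m = np.stack([z * ratio[0], z * ratio[1]])
    c = np.array([theta.sigma0_sq * ratio[0], theta.sigma0_sq * ratio[1]])
    return w, m, c


def posterior_variance(z, theta: MixtureParams, design: DesignContext) -> np.ndarray:
    """Posterior variance of sqrt(n)*delta given z (mixture-of-normals form).

    Var = sum_j w_j (m_j^2 + c_j) - (sum_j w_j m_j)^2 with w = (fdr, tdr).
    """
    z = _check_z(z)
    w, m, c = _component_posterior_moments(z, theta, design)
    second = w[0] * (m[0] ** 2 + c[0]) + w[1] * (m[1] ** 2 + c[1])
    first = w[0] * m[0] + w[1] * m[1]
    var = second - first ** 2
    if np.any(var < -1e-8 * (1.0 + np.abs(second))):
        raise FloatingPointError("negative posterior variance: formula inconsistency")
    return np.maximum(var, 0.0)


def posterior_second_moment(z, theta: MixtureParams, design: DesignContext,
                            component: str = "all") -> np.ndarray:
    """Posterior E{(sqrt(n) delta)^2 | z}, in full or restricted to large effects.

    ``component="all"`` returns mu^2 + Var; ``component="large_only"`` returns
    the large-effect (H=2) term tdr(z) * (m2^2 + c2) of the same sum, the
    quantity entering the large-effect variance-explained ratio.
    """
    z = _check_z(z)
    w, m, c = _component_posterior_moments(z, theta, design)
    if component == "all":
        return w[0] * (m[0] ** 2 + c[0]) + w[1] * (m[1] ** 2 + c[1])
    if component == "large_only":
        return w[1] * (m[1] ** 2 + c[1])
    raise ValueError(f"component must be 'all' or 'large_only', got {component!r}")


def replication_probability(z, theta: MixtureParams, design_train: DesignContext,
                            design_rep: DesignContext, c_alpha: float) -> np.ndarray:
    """Finite-sample probability that a SNP replicates in a de novo study.

    Replication means the replication z-score Z_r has the same sign as the
    training z and |Z_r| >= c_alpha.  Conditional on the component H=j and on
    z, Z_r is normal with mean sqrt(n_r/n) (s_j/v_j) |z| (towards the training
    sign) and variance sigma0^2 (1 + (n_r/n) s_j/v_j); the replication
    probability is the fdr/tdr-weighted mixture of the two normal tail masses.
    """
    if not c_alpha > 0:
        raise ValueError(f"c_alpha must be > 0, got {c_alpha}")
    if not math.isclose(design_train.p_bar, design_rep.p_bar, rel_tol=1e-12):
        raise ValueError("training and replication designs must share p_bar")
    z = _check_z(z)
    rho = design_rep.n_eff / design_train.n_eff
    w, comp = _posterior_weights(z, theta, design_train)
    ratio = comp.s / comp.v
    prob = np.zeros_like(z, dtype=float)
    for j in (0, 1):
        mean = np.sqrt(rho) * ratio[j] * np.abs(z)
        var = theta.sigma0_sq * (1.0 + rho * ratio[j])
        # P(N(mean, var) >= c_alpha), the mass beyond the threshold on the
        # training-sign side; the opposite tail is part of non-replication.
        prob = prob + w[j] * ndtr((mean - c_alpha) / math.sqrt(var))
    return np.clip(prob, 0.0, 1.0)


def tweedie_posterior(z, marginal_logdensity, sigma0_sq: float, step: float = 1e-3):
    """Posterior mean and variance of sqrt(n)*delta via Tweedie's formula.

    Given any twice-differentiable marginal log density log f, returns

        mean = z + sigma0^2 d/dz log f(z)
        var  = sigma0^2 (1 + sigma0^2 d^2/dz^2 log f(z))

    with five-point central stencils of width ``step`` (truncation O(step^4),
    round-off O(eps / step^2)); the default balances the two near 1e-8 for
    marginals with curvature of order one.  Very sharp marginals need a
    proportionally smaller step — the trade-off is the caller's, not hidden.
    """
    z = _check_z(z)
    h = step
    f = lambda x: np.asarray(marginal_logdensity(x), dtype=float)
    fp2, fp1, f0, fm1, fm2 = f(z + 2 * h), f(z + h), f(z), f(z - h), f(z - 2 * h)
    d1 = (-fp2 + 8.0 * fp1 - 8.0 * fm1 + fm2) / (12.0 * h)
    d2 = (-fp2 + 16.0 * fp1 - 30.0 * f0 + 16.0 * fm1 - fm2) / (12.0 * h * h)
    mean = z + sigma0_sq * d1
    var = sigma0_sq * (1.0 + sigma0_sq * d2)
    return mean, var
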
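"""Method-of-moments fitting of the mixture parameters.

The four parameters theta = {pi1, sigma0^2, sigma1^2, sigma2^2} are estimated
by minimizing quadratic estimating equations: the sum over bins (and over
split schemes) of squared discrepancies between the smoothed nonparametric
replication moments and the model's predicted replication mean and variance,

    Q(theta) = sum_scheme sum_m [ Zbar_r,m - sqrt(rho) mu(Z_m | theta) ]^2
                               + [ Var_r,m - rho sigma^2(Z_m | theta) - sigma0^2 ]^2,

where mu and sigma^2 are the posterior mean and variance of sqrt(n) delta at
the training sample size, rho = n_rep / n_train, and Z_m is the bin midpoint.
The replication mean scales with sqrt(rho) because Z_r = sqrt(n_r) delta + noise
= sqrt(rho) sqrt(n) delta + noise; its conditional variance is rho times the
posterior signal variance plus the noise floor sigma0^2.

Minimization is Nelder-Mead simplex in a transformed space (logit pi1, log
variances) so the box constraints hold by construction, with seeded
multi-start.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .core_model import DesignContext, MixtureParams, posterior_mean, posterior_variance
from .resampling import BinnedMoments

logger = logging.getLogger(__name__)

__all__ = ["FitResult", "objective_Q", "fit", "DEFAULT_INIT"]

DEFAULT_INIT = MixtureParams(pi1=0.99, sigma0_sq=1.0, sigma1_sq=1e-6, sigma2_sq=1e-3)

# when the fitted large-component excess X*sigma2^2 is below this fraction of
# the noise variance, the two mixture components are indistinguishable on the
# z scale and pi1 is not identified
_DEGENERATE_SEPARATION_FRAC = 1e-3


@dataclass
class FitResult:
    theta_hat: MixtureParams
    objective: float
    converged: bool
    n_restarts: int
    degenerate: bool = False
    rho_set: tuple = ()
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "theta_hat": self.theta_hat.to_dict(),
            "objective": self.objective,
            "converged": self.converged,
            "n_restarts": self.n_restarts,
            "degenerate": self.degenerate,
            "rho_set": list(self.rho_set),
            "provenance": self.provenance,
        }


def _as_moment_list(moments) -> list[BinnedMoments]:
    if isinstance(moments, BinnedMoments):
        return [moments]
    if isinstance(moments, Mapping):
        return list(moments.values())
    return list(moments)


def objective_Q(theta: MixtureParams, moments, design: DesignContext,
                mean_scale: str = "sqrt_rho", count_weight: bool = True) -> float:
    """Quadratic estimating-equation objective over one or more split schemes.

    ``design`` supplies the mean allele frequency; the effective sample size
    entering the posterior moments is each scheme's training size.
    ``mean_scale`` selects sqrt(rho) (measurement-model-consistent, default)
    or rho for the replication-mean scale factor.  By default bins are
    weighted proportionally to their training counts (the inverse-variance
    weighting for bin means, normalized so Q keeps the equal-weight scale);
    ``count_weight=False`` gives every populated bin equal weight, which lets
    the noisy near-empty tail bins dominate.
    """
    if mean_scale not in ("sqrt_rho", "rho"):
        raise ValueError(f"mean_scale must be 'sqrt_rho' or 'rho', got {mean_scale!r}")
    mlist = _as_moment_list(moments)
    total = 0.0
    any_bins = False
    for bm in mlist:
        mask = bm.populated & np.isfinite(bm.mean_rep)
        if not mask.any():
            continue
        any_bins = True
        zm = bm.bin_mid[mask]
        d_train = DesignContext(n_eff=bm.n_train, p_bar=design.p_bar)
        mu = posterior_mean(zm, theta, d_train)
        sig2 = posterior_variance(zm, theta, d_train)
        scale = math.sqrt(bm.rho) if mean_scale == "sqrt_rho" else bm.rho
        model_mean = scale * mu
        model_var = bm.rho * sig2 + theta.sigma0_sq
        resid_mean = bm.mean_rep[mask] - model_mean
        resid_var = bm.var_rep[mask] - model_var
        w = bm.count[mask] / bm.count[mask].sum() * mask.sum() if count_weight else 1.0
        total += float(np.sum(w * (resid_mean**2 + resid_var**2)))
    if not any_bins:
        raise ValueError("no populated bins: cannot evaluate objective")
    return total


def _pack(theta: MixtureParams) -> np.ndarray:
    p = min(max(theta.pi1, 1e-12), 1 - 1e-12)
    return np.array([
        logit(p),
        math.log(theta.sigma0_sq),
        math.log(max(theta.sigma1_sq, 1e-30)),
        math.log(max(theta.sigma2_sq, 1e-30)),
    ])


def _unpack(x: np.ndarray) -> MixtureParams:
    return MixtureParams(
        pi1=float(expit(x[0])),
        sigma0_sq=float(np.exp(np.clip(x[1], -60, 60))),
        sigma1_sq=float(np.exp(np.clip(x[2], -700, 60))),
        sigma2_sq=float(np.exp(np.clip(x[3], -700, 60))),
    )


def fit(moments, design: DesignContext, init: MixtureParams | None = None,
        n_restarts: int = 10, seed: int | None = 0, mean_scale: str = "sqrt_rho",
        count_weight: bool = True, xatol: float = 1e-8, fatol: float = 1e-12,
        maxiter: int = 4000) -> FitResult:
    """Estimate theta by seeded multi-start Nelder-Mead on the Q objective.

    Restart 0 starts from ``init`` (weakly informative default: nearly-null
    mixture); further restarts perturb the transformed coordinates with a
    seeded generator, so the fit is deterministic given (moments, seed, init).
    """
    mlist = _as_moment_list(moments)
    if not mlist:
        raise ValueError("need at least one BinnedMoments")
    init = init or DEFAULT_INIT
    x0 = _pack(init)
    rng = np.random.default_rng(seed)

    def loss(x: np.ndarray) -> float:
        try:
            return objective_Q(_unpack(x), mlist, design,
                               mean_scale=mean_scale, count_weight=count_weight)
        except FloatingPointError:
            return np.inf

    best = None
    n_converged = 0
    for r in range(max(n_restarts, 1)):
        start = x0 if r == 0 else x0 + rng.normal(scale=[2.0, 0.2, 3.0, 3.0])
        res = minimize(loss, start, method="Nelder-Mead",
                       options={"xatol": xatol, "fatol": fatol,
                                "maxiter": maxiter, "maxfev": maxiter})
        if res.success:
            n_converged += 1
        if best is None or res.fun < best.fun:
            best = res
        logger.debug("restart %d: Q=%.6g success=%s", r, res.fun, res.success)

    # polish the winner from its own solution
    res = minimize(loss, best.x, method="Nelder-Mead",
                   options={"xatol": xatol, "fatol": fatol,
                            "maxiter": maxiter, "maxfev": maxiter})
    if res.fun <= best.fun:
        best = res
    theta_hat = _unpack(best.x)

    # with X*sigma2^2 ~ 0 the two components coincide and pi1 is arbitrary
    x_train = 2.0 * design.p_bar * (1.0 - design.p_bar) * mlist[0].n_train
    degenerate = (x_train * theta_hat.sigma2_sq
                  < _DEGENERATE_SEPARATION_FRAC * theta_hat.sigma0_sq)
    if degenerate:
        logger.warning("sigma2^2 ~ 0 at the optimum: pi1 is not identified")
    if n_converged == 0:
        logger.warning("no Nelder-Mead restart met tolerance; returning best point")

    return FitResult(
        theta_hat=theta_hat,
        objective=float(best.fun),
        converged=n_converged > 0,
        n_restarts=max(n_restarts, 1),
        degenerate=degenerate,
        rho_set=tuple(bm.rho for bm in mlist),
        provenance={
            "seed": seed,
            "init": init.to_dict(),
            "mean_scale": mean_scale,
            "count_weight": count_weight,
            "n_bins": [int(bm.populated.sum()) for bm in mlist],
            "train_fractions": [bm.train_fraction for bm in mlist],
            "p_bar": design.p_bar,
        },
    )
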
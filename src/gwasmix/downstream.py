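"""Post-fit inference: thresholds, variance explained, genomic control, power.

Everything here consumes a fitted :class:`~gwasmix.core_model.MixtureParams`
plus a :class:`~gwasmix.core_model.DesignContext` and produces the quantities a
GWAS consortium actually reports: the |z| threshold matching a local-fdr
cutoff, the share of additive variance captured by significant SNPs, the
genomic inflation factor lambda_GC, projected power at larger sample sizes,
and model-vs-empirical replication comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import integrate, stats
from scipy.optimize import brentq

from .core_model import (
    DesignContext,
    MixtureParams,
    decompose,
    local_fdr,
    posterior_second_moment,
    replication_probability,
)

__all__ = [
    "PowerCurve",
    "ReplicationReport",
    "fdr_threshold",
    "variance_explained",
    "lambda_gc",
    "power_projection",
    "required_multiple",
    "replication_curves",
    "replication_report",
    "CHI2_1_MEDIAN",
]

# median of the chi-square distribution with 1 df, the lambda_GC denominator
CHI2_1_MEDIAN = float(stats.chi2.median(1))

GENOME_WIDE_P = 5e-8


def fdr_threshold(theta: MixtureParams, design: DesignContext, alpha: float):
    """|z| threshold at which the local fdr equals ``alpha``.

    Returns ``(z_threshold, two_sided_p)``.  The fdr is monotone
    non-increasing in |z| when sigma2^2 > 0, so bisection applies; if even
    fdr(0) <= alpha the threshold is 0 (every SNP passes).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if theta.sigma2_sq <= 0.0:
        raise ValueError("fdr threshold undefined when sigma2_sq == 0 (components coincide)")

    def g(z: float) -> float:
        return float(local_fdr(z, theta, design)) - alpha

    if g(0.0) <= 0.0:
        return 0.0, 1.0
    hi = 1.0
    while g(hi) > 0.0:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError(
                "fdr never reaches alpha: components insufficiently separated")
    z_thr = brentq(g, 0.0, hi, xtol=1e-12, rtol=1e-14)
    return float(z_thr), float(2.0 * stats.norm.sf(z_thr))


def variance_explained(z_scores, theta: MixtureParams, design: DesignContext,
                       z_threshold: float, component: str = "all") -> float:
    """Share of posterior additive variance held by SNPs with |z| >= threshold.

    Ratio of summed posterior second moments E{(sqrt(n) delta)^2 | z_i}
    (optionally the large-effect contribution only) over selected vs all SNPs.
    """
    z = np.asarray(z_scores, dtype=float)
    if z.size == 0:
        raise ValueError("z_scores must be non-empty")
    e2 = posterior_second_moment(z, theta, design, component=component)
    denom = float(e2.sum())
    if denom == 0.0:
        return 0.0
    sel = np.abs(z) >= z_threshold
    return float(e2[sel].sum() / denom)


def _model_median_abs_z(theta: MixtureParams, design: DesignContext) -> float:
    comp = decompose(theta, design)
    sd1, sd2 = math.sqrt(comp.marginal_var_small), math.sqrt(comp.marginal_var_large)

    def g(q: float) -> float:
        return (theta.pi1 * (2.0 * stats.norm.cdf(q / sd1) - 1.0)
                + theta.pi2 * (2.0 * stats.norm.cdf(q / sd2) - 1.0) - 0.5)

    hi = 10.0 * max(sd1, sd2)
    return brentq(g, 0.0, hi, xtol=1e-12, rtol=1e-14)


def lambda_gc(z_scores=None, theta: MixtureParams | None = None,
              design: DesignContext | None = None) -> float:
    """Genomic inflation factor median(z^2) / median(chi^2_1).

    Empirical mode when ``z_scores`` is given; model mode (median of the
    mixture marginal's z^2 by root finding on its cdf) when ``theta`` and
    ``design`` are given.
    """
    if z_scores is not None:
        z = np.asarray(z_scores, dtype=float)
        if z.size == 0:
            raise ValueError("z_scores must be non-empty")
        return float(np.median(z * z) / CHI2_1_MEDIAN)
    if theta is None or design is None:
        raise ValueError("provide either z_scores or (theta, design)")
    q = _model_median_abs_z(theta, design)
    return q * q / CHI2_1_MEDIAN


@dataclass
class PowerCurve:
    """Projected share of large-effect variance discovered vs sample size."""

    multiples: np.ndarray
    proportion: np.ndarray
    p_threshold: float
    gc_mode: str
    lambda_used: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.multiples = np.asarray(self.multiples, dtype=float)
        self.proportion = np.asarray(self.proportion, dtype=float)


def _discovered_large_fraction(theta: MixtureParams, design: DesignContext,
                               z_c: float) -> float:
    """E{(sqrt(n) delta)^2 1[|Z| >= z_c] | H=2} / E{(sqrt(n) delta)^2 | H=2}.

    Joint model: given H=2, sqrt(n) delta ~ N(0, s2) and Z | delta ~
    N(sqrt(n) delta, sigma0^2); integrate the detection probability against
    the delta prior by adaptive quadrature.
    """
    comp = decompose(theta, design)
    s2 = comp.signal_var_large
    if s2 <= 0.0:
        return 0.0
    sd = math.sqrt(s2)
    s0 = math.sqrt(theta.sigma0_sq)

    def integrand(d: float) -> float:
        p_detect = stats.norm.sf(z_c, loc=d, scale=s0) + stats.norm.cdf(-z_c, loc=d, scale=s0)
        return d * d * p_detect * stats.norm.pdf(d, scale=sd)

    val, err = integrate.quad(integrand, -12.0 * sd, 12.0 * sd, limit=400)
    if not np.isfinite(val) or err > 1e-6 * max(abs(val), s2):
        raise RuntimeError(f"power quadrature did not converge (value {val}, abserr {err})")
    return min(val / s2, 1.0)


def power_projection(theta: MixtureParams, design: DesignContext,
                     multiples: Sequence[float], p_threshold: float = GENOME_WIDE_P,
                     gc_mode: str = "fixed") -> PowerCurve:
    """Projected large-effect discovery power at multiples of the sample size.

    For each multiple m the heterozygosity scale X is stretched to m*X and the
    genome-wide threshold ``p_threshold`` is mapped to an effective z cutoff
    z_c = Phi^{-1}(1 - p/2) * sqrt(lambda_GC).  ``gc_mode``:

    - ``"fixed"`` (default): lambda_GC from the model marginal at the current
      sample size, applied unchanged at every multiple — the standard genomic
      control of the data in hand;
    - ``"per_multiple"``: lambda_GC recomputed from the model at each projected
      size (power then saturates, since inflation grows with n);
    - ``"none"``: no genomic control.
    """
    if gc_mode not in ("fixed", "per_multiple", "none"):
        raise ValueError(f"unknown gc_mode {gc_mode!r}")
    multiples = np.asarray(multiples, dtype=float)
    if np.any(multiples <= 0):
        raise ValueError("multiples must be > 0")
    z_nominal = float(stats.norm.isf(p_threshold / 2.0))
    lam_fixed = lambda_gc(theta=theta, design=design) if gc_mode == "fixed" else 1.0
    props, lams = [], []
    for m in multiples:
        d_m = design.scaled(m)
        if gc_mode == "per_multiple":
            lam = lambda_gc(theta=theta, design=d_m)
        elif gc_mode == "fixed":
            lam = lam_fixed
        else:
            lam = 1.0
        z_c = z_nominal * math.sqrt(lam)
        props.append(_discovered_large_fraction(theta, d_m, z_c))
        lams.append(lam)
    return PowerCurve(multiples=multiples, proportion=np.asarray(props),
                      p_threshold=p_threshold, gc_mode=gc_mode,
                      lambda_used=np.asarray(lams))


def required_multiple(theta: MixtureParams, design: DesignContext,
                      target: float = 0.90, p_threshold: float = GENOME_WIDE_P,
                      gc_mode: str = "fixed", max_doublings: int = 12) -> float:
    """Smallest power-of-two sample-size multiple reaching the target power.

    Walks the doubling grid 1, 2, 4, ... (the usual x-axis of sample-size
    projections) and returns the first multiple whose projected large-effect
    variance share meets ``target``.
    """
    if not 0.0 < target < 1.0:
        raise ValueError("target must be in (0, 1)")
    grid = 2.0 ** np.arange(max_doublings + 1)
    curve = power_projection(theta, design, grid, p_threshold=p_threshold, gc_mode=gc_mode)
    hit = np.nonzero(curve.proportion >= target)[0]
    if hit.size == 0:
        raise RuntimeError(
            f"target power {target} not reached within {grid[-1]:.0f}x "
            f"(max projected {curve.proportion.max():.3f}); inflation growth "
            "may bound the attainable power")
    return float(grid[hit[0]])


def replication_curves(theta: MixtureParams, design_train: DesignContext,
                       design_rep: DesignContext, z_grid, c_alpha: float,
                       z_train=None, z_rep=None, n_curve_bins: int = 41):
    """Model-predicted and (optionally) empirical replication-rate curves.

    The model curve evaluates the finite-sample replication probability on
    ``z_grid``.  If paired training/replication z-score vectors are supplied,
    the empirical curve is the per-bin proportion of SNPs whose replication
    score passes (same sign, one-sided level matching ``c_alpha``).
    Returns ``(model_curve, empirical)`` where ``empirical`` is ``None`` or a
    dict with bin mids, counts, and observed proportions.
    """
    z_grid = np.asarray(z_grid, dtype=float)
    model_curve = replication_probability(z_grid, theta, design_train, design_rep, c_alpha)
    empirical = None
    if z_train is not None and z_rep is not None:
        z_train = np.asarray(z_train, dtype=float)
        z_rep = np.asarray(z_rep, dtype=float)
        success = (np.sign(z_rep) == np.sign(z_train)) & (np.abs(z_rep) >= c_alpha)
        lo, hi = z_grid.min(), z_grid.max()
        edges = np.linspace(lo, hi, n_curve_bins + 1)
        idx = np.clip(np.digitize(z_train, edges) - 1, 0, n_curve_bins - 1)
        inside = (z_train >= lo) & (z_train <= hi)
        counts = np.bincount(idx[inside], minlength=n_curve_bins).astype(float)
        hits = np.bincount(idx[inside], weights=success[inside].astype(float),
                           minlength=n_curve_bins)
        with np.errstate(invalid="ignore"):
            prop = np.where(counts > 0, hits / counts, np.nan)
        empirical = {"bin_mid": 0.5 * (edges[:-1] + edges[1:]),
                     "count": counts, "proportion": prop}
    return model_curve, empirical


@dataclass
class ReplicationReport:
    """Observed vs predicted replication per local-fdr bin."""

    fdr_edges: np.ndarray
    count: np.ndarray
    observed_proportion: np.ndarray   # NaN where the bin is empty
    predicted_probability: np.ndarray


def replication_report(z_discovery, z_replication, theta: MixtureParams,
                       design_disc: DesignContext, design_rep: DesignContext,
                       fdr_bins=None, one_sided_p: float = 0.05) -> ReplicationReport:
    """Independent-split replication analysis binned by discovery local fdr.

    Replication is defined as (i) discovery and replication z-scores share a
    sign and (ii) the replication one-sided p-value is <= ``one_sided_p``.
    Each fdr bin reports its SNP count, the observed replication proportion
    (NaN when the bin is empty), and the mean model-predicted finite-sample
    replication probability.
    """
    z_d = np.asarray(z_discovery, dtype=float)
    z_r = np.asarray(z_replication, dtype=float)
    if z_d.shape != z_r.shape:
        raise ValueError("discovery and replication z-score vectors must align")
    edges = np.arange(0.0, 1.0 + 1e-9, 0.10) if fdr_bins is None else np.asarray(fdr_bins, float)
    c_alpha = float(stats.norm.isf(one_sided_p))
    fdr = local_fdr(z_d, theta, design_disc)
    pred = replication_probability(z_d, theta, design_disc, design_rep, c_alpha)
    success = (np.sign(z_r) == np.sign(z_d)) & (np.abs(z_r) >= c_alpha)
    nb = len(edges) - 1
    idx = np.clip(np.digitize(fdr, edges) - 1, 0, nb - 1)  # last bin closed
    count = np.bincount(idx, minlength=nb).astype(float)
    hits = np.bincount(idx, weights=success.astype(float), minlength=nb)
    pred_sum = np.bincount(idx, weights=pred, minlength=nb)
    with np.errstate(invalid="ignore"):
        observed = np.where(count > 0, hits / count, np.nan)
        predicted = np.where(count > 0, pred_sum / count, np.nan)
    return ReplicationReport(fdr_edges=edges, count=count,
                             observed_proportion=observed,
                             predicted_probability=predicted)
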
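"""Seeded generators for sub-study z-score panels and LD-block simulations.

The fast path draws z-scores directly from the measurement model — per-allele
standardized effects from the two-component scale mixture, multiplied by the
SNP's heterozygosity and the sub-study's sqrt(sample size), plus unit-scale
noise — which is exactly the statistical structure the fitting procedure
assumes.  Violation modes perturb per-study allele frequencies or effects to
emulate departures from the meta-analysis exchangeability assumptions.  A
separate LD-block simulator produces massively-univariate z-scores whose
expectations are LD-weighted sums of causal effects, demonstrating how LD
"blurs" effect-size distributions and inflates the apparent non-null
proportion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.linalg import cholesky
from scipy.special import expit, logit

from .core_model import MixtureParams
from .resampling import SubstudyPanel

__all__ = [
    "GenerativeConfig",
    "LDBlockConfig",
    "LDBlockSim",
    "draw_effects",
    "make_substudy_panel",
    "simulate_panel",
    "simulate_ld_blocks",
    "ld_prune",
    "supplementary_grid",
]

# parameter grid of the simulation studies; the printed mixture-proportion
# values (1-5%) are read as the LARGE-effect share by default, with the
# literal small-effect reading available via proportion_is_large=False
GRID_PROPORTIONS = (0.01, 0.02, 0.05)
GRID_SIGMA1 = (0.0, 0.001, 0.01)
GRID_SIGMA2 = (0.01, 0.05, 0.1)


def supplementary_grid(sigma0: float = 1.0, proportion_is_large: bool = True):
    """Full factorial grid of generative mixture settings used in simulations."""
    out = []
    for p in GRID_PROPORTIONS:
        for s1 in GRID_SIGMA1:
            for s2 in GRID_SIGMA2:
                pi2 = p if proportion_is_large else 1.0 - p
                out.append(MixtureParams.from_sd(pi2=pi2, sigma0=sigma0,
                                                 sigma1=s1, sigma2=s2))
    return out


@dataclass(frozen=True)
class GenerativeConfig:
    """Study conditions for the direct z-score generator.

    Defaults emulate a Crohn's-disease-scale meta-analysis: 8 equal
    sub-studies totalling ~24,000 effective samples, allele frequencies
    uniform on (0.05, 0.5).
    """

    theta_true: MixtureParams
    n_snps: int = 100_000
    n_k: tuple = (3000,) * 8
    maf_low: float = 0.05
    maf_high: float = 0.5
    violation_mode: str = "none"  # none | maf_jitter | effect_heterogeneity
    violation_scale: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if any(n <= 0 for n in self.n_k):
            raise ValueError("all sub-study sizes must be > 0")
        if not 0.0 < self.maf_low < self.maf_high <= 0.5:
            raise ValueError("need 0 < maf_low < maf_high <= 0.5")
        if self.violation_mode not in ("none", "maf_jitter", "effect_heterogeneity"):
            raise ValueError(f"unknown violation_mode {self.violation_mode!r}")

    def with_seed(self, seed: int) -> "GenerativeConfig":
        return replace(self, seed=seed)


def draw_effects(theta_true: MixtureParams, n_snps: int, rng: np.random.Generator):
    """Per-allele standardized effects from the two-component scale mixture.

    Returns ``(effects, labels)`` with labels 1 (small, N(0, sigma1^2)) or
    2 (large, N(0, sigma1^2 + sigma2^2)).  The SNP-specific heterozygosity
    factor sqrt(2 p (1-p)) is applied later by the panel builder.
    """
    labels = 1 + (rng.random(n_snps) < theta_true.pi2).astype(int)
    sd = np.where(labels == 2,
                  math.sqrt(theta_true.sigma1_sq + theta_true.sigma2_sq),
                  math.sqrt(theta_true.sigma1_sq))
    return rng.standard_normal(n_snps) * sd, labels


def make_substudy_panel(effects: np.ndarray, config: GenerativeConfig,
                        rng: np.random.Generator, allele_freq: np.ndarray | None = None):
    """Sub-study z-score panel from drawn effects under the measurement model.

    z_{k,i} = sqrt(2 p_i (1 - p_i) n_k) * effect_i + omega_{k,i} with
    omega ~ N(0, sigma0^2).  ``maf_jitter`` replaces p_i by per-study
    logit-normal perturbations p_{k,i}; ``effect_heterogeneity`` multiplies
    effects by per-study lognormal-free factors (1 + scale * eps).
    Returns ``(panel, delta)`` where delta = sqrt(2 p (1-p)) * effect is the
    per-SNP standardized effect size entering z = sqrt(n) delta + noise.
    """
    effects = np.asarray(effects, dtype=float)
    n = effects.shape[0]
    if allele_freq is None:
        allele_freq = rng.uniform(config.maf_low, config.maf_high, size=n)
    het = 2.0 * allele_freq * (1.0 - allele_freq)
    delta = np.sqrt(het) * effects
    sigma0 = config.theta_true.sigma0
    n_k = np.asarray(config.n_k, dtype=float)
    z = np.empty((n, len(n_k)))
    for k, nk in enumerate(n_k):
        eff_k = effects
        het_k = het
        if config.violation_mode == "maf_jitter":
            p_k = expit(logit(allele_freq) + config.violation_scale * rng.standard_normal(n))
            het_k = 2.0 * p_k * (1.0 - p_k)
        elif config.violation_mode == "effect_heterogeneity":
            eff_k = effects * (1.0 + config.violation_scale * rng.standard_normal(n))
        z[:, k] = np.sqrt(nk * het_k) * eff_k + sigma0 * rng.standard_normal(n)
    panel = SubstudyPanel(
        snp_ids=np.array([f"snp{i}" for i in range(n)]),
        z=z, n_k=n_k, allele_freq=allele_freq)
    return panel, delta


def simulate_panel(config: GenerativeConfig):
    """End-to-end draw: effects, labels, allele frequencies, z-score panel.

    Returns ``(panel, truth)`` where truth holds the per-SNP standardized
    effects (``delta``), raw mixture draws (``effect``), component labels and
    the seed, for downstream oracle checks.
    """
    rng = np.random.default_rng(config.seed)
    effects, labels = draw_effects(config.theta_true, config.n_snps, rng)
    panel, delta = make_substudy_panel(effects, config, rng)
    truth = {"delta": delta, "effect": effects, "labels": labels,
             "allele_freq": panel.allele_freq, "seed": config.seed}
    return panel, truth


@dataclass(frozen=True)
class LDBlockConfig:
    """Worst-case LD layout: one causal SNP centred in each correlated block.

    ``n_null_independent`` adds unlinked null SNPs outside the blocks,
    mirroring the real-genome situation where causal effects sit in regions
    of higher-than-average total LD; it is this heterogeneity that makes
    random pruning remove blurred-effect carriers preferentially.
    """

    n_blocks: int = 100
    block_size: int = 51
    ar1_rho: float = 0.9
    causal_sd: float = 0.05     # per-allele effect sd of the causal SNPs
    n_k: tuple = (6000,) * 4
    p_bar: float = 0.25
    sigma0_sq: float = 1.0
    n_null_independent: int = 5100
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.ar1_rho < 1.0:
            raise ValueError("ar1_rho must be in [0, 1)")
        if self.block_size < 1 or self.n_blocks < 1:
            raise ValueError("block_size and n_blocks must be >= 1")
        if self.n_null_independent < 0:
            raise ValueError("n_null_independent must be >= 0")


@dataclass
class LDBlockSim:
    """Output of the LD-block simulator."""

    panel: SubstudyPanel
    causal_effects: np.ndarray   # per-allele scale, non-zero at block centres
    blurred_effects: np.ndarray  # R @ causal: expectation of univariate estimates
    r2_pairs: list               # (i, j, r2) within-block pairs
    causal_proportion: float
    config: LDBlockConfig


def _block_correlation(block_size: int, ar1_rho: float) -> np.ndarray:
    idx = np.arange(block_size)
    r = ar1_rho ** np.abs(idx[:, None] - idx[None, :])
    return r


def simulate_ld_blocks(config: LDBlockConfig) -> LDBlockSim:
    """Univariate GWAS z-scores over AR(1)-correlated LD blocks.

    In each block only the centre SNP is causal; every univariate regression
    estimate has expectation equal to the LD-weighted sum of causal effects,
    E{b_hat} = R b, and the noise shares the same correlation R.  Sub-study
    z-scores are built as z_k = sqrt(2 p (1-p) n_k) R b + chol(R) eta_k so the
    panel can be fed straight into the resampling/fitting pipeline to measure
    the apparent (blurred) non-null proportion.
    """
    rng = np.random.default_rng(config.seed)
    B, nb = config.block_size, config.n_blocks
    R = _block_correlation(B, config.ar1_rho)
    try:
        L = cholesky(R, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - AR(1) is PD
        raise ValueError("block correlation matrix is not positive definite") from exc
    n_block_snps = B * nb
    n_extra = config.n_null_independent
    n_snps = n_block_snps + n_extra
    centre = B // 2
    causal_blk = np.zeros((nb, B))
    causal_blk[:, centre] = rng.standard_normal(nb) * config.causal_sd
    blurred_blk = causal_blk @ R.T  # per block: R @ b (R symmetric)
    causal = np.concatenate([causal_blk.ravel(), np.zeros(n_extra)])
    blurred = np.concatenate([blurred_blk.ravel(), np.zeros(n_extra)])
    het = 2.0 * config.p_bar * (1.0 - config.p_bar)
    sigma0 = math.sqrt(config.sigma0_sq)
    n_k = np.asarray(config.n_k, dtype=float)
    z = np.empty((n_snps, len(n_k)))
    for k, nk in enumerate(n_k):
        eta = rng.standard_normal((nb, B)) @ L.T * sigma0
        eta_extra = rng.standard_normal(n_extra) * sigma0
        z[:, k] = np.sqrt(het * nk) * blurred + np.concatenate([eta.ravel(), eta_extra])
    r2 = R * R
    pairs = []
    for b in range(nb):
        off = b * B
        for i in range(B):
            for j in range(i + 1, B):
                if r2[i, j] > 1e-3:
                    pairs.append((off + i, off + j, float(r2[i, j])))
    ids = [f"blk{b}_snp{i}" for b in range(nb) for i in range(B)]
    ids += [f"null{i}" for i in range(n_extra)]
    panel = SubstudyPanel(snp_ids=np.array(ids), z=z, n_k=n_k,
                          allele_freq=np.full(n_snps, config.p_bar))
    return LDBlockSim(panel=panel, causal_effects=causal,
                      blurred_effects=blurred, r2_pairs=pairs,
                      causal_proportion=nb / n_snps, config=config)


def ld_prune(pairwise_r2, threshold: float = 0.20, seed: int | None = 0,
             n_snps: int | None = None) -> np.ndarray:
    """Random-order greedy pruning to pairwise r^2 <= threshold.

    ``pairwise_r2`` is either a dense symmetric matrix or an iterable of
    ``(i, j, r2)`` pairs (pairs omitted are taken as r^2 = 0, i.e. sparse
    input lists only correlated pairs).  SNPs are visited in a seeded random
    order; a SNP is kept iff its r^2 with every previously kept SNP is within
    the threshold.  Returns the sorted kept indices.
    """
    rng = np.random.default_rng(seed)
    if isinstance(pairwise_r2, np.ndarray) and pairwise_r2.ndim == 2:
        r2 = pairwise_r2
        if r2.shape[0] != r2.shape[1]:
            raise ValueError("r2 matrix must be square")
        if not np.allclose(r2, r2.T, atol=1e-10):
            raise ValueError("r2 matrix must be symmetric")
        n = r2.shape[0]
        order = rng.permutation(n)
        kept: list[int] = []
        for i in order:
            if all(r2[i, j] <= threshold for j in kept):
                kept.append(int(i))
        return np.sort(np.array(kept, dtype=int))
    # sparse pair list
    pairs = list(pairwise_r2)
    if n_snps is None:
        n_snps = 1 + max((max(i, j) for i, j, _ in pairs), default=-1)
    heavy: dict[int, set[int]] = {}
    for i, j, r in pairs:
        if r > threshold:
            heavy.setdefault(int(i), set()).add(int(j))
            heavy.setdefault(int(j), set()).add(int(i))
    order = rng.permutation(n_snps)
    kept_set: set[int] = set()
    kept = []
    for i in order:
        i = int(i)
        if heavy.get(i, set()).isdisjoint(kept_set):
            kept_set.add(i)
            kept.append(i)
    return np.sort(np.array(kept, dtype=int))
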
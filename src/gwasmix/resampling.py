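"""Resampling of meta-analysis sub-studies into discovery/replication splits.

Large GWAS meta-analyses distribute per-sub-study z-scores.  Randomly (or
exhaustively) partitioning the K sub-studies into disjoint training and
replication sets, combining each side with sample-size weights, binning the
training z-scores and averaging the replication z-scores per bin yields
nonparametric, winner's-curse-free estimates of the conditional replication
moments E{Z_r | Z in bin} and E{Z_r^2 | Z in bin}.  Averaged over many
partitions these smoothed moments are the data the mixture model is fitted to.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SubstudyPanel",
    "PartitionScheme",
    "BinnedMoments",
    "meta_combine",
    "partition",
    "bin_replication",
    "smooth_moments",
    "resample_moments",
]


@dataclass
class SubstudyPanel:
    """N x K panel of per-sub-study z-scores with effective sample sizes."""

    snp_ids: np.ndarray
    z: np.ndarray
    n_k: np.ndarray
    allele_freq: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids)
        self.z = np.asarray(self.z, dtype=float)
        self.n_k = np.asarray(self.n_k, dtype=float)
        if self.z.ndim != 2:
            raise ValueError("z must be an N x K matrix")
        n, k = self.z.shape
        if len(self.snp_ids) != n:
            raise ValueError("snp_ids length must match z rows")
        if len(self.n_k) != k:
            raise ValueError("n_k length must match z columns")
        if np.any(~np.isfinite(self.z)):
            raise ValueError("panel contains missing or non-finite z-scores")
        if np.any(self.n_k <= 0):
            raise ValueError("all effective sample sizes must be > 0")
        if self.allele_freq is not None:
            self.allele_freq = np.asarray(self.allele_freq, dtype=float)
            if len(self.allele_freq) != n:
                raise ValueError("allele_freq length must match z rows")

    @property
    def n_snps(self) -> int:
        return self.z.shape[0]

    @property
    def n_studies(self) -> int:
        return self.z.shape[1]

    @property
    def p_bar(self) -> float | None:
        """Mean effect-allele frequency folded onto (0, 0.5]."""
        if self.allele_freq is None:
            return None
        p = np.minimum(self.allele_freq, 1.0 - self.allele_freq)
        return float(np.mean(p))


@dataclass(frozen=True)
class PartitionScheme:
    """How to split K sub-studies into training and replication sets."""

    n_iterations: int = 100
    train_fraction: float = 0.5
    mode: str = "random"  # or "exhaustive"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.mode not in ("random", "exhaustive"):
            raise ValueError(f"unknown partition mode {self.mode!r}")
        if self.mode == "random" and self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class BinnedMoments:
    """Smoothed per-bin replication moments for one split scheme.

    ``mean_rep``/``meansq_rep`` are NaN for bins never populated in any
    iteration; ``count`` aggregates training z-scores over all iterations.
    ``rho`` is the ratio of replication to training effective sample size used
    when converting posterior moments to the replication scale.
    """

    bin_edges: np.ndarray
    count: np.ndarray
    mean_rep: np.ndarray
    meansq_rep: np.ndarray
    rho: float
    n_train: float
    n_rep: float
    train_fraction: float | None = None
    n_iterations: int = 1
    meta: dict = field(default_factory=dict)

    @property
    def bin_mid(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def populated(self) -> np.ndarray:
        return self.count > 0

    @property
    def var_rep(self) -> np.ndarray:
        """Per-bin replication variance estimate E{Z_r^2} - E{Z_r}^2."""
        return self.meansq_rep - self.mean_rep**2


def meta_combine(z_matrix: np.ndarray, n_k: Sequence[float],
                 subset: Sequence[int] | None = None):
    """Sample-size-weighted meta-analysis combination of sub-study z-scores.

    z_meta = sum_k sqrt(n_k) z_k / sqrt(sum_k n_k) over the chosen subset;
    the sqrt(n_k) weighting preserves unit noise variance.  Returns the
    combined z-scores and the combined effective sample size.
    """
    z_matrix = np.asarray(z_matrix, dtype=float)
    n_k = np.asarray(n_k, dtype=float)
    if subset is None:
        subset = np.arange(z_matrix.shape[1])
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        raise ValueError("subset must be non-empty")
    n_sub = n_k[subset]
    if np.any(n_sub <= 0):
        raise ValueError("effective sample sizes must be > 0")
    w = np.sqrt(n_sub)
    n_comb = float(n_sub.sum())
    z_meta = z_matrix[:, subset] @ w / np.sqrt(n_comb)
    return z_meta, n_comb


def partition(k_studies: int, scheme: PartitionScheme) -> list[tuple[np.ndarray, np.ndarray]]:
    """Sequence of ordered (train, replication) index pairs over K sub-studies.

    Exhaustive mode enumerates every C(K, round(K * train_fraction)) choice of
    training set (the 4-of-8 case yields the 70 ordered splits); random mode
    draws ``n_iterations`` seeded splits.
    """
    if k_studies < 2:
        raise ValueError("need at least 2 sub-studies to partition")
    n_train = int(round(scheme.train_fraction * k_studies))
    if n_train < 1 or n_train >= k_studies:
        raise ValueError(
            f"train_fraction {scheme.train_fraction} leaves an empty side for K={k_studies}")
    all_idx = np.arange(k_studies)
    if scheme.mode == "exhaustive":
        out = []
        for train in itertools.combinations(range(k_studies), n_train):
            train = np.asarray(train, dtype=int)
            rep = np.setdiff1d(all_idx, train)
            out.append((train, rep))
        return out
    rng = np.random.default_rng(scheme.seed)
    out = []
    for _ in range(scheme.n_iterations):
        perm = rng.permutation(k_studies)
        out.append((np.sort(perm[:n_train]), np.sort(perm[n_train:])))
    return out


def bin_replication(z_train: np.ndarray, z_rep: np.ndarray, c: float, m_bins: int = 201):
    """Bin replication z-scores by their training z-score, one iteration.

    Training scores in half-open equal-width bins on [-c, c); scores with
    |z_train| outside the range are excluded.  Returns (bin_edges, counts,
    means, mean squares) with NaN marking empty bins.
    """
    if not c > 0:
        raise ValueError("c must be > 0")
    if m_bins < 2:
        raise ValueError("need at least 2 bins")
    z_train = np.asarray(z_train, dtype=float)
    z_rep = np.asarray(z_rep, dtype=float)
    edges = np.linspace(-c, c, m_bins + 1)
    width = edges[1] - edges[0]
    keep = (z_train >= -c) & (z_train < c)
    idx = np.floor((z_train[keep] + c) / width).astype(int)
    idx = np.minimum(idx, m_bins - 1)  # right edge guard for float round-off
    zr = z_rep[keep]
    counts = np.bincount(idx, minlength=m_bins).astype(float)
    sums = np.bincount(idx, weights=zr, minlength=m_bins)
    sumsqs = np.bincount(idx, weights=zr * zr, minlength=m_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / counts, np.nan)
        meansqs = np.where(counts > 0, sumsqs / counts, np.nan)
    return edges, counts, means, meansqs


def smooth_moments(iterations: Iterable[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]],
                   rho: float, n_train: float, n_rep: float,
                   train_fraction: float | None = None,
                   meta: dict | None = None) -> BinnedMoments:
    """Average per-iteration binned moments (equal weight per populated iteration).

    Each element of ``iterations`` is a (bin_edges, counts, means, meansqs)
    tuple from :func:`bin_replication` on a common grid.  Bins never populated
    in any iteration stay NaN.
    """
    iterations = list(iterations)
    if not iterations:
        raise ValueError("need at least one iteration")
    edges0 = iterations[0][0]
    counts = np.zeros(len(edges0) - 1)
    means = np.full((len(iterations), len(edges0) - 1), np.nan)
    meansqs = np.full_like(means, np.nan)
    for i, (edges, cnt, mn, msq) in enumerate(iterations):
        if edges.shape != edges0.shape or not np.allclose(edges, edges0):
            raise ValueError("all iterations must share the same bin grid")
        counts += cnt
        means[i] = mn
        meansqs[i] = msq
    populated_iters = np.sum(~np.isnan(means), axis=0)
    with np.errstate(invalid="ignore"):
        mean_rep = np.where(populated_iters > 0,
                            np.nansum(means, axis=0) / np.maximum(populated_iters, 1), np.nan)
        meansq_rep = np.where(populated_iters > 0,
                              np.nansum(meansqs, axis=0) / np.maximum(populated_iters, 1), np.nan)
    return BinnedMoments(
        bin_edges=edges0, count=counts, mean_rep=mean_rep, meansq_rep=meansq_rep,
        rho=rho, n_train=n_train, n_rep=n_rep, train_fraction=train_fraction,
        n_iterations=len(iterations), meta=dict(meta or {}))


def resample_moments(panel: SubstudyPanel, scheme: PartitionScheme,
                     c: float, m_bins: int = 201) -> BinnedMoments:
    """Full resampling pass for one split scheme.

    For every partition: meta-combine the training and replication sub-study
    sets separately (disjoint, hence independent), bin, then smooth across
    partitions.  ``rho`` and the effective sizes are averaged over partitions
    (they vary when sub-study sizes are unequal).
    """
    splits = partition(panel.n_studies, scheme)
    per_iter = []
    n_trains, n_reps = [], []
    for train, rep in splits:
        z_tr, n_tr = meta_combine(panel.z, panel.n_k, train)
        z_re, n_re = meta_combine(panel.z, panel.n_k, rep)
        per_iter.append(bin_replication(z_tr, z_re, c=c, m_bins=m_bins))
        n_trains.append(n_tr)
        n_reps.append(n_re)
    n_train = float(np.mean(n_trains))
    n_rep = float(np.mean(n_reps))
    return smooth_moments(
        per_iter, rho=n_rep / n_train, n_train=n_train, n_rep=n_rep,
        train_fraction=scheme.train_fraction,
        meta={"mode": scheme.mode, "seed": scheme.seed, "c": c, "m_bins": m_bins,
              "n_partitions": len(splits)})
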
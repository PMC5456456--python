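# Methods

## Model and assumptions

The package models per-SNP GWAS Wald statistics through
`z = sqrt(n) delta + omega`, `omega ~ N(0, sigma0^2)`, with standardized
effects `delta` drawn i.i.d. from a two-component scale mixture of centered
normals: weight `pi1` on variance `sigma1^2` ("small" effects, including the
sharp null when `sigma1 = 0`) and weight `pi2 = 1 - pi1` on
`sigma1^2 + sigma2^2` ("large" effects).  The normal noise and independence of
`delta` and `omega` are the only distributional requirements for the posterior
identities used; the mixture form is a modelling choice that buys closed-form
fdr, posterior moments and replication probabilities at the cost of
potentially underfitting heavy tails (see Limitations).

Per-SNP allele frequencies enter only through the heterozygosity scale
`X = 2 p_bar (1 - p_bar) n` with the panel-mean frequency `p_bar` substituted
for every SNP.  Per-SNP frequencies can be supplied to the quadrature/oracle
paths, but the fitting surface deliberately uses `p_bar` — the residual
approximation error appears as a mild (<10%) downward pull on the fitted
effect sds, quantified below.

Meta-analysis sub-studies are assumed exchangeable draws from one population:
common residual variances, allele frequencies and effect sizes across
sub-studies.  These are the same assumptions that justify fixed-effects
meta-analysis itself; the synthetic-data module provides explicit violation
modes to measure what happens when they fail.

## Resampling estimator

Sub-studies are split into disjoint training/replication sets — exhaustively
(all 70 four-vs-four splits of 8 studies) or by seeded random draws.  Each
side is combined with `sqrt(n_k)` weights normalized by `sqrt(sum n_k)`,
which preserves unit noise variance.  Training z-scores are binned into
M = 201 equal half-open bins on `[-c, c)`; the replication mean and mean
square per bin are averaged across partitions with equal weight per populated
iteration.  Under the exchangeability assumptions the smoothed bin means
estimate `sqrt(n_r/n) E{sqrt(n) delta | Z in bin}` and the bin variances
estimate `(n_r/n) Var{sqrt(n) delta | Z in bin} + sigma0^2`; both facts are
verified by simulation in the test suite.

`c` should span the observed training z-scores (the pipelines in the tests
use `max(10, ceil(max |z|) + 1)`); bins outside the data are flagged missing,
never zero-filled.

## Estimating equations

The parameters minimize the sum over bins (and over split schemes with
different training fractions) of squared discrepancies between the smoothed
moments and the model's predicted replication mean `sqrt(rho) mu(z_bin)` and
variance `rho sigma^2(z_bin) + sigma0^2`, where `mu` and `sigma^2` are the
posterior mean and variance of `sqrt(n) delta` at the training sample size
and `rho = n_rep / n_train`.  The `sqrt(rho)` mean scale is forced by the
measurement model (`Z_r = sqrt(rho) sqrt(n) delta + noise`); a literal-`rho`
variant is retained behind `mean_scale="rho"` for comparison.

Bins are weighted proportionally to their training counts by default.  The
bin-mean sampling variance is `~sigma0^2 / count`, so count weighting is the
inverse-variance choice; with equal weights the ~hundred near-empty tail bins
dominate the objective and measurably bias the estimator at realistic scales
(replicate medians at the conditions below: sigma0 -2.1% and pi2 -27% under
equal weights, versus -0.04% and -6% with count weights).  Equal weighting
remains available via `count_weight=False`.

Minimization is Nelder-Mead in `(logit pi1, log sigma0^2, log sigma1^2,
log sigma2^2)` so the constraints hold by construction, with 10 seeded
restarts (default start: `pi1 = 0.99`, `sigma0^2 = 1`, `sigma1^2 = 1e-6`,
`sigma2^2 = 1e-3`, a weakly informative sparse-effects prior guess) and a
final polish from the best point.  With noise-free model-generated moments
the fit returns the generating parameters to ~1e-9 relative error, which is
the cleanest identifiability statement available for this objective.  When
the fitted separation `X sigma2^2` falls below `1e-3 sigma0^2` the two
components are indistinguishable on the z scale and `pi1` is not identified;
the result is flagged `degenerate` rather than silently reported.

No confidence intervals are produced: the estimating equations correlate
across overlapping resampled splits and across SNPs in residual LD, so naive
curvature-based intervals would be wrong.

## Downstream quantities

- **fdr threshold**: bisection on `|z|` (fdr is monotone when
  `sigma2^2 > 0`), solved to 1e-10.
- **Variance explained**: ratio of summed posterior second moments of
  `sqrt(n) delta` over selected vs all SNPs, with a large-effect-only variant
  that keeps the `H = large` term of the mixture decomposition.
- **lambda_GC**: `median(z^2) / 0.4549` empirically, or the model marginal's
  median by root finding.
- **Power projection**: for a sample-size multiple m, scale `X -> mX`
  (`p_bar` fixed), map the p-value threshold to
  `z_c = Phi^{-1}(1 - p/2) sqrt(lambda)`, and integrate
  `E{d^2 1(|Z| >= z_c) | H = large} / E{d^2 | H = large}` by adaptive
  quadrature over the large-effect prior.  Genomic control defaults to
  `gc_mode="fixed"`: lambda is estimated from the model at the observed
  sample size and held fixed across multiples, matching how analysts correct
  the data in hand before projecting.  Recomputing lambda at each projected
  size (`gc_mode="per_multiple"`) is also available but caps attainable
  power: as m grows, the ratio `z_c^2 / (m X (sigma1^2 + sigma2^2))` tends to
  a constant proportional to `sigma1^2 / (sigma1^2 + sigma2^2)`, so a study
  with a strong small-effect background can never reach high large-effect
  power under that convention —
  the fixed convention is the one under which published doubling projections
  are coherent.  Required-multiple searches walk the doubling grid
  1, 2, 4, ... that sample-size projections are conventionally displayed on.

## Synthetic data

The generator draws mixture effects, scales each SNP by its own
`sqrt(2 p (1-p))` with `p ~ Uniform(0.05, 0.5)` (a flat common-variant MAF
spectrum; the real spectrum is skewed toward rare alleles, which would only
widen the heterozygosity dispersion modelled here), and adds independent
`N(0, sigma0^2)` noise per sub-study.  Defaults emulate a Crohn's-scale
meta-analysis: 100,000 SNPs, 8 equal sub-studies, total effective n = 24,000.
Because the generator uses per-SNP heterozygosity while the fitting surface
uses `p_bar`, fitted effect sds sit ~4-8% below truth by construction — a
deliberate mirror of the real approximation, and well inside the recovery
tolerances used in the tests.

Violation modes: `maf_jitter` perturbs per-study allele frequencies on the
logit scale (scale 2.5 in the tests, i.e. per-study MAFs essentially
decoupled — the "large departures" regime; meta-averaging over 4 studies per
side damps milder jitter into invisibility), and `effect_heterogeneity`
multiplies per-study effects by `1 + scale * eps`.  Under strong MAF jitter
the documented bias pattern appears: `pi2` roughly unchanged, `sigma0`
slightly up, `sigma1`/`sigma2` pulled down.

The LD-block simulator places one causal SNP at the centre of each AR(1)
block (correlation 0.9, block size 51) and adds an equal-sized complement of
unlinked null SNPs.  Univariate-regression z-scores then have expectation
equal to the LD-weighted sum of causal effects (noise shares the block
correlation), so the apparent large-effect proportion from a naive fit is an
order of magnitude above the causal proportion.  The unlinked complement
matters: causal effects sit in higher-than-average total LD, which is exactly
why random pruning to pairwise r^2 <= 0.2 removes blurred-effect carriers
preferentially and pulls the fitted proportion back toward the causal value.
In a genome where all SNPs sat in identical blocks, pruning would thin
carriers and nulls at the same rate and change nothing.

What the generator does **not** emulate: realistic LD maps, allele-strand
mismatches, imputation quality, case-control liability-scale nonlinearity,
population stratification, and heavy-tailed effect distributions.  Passing
tests therefore demonstrate correctness of the estimator under its own
assumptions plus the two modelled violations — not robustness to everything
real summary statistics contain.

## Problem sizes used by the automated checks

Parameter-recovery checks run 3 representative grid cells
(`pi2 ∈ {0.01, 0.02, 0.05}`, `sigma1 ∈ {0, 0.001, 0.01}`,
`sigma2 ∈ {0.05, 0.1}`) at 50,000 SNPs and 10 replicates per cell, with
medians required inside ±25% for `pi2` and `sigma2` and ±2% for `sigma0`.
Cells with `sigma2 = 0.01` are excluded: at the default sample size
`X sigma2^2 ≈ 0.9`, i.e. the large-effect signal sits below the noise floor,
and the resampling estimator genuinely needs a sizable signal before `pi2`
and `sigma2` are estimable — a known limitation of the method, not of the
implementation.  Monte-Carlo cross-checks of the replication probability use
1e5 importance-sampled draws per training z-score.

## Numerical choices

- All densities, fdr weights and mixture sums are computed in log space with
  log-sum-exp; the fdr is stable beyond |z| = 50.
- The generic Tweedie-formula path uses five-point central stencils
  (default step 1e-3), balancing O(step^4) truncation against round-off;
  the closed-form and Tweedie paths agree to 1e-6 relative on randomized
  parameter grids and the trade-off is documented at the call site rather
  than hidden behind adaptive magic.
- Posterior variances are clipped at zero only after an internal consistency
  check; a materially negative value raises instead of being masked.
- Half-open binning `[-c + (m-1)h, -c + mh)` with the right edge excluded;
  float round-off at the top edge is guarded by index clamping.
- Replication-probability tail masses use `Phi((mean - c)/sd)` directly so
  the sign convention (success mass on the training-sign side) is explicit.

## Limitations

- Two components underfit heavy-tailed effect distributions; fdr, replication
  probabilities and power then come out conservative in the extreme tail.
  The mixture is an explicit extension point (two parameters per extra
  component) but only two components are implemented.
- The estimator needs a sizable aggregate signal; with
  `X sigma2^2 <~ sigma0^2` the large-effect parameters are weakly identified
  and the degeneracy flag should be heeded.
- No standard errors for the fitted parameters (see above).
- Sub-study z-scores are assumed pre-harmonized to a common effect allele;
  no strand or allele flipping is performed anywhere.
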
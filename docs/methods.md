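# Methods

This note records the statistical model, the simulation design, and the
numerical and design choices the package makes where several defensible
options exist.

## Estimation targets and notation

Areas (provinces) are indexed by i, census post-strata (cells) by g; a cell
is one combination of categorical covariates shared between survey and
census (default sex × age × residence). N_ig is the census count of cell g
in area i, N_i = Σ_g N_ig. The estimand is the area prevalence of a binary
outcome, and every estimator reports (estimate, MSE, 95% interval, CV, n)
per area.

## Direct estimator

The Hajek ratio mean p̂_i = Σ w_j y_j / Σ w_j over the area's respondents,
with the with-replacement single-stage linearization variance

    v(p̂_i) = Σ_j w_j² (y_j − p̂_i)² / (Σ_j w_j)².

The survey's stratum/PSU structure is not modelled (it is not part of the
data contract); the single-stage form is the standard conservative default.
Intervals are Wald, p̂ ± 1.96√v, and deliberately **untruncated**: the
published synthetic-method tables show negative lower bounds, so truncation
would break comparability (a `clip01` flag exists). The variance doubles as
the reported MSE since the estimator is design-unbiased. CV = √v / p̂ is
undefined (NaN) at p̂ = 0, and an empty domain returns an explicit
inestimable record rather than a zero.

One subtlety the tests exercise: with proportional cell allocation and very
small n, cells can receive no sample and are then simply omitted; the
direct estimator is exactly design-unbiased only when every cell is
sampled. The unbiasedness test therefore uses uniform allocation.

## Predictor screening

A multivariable logistic regression with design weights as a
pseudo-likelihood (statsmodels GLM, frequency weights) provides the point
estimates; the covariance is the explicit linearization sandwich
H⁻¹(Σ w_j² s_j s_j′)H⁻¹ computed from unit scores, not the model-based
covariance. A factor is retained at level α (default 0.1, the conventional
screening level for model building) when any of its level coefficients has
Wald p < α, strictly. Perfect separation is detected by coefficient blow-up
and reported with the offending column.

## Post-stratified synthetic and composite estimators

Synthetic: p̂_syn,i = Σ_g (N_ig/N_i) p̂_g with p̂_g the national
design-weighted stratum rate; the naive variance Σ (N_ig/N_i)² v(p̂_g)
only reflects the national rates' sampling error. The reported MSE is the
design-based contrast estimator

    mse_syn,i = max(0, (p̂_syn,i − p̂_dir,i)² − v(p̂_dir,i)),

truncated at zero because the untruncated area-specific form is negative
whenever sampling noise dominates the bias; a smoothed variant (averaging
the untruncated contrast over areas before truncating) trades area detail
for stability and is selectable (`mse_method="rao-smoothed"`). Which of the
several textbook synthetic-MSE estimators the motivating analysis used is
not documented; both variants are labelled in output.

Composite: φ_i = mse_syn,i / (mse_syn,i + mse_dir,i) — the MSE-optimal
weight under independent errors — with 0/0 resolved to ½, and
mse_comp = φ² mse_dir + (1−φ)² mse_syn (the error covariance is ignored;
the result is bounded by min(mse_dir, mse_syn) under the optimal φ). A
sample-size weight φ_i = n_i/(n_i + δ), δ = 100 by default, is available
for settings where the MSE inputs are too noisy to be trusted.

Default synthetic strata are the factors retained by screening, mirroring
covariate-driven post-stratification.

## Hierarchical Bayes model

Unit-level Bernoulli-logit with exchangeable area intercepts:

    y_ij | β, v_i ~ Bernoulli(expit(x_g(j)′β + v_i)),   v_i ~ N(0, σ_v²),
    β_k ~ N(0, 10²),   σ_v ~ half-Normal(1)  (default).

Covariates live at the cell level, so the likelihood collapses to cell
binomials and an MCMC sweep costs O(#cells). Survey weights do **not**
enter the likelihood: the two-step small-area logic is to fit the
unit-level model and let the census composition reweight the prediction,
P_i = Σ_g (N_ig/N_i) expit(x_g′β + v_i), computed for every retained draw.
A weighted-pseudo-likelihood flag exists for sensitivity analysis. The
area estimate is the posterior mean of P_i, its MSE the posterior
variance, and the interval the central 95% posterior quantiles.

Priors: the β scale of 10 is effectively flat on the logit scale;
half-Normal(1) on σ_v is weakly informative for between-area spreads seen
in prevalence applications (σ_v of 0.1–1). An Inverse-Gamma(0.001, 0.001)
option on σ_v² is provided for parity with BUGS-style conventions, with a
conjugate Gibbs update. A spatially structured random effect is
deliberately absent: the package instead provides Moran's I on the area
estimates as the justification check, matching the modelling decision the
pipeline is built around.

### Sampler

Self-contained Metropolis-within-Gibbs, chosen over an external MCMC engine
for determinism under a fixed seed and a zero-dependency core:

* β: random-walk Metropolis per coordinate;
* v: one vectorized random-walk update of all areas at once (conditionally
  independent given β, σ_v);
* σ_v: the centered update (log-scale random walk under the half-Normal
  prior, conjugate Gibbs under Inverse-Gamma), **plus an interweaved
  non-centered step**: holding u = v/σ_v fixed, propose σ_v on the log
  scale and rescale v with it. The centered update alone mixes very slowly
  in the funnel near σ_v ≈ 0 (effective sample sizes of a few dozen in
  long chains when the true variance is zero); the interweaving step moves
  along the funnel axis and restores healthy ESS, which matters for the
  variance-component test below.

Proposal scales adapt toward 44% acceptance in batches of 50 during
burn-in only, so retained draws come from a time-homogeneous chain.
Initialization: β at the pooled logit rate, v = 0, σ_v at half the prior
scale; a non-finite initial likelihood or post-adaptation acceptance below
1% raises with diagnostics. Defaults are 25,000 iterations with 5,000
burn-in, thinning 1, one chain; the package's own validation runs shorter
chains (below).

### Diagnostics and the variance-component flag

ESS uses Geyer's initial-positive-sequence estimator on per-chain-centered
autocorrelations (a constant chain reports ESS = 1 with a warning); PSRF is
the split-R̂, computed between chains when ≥2 are run and on split halves
otherwise, with a warning threshold of 1.1. The between-area random effect
is called "supported" when the central 95% posterior interval of σ_v lies
entirely above ε = 0.01 — a practical-equivalence margin roughly an order
of magnitude below between-area spreads that matter on the logit scale.

## Evaluation statistics

Area estimates are aggregated to R regions (default 8) by census
population, P_r = Σ N_i p̂_i / Σ N_i, and compared with the pooled
region-level direct estimate as reference: MSE, MAD, MRAD (requires a
nonzero reference), the rank statistic RS, and Pearson CC (undefined for a
constant vector). RS is defined here as the **normalized Spearman
footrule**, mean|rank(e) − rank(d)| / (R − 1) with average ranks on ties —
the term "rank statistic" is used loosely in the SAE validation literature,
so the definition is fixed and documented. The external-correlation helper
removes outliers by a 1.5·IQR fence (default; z > 3 and "none" available)
from both vectors before computing Pearson r.

## Jenks natural breaks

Exact Fisher dynamic programming over contiguous partitions of the sorted
values (O(kn²), trivial at 31 areas), not the iterative heuristic. Ties
between optimal partitions are broken toward the lexicographically
smallest class-size sequence, which makes the result deterministic and
testable against brute-force enumeration. Breaks are reported as class
maxima (GIS convention); GVF = 1 − SSD_within/SSD_total. The default map
legend is k = 5 classes grouped 2/1/2 into low/moderate/high bands, the
configuration implied by a two-shades-per-extreme choropleth legend.

## Moran's I

I = (n/W) ΣΣ a_ij (z_i − z̄)(z_j − z̄) / Σ(z_i − z̄)², binary symmetric
adjacency without self-loops; E[I] = −1/(n−1). The p-value is a two-sided
permutation tail on |I − E[I]| with the observed labelling counted among
the permutations; exact enumeration of all n! relabelings is available for
n ≤ 8 and is the oracle in tests.

## Synthetic-data generator

The generator emulates the structure of the motivating design — a national
household survey of 7,886 respondents aged 15–64 spread very unevenly over
31 provinces (60 to 893 per province, taken from the packaged design
table) — without claiming to reconstruct its unpublished multistage
weighting:

* **Census**: full cross-classification of sex(2) × age(3) × residence(2)
  per area. National marginal shares (sex 50/50, age 47/38/15, residence
  73/27) follow the census composition reported with the survey; each
  area's cell shares are a Dirichlet perturbation (concentration 300) of
  the national shape, giving mild, realistic compositional heterogeneity.
  Area populations are lognormal (σ = 0.6) around a configurable mean —
  a few metropolitan areas, many small ones. Tests and the acceptance
  script use a mean of 30,000 with σ = 0 (deterministic totals); weights
  scale out of every estimator, so population magnitude is a free choice.
* **Truth**: fixed effects default to the published adjusted odds ratios
  (female OR 1.39, rural OR ≈ 0.78, a mild decline at older ages) with the
  intercept set so national prevalence is ≈ 23.6%; σ_v defaults to 0.3,
  which reproduces a between-area prevalence spread comparable to the
  published HB range (roughly 13–37%).
* **Survey**: per-area totals allocated to cells (largest-remainder,
  proportional to cell population or uniform), outcomes drawn at the
  cell's true rate, weights w = N_ig/n_ig exactly, so fully-sampled areas
  satisfy Σw = N_i to the last digit.

Reproducibility: one user seed, split into named substreams (census /
truth / survey / chain) via `numpy.random.SeedSequence`, so regenerating
one artifact never perturbs another.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real surveys: multistage cluster sampling and design
effects, nonresponse and calibration adjustments, measurement error in the
diagnostic instrument, and spatially structured (rather than exchangeable)
area effects. Results on synthetic data validate the estimators under
their own assumptions, not the survey's field conditions.

## Problem sizes used in validation

The package's validation suite runs the full published design (31 areas,
7,886 respondents) but shortened chains, a deliberate scaling of the
simulation studies: HB interval-coverage recovery uses 50 replicates at
2,000 iterations / 500 burn-in (coverage is driven by the area intercepts,
which mix fast); the variance-component null study uses 6,000 / 1,000,
where σ_v itself must mix; the quadrature-oracle comparison uses 40,000
draws on a 3-parameter toy. Direct-estimator coverage uses 500 replicate
surveys of four areas at n = 450 each. Observed results at these sizes:
direct coverage ≈ 95%, HB coverage ≈ 94–95%, MCMC-vs-quadrature
disagreement ≤ 0.3%, zero false "supported" variance flags in ten null
replicates.

## Known limitations

* The direct variance ignores any real stratification/clustering, so CI
  coverage statements transfer to real data only as far as the
  with-replacement approximation does.
* The synthetic-MSE contrast estimator is noisy area-by-area; its
  truncation at zero biases it downward where direct variance is large.
* The HB model shares one σ_v across areas and assumes exchangeability;
  strong spatial structure would violate it (the Moran check is the
  guard, not a fix).
* The packaged published tables are transcriptions; one table (the direct
  method's) is internally inconsistent in print and is flagged `suspect`
  rather than corrected, and a handful of printed MSE entries in the HB
  table fail the Wald CI/MSE identity — the consistency checker reports
  exactly those rows.
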
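# Methods

## The twin likelihood

Each trait is analysed independently. After preprocessing, the trait's
values across the cohort are modelled as samples from a structured
multivariate normal: a complete twin pair (x₁, x₂) has mean (μ, μ) and an
exchangeable 2×2 covariance with common variance a²+c²+e² and
within-pair covariance a²+c² (MZ) or ½a²+c² (DZ); singletons and the
observed member of a pair with one missing value contribute the
univariate marginal N(μ, a²+c²+e²). Marginalising half-missing pairs
rather than dropping them is the likelihood-consistent treatment and
matches a cohort design that retains singletons after one co-twin fails
QC.

The log-likelihood is evaluated from per-group sufficient statistics
(pair counts, sums, sums of squares and cross-products), making each
evaluation O(1) in the data. For n exchangeable pairs with variance v
and covariance s,

log L = −n·log 2π − (n/2)·log(v²−s²) − [v·Σ(d₁²+d₂²) − 2s·Σd₁d₂] / (2(v²−s²)),

with d the deviations from μ. Non-positive-definite parameter points
return −∞ and are rejected by the optimizer. The implementation is
cross-checked in the test suite against brute-force
`scipy.stats.multivariate_normal` density evaluation at random
parameter/data points (agreement to 1e-9).

## Fitting, selection, intervals

**Parameterization.** Models are parameterized by path coefficients
(a, c, e) that are squared into variances, so component non-negativity is
automatic and no constrained optimizer is needed. The unique-environment
variance is floored at (1e-6 × sample sd)² to keep the covariance
positive definite when the optimum approaches the boundary.

**Optimisation.** Nelder–Mead (xatol 1e-8, fatol 1e-10) from five
deterministic starts spanning the (a², c²) simplex plus a
method-of-moments start derived from the sample double-entry
correlations. The E-only model has a closed-form MLE (pooled mean and
MLE variance). When all four models are fitted together the AE and CE
optima are passed to the ACE fit as additional warm starts, which
enforces the nesting inequality log L(ACE) ≥ log L(AE), log L(CE) ≥
log L(E) up to optimizer tolerance (tested at 1e-6).

**Parameter counts.** The estimated mean is counted as a free parameter:
k = 4 (ACE), 3 (AE, CE), 2 (E); AIC = −2 log L + 2k. After rank-based
preprocessing the mean is ≈0 by construction, but it is estimated
regardless so the likelihoods remain comparable on arbitrary input
scales.

**Model selection.** Lowest AIC among converged fits wins; AIC ties
(within 1e-9) break toward fewer parameters, then by the fixed order
E < CE < AE < ACE. LRT p-values against ACE are attached for reporting
but do not override AIC. The LRT uses the standard χ² reference with
df = Δk even though the null value of a variance component lies on the
boundary of the parameter space; this makes the test conservative
(asymptotically the df=1 statistic is a ½χ²₀ + ½χ²₁ mixture, so nominal
α = 0.05 rejects ~2.5% of the time), which the acceptance suite verifies
empirically rather than "corrects".

**Confidence intervals.** 95% intervals for the standardized fractions
are profile-likelihood sets {p : ℓ\*(p) ≥ ℓ̂ − ½χ²₁(0.95)}, bounded to
[0, 1]. The profile optimises the nuisance parameters (mean, log total
variance and, in ACE, a logit split of the remaining variance mass) at
each fixed fraction; interval endpoints are located by Brent root
finding with the boundary returned when the profile never crosses the
cut. Empirical coverage for a² at the default cohort size (75 MZ + 170 DZ
pairs, truth a²=0.6, c²=0.2) is ~0.94 over 200 replicates.

**Pair correlations.** Pearson correlations are computed on
double-entered pairs — each pair contributes (x₁, x₂) and (x₂, x₁) — so
the statistic does not depend on an arbitrary twin-1/twin-2 assignment.
Falconer's h² = 2(r_MZ − r_DZ) is reported unclipped, with a companion
value clipped to [0, 1]; it is a moment approximation, noisier than the
structural estimate, and the two agree in expectation under additive
truth (verified on replicate means, since a single cohort-sized draw of
their difference has sd ≈ 0.05 at 1,000 pairs per zygosity).

## QC filters

Filters run in a fixed order — value window, longitudinal
reproducibility, lineage exclusion — and each eliminated trait is
attributed to the first criterion it fails, so the per-criterion counts
plus survivors always equal the input count. All thresholds are strict
inequalities (CSF summary in (0.1, 99) percent, SPEL median intensity
> 100, test–retest r > 0.7). The final robust set is order-independent
because the criteria are per-trait and independent; only the attribution
depends on the order.

The value window is applied to the across-subject **median** by default.
For SPEL traits the quantity is literally a median fluorescence
intensity; using the median for CSF traits as well is consistent and
robust to single-subject outliers. A `summary` option switches to the
mean or to an every-subject rule.

Reproducibility is the Pearson correlation across controls between the
two blood-draw time points, using original vials only; replicate vials
of the same draw measure run-to-run rather than longitudinal variation
and are excluded from the filter. At least 3 complete control pairs are
required, otherwise the trait fails with an "insufficient controls"
status.

## Preprocessing

Fixed order per trait: (1) single-pass removal of values more than
4 sample-sd from the raw mean (not iterated, and computed before the age
regression); (2) OLS regression on age with intercept, keeping
residuals; (3) rank-based inverse normal transform
z = Φ⁻¹((r − c)/(n − 2c + 1)) with Blom offset c = 3/8 (configurable;
0 gives van der Waerden, 0.5 Tukey scores) and average ranks for ties.
Missing values are excluded pairwise per trait, so a subject removed for
one trait is retained for others. Because INT depends only on ranks, the
transform is invariant to any strictly monotone distortion of the
measurement scale — which is also why the simulator's observed-scale
transforms are irrelevant to the downstream model fits. A Shapiro–Wilk
spot check on a seeded random sample of processed traits (whole cohort
and MZ/DZ subgroups) guards against degenerate inputs such as heavy
ties.

The Blom offset and the single-pass outlier rule are conventions chosen
here; pipelines in quantitative genetics vary on both and the package
exposes them as parameters.

## The synthetic cohort generator

The generator emulates the study design the package targets: 75 MZ
pairs, 170 DZ pairs and 7 singletons, all female; DZ ages uniform on
[41, 75] and MZ ages uniform on [43, 77], so ages stay within 41–77 and
the MZ−DZ mean age difference is exactly the configured 2-year offset in
expectation; 29 longitudinal controls drawn at two time points, 14 with
a replicate vial.

Latent trait values follow the generative ACE decomposition: per family,
C is a shared standard-normal draw; A is shared wholesale by MZ co-twins
while DZ co-twins mix √½·family + √½·individual draws (within-pair A
correlation ½ at unit variance); E is independent per subject. An
optional linear age effect (default 0.01 sd/year, a magnitude typical of
immune-trait age trends) is added on the latent scale. Observed values
are produced by strictly monotone maps — scaled logistic onto (0, 100)
percent for CSF traits, exponential of an affine map for SPEL traits —
chosen for their ranges, not as claims about real marginal
distributions; rank-based preprocessing makes the choice immaterial to
the fits. Longitudinal controls share a stable unit-variance subject
component across draws, with independent measurement error of sd 1/3 per
vial, giving an expected test–retest correlation 1/(1+1/9) = 0.9.

When per-trait fractions are not specified, they are drawn from a
three-class mixture (54% AE-like traits with a² centred on 0.62, 24%
CE-like with c² centred on 0.43, 22% ACE-like with a² ≈ 0.40 and c² ≈
0.25, each with ±~0.1 spread and at least 5% unique-environment
variance), emulating the heterogeneous composition of a large
immunophenotype panel. The default panel size is 40 traits for
interactive use; the acceptance script uses 200.

**What the simulation does not emulate:** flow-cytometry gating, batch
or plate effects beyond a single error term, non-female subjects,
dominance or gene–environment interaction, and correlation *between*
traits (traits are generated independently given the family structure,
whereas real panels are strongly inter-correlated). Passing tests
therefore demonstrate correctness of the estimators under the assumed
ACE generative model, not robustness to those real-data features.

## Problem sizes and numerical conventions

Test and validation runs use scaled-down panels chosen to exercise the
full pipeline: 200 traits for recovery/coverage studies at the default
cohort size, 500 replicates for the boundary-LRT calibration, 5,000
pairs per zygosity for asymptotic agreement checks, and 14–24-trait
panels for end-to-end determinism runs. Quantiles (interquartile ranges)
use the linear-interpolation convention. All TSV output is written with
a fixed `%.10g` float format so identical configurations and seeds give
byte-identical files. Every random draw flows from a single integer
seed through `numpy.random.default_rng`; sub-streams for traits and
controls are derived from (seed, k) tuples so stages stay independent
but reproducible.

## Known limitations

- No dominance (ADE), sex-limitation, age-moderation or multivariate
  twin models; one trait at a time.
- The LRT's boundary conservativeness is documented, not corrected
  (no ½χ² mixtures).
- Profile CIs are reported per component; they are not simultaneous.
- QC cannot reproduce any particular study's elimination counts without
  that study's data; it reproduces the accounting structure exactly.
- Traits with fewer than 10 complete pairs after preprocessing are
  flagged unmodelled rather than fitted.
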
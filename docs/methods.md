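# Methods

## The estimation problem

A complex-design health survey yields respondent records (binary outcome
y, demographic raking cells, zip code, and a census-tract geocode that may
be missing) over a county partitioned into tracts, which nest into health
reporting areas (HRAs); zips overlap both.  The goal is a prevalence
estimate with an uncertainty interval for every tract and HRA, including
tracts with few or zero respondents, while (i) respecting the sampling
design, (ii) borrowing strength across neighbouring areas, and (iii)
propagating the uncertainty of allocating respondents with missing
geocodes.

## Design-based stage

Weights start from inverse selection intensities and are raked by
iterative proportional fitting (IPF) until every margin's weighted totals
match known population totals (default tolerance 1e-8 relative, 100 sweep
cap).  IPF on consistent margins converges monotonically; with a single
margin it reduces to post-stratification in one sweep, which the tests
check in closed form.

Per area the direct estimator is the Horvitz–Thompson ratio
p̂ = Σwᵢyᵢ/Σwᵢ with the single-stage with-replacement variance
v̂ = Σwᵢ²(yᵢ−p̂)²/(Σwᵢ)².  No finite-population correction is applied
(samples are a negligible fraction of the population), and no
degrees-of-freedom correction is applied to v̂.  The working observation
for the spatial model is the empirical logit θ̂ = log(p̂/(1−p̂)) with
delta-method variance V = v̂/(p̂(1−p̂))².  Areas with p̂ ∈ {0,1}, v̂ = 0
or no respondents are *degenerate*: they carry no working likelihood and
are estimated purely from the spatial prior (prediction-only), which is
how an area whose direct estimate is 0% ends up with a strictly positive
smoothed estimate.

## The smoothing model

Stage 1 treats θ̂_i as Normal(η_i, V_i) with V_i known.  Stage 2 is the
Besag–York–Mollié decomposition η_i = μ + u_i + v_i: u is an intrinsic
conditional autoregressive (ICAR) field on the area adjacency graph —
improper density ∝ τ_u^{(n−1)/2} exp(−τ_u/2 Σ_{i∼j}(u_i−u_j)²), identified
by a sum-to-zero constraint — and v_i are i.i.d. Normal(0, 1/τ_v).
Reduced structures (`icar_only`, `iid_only`) drop one component.  Stage 3
places Gamma(0.5, 0.0005) hyperpriors on both precisions (a conventional
vague choice for this model family; configurable) and a flat prior on μ.
τ_u scales the *pairwise-difference* precision; its variance
interpretation is conditional, not marginal — on our grid graphs the
marginal standard deviation of u is roughly half of 1/√τ_u.

### Gibbs sampler

With V_i fixed, every full conditional is Gaussian or Gamma:

* u | rest ~ N(Q⁻¹b, Q⁻¹) with Q = τ_u L + diag(P), b = P(θ̂−μ−v), where
  L is the graph Laplacian and P_i = 1/V_i (0 for degenerate areas).  The
  whole field is drawn in one block via a dense Cholesky factorisation —
  at the intended scale (hundreds of areas) this costs ~1 ms and is
  essential: single-site sweeps mix pathologically along the (u, τ_u)
  ridge (effective sample sizes of single digits at 20,000 iterations),
  which we confirmed against an importance-sampling evaluation of the
  exact marginal posterior.  After each draw u is re-centred to sum to
  zero and the removed mean is absorbed into μ, leaving η unchanged.
* v | rest is conditionally independent Normal; μ | rest is Normal with
  precision ΣP; τ_u | u ~ Gamma(a+(n−1)/2, b+½Σ_{i∼j}(u_i−u_j)²) and
  τ_v | v ~ Gamma(a+n/2, b+½Σv_i²).

Default chain: 20,000 iterations, 5,000 burn-in, thinning 5; effective
sample sizes (arviz) are reported in `summary()` and the pipeline log.
The pipeline experiments in this repository use shorter chains
(1,200/400/2); with the blocked u-update the quantities those experiments
consume (posterior medians and interval endpoints) are insensitive to the
slower-mixing precision parameters, and the calibration experiment passes
at exactly these settings.  Initialisation: μ at the mean working logit, u=v=0,
precisions at the inverse residual variance.  A non-finite state aborts
with diagnostics.  Seeded runs are reproducible draw for draw; all
sub-seeds derive from one master seed by a fixed SeedSequence counter
scheme.

Point estimates are posterior medians of expit(η_i) (robust under the
nonlinear transform); intervals are equal-tailed quantiles on the
prevalence scale, so bounds always lie inside (0,1).  Quantile summaries
refuse fewer than 100 retained draws.

### Model comparison

CPO_i — the leave-one-out predictive density of θ̂_i — is estimated by the
harmonic-mean identity CPO_i = [mean_t 1/N(θ̂_i | η_i^{(t)}, V_i)]⁻¹ over
retained draws, non-degenerate areas only; the structure with the highest
Σ log CPO_i wins, exact ties going to the simpler structure.  The
harmonic-mean estimator's inverse-density weights have finite variance
only when the posterior spread of η_i is below V_i/2; that holds in
realistic fits (many areas, strong pooling) and in the oracle tests, but
the estimator degrades for tiny-n, weak-prior toys.

## Missing geocodes and multiple imputation

Each missing tract is drawn categorically within the respondent's zip with
probabilities equal to the crosswalk's residential-address ratios;
observed tracts are never altered.  The chain (direct estimation →
empirical logit → smoothing) is re-run on each of M completed data sets
(default M=100; raking weights held fixed, since only geography is
re-drawn) and the M posteriors are pooled as an equally-weighted mixture
of their prevalence-scale draws.  Mixture pooling propagates
between-imputation spread automatically (law of total variance: pooled
variance ≥ mean within-imputation variance), reduces to the single fit at
M=1, and avoids the normality assumptions of moment-combination rules; it
is a deliberate design choice where a published combination formula is not
available to us.

HRA estimation uses single, not multiple, assignment (direct estimation
needs a fixed designation): tract-geocoded respondents take their tract's
HRA; others go deterministically to an HRA holding ≥95% of their zip's
population, else by a categorical draw over the zip's population shares.

## Synthetic county generator

Tracts are cells of a near-square grid (shared-edge adjacency — adjacency
topology, not geometry, is what the model consumes); consecutive runs of
tracts form zips and, independently, HRAs, so zips can straddle HRA
boundaries.  Tracts nest exactly in zips and HRAs.  Crosswalk ratios are
Dirichlet(2) draws per zip.  The truth surface follows the model's own
stage 2: u drawn from the ICAR law via the eigendecomposition of the graph
Laplacian with the null space removed (Cov = σ_u²L⁺), v i.i.d. Normal.
Defaults: μ = logit(0.12) (adult-smoking-scale prevalence), σ_u = 0.35,
σ_v = 0.15 — visible spatial structure with modest unstructured noise.

Respondents sample tracts proportional to residential population and
demographic cells proportional to population share × selection intensity;
defaults over-represent older, female, white respondents (the familiar
landline-survey skew), with age/sex/race log-odds effects on the outcome
so that unweighted means are biased and raking has work to do.  The
base weight is the inverse product intensity.  A region covariate (south =
lower half of the zip range) is derived from the zip.  Geocode missingness
follows a logistic model on age, race and region (younger, nonwhite and
southern respondents more often missing); the intercept is calibrated
numerically so the marginal missing rate is 26% under the default
selection mix.  The generator does *not* emulate: telephone-frame
nonresponse structure, address-level geocoding error, multi-zip tracts,
population pyramids of any real county, or cluster/stratum design
features — so passing tests demonstrate correctness of the estimators
under a faithful area-level data-generating process, not robustness to
every real-survey complication.

## Calibration experiment

`saeprev.calibration.interval_calibration` audits the entire Bayesian
machinery: per replicate it draws τ_u, τ_v from the *same* Gamma hyperprior
the model is fitted with (self-consistency), a BYM truth from stage 2,
tract sample sizes by multinomial allocation (median ≈ 30 respondents at
the default 6,000 over 200 tracts; empty tracts become prediction-only),
and working observations from stage 1 with V_i = 1/(n_i p_i(1−p_i)).
Under this design nominal 90% intervals must cover at 90% up to
Monte-Carlo error, and the acceptance suite checks exactly that.  The
experiment's hyperprior is Gamma(6, 1) — the vague analysis default would
draw essentially flat prevalence maps and make the check vacuous.

A deliberate limitation, worth stating plainly: with real binomial counts
and *estimated* V_i, stage 1 holds only asymptotically.  At median tract
samples around 30 the estimated-variance noise and the small-count bias of
the logit transform push empirical coverage below nominal — the
well-known estimated-sampling-variance problem of area-level
(Fay–Herriot-type) models.  That slack is a property of the empirical-logit
working likelihood itself, not of the sampler (which the calibration
experiment shows to be exact), and is shared by any implementation of this
approach; remedies such as variance smoothing are out of scope here.

## Problem sizes used in the shipped experiments

Unit and oracle tests run on toys (2–100 areas).  The calibration check
uses 200 tracts × 50 replicates with 1,200-iteration chains.  The
study-scale comparison (methods A/B/C) uses 396 tracts, 57 zips, 48 HRAs,
16,000 respondents, 26% missingness, M=5 imputations and 10 replicates —
M and the replicate count are scaled down from the defaults to keep the
experiments quick, with the win-fraction threshold (≥90% of replicates)
unchanged.

## Known limitations

* Single-stage with-replacement design variance only; no replicate-weight
  or clustered variance estimation.
* The imputation model conditions on zip alone, not on respondent
  covariates, matching the crosswalk-ratio allocation rule.
* Under-coverage of credible intervals at small per-area counts, as above.
* The dense-Cholesky u-update scales as O(n³) per sweep; beyond a few
  thousand areas a sparse factorisation would be needed.
* CPO via the harmonic-mean identity can be unstable when per-area
  variances are small relative to posterior spread (see above).
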
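# saeprev

Small-area estimation of survey prevalence for subcounty geographies.

Health surveys such as a county's random-digit-dial behavioral risk factor
sample are sized for county-level reporting; at the census-tract level a
typical tract contributes a few dozen respondents, direct design-based
estimates are wildly unstable (rates of 0% or 50% from a handful of
interviews), and a quarter of respondents may lack a usable tract geocode
altogether.  `saeprev` implements the standard remedy end to end, for
epidemiologists and health-department analysts:

* **raked survey weights** — iterative proportional fitting of base design
  weights to known population margins;
* **design-based direct estimation** — the Horvitz–Thompson ratio estimate
  p̂_i = Σw_j y_j / Σw_j per area with with-replacement design variance,
  summarised as an empirical logit θ̂_i = logit(p̂_i) with delta-method
  variance V_i;
* **hierarchical Bayesian spatial smoothing** — the three-stage area-level
  model

      stage 1:  θ̂_i | η_i ~ N(η_i, V_i)                (V_i fixed)
      stage 2:  η_i = μ + u_i + v_i,   u ~ ICAR(τ_u),  v_i ~ N(0, 1/τ_v)
      stage 3:  τ_u, τ_v ~ Gamma(a, b),  μ flat

  (the Besag–York–Mollié structure; reduced forms with only the spatial or
  only the unstructured effect are available), fitted by a blocked Gibbs
  sampler, with conditional-predictive-ordinate (CPO) sums for comparing
  the candidate random-effect structures;
* **multiple imputation of missing geocodes** — respondents with a zip code
  but no tract are allocated to tracts with probabilities equal to the
  zip→tract residential-address crosswalk ratios, the whole estimation
  chain is re-run M times, and the M posteriors are pooled as an
  equal-weight mixture of prevalence draws so imputation uncertainty widens
  the intervals;
* **health reporting area (HRA) assignment** — deterministic when ≥95% of a
  zip's population lies in one HRA, otherwise a categorical draw over the
  zip's population shares;
* **a synthetic county generator** — grid geography with tract adjacency,
  zip/HRA nesting, Dirichlet crosswalk ratios, a BYM truth surface,
  informative selection, and covariate-dependent geocode missingness — so
  every stage is testable without restricted survey microdata.

## Worked example

```python
import saeprev as sp

cfg = sp.PipelineConfig(
    n_tracts=396, n_zips=57, n_hras=48, n_respondents=16_000,
    smoothing=sp.SmoothingSpec(iterations=1200, burn_in=400, thinning=2),
    M=5, seed=11,
)
results = sp.run_tract_pipeline(cfg)
for s in results.summaries.values():
    print(f"{s.method}: prevalence {100*s.prev_min:.0f}-{100*s.prev_max:.0f}%"
          f" (median {100*s.prev_median:.0f}%), CI half-width median"
          f" {100*s.hw_median:.0f} pp")
print(results.comparison.correlations)
```

prints (method A = direct on geocoded respondents, B = smoothed, C =
smoothed + multiple imputation):

```
A: prevalence 0-71% (median 12%), CI half-width median 12 pp
B: prevalence 10-20% (median 14%), CI half-width median 4 pp
C: prevalence 10-20% (median 14%), CI half-width median 4 pp
  pair   pearson  spearman  n_areas
0  A-B  0.379378  0.395837      393
1  A-C  0.391486  0.410031      393
2  B-C  0.958168  0.957342      396
```

The direct method ranges from 0% to 71% because many tracts have a handful
of respondents; smoothing pulls every tract toward its neighbours and the
county level, shrinking the interval half-widths by roughly two thirds,
and the two smoothed methods agree closely with each other (r = 0.96)
while correlating only moderately with the noisy direct estimates.

The model/results layer is also usable directly, statsmodels-style:

```python
model = sp.PrevalenceSmoother(directs, geo.tract_graph(), sp.SmoothingSpec())
fit = model.fit(seed=1)
print(fit.summary())          # structure, ESS diagnostics, sum log CPO
table = fit.estimates(0.90)   # per-area medians and credible intervals
```

A thin CLI wraps the pipelines:

```bash
saeprev simulate --seed 1 --out sim/
saeprev tract-pipeline --seed 1 --out report/
saeprev hra-pipeline --seed 1 --out report-hra/
```

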
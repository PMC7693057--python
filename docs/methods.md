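# Methods

## The model

`msar` estimates how a freshwater community's **mean species abundance
(MSA)** declines along a chemical exposure gradient, using nothing beyond
standard chronic laboratory toxicity tests.

**Species-level dose response.** Each (species, endpoint) group is fitted
with the 2-parameter log-logistic

    Y(c) = 1 − 1 / (1 + (c/C50)^β),

where `Y` is the fraction affected, `C50` the half-maximal effective
concentration (EC50 for reproduction, LC50 for survival, µg/L) and `β` the
Hill slope. The lower and upper asymptotes are fixed at 0 and 1; no
hormesis or 3-/4-parameter variants are offered.

**From endpoints to abundance.** Joint effects on survival and reproduction
multiply through the lifetime fecundity,

    R0(c)/R0(0) = [1/(1+(c/EC50)^βrep)] · [1/(1+(c/LC50)^βsurv)].

Under logistic growth with intrinsic rate r = ln(R0)/Tg and a generation
time unaffected by exposure,

    r(c)/r(0) = 1 − [ln(1+(c/EC50)^βrep) + ln(1+(c/LC50)^βsurv)] / ln R0(0),

and since a proportional decrease in r corresponds to a proportional
decrease in the carrying capacity K, this ratio is read as the relative
equilibrium abundance K(c)/K(0). Negative values mean the population is not
viable at that exposure; they are clamped to 0, which is forced by the MSA
being defined on [0, 1]. (Averaging unclamped curves would yield lower
community values at high concentrations; the clamp is the only choice
consistent with an abundance interpretation.)

Abundance or population-growth endpoints (algae) skip the conversion: the
same carrying-capacity form

    K(c)/K(0) = max(0, 1 − ln(1+(c/C50)^β) / ln R0)

is fitted to the observed fraction-of-control directly. The clamp is part
of the *fitted* model here too — observed abundances cannot be negative,
and without it data containing nonviable concentrations cannot be
recovered even noise-free.

**Community aggregation.** The MSA relationship (MSAR) is the unweighted
mean of the n species curves, MSA(c) = (1/n) Σ K(c)i/K(0)i, evaluated on a
grid of 200 log-spaced concentrations from min(tested)/100 to
max(tested)·100 with c = 0 prepended. A decreasing log-logistic
MSA_fit(c) = 1/(1+(c/a)^β) is refitted through the grid values; hazard
metrics are read off this refit by default (`hc5_on: raw` uses log-linear
interpolation of the piecewise curve instead). The **HC5** — 5% community
abundance loss — is a·(1/19)^(1/β).

**Companion SSD.** For comparison, a species sensitivity distribution is
fitted by maximum likelihood (log-logistic, `scipy.stats.fisk`, location
fixed at 0) to one EC10 per species — the minimum across that species'
endpoints, the regulatory most-sensitive-endpoint convention (the choice is
isolated in `species_ec10` and easy to change). For direct abundance fits
the "EC10" is the concentration at 10% abundance loss,
C50·(R0^0.1 − 1)^(1/β). The SSD HC5 is scale·(1/19)^(1/shape); its CI is a
nonparametric bootstrap over species (percentile, 1000 resamples).

## Fitting details

* Parameters are optimized on (log C50, log β): positivity for free and a
  better-conditioned covariance. Reported on the natural scale.
* Deterministic multistart over β ∈ {1, 0.5, 2, 4, 8}; the C50 start is the
  geometric mean of the concentrations bracketing the half response
  (fallback: median positive tested concentration). Levenberg–Marquardt
  with analytic Jacobians, cost tolerance 1e-10; remaining starts are
  skipped once a start reaches numerically zero cost.
* c = 0 is handled exactly (the model is evaluated, never log-transformed
  in c).
* The parameter covariance is the asymptotic least-squares estimate
  `σ̂² (JᵀJ)⁻¹` at the optimum on the log scale, with σ̂² = SSE/(n−2);
  tiny negative eigenvalues from finite arithmetic are clipped to zero.
* Responses are unweighted means by default; `weight_by_n` weights
  residuals by the per-point number of test subjects.
* Control normalization (Abbott's correction, (r − r0)/(1 − r0), floored at
  0) is applied per group whenever the control shows a nonzero response.
* Step-variant tie-break: at exactly c = C50 the species counts as lost
  (the step is closed on the right). Arbitrary but fixed.

## Uncertainty propagation

One Monte-Carlo iteration draws (log C50, log β) for every fit from a
multivariate normal with the fit's covariance, rebuilds every species
curve, aggregates one possible MSAR, refits the community log-logistic
(warm-started from the deterministic fit) and records its HC5. 1000
iterations by default; pointwise 2.5/97.5 percentiles give the 95%
confidence band. Species are sampled independently, and R0 values are held
fixed — only exposure-response fit uncertainty is propagated. Bands are
parameter-only (confidence) bands; `include_residual` adds a per-species
draw from the residual error, moving them toward prediction bands.

Two numerical guards apply to sampling. Near-step fits (large β with few
points in the transition) have nearly singular Jacobians, so the
linearized covariance can claim absurd spread; the per-parameter sd on the
log scale is capped at 2 (a 7-fold one-sigma, already "essentially
unconstrained" at assay scale) with correlations preserved, and draws are
truncated at ±6 log units. Without these guards most iterations produce
degenerate curves and the refit fails.

The **HC5 interval** is the percentile interval of the iteration HC5s with
a multiplicative median-bias correction: the interval is rescaled so its
median coincides with the deterministic HC5. The simulated HC5
distribution is left-skewed around the plug-in estimate (a small-β draw
depresses the low-concentration tail far more than a large-β draw can
raise it), and in calibration experiments on synthetic panels the raw
percentile interval covered the true HC5 in only ~87% of replicates versus
~95% after correction. Iterations whose refit fails are dropped and
counted; more than 10% failures aborts.

`ci_from_samples` itself is the plain linear-interpolation percentile
interval and is used unchanged for the MSA band and the SSD bootstrap.

## Synthetic panels

The generator (`msar.synthetic`) emulates the structure of a compiled
chronic-toxicity dataset for one chemical at the scale of a published
metals case study:

* 16 species by default (the case-study chemicals spanned 10–18), mixed
  60% animals with both endpoints, 10% survival-only animals, 30% clonal
  algae with direct abundance tests;
* interspecies EC50s log-normal with median 10 µg/L and sd 0.5 log10 units
  (≈ one order of magnitude spread); LC50 = EC50 · 10^U(0.3, 1.0), making
  reproduction the more sensitive endpoint, as chronic data typically show;
* Hill slopes uniform on [1, 4]; animal R0 log-uniform on [5, 100]; algae
  R0 = 2 (clonal division);
* 6 concentrations per test, log-spaced ±1.5 decades around the species'
  half-effect region, plus a control at 0;
* noise by assay mechanism: survival = binomial counts out of 20
  organisms; reproduction/abundance fractions = additive N(0, 0.05²)
  truncated to [0, 1].

Ground truth is returned with every panel, so recovery is directly
checkable; `true_msar` pushes the generating parameters through the same
population and aggregation code. What the generator does **not** emulate:
between-study heterogeneity, uneven designs across species, partial
reproduction-cycle endpoints, censoring, or bioavailability differences.
Passing recovery and coverage tests therefore demonstrate correctness of
the estimation machinery under the stated noise mechanisms, not field
validity of the model assumptions.

Problem sizes used in the shipped test suite: noise-free panels of 8–10
species for exact-inverse checks; 100 noisy replicates of 15 species for
recovery; 200 replicates × 200 Monte-Carlo iterations for interval
calibration.

## Design choices where the design was open

* **Response orientation.** Everything is stored internally as fraction
  affected; abundance data (reported as fraction-of-control) are inverted
  exactly once at the I/O boundary and written back in their native
  orientation, so file round trips are identities.
* **Reproduction-only variant.** Survival-only animals leave the panel and
  algae direct-abundance curves are retained unchanged — an abundance fit
  carries no separable survival term to exclude.
* **No-intraspecies-variation variant** is the pure step at each species'
  min(EC50, LC50): the community curve is exactly 1 minus the (right-
  closed) empirical CDF of those thresholds. The alternative — passing the
  step through the growth model, which would shift each species' collapse
  point off its C50 by the R0 term — was rejected because the variant's
  purpose is to depend on the half-effect concentrations alone.
* **Per-species EC10 = most sensitive endpoint**, matching regulatory SSD
  practice; reproduction-preferred or pooled alternatives would plug into
  `species_ec10`.
* **Partial reproduction-cycle endpoints** (hatchability, gravid females,
  egg counts) are all mapped to the reproduction class and treated
  identically — the configurable label table is the extension point.
* **Allometric R0.** r(W) = a_r·W^−1/4 and Tg(W) = a_T·W^+1/4 with
  intercepts that must be supplied per taxon/temperature (no universal
  default is defensible). With exactly opposite exponents the resulting
  R0 = exp(a_r·a_T) is mass-independent, which is why the allometric route
  is serviceable when only body mass is known.

## Limitations

* Tg is assumed concentration-independent; there is no Tg(c) hook.
* No bioavailability normalization (pH, DOC, hardness); concentrations are
  taken as reported.
* No interspecies interactions; the community mean treats species
  independently, which may understate community-level impacts.
* R0 uncertainty is not propagated.
* The r-to-K proportionality is assumed, not estimated.
* The asymptotic covariance (and hence the envelope) is unreliable for
  step-like fits; the sampling guards bound, but cannot repair, that
  information loss.
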
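# Methods

## Setting and estimand

The package estimates annual state-level trends, 2000–2013, for
survey-measured maternal and child health indicators across Nigeria's 36
states and the Federal Capital Territory, grouped into the six geopolitical
zones. The atomic datum is a state-year-indicator proportion with a sampling
variance, tabulated from one survey. From such sparse, irregular estimates
the pipeline produces: a complete annual posterior trend per state with 95%
intervals; a population-weighted national trend; an under-5 mortality (5q0)
series from complete birth histories; and an equally weighted composite of
11 intervention coverages.

## Harmonization rules

* **Tabulation.** Within a survey, per (state, event year):
  p = Σwᵢoᵢ/Σwᵢ with the design-weighted ratio-estimator variance
  Σwᵢ²(oᵢ−p)²/(Σwᵢ)², which reduces to p(1−p)/n under equal weights.
  Microdata here carry sampling weights but not full stratum/PSU structure,
  so no stratified variance is attempted. All-0/all-1 cells fall back to a
  binomial variance at the clamped proportion with the Kish effective n, so
  variances stay positive.
* **Clamping.** Proportions are clamped to [0.001, 0.999] before the logit
  transform; this bounds the delta-method variance
  var_y = var_p/(p(1−p))² and prevents infinite logits from zero cells in
  small states.
* **Attribution and recall windows.** ANC1/ANC4, skilled birth attendance
  and in-facility delivery are retrospective over births and attributed to
  the child's birth year; full-birth-history instruments contribute births
  up to 6 years before the survey, most-recent-birth instruments up to 2
  years (beyond that they are no longer population-representative).
* **Card-only immunization crosswalk.** Surveys recording vaccination only
  from health cards underestimate coverage relative to card-or-recall
  ascertainment. The adjustment multiplies card-only estimates by the
  unweighted mean of total/card ratios from surveys that record both
  (variance scales by the ratio squared; results capped at 0.999). A single
  pooled ratio per vaccine is used; no zone-level heterogeneity is modelled,
  as there is no principled basis for allocating it.
* **Pre-policy imputation.** Malaria interventions are pinned at 0.01%
  coverage (p = 0.0001, exempt from the clamp floor) for years before
  formal adoption — before 2000 for ITN ownership and IRS (with per-state
  overrides for phased IRS roll-out), 2001 for IPTp2, 2004 for ACTs. The
  pseudo-observations carry a fixed variance of 1e-8: effectively known
  values that pin the GP near zero without a singular noise matrix. The
  exact variance is a free choice; anything small enough to dominate the
  kernel behaves identically.
* **Exclusions** are an explicit (indicator, state, source) configuration
  list, applied as flags; flagged rows never enter any fit. Automating
  outlier exclusion would invent a rule where judgement was used.

## Stage 1: mixed-effects logit prior

On the logit scale, y_{s,t} = α + **T**(β + b_s + b_z) + u_s + u_z + ε_{s,t},
with IID mean-zero random intercepts u and slopes b at state and zone level.
Candidate specifications cross two time bases (linear; natural cubic spline
with one interior knot) with the seven random structures in which a slope
appears only alongside its same-level intercept — 14 models. Stage-1
observations are equally weighted; the sampling variances enter only at the
GP stage.

**Time basis.** The spline's interior knot sits at the median observed year
and the boundary knots at the min/max, beyond which the function continues
linearly. Basis columns are centered at their grid means and standardized to
unit grid SD. Standardization leaves the column space (and hence every
fitted curve) unchanged, but it is essential for the random-slope model: the
raw truncated-power columns differ in scale by an order of magnitude, and a
single shared slope variance across them is then meaningless — in simulation
the variance components were mis-estimated by factors of 30 on raw columns
and recover within ~10–25% on standardized ones.

**Estimation.** Mixed specifications are fitted by REML (statsmodels
MixedLM). Every random term is encoded as a variance component with exactly
one variance — zone-level terms through zone groups, state-level terms
through state-indicator variance-component columns — so the IID structure is
imposed rather than MixedLM's default unstructured covariance. The empty
random structure is OLS. A variance component estimated at the zero boundary
can make BLUP prediction singular; realized effects are then zero, which is
the correct limit. Data with a single zone (or state) cannot identify the
corresponding terms; they are fixed at zero with a warning.

**Model selection.** Repeated random hold-out: each of 100 replicates holds
out 20% of state-year observations (individual observations, unstratified),
fits every candidate on the remainder, and scores RMSE of logit-scale
predictions on the hold-out. RMSE is computed on the logit scale because
that is the estimation scale. A state entirely held out is predicted from
its zone and fixed effects. Non-converging replicate-fits are dropped from
that specification's mean. Ties break toward fewer random terms, then the
linear basis — parsimony, deterministically.

## Stage 2: Gaussian process smoothing

Per state, the residual y − (stage-1 mean) is a zero-mean GP with Matérn
covariance. Defaults: ν = 3/2 (once-differentiable trends — annual health
series should be smooth but not analytic), length scale 5 years, amplitude
1.4826 × median |stage-1 residual| per indicator (a robust MAD-to-SD
conversion that self-tunes to how much structure the prior leaves
unexplained). All three are configuration-exposed. Observations enter with
their delta-method logit variances as independent heteroskedastic Gaussian
noise; no extra non-sampling variance is added. Conditioning is exact
Gaussian algebra via Cholesky, with diagonal jitter starting at 1e-10·σ²
and escalating tenfold to at most 1e-6·σ² before failing. Each state is
smoothed independently; cross-state structure lives entirely in the prior.

1,000 draws are sampled from the posterior (jitter-stabilized Cholesky,
seeded). Summaries use the ordered-draw rule: lower/upper are the 25th and
975th ordered draws, the median the mean of the 500th and 501st; with other
draw counts an empirical-quantile fallback is available but the canonical
rule is strict. Back-transformation to proportions is monotone, so interval
ordering is preserved.

## Aggregation and the composite index

National values are population-weighted means of state values computed per
(year, draw) on the proportion scale — weighted means of proportions are the
estimand; averaging logits would bias — and re-logit-transformed for
storage. Weights are total population for coverage indicators and live
births for under-5 mortality (the natural denominator for a birth-cohort
probability); the basis is selectable. The composite coverage index is the
unweighted mean of 11 intervention coverages, wasting entering as its
complement ("not wasted"); it is computed at the draw level when draws are
available so the composite carries uncertainty, falling back to medians
otherwise. Benchmarking helpers compute state ranges (max − min with the
extremal units), signed paired gaps, and relative declines
100·(v₀ − v₁)/v₀.

## Under-5 mortality

**Synthetic-cohort 5q0.** Within a calendar year, each standard age segment
(0, 1–5, 6–11, 12–23, 24–35, 36–47, 48–59 months) accumulates weighted
deaths D_a and person-months of exposure PM_a, allocating each child's
exposure by the overlap of its age interval with the period and truncating
at death or censoring. The monthly rate m_a = D_a/PM_a converts to a
segment probability q_a = 1 − exp(−m_a w_a) (exact under piecewise-constant
hazards), and q5 = 1 − Π(1 − q_a). The variance sums weighted-Poisson
segment contributions w_a²·Σw²_deaths/PM_a² on the log-survival scale and is
delta-transformed back. An estimate is only emitted when every segment has
positive exposure *under the observation design* (censoring only): periods
at the edge of a source's reporting horizon observe only young children,
and a cohort probability over a truncated age range is structurally biased
downward — in simulation such periods inverted the fitted national trend.
Segments emptied by mortality itself do not suppress the estimate.

**Trend model.** Logit-5q0 is smoothed by the one-interior-knot spline with
IID state and survey (source) random intercepts, fitted by REML as a single
crossed variance-component model. Survey intercepts absorb systematic
between-source level differences. Uncertainty is by parametric bootstrap:
1,000 draws of the fixed effects from their GLS covariance
(XᵀV⁻¹X)⁻¹ at the estimated variance components — computed directly because
the observed-information covariance can be indefinite at boundary
solutions — with state effects held at their BLUPs. Only complete birth
histories are supported; summary-history conversion is out of scope.

**Scaling.** Per year, the factor r_t = reference_t / (births-weighted
national aggregate of state point estimates) multiplies every state's
estimate and draws. The re-aggregated national series then equals the
reference exactly, and between-state ratios within each year are unchanged.
A year-specific multiplicative factor is the minimal rule achieving that
conservation; nothing in the scaled series depends on how the reference was
produced.

## Synthetic data: what it emulates, and what it does not

The generator is the generative twin of the estimator. Defaults define the
study conditions: 37 states in 6 zones on a 2000–2013 grid; a spline-shaped
logit truth rising from roughly 25% to 40% (α = −0.8, β = (0.16, 0.06) on
standardized columns) with random intercept SDs 0.30 and slope SDs 0.08 per
level; six survey sources at the irregular years 2003, 2007, 2008, 2010,
2011, 2013; 500 respondents per state per survey with design effect 1.5
(typical of cluster-sampled household surveys), sampled as
successes ~ Binomial(n/deff, truth). Birth histories: 2,000 children per
state per survey (full-history files are large at DHS scale), births uniform
over the 15 years before each of three surveys (2003, 2008, 2013),
piecewise-constant monthly hazards with an infancy-heavy age profile scaled
so period 5q0 declines linearly from 0.18 to 0.13 nationally, with
lognormal state multipliers (SD 0.15 on the log cumulative hazard). Hazards
are keyed to the calendar year of exposure so the period 5q0 the estimator
targets is exactly defined. A separate model-equation generator draws
logit observations directly from the stage-1 display (normal errors, equal
slope variance per standardized column) and is the oracle for
parameter-recovery tests of the REML machinery, uncontaminated by
logit-transform bias of binomial proportions.

Deliberately not emulated: questionnaire-level nonresponse, recall bias,
non-sampling survey error beyond the design effect, within-state (LGA)
heterogeneity, and cluster-level correlation structure. Passing calibration
tests therefore demonstrates that the pipeline is correct and calibrated
*under its own assumptions*; on real data, unmodelled non-sampling error
would widen true uncertainty relative to the reported intervals.

## Numerical and testing choices

* All randomness flows through numpy Generators; every simulation entry
  point is seed-deterministic, and a fixed seed reproduces draw matrices
  bit for bit.
* Simulation-study sizes: interval calibration uses 200 pipeline replicates
  at the default conditions with the fixed stage-1 specification
  ncs1~u_s+u_z — the package's default for simulation studies, leaving
  state-specific slope deviations to the GP stage (running full 14-model CV
  inside a replicate loop is computationally disproportionate). Measured
  pooled coverage is ~92%. Fitting the fully loaded specification instead
  yields ~89%: per-state BLUP slopes track the noisy observations, the
  residual MAD shrinks, and the GP amplitude with it — a known limitation
  of residual-scale amplitude selection. Fixed-effect recovery uses 200
  replicates of the fully loaded model; CV basis selection uses 50
  independent runs of 20-replicate CV over a 4-model candidate set under a
  strongly curved truth; the unit-test suite runs reduced versions of the
  heavier studies.
* The in-package benchmarking arithmetic is exercised against published
  national and state point estimates (stored with the evaluation module) —
  e.g. the 2000→2013 national under-5 decline of 30% and the 206 → 137
  narrowing of the state range — as pure-arithmetic identities.

## Known limitations

* GP hyperparameters are fixed defaults, not learned by marginal
  likelihood; the amplitude heuristic under-covers slightly when the prior
  is very flexible (above).
* Stage-2 treats the stage-1 mean as known; prior-estimation uncertainty is
  not propagated.
* No spatial adjacency structure: zones are the only spatial pooling.
* The u5m parametric bootstrap ignores uncertainty in the variance
  components and in the state BLUPs.
* Summary birth histories, maternal mortality, and wealth-quintile equity
  decompositions are out of scope.
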
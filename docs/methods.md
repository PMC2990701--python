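# Methods

## The problem and the model

Passive snakebite surveillance records a case only when the victim
reaches, and is registered by, the health system. At the municipality
level the observed count is therefore a thinned version of the true
count, and the thinning is not random: it is strongest exactly where
true incidence is plausibly highest — deprived, rural, remote
municipalities. snakemap implements three complementary instruments for
this problem: an ecological Poisson rate model, a deprivation rank
index, and a within-region rank-comparison rule, together with a
synthetic data generator that encodes the deprivation-dependent
reporting mechanism explicitly so all three can be validated against a
known truth.

### Poisson incidence-ratio model

Municipality case totals over the study period are modelled as

    y_i ~ Poisson(mu_i),
    log mu_i = log pop_i + x_i' b

with population as an offset (coefficient fixed at 1), so exp(b_j) is an
incidence ratio: the multiplicative effect of term j on the reported
rate. Environmental region and underreporting-index category enter as
indicator blocks (reference levels: the largest region, and the "good"
index category — in both cases the most populous level, which gives the
most stable reference); rural %, % under 15 years and % male surplus
enter as untransformed percentages, so their IRs read "per percentage
point". The three standard model columns are: every term in its own
model, region + demographics, and all terms.

Fitting is iteratively reweighted least squares on the canonical log
link: working response `eta + (y - mu)/mu`, weights `mu`, initialized at
the pooled log rate `log(sum y / sum pop)` with all slopes 0;
convergence when the largest absolute coefficient change falls below
`tol` (default 1e-8, maximum 100 iterations). Non-convergence is
returned as a flagged fit with diagnostics rather than raised, since a
flat or separated likelihood is an analysis finding, not a programming
error. Standard errors come from the inverse expected information at
the optimum; 95% intervals are Wald, `exp(b ± 1.96 se)`. A sandwich
(robust) SE option exists but is off by default — the model is a plain
Poisson fit without overdispersion adjustment, and covariates are
deliberately not centered or scaled so IRs stay on their natural
per-unit scale. The linear predictor is clipped to ±30 inside IRLS to
keep early iterations from overflowing; at any interior optimum the
clip is inactive. Rank-deficient designs are refused with the collinear
columns named (pivoted-QR diagnostic). Tests verify the fitter against
an independent coarse-to-fine grid search over the written-out
log-likelihood and against a second GLM implementation.

### Underreporting index

Each of six variables — distance to hospital (m), % households > 5 km
from a health centre, % poverty, % illiteracy, % area > 1 km from a
road, births outside the health system per inhabitant — is ranked over
the n municipalities with the most favourable value receiving rank n,
and the ranks are summed with equal weight (no theoretical grounds
exist for differential weights). The attainable range is [6, 6n]. Ranks
are ordinal with ties broken by ascending municipality id: average-rank
tie handling would break the integer bounds, and an explicit
deterministic tie rule keeps every run reproducible. The index is cut,
best to worst, into five categories with default shares 32/152, 45/152,
45/152, 20/152, 10/152 — small extreme categories so effects at the
tails of the deprivation distribution remain visible. Sizes are
round(share × n) with rounding remainders assigned to the reference
category "good"; sizes depend only on n, never on the data.

### Low-reporter rule

Within each region municipalities are ranked by reported incidence
(ascending) and rural population share (descending); a municipality in
the top 40% of the rural ranking and the bottom 40% of the incidence
ranking is flagged. "Top/bottom 40%" is rank position ≤ ceil(0.4 ×
region size) — ceiling so that even a 3-municipality region can flag
one member; regions smaller than 3 are skipped with a warning because a
40% cut is degenerate there. Ties break by ascending municipality id.
The rule is monotone (lowering a flagged municipality's count can never
unflag it) and region-closed (changes in one region never affect
another's flags).

### Regions

The grouping criteria are altitude, precipitation and geographical
location. snakemap implements them as agglomerative (Ward) clustering
on z-scored altitude and precipitation (optionally weighted, with the
standardized map coordinates as additional location features) under a
connectivity constraint from the symmetrized 4-nearest-neighbour graph
of municipality centroids. The constraint makes every region one
connected component of that graph — the reproducible counterpart of
drawing contiguous regions by eye on a map. Cluster labels are
canonicalized by the smallest municipality id they contain, so the
partition is invariant to input row order. Default k = 7 regions.

### Descriptives

Cumulative incidence per 100,000 = 1e5 × total cases / total
population; annual incidence = cumulative / years (exactly, so the two
are consistent pre-rounding); mortality per 100,000 analogous with
deaths; case fatality rate = 100 × deaths / cases, defined as 0 with a
warning when there are no cases. Presentation rounding: incidence to
integers, CFR to integer percent, mortality to one decimal. The
seasonal profile is the mean count per epidemiological week across
years (week 53 folded into week 52), smoothed with a centered 5-week
sliding mean applied circularly — week 1 neighbours week 52 — so the
smoother preserves the annual mean exactly; boundary handling is a
design choice, and the circular rule is the only one under which a
52-week periodic signal is treated without edge bias. Smoothing
operates on counts; within a fixed region counts and rates differ only
by a population constant, so the shape is identical.

## The synthetic country

The generator emulates a tropical country of 152 municipalities
(defaults; everything is configurable) in 7 environmental regions over
5 years of 52 weeks.

**Municipalities.** Populations are log-normal (median 28,000, sigma
0.8 — national total ≈ 5–6 M). Rural share is anticorrelated with
population size. The six deprivation variables each load on a latent
axis shared with rurality (Spearman correlation > 0.3 by construction,
typically 0.5–0.7) and are mapped to plausible units (log-normal
distances, logistic percentages). Altitude and precipitation are drawn
around region-specific means; centroids scatter (sd 9 km) around
well-separated region centres so generated regions are spatially
contiguous and recoverable by the clustering module. With 7 regions the
canonical layout is used: region shares, incidence multipliers (0.43 to
3.36, the published per-region incidences divided by the national 56
per 100,000), and coastal-west-to-east climate gradients.

**True cases.** The relative 5-year rate of municipality i is
`pop_i × multiplier(region_i) × exp(b_rural × rural%_i)`, with
`b_rural = log(1.017)` per percentage point by default (the
unadjusted rural IR scale). One national constant rescales the rates so
the population-weighted national rate equals `baseline_rate` (default
56 per 100,000 over the period) exactly. This calibration keeps the
default country at the observed national incidence while leaving every
ratio — which is all the incidence model estimates — untouched; the
closed-form per-municipality expectations are exposed
(`expected_case_totals`) and used as the oracle in tests. Weekly
expectations multiply a per-region sinusoid `1 + a cos(2π(w - peak)/52)`
with unit weekly mean; default amplitude a = 0.5 gives a peak/trough
ratio of 3 (incidence roughly tripling between the low and high months)
with the peak in week 50 (December). Weekly true counts are Poisson.

**Reporting.** Observed counts are a binomial thinning of true counts —
binomial rather than a deterministic fraction, to preserve integer
counts and Poisson-like dispersion. The reporting probability is a
piecewise-linear function of the deprivation rank quantile d (from the
same six-variable rank-sum index the analysis uses): 1 for d ≤ knee,
decaying linearly to `reporting_floor` at d = 1. The mechanism is
qualitative in the source setting — no functional form or magnitude is
observable — so the defaults are simulation choices: floor 0.5, knee
0.85 (the decay concentrated in roughly the worst index category, which
is where the incidence-ratio dip is expected to appear), and a truth
flag at reporting probability < 0.7 (≈ the worst 10 municipalities
under the defaults). Deaths are a further binomial thinning of observed
counts at a 1% case fatality rate.

**Randomness.** One seed drives everything: municipality attributes use
the stream keyed `seed`, weekly counts the child stream keyed
`(seed, 1)`, so the municipality table is reproducible independently of
the case series and partial re-runs are deterministic.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: no spatially explicit snake populations or
habitat covariates beyond the region multiplier; no individual-level
victims, referral between municipalities, or hospital catchment
effects; no migration or census error in the population denominators;
reporting depends on deprivation only through the rank index (in
reality access barriers need not align with any index); and the
seasonal forcing is a single harmonic. Detection sensitivities measured
on synthetic data are properties of this mechanism, not estimates for
any real surveillance system.

## Validation design

* Closed-form identities: pooled-rate intercept, saturated two-group
  IR, offset-shift invariance, rank-sum bounds 6 and 6n, category sizes
  (32, 45, 45, 20, 10) at n = 152, smoothing linearity and circular
  mean preservation.
* Independent oracles: a coarse-to-fine grid search over the Poisson
  log-likelihood (decorrelated parametrization, concavity guarantees
  the zoom) checks IRLS to 1e-3 on 20 random small datasets; a second
  GLM implementation cross-checks coefficients and SEs; hand-enumerated
  rank examples check the detector.
* Simulation properties, at the default study conditions: with full
  reporting, region rate ratios and the rural slope are recovered
  within 2 Wald SEs for ≥ 90% of parameter-replicate pairs over 50
  replicates (pooled per-parameter coverage, the standard
  simulation-study metric); with thinning on, the region-adjusted
  index-category IRs rise from "best" through "bad" and dip in "worst"
  in the majority of 20 replicates; and the low-reporter rule catches
  true underreporters at a pooled rate above the q² = 0.16 independence
  baseline over 20 replicates. The rise-then-dip check uses the
  region + categories model without the continuous rural term: the
  generator's entire deprivation–rate channel is the log-linear rural
  effect, so a model containing that exact term absorbs the gradient
  and leaves the categories to express thinning alone; the categorical
  gradient is the phenomenon of interest.
* Pipeline: byte-identical outputs under identical config and seed
  (headers carry version, config hash and seed, never timestamps), and
  validation failures abort with the offending table, row and column
  named.

Problem sizes in the test suite (152 municipalities, 20–50 replicates,
5 simulated years) are the package's default study conditions; each
replicate runs in well under a second, so the full suite completes in a
few seconds.

## Known limitations

* The deprivation–reporting link is assumed monotone and piecewise
  linear; the analysis modules make no such assumption, but their
  measured sensitivity does depend on it.
* Ward-with-connectivity clustering is greedy; it reproduces clearly
  separated climate/location groups but is not guaranteed to find the
  globally optimal contiguous partition.
* Wald intervals can be poor for categories with very few cases;
  profile-likelihood intervals are out of scope.
* The low-reporter rule compares within regions only; a region that is
  uniformly underreporting leaves no within-region contrast to detect.
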
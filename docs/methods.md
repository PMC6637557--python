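# Methods

## The problem

Satellite-tagged blue whales in an eastern-boundary upwelling system switch
between two movement modes: fast, directed *transiting* between prey patches
and slow, tortuous *area-restricted search* (ARS), taken as a proxy for
foraging.  A Bayesian switching state-space model (fitted upstream; its
outputs are this package's inputs) turns raw Argos fixes into one location
per day with (i) a continuous behavioral-mode value in [1, 2] and (ii) a
posterior 95% credible-limit box in longitude and latitude.  This package
implements everything downstream of that model: filtering, environmental
annotation, a nonparametric habitat model of ARS likelihood, climatic-regime
cross-validation, binary-classification assessment, and spatial
autocorrelation diagnostics.

## Track preparation

A mode value above 1.75 is classified ARS, below 1.25 transiting, anything
between is *uncertain* (strict inequalities; both boundaries are uncertain).
Track-level retention requires duration > 14 d **or** cumulative great-circle
path length >= 888 km (a disjunction: short but fast tracks stay).
Location-level rules, applied in a fixed order so removal logs are
comparable across runs: study months (July-November), study-area polygon
(boundary points count as inside), credible-limit half-width above 100 km,
uncertain mode, unclassified terminal locations, and seafloor depth beyond
2000 m.

Two conventions deserve note:

* **"100 km in radius"** is interpreted as the larger of the two
  credible-limit half-widths, converted to km at the point's latitude
  (1 degree latitude = 111.32 km; longitude scaled by cos(latitude)).  Max
  across axes is the conservative reading of a box radius.
* **Terminal locations** are identified by their missing behavioral-mode
  value (the state-space model does not classify the last location of a
  track), not by position alone.  This keeps the filter idempotent:
  re-filtering an already-filtered track removes nothing.

All great-circle distances use the haversine formula on a 6371-km sphere.

## Environmental annotation

Each predictor value is a kernel-weighted average over the grid cells whose
centers fall inside the location's credible box (half-open on the east and
north edges, so a cell belongs to exactly one adjacent box).  The weight
decays with great-circle distance d from the estimated location,

    w(d) = (1 - (d/d_max)^2)^2,

a smooth Bézier-profile taper reaching 0 at the farthest box corner
(d_max).  The profile function is injectable for sensitivity analysis.  For
time-resolved grids the nearest time slice within one native compositing
period is used; otherwise the value is missing.  A value is missing only if
no non-missing cell center lies in the box — averaging over the box rather
than taking the nearest pixel is also what keeps cloud-masked products
usable.

Variables with a basin-scale latitudinal trend (temperature, sea-surface
height) are detrended with a locally linear loess smoother on latitude
(tricube weights, span 0.75), giving "spatial anomaly" predictors.  A loess
smoother is not a projection, so detrending is only *nearly* idempotent: a
second pass moves anomalies at the sigma/sqrt(span x n) level (about 2% of
the anomaly scale at n = 1000), which the test suite checks in place of
exact idempotency.

Collinear predictor pairs (pairwise-complete Pearson |r| >= 0.7) are
resolved iteratively: the pair with the largest |r| loses its member with
the lower single-predictor logB, until no flagged pair remains.

## The habitat model (NPMR)

The response is binary: presence (1) of ARS versus absence (0, transiting).
The estimate at a target point is a leave-one-out weighted average of the
response over all other sample units, with multiplicative Gaussian kernel
weights — one factor per continuous predictor, standard deviation sigma_j
(the predictor's *tolerance*), and an exact-match indicator for categorical
predictors such as individual identity.  The weight sum at a target is its
neighborhood size n*; estimates are withheld where n* < n_min.

Because the published definition of n_min (0.25 x average neighborhood
size) is circular with the set of rows that receive estimates, it is
resolved in one pass: n_min = 0.25 x mean n* over all complete-case rows;
the sample units SU are those with n* >= n_min; N_ave is the mean n* over
SU.

Fit statistics over SU rows, with p-bar the observed prevalence:

* logB = sum log10 [ L(y_i | y-hat_i) / L(y_i | p-bar) ], Bernoulli
  likelihoods; estimates are clamped to [eps, 1 - eps] with eps = 1/(2 SU)
  so a pure neighborhood cannot contribute an infinite term.
* B_ave = 10^(logB / SU), the per-unit likelihood ratio.
* xR^2 = 1 - SSE/SST (cross-validated pseudo-R^2), r = Pearson(y, y-hat),
  chi^2 = 2 ln(10) logB.
* The naive model (y-hat = p-bar everywhere) has logB = 0, B_ave = 1,
  xR^2 = 0 exactly.

*Sensitivity* Q_j nudges each row's predictor j by +/-5% of its range,
re-estimates (leave-one-out, against unperturbed neighbors), and averages
|change in estimate| over rows and directions, divided by the nudge
fraction.  Q = 0.71 therefore reads: a 20% predictor change moves the
estimated ARS likelihood by about 14% of its range.

*Model search* is forward-stepwise ("free search"): every candidate is
scanned over a tolerance grid (5%-100% of its observed range in 5% steps,
larger tolerances preferred on ties); the best size-k model's predictors
and tolerances are kept and each remaining candidate is scanned as an
extension.  A larger model is accepted only if logB improves by at least 5%
of the incumbent's (or by 1.0 when the incumbent's logB <= 0), and model
size is capped at one predictor per 30 rows.  *Tuning* then refines each
tolerance coordinate-wise over +/- one coarse step in 1%-of-range
subdivisions until a pass gains < 0.01 logB; it never lowers logB.

*Validation* under a different climatic regime holds the building-set
tolerances fixed and estimates validation rows against the building rows
(no leave-one-out; an identical row simply includes itself as neighbor).
n_min is recomputed on the validation neighborhoods, which shrink when the
new rows occupy sparse predictor space.

*Uncertainty*: logB confidence intervals by case-resampling bootstrap
(refit per replicate, percentile interval); significance by shuffling the
response and re-running the full free search per replicate, with
p = (1 + #{null >= observed}) / (1 + R) so p is never zero.

## Classification assessment

Continuous estimates become presence/absence at the cutoff (among the
unique estimate values plus 0 and 1; presence iff estimate >= cutoff) that
maximizes TSS = TPR + TNR - 1; ties go to the lowest cutoff.  The report
includes the confusion cells, prevalence (observed and predicted),
accuracy, precision, the rates, AUC (pairwise concordance with ties at
1/2), RMSE and the Brier score (= RMSE^2).  Rows without an estimate are
excluded from every denominator and counted explicitly — which is why a
fitted model can report fewer classified rows than complete cases.

## Spatial diagnostics

A purely spatial model (longitude x latitude, both forced) is fitted by an
exhaustive two-axis tolerance scan plus tuning.  Its axis tolerances,
expressed as percent of range, give the anisotropy of the behavioral field.
Sample variograms (Matheron estimator, great-circle lags, default 20-km
bins to 500 km) of neighborhood size and of the estimates, for both the
spatial and environmental models, localize residual autocorrelation scales.
The recovered correlation range of a field is read off the variogram as the
lag where semivariance first reaches 95% of the sill (taken as the sample
variance), linearly interpolated between bins.  No variogram model is
fitted.

## Synthetic data: what it emulates, and what it does not

The simulator is the test bed: a two-state correlated random walk with
gamma step lengths (shape 4; means 81.5 km/day transiting, 27.3 km/day
ARS), persistent headings while transiting and near-uniform turning in ARS.
The daily probability of ARS is a named link function of the local
environment (logistic or Gaussian-bump in chlorophyll by default), so the
true response surface is known.  The mode value is the true state plus
uniform noise within +/-0.2, with 10% of locations drawn inside the
uncertain band (so thresholding recovers the truth exactly on the rest, and
every filter branch is exercised); terminal locations carry a missing mode.
Credible-box half-widths are gamma-distributed (mean 30 km, shape 4), so a
small tail exceeds the 100-km filter.  Fields: lognormal chlorophyll,
temperature with a -0.5 degC per degree-latitude trend plus correlated
anomaly, a static shelf-to-abyss depth ramp, and slope eastness in [-1, 1].
Anomalies are Gaussian random fields built by kernel-smoothing white noise,
with the kernel sd set to range/3.4616 so the variogram's 95%-of-sill
crossing equals the configured correlation range; 15% of dynamic-field
cells are masked to emulate cloud cover.  A "warm regime" switch (negative
North Pacific Gyre Oscillation phase) adds 2 degC and halves median
chlorophyll, depressing ARS probability through the link — the mechanism
behind the building/validation contrast.

Deliberately not emulated: Argos location-class error structure and duty
cycles, sub-daily movement, bathymetric realism beyond the parametric
shelf, and the state-space model itself (the simulator inverts its output
description instead).  Passing tests therefore demonstrate that the
pipeline recovers known structure from data of this form — not that the
movement model is a faithful whale simulator.

## Problem sizes and numerical choices

The bundled demo and the test suite run deliberately small configurations
(a few whales x ~100 days per season; 20-replicate recovery experiments;
49-100 randomizations), chosen so a full run completes in minutes on one
CPU while keeping every statistical check well-powered.  Notable numerical
conventions: tolerance grids and tuning are deterministic with ties broken
toward fewer predictors and larger tolerances; all stochastic operations
take explicit seeds and derive replicate streams by fixed offsets;
zero-variance predictors are dropped as degenerate before correlation
screening; estimates, being weighted means of 0/1 responses, can never
leave [0, 1].

## Known limitations

* The exact Bézier kernel of the original extraction and the precise
  definitions behind the "medium" overfitting controls are not published;
  both are implemented as documented conventions with the discretionary
  constants exposed in configuration.
* The forward free search scans the added predictor's tolerance while
  holding the incumbent's fixed (tuning refines afterwards); a full joint
  re-scan would be costlier and can in principle find different models.
* With weak signals (logB of order 1), the 5%-relative improvement rule
  admits uninformative predictors more easily; the randomization test is
  the guard against over-interpreting such fits.
* Validation-set B_ave values published for the spatial model are not
  reproducible from B_ave = 10^(logB/SU) with the printed SU; the
  environmental rows are, and they anchor this implementation's formula.
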
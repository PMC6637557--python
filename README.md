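# npmrtrack

Habitat modeling of whale movement behavior: does the local environment
predict whether a satellite-tracked blue whale is *foraging* (area-restricted
search, ARS) or *transiting* between prey patches?

The package is a tested, end-to-end pipeline for analysts working with
state-space-processed marine telemetry: it filters regularized daily tracks,
attaches gridded ocean predictors through an uncertainty-aware kernel
extraction, fits nonparametric multiplicative regression (NPMR) models of
ARS likelihood, cross-validates them across climatic regimes, converts the
continuous estimates to presence/absence at the skill-maximizing cutoff, and
diagnoses spatial autocorrelation with variograms.  A first-class synthetic
data generator with known ground truth makes every stage testable without
any data download.

## The model

The response at daily location *i* is `y_i = 1` (ARS) or `0` (transiting),
obtained by thresholding the state-space behavioral mode at 1.75 / 1.25.
NPMR estimates the likelihood of ARS at a target point *t* as a leave-one-out
weighted average of the response,

    ŷ_t = Σ_{i≠t} w_ti y_i / n*_t ,      n*_t = Σ_{i≠t} w_ti ,
    w_ti = Π_j exp( −((x_tj − x_ij) / σ_j)² / 2 ) ,

with one Gaussian factor per predictor (σ_j is the predictor's *tolerance*,
its smoothing scale) combined multiplicatively, and an exact-match kernel
for categorical covariates (e.g. individual).  `n*` is the *environmental
neighborhood size*; estimates are withheld where `n* < n_min = 0.25 N_ave`.
Model quality is `logB`, the base-10 log likelihood ratio against a naive
model predicting the observed prevalence everywhere; model selection is a
forward free search over predictors and a tolerance grid with overfitting
controls, followed by local tuning, bootstrap intervals, and a
response-shuffling randomization test.  Binary skill is assessed with
TSS = TPR + TNR − 1 at the TSS-maximizing cutoff, plus AUC, RMSE and the
Brier score.  See `docs/methods.md` for the full account.

## Worked example

Run the bundled synthetic demonstration (three simulated seasons — two in a
cool, productive regime used for model building, one warm season held out
for validation):

```bash
npmrtrack demo --out-dir demo_run --seed 0
```

which prints

```
environmental model: predictors=['CHL'] logB=15.34 N_ave=53.0
run complete -> demo_run/summary.json
```

The free search recovered chlorophyll — the variable that actually drives
ARS in the simulator's link function — as the sole predictor, with a
likelihood ratio of 10^15.34 over the naive model across 256 classified
building locations and an average environmental neighborhood of ~53
locations.  `demo_run/summary.json` holds the full report; highlights from
this run:

* spatial (longitude × latitude) model: logB = 8.24, with axis tolerances
  of 10.0% (lon) and 2.0% (lat) of range — the simulated field's anisotropy;
* TSS of the environmental model's binary conversion on the building set:
  0.49 at its optimal cutoff;
* randomization test (19 shuffles in the demo): p = 0.05, the smallest
  value 19 shuffles can resolve — the fit is far outside the null;
* variograms of neighborhood size and estimates for both models in
  `demo_run/variograms.csv`, and per-stage row counts reconciled in
  `demo_run/manifest.json`.

The same stages are available programmatically (`npmrtrack.run_pipeline`,
or the individual functions `filter_locations`, `kernel_weighted_extract`,
`free_search`, `predict`, `evaluate_estimates`, `empirical_variogram`, ...)
and as file-based CLI subcommands (`simulate`, `prep`, `extract`, `run`,
`validate-config`).

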
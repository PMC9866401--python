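# Methods

`stemtherm` models the temperature dependence of immature development in
four maize stemborer moths — *Chilo partellus*, *Busseola fusca*,
*Ostrinia nubilalis* and *Sesamia nonagrioides* — and propagates it to a
climate-warming impact metric. This note documents the models, the
numerical choices, and what the synthetic-data machinery does and does not
emulate.

## Thermal performance curves

Development rate `r(T)` (day⁻¹) is the inverse of mean development time at
a constant temperature `T` (°C). The catalog (`stemtherm.models`) holds
eleven classical nonlinear rate models, chosen because each exposes the
critical thermal minimum `CTmin` and maximum `CTmax` as parameters and
admits an optimum `Topt` between them. Linear (degree-day) models are
deliberately absent: they cannot represent the thresholds or the
high-temperature decline.

All curves are evaluated under one contract: the raw formula is clamped to
non-negative values, and the rate is exactly zero at and beyond the
thresholds (`T ≤ CTmin` or `T ≥ CTmax`), because development is null under
thermal stress. Expressions that are undefined outside the domain (square
roots of negative numbers in the Brière forms, overflowing exponentials)
also evaluate to zero rather than propagating NaNs. Whether the original
analyses clamped negative raw values or simply never evaluated outside the
domain is unknowable from the published material; clamping is this
package's contract and is what the tests pin down.

Two equations in the secondary literature are typeset ambiguously
(unbalanced parentheses, orphaned symbols), so the Hilbert–Logan and
Régnière forms were transcribed from their original formulations; the
exact formulas used are recorded in their function docstrings and both are
tested for non-negativity and unimodality on realistic parameter sets. In
the Régnière form the base and lethal temperatures play the roles of
`CTmin`/`CTmax` and the two decay widths are `deltab`/`deltam`.

`Topt` is located numerically: a 0.01 °C grid scan brackets the maximum
(first maximizer wins on ties, i.e. the lower temperature), then bounded
scalar minimization refines it below 1e-4 °C. For the Kontodimas and
Brière-1 curves the stationary points have closed forms —
`(2·CTmax + CTmin)/3` and
`(4·CTmax + 3·CTmin + √(16·CTmax² + 9·CTmin² − 16·CTmin·CTmax))/10` —
which serve as independent oracles for the numeric path (agreement to
1e-3 °C is enforced in the tests).

## Fitting and model selection

Observed mean development times, pooled across source studies per species
× life stage, are inverted to rates and fitted by unweighted nonlinear
least squares with the Levenberg–Marquardt algorithm
(`scipy.optimize.least_squares`). Because LM is local and the likelihood
surfaces are multimodal, each fit runs 20 restarts jittered around a
data-driven start: `CTmin₀ = min(T) − 2 °C`, `CTmax₀ = max(T) + 2 °C`,
shape parameters at fixed defaults, and the scale parameter solved so the
curve passes through the largest observed rate. The best residual sum of
squares wins. Standard errors are the usual Gauss–Newton ones,
`diag((JᵀJ)⁻¹ · RSS/(n−k))^½`, at the optimum.

The information criterion is the Gaussian least-squares AIC,
`n·ln(RSS/n) + 2(k+1)` with one extra parameter for the error variance.
The additive constant dropped by this convention cancels in ΔAIC, which is
all the selection uses. The selection ledger, in order: discard fits with
ΔAIC ≥ 10 from the best; flag fits with ΔAIC ≤ 2 as statistically
equivalent; discard fits whose estimated `CTmin` is below 0 °C or `CTmax`
above 50 °C regardless of their AIC (development of these species is
inhibited by thermal stress at such temperatures — and a fit converging to
a bound is discarded, not clipped); select the lowest-AIC survivor. A zero
RSS maps to an AIC of −∞ with a perfect-fit flag so noise-free round-trip
tests behave sensibly.

Pooling across studies precludes a random study effect in the NLS itself,
so the study-effect check is post hoc: a one-way ANOVA of fit residuals
grouped by source study. That operationalization (residuals, not raw
rates) is this package's choice and is labelled as such in its output.
Residual diagnostics (Shapiro–Wilk statistic, a scale–location slope, and
the full residual table) are exported for inspection; nothing is rejected
automatically.

## Individual-based development simulation

For a cohort of `n` individuals at constant `T`, the rate of individual
`i` in stage `j` is drawn from `N(τ_j(T), cv·τ_j(T))` truncated to
`[0, ∞)`, with `τ_j` the stage curve and `cv = 0.15` — a constant
inter-individual coefficient of variation, shared by all stages and
species, adopted from published estimates for other phytophagous insects
in the absence of species-specific variance data. Draws are independent
across stages within an individual (no correlation structure is asserted
by the underlying biology). Stage times are `1/r_ij`; the total immature
time is their sum; a zero stage rate (τ = 0, outside that stage's thermal
limits) makes the total infinite. All eggs are laid at once; diapause and
temperature-dependent mortality are intentionally outside the model.

Sampling is by rejection (redraw negatives) with an inverse-CDF fallback;
at cv = 0.15 the truncated mass is ~1e-11, so the method choice is
numerically immaterial but must be deterministic: one named seed governs a
run, and each temperature gets its own stream derived from
`(seed, round(1000·T))`, so refining a temperature grid never reshuffles
draws at previously visited temperatures.

An individual fails when its total time strictly exceeds the growing
season of the host plant, 182 days (6 months: the gap between dry seasons
in sub-Saharan Africa, or spring–autumn at temperate latitudes); equality
counts as success. The thermal window `(T50min, T50max)` brackets the
temperatures where at most half the cohort fails, located by a 0.5 °C scan
of [0, 50] followed by bisection to 0.05 °C. With the default cohort of
5000, doubling the cohort moves the bounds by well under 0.05 °C
(verified in the suite). Cohort summaries report the mean and the
empirical 2.5%/97.5% quantiles (order statistics, so infinite times are
handled exactly).

The deterministic companions are the total-rate curve
`r(T) = 1/Σ_j 1/τ_j(T)` — zero wherever any stage is outside its limits —
and its maximum `rmax`, found by grid search on [0, 50] at 0.01 °C. The
simulated median total time agrees with `Σ_j 1/τ_j(T)` to within 2%
wherever all stage rates exceed 0.01 day⁻¹ (the rate distribution is
nearly symmetric at cv = 0.15), which justifies computing the climate
metric below on the deterministic curve rather than by simulation.

A caution established by the test suite: with the shipped parameter sets,
the simulated windows reproduce the published ones for *C. partellus*
(16.6, 37.1 °C) and *B. fusca* (15.2, 33.0 °C) but not for the other two
species — the published *O. nubilalis* upper bound (38.9 °C) exceeds that
species' own pupal `CTmax` (36.3 °C), which no simulation from those
parameters can produce. The two reproducible species are the regression
anchors; the discrepancy is documented, not papered over.

## Climate impact metric

Monthly mean near-surface temperatures per region come from an ensemble of
global circulation models (GCMs), as flat tables
(`region, scenario, gcm, year, month, tas_C`) in the shape of the IPCC WGI
Interactive Atlas regional exports (the reader normalizes scenario
spellings; regions arrive pre-aggregated). For each GCM, calendar-month
climatologies are averaged (equal month weights) over 1990–2014 for
current conditions and 2081–2100 for the future under SSP1-2.6 or
SSP5-8.5; any missing year-month is a hard error naming the gap.

The metric is `r/rmax`: the deterministic total rate at the monthly mean
temperature divided by the species' maximum rate — the fraction of maximal
development attainable that month, in [0, 1], exactly 0 if any stage
cannot develop. The impact of warming is the per-month difference
future − current, in [−1, 1]: positive when warming moves the month toward
the optimum, negative when it overshoots toward (or past) `CTmax`.
Across-GCM summaries report the mean, extrema and quartiles per month;
GCMs present under only one scenario are skipped (ensemble sizes are
properties of the data, and the reader reports the counts).

## Synthetic data

The observation generator mirrors how literature means arise: it simulates
`n_reps` individuals per study × temperature × stage under the same
truncated-normal rate model the simulator assumes, and records the mean of
the individual times (not a noised-up rate), optionally multiplied by a
per-study bias to inject a study effect. Combinations where the true curve
predicts no development are omitted, as real rearing studies report no
time there. Defaults — 50 replicates per temperature, cv = 0.15, rearing
temperatures chosen inside the curve's domain — reflect the cohort sizes
and designs typical of the source rearing studies. Stage totals are
generated directly; per-instar larval times are not modelled (the
instar-level bookkeeping of the source studies is not recoverable).

The ensemble generator is shift-plus-noise plumbing: a 12-month baseline,
a warming offset per scenario (defaults 1.5 °C for the low-emission and
4 °C for the high-emission pathway, indicative end-of-century regional
values), a once-per-GCM shift (default sd 0.5 °C) for between-model
disagreement, and interannual noise (default sd 0.5 °C). It emulates no
spatial fields, trends within periods, or autocorrelation — it exists so
the impact pipeline's schema, statistics and invariants are testable
without downloads. Consequently, green tests certify the pipeline's
arithmetic and determinism, not the realism of any particular climate
projection; real Atlas exports can be dropped in through the same reader.

## Problem sizes and runtimes

The suite and the acceptance script use the analysis-scale settings
directly — 5000-individual cohorts, 0.5 °C scans with 0.05 °C bisection,
0.01 °C grids for optima — since a full four-species window computation
takes on the order of a second. The parameter-recovery study runs 100
seeded datasets of 6 rearing temperatures × 50 replicates. The
failure-fraction oracle integrates the truncated-normal stage-time laws by
discretizing each on a 0.02-day grid up to the deadline and convolving;
its agreement band with the 5000-draw Monte Carlo estimate is 0.02.

## Known limitations

Constant-temperature development only: no daily temperature fluctuation,
no rate summation over a temperature series, no microclimate (stem
interiors, canopy shade), no diapause induction/termination, and no
temperature-dependent mortality — each of which can alter field phenology.
The cv is assumed temperature- and stage-independent. Monthly regional
means smooth over exactly the extremes (heatwaves above `Topt`) that
damage development nonlinearly, so impacts near the optimum are likely
conservative. Parameter uncertainty from Table-level standard errors is
carried but not propagated into the windows or the impact metric.
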
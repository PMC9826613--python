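# Methods

This note records the conventions, model definitions and design
choices behind `reefstress`, in the spirit of a statistical methods
appendix.  Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Temperature ingestion and daily summaries

Logger exports are CSVs with a timestamp and a temperature column; the
`LoggerDialect` names both and optionally fixes a strftime format (a
HOBO-style preset is provided).  Rows are sorted by time; duplicate
timestamps are averaged with a warning; a timestamp or temperature
that fails to parse is an error naming the line.  Temperatures must be
finite and inside a sanity band (default −5…45 °C) — no despiking or
depth/tide correction is attempted beyond that band.  The two loggers
used in a deployment may differ in accuracy (e.g. ±0.21 vs ±0.53 °C);
this is carried as a label only, never as a correction.

Days are bounded by the logger clock's calendar midnight; no timezone
arithmetic.  A day is QC-valid when it has at least `min_obs`
observations (default 20 of 24 hourly readings — tolerant of short
gaps without letting a half-day bias the daily extremes).  Partial
days at deployment/retrieval therefore appear flagged `valid=False`
rather than silently dropped.  All thermal indices ignore invalid
days; this invariance is property-tested.

Year-to-year pairing is by calendar (month, day), restricted to days
valid in both years; Feb 29 is excluded so every pairing unit exists
in both years.

## Thermal indices

All indices are referenced to MMM_max, the mean over (year, month) of
the monthly mean of daily-mean temperature for the two warmest months
(July and August) of the study years.  Using the bleaching years' own
summer maximum makes the reference high and the resulting accumulation
small; the indices rank heat stress *between years at one site* and
deliberately do not reproduce satellite degree-heating-week semantics
(90-day rolling windows, long-term climatology, alert thresholds).

* **Hotspots.**  HS_i = STSP_i − MMM_max, computed from the daily
  *mean* temperature by default.  The `hotspot_basis` switch allows
  the daily maximum instead, but the companion degree-heating-day
  index is defined on daily means with the same reference, and
  seasonal mDHW maxima of a few tenths °C-week are only consistent
  with the daily-mean reading; the mean is therefore the default.
  Negative hotspots are retained — thresholding belongs to the
  consuming index.

* **mDHW.**  Cumulative within the configured heat window (default
  Jul 1–Aug 31): running value (1/7)·Σ HS_i·[HS_i ≥ α] in °C-week,
  α = 1 °C; the seasonal maximum is the final running value.  The
  running series is non-decreasing by construction.  A nominal
  12-week summation limit sometimes attached to this statistic
  exceeds the 62-day window and is treated as notational; the
  accumulation simply runs over the window.

* **DHD** (°C-days): Σ max(0, STSP_daily − MMM_max) over the window —
  no α threshold, so DHD ≥ 7·mDHW_max term-by-term.

* **CSA** (°C-days): trapezoidal integral, at unit day spacing, of the
  hotspot series with sub-α values replaced by 0.  An isolated
  qualifying day flanked by zeros contributes a triangle; a single-day
  window has no interval and returns 0 with a warning.

* **DHM** (°C-month): monthly hotspots MHS_m = monthly mean − MMM_max,
  summed over the year where MHS_m ≥ α.

* **Acute 1 / acute 2** (% of days): share of valid days in the year
  with HS ≥ 1 °C and ≥ 2 °C.

* **max3d** (°C): maximum 3-day running mean of daily means over runs
  of consecutive valid days in the heat window (`max3d_basis`
  switches to the maximum single daily-max reading inside such runs;
  the running mean is the default since a 3-day index describes
  sustained exposure).  Fewer than 3 consecutive valid days is an
  error, not a silent 0.

* **Heating rate 1** (°C/day): DHD divided by the number of days with
  STSP_daily above MMM_max; undefined (None, flagged) when no day
  exceeds.

* **DTR statistics**: mean daily temperature range over the year
  (DTR-total) and the heat window (DTR-heat); shape of DTR-total as
  moment skew g1 = m3/m2^1.5 and *excess* kurtosis g2 = m4/m2² − 3
  with population (divisor-n) central moments.  Constant DTR leaves
  the shape statistics undefined rather than 0.

## Environmental tests

The repeated-measures unit for between-year comparisons is the
calendar day: the Friedman test runs with blocks = month-day pairs and
k = 2 treatments (years) — degenerate (it reduces to a sign test with
tie correction) but faithful to the blocked design.  Within-block ties
get average ranks and the standard tie correction; a fully tied table
yields statistic 0.

The Wilcoxon signed-rank test drops zero differences, uses average
ranks, and computes the two-sided p exactly for n ≤ 25 by dynamic
programming over sign assignments on a 2×-scaled rank grid (valid
under ties); beyond that, a normal approximation with continuity and
tie corrections.  Its default pairing unit for cumulative series
(running mDHW) is the day pair; weekly pairing is a caller choice.
The Mann-Whitney U test reports U for the first sample and the
tie-corrected Z; p is exact (Gaussian-binomial recursion) for two
small tie-free samples, otherwise the continuity-corrected normal
approximation.  McNemar's test uses the discordant counts with the
continuity correction by default (switchable); no discordant pairs is
a degenerate-input error.

**Heating-rate contrast.**  The pre-peak window for each year ends the
day before the Monday of the ISO week with the highest mean daily
temperature (ties to the earliest week) and reaches back 3 calendar
months, truncated with a warning at the record start.  Daily means
from both windows enter one regression on time (days from window
start), year, and time×year, with AR(1) errors within each year.  The
fit is full ML (single-model inference on a fixed design; REML's
fixed-effects-invariance rationale buys nothing here): for candidate
ρ the data are whitened by the Prais-Winsten transform per year, β and
the innovation variance profiled out, and the profile likelihood
maximised over ρ ∈ (−0.999, 0.999); ρ̂ within 0.02 of the bound warns.
A Wald z on the interaction answers whether the years heated at
different rates.  At ρ = 0 the estimator reproduces OLS exactly, and a
0.001-step grid search over ρ agrees with the optimiser (tested).

## Colony survey accounting

Colony size is ln of the mean diameter MD = 2√(PA/π) from the planar
area under a circular-colony assumption (elliptical refinements have
been found to change PA negligibly for these growth forms).  Colonies
below 3 cm MD at first sighting are excluded at ingest.  The t1 growth
rate is (PA_2017 − PA_2016)/PA_2016: 0 = no change, negative =
shrinkage from partial mortality, positive = growth.  (Descriptions of
this quantity that put the no-change point at 1 describe the ratio
PA_end/PA_start; the difference ratio with its natural zero is used
here.)

Analysis groups are the two dominant species, the tabular growth form
(tabular species being hard to separate morphologically), and
"others"; any named group under 9 colonies collapses into others.
Bleaching is UB < PB < CB, where PB includes a uniformly pale colony —
paleness is an input label, not an image computation.  Bleaching-rate
denominators are the colonies with a state recorded at that year's
survey; trajectory denominators are per-group colonies scored in both
years, and each group's nine transition cells sum to 100 %.

Mortality is scored per interval (t1 = Apr 2016–Apr 2017,
t2 = Apr 2017–May 2018) as whole (entire colony dead) or partial (part
died, living tissue remained), mutually exclusive; a colony dead at
the interval start is excluded from the risk set, never scored (0, 0).
Model frames differ by risk set: the two-year bleaching frame has two
rows per colony scored in both years (size = ln MD at the preceding
April); the whole-mortality frame includes every colony alive at each
interval start; the partial-mortality frame only interval survivors.
Rows missing a covariate are dropped with a logged count.

## Likelihood machinery

**Ordinal model.**  P(Y ≤ j | x) = logistic(θ_j − xβ) with θ strictly
increasing, so positive β pushes toward the more-bleached end — the
sign convention matters for probability surfaces and is fixed
package-wide.  Optimisation is quasi-Newton (L-BFGS with analytic
gradients) on (θ_1, log-increments, β), started at the empirical
cumulative logits; convergence requires a follow-up polish to move the
log-likelihood by < 1e-8.  The covariance matrix is the inverse
observed information, obtained by central differences of the analytic
gradient in the natural (θ, β) space.  Quasi-separation is flagged
when any standardized slope exceeds 15.

**Logistic model.**  Newton-Raphson with step-halving; convergence at
log-likelihood change < 1e-8.  Separation (which interaction-rich
mortality models invite on small cohorts) is flagged when a
standardized coefficient passes 15 while the likelihood still
improves; the fit is returned flagged rather than failed, since the
likelihood-ratio statistics remain usable.

**Selection.**  Backward elimination: each round tests the removal of
every candidate term, honouring marginality (an interaction leaves
before its main effects), drops the single term with the largest
p > 0.05, and stops when all candidates are significant.  Comparisons
are against the current model by default; `compare_to="full"` keeps
the full model as the reference, matching a stricter reading of
"compared nested models with the full model".  The trace records round,
term, N, df, LRT and p for every comparison — enough to reconstruct a
report-ready selection table.

**Brant test.**  The J−1 threshold logits of 1{Y > j} are fitted on
the same design; the joint covariance of their slopes uses the
shared-observation weights w_jl = π_l − π_j π_l (j ≤ l); slope
equality across thresholds is a Wald χ² per variable and for the whole
model, df = (J−2)·(number of slopes).  Near-boundary category
frequencies (e.g. almost no unbleached colonies in a severe year)
push the threshold logits toward separation; the result then carries a
separation flag and the Wald statistic degrades gracefully toward 0.

**Adjusted contrasts.**  All pairwise differences of a factor's levels
on the link scale, with single-step max-|Z| adjustment: the reference
distribution of the largest absolute standardized contrast is
evaluated by scrambled-Sobol quasi-Monte Carlo (2^16 points, fixed
seed — deterministic) in the coefficient space, because the contrast
covariance itself is singular.  Holm and Bonferroni are available
alternatives; outputs are labelled with the method.

**Random-intercept check.**  The selected model is refitted with a
colony-level Gaussian random intercept, integrating the marginal
likelihood by 15-node Gauss-Hermite quadrature (for a scalar random
effect this is effectively exact, and simpler to verify than a Laplace
approximation).  The variance is tested against zero by a
likelihood-ratio test with the boundary correction (p halved), and the
report records whether any fixed-effect conclusion changes.

## Synthetic data

Hourly temperature: base mean + annual cosine peaking in early August
+ diurnal cosine peaking at 14:00 + additive box-car anomalies + AR(1)
noise (ρ is the hour-to-hour correlation; `noise_sd` is the stationary
SD, innovations scaled accordingly).  Box-car anomalies keep the
index oracles closed-form: a +1.5 °C, 3-day episode on an at-reference
baseline must yield exactly 4.5/7 ≈ 0.643 °C-week.

Colony cohorts: per-group sizes; ln MD drawn normal; bleaching states
drawn from the proportional-odds model with linear predictor over
time, ln MD, group offsets and (for the second year) the t1 growth
rate; whole then partial mortality drawn from logistic models
(mutually exclusive by construction); growth for a partial-mortality
colony is deterministically −`partial_shrink`, otherwise drawn
truncated at zero, so shrinkage and partial mortality coincide exactly
and the growth–bleaching association is controllable.  Every generator
is a pure function of config + seed (bit-identical repeats,
property-tested).

The `study-shaped` preset describes a repeat-bleaching field scenario:
four groups of 39/40/18/26 colonies; bleaching cutpoints
(−5.15, −2.20) and β_time = −3.41 — the least-squares proportional-odds
fit to target marginal rates of ~93 % completely bleached in year 1
against ~71 % partially / ~18 % completely in year 2; ln-size SD 0.65
(diameters ~2–30 cm); whole-mortality coefficients reproducing ~36 %
(A. digitifera) to ~70 % (A. gemmifera) first-interval mortality with a
marginal decline in t2; partial mortality rising steeply with size in
t1 only (a size×time interaction); summer means of 29.88/29.98 °C so
the computed MMM_max lands at 29.9 °C, with one or two short anomaly
days giving seasonal mDHW maxima of a few tenths °C-week.  A `null`
preset zeroes all effects; `strong-effects` provides large time, size
and growth coefficients for power studies.

What the generator does *not* emulate: spatial structure among plots,
tides and stratification, non-sinusoidal weather, misclassification of
bleaching states, and measurement error in planar areas.  Passing
tests therefore validate the statistical machinery under the assumed
models, not the field protocol.

## Problem sizes and numerical choices

The validation suite runs at desk scale, chosen to finish in minutes
on one core: oracle equivalence of the index implementations against
naive day-loop re-implementations on 1,000 random series at 1e-12;
null calibration on 2,000 simulated datasets per nonparametric test,
1,000 for the logistic LRT (with a Kolmogorov-Smirnov check against
χ²₁) and 500 for the Brant test (acceptance band 0.03–0.08 at nominal
0.05); ordinal effect recovery over 200 replicates of 400 colonies ×
2 years; AR(1)-GLS slope recovery over 200 replicates of 90 days ×
2 years (|bias| < 0.005 on a slope of 0.05); selection consistency
over 100 study-shaped replicates.  One caveat is documented rather
than hidden: with a 123-colony cohort and near-universal complete
bleaching in year 1, the df-3 group LRT is slightly anti-conservative
(≈8 % null rejection at nominal 5 % in 300 simulations), so backward
selection ends at the time-only model in ≈88 % of replicates rather
than the ≥95 % that perfectly calibrated α = 0.05 tests would give;
the corresponding suite check is left strict and failing to keep the
discrepancy visible.

Convergence tolerances are 1e-8 on the log-likelihood for both GLMs;
the AR(1) profile search uses |ρ| < 0.999 with 1e-8 x-tolerance;
separation bounds are |β_std| > 15.  Ties in rank tests always use
average ranks.  Exact-test cutoffs: Wilcoxon n ≤ 25, Mann-Whitney
n ≤ 12 per sample without ties.
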
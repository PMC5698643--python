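# Methods

`grousepheno` implements a complete climate–phenology–demography analysis
for a two-species boreal forest grouse system (capercaillie *Tetrao
urogallus* and black grouse *T. tetrix*) observed over a multi-decade
August survey series, together with a synthetic-data generator that
emulates the study system so the entire pipeline can be exercised, tested
and replicated without field data.  This note documents the models, the
parameters that matter, the numerical conventions, and what the synthetic
system does and does not capture.

## 1. Weather and phenological onsets (`weather`)

Daily station records (t_min, t_avg, t_max in °C; precipitation; ordinal
snow score 0–5) are transferred to the study site with a fixed lapse rate
(default 0.65 °C per 100 m; `elevation_diff` is site minus station, so a
site above the station is made cooler).  Three per-year onset statistics
are derived:

* **Snow-free date** — earliest day (scanning 1 Jan–30 Jun) with snow
  score ≤ 0; the first occurrence counts even if snow returns.
* **Frost-free date** — centre day of the first 7-day window whose mean
  t_min exceeds 0 °C.  A *centred* moving average is used (symmetric
  smoothing is the standard phenological reading of a "7-day moving
  average"); the crossing rule is "first positive mean", with no
  persistence requirement.  Under this rule warming a series can never
  delay the date (a tested invariant).
* **GDD onset ("arrival of summer")** — first day the cumulative sum of
  max(t_avg − 5 °C, 0) from 1 January reaches 200 degree-days.  Winter
  days contribute essentially nothing under the base-5 clamp, so the
  1 January start is an insensitive convention; both base and start are
  configurable.  GDD₅ = 200 is used because it tracks the completion of
  bilberry shoot growth, the host plant of the caterpillars that young
  grouse chicks depend on.

Dates are handled as (year, 1-based day-of-year); windows are closed day
intervals.  Window means fail loudly (`MissingDataError`, with a gap
count) rather than silently averaging over holes; derived onset dates
propagate "missing" instead.  The breeding season (1 Apr–30 Jun, 91 days)
tiles exactly into 13 weekly bins, available as `weekly_windows`.

## 2. Breeding phenology (`breeding`)

Capercaillie peak-mating dates anchor everything.  Defaults: hatch =
mating + 38 days, incubation = 26 days (hence a 12-day laying period) —
values consistent with late-April mating and early-June hatching and with
the interspecific lags below; all are configurable because only the lags
are published.  Black-grouse dates are the capercaillie dates shifted by
+5 (mating), +8 (incubation start) and +6 (hatch) days.

Four analysis windows per species-year, whole days, closed intervals,
"4 weeks" = 28 days: `pre8` [hatch−56, hatch−1], `pre_inc4`
[inc−28, inc−1], `inc` [inc, hatch−1], `post4` [hatch, hatch+27].

Years without an observed mating date inside the observed span are imputed
from the OLS trend of the observed dates and flagged `imputed` so
inference can exclude them; trend imputation (rather than carry-forward)
respects the slow advance of mating and is exactly linear interpolation
when two neighbouring years bracket the gap.

## 3. Survey metrics (`surveys`)

August pointing-dog records per sampling block (hours searched, females
without brood, chick count per brood) are pooled within species-year
before any ratio is formed (ratio of sums, not mean of ratios), yielding

* breeding success = chicks / females,
* brood frequency = broods / females,
* brood size = chicks / broods (missing when no broods),

so breeding success = brood frequency × brood size holds *exactly*
whenever at least one brood was seen.  "Females" counts lone plus brooded
hens: August surveys cannot separate failed breeders from non-breeders, a
documented limitation, not a modelled one.  Encounter rates are birds per
10 h of pooled effort and are invariant to splitting a block's effort into
sub-records.  Input records are assumed deduplicated (double-count
resolution happens in the field protocol, not here).

## 4. Trend and regression battery (`trends`)

* `ols_trend`: OLS of an annual series on calendar year; slope β, its
  s.e., Pearson r, two-sided p, and total change Δ = β × span.  The span
  default is 38 years — the full study-period length — because that
  convention reproduces the printed total changes from the printed slopes
  (×37 does not).
* `gls_ar_compare`: the year-trend model fitted by exact maximum
  likelihood with independent, AR(1) and AR(2) errors (ARIMA(p,0,0) with
  the year as exogenous regressor) so the three AICs are directly
  comparable.  For white-noise residuals the no-correction model is
  expected to win with probability P(χ²₁ ≤ 2) ≈ 0.84.
* `normalized_trend`: β divided by the series mean — a scale-free relative
  trend per year that makes brood frequency and brood size comparable.
* `log_ratio_trend`: OLS of log(yA/yB) on year; tests whether two species
  diverge in relative terms; non-positive years are dropped with a
  warning.
* `slope_difference_test`: t = (β₁−β₂)/√(se₁²+se₂²) with
  Welch–Satterthwaite degrees of freedom from the two residual dfs (the
  df formula is a package choice; only t and p conventions are fixed by
  the field).
* `temp_response`: OLS of an annual metric on an annual window-temperature
  mean (regressor is temperature, not year).
* `partial_regression`: metric on temperature + √rodents + ln fox.  β_p is
  the multiple-regression temperature coefficient; r_p comes from the
  residual-on-residual regression, whose slope equals β_p by the
  Frisch–Waugh theorem (asserted to 1e-10 in tests).  Zero fox indices are
  log-transformed after adding half the smallest positive value, and the
  shift is reported.  A design condition number above 1e8 raises a
  collinearity flag.
* `lagged_response`: metric on mean June–August t_avg one or two years
  earlier ("summer temperature" is interpreted as the June–August mean of
  the daily average).

Two-sided p-values throughout; α = 0.05 with a labelled "near-significant"
band at 0.05–0.10; no multiple-testing correction is applied, matching how
such batteries are reported in this literature — a caveat the output
labels do not hide.  Missing years are handled pairwise per regression.

## 5. Mismatch analysis (`mismatch`)

The mismatch offset of a species-year is hatch day minus the GDD₅ = 200
day (negative = hatched before summer onset).  Breeding success is
regressed on the offset with first- and second-order polynomials; the
model is chosen by AICc (small-sample AIC, the appropriate criterion at
n ≈ 38 with 2–3 parameters; parameter count includes the error variance).
The overall p is the F-test against the intercept-only model.  A concave
quadratic yields the estimated optimum −b₁/(2b₂).  Pooling imputed
phenology years into the fit is accepted (they are flagged upstream for
anyone who wants to exclude them).

## 6. Synthetic study system (`simulate`)

One integer seed generates the four mutually consistent inputs.

**Weather.**  t_avg = annual-mean 4.0 °C + 11.5 °C sinusoid peaking on
day 200 + month-specific linear warming + AR(1) noise (φ = 0.6, innovation
s.d. 2.7 °C).  Warming slopes default to the study system's published
monthly values (April 0.050/0.069/0.101 °C/yr for min/avg/max; May and
June as printed; a 0.03 °C/yr background elsewhere).  t_min and t_max are
t_avg minus/plus positive spreads whose own monthly trends reproduce the
min/max slopes; a 0.5 °C floor keeps the ordering strict by construction.
Snow score is a banded function of the 15-day smoothed t_avg (score 0 at
≥ 4 °C), which melts out every spring and earlier in warmer years.  The
noise level was calibrated, before any testing, to the study's printed
year-to-year standard errors of monthly and window means (≈ 0.20–0.24,
i.e. an annual window-mean s.d. of ≈ 1.2–1.4 °C).

**Covariates.**  Rodents: mean 3 + 2.5·sin cycle (period 3.5 yr) +
0.22 × same-year summer-temperature anomaly + noise, floored at 0.05.
Fox: 1 + 0.078 × last year's rodent index + noise.  Both couplings are the
published values and are recovered by regression in expectation (tested).

**Breeding phenology.**  Capercaillie mating = day 118 − 0.12·year +
0.10 × frost-free anomaly + noise (s.d. 1.5 d).  The configured −0.12 is
the direct trend; the realized total advance is slightly steeper (≈ −0.14
day/yr) because the spring-onset coupling itself trends — a structural
feature, which is why the recovery test switches the coupling off.

**Demography.**  Per species-year, females ~ Poisson(22) (with ~12 other
birds per species this yields ≈ 130–150 classified birds/year, matching
the reported survey intensity).  Each female broods with probability
logit⁻¹(a_s + b_s·T_preinc + 0.25·√rodents − k_s·offset²); brood size is
1 + Binomial(7, q) with logit q = d_s + 0.08·T_post − m_s·offset².
Baselines give brood frequencies ≈ 0.37/0.50 and brood sizes ≈ 3.8/4.2
(cap/bg).  Link slopes are scale-matched to the published linear
regression coefficients: b_cap = 0.21 on the logit ≈ 0.049 per °C on the
probability scale at baseline; b_bg = 0 (the published black-grouse
pre-hatch response is null); 0.08 on the chick logit ≈ 0.13 chicks per °C
at baseline.  Brood size is a *clutch-thinning binomial* rather than a
truncated Poisson: chicks in August are survivors of a 7–9 egg clutch, so
binomial thinning is the realistic chick-survival model, and it reproduces
the annual brood-size variability implied by the published β/r pairs
(≈ 0.5 chicks s.d.), which a truncated Poisson at ~7–9 broods/year
roughly doubles.
The mismatch penalty is asymmetric between species and channels, mirroring
the published pattern: an egg-stage penalty (k = 0.003 logit/day²) only in
capercaillie — black grouse, which hatches ~6 days past the summer-onset
date yet shows no pre-hatch temperature response in the field, gets none —
plus a mild chick-stage penalty (m = 0.001) in both.  Observations are
scattered over 25 blocks with U(8, 15) h effort; no block geography is
modelled.

Two named variants: `null()` switches off every demographic driver (for
type-I-error studies: indices become pure sampling noise), and
`mismatch_emphasis()` places a single strong chick-survival penalty
(m = 0.01) at zero offset with all other drivers off (for studying the
polynomial mismatch machinery in isolation: breeding success then responds
to nothing but the hatch-vs-summer offset).

**What the generator does not emulate.**  No spatial block structure or
observer effects, no double counts, no individual predator behaviour, no
year-to-year population feedback (breeding success is generated, not
propagated into next-year abundance), no precipitation effects, and
month-boundary steps in the warming trend rather than a smooth seasonal
trend field.  Passing tests therefore demonstrate that the *pipeline*
recovers the structure this generator encodes at field-realistic noise;
they do not validate the ecological model against real data.

## 7. Replication studies and problem sizes

The replicated checks run 38-year studies end to end (generator →
phenology → windows → indices → regressions): 200 replicates for
sign-recovery of the three configured temperature effects and for the
centring of the black-grouse null (operationalized as |mean β̂| ≤ 0.02,
under half the configured capercaillie effect), 300 null replicates for
the type-I error of the temperature response (nominal 0.05 within three
Monte-Carlo standard errors), and 200 mismatch-emphasis replicates for
quadratic selection and vertex recovery (|mean optimum| ≤ 3 days).  These
sizes put Monte-Carlo error comfortably below the assertion margins while
keeping the whole suite desk-scale.  `scripts/acceptance.py` averages 40
replicate studies.

## 8. Known limitations

* The AR-error comparison refits with ARIMA maximum likelihood; for very
  short series (n ≈ 6) individual structures may fail to converge and are
  reported as failures rather than raised.
* The mismatch optimum −b₁/(2b₂) is unstable when the fitted curvature is
  near zero; it is reported only for concave fits, and replication
  averages should be taken over AICc-selected quadratic fits (as the tests
  do).
* Normalized trends require a positive series mean and are undefined
  otherwise.
* The black-grouse null centring bound absorbs a small structural bias:
  both the warming trend and (through the shared spring) the rodent
  channel couple weakly to pre-incubation temperature across years.
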
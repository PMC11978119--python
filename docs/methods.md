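# Methods

`lifexpect` estimates life expectancy (LE), loss of life expectancy and
discounted lifetime healthcare cost for a registry cancer cohort whose
follow-up is far shorter than its remaining lifetime. The estimator family
is the semiparametric relative-survival extrapolation used for
registry-based LE studies: observed survival is carried to the lifetime
horizon by modelling how the cohort's survival *ratio* to demographically
matched referents evolves, rather than by fitting a parametric lifetime
distribution to the observed window alone.

## Model and procedure

**Matched referents.** For every patient, `n_replicates` referents with the
same sex, age and calendar year at the index date are walked month-by-month
through the national life table (annual death probability q converted to a
constant-within-year monthly survival factor `(1-q)^(1/12)`). Attained age
and calendar year advance together at index anniversaries; calendar years
beyond the table reuse its last year (period convention) and ages beyond the
terminal age die with certainty, so the walk terminates by the age cap
(110 by default). The pooled survivor fraction S_r(t) is the reference
curve. Sampling is by inverse CDF of each entry cell's discrete death-month
distribution, which is distribution-identical to the Bernoulli walk and
seed-deterministic. The referent age/sex/year mix equals the patient mix by
construction.

**Observed survival.** Patient survival S_p(t) is the product-limit
(Kaplan-Meier) estimate on the month grid, with deaths processed before
censorings within a month. Months whose risk set has fallen below
`min_at_risk` (default 25) are discarded before extrapolation: under
staggered entry the far tail of the KM curve is supported by a handful of
the earliest-diagnosed patients and goes artificially flat, and a fit
anchored there tilts the extrapolated ratio upward.

**Estimability.** The method assumes patients fare materially worse than
referents. A stratum is extrapolated only when the observed-window area
under S_p is (i) below `auc_ratio_threshold` (default 0.98) times the area
under S_r **and** (ii) below it by at least `estimability_z` (default
1.645) standard errors of the ratio, with the SE from the Greenwood-type
restricted-mean variance of the KM curve. The significance clause exists
because a fixed margin alone cannot separate true excess mortality from KM
noise in small strata: without it, about 13% of no-excess cohorts of 500
patients would slip through; with it the refusal rate under the null is
~97%. A stratum is also refused when more than `max_ratio_violations`
(default 20%) of observed months have ratio ≥ 1. Refusals are reported as
results ("–" rows), not errors — early-stage strata behave exactly this way
in national data.

**Logit-ratio rolling extrapolation.** For observed months the series
W(t) = logit(S_p(t)/S_r(t)) is formed; months with ratio outside (0,1) are
masked, not imputed. A restricted cubic spline in time (4 knots at the
0.05/0.35/0.65/0.95 quantiles of the window, linear beyond the boundary
knots — Harrell's truncated-power basis, ordinary least squares) is fitted
over a rolling window and its linear tail predicts W one month ahead;
survival follows as S_p(t+1) = expit(W)·S_r(t+1). The prediction is
appended as data, the window's oldest month dropped, and the step repeated
until S_p ≤ `epsilon` (1e-4), the referent curve is exhausted, or the
horizon cap (youngest patient reaching the age cap) is hit — the last case
flags LE as a truncated lower bound. For consecutive windows the one-step
prediction is a fixed linear functional of the window's W values
(translation equivariance), so the whole loop is a sequence of dot
products.

**Window length.** The window defaults to 75% of the valid observed months
rather than a short fixed span. A simulation calibration (three-stratum
registries, excess hazard 2 and 4, ~5,000 patients per stratum, 8–12
replicate seeds per setting) showed that a 24-month window anchors the
extrapolation on the noisiest end of the KM curve and yields LE errors of
±15–25%, while near-full windows stabilise the fitted trend; 75% keeps
enough early months out of the window for the rolling scheme to matter.
Fixed-length windows remain available via `ExtrapolationConfig.window`.

**Unit of analysis.** Extrapolation operates within age bands
(20–64 / 65–74 / 75–89), as in registry practice. The pooled ratio of a
cohort mixing widely different ages flattens as younger patients come to
dominate the tail, and no local-trend extrapolation tracks that shape;
within bands the ratio is close to the proportional-hazards form the
method expects. Cohort-level estimates are patient-weighted aggregates of
band estimates (`estimate_age_banded`); the identity loss + LE = referent
LE is preserved exactly by construction.

**LE and loss of LE.** LE is the trapezoidal area under the monthly curve
divided by 12 (second-order accurate on the month grid); loss of LE is
referent LE minus patient LE and equals the area between the curves.

**Costs.** Monthly mean cost among survivors is decomposed into a chronic
component c(t) (mean by month since diagnosis over person-months not
within K months of an observed death; denominator = patients under
follow-up, so missing billing rows count as zero) and a terminal profile
d(k), k = 1..K months before death (k = 1 is the death month; K defaults
to 6). Beyond follow-up the expected cost of a survivor re-mixes the two
with death probabilities from the extrapolated curve:
mu(t) = Σ_k p_k(t)·d(k) + (1−Σ_k p_k(t))·c_∞, with c_∞ the mean chronic
level over the last 12 observed months. Lifetime cost is
Σ_t ½(S(t−1)+S(t))·mu(t)·(1+r)^(−t/12)/X, with annual discount rate r
(default 3%) and exchange rate X (default 30.93 TWD/USD); the mid-month
survival weight makes the constant-cost identity
(cost = c·12·LE/X at r = 0) exact on the trapezoidal grid. A per-calendar-
year CPI multiplier table can be supplied in config and is applied to raw
cost records (pass-through; the package computes no price indices).
"Cost per year" is not uniquely defined in the source literature, so both
candidates are exposed behind `cost_per_year_method`:
undiscounted-total ÷ LE (default) and 12 × survival-weighted mean monthly
cost. Neither is externally validated.

**Uncertainty.** Standard errors come from a patient-level bootstrap
(default B = 100): patients are resampled with replacement, their cost
histories travel with them, and the full pipeline — including a freshly
seeded referent simulation — is re-run per replicate, so referent Monte
Carlo noise is inside the SE. Non-estimable resamples are counted, not
imputed; more than 50% failures aborts the SE as unstable. The cohort is
put in a canonical id order before resampling, so the SE is invariant to
input row order.

## Synthetic registry and what it does (not) show

The generator emulates the study conditions: males aged 20–89 (truncated
normal, mean 72.5, sd 9 — matching the registry's band mix), uniform
diagnosis months 2008–2019 with administrative censoring at 2019-12, a
Gompertz life table (q(a) = 1 − exp(−b·e^(θa)), b = 3.3e-5, θ = 0.0916,
roughly male mortality at ages 70–90, closed at age 110), stage mix
11.5/42.7/13.2/32.6% with excess hazard only in stage 4 (default HR 3;
HR 1 elsewhere reproduces the refusal phenomenon), independent PSA/Gleason
labels (no attached biology, by design), chronic lognormal costs
(mean 15,000 TWD/month, CV 1) and a 60,000 TWD/month surge in the final
6 months of life. Ground truth (per-stratum LE, loss, expected discounted
lifetime cost) is computed by exact summation over the discrete generating
model — the model is genuinely monthly, so there is no integration error
to tolerate.

Passing recovery tests therefore show that the pipeline inverts its own
generating mechanism (proportional excess hazard, independent censoring,
stationary chronic costs). They do not show robustness to what real
registries add: non-proportional excess hazard (cure fractions, treatment
eras), cohort mortality improvement, informative censoring, stage
migration, or cost trends within the chronic phase.

## Validation design and measured behaviour

The validation studies (`lifexpect.studies`, driven by `analysis/` and
`scripts/acceptance.py`) use: recovery on 20 replicate three-stratum
registries comparing mean recovered values with exact truth (a single
replicate's sampling sd is ~5–8% for LE — the same order as the SEs
registry studies of this design report — so single-replicate comparison
would measure luck, not bias); null refusal on 200 cohorts of 500; interval
coverage on 100 oldest-band (75–89) cohorts of 300 patients with B = 80
bootstrap replicates; and SE root-n scaling on 20 paired cohorts of the
same design. Sizes were chosen so the whole suite runs in minutes on one
CPU while keeping Monte Carlo error on each summary below its decision
margin. Two choices in the coverage design matter and were set by a small
calibration study: B = 80 keeps the bootstrap SE's own ~10% relative noise
from eroding interval coverage, and the oldest band is used because
interval calibration presupposes a near-unbiased point estimator — the
short extrapolation horizon there puts the measured bias at +0.06 years
(0.13 sd), and coverage lands at 92–93% across independent batches,
against ~89% for a longer-horizon band where extrapolation bias is a
third of the SE.

## Numerical choices and degenerate inputs

- Trapezoid on months everywhere an area is needed; curves are closed with
  survival 0 at the age cap.
- Knot sets that collapse (short or degenerate windows) fall back to a
  straight line; constant-time windows are rejected.
- The emitted extrapolated curve is made non-increasing by a running
  minimum (predictions themselves are left untouched inside the loop).
- Months with zero chronic survivors carry the last estimable cost value
  forward; terminal-profile cells with no observed deaths fall back to the
  chronic level.
- Deaths recorded at month 0 would force S(0) < 1; the generator never
  produces them (death months start at 1) and the KM layer warns if real
  data do.
- All randomness flows through `numpy.random.default_rng` seeds; identical
  seeds give byte-identical CSVs and bit-identical curves.

## Known limitations

- The extrapolated tail inherits the linearity of the logit-ratio trend:
  long horizons (young strata) are intrinsically high-variance, and the
  bands' point estimates can err by ~10% in a single cohort of a few
  thousand patients — consistent with the large SEs such strata carry in
  published registry analyses.
- The terminal cost window K is a fixed design constant; costs that ramp
  over more than K months leak into the chronic component (and do so in
  censored patients' last observed months regardless).
- The estimability test is one-sided and calibrated under the null; true
  but tiny excess mortality (AUC ratio just under 1) is deliberately
  refused rather than extrapolated.
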
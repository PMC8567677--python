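# Methods

## The estimand and the generative model

The quantity of interest is a county-specific log odds ratio β_c: the log
change in the odds of a heat-sensitive health event per 1 °C of daily
exposure. The synthetic generator realizes the simplest data-generating
process for which this estimand is exact: daily county event counts are
independent Poisson,

    N_cd ~ Poisson( baseline_rate · exp( β_c · (T_cd − T̄_c) ) ),

with T the daily mean temperature and T̄_c the county's seasonal mean.
Under Poisson sampling, conditioning an event's day on a fixed set of
candidate days yields exactly the conditional logistic likelihood with
coefficient β_c, so the case-crossover estimator targets the planted
truth without approximation. The exposure–response form is log-linear by
construction — a modeling choice of this package, made so that truth is
well-defined; nothing in the fitting stage assumes the generator.

County heterogeneity is planted linearly in the covariate table:

    β_c = γ₀ + Σ_k γ_k · sdoh_ck + u_c,

where u_c is iid N(0, σ_β²) noise, optionally filtered through the
simultaneous-autoregressive operator (I − ρ·W_row)⁻¹ (row-normalized
lattice weights) so that the planted surface lies in the same family as
the stage-2 spatial lag model. The linear part is recoverable exactly
from (γ₀, γ, sdoh), which the tests verify.

## Referent selection

Two schemes are implemented.

**`time_stratified` (default).** The season is partitioned into fixed
28-day blocks anchored at the season start; a case's stratum is the four
same-weekday days of its block, and the referents are the other three
(each at ±7, ±14 or ±21 days). Because the stratum is a fixed calendar
object, under the null every day of the stratum is equally likely to host
the event, and the design is exactly unbiased whatever the seasonal
shape of exposure. Weekly cycles cancel by construction. The cost: a
153-day May–September season holds five complete blocks (140 days), and
cases in the truncated trailing block (≈8.5 % of season days) have no
complete stratum and are dropped, with a logged count. Controls remain
exactly 3 × analyzed cases.

**`random_sign`.** The case-anchored alternative: for each offset
magnitude k ∈ {7, 14, 21} a side ±k is chosen with equal probability,
falling back to the other side at the season boundary. It retains every
case, but the boundary fallback plus edge undersampling make referents
oversample the warm mid-season; with a realistic within-season
temperature cycle this produces a constant additive bias in β̂ of about
−0.05/°C (measured in this package's simulations: planted 0.5 → 0.457,
0.2 → 0.155, 0.05 → ≈0). It is retained for comparison and for designs
where exposure has no within-season trend; the default is the unbiased
scheme. In both schemes every referent is at |Δ| ∈ {7, 14, 21} days
inside a 28-day comparison window. Random signs are keyed on
(patient id, date) — never on row order — so all estimates are invariant
to permuting the event table.

## Conditional logistic fitting

The matched-set likelihood is one-dimensional; exposures are centered
within each stratum (the likelihood is invariant to per-stratum shifts),
and Newton–Raphson starts from β = 0 with at most 50 iterations. The
score tolerance is 1e-10 scaled by the stratum count (the score is a sum
over strata, so a size-independent absolute tolerance would be
unattainable in double precision at large n). The MLE does not exist when
the case exposure is the stratum maximum (or minimum) in every stratum;
this is detected exactly and the estimate is capped at |β| = 10 and
flagged non-converged. Strata with no exposure contrast contribute no
information; if every stratum is contrast-free the fit is flagged
degenerate with β = 0 and infinite SE. AIC = 2 − 2ℓ(β̂) (one parameter).
Counties with fewer than `min_cases = 30` analyzed strata are omitted,
mirroring the convention of leaving small-count counties blank on OR
maps.

Metric/lag selection sums per-county AICs within each of the 44
metric × lag cells (4 metrics × lags 0–10) and takes the minimum; the
full grid is emitted. Cells are compared on the counties each supports;
lagged exposures reaching before the season start drop the affected
strata.

## Heat Index

The Rothfusz nine-coefficient regression polynomial is evaluated in °F
for T ≥ 80 °F, with the standard NWS adjustments: for RH < 13 % and
T in [80, 112] subtract ((13−RH)/4)·√((17−|T−95|)/17); for RH > 85 % and
T in [80, 87] add ((RH−85)/10)·((87−T)/5). Below 80 °F the simple-formula
average 0.5·(T + 61 + (T−68)·1.2 + 0.094·RH) is used. Gating on T keeps
the index strictly increasing in T above 80 °F; the seam at 80 °F is a
known quirk of the two-branch convention, bounded by ≈2 °F up to RH 70 %
and ≈2.8 °F near RH 80 % (measured, and asserted as such in the tests).
Each branch is flag-controlled so a pure-polynomial mode exists for
oracle comparisons. All downstream quantities are in °C (ORs are per °C);
the HI is computed in °F and converted. With hourly input the daily
maximum HI is the maximum over hourly values; with daily input it is the
HI of daily maximum temperature at the day's humidity.

Missing weather days raise an error rather than being interpolated:
silent gap-filling would distort referent contrasts.

## Stage 2

- **Dependent variable**: the OR itself (not the log-OR), with a
  configuration switch for log-OR. For ORs near 1 the two scales differ
  by O(β²).
- **Pruning**: greedy — while any pair exceeds |r| = 0.7, drop the member
  of the worst pair with the larger mean absolute correlation against
  the remaining variables, ties broken by column order. A user-supplied
  drop list (e.g. the conventional 12-variable drop from the 30-variable
  roster, leaving 18 candidates) bypasses the greedy search.
- **Stepwise**: backward from the full model, deleting the single
  variable whose removal lowers AIC most, stopping when none does.
  Selection uses the aspatial fitter by default (a flag switches to the
  spatial fitter); both models are then fit on the selected set. The OLS
  AIC convention counts p + 2 parameters (intercept and variance).
- **Diagnostics**: one-sample KS test of standardized residuals against
  N(0,1); global Moran's I with z mean-centered and S₀ = Σw, with a
  two-sided Monte-Carlo permutation p (999 permutations by default,
  smaller-tail doubling, the (1+extreme)/(1+n) convention).
- **Spatial lag**: ML with the log-determinant via the eigenvalues of the
  symmetric binary W, ρ maximized over (1/λ_min, 1/λ_max) by bounded
  scalar search; β from least squares on the filtered response; standard
  errors from the (β, ρ, σ²) information matrix. A ρ̂ pinned at an
  interval endpoint is flagged non-converged; an all-zero W degenerates
  to OLS with ρ forced to 0, flagged. AIC counts p + 3 parameters.
- **Model choice**: spatial lag iff residual Moran permutation p ≤ 0.05
  or spatial AIC strictly below the aspatial AIC; ties go aspatial.
- **Impacts**: global average total impacts n⁻¹·1ᵀ(I−ρW)⁻¹1·β_k.
  Reported p-values are those of the underlying β_k; no simulation-based
  impact inference is attempted.
- **Gating**: an outcome/stream cell needs at least max(10, p+5)
  counties with ORs; smaller cells are skipped with a reason, mirroring
  outcomes too rare to model.
- No precision-weighting of ORs by their stage-1 SEs is applied (the
  regressions are unweighted), and no multiple-testing correction is
  made; significance is marked at p ≤ 0.05.

## What the generator emulates — and what it does not

Emulated: the warm-season calendar (May 1 – September 30, default
2008–2012), a within-season temperature cycle with county offsets and
AR(1) day-to-day persistence at realistic Florida-like levels (base
26.5 °C, amplitude 2 °C, AR ϕ = 0.7), county covariates at realistic
means/spreads with a planted |r| = 0.95 income pair to exercise pruning,
a 7×10 queen-contiguity lattice standing in for a ~67-county state, and
duplicate patient visits planted inside the dedup windows (7 days for
dehydration/heat-related/respiratory, 28 for cardiovascular/acute
renal).

Not emulated: real county geography and coastal weather bias, ICD-9
frequency structure across outcomes (each run generates one
outcome/stream), multi-cause patients, population size heterogeneity
across counties, and harvesting/displacement dynamics. Passing tests
therefore demonstrate the statistical machinery is correct and
calibrated under the stated model — not that any particular real-world
coefficient is reproduced.

## Problem sizes used in validation

Chosen to give tight Monte-Carlo error at desk scale: stage-1 recovery
uses 100 replicates of one county with ~5,100 analyzed cases (planted
log-OR 0.05/°C, checked within 3 SE); type-I error uses one 500-county
null study (~140 cases per county); stage-2 recovery uses 50 replicates
of 100 counties at ~2,100 cases per county with effects ±0.01 per unit
planted on 2 of 6 covariates; ρ recovery uses a 7×7 lattice where
ρ = 0.1 sits safely inside the non-row-standardized feasible interval
(≈ (−0.29, 0.17)).

## Known limitations

- A single scalar exposure per model: no distributed-lag or spline
  (DLNM) exposure–response surfaces, and no covariates inside the
  conditional logistic model (the design handles time-invariant
  confounding; referent strata handle seasonality).
- Counties are fitted independently; no pooling or shrinkage of noisy
  small-county ORs, and stage 2 ignores the stage-1 sampling error
  (errors-in-response attenuates stage-2 precision, not consistency).
- Spatial error/SARAR/GWR alternatives and direct/indirect impact
  decompositions are out of scope; only the lag model and total impacts
  are provided.
- Queen weights come from the lattice generator or an edge-list CSV;
  deriving them from polygon files is not implemented.
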
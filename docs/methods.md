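# Methods

## Structural model

The dose-to-mother deuterium technique is modelled as two linked
one-compartment water pools. The mother's pool (volume `V_m`, litres) is
dosed orally at t = 0 and eliminates tracer with total rate constant `k_mm`
(1/day), of which the flow `CL_mb` (L/day) passes to the infant through
breastmilk; the infant pool eliminates with clearance `CL_bo`. Because D₂O
traces water, these are water clearances, and dilute heavy water is taken at
density 1.0 kg/L so litres and kilograms coincide. The analytic solutions
are monoexponential for the mother and biexponential (flip-flop) for the
infant; when `k_mm` and `k_bo` coincide within a relative tolerance of 1e-8
the L'Hôpital limit `dose·k_mb·t·e^(−kt)` replaces the generic form, which
suffers catastrophic cancellation there. Tests verify both forms against
adaptive numerical integration of the differential system to 1e-8 relative
accuracy.

Assumptions: the mother's volume is constant over the 14-day study (her
hydration status is assessed in the field); no back-transfer of tracer from
infant to mother; no isotope fractionation correction; single maternal
compartment.

### Infant pool growth

The infant's distribution volume is not separately identifiable from the
milk transfer, so it is fixed from weight: `V_b(t) = f_w · BWT(t) / ρ`, with
body weight interpolated linearly between the enrolment and day-14
measurements and water fraction `f_w = 0.60` by default (a 5 kg infant then
carries 3 L of body water). A height-based alternative is deliberately not
implemented; `f_w` is configurable everywhere it enters. The analytic
solution needs a single `k_bo = CL_bo/V_b`; we evaluate it at the mid-study
volume and use the time-varying `V_b(t)` only for the amount-to-concentration
scaling. Over a 14-day window with ~5% weight gain the distinction is well
below residual noise.

## Hierarchy and priors

* Stage 1: `y_ij ~ N(f_ij, σ_add² + (σ_prop·f_ij)²)` — the combined residual
  model standard in population pharmacokinetics; `error_model="additive"`
  fixes `σ_prop = 0`. Baseline (pre-dose) rows are used only to define the
  above-baseline scale and are excluded from the likelihood.
* Stage 2: `ln θ_i ~ N₄(ln μ_i, Ω)` with `Ω = VρV`, `V = diag(λ)`. The full
  covariate model sets `ln V_m` linear in `ln(MWT/70 kg)` and `ln CL_bo`
  linear in `ln(BWT/5 kg)`, both allometry-style power laws centred at the
  reference weights; "base" drops both slopes.
* Stage 3: `ln μ ~ N(0, 1000)`, `λ_j ~ N(0, 1000)` truncated positive,
  `ρ ~ LKJ(1)` (uniform over correlation matrices), σ components half-normal
  with sd 1000.

The support is truncated to `CL_mb < k_mm·V_m`: the milk route cannot exceed
the mother's total water output, so the derived `CL_mo` is positive by
construction.

## Sampler

No gradient-based sampler is available to this package, so inference uses an
adaptive Metropolis-within-Gibbs scheme designed around the model's
structure:

1. **Individual parameters.** One 4-dimensional random-walk Metropolis step
   per pair, executed vectorised across pairs. During warmup each pair's
   proposal covariance is estimated online (Welford) and its scalar step size
   tuned by Robbins–Monro toward an acceptance rate of 0.234; adaptation
   freezes at the end of warmup, so retained draws come from a valid Markov
   chain.
2. **Population coefficients.** Given the individual log-parameters and Ω,
   the coefficient vector (intercepts and slopes) is a linear-Gaussian
   conditional and is drawn exactly (conjugate Gibbs), which removes the
   slowest random-walk component entirely.
3. **Scales, correlations, residual σ.** Log-scale random-walk Metropolis on
   λ and σ (with the half-normal prior and Jacobian), and entry-wise
   random-walk updates of ρ with positive-definiteness enforced by Cholesky
   feasibility; all step sizes warmup-adapted.

Chains are initialised from cheap per-pair estimates (log-linear regression
on the mother curve, bounded least squares on the infant curve) plus
per-chain jitter, and run independently from spawned seed streams; a run is
bit-reproducible from its integer seed. Because random-walk moves mix more
slowly than gradient samplers, draws are thinned (default `thin=5`) so the
retained-draw count matches the protocol; the default protocol is 3 chains ×
10,000 retained draws after 1,000 warmup sweeps. Tests and the acceptance
script use a desk-scale profile — 3 chains × 1,000 retained draws, 1,500
warmup — chosen as the package's standard small profile; at that scale a
20-pair fit takes well under a minute and population Rhat values are
typically below 1.03.

Convergence reporting uses rank-normalised split-Rhat and autocorrelation
ESS (via arviz). A fit warns when max Rhat exceeds 1.05 or any per-pair
acceptance rate collapses below 5%; the CLI `fit` command exits non-zero
beyond a configurable Rhat threshold.

## Model comparison

WAIC is computed from its definition on the deviance scale
(`−2·lppd + 2·p_waic`, with `p_waic` the across-draw variance of each
pointwise log density, sample variance with S−1); PSIS-LOO is delegated to
arviz and reported with per-observation Pareto-k diagnostics, flagging
k > 0.7. In a hierarchical model with only ~7 observations per subject and
curve, case deletion genuinely moves the individual posterior, so moderate
numbers of flagged observations are expected and are a property of the
design, not a bug; comparisons between candidate models on identical data
remain informative. Individual visual predictive checks pool all chains and
overlay observations on 2.5/50/97.5% posterior-predictive bands (residual
noise included by default; a noiseless structural band is available).

## Water balance and the cut-off

For each retained posterior draw,

```
R_in = CL_bo + dV_b/dt        # total infant water input, L/day
Rs   = (1 − f_a)·R_in − CL_mb # non-breastmilk ingestion, ×1000 ⇒ g/day
```

The growth term `dV_b/dt = f_w·(BWT_end − BWT_start)/14` is includable by
configuration (default on). The atmospheric absorption fraction is treated
as an uncertain constant, `f_a ~ N(0.063, 0.017)` truncated to [0, 1),
drawn once per posterior draw; its reference estimate comes from a temperate
climate and is likely conservative in humid regions. Metabolic water
production is not separately modelled; the balance accepts an additional
input-correction term if one becomes available. Negative `Rs` draws are
retained — truncation at zero would bias the pooled quantile upward.

The population cut-off is the inverted-CDF empirical quantile (default the
90th percentile, an elicited prior belief about the fraction of truly EBF
pairs in a calibration cohort) of the equal-weight concatenation of all
pairs' draws. `P(EBF)` is the fraction of a pair's draws strictly below the
cut-off; the EBF/non-EBF label merely thresholds it at 0.5.

`theoretical_lower_limit` quantifies the design's detection floor: simulate
pairs whose generating balance has exactly zero non-milk intake, fit, and
take the one-sided 95% upper bound of their `Rs` posteriors (averaged over
pairs, with a Monte-Carlo standard error over replicate seeds). It is
positive whenever measurement noise or constant uncertainty is, shrinks as
those are removed, and grows with `sd(f_a)` — below it, a pair is
indistinguishable from a perfect EBF pair no matter how careful the field
work.

## Synthetic cohorts

The generator reproduces the calibration design: ~30 g dose, sampling days
0 (pre-dose), 1, 2, 5, 6, 13, 14, duplicate samples on day 0, day 5-or-6
(chosen at random per pair) and day 14 jittered ±15 min and later averaged
per protocol, maternal weights log-normal around a 53.1 kg median clipped to
34.5–93.1 kg, infant entry weights around 5.9 kg clipped to 3.9–8.4 kg with
~0.3 kg growth over the study. Default population values are the reported
covariate-model estimates (`ln V_m`: 3.49 + 0.62·ln(MWT/70); `ln CL_bo`:
−0.16 + 0.17·ln(BWT/5)); `k_mm = 0.10/day` and `CL_mb = 0.80 L/day` are
plausible water-turnover values chosen once (they are not reported in the
source estimates available to us). Between-subject variability defaults to
independent log-sd 0.2 per parameter, and residual noise to σ_add = 2 mg/kg
with σ_prop = 2% — a small combined noise consistent with an FTIR assay CV
of ~0.5% plus biological variation; both live in `SimulationTruth`, not in
code.

Two generation modes exist. By default all four parameters are drawn from
the multivariate log-normal (rejection-sampling the truncated support) and
each pair's implied true `Rs` is recorded; because `CL_mb` and `CL_bo` are
then independent, the implied `Rs` spread is wider than in a genuinely EBF
cohort. Supplying `rs_per_pair` instead derives `CL_mb` from the balance so
the stated `Rs` (e.g. exactly zero for perfect-EBF pairs) is true by
construction. Values below the 20 mg/kg limit of quantitation are flagged,
not censored (censoring is a design option).

What passing tests on these cohorts do **not** show: robustness to assay
drift, to missed visits or dropout, to hydration-status changes invalidating
the constant-`V_m` assumption, or to a humid-climate `f_a` differing from
the temperate reference. Cohort-specific cut-offs from real calibration data
cannot be reproduced from synthetic cohorts and are out of scope.

## Numerical choices

* Equal-rate switch in the biexponential at relative difference 1e-8.
* Empirical quantiles use the inverted-CDF convention, so a pooled mixture
  of {0 × 9/10, 100 × 1/10} has a 90th-percentile cut-off of exactly 0.
* Duplicate averaging requires the two linked samples within 1 h (config);
  unpaired or out-of-window duplicates are validation errors, not silently
  averaged.
* The plausibility rule excludes a pair only when the CL_bo summary
  (posterior mean by default) is **strictly** greater than 40% of the
  infant's starting body weight per day.
* The 90th-percentile default, reference weights (70 kg, 5 kg) and the
  f_a moments are data, not constants baked into formulas — all are
  constructor arguments.

## Known limitations

* Random-walk MCMC needs thinning and careful warmup; very small cohorts
  (1–3 pairs) identify Ω weakly and population Rhat can stay above 1.05
  even when individual-level quantities (and hence `Rs`) are stable.
* `V_b` uncertainty is not propagated into the likelihood (weight is treated
  as measured exactly); it enters `Rs` only through the growth term.
* The additive error model is retained for comparison but is misspecified
  for enrichments spanning three orders of magnitude, and WAIC/LOO
  consistently reject it — as intended.
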
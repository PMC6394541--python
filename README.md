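# dtmilk

Analysis of exclusive breastfeeding with the dose-to-mother (DTM) deuterium
oxide dilution technique. A mother receives ~30 g of D₂O orally; the tracer
spreads through her body water and reaches her infant through breastmilk.
Saliva enrichments sampled in both subjects over 14 days identify the water
flows of a linked two-compartment system, and from those flows the infant's
water intake from **non-breastmilk sources** (`Rs`, g/day) — the biomarker of
breastfeeding exclusivity — is computed with full posterior uncertainty.

`dtmilk` is aimed at nutrition and global-health groups running DTM field
studies: it simulates calibration-style cohorts, fits the kinetic model in a
three-stage Bayesian hierarchy, compares candidate models by WAIC and
PSIS-LOO, derives a population `Rs` cut-off, and assigns each mother–infant
pair a posterior probability of exclusive breastfeeding (EBF).

## The model

Amounts of D₂O in mother (m) and infant (b) follow

```
dA_m/dt = −k_mm·A_m                 A_m(0) = dose
dA_b/dt =  k_mb·A_m − k_bo·A_b      A_b(0) = 0
```

with water-clearance parameterisation `k_mb = CL_mb/V_m`, `k_bo = CL_bo/V_b`;
measured saliva enrichment above baseline is the amount divided by the water
pool (density 1 kg/L). The infant pool `V_b(t)` grows linearly with measured
weight. The hierarchy is:

* **Stage 1** — observations `y_ij ~ N(f(θ_i, t_ij), σ_add² + (σ_prop·f)²)`
  (combined residual model; an additive-only variant is available);
* **Stage 2** — individual log-parameters
  `ln θ_i = (ln CL_mb, ln CL_bo, ln k_mm, ln V_m) ~ N(ln μ_i, Ω)`, with
  `Ω = VρV` and covariate sub-models
  `ln V_m,i = β_V + β_MWT·ln(MWT_i/70 kg)` and
  `ln CL_bo,i = β_b + β_BWT·ln(BWT_i/5 kg)`;
* **Stage 3** — vague priors: `N(0, 1000)` on log-means, half-normal(1000)
  on scales and σ, LKJ(1) on the correlation matrix ρ.

Posterior sampling is an adaptive Metropolis-within-Gibbs scheme written for
this model (per-pair adapted multivariate proposals, exact conjugate updates
of the population coefficients). Each pair's `Rs` posterior follows from the
infant water balance `Rs = (1−f_a)·(CL_bo + dV_b/dt) − CL_mb`, where the
atmospheric-moisture fraction `f_a ~ N(0.063, 0.017)` truncated to [0, 1) is
propagated as an uncertain constant. Pooling all pairs' draws into an
equal-weight mixture and taking its 90th percentile yields the population
cut-off; `P(EBF)` for a pair is the fraction of its draws below the cut-off.

## Worked example

```python
import dtmilk

truth = dtmilk.SimulationTruth()            # reported covariate-model values
design = dtmilk.CohortDesign(n_pairs=20)    # days 0,1,2,5,6,13,14; duplicates
cohort = dtmilk.simulate_cohort(truth, design, seed=1)

model = dtmilk.HierarchicalDtmModel(
    n_chains=3, n_draws=1000, n_warmup=1500, thin=5, random_state=1,
).fit(cohort.pairs)
print(model.posterior_.beta_summary().round(3))

posts = dtmilk.cohort_rs_posteriors(model, seed=1)
cut = dtmilk.pooled_cutoff(posts, percentile=0.90)
print(f"cut-off: {cut.cutoff:.1f} g/day ({cut.n_draws} pooled draws)")
```

prints

```
                 mean     sd   q2.5  q97.5
lnCL_mb        -0.198  0.055 -0.305 -0.090
lnCL_bo        -0.171  0.044 -0.259 -0.086
lnk_mm         -2.405  0.051 -2.507 -2.305
lnV_m           3.687  0.105  3.485  3.901
slope_Vm_MWT    1.436  0.344  0.764  2.147
slope_CLbo_BWT  0.146  0.146 -0.147  0.427
cut-off: 242.2 g/day (60000 pooled draws)
```

The four `ln`-rows are population means of the kinetic parameters at the
reference covariates (e.g. `lnV_m = 3.687` ⇒ a 70 kg mother's distribution
volume ≈ 40 L; the generating value was 3.49); the two slopes are the weight
exponents. Every population Rhat in this run is below 1.02. The cut-off is
the 90th percentile of the pooled `Rs` mixture of this synthetic cohort —
its value depends on how much supplementation the generating truth implies,
and per-pair `cut.p_ebf` gives each pair's posterior probability of being
exclusively breastfeeding.

The same pipeline is scriptable from the shell:

```sh
dtmilk simulate --n-pairs 20 --seed 1 --out cohort/
dtmilk fit --records cohort/records.csv --covariates cohort/covariates.csv --out fit/
dtmilk evaluate --records cohort/records.csv --covariates cohort/covariates.csv --out eval/
dtmilk cutoff --fit-dir fit/ --records cohort/records.csv --covariates cohort/covariates.csv --out cut/
dtmilk classify --fit-dir fit/ --records ... --covariates ... --cutoff 86.6 --out classified.csv
```

## Layout

| module | contents |
| --- | --- |
| `dtmilk.kinetics` | closed-form disposition model, infant pool growth |
| `dtmilk.io` | CSV panel dialect, duplicate averaging, plausibility filter |
| `dtmilk.simulate` | seeded synthetic cohorts, perfect-EBF construction |
| `dtmilk.inference` | hierarchical model, MCMC sampler, Rhat/ESS |
| `dtmilk.model_eval` | WAIC, PSIS-LOO, individual visual predictive checks |
| `dtmilk.rs` | water balance, pooled cut-off, EBF classification |
| `dtmilk.cli` | `dtmilk` command-line workflow |

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
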
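# Methods

## The forecasting problem

Midcontinent mallard harvest management forecasts spring breeding abundance
N_{t+1} (millions of birds) from the current survey estimate N_t, May pond
counts W_t (millions), and per-class harvest rates, using four mechanistic
models whose annual one-step-ahead predictive densities drive Bayesian
model-weight updating. This package reconstructs that machinery and
benchmarks it against two ecological null models. Because the official
submodel coefficients and bias-correction factors live in agency reports and
are not inputs here, all mechanistic-model coefficients are configurable,
with documented synthetic defaults; the scientific content being tested is
the *benchmarking method*, not the official parameterization.

## Mechanistic models

Survival per age–sex class (adult/juvenile × male/female) is driven by the
kill rate K = h/(1−c), the harvest rate h inflated for crippling loss c
(default 0.2). Two hypotheses:

- additive: S = s₀(1−K), every kill adds to natural mortality;
- completely compensatory: S = s₀ for K ≤ C and S = 1−K beyond, with
  threshold C = 1−s₀ (the classic threshold form; continuous at C).

Reproduction is zero-truncated linear, R_t = max(0, a₀ + a₁N_t + a₂W̃_t),
with W̃ the standardized pond count; "weak" vs "strong" density dependence
differ in the magnitude of a₁ (defaults −0.05 and −0.15 per million birds).
The balance equation

N_{t+1} = γ_S N_t [ m·S_am + (1−m)( S_af + γ_R R_t (S_jf + S_jm φ_f/φ_m) ) ]

nests recruitment inside the female share, so recruits scale with the number
of adult females; γ_S = γ_R = 1 by default (bias-correction multipliers are
accepted via config). Process noise is multiplicative lognormal with
log-scale sd `process_sd` (default 0.05), so the predictive distribution is
lognormal with median at the deterministic projection; a supplied survey SE
is mapped to the log scale by the delta method and added on the variance
scale.

### Default parameter values (synthetic, illustrative)

| quantity | default | units / meaning |
|---|---|---|
| s₀ (am, af, jm, jf) | 0.85, 0.75, 0.80, 0.70 | annual survival absent hunting |
| crippling loss c | 0.2 | fraction of kill unretrieved |
| a₀, a₁ (weak) | 1.1, −0.05 | young per adult female; per million birds |
| a₀, a₁ (strong) | 1.9, −0.15 | intercepts chosen so both submodels agree at N = 8 |
| a₂ | 0.2 | per wetland z-unit |
| m | 0.55 | male share of breeding population |
| φ_f/φ_m | 0.9 | juvenile summer-survival sex ratio |
| process_sd | 0.05 | log-scale process noise |

The weak/strong intercepts are deliberately calibrated to cross at 8 million
birds: both reproduction hypotheses are then viable near typical abundances
but diverge away from them, which is what makes them competing hypotheses
rather than one being trivially absurd. With the default harvest rates the
four models equilibrate between roughly 8.6 and 15 million birds, bracketing
the survey's historical range.

## Ecological null models

**Persistence.** N_{t+1} = N_t + ε_t, ε ~ N(0, σ²). The point forecast is
the last observation; σ is the sample sd (n−1) of the one-step differences
in the history, on the natural scale to match the additive noise form. A
single difference contributes its absolute value.

**Wetland model.** N_{t+1} = λ_t N_t, log λ_t = r_eq + βW̃_t + ε_t with
r_eq pinned at 0 (a population at stochastic equilibrium has mean log growth
zero, so no intercept is estimated). β and σ² are estimated by conjugate
Bayesian regression through the origin with a normal–inverse-gamma prior
(defaults: β | σ² ~ N(0, 100σ²), σ² ~ IG(0.01, 0.01) — vague at the scales
involved). The posterior predictive for log N_{t+1} is Student-t with
location log N_t + β̂W̃_t, scale √(b/a·(1+vW̃_t²)) and df = 2a, so parameter
uncertainty propagates into scoring and weight updating. A conjugate rather
than plug-in fit was chosen precisely so the predictive density used in
Bayes updating is a genuine posterior predictive. Before three growth
observations exist the harness substitutes the persistence forecast
(identical information set; avoids undefined fits), flagging the record.

Since exp of a t variate has no finite moments, the abundance-scale
mean/sd stored on the forecast record are moment-matched through a normal
approximation to the log-scale t (variance scale²·df/(df−2)); at the dfs and
scales this pipeline produces (df ≳ 20, scale ≈ 0.05) the approximation
error is orders of magnitude below Monte-Carlo resolution at 10⁵ draws.

## Evaluation design

Forecasts are strictly one-step-ahead on an expanding window: the forecast
for target year y uses abundance, wetland and harvest data through y−1 only.
Wetland standardization defaults to *recursive* mode — the z-score for year
t uses the mean and sample sd of pond counts through year t — so no future
wetland information leaks into a forecast; fixed-baseline standardization is
available to mimic a published-constants workflow. Survey gaps are explicit:
a target year is skipped when it or its predecessor lacks an observation,
and growth rates are never formed across a gap.

Scores are computed on predictive *means* (RMSE-type scores are minimized by
the mean): NRMSE = RMSE/mean(obs) and NMSD = mean(pred−obs)/mean(obs), with
error defined as predicted − observed so systematic underprediction is
negative. Scores use only years where every compared model has a forecast
and an observation exists, keeping benchmark ratios comparable; "k times
better" than the null is the ratio of absolute NMSDs (NMSD is signed, so
"better" must be magnitude-based). A null NMSD of exactly 0 yields flagged
infinite ratios rather than an error.

Weight updating starts from the uniform prior (0.25 per model for the four
mechanistic candidates) and multiplies each weight by the model's predictive
density at the new observation, in log space, renormalizing each year. The
weighted-average forecast for year y uses the weights available at the
*start* of y (posterior through y−1) — the forecast a manager could actually
have issued. Degenerate sd = 0 forecasts are treated as point masses with a
1e-9 hit tolerance and logged loudly; no weight floor is applied by default,
so weights may reach 0.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes:
pond counts follow a stationary lognormal AR(1) (median 4 million, φ = 0.5,
innovation sd 0.25 — giving realistic 2–7 million pond swings); harvest
rates are i.i.d. truncated normal per class (means 0.14/0.09/0.18/0.12 for
am/af/jm/jf, sd 0.03, bounded to [0.01, 0.35)); latent abundance starts at
8 million and propagates under any candidate process with lognormal process
noise; observations get multiplicative lognormal noise with CV 0.05,
approximating reported survey precision. The default record is 48 years
shaped so the final 24 form the evaluation window. When the wetland-null
generator applies its β effect it standardizes the pond series over the full
simulated record, so the covariate it used is exactly reconstructable from
the emitted CSV.

What the generator does *not* emulate — and hence what passing tests cannot
show about the real system: harvest-policy feedback (real harvest rates are
set in response to abundance, confounding survival inference; an optional
density-linked mode is a natural extension), age-structured observation
error, survey design effects, and non-stationary wetland trends. Simulation
studies here demonstrate the *method's* correctness and power under its own
assumptions, not the historical conclusions about mallards.

## Numerical choices

- Sample sd (n−1) everywhere a standard deviation is estimated.
- Weight updates and batch/sequential equivalence are computed in log space
  with log-sum-exp normalization; weights renormalize to 1 within 1e-12.
- Mixture variance uses the within+between decomposition
  Σw(sd² + (mean−m̄)²) to avoid catastrophic cancellation.
- The latent simulator aborts, naming the year, if abundance leaves
  [1e-3, 1e3] million (unstable parameterization rather than silent nonsense).
- CSV round-trips use pandas' `float_precision="round_trip"` parser so
  written series reread bit-exactly.
- The balance-equation map under strong density dependence approaches its
  fixed point with damped oscillation when started far below equilibrium;
  the corresponding test asserts uniqueness and contraction rather than
  strict monotonicity.

## Study sizes used in tests and the acceptance script

Score identities use 3-point hand fixtures; conjugacy and no-look-ahead
checks use 50-year simulations; β recovery uses 100-year series (50
replicates in the coverage test); learning self-consistency uses 20
replicates of 50-year series per generator (10 per generator in the
acceptance script); the structural-mismatch benchmark uses the default
48-year/24-target design. These sizes give decisive signal for every
qualitative claim while keeping the full suite fast on a single CPU.

## Known limitations

- Mechanistic-model coefficients are synthetic defaults, not the official
  values; absolute NRMSE/NMSD magnitudes on synthetic data are therefore
  illustrative, though the *ordering* phenomena (nulls beating misspecified
  mechanistic models on bias) are robust across seeds.
- Only completely additive and completely compensatory survival are
  implemented; partial compensation is not.
- One-step forecasts only; no multi-year projection or harvest-policy
  optimization.
- The wetland model regresses on a single standardized covariate; no
  additional null families (climatology, AR(k)) are built in.
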
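# Methods

## Model

Fifteen coupled ODEs over a 5-week horizon (time in weeks), split across a
prostate and a lymphoid compartment. State vector:

```
A  V  B_I  B_R          treatment inputs
S  R  Ag                prostate tumor: CSPC, CRPC, shed antigen
D_L Dr_L C_L G_L I_L    lymphoid: functional DC, regulatory DC, CTL, Treg, IL-2
C_P G_P I_P             prostate-infiltrating CTL, Treg, IL-2
```

With `h(A) = A / (θ_A + A)` (androgen gating), `crowd = 1 − (S+R)/κ`
(shared logistic crowding) and `stim = Ag + ω_V V` (dendritic-cell
activation signal):

```
A'   = −δ_A χ_CX A                         (χ_CX = 1 iff castrated)
V'   = −δ_V V;   B_I' = −δ_BI B_I;   B_R' = −δ_BR B_R
S'   = ρ_S h S crowd − δ_S S − λ_SR (1−h) S − η_S C_P S
R'   = ρ_R R crowd − δ_R R + λ_SR (1−h) S − η_R C_P R
Ag'  = σ_Ag (δ_S S + δ_R R + η_S C_P S + η_R C_P R) − δ_Ag Ag
D_L' = α_D stim − δ_D D_L
Dr_L'= α_Dr stim G_L − δ_Dr Dr_L
C_L' = α_C D_L (1 + β_I I_L) − ξ_C G_L C_L − (μ_C + τ_C) C_L
G_L' = α_G I_L G_L + ζ Dr_L − (μ_G + τ_G) G_L − κ_AR B_R G_L
I_L' = σ_I C_L − δ_I I_L − κ_AI B_I I_L
C_P' = τ_C C_L − ξ_C G_P C_P − μ_C C_P
G_P' = τ_G G_L + α_G I_P G_P − μ_G G_P − κ_AR B_R G_P
I_P' = σ_I C_P − δ_I I_P − κ_AI B_I I_P
```

All quantities are relative populations: every biological state starts at 1
(the pre-treatment baseline), androgen starts at 1, and the treatment
inputs start at 1 exactly when their regimen flag is on. The non-negative
orthant is invariant (every state's derivative is non-negative on its zero
face; property-tested).

**Estimated parameters (25).** `rho_S, delta_S, lambda_SR, rho_R, delta_R,
eta_S, eta_R, theta_A, sigma_Ag, delta_Ag, alpha_D, omega_V, delta_D,
alpha_Dr, delta_Dr, alpha_C, beta_I, xi_C, mu_C, tau_C, alpha_G, zeta,
mu_G, tau_G, sigma_I`, in this canonical order; positions 4 and 5 are CRPC
proliferation and apoptosis. Default search bounds `[1e-3, 1e2]` per rate
with log-uniform initialization, since plausible rates span decades.

**Fixed constants (8).** `δ_A = 2`, `δ_V = δ_BI = δ_BR = 1`, `κ = 20`,
`κ_AI = κ_AR = 1`, `δ_I = 1` (per week). These set treatment
pharmacokinetics and scales that the two-time-point data cannot separate
from the estimated rates.

## Numerics

* **Reference integrator:** `scipy.integrate.solve_ivp` with LSODA,
  `rtol 1e-6`, `atol 1e-8`, uniform output grid (step 0.05 wk), states
  floored at 0; a failed solve or any state above `1e7` marks the
  trajectory invalid. On the pure-exponential treatment inputs the relative
  error is below `1e-5` wherever the analytic value exceeds `1e-3` (below
  that the absolute tolerance floor dominates — androgen decays through
  four decades by week 5).
* **Batch integrator:** the GA needs millions of model evaluations, so the
  objective uses a numba-compiled fixed-step RK4 vectorized over parameter
  sets (`simulate_batch`), ~40× faster than per-individual LSODA, with a
  pure-numpy fallback. The system is non-stiff on this horizon.
  `n_steps = 100` (dt = 0.05) puts the measurement times 2.5 and 5.0
  exactly on grid nodes; the SSE at the generating truth is then ~1e-11,
  i.e. discretization error is far below any fitting tolerance.
* Outcomes: type I is tumor size (relative to baseline) at week 5; type II
  is the trapezoid average over weeks 0–5 divided by 5.

## Synthetic data

Real calibration data would be cohort measurements from treated mice. The
generator reproduces their *structure*: 7 fitted arms (SX, CX, CX+AI,
CX+AR, SX+V, CX+V, CX+V+AR) × 5 observables (relative tumor burden,
CTL/Treg in prostate and lymphoid tissue) × weeks {2.5, 5} × N replicates.
Noise is multiplicative lognormal with **median** 1 (`value = model ·
exp(σz)`, default σ = 0.15, 5 replicates), keeping measurements positive
and the noise-free value the median of the replicate distribution. The
default missingness drops the lymphoid boxes of the two antibody-only arms,
mimicking sparse lymphoid sampling.

What it deliberately does **not** emulate: inter-animal biological
variability (one truth generates all arms), censoring/dropout, measurement
detection limits, or correlations between observables within an animal.

**Packaged ground truth.** The defaults were chosen once, by a randomized
search over parameter space scored purely on qualitative behavior —
untreated tumors growing severalfold in 5 weeks; castration helping but
leaving a resistant population; inhibition orderings CX+AR > CX+AI > CX and
CX+V+AR > CX+V > V; component ordering AR > V > CX > AI; CX/V antagonism
(Bliss CI > 1) but CX+V/AR synergy (CI < 1); a post-castration lymphoid CTL
surge-then-contraction with Treg expansion; and strong type-I/type-II
outcome correlation — then rounded to 3 significant digits and frozen. The
mechanistic core of that behavior is an IL-2–Treg positive feedback: CTL
expansion secretes IL-2, IL-2 expands Tregs, and Tregs suppress CTLs, which
makes vaccination partly self-defeating unless Tregs are depleted.

## Calibration (MGA)

Real-coded genetic algorithm: binary tournament selection, simulated binary
crossover (per-pair probability `p_c`, per-variable exchange 1/2),
polynomial mutation (per-variable probability 1/25), one-elite carryover;
deterministic per seed, with a non-increasing best-objective trace. The
"modified" GA wraps it in hyperparameter self-tuning: run once per
configuration of a candidate grid (default 3 levels for each of
generations, population, crossover probability and both distribution
indices = 243 configurations), then pick each setting's level by smallest
median error across the grid (coordinate-wise), then refit N times
(default 20) with independent seeds under the selected configuration and
keep the best.

Empirical note baked into the scaled-down defaults used in tests and the
acceptance script: on this problem a *low* crossover distribution index
(`eta_crossover = 2`, i.e. exploratory SBX) is what drives tail
convergence; large mutation indices polish but cannot rescue a
prematurely concentrated population. With data at only two time points per
box the SSE landscape is sloppy — near-optimal parameter sets form a
manifold — which is precisely why the identifiability machinery exists:
bootstrap resampling of replicates within boxes, one refit per resample,
and a coefficient of variation (sd/mean) per parameter, flagged
non-identifiable above 1.

## Validation and synergy

Cross-validation refits the model on the training split with independent
GA seeds and forms normal-theory 95% bands (mean ± 1.96·sd over replicate
predictions) for the held-out arm (leave-one-condition-out) or box
(leave-one-box-out). Band coverage is evaluated against the noise-free
truth. Because the bands measure the spread of replicate fits, *shorter*
GA budgets give honester (wider) bands; long budgets concentrate replicates
and under-cover.

Synergy uses Bliss independence: for disjoint treatment groups with
inhibition fractions `e_a`, `e_b` and combined `e_ab`,
`CI = (e_a + e_b − e_a e_b) / e_ab`; CI < 1 synergy, > 1 antagonism.
Effects are clipped to `[0, 0.999]` (negative inhibition counts as zero
effect, with a warning) and the CI is NaN when the combined effect is not
positive. The 15 non-empty component subsets form a symmetric 15×15 matrix
with NaN on overlapping pairs. Component summaries average inhibition over
the 8 regimens containing a component and average CI over synergistic
entries of its singleton row (unmixed) or all containing-group rows
(mixed). Local sensitivity perturbs one rate at a time by +5% and reports
the percent change of both outcomes per condition.

## Design decisions and limitations

* Seeds: every stage derives 31-bit seeds from the master seed plus a stage
  label through `numpy.random.SeedSequence`, so stages are independent and
  reruns byte-identical.
* `mga_fit` returns the best stage-3 replicate, falling back to the
  stage-1 run of the selected configuration if that was better, so the
  reported objective never exceeds any run it performed under that
  configuration.
* Scale: the original analysis used hundreds of replicate fits per stage on
  a cluster. All defaults here are desk-scale; every replicate count and GA
  budget is an explicit argument, so the full-scale experiment is the same
  call with larger numbers.
* Parameter recovery from wide bounds is limited by landscape sloppiness,
  not optimizer quality: from a ±50% box at σ = 0.05 the number of rates
  recovered within 25% varies widely with the noise realization (observed
  range roughly 14–21 of 25 across dataset seeds) while the SSE is already
  far below the noise floor. Tight-box recovery (±10%) reaches SSE < 1e-4
  on noise-free data.
* The t-test helper assumes equal variances (pooled); with 5 replicates per
  box a Welch correction would be underpowered anyway.
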
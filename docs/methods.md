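# Methods

`abmassim` implements dynamic calibration of stochastic, event-driven
crowd models against streaming count data, built around a perturbed-
observation ensemble Kalman filter (EnKF). This note records the models,
the numerical choices, what the synthetic data do and do not emulate, and
the design decisions taken where more than one reading was defensible.

## Models

### Immigration–death ("box") process

People enter a region at constant rate α (events per unit time) and leave
independently at per-capita rate β (per unit time), so at count x the
departure rate is βx. The count is a birth–death chain with master
equation

    dp_n/dt = α p_{n−1} + β(n+1) p_{n+1} − (α + βn) p_n ,

mean `u(t) = γ + (u0 − γ) e^{−βt}` and variance
`v(t) = γ + (u0 − γ) e^{−βt} + [v0 − γ − (u0 − γ)] e^{−2βt}`, where
γ = α/β is the stationary mean. A Poisson initial law stays Poisson with
mean u(t) (the bracketed variance term cancels when v0 = u0), and the
stationary autocorrelation decays as e^{−βh}. These closed forms are the
analytic oracles for everything stochastic in the package.

Simulation is the exact stochastic simulation algorithm (exponential
waiting times at total rate α + βx, event chosen proportionally to rate).
Recording is lazy: the state reported at an output time is the state
carried forward from the last event before it, which is the exact marginal.
An ensemble variant advances all realisations in lock-step with vectorised
draws; realisations remain mutually independent.

The master-equation integrator truncates the generator at
`n_max = γ + 10 √γ` (configurable) and applies the exact sparse matrix
exponential (`scipy.sparse.linalg.expm_multiply`) to the initial law.
Probability flowing past the truncation bound is dropped and reported as
`leak`; a leak above 1e−8 raises a warning on the result rather than
failing silently. Moments of the integrated law match the closed forms to
better than 1e−6 relative error across α ∈ {5, 50, 500}, β ∈ {0.1, 0.25, 1}
and t ∈ {0.5, 1, 4, 20} (tested).

### WHIRS shopper/worker model

A fixed pool of N agents contains N_w workers and N − N_w shoppers.
Shoppers cycle susceptible (S) → in town (I) → returned (R), with all R
becoming S at midnight; workers cycle home (H) ↔ work (W). Gated,
piecewise-constant rates (all per hour, half-open windows):

| event | move | rate | window | guard |
|---|---|---|---|---|
| shopper arrival | S→I (batch) | ε + α·S·(I+W)/N | 09:00–18:00 | S > 0 |
| shopper departure | I→R (batch) | β·I | all day | I > 0 |
| worker to work | H→W (single) | γ₋ + δ₋·W | 06:00–10:00 | H > 0 |
| worker to home | W→H (single) | γ₊ + δ₊·W | 14:00–23:00 | W > 0 |

The α term is a rich-gets-richer amplification — the fraction of agents in
town proxies for unobserved attractors (weather, events) — and is what
lets the model produce realistic day-to-day volatility. Shopper events
move a batch of agents whose size is a rounded lognormal (log-mean μ,
log-s.d. σ), clamped to [1, available agents]; batches model correlated
arrivals (buses, trains). A virtual camera counter C adds the batch size
(or 1 for worker moves) on every event — cameras are direction-blind — and
is read and reset on the hour.

Simulation is again exact: a candidate waiting time that would cross the
next boundary (hour mark, window edge, midnight) is discarded, the clock
jumps to the boundary, scheduled actions fire, and the draw is retaken,
which is valid by memorylessness. The time axis is weekday-continuous
(hour 23 of one day is followed by hour 0 of the next; weekends are
outside the model's scope).

Interpretations fixed here (the prose leaves them open): departure batches
use the same (μ, σ) law as arrival batches, capped at I; worker moves are
single-agent and do count toward C; oversize batch draws are capped at the
available pool rather than redrawn; window edges are half-open to avoid
double-firing at boundaries.

**Default parameters.** No reference parameter values are documented for
the WHIRS model, so the defaults here are this package's own calibration,
chosen once to reproduce the documented magnitudes of the real data: ≈5 000 shopper arrivals per
weekday, peak hourly camera counts 1 300–2 000, log-count growth ≈0.5/h
over 06:00–12:00 and decay ≈0.37/h over 13:00–19:00. They are
N = 20 000, N_w = 1 000, ε = 60, α = 0.15, β = 0.35, γ₋ = 60, δ₋ = 0.5,
γ₊ = 40, δ₊ = 0.25, μ = 1.0, σ = 0.5.

A deterministic mean-field integrator (`mean_field_hourly_counts`) solves
the expected-flow ODEs with the same gating, vectorised over (α, β) pairs.
It tracks the stochastic ensemble mean within ~15% during busy hours and
serves as the identifiability yardstick for the rate-identification
experiment (below).

## The ensemble Kalman filter

The simulator is treated as a deterministic map of supplied randomness,
`X_{k+1} = M_k(x_k; ξ_k)`: given the same state, interval and generator
state the output is identical, so all stochasticity lives in per-member
substreams (spawned from one seeded parent for reproducibility). One cycle:

1. **Forecast** — evolve each member independently to the next observation
   time; ensemble mean and 1/(N−1) covariance summarise the forecast.
2. **Analysis** — draw per-member virtual observations z(i) = z + ν(i),
   ν(i) ~ N(0, R), and update
   `x̂(i) = x_f(i) + K [z(i) − H x_f(i)]` with
   `K = P_f Hᵀ (H P_f Hᵀ + R)⁻¹` (computed by a linear solve, never an
   explicit inverse). Virtual observations are required for the posterior
   spread to be correct in expectation.

Parameters are estimated sequentially by appending them to the state
vector: they persist through the forecast and are moved only by their
ensemble covariance with observed components. Numerical guard rails,
applied in raw space after each analysis: count components are rounded
half-away-from-zero and clamped at 0 before the next event-driven forecast
(the update is linear and real-valued; the simulator needs integers), and
rate components are clamped to a small positive floor (default 1e−6).

For states spanning orders of magnitude a per-component log mask stores
components in natural-log space; raw values below a floor (default 1, since
real data contain zero-count hours) are clamped before logging, with clamp
events counted. The WHIRS filter state is
(S, I, H, C, N, N_w, α, β, ε, γ₋, γ₊, δ₊, δ₋, σ, μ), everything but μ
logged (μ may be negative); R and W are reconstructed from the
conservation identities R = (N − N_w) − S − I and W = N_w − H, clamping
with pool-restoring adjustment if an update overshoots. A `tie_gamma`
switch collapses γ₋/γ₊ to one component for the 14-component layout; the
split layout is the default since the two worker windows have no physical
reason to share a base rate.

No covariance localisation or inflation is used — the state dimension is
at most 15 — and only the stochastic (perturbed-observation) EnKF is
implemented; the daily rate resampling below plays the inflation role.

**Verification.** On a scalar linear-Gaussian system the EnKF analysis
mean and variance at N = 10⁴ match the exact Kalman recursion within 2% at
every step. Because a single ensemble's sample variance at N = 10⁴ has
~1.4% relative noise, the check averages 8 independent filter replicates —
this separates Monte-Carlo noise from genuine bias, which is what the
convergence claim is about.

## Daily rate resampling with likelihood weighting

Real daily peaks are roughly lognormal with ≈45% spread and only ≈0.30
correlation between consecutive days, so a filter that tunes one rate pair
converges to a low-volatility compromise. The hybrid scheme instead
redraws each member's (growth, decay) pair every midnight from a bivariate
normal fitted to history (per day: least-squares slope of ln counts over
06:00–12:00, and the magnitude of the slope over 13:00–19:00, counts
floored at 1; a two-point endpoints mode is available). Members then run a
free 24 h forecast, and hourly observations only re-weight them:

    w_k(i) ∝ w_{k−1}(i) · N(ln z_k | ln f_k(i), σ²) ,

with σ = 0.05 matching the 5% multiplicative observation error. Weights
are maintained in log space with log-sum-exp normalisation, so extreme
outliers renormalise exactly instead of underflowing. Weights reset to
uniform at midnight — each day is fitted separately, which is the point of
daily resampling — and the day-end "update" is configurable: systematic
resampling of member states by final weights (default), or none (in which
case the day-end weights provably equal the normalised product of hourly
likelihoods, tested against that oracle). The rapid collapse of the
weights, a pathology in a particle filter, is the desired behaviour here:
it names the best-fitting rate pair early in the day.

**Identifiability and the planted-truth experiment.** Recovery of a known
planted rate pair among decoys is the scheme's acid test, but two effects
bound what any weighting can resolve: (i) hourly camera counts respond to
(α, β) along a near-unidentifiable ridge — within opening hours the
departure flux tracks the arrival flux whatever β is, so raising both
rates together barely changes the profile — and (ii) each member is a
single stochastic realisation whose own trajectory noise (≈5–13% per hour
depending on batch over-dispersion) is indistinguishable from rate signal
below that scale. Decoys are therefore screened in *profile space*: a
decoy is admitted only if the rms log-distance between its mean-field
hourly profile and the truth's is at least 0.25 (five times the 5%
observation error) over the in-window hours. The experiment itself runs the
shopper-only, unit-batch configuration (N = 20 000, ε = 180, α = 0.15,
β = 0.35, workers and batching off), where trajectory noise is ~5% per
hour and the counts match the calibrated scale; with 99 screened decoys the
planted member takes the top weight by 19:00 in ≥90% of replicates, and a
companion test shows recovery degrading monotonically as decoys approach
the truth. Parameter-space separation alone — however many prior s.d.s —
does not give reliable top-1 recovery, because of the ridge.

## Synthetic footfall generator

The generator emulates the documented structure of weekday footfall: per
day d it draws a (growth, decay) pair from N((0.5302, 0.3468),
diag(0.0851², 0.0884²) with covariance −0.0031), and a log-peak deviation
from a stationary AR(1). The hourly intensity rises exponentially from
06:00 to the 12:00 peak at the growth rate, decays exponentially to 19:00
at the decay rate, and sits on an overnight floor (30 counts/h) elsewhere.
Truth counts are Poisson around the intensity — giving the √mean
within-day noise a counting process must have, with all excess volatility
carried by the peak multiplier — and observations apply either additive
Gaussian (variance 16) or multiplicative lognormal (log-s.d. 0.05) error.
Daily peaks default to log-mean 8.43, log-s.d. 0.42 (≈4 600 mean, ≈45%
spread). Because the correlation target is quoted on the *count* scale,
the AR coefficient is set to
`ln(1 + ρ (e^{σ²} − 1)) / σ²` to undo lognormal attenuation (0.319 for
ρ = 0.30, σ = 0.42). A deterministic mode (`poisson_truth=False`,
`noise=None`) emits the exact intensity as a float-valued truth series, so
slope fitting recovers configured rates to 1e−10 — integer rounding would
otherwise put a floor on the recovery error.

What the generator does **not** emulate: weekly seasonality (weekdays are
exchangeable, so the "same hour last week" baseline holds no edge here,
unlike in real data where it is the strongest), holidays and one-off
events, daylight-saving 23/25-hour days (the reader flags them as gaps and
does not repair them), and weekend behaviour. Tests passing on generated
data therefore validate the estimators and the filter machinery, not those
aspects of real footfall.

## Replication experiments and problem sizes

The two box-model calibration experiments reproduce the documented setup:
rates α = 52.52, β = 0.2580 (themselves one draw from N(50, 25) and
N(0.25, 10⁻⁴)); ground truth from a rounded-normal(200, 200) start,
observed at t = 1..100 with additive noise variance R = 16; ensemble of
N = 100 members initialised like the truth. Parameter estimation
additionally draws each member's rates from the two priors. RMSEs are
scored at t = 1..100 (the initial time is not scored) and pooled across 30
seeds as the root of the grand mean squared error; the documented
single-run reference values sit inside the corresponding pooled bands. "Rounded normal" means
round half away from zero, then clamp at 0 — counts are people.

The WHIRS train/test workflow runs on data the model generates itself
(known parameters, 5% lognormal observation error), assimilating the log
camera count hourly; the final training ensemble seeds the test window and
the one-hour-ahead forecast is scored against the four baselines (per-hour
training mean; lags 1, 24, and 120 on the weekday-contiguous axis — five
24 h weekdays to a week). Member priors are lognormal jitter around the
truth (25% for parameters, 10% for state), this package's own choice since
no reference priors are documented. Default experiment sizes — 30 seeds
for the box experiments, 4 + 4 days × 3 seeds with N ∈ {10, 100} for the
WHIRS ordering check, 50 replicates for planted-truth recovery, 10⁶ events
for the invariant audit — were chosen so the full suite completes in a few
minutes on one CPU; all are plain function arguments.

## Known limitations

- The EnKF update is linear; for strongly non-Gaussian states (hour-9
  onset of the shopper window, near-empty compartments) it is only a
  best-linear approximation, which is visible as slow parameter drift.
- Single-day rate identification resolves only the ridge-transverse
  combination of (α, β); several days or exogenous information are needed
  to pin both.
- The real-data RMSE and rate-moment figures quoted in
  `evaluation.BRIGGATE_REFERENCE_RMSE` and
  `daily_filter.LEEDS_BRIGGATE_RATES` require the external Leeds dataset;
  they are carried as documented reference values and exercised only
  through the synthetic substitutes described above.
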
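# Methods

## Model

Windowed asynchrony-event counts x_1..x_n from one patient are modelled by
a hidden Markov chain with Poisson emissions: z_t ∈ {1..K} follows a
first-order Markov chain (initial distribution π, transition matrix A) and
x_t | z_t = j ~ Poisson(λ_j). The model is intercept-only: no covariates
enter the transition or emission side, so each state has a single fixed
event intensity and all temporal structure lives in the chain. Multiple
patients are assumed to share one parameter set; their sequences enter the
likelihood as independent chains (sufficient statistics are summed across
sequences in the M-step). A per-patient alternative —
`fit_per_sequence_average`, which fits each patient separately and averages
the canonically ordered parameters — is provided for sensitivity analysis,
but the pooled fit is the default and the headline.

Assumptions worth stating explicitly: counts are conditionally independent
given the state path (no within-state autocorrelation beyond state
persistence); emission variance equals the mean (Poisson), which is
adequate for regime-switching zero-heavy series because the mixture itself
produces the marginal overdispersion; and the chain is homogeneous in time.

## Estimation

Baum-Welch EM with scaled forward-backward recursions. Emission
log-probabilities are computed by log-gamma and shifted per window before
exponentiation, so the recursions stay finite for sequences of 10^5+
windows and means up to 10^3. M-step: λ_j is the γ-weighted mean count, A
rows are normalised expected transition counts, π is the mean first-window
posterior across sequences. Convergence: relative log-likelihood change
below `tol` (default 1e-6) or 500 iterations. Floors λ ≥ 1e-6 and
transition entries ≥ 1e-12 (before row normalisation) keep degenerate data
(e.g. all-zero series) finite; such fits also raise a warning.

Initialisation and restarts (default 10): the first restart clusters
log(1+x) with a short 1-D Lloyd pass seeded at quantiles — on the log scale
the regimes of a zero-heavy count series separate cleanly — and the
remaining restarts draw K random exemplars from the distinct observed
values. The exemplar restarts matter: deterministic starts can land every
restart in the same merged-state local optimum (two high-intensity regimes
fused into one intermediate λ), which random exemplars escape. The best
restart by final log-likelihood wins, and states are re-ordered so λ is
strictly increasing; all reported quantities are invariant to
initialisation label permutations.

## Decoding, intervals, forecasting

Smoothed posteriors γ_t and expected transition counts come from the same
forward-backward pass; the jointly most probable path comes from a
log-space Viterbi recursion. Time spent per state (`tspent`) is reported as
Viterbi-path occupancy, with the mean-γ version alongside — the two agree
closely on persistent chains, and Viterbi occupancy is the headline because
it corresponds to the decoded state assignment used everywhere else.

Per-state count intervals are equal-tailed Poisson intervals from the exact
quantile function: lo is the smallest k with CDF(k) ≥ (1−level)/2 and hi
the smallest k with CDF(k) ≥ 1−(1−level)/2. Equal-tailed (rather than
highest-density) is an interpretive choice; at small means the two
coincide, and the equal-tailed convention is the one whose endpoints match
the package's reference values across all four states.

One-step-ahead forecasts propagate the filtered posterior α_t through A;
the expected count is (α_t A)·λ and the predictive interval is equal-tailed
on the exact Poisson-mixture CDF. Because the mixture is skewed, the
expected count is not forced to lie inside the interval (it does in
practice). `risk_state_probability` sums the forecast state probabilities
from a threshold state upward — the quantity an alarm would monitor.
Empirical coverage of the 95% predictive intervals on 2000 simulated
windows lies within [92%, 98%]; discreteness makes intervals err on the
conservative side in the lowest state.

## Rates

Counts convert to an approximate per-breath rate via exposure: rate_j =
100·λ_j / e_j where e_j is the γ-weighted mean number of respiratory cycles
per window in state j — the fitted value of a log-link intercept-plus-state
exposure model. An equivalent Poisson-GLM route (statsmodels GLM of counts
on the Viterbi state with log-exposure offset) is available via
`method="glm"`; the two agree on well-separated states and the GLM route is
also used as a cross-check in the tests. With equal exposure across states,
rates are ordered exactly as λ.

## Cross-validated evaluation

Forecast error is assessed by k-fold cross-validation (default k = 5) with
*patients* (sequences) partitioned across folds — windows of one patient
never appear on both sides of a split. For each fold the model is fitted on
the training patients, frozen, and used to filter each held-out sequence;
forecasts start at the second window (the first has no history), and the
zero-prediction base model is scored on exactly the same windows. Per-fold
RMSE pools all windows in the fold (the variance-minimising convention; the
per-patient-average alternative weights short sequences up). Summary: mean
RMSE and SE = SD/√k per model.

## Cardiovascular episode analysis

Within-window HR/SpO2 samples are treated as equally spaced, so the time
fraction in episode is the fraction of samples beyond the threshold
(bradycardia HR < 60 bpm, tachycardia HR > 100 bpm, hypoxemia SpO2 < 90%).
Per state: %episode is the percentage of that state's windows with at least
one episode, and tepisode the mean (SD) of the within-window time
percentage. Windows without samples are missing, excluded rather than
imputed; a state with no windows gets NaN, never 0. The analysis is
deliberately descriptive — no significance testing and no causal claims.

## Synthetic data

The generator defines the study conditions for every test. Reference
ground truth (`default_ground_truth`): K = 4 states with λ = (1, 11, 38,
119) events per 15-min window; lowest-state transition row (0.85, 0.13,
0.02, 0.00); the remaining rows completed by detailed balance against the
long-run occupancy (0.52, 0.28, 0.14, 0.06) with small chosen up-rates
(0.05, 0.01, 0.05), which makes that occupancy the exact stationary
distribution while keeping every row diagonal-dominant and switches
concentrated on neighbouring states. Exposure defaults to 330 breaths per
15-min window (≈22 breaths/min, a typical ventilated respiratory rate).

`make_persistent_matrix` builds birth-death chains for arbitrary target
stationary distributions: up-rates u_i = min(1, π_{i+1}/π_i), down-rates by
detailed balance, all off-diagonals scaled uniformly so the busiest row's
diagonal sits exactly on the persistence floor. Detailed balance makes the
target distribution stationary analytically (verified to 1e-8 against an
eigen-decomposition oracle in the tests).

The breath-stream generator draws Poisson breath totals per window,
uniform timestamps within the window, and at most one asynchrony type per
breath (categorical draw) — adequate to exercise the indexing stage, which
itself handles multi-type breaths from external data. Cardiovascular series
are state-conditional Gaussians (HR mean ≈ 86-90 bpm, SD 14, similar across
states; SpO2 mean 96.5 down to 93.5 in the top state, SD 2.2-3.0), SpO2
clamped to (0, 100]. Only the *ordinal* pattern — hypoxemia burden rising
with the risk state — is treated as meaningful; the generator does not
calibrate episode magnitudes, distributional shape, or HR/SpO2
cross-correlation to real ICU data. Passing tests therefore demonstrate
that the pipeline recovers known structure of this kind, not that real
patients obey Gaussian vitals or exact Poisson emissions.

What the generator does not emulate: 200-Hz airway waveforms (asynchronies
exist only as labels), between-patient parameter heterogeneity (all
sequences share one chain), missing data and monitoring gaps, and
non-stationarity over a multi-day stay.

## Problem sizes and numerical choices

Recovery checks run at 20,000 simulated windows (≈208 patient-days at 15
min), where EM recovers λ within a few percent and the informative
low-state transition entries within ±0.01. The replicate-level recovery
property (λ within 10%, every A entry within ±0.03, in ≥90% of 20
replicates) is tested at 5,000 windows on a uniform-occupancy persistent
chain so each state is visited ≈1,250 times and the band sits several
standard errors above estimator noise; with rare-state occupancies as low
as 6%, a ±0.03 band on that state's row is not a 3-SE statement at that
sample size. Cross-validation experiments use cohorts of 20 patients × 240
windows (2.5 days each); the HMM's pooled-fold RMSE beats the zero
baseline in ≥19/20 seeded replicates under these conditions.

Tie-breaks and degenerate inputs: Viterbi ties resolve to the lower state
index (argmax convention); empty breath tables index to an empty series
rather than an error; windows are half-open with the boundary breath in the
later window, the origin is the first timestamp truncated to the minute,
and the trailing partial window is dropped so Poisson exposure stays
homogeneous — judged against an explicit recording `end` when supplied,
else the last breath's timestamp.

## Known limitations

Single emission family (no negative-binomial or zero-inflated
alternatives), no covariates, no Bayesian uncertainty on (π, A, λ) —
intervals quantify count variability given the state, not parameter
uncertainty. K is user-set, not selected by information criteria. The rate
conversion assumes exposure is well estimated per state and does not model
breath-rate dynamics.
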
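# Methods

This note documents the models, estimators and numerical choices behind
`spikeswitch`, and what the synthetic-data validation does and does not
establish.

## Rate series

The analysis epoch is the last 500 ms before the saccade (saccade onset =
0 ms; the test bar appears near −510 ms). r(t) averages the spike count in
a 100 ms window slid in 20 ms steps. A 100 ms window confined strictly to
a 500 ms epoch yields 21 interior positions, which conflicts with the
stated 25-bin discretization of the epoch; we keep one bin per 20 ms step
(500/20 = 25), windows centered at −490 + 20k ms, so the first window
reaches back to −540 ms and the last forward to +40 ms. This preserves
both the bin count and a constant 100 ms denominator; the alternative
(truncated edge windows) is noted but not implemented. Windows are
half-open `[c−50, c+50)` so a boundary spike is counted exactly once.

## Permutation linear models

Each model regresses r(t) on a per-trial scalar independently per bin:
MT on all completed trials (`lm_mt`); signed TRO on correct trials of one
response side (`lm_tro_pos`/`lm_tro_neg`); |TRO| on all correct trials
(`lm_diff`). Error trials are excluded from the difficulty models because
error counts per neuron are small and error activity may differ in kind.
Whether the MT model should also exclude error trials is not determined by
the design; all completed trials are pooled by default.

The null distribution permutes the regressor labels across trials — one
permutation per surrogate shared by all 25 bins, which preserves the
temporal autocorrelation of r(t) under the null; that autocorrelation is
exactly why a per-bin test alone is not trusted. Defaults: 100 surrogates;
per-bin significance at α = 0.05, two-sided for the slope (the null
envelope is symmetric) and upper one-sided for R². The run-length null
scores each surrogate's per-bin statistics against the empirical envelope
pooled over all surrogates (including itself) and takes its longest run;
leave-one-out scoring would remove a negligible bias at n = 100 at 100×
the cost, so pooled is the default. Monte-Carlo p-values use the add-one
rule p = (1 + #{null ≥ obs})/(n + 1), so p > 0 always.

Population decisions: Benjamini–Hochberg step-up (via
`statsmodels.stats.multitest`) on the slope run-length p-values and,
separately, on the R² run-length p-values; a neuron is flagged when both
survive at the stage's Q (0.05 for `lm_mt`, 0.1 for the difficulty
models) *and* the two significance masks intersect in at least one bin.
The largest such intersection is the encoding window; when a response
side has both a TRO-model and a |TRO|-model window, the longer one wins,
ties going to the earlier interval.

The bin-wise OLS is the closed-form simple-regression solution evaluated
as matrix products over (surrogates × bins); with constant response in a
bin (zero variance) the contract is slope 0, R² 0.

## Switch-point HMM

Within a trial the neuron occupies one of two hidden states emitting
spikes as a Poisson process with intensity λ_q; at 2 ms bins this gives a
Bernoulli observation model with per-bin spike probability
E_q = 1 − exp(−λ_q·0.002), and bins holding more than one spike are
clipped to 1. Parameters (2×2 transition matrix, two emission
probabilities, initial distribution) are estimated by Baum–Welch on a
seeded random 80% of the trials of one response side; the model then
Viterbi-decodes *all* trials of that side. The initial distribution is
estimated, not forced: trials empirically start in the low state because
the data say so.

EM initialization: emissions at 0.5× and 1.5× the pooled spike
probability with multiplicative log-normal jitter (σ = 0.1), transition
diagonal 0.98, uniform initial distribution; 5 restarts keep the best
training likelihood. Emission probabilities are floored at 1e-6 (and
capped at 1 − 1e-6); transition rows and the initial distribution are
floored at 1e-8 and renormalized. Convergence at absolute log-likelihood
change < 1e-6 or 300 iterations. All-empty training data is a valid
degenerate input: both emissions sit at the floor and the fit is flagged.
States are relabeled so emission probability increases with index
(state 0 = low); Viterbi ties break toward the lower-index state.

Reliability (all three required): (a) the mean dwell time of every
visited state, pooled over visits and trials of both sides, is at least
25 ms; (b) no decoded trial changes state more than three times; (c) at
least five trials of each response side contain a state change. Dwell
times are pooled over visits rather than averaged per trial (a per-trial
variant is a config option on `reliability_check`). t90 is the
ceil(0.9·n)-th order statistic of the switch times of switching trials
and requires at least five of them. A 3-state variant is available for
BIC comparison (`compare_state_counts`), with p = Q² − 1 + Q free
parameters (Q(Q−1) transition + Q−1 initial + Q emission) and T = total
observed bins.

**Known limitation — single-trial timing precision.** For a rate step of
5 → 30 Hz in 2 ms Bernoulli bins, the per-bin Kullback–Leibler divergence
between the two emission distributions is ≈ 0.05 nats, so any changepoint
estimator's single-trial error has scale ≈ 1/KL ≈ 18 bins ≈ 36 ms. On
generator data the exact maximum-likelihood changepoint with the true
rates known achieves a median absolute error of ≈ 35 ms; the fitted-HMM
Viterbi decoder matches this (≈ 38 ms) with near-zero median bias
(≈ +7 ms). Per-trial switch times at these rates are therefore accurate
to roughly ±2 rate bins, not to one; population-level statistics (t90,
Kendall correlations with |TRO|) are much more precise because the bias
is small and errors average out.

## Mechanism tests

Difficulty is operationalized as |TRO| (larger = easier). Both Kendall
tests use the tie-corrected tau-b (scipy) with two-sided p-values and
pool correct trials of both response sides; all-tied data return τ = 0,
p = 1 by contract. The switch-time test correlates per-trial decoded
switch times with |TRO| over correct switching trials. The rate test
correlates the per-trial mean rate in [t90, end of encoding window) with
|TRO|; a side whose t90 falls at or after its window end is skipped.

The binary test takes the per-trial mean rate in the encoding window
(correct trials of one response side) and compares a single Gaussian
(ML fit, 1/n variance) with the equal-weight mixture
0.5·N(μ1,σ1) + 0.5·N(μ2,σ2). The weights are structurally fixed at 0.5 —
the mixture has exactly 4 free parameters; a free-weight variant (p = 5)
is not the default. EM updates only means and SDs; restarts are seeded
random pairs of data points with the pooled SD, plus one restart at the
single-Gaussian solution — an EM fixed point whose likelihood equals the
single Gaussian's, which guarantees the mixture likelihood never falls
below it. Convergence at relative log-likelihood change < 1e-8 or 500
iterations; best of 10 restarts; components returned with μ1 ≤ μ2.
Component SDs are floored at 1e-3 of the data SD (1e-6 absolute if the
data are constant) to keep the likelihood bounded away from single-point
collapse.

ΔBIC = BIC_mixture − BIC_single with BIC = −2 lnL + p ln T, T = number of
trials. ΔBIC ≥ 0 ends the test (not binary); otherwise the null
distribution of ΔBIC is built by refitting both models on datasets drawn
from the fitted single Gaussian (default 2000 resamples) and
p = (1 + #{null ΔBIC ≤ observed})/(resamples + 1). If more than 5% of
resample EMs fail to converge the comparison carries a warning flag.

Classification applies BH-FDR at Q = 0.05 within each family (switch-time
τ, rate τ, ΔBIC p over neuron × side); `binary_any_side` needs one
significant side, `binary_both_sides` both. Switch-time and rate flags
additionally require a reliable HMM. Intersection counts over the three
mechanism classes (and MT × difficulty) are recomputable from the
per-neuron flags in the report.

## Synthetic sessions

The generator reproduces the statistical structure the analysis assumes,
not the biophysics. Choices follow a logistic psychometric curve
P(left | TRO) = 1/(1 + exp(β·TRO)) with β = 1.1 /deg by default, chosen so
errors are common at |TRO| = 1 (≈ 25%) and rare at 4 (≈ 1%), the shape of
a typical psychometric curve in this task class. MT is Gaussian around
mt_base − mt_gain·|TRO| on correct trials and mt_base + mt_gain·|TRO| on
errors (the minimal model producing the X-shaped chronometric pattern),
truncated to (0, 1200] ms; defaults mt_base = 300 ms, mt_gain =
10 ms/deg, mt_sd = 50 ms make the pattern detectable at ≈ 40 trials per
level. Default task: TRO ∈ {±1..±4}°, 40 trials/level.

Spike trains are exact inhomogeneous-Poisson draws (per-segment Poisson
counts, uniform placement) over the recorded epoch [−1000, +100] ms.
Mechanisms: `switch_time` steps λ_low → λ_high at
switch_anchor − switch_gain·|TRO| + N(0, jitter); `rate_code` steps at
switch_anchor + jitter to λ_high + rate_gain·|TRO|; `binary` steps with
probability clip(p0 + p1·|TRO|, 0, 1) or stays low; `mt_code` fires
homogeneously at clip(λ_low + mt_gain_hz·(MT − mt_base), 0, ∞); `null`
homogeneously at λ_low. Defaults: λ_low = 5 Hz, λ_high = 30 Hz (20 Hz
baseline for `mt_code`/`null`), switch_anchor = −250 ms, switch_gain =
25 ms/deg, jitter SD = 20 ms, rate_gain = 2 Hz/deg, p0 = 0.2,
p1 = 0.15/deg, mt_gain_hz = 0.1 Hz/ms. Each neuron's random substream is
keyed by (master seed, neuron id), so rosters can change without
perturbing other neurons.

What passing tests on these sessions shows: the estimators are calibrated
(type-I control of the permutation/run-length/FDR chain; ΔBIC null rate),
powerful against their designated alternatives, and internally consistent
(oracle agreement for OLS, BH, Viterbi; EM monotonicity). What it does
not show: robustness to features real recordings have and the generator
lacks — non-Poisson variability, refractoriness and bursting, slow
nonstationarities, gradual ramps rather than steps, and correlated noise
across simultaneously recorded neurons.

## Pipeline and problem sizes

`run_pipeline` executes behavior → linear models → HMM (difficulty
neurons only, by default) → mechanism tests → classification, all seeded
from one master seed; per-stage summaries, skip reasons and the config go
into a versioned JSON report. The validation suite and
`scripts/acceptance.py` choose problem sizes that keep a desk run
comfortable while leaving estimates well-determined: 100–200 neurons for
calibration runs, 320 trials per session, 100 permutation surrogates,
300–500 ΔBIC resamples (the full 2000 is the analysis default), and
10–20 neurons per mechanism for the end-to-end confusion runs.
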
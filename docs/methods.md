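# Methods

This note documents the models, estimators and numerical choices behind
`nirsgc`, and what the synthetic benchmarks do and do not establish.

## Signal model and preprocessing

The pipeline consumes trial-epoched ΔHbO signals, `channels × time ×
trials`, sampled at `dt = 0.13 s`. Continuous recordings are conditioned
by a zero-phase Butterworth bandpass (0.02–0.3 Hz, 4th order per pass,
8th-order effective magnitude), after which a constant is subtracted per
channel so the first sample is zero; bidirectional optical-pathway pairs
are averaged; epochs span [−5, 15) s around each trial onset and are
baseline-corrected by the [−5, 0) s mean.

Numerical choices. Window membership is half-open in sample time
(`a ≤ t(k) < b`), fixed once for epochs, baselines and all summary
windows; with `dt = 0.13 s` a 20 s epoch has 154 samples. Filter edge
transients are handled by reflective padding scaled to the slow cutoff
(`max(3·(2·order+1), 0.5/(low·dt))` samples), and the filter output is
symmetrized over time reversal — the mean of filtering the signal and of
time-reverse-filtering its reverse — so the zero-phase property
`filter(reverse(x)) = reverse(filter(x))` holds exactly rather than up to
an edge transient. Onsets whose epoch would cross a recording edge are
skipped with a logged warning.

## Time-varying MAR estimation (self-tuning Kalman filter)

The tvMAR model is `x(t) = Σ_k A(k,t) x(t−k) + ε(t)` with innovation
covariance `Σε(t)` and a random-walk prior on the coefficients. The
estimator is a per-time-point Kalman update in which the `R` trials at
trial time `t` enter as one observation batch; the state is the stacked
coefficient matrix (`n·p × n`). Because every update is a symmetric sum
over trials, the fit is exactly invariant to trial ordering.

The random-walk noise covariance is never estimated explicitly. Its
effect is absorbed into a self-tuning adaptation constant: before each
update the state covariance is inflated by `(1 + c_t)` with

`c_t = clip( adapt_init · m_t / m̄_{t−1}, adapt_min, adapt_max )`,

where `m_t` is the mean squared across-trial innovation at time `t` and
`m̄` its exponential moving average. At steady innovation magnitude the
filter forgets at the baseline rate `adapt_init` (default 0.05, bounds
[1e−4, 0.5]); a burst of innovation (e.g. a step change in a coupling)
transiently raises the gain. On a synthetic mid-epoch step the fitted
coefficient crosses the midpoint between pre- and post-values within
about 1.6 s (the tests require ≤ 2 s).

Gain computation uses whichever space is smaller: a trials-space solve of
`Z P Z' + r I` by eigendecomposition with a relative eigenvalue floor of
1e−8, or, when trials outnumber coefficients, the Woodbury
coefficient-space form `(I + P Z'Z/r) K = P Z'/r`, where the
observation-noise identity term regularizes rank-deficient regressor
covariances. The state covariance is symmetrized and eigenvalue-floored
at zero after each update.

`Σε(t)` is the across-trial sample covariance of the prior one-step
prediction errors, smoothed by an exponential moving average with a 0.5 s
half-life (raw per-time covariances are noisy at realistic trial counts),
with diagonal entries floored at 1e−12 times the channel variance so GC
log-ratios stay finite. Initialization: zero coefficients, state
covariance `10 · I`; the first 3 s of the fitted window are treated as
estimator burn-in and excluded from default GC reporting (the standard
analysis fits [−5, 10] s and reports [−2, 10] s). The first `p` epoch
samples serve only as lagged regressors, so coefficient estimates start
`p` samples (1.95 s at the standard settings) after the epoch begins. The defaults `p = 15`,
fit window [−5, 10] s and report window [−2, 10] s are the standard
analysis settings; synthetic benchmarks use smaller orders matched to
their generating models.

## Conditional Granger causality

For each fitted time `t`, the model `A(·,t), Σε(t)` is treated as locally
stationary. The full-model residual variance of target `j` is
`σ_j(t) = Σε(t)[j,j]`. The reduced variance `σ_{j∖i}(t)` — target `j`
predicted from all channels except source `i` — is computed without
refitting on data:

1. the exact autocovariance sequence `Γ_0 … Γ_q` of the time-local VAR is
   obtained from the companion-form discrete Lyapunov equation, solved by
   a doubling recursion batched over time points, and extended by the
   Yule–Walker recursion;
2. an AR(`q`) model for the non-source channels is solved from the exact
   autocovariances (multivariate Yule–Walker, block-Toeplitz system with
   a 1e−10 relative ridge), giving the reduced residual covariance
   `Γ_0 − Σ_m B_m Γ_m'`.

The sub-process of a VAR is VARMA, so the AR(`q`) reduction approximates
`σ_{j∖i}` from above with a bias that decays geometrically in `q`;
the default `q = max(3p, 8)` makes the bias negligible against the
estimators' sampling noise (the efficient path agrees with a full
reduced-model refit to a median absolute difference of ~5e−4 on the
4-channel benchmark, against a 0.05 tolerance). This reduction was chosen
over iterative spectral factorization on a frequency grid because it is
exact up to the truncation order, has no convergence failure mode, and
batches cleanly over time.

In exact arithmetic `σ_{j∖i} ≥ σ_j`, so `GC ≥ 0`; values that fail by
numerical error are clipped to zero and the clipped fraction and raw
minimum are reported in the tensor's diagnostics. Time points whose local
model is unstable (companion spectral radius ≥ 1, typically early fit
times at very small trial counts) are marked missing (NaN) and logged,
never silently zeroed. The definitional route — refitting the tvMAR on
all channels except the source — is retained as
`conditional_gc_reduced_refit`, the correctness oracle in the tests.

## Region-level summaries

Channel-level changes are `post − pre` GC differences per ordered pair
and time. For ROIs A ≠ B, the region-level increase is the largest
positive channel-level change over pairs `(i ∈ A, j ∈ B)` and the
decrease the smallest negative one, each set to zero when no change of
that sign exists; time-integrated summaries first sum the positive and
negative parts over the window, then take the max/min across pairs. The
five 4 s windows [−2,2), [0,4), [2,6), [4,8), [6,10) are exactly
half-overlapping under the half-open convention and their union equals
the whole [−2, 10) window, so whole-window and union-of-windows
integration agree exactly. Relative changes are
`ΔGC⁺_aff − ΔGC⁺_unaff` and `|ΔGC⁻_aff| − |ΔGC⁻_unaff|` (positive =
more pronounced for affected-hand use). Hemisphere means average the
whole-window summaries over all ordered ROI pairs in each group (ip–ip,
co–co, ip–co), with non-significant entries contributing zero; medial
ROIs (the SMA) count toward both within-hemisphere groups and never
toward ip–co, and cross-hemisphere pairs are pooled over both directions.
Within-ROI channel pairs are excluded from region summaries but included
in the channel-level increase matrix and seed-channel views. Ties in the
max/min keep the value (the summaries are scalars; no argmax is
reported).

## Permutation inference and FDR

Significance of any scalar family is assessed by permuting the pre/post
labels of the pooled trials — within each hand condition separately,
preserving group sizes — and recomputing the full statistic (model refit
included) per surrogate. `p = #(|surrogate| ≥ |observed|)/B`; `p = 0` is
reported as-is, with the conservative `(r+1)/(B+1)` estimator available
as an option. Surrogate streams are counter-based
(`SeedSequence(seed, spawn_key=(surrogate, attempt))`), so results are
reproducible and independent of evaluation order; a failed surrogate is
retried on its next sub-stream and counted. BH step-up flags are computed
collectively over each analysis family at `q = 0.1`, with no dependency
correction.

One property worth knowing: one-sided positive-part statistics (ΔGC⁺)
have a point mass at zero, which makes their permutation p-values valid
but conservative rather than uniform under the null. The calibration and
uniformity tests therefore use the continuous net integrated change; the
type-I error rate at the 0.05 level is 0.04 over 500 null repeats with
`B = 199`.

## Synthetic data

The generator emulates the study conditions: trial-structured epochs
(default 154 samples = [−5, 15) s at `dt = 0.13 s`, onset at sample 38),
trial counts in the hundreds (default 300), independent trials sharing a
piecewise-constant time-varying VAR coefficient schedule, Gaussian
innovations with configurable covariance, i.i.d. Gaussian measurement
noise added after generation (default sd 0.1), and an optional
trial-amplitude variability knob (lognormal, default off, since
trial-to-trial ΔHbO amplitude variability is not well characterized). A
burn-in of `10·order` samples is discarded so trials start near
stationarity, mirroring trials excerpted from ongoing recording. Every
schedule is checked for companion spectral radius < 1 at all times before
generation; violations are rejected with the offending time index.
Signals are generated directly in the hemodynamic band through the
sampling interval and smooth AR dynamics — no hemodynamic response
convolution, optics simulation, or deoxygenated-hemoglobin channel — so
the benchmarks exercise the estimation pipeline, not the biophysics.
Passing tests therefore establish estimator correctness on VAR-generated
hemodynamic-band data; they do not establish robustness to motion
artifacts, physiological confounds, or HRF-induced temporal blurring in
real recordings.

## Benchmark problem sizes

The test suite and acceptance script run desk-scale versions of each
check, chosen once as the smallest sizes at which the quantities of
interest are stable: the bivariate and 4-channel stationary benchmarks
use 200 trials × 80 samples with fit order 3; the null-calibration
scenario uses 2 channels, 10 trials per condition, 24-sample epochs, fit
order 1, 500 repeats at `B = 199`; end-to-end recovery uses the 5-channel
demo scenario (3 ROIs, one planted coupling increase of 0.3) with 100
trials over 20 seeded repeats. The documented standard settings
(`p = 15`, `B = 1000`, 27–30 channels) remain the defaults of the
pipeline configuration.

## Known limitations

- The adaptation law of the self-tuning filter is one reasonable member
  of a family; its constants are exposed in `StokOptions` rather than
  claimed optimal.
- The AR-truncated reduction is exact only in the limit `q → ∞`;
  pathological near-unit-root models may need a larger `reduced_order`.
- One tvMAR is fitted per condition (all trials pooled); per-session
  fitting is not implemented.
- Frequency-band-resolved GC is out of scope; only the time-domain index
  is reported.
- The SNIRF reader is minimal (one data block, uniform sampling,
  stimulus onsets only).
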
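# Methods

This note documents the models and estimators implemented in `painlfp`, the
defaults and why they were chosen, the statistical structure of the
synthetic sessions the tests run on, and the package's known limitations.

## Session model and conventions

A session holds per-region channel × time LFP matrices in µV on a common
clock (seconds, float64, session-relative), sorted spike trains, and an
event table (stimulus / spontaneous-behavior / control events with optional
paw-withdrawal latency and stimulus intensity; missing optional values are
NaN, never zero). LFP is stored and analyzed at 1000 Hz: all analysis bands
live below 100 Hz, so 1 kHz preserves the full band with a 5× margin over
Nyquist. Episode windows are defined relative to event onsets — evoked
analyses use [0, 5] s after the stimulus, spontaneous analyses [−5, 5] s
around the behavior onset — and window slicing is sample-exact with spike
times re-referenced to the window start.

On disk a session is a directory of `lfp_<region>.h5` (float32 µV,
channels × samples, with `fs` and `channel_ids` attributes), `spikes.csv`,
`events.csv`, and `session.json` (regions, clock origin, provenance
including the generator seed). Loading validates every container invariant:
shared time axis, spikes and events within the extent, strictly increasing
spike times, no NaN.

## Synthetic sessions

The generator produces data with exactly the statistical structure the
estimators assume, with exported ground truth, so each downstream stage can
be tested against known answers.

**LFP mixture.** Each region's shared signal is
1/f background + theta + gamma + ERPs; channels add independent white noise
(default SD 10 µV over 4 channels). The background is spectrally shaped
white noise (power ∝ 1/f^α, α = 1, DC removed, SD 15 µV). Theta is a
25 µV sinusoid at 6 Hz with a random initial phase. The gamma carrier
(50 Hz, base envelope 10 µV) has instantaneous amplitude
`gamma_base_amp · (1 + m·cos(φ_θ(t) − φ₀))`, where φ_θ is the phase of the
*noiseless* theta component — so the injected coupling depth m ∈ [0, 1] and
preferred phase φ₀ are exact ground truth. ERP templates are biphasic
difference-of-Gaussians waveforms, trough-then-peak, 225 ms long (within
the 200–250 ms range a cortical pain ERP occupies), normalized so the
peak-to-trough amplitude equals the requested value; the trough is the
alignment point. Event-related gamma synchronization is modeled as a
multiplicative envelope gain after event onsets.

**Spikes.** A scalar AR(1) latent z_t = a·z_{t−1} + ε_t (a = 0.9,
σ_ε = 0.2, stationary start) drives per-unit Poisson counts
y_it ~ Poisson(exp(c_i·z_t + d_i)·Δ) in Δ = 50 ms bins. By default 60% of
units load positively (c = +0.5), 20% negatively (−0.5), 20% not at all,
with baseline rates exp(d) = 8 Hz — a mid-range cortical rate that keeps
per-bin counts informative without saturating. Evoked episodes add a
transient step (+1.5 by default, 2 s long — the timescale of a phasic
nociceptive response) to the latent mean, with onset jittered together with
the trial's ERP time and magnitude co-varying with the ERP amplitude, so
rate–ERP and detection–ERP correlations exist by construction. Spike times
are uniform within bins; optional theta phase-locking draws within-bin times
with von Mises weights exp(κ·cos φ_θ).

**Scenario.** A default session is a 60 s pain-free lead-in (tiled into
control windows), 30 evoked trials at ~24 s intervals with stimulus
intensity cycling through 100–250 mW, and 10 spontaneous events in the
inter-trial intervals. A per-trial nociceptive drive (intensity plus
trial-to-trial noise) sets both ERP latency (mean 0.8 s, shorter for
stronger drive) and amplitude (larger for stronger drive); the withdrawal
latency is a noisy affine function of the ERP latency. This yields the
positive latency–withdrawal and negative amplitude–withdrawal correlations
the analyses measure. Spontaneous episodes differ from evoked ones by
smaller ERPs (150 vs 250 µV base), probabilistic occurrence per region
(ACC 0.9, S1 0.7), an S1 lead of 80 ± 50 ms (applied in both conditions),
and a gamma-envelope increase confined to S1. The schedule enforces
non-overlapping [−5, 5] s episode windows.

**What the generator does not emulate** — and hence what green tests do
not certify about recorded data: non-stationary background and movement
artifacts, volume conduction between regions, spike-sorting errors,
non-Poisson firing (bursting, refractoriness), latent dynamics beyond a
scalar AR(1), frequency drift of the oscillations, and condition-dependent
changes in coupling depth (only the gamma envelope gain changes between
conditions).

## Signal primitives

Filtering is a 4th-order Butterworth applied forward–backward
(`sosfiltfilt`), i.e. zero-phase with no group delay. The analytic signal
reflect-pads by 1 s before the Hilbert transform and trims afterwards to
suppress edge transients. The dominant component is the first principal
component of the channel-centered matrix over the analysis window only,
rescaled to mean-channel units (so amplitudes remain comparable to µV on a
single channel) and sign-oriented so the largest deflection is
negative-going, matching the trough-first ERP convention. The theta band
defaults to 4–8 Hz and is configurable.

## Single-trial ERP detection

Pipeline: slice the episode window → band-pass 2–15 Hz → dominant
component → extremal trough (optionally restricted to a search
sub-interval, e.g. [0, 5] s post-stimulus) → flanking peak within one ERP
duration (250 ms) on either side. SNR is the peak-to-trough amplitude over
twice the baseline SD of the band-limited component, with the baseline
running from the window start to 1 s before the trough; when that leaves
under 250 ms of data the baseline falls back to the window excluding
±0.5 s around the trough. The acceptance threshold defaults to SNR ≥ 3,
which keeps the false-positive rate on noise-only windows at or below a few
percent (the flanking-peak constraint is what bounds it: the peak must
occur within 250 ms of the trough, so noise extrema rarely pair up).
One ERP per episode per region (the extremal candidate). ACC–S1
co-occurrence uses greedy nearest-in-time pairing within ±3 s; the lag is
ACC minus S1 peak time, positive when S1 leads.

## Multitaper estimation

All spectral estimates use unit-energy Slepian (DPSS) tapers,
N = 2·TW − 1 of them: TW = 5 (9 tapers) for spectrograms, band power and
LFP–LFP coherence; TW = 3 (5 tapers) for spike–field coherence. PSDs are
one-sided and normalized so the integral over frequency equals the signal
variance; dB values reference 1 µV²/Hz. Spectrograms use 0.5 s moving
windows with a configurable step (1 ms nominal; the analysis drivers use
20–100 ms steps, which changes only the time grid, not the estimate).
Z-scored spectrograms standardize each frequency row by the mean/SD over
the 5 s pre-stimulus baseline columns. Coherence is the magnitude of the
cross-spectrum normalized by the auto-spectra, averaged over tapers and
trials; jackknife standard errors leave one independent estimate
(taper × trial) out. For independent signals the n-estimate null quantile
of magnitude coherence is sqrt(1 − (1 − q)^(1/(n−1))), used as the bias
floor in tests. Spike–field coherence bins spikes at the LFP rate (1 ms),
removes the mean rate, and runs the same estimator; fewer than 50 spikes
triggers a warning. Cross-correlograms band-pass both signals to 4–80 Hz
and normalize by the geometric mean of the energies.

## Phase–amplitude coupling

Theta phase and gamma amplitude come from the analytic signals of the
band-passed dominant component (defaults: phase 4–8 Hz, amplitude
30–80 Hz, with 30–50 and 50–80 Hz sub-bands available). The histogram has
18 equal bins over 0–360°; an empty bin (too little data) is an error
naming the bins. The r-statistic fits an identity-link GLM with a periodic
cubic B-spline basis (10 evenly spaced control points — enough to resolve
one- and two-lobe modulations without chasing noise) against the constant
null model A₀ (the mean amplitude), and evaluates
r = max |1 − A_s(φ)/A₀| on a 360-point phase grid. Confidence intervals
are a parametric bootstrap: 1000 coefficient draws from the fitted GLM's
Gaussian sampling distribution, r recomputed per draw, 2.5/97.5
percentiles. The preferred phase is the angle of
Σ_b A_b·exp(i·φ_b) over the 18 bins; since the bin phases sum to zero,
only the modulated part of the amplitude contributes.

On noiseless amplitude samples A₀(1 + m·cos(φ − φ₀)) the statistic equals
m to within spline-approximation error (< 0.02). On full synthetic LFP the
measured r is an attenuated, monotone function of the injected depth
(≈ 0.4 at m = 0.5, ≈ 0.74 at m = 0.8): band-pass filtering, the envelope
of a noisy carrier, and phase-estimation noise all shrink the apparent
modulation. Tests therefore assert the exact value only in the closed-form
limit, and monotonicity plus preferred-phase recovery on generated signals.

## Poisson linear dynamical system

Counts are binned over half-open-left intervals ((t−1)Δ, tΔ]; a spike
exactly on an edge belongs to the earlier bin. Δ = 50 ms matches the
evoked PSTH bin size.

**EM.** The E-step is a Laplace (Gaussian) approximation: a mode-finding
forward filter (3 Newton steps per bin on the log posterior of z_t given
the prediction) followed by an RTS smoother, giving smoothed means,
variances, and lag-one covariances. The M-step updates a and σ_ε in closed
form from the latent second moments and each unit's (c_i, d_i) by damped
2×2 Newton on the expected Poisson log-likelihood, using
E[exp(c·z + d)] = exp(c·m + c²V/2 + d). Identifiability is fixed after
every M-step by normalizing ‖c‖ = 1 with mean(c) ≥ 0 and absorbing the
scale into σ_ε (an exact invariance of the model). Initialization:
a = 0.9, σ_ε = 0.1, d = log(mean rate), c = the first principal direction
of the square-root-transformed counts; up to 3 seeded restarts keep the
best approximate log-likelihood. Convergence: relative log-likelihood
change < 1e−6 or 200 iterations. On data simulated at the study
conditions (a = 0.9, σ_ε = 0.2, 20 units, 2000 bins) the median error in
â is ~0.03 and baseline rates are recovered within a few percent.

**Forward filter.** The online detector uses the one-step recursions:
predict ẑ_{t|t−1} = a·ẑ_{t−1|t−1}, Q_{t|t−1} = a²Q_{t−1|t−1} + σ_ε²;
update with posterior precision
Q_{t|t}^{-1} = Q_{t|t−1}^{-1} + cᵀdiag(ŷ_{t|t−1})c and mean
ẑ_{t|t} = ẑ_{t|t−1} + Q_{t|t}·cᵀ(y_t − ŷ_{t|t−1}), where
ŷ_{t|t−1} = exp(c·ẑ_{t|t−1} + d)·Δ. The Z-score standardizes ẑ_{t|t}
by the empirical mean/SD of the filtered latent over the baseline bins
([−4, −1] s before the event); the filtered variance enters only through
the CI half-width 1.96·√Q_{t|t} (scaled by the baseline SD). The onset is
the first post-onset bin whose lower CI bound exceeds +θ₀ (or upper bound
falls below −θ₀); θ₀ = 1.65 corresponds to a one-sided Gaussian tail of
0.05. Spontaneous episodes reuse the evoked-fit parameters unchanged.

**Numerical regime of the one-step filter.** The precision update
linearizes the Poisson observation at the predicted mean, so its agreement
with the exact (numerically integrated) posterior depends on the innovation
scale: at σ_ε = 0.15 and a 20 Hz unit the maximum deviation of the
posterior mean over 50 bins is ~0.02–0.04; at σ_ε = 0.3 it can reach
~0.25. The oracle-equivalence test runs in the former regime, which is
also where the detector operates (per-bin latent increments are small
relative to the information in a 20-unit ensemble).

## Pain-modulated units

Stimulus-aligned PSTHs use 50 ms bins; ERP-peak-aligned PSTHs use 10 ms
bins smoothed with a 20 ms Gaussian kernel (reflecting boundaries, so the
area is conserved). A unit is modulated when its per-trial post ([0, 5] s)
vs baseline ([−5, 0] s) rates differ by a Wilcoxon signed-rank test at
α = 0.05, with direction from the sign of the median change; the rank test
was chosen because per-trial rate differences are small-sample and
non-Gaussian. The rate–ERP relation is ordinary least squares of per-episode
Z-scored rates (absolute values supported for population summaries) on ERP
peak-to-trough amplitudes, with the Pearson p-value.

## Classification of spontaneous episodes

Features are integrated multitaper band powers (dB) in the five canonical
bands × two regions × the pre ([−5, 0] s) and post ([0, 5] s) periods —
20 features per episode. Controls are count-matched, non-overlapping 10 s
windows tiled in the pain-free period before the first stimulus. The SVM
uses a polynomial kernel of degree 3 with C = 1 (both configurable; the
degree/penalty were fixed a priori at the library defaults for a small
feature space). Standardization to zero mean/unit variance and the SVM fit
see only training folds; accuracy is the mean over stratified 5-fold test
folds and AUROC comes from pooled decision values. Permuted-label runs
(labels reshuffled once per repeat) verify the 50% / 0.5 chance levels; a
linear-kernel run reports per-feature weights, which on synthetic data
correctly rank the S1 post-onset gamma features highest.

## Problem sizes

The test suite and the acceptance script run entirely on generated data at
these sizes, chosen to make every calibration statistically meaningful at
desk scale: EM recovery over 20 seeds of 20 units × 2000 bins; filter
oracle on 1 unit × 50 bins against a 4001-point grid integration;
PAC monotonicity over 4 depths × 10–20 seeds of 100 s signals; ERP
sensitivity over 40 injected windows and false positives over 200
noise-only windows; onset detection over 50 step trials and 200
constant-rate null trials; classification over 252 spontaneous + 252
control episodes pooled from 6 generated sessions with 20 permuted-label
repeats.

## Known limitations

- **Laplace-EM on unmodulated data.** When the data are independent Poisson
  (no latent), the Gaussian-approximate EM does not drive the latent
  variance to zero: σ_ε stabilizes at a residual floor (~0.08–0.16 across
  rates and durations tested) because the approximate E-step moments are
  self-consistent with a nonzero prior variance. The fitted model on null
  data therefore retains ~20–40% spurious rate-profile excursions. Null
  behavior of the *detector* is unaffected (the CI-crossing rule stays
  calibrated), and fits on genuinely modulated data recover the parameters;
  but fitted σ_ε near the floor should not by itself be read as evidence of
  latent dynamics.
- **One-step filter linearization.** See the numerical-regime paragraph
  above; with large per-bin latent jumps the one-step update undershoots
  the exact posterior.
- **Within-bin theta locking.** The generator locks spike times to theta
  only within each bin, so achievable locking strength grows with the bin
  width; bins shorter than a theta cycle cannot produce strong phase
  preference. Tests that need strong locking either use wide bins or draw
  inhomogeneous-Poisson spikes directly.
- **PAC scale.** The r-statistic on filtered field data is an attenuated
  measure of the generative coupling depth; comparisons are meaningful
  within a fixed band/filter configuration, not across them.
- **Single-session scope.** The classifier is evaluated per synthetic
  dataset (episodes pooled across generated sessions); cross-session
  transfer on recorded data is out of scope.
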
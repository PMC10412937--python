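# Methods

This note records the models, parameter choices and numerical decisions
behind `laminarfp`, and what the synthetic benchmark does and does not
establish about real recordings.

## Signal model and separation

Field potentials from a laminar probe are treated as an instantaneous
linear mixture `u(t) = V s(t) + noise` of a few spatially fixed generators.
The assumptions are the usual ones for ICA on local field potentials:
stationary mixing over the analysis epoch, at most one Gaussian source, and
more samples than 50× the component count. Separation runs FastICA with the
logcosh (negentropy) contrast on PCA-whitened data, with a best-of-5
multi-restart keyed off a single seed: each restart's summed
non-Gaussianity is scored and the best convergent run wins, which removes
most of FastICA's run-to-run variability. Output is canonicalized — unit-
norm profiles, largest-|loading| channel positive, amplitude carried by the
time course, components ordered by variance fraction — so results are
comparable across runs and sides. Generators below 1% relative variance
(reconstruction variance over total data variance, computed after PCA) are
rejected.

Two or more near-Gaussian sources make the ICA rotation arbitrary in their
subspace; the estimator warns (excess kurtosis below 0.1 on at least two
components) rather than failing.

Left/right profiles are matched by correlation distance `1 − r` with a
one-to-one assignment minimizing total distance; pairs are accepted below
0.2, the distance below which homologous profiles cluster. For profiles
that are nearly channel-constant (volume-conducted sources) the centred
correlation is dominated by residual ripple, so the metric falls back to
cosine similarity when a profile's spread is under 20% of its mean loading.
An average-linkage tree over the pooled profiles is returned for
inspection.

The minimal stable epoch length grows epochs from the record start in 5 s
steps and returns the first length from which every longer epoch's
bilateral correlation stays within 3% of the running mean of the shorter
epochs; if stability never sets in (e.g. the coupling is nonstationary) a
not-converged flag is returned.

## Preprocessing

Filters are 4th-order Butterworth applied forward-backward (zero phase);
passband amplitude is preserved to well under 1% once edges are trimmed.
Edge trimming uses three time constants of the *slowest pole* — for a
4th-order Butterworth that pole sits at cos(67.5°) ≈ 0.38 of the cutoff
radius, so the naive 1/ω_c constant underestimates settling by ~2.6×.
Down-sampling is polyphase rational resampling (anti-alias filter
included); non-rational rate ratios are rejected. Faulty interior channels
are replaced by the mean of their two neighbours; outer channels are
rejected. Large transients (sharp-wave-like events) are detected against a
median baseline with MAD×1.4826 as robust SD (default k = 5, 50 ms pad);
the resulting keep-mask is honoured by the coherence and windowed-Pearson
estimators, which drop any segment or window touching a masked stretch.

## Coupling statistics

Cross-correlation uses the biased normalization (divide by n), with the
convention that a positive peak lag means the second series trails the
first. Welch coherence uses 1 s Hann segments with 50% overlap at the
250 Hz analysis rate and per-segment mean removal; per-frequency
significance thresholds are the 95th percentile of coherences from
phase-randomized surrogates of *both* inputs (spectrum preserved exactly;
DC kept so the mean survives; the Nyquist bin gets a random sign). The
surrogate path runs in single precision with batched FFTs — the null
quantile is far coarser than float32 resolution — which makes the default
1000-surrogate test take about a second per minute of signal.

Windowed Pearson histograms use 41 uniform bins on [−1, 1]; windows with
zero variance (or masked samples) are recorded as missing, never as zero.
For independent inputs the per-window r has SD ≈ 1/√(n−1), so the
histograms flatten as Δt shrinks — this monotonicity is tested.

The gamma mean frequency is the reciprocal lag of the first positive-lag
autocorrelation maximum of the 30–100 Hz band-passed series, with a noise
floor of 3/√n; below it an undefined-frequency flag (NaN) is returned.

## Granger causality

Per 5 s window (80% overlap, order 12 at 250 Hz), reduced (own past) and
full (own + other's past) models are fitted by OLS on a shared design
matrix; `F = ln(RSS_reduced/RSS_full)`, averaged over windows. Windows
whose bivariate companion matrix has spectral radius ≥ 1 are dropped from
the average and counted. Window fits are batched: one lag embedding for the
whole series, per-window Gram matrices by a single matmul, and batched
25×25 solves, with a pinv fallback for exactly singular windows (which
arise when a block-resampling cut shifts a series by less than the model
order, duplicating lag columns). Spectral causality is Geweke's
decomposition evaluated on the full-series VAR transfer function — exact
for the model class fitted, with a logged jitter when the residual
covariance is near-singular; its frequency average agrees with the temporal
statistic within 10% on stable simulated VARs (tested).

Significance: the putative source is cut at one uniformly random point and
the blocks swapped (sample multiset and almost all autocorrelation
preserved), the window-averaged statistic recomputed, a normal fitted to
the surrogate values, and the threshold set at its 95th percentile. A
`resample="both"` flag also resamples the target. Surrogate windows are not
stability-filtered (the observed statistic is); non-finite surrogate values
(perfect-prediction degeneracies) are excluded, and the fit errors out if
fewer than half survive. The normal approximation slightly under-covers the
right tail of the skewed null, so measured false-positive rates sit a
little above the nominal 0.05 — the calibration experiment
(`laminarfp.calibration`) quantifies this. The calibration uses 120
surrogates per repetition: the normal fit needs only the null's mean and
SD, which are stable at that count, while the package default for single
analyses remains 1000.

## Deconvolution

Gamma waves are pulses `w f(t−τ; δ)` with `f(t;δ) = H(t)(t/δ²)e^(−t²/2δ²)`
(unit area; peak `e^{−1/2}/δ` at `t = δ`). Under iid Gaussian residual
noise, maximizing the log-likelihood is penalized least squares; the fitter
is greedy matching pursuit: matched filtering over a 12-point log grid of δ
(2–80 ms) picks the event giving the largest residual reduction, a local
least-squares pass refines (w, τ, δ), and a final global pass re-fits all
weights plus a constant baseline linearly. Two stopping rules: the
candidate's peak must exceed 4× the robust residual SD, and its mean-square
residual reduction *over its own support* must exceed 0.5% of the signal's
overall mean square. The support normalization keeps the rule meaningful at
any record length — a 5 ms pulse is a vanishing fraction of a 60 s record's
total energy no matter how large its amplitude, so an energy-fraction rule
would stop after a handful of events.

The method presumes a stable baseline (the Schaffer generator's regime);
when more than half the power lies below 4 Hz a quality warning is emitted,
since slow baseline fluctuations are absorbed into spurious wide pulses.

An event's support is `[τ, τ+3δ]` (the template has fallen to ≈5.5% of its
peak), and bilateral partners must overlap for ≥ 70% of the *shorter*
support; among admissible candidates a one-to-one assignment maximizes
total overlap with an ε-weighted onset-difference tie-break. Amplitude
covariation of paired events reports Pearson r of the absolute peak
amplitudes, the orthogonal (total-least-squares) slope, and the RMS
perpendicular distance to the identity line after normalizing both sides to
the largest amplitude.

## Synthetic scenes

The generator reproduces the analysis model exactly: per side,
`samples = profiles · timecourses + iid Gaussian noise`, with ground truth
(mixing, time courses, event lists, pairing map, directed links) stored
alongside. Profile shapes are Gaussian bumps, a single-reversal profile,
and a flat (volume-conducted) profile. Time courses are composed of

- Poisson trains of the canonical pulse (negative-going for synaptic
  generators), with bilateral pairing: a left event gets a right partner
  with the configured probability (onset jitter 2 ms by default), and
  independent right events restore the rate;
- sparse wide pulses (δ 30–60 ms) emulating sharp waves, always paired with
  tightly covarying amplitudes (5% per-side noise on a common weight);
- band-limited slow waves with a mild multiplicative bout envelope
  (mean ≈ 1, SD 0.8, clipped at zero, ~1 s timescale). The envelope makes
  the sources super-Gaussian — which is what lets ICA tell slow-wave
  generators apart — while preserving the analytic coherence construction:
  with a shared fraction `a = target^{1/4}` of the slow SD on both sides,
  the in-band magnitude-squared coherence is `a⁴ = target`. Narrowband
  filtering is done on padded noise so zero-phase edge transients never
  enter the record.

The default scene has six generators per side (Schaffer, L-M, LPP, MPP,
GCsom, remote) on a 32-channel probe with target channel-space SDs
1.0/0.9/0.7/0.5/0.35/0.6 (variance shares ≈ 33/27/16/8/4/12%, achieved by
dividing each target SD by its profile column norm — the flat profile alone
has squared norm 32). Slow-band coherence targets are 0.8 for Schaffer, L-M
and MPP, 0.9 for the remote source, and 0 for LPP and GCsom; only the
Schaffer generator has bilateral gamma pairing (probability 0.9). Slow-wave
generators carry small-weight gamma (mean weight 0.05): a unit-area pulse
train has flat low-frequency power, and since the two sides' trains are
independent, heavier gamma would dilute the coherent slow band below its
configured target. GCsom inherits 40% of its SD from the LPP time course (a
soma-layer generator echoing a synaptic input); the inherited fraction was
chosen analytically so that both generators remain recoverable — at
fraction c, the GCsom time-course correlation with its own ground truth is
√(1−c²) ≈ 0.92, and the LPP profile distortion stays below 2%. Paired gamma
weights are drawn independently per side, so bilateral gamma amplitude
covariation is weak by construction even though the waves themselves are
paired — the regime the Schaffer pathway shows in vivo — while sharp-wave
amplitudes covary tightly. No quantitative sharp-wave rate or amplitude
distribution is established for this preparation; the defaults (0.2/s,
weight 4) are placeholders labelled as such in the scene config.

What passing the synthetic benchmark does **not** show: the generator uses
the same linear instantaneous mixing the analysis assumes (no volume-
conductor forward model, no electrode drift), stationary statistics, and
Gaussian sensor noise. Recovery quality on real data will be bounded by
violations of those assumptions, notably co-activated pathways with
overlapping territories and state changes within an epoch.

## Problem sizes and determinism

Tests and the acceptance script run the protocol at desk scale: 60 s
records at the native analysis rates (1 kHz synthesis, 250 Hz for
coherence/Granger, 4 kHz for the windowed-Pearson null), 200 repetitions
for both null calibrations, 1000 phase-randomization surrogates, and 120
block-resampling surrogates per Granger repetition (see above), 200
injected pulses for deconvolution recovery, and 20 seeds for the end-to-end
coupling-contrast check, where "significant bilateral coherence" means a
majority of delta-band bins above threshold — a single bin above an α=0.05
threshold is expected by chance in a 4-bin band. Every stochastic stage
takes an explicit seed; the pipeline expands one global seed into
independent per-stage streams via `SeedSequence`, so toggling one stage
never shifts another's randomness, and a fixed seed reproduces recordings
and reports bit-identically.

## Known limitations

- Pairwise (not conditional) Granger causality only; common-driver effects
  between bilaterally coherent generators will flag both directions.
- The deconvolution K-selection is a greedy reconstruction validated by
  recovery tests, not a likelihood-ratio model-order criterion.
- kernel-density ICA is not implemented; the contrast is pluggable and
  FastICA's recovery meets the benchmark, but rhythmic-content-heavy data
  may benefit from a kdICA backend.
- The flat-profile fallback metric (cosine) means two *different*
  volume-conducted sources would match each other; with one remote
  generator per side, as here, that is moot.
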
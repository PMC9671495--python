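# Methods notes

## The generative model

Each simulated retrieval trial is

```
x_c(t) = n_c(t) + snr * [ p_c^T * g_T(t) * w(t)  (+ p_c^C * g_C(t) * w(t) on CC trials) ]
```

per channel `c`, where `n` is 1/f background noise (spectrally shaped
white noise, amplitude ∝ f^(−exponent/2), unit variance per channel so
`snr` is an amplitude ratio), `p^T`/`p^C` are fixed unit-norm spatial
patterns drawn once per subcategory and participant, `w(t)` is a boxcar
over the reactivation window (default 500–3000 ms post-cue), and the
gains follow the assumed phase-coding law

```
g(t) = 1 + depth * cos(phi(t) − phi_pref),   g in [1−depth, 1+depth].
```

`phi(t)` is the phase of a single planted oscillation (default 3 Hz) with
a random per-trial offset; the reference channel carries that oscillation
plus white noise at a separate SNR, because phase-estimation quality and
decodability are independent failure modes.  The competitor's preferred
phase is `phi_pref + planted_lag`, so a positive lag means the competitor
reactivates later in the cycle than the target.  Behavioural responses
realise the configured per-condition accuracies; errors flip the
supraordinate choice (or, at a configurable rate, become "no memory"),
and on competitive trials the erroneous subordinate choice matches the
competitor's subcategory with probability `intrusion_bias`.

What the generator deliberately does **not** emulate: continuous raw
recordings, sensor physics and geometry, physiological artifacts
(blinks/cardiac), trial-to-trial latency jitter of reinstatement,
non-sinusoidal or drifting oscillations, and any dependence of behaviour
on the neural signal.  Passing recovery tests therefore demonstrates that
the analysis chain measures what it claims under its own assumptions, not
that those assumptions hold in recorded data.

### Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `osc_freq` | 3 Hz | modulating rhythm; all phase analyses lock to it |
| `modulation_depth` | 0.6 | fractional amplitude modulation of reactivation |
| `planted_lag` | 34° | competitor − target preferred-phase difference |
| `pattern_snr` | 1.0 | pattern amplitude / per-channel noise SD |
| `ref_snr` | 5.0 | reference oscillation amplitude / reference noise SD |
| `accuracy` | .577/.789/.532 | per-condition P(both questions correct) |
| `intrusion_bias` | 0.85 | P(error subordinate = competitor's subcategory) |

The behavioural accuracies mirror the condition means of the experiment
this package models; no effect sizes (depth, SNRs) are reported for that
experiment, so the defaults are chosen once as values at which a
well-powered desk-scale study recovers its ground truth without being
trivially clean, and they are config-exposed rather than asserted.
Sample-size defaults (21 participants, 48 associations per condition, 204
channels) match the recorded study; tests and the calibration script use
reduced sizes (typically 12 participants, 8 associations, 16–24 channels)
as their stated problem sizes.

## Decoding

Features are per-channel amplitudes at one timepoint after 40 ms FWHM
Gaussian smoothing of the trial series; classifiers are binary LDA with
the pooled covariance shrunk toward a scaled identity using the analytic
Ledoit–Wolf intensity (computed on class-centred data, ML covariance
normalisation).  Equal class priors are used; the decision value is
oriented per trial so that positive d = evidence for that trial's true
designated subcategory.  Within-condition decoding uses stratified
10-fold cross-validation repeated 5 times with out-of-fold d-values
averaged over repeats; folds are stratified by subcategory.  Target and
competitor evidence on the same competitive trial always come from the
two different superordinate-category classifiers, trained only on
non-competitive trials.  Only correct competitive trials enter phase
analyses by default (`correct_only=False` reproduces the incorrect-trial
check).  A one-trial-per-fold overlap audit is part of the test suite.

## IRASA

Trials are cropped (default 500–3000 ms), mean-removed, Hann-tapered and
zero-padded to the next power of two; tapering precedes padding because a
hard zero edge biases the resampled spectra.  For each factor
h ∈ {1.1, 1.15, …, 1.9} the padded series is Fourier-resampled by h and
1/h and periodograms are computed on the nominal sampling rate; the
fractal spectrum is the median over factors of the geometric mean of each
h-pair, and oscillatory = total − fractal exactly.  Periodograms are
estimated per trial and **averaged across trials before** the geometric
mean and median: applying those nonlinear steps to single-trial
(exponentially distributed) periodogram bins biases the fractal estimate
low by ~25–30%, which would masquerade as broadband oscillatory power.
Spectra are reported up to `fs / (2·max h)`, the highest frequency with
valid resampled support.  The surrogate group test draws, 1000 times, one
label-shuffled spectrum per participant, forms group means per 1 Hz band
(bins `[k, k+1)` Hz, 3–8 Hz), and compares
`z = (real − mean_null)/sd_null` to the one-sided Bonferroni critical
value `z = Phi^-1(1 − 0.05/5) ≈ 2.32`.  A null with (numerically) zero
spread raises rather than reporting infinite z.

## Phase coupling and circular statistics

Reference phase comes either from a unit-normalised complex Morlet
convolution (0.5 s ≈ 1.5 cycles at 3 Hz; samples within the kernel
half-length of an edge are NaN) or from band-pass (±1 Hz) plus Hilbert
transform; phase 0 = cosine peak.  Pooled (trial, timepoint) fidelity
amplitudes are sorted into 10 bins partitioning (−π, π], left-closed
except the last bin (−π falls in bin 1, +π in bin 10).  The modulation
index shifts bin means by the global minimum *only when negative values
are present* — an unconditional shift would make the uniform profile
all-zero and MI(uniform) undefined — then normalises and computes
`MI = (ln N − H)/ln N`, clamped to [0, 1] against float rounding.  Signed
d-values are binned by default; this is one of two defensible readings of
"fidelity amplitude", and rectified variants can be built by
preprocessing the course.  Preferred phase is computed per trial (max-bin
centre, ties to the lowest bin) and circularly averaged per participant;
a small resultant length flags the angle as unreliable.  Rayleigh
(`z = nR²` with the standard small-sample exponential correction) and
V tests are implemented directly and validated against 100k-draw
Monte-Carlo nulls in the acceptance suite.  The intrusion-split
comparison computes within-participant target/competitor phase
similarity `|cos(Δ/2)|`, equates group sizes by seeded random removal,
and applies a Wilcoxon signed-rank test to the rank-ordered similarities.

## Cross-correlation lag

Fidelity courses are zero-phase band-filtered at the dominant frequency
(Butterworth, ±1 Hz), then correlated in sliding windows of one period
(330 ms at 3 Hz → nearest odd count, 83 samples = 332 ms at 250 Hz;
41 samples = 328 ms on the 8 ms fidelity grid).  Lags run to ±half a
period in integer samples (±177° at 250 Hz — the grid cannot represent
exactly ±180°), `deg = 360·lag_s·freq`.  Correlation is computed per
trial and averaged.  Sign convention, fixed and verified for internal
consistency: **positive lag / positive phase difference = competitor lags
the target**, in both the cross-correlation peak and the Hilbert
phase-difference timecourse (θ = target phase − competitor phase of a
delayed competitor is positive); the two estimates agree within 10° on
clean planted lags.  Surrogate lag maps give elementwise
`z = (real − mean_surr)/sd_surr` with zero-sd cells masked, forwarded to
the cluster permutation test over time × lag.

## Cluster permutation test

Per-cell one-sample or paired t statistics; cells with zero variance are
masked.  The forming threshold is the critical t of a configurable tail
at `forming_alpha` (library default: two-sided 0.05; the lag and
time-frequency analyses use one-sided presets).  Clusters use 1-D
adjacency or 2-D 4-connectivity, a minimum-size filter (default 1), and
mass = summed t.  The null is the distribution of the maximal |cluster
mass| over sign-flip permutations;
`p = (1 + #{null ≥ |observed|})/(n_perm + 1)`, so p can never be zero and
is permutation-exact.  Sensor-space neighbourhoods are out of scope.

## Numerical and design choices

- Polynomial detrending fits a Legendre basis on unmasked samples only
  (least squares via a shared pseudo-solve across channels); degree-30
  fits on a [−1, 1] domain stay well-conditioned.  For epoched-only data
  the epoch is reflection-padded by one epoch length on each side before
  masked fitting, standing in for the unavailable continuous context.
- MAD rejection: keep iff `|score − median| ≤ k·MAD`; with MAD = 0 and
  unequal scores only median-equal items survive.  The trial score is max
  |amplitude| after a 100 Hz high-pass (the statistic is configurable;
  max targets high-frequency bursts), the channel score its 1–100 Hz
  analogue with k = 3.  Rejected channels are replaced by the mean of the
  k nearest sensors on a stored 2-D layout (a synthetic grid by default).
- Band-pass filtering is a two-pass (zero-phase) Butterworth of order 3;
  any family meeting the ≥0.9 passband / ≤0.1 octave-away stopband
  contract would do.
- All stochastic steps take explicit seeds (`numpy.random.Generator` /
  `SeedSequence`); identical config + seed reproduces studies
  bit-identically.
- Degenerate inputs raise (`ValueError` subclasses) rather than returning
  NaN: single-class training sets, empty phase bins (with counts in the
  message), all-zero MI distributions, zero-spread surrogate nulls,
  < 3 angles, < 5 participants in the cluster test.

## Known limitations

- The epoch convention stores −1000…+3000 ms at 250 Hz with time 0 at cue
  onset; analyses default to −500/+500…3000 ms windows.
- Per-trial max-bin preferred phases are quantised to 36° bin centres;
  sub-bin resolution at the participant level relies on across-trial
  dithering, so single-trial phase estimates should not be
  over-interpreted.
- The sliding cross-correlation assumes both courses are dominated by the
  filtered frequency; broadband inputs yield flat, uninterpretable maps
  (the surrogate z-scoring is the guard).
- `morlet_power` NaN-pads frequencies whose wavelet exceeds the epoch and
  flags wavelet-length edge regions; values inside those regions are not
  estimable from the epoch alone.
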
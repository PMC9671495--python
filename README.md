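# thetasep

Tools for studying **phase separation of competing memory reactivations
along a slow oscillation**, built for cognitive electrophysiologists who
analyse time-resolved decoding of MEG/EEG epochs.

When a retrieval cue is linked to two overlapping memories (a relevant
*target* and an interfering *competitor*), theories of oscillating
inhibition predict that the two representations become decodable at
distinct phases of a slow (≈3 Hz, "theta") rhythm.  `thetasep` implements
the complete analysis chain needed to test that prediction, together with
a synthetic-data generator that plants known phase-coding structure so
every stage can be validated by parameter recovery:

- **simulate** — gradiometer-like epoched studies (default 204 channels,
  250 Hz, −1000…+3000 ms): 1/f background noise, category-specific spatial
  patterns whose reactivation gain is `g(t) = 1 + d·cos(φ(t) − φ_pref)`,
  a planted angular lag between target and competitor preferred phases, a
  noisy single-channel phase reference, and a behavioural table with
  condition-dependent accuracy and competitor-biased errors.
- **preprocess** — trial-masked robust polynomial detrending (orders 1 and
  30), MAD-based trial (4×) and channel (3×) rejection, 40 ms FWHM
  Gaussian smoothing, −400…−50 ms baseline correction, zero-phase
  band-pass filtering.
- **decode** — time-resolved shrinkage LDA (analytic Ledoit–Wolf lambda),
  trained per 8 ms timepoint on the sensor pattern; signed decision values
  (*d-values* / fidelity values) index memory reinstatement, with 10-fold
  × 5 cross-validation for within-condition decoding, response-locked
  realignment, and label-shuffled surrogate decodings.
- **spectral** — IRASA separation of oscillatory from fractal (1/f)
  spectra of the fidelity timecourses; surrogate-based group z-test per
  1 Hz band (3–8 Hz) against the Bonferroni-corrected critical z = 2.32;
  Morlet time-frequency power with `n_cycles(f) = max(5, 0.5·f)`.
- **phase** — Morlet/Hilbert phase of the reference channel; fidelity
  amplitudes sorted into 10 phase bins; the modulation index
  `MI = (ln N − H(p)) / ln N` (normalised Kullback–Leibler distance from
  uniform); preferred phases, wrapped phase differences, Rayleigh and
  V tests, intrusion-split phase-similarity comparison.
- **crosslag** — 330 ms sliding-window cross-correlation between target
  and competitor fidelity timecourses expressed as phase lag (−180…180°),
  surrogate z-maps, and a Hilbert phase-difference timecourse.
- **clusterstats** — one-sample/paired cluster-based permutation tests on
  1-D and 2-D maps with permutation-exact p-values.
- **behaviour** — condition accuracies, interference score (NC1 − CC),
  intrusion score (fraction of supraordinate errors matching the
  competitor's subcategory; chance 50%), repetition-slope Wilcoxon tests.

## Worked example: recovering a planted 34° phase lag

Simulate 12 participants in which the competitor's preferred phase lags
the target's by 34°, decode target and competitor fidelity on correct
competitive trials, bin fidelity by the 3 Hz reference phase, and test the
per-participant phase differences:

```python
import numpy as np
from dataclasses import replace
from thetasep import SimConfig, generate_study
from thetasep.decode import decode_target_competitor
from thetasep.phase import (extract_phase, per_trial_preferred_phases,
                            preferred_phase_per_participant, phase_difference,
                            circ_mean, rayleigh_test, v_test)

cfg = SimConfig(n_participants=12, n_trials_per_condition=8, n_channels=24,
                modulation_depth=0.6, planted_lag=np.deg2rad(34.0), seed=77)
study = generate_study(cfg)

deltas = []
for part in study.participants:
    cc = part.trials.select((part.trials.metadata["condition"] == "CC").to_numpy())
    target, competitor = decode_target_competitor(part.trials, cc, window=(500, 3000))
    ph = extract_phase(part.reference, cfg.fs, cfg.osc_freq, "wavelet",
                       times=part.trials.times)
    ph_cc = replace(ph, phases=ph.phases[target.metadata["trial"].to_numpy()])
    t_ang, _ = preferred_phase_per_participant(per_trial_preferred_phases(target, ph_cc))
    c_ang, _ = preferred_phase_per_participant(per_trial_preferred_phases(competitor, ph_cc))
    deltas.append(phase_difference(c_ang, t_ang))

mean_angle, resultant = circ_mean(deltas)
ray = rayleigh_test(deltas)
v = v_test(deltas, mu=0.0)
print("planted lag: 34.0 deg")
print(f"recovered group lag: {np.rad2deg(mean_angle):.1f} deg (resultant R = {resultant:.2f})")
print(f"Rayleigh test: z = {ray.statistic:.2f}, p = {ray.p:.2e}")
print(f"V test vs 0 deg:  u = {v.statistic:.2f}, p = {v.p:.2e}")
```

Output:

```
planted lag: 34.0 deg
recovered group lag: 25.8 deg (resultant R = 0.94)
Rayleigh test: z = 10.67, p = 5.66e-07
V test vs 0 deg:  u = 4.16, p = 1.59e-05
```

The recovered group lag sits within half a phase-bin width (18°) of the
planted 34°; the Rayleigh test confirms the lag is consistent across
participants and the V test that it differs from zero.  With
`modulation_depth=0` the same pipeline yields non-significant Rayleigh
p-values — the phase separation is driven entirely by the planted
coupling.

A thin CLI covers the file-oriented stages:

```sh
thetasep simulate --config cfg.json --out study/ --seed 1
thetasep preprocess --in study/ --out study_clean/
thetasep report-behaviour --study study/ --out behav.tsv
```

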
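"""Phase extraction, phase-binned coupling, and circular statistics.

The phase of the slow reference oscillation (default 3 Hz) is estimated
either by complex Morlet convolution (unit-normalised, ~500 ms long) or by
band-pass + Hilbert transform.  Single-trial fidelity values are then
sorted into 10 phase bins; the modulation index (MI) is the
Kullback–Leibler divergence of the binned amplitude distribution from
uniform, normalised by log(N): 0 = no coupling, 1 = all amplitude in one
bin.  Phase convention: 0 rad = peak of the cosine reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.signal import fftconvolve, hilbert

from .containers import FidelityCourse
from .preprocess import bandpass

logger = logging.getLogger(__name__)


@dataclass
class PhaseCourse:
    """Per-trial instantaneous phase in (-pi, pi]; NaN at edge samples."""

    phases: np.ndarray  # trials x samples
    times: np.ndarray  # ms
    freq: float
    method: str


@dataclass
class BinnedProfile:
    bin_means: np.ndarray
    bin_edges: np.ndarray
    bin_counts: np.ndarray
    mi: float
    max_bin: int  # 1-based
    preferred_phase: float  # centre of the max bin, radians


@dataclass
class CircResult:
    mean_angle: float
    resultant_length: float
    statistic: float
    p: float
    n: int
    test: str


def wrap_angle(angle):
    """Wrap angles to (-pi, pi]."""
    return np.angle(np.exp(1j * np.asarray(angle, dtype=float)))


def _morlet_kernel(freq, fs, n_cycles):
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(3.5 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    kernel = np.exp(2j * np.pi * freq * t) * np.exp(-(t**2) / (2.0 * sigma_t**2))
    return kernel, half


def extract_phase(
    reference,
    fs,
    freq=3.0,
    method="wavelet",
    times=None,
    n_cycles=None,
    band_halfwidth=1.0,
) -> PhaseCourse:
    """Instantaneous phase of the reference signal at ``freq``.

    ``wavelet``: complex Morlet convolution with cycles ≈ 0.5 s * freq
    (1.5 cycles at 3 Hz), each complex sample divided by its magnitude;
    edge samples within the kernel half-length are NaN.  ``hilbert``:
    band-pass at ``freq ± band_halfwidth`` then analytic-signal angle,
    with one period flagged NaN at each edge.
    """
    if fs <= 2.0 * freq:
        raise ValueError("fs must exceed twice the target frequency")
    x = np.atleast_2d(np.asarray(reference, dtype=float))
    n = x.shape[-1]
    if times is None:
        times = np.arange(n) * 1000.0 / fs
    if method == "wavelet":
        if n_cycles is None:
            n_cycles = 0.5 * freq
        kernel, half = _morlet_kernel(freq, fs, n_cycles)
        conv = fftconvolve(x, kernel[None, :], mode="same", axes=-1)
        phases = np.angle(conv)
        margin = min(half, n)
    elif method == "hilbert":
        bp = bandpass(x, fs, (freq - band_halfwidth, freq + band_halfwidth))
        phases = np.angle(hilbert(bp, axis=-1))
        margin = min(int(round(fs / freq)), n)
    else:
        raise ValueError(f"unknown method {method!r}")
    if margin > 0:
        phases[:, :margin] = np.nan
        phases[:, n - margin:] = np.nan
    return PhaseCourse(phases=phases, times=np.asarray(times, dtype=float),
                       freq=freq, method=method)


def bin_edges(n_bins=10) -> np.ndarray:
    """Edges partitioning (-pi, pi] into equal bins (bin 1 starts at -pi)."""
    return np.linspace(-np.pi, np.pi, n_bins + 1)


def _bin_index(phases, n_bins):
    width = 2.0 * np.pi / n_bins
    idx = np.floor((np.asarray(phases) + np.pi) / width).astype(int)
    return np.clip(idx, 0, n_bins - 1)  # phase exactly +pi -> last bin


def modulation_index(bin_means) -> float:
    """Normalised KL divergence of the binned distribution from uniform.

    Negative bin means (signed d-values) are handled by shifting all bins
    by the global minimum before normalising; a distribution that is
    all-zero after the shift is undefined and raises.
    """
    means = np.asarray(bin_means, dtype=float)
    mn = means.min()
    if mn < 0:
        means = means - mn
    total = means.sum()
    if total <= 0:
        raise ValueError("all-zero distribution after shift; MI undefined")
    if np.all(means == means[0]):
        return 0.0  # exactly uniform
    p = means / total
    nz = p > 0
    entropy = -np.sum(p[nz] * np.log(p[nz]))
    # clamp float rounding so MI stays in [0, 1]
    return float(min(max((np.log(p.size) - entropy) / np.log(p.size), 0.0), 1.0))


def bin_fidelity_by_phase(
    fid: FidelityCourse,
    ph: PhaseCourse,
    n_bins: int = 10,
    window: tuple[float, float] = (500.0, 3000.0),
    strict: bool = True,
    trial_mask=None,
) -> BinnedProfile:
    """Pool (trial, timepoint) fidelity amplitudes into phase bins.

    Phase samples are matched to the fidelity time grid by time value;
    NaN phases (wavelet edges) are dropped.  With ``strict`` an empty bin
    raises (reporting counts); otherwise empty bins yield NaN means.
    """
    f_sel = (fid.times >= window[0]) & (fid.times <= window[1])
    p_idx = np.searchsorted(ph.times, fid.times[f_sel])
    p_idx = np.clip(p_idx, 0, ph.times.size - 1)
    if not np.allclose(ph.times[p_idx], fid.times[f_sel], atol=1e-6):
        raise ValueError("fidelity and phase courses do not share a time grid")

    vals = fid.values[:, f_sel]
    phases = ph.phases[:, p_idx]
    if trial_mask is not None:
        vals = vals[trial_mask]
        phases = phases[trial_mask]
    if vals.shape != phases.shape:
        raise ValueError("fidelity and phase must share the trial axis")

    ok = np.isfinite(phases) & np.isfinite(vals)
    idx = _bin_index(phases[ok], n_bins)
    v = vals[ok]
    counts = np.bincount(idx, minlength=n_bins)
    if strict and np.any(counts == 0):
        raise ValueError(f"empty phase bin(s); counts = {counts.tolist()}")
    sums = np.bincount(idx, weights=v, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    edges = bin_edges(n_bins)
    centres = (edges[:-1] + edges[1:]) / 2.0
    finite = np.isfinite(means)
    max_bin = int(np.nanargmax(means)) if finite.any() else 0
    ties = np.flatnonzero(np.isclose(means, means[max_bin]))
    if ties.size > 1:
        logger.info("tie for max bin at %s; keeping the lowest index", ties.tolist())
        max_bin = int(ties[0])
    mi = modulation_index(means[finite]) if finite.all() else float("nan")
    return BinnedProfile(
        bin_means=means,
        bin_edges=edges,
        bin_counts=counts,
        mi=mi,
        max_bin=max_bin + 1,
        preferred_phase=float(centres[max_bin]),
    )


def per_trial_preferred_phases(fid, ph, n_bins=10, window=(500.0, 3000.0)):
    """Preferred-phase angle (max-bin centre) of every single trial."""
    angles = np.full(fid.n_trials, np.nan)
    for i in range(fid.n_trials):
        mask = np.zeros(fid.n_trials, dtype=bool)
        mask[i] = True
        prof = bin_fidelity_by_phase(fid, ph, n_bins, window, strict=False,
                                     trial_mask=mask)
        finite = np.isfinite(prof.bin_means)
        if finite.sum() >= n_bins // 2:
            angles[i] = prof.preferred_phase
    return angles


def circ_mean(angles):
    """Circular mean angle and resultant length of finite angles."""
    a = np.asarray(angles, dtype=float)
    a = a[np.isfinite(a)]
    if a.size == 0:
        raise ValueError("no finite angles")
    vec = np.mean(np.exp(1j * a))
    return float(np.angle(vec)), float(np.abs(vec))


def preferred_phase_per_participant(trial_angles):
    """Participant-level preferred phase: circular mean of per-trial
    max-bin angles (unit amplitude).  Returns ``(angle, resultant)``;
    a small resultant flags the angle as unreliable."""
    return circ_mean(trial_angles)


def mi_null_threshold(surrogate_mis, q=95.0) -> float:
    """q-th percentile (linear interpolation) of a surrogate MI sample."""
    mis = np.asarray(surrogate_mis, dtype=float)
    if mis.size == 0:
        raise ValueError("empty surrogate list")
    return float(np.percentile(mis, q))


def phase_difference(x, y):
    """Wrapped angular difference x - y in (-pi, pi]."""
    return np.angle(np.exp(1j * (np.asarray(x) - np.asarray(y))))


def rayleigh_test(angles) -> CircResult:
    """Rayleigh test for non-uniformity of circular data.

    z = n R^2 with the standard small-sample corrected p-value
    ``p = exp(sqrt(1 + 4n + 4(n^2 - (nR)^2)) - (1 + 2n))``.
    """
    a = np.asarray(angles, dtype=float)
    a = a[np.isfinite(a)]
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 angles")
    mean_angle, r = circ_mean(a)
    z = n * r**2
    p = np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n**2 - (n * r) ** 2)) - (1.0 + 2.0 * n))
    return CircResult(mean_angle=mean_angle, resultant_length=r, statistic=float(z),
                      p=float(min(max(p, np.finfo(float).tiny), 1.0)), n=n,
                      test="rayleigh")


def v_test(angles, mu=0.0) -> CircResult:
    """V-test for clustering around a specified mean angle ``mu``.

    V = R cos(mean - mu); u = V sqrt(2n); p = 1 - Phi(u).
    """
    a = np.asarray(angles, dtype=float)
    a = a[np.isfinite(a)]
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 angles")
    mean_angle, r = circ_mean(a)
    v = r * np.cos(mean_angle - mu)
    u = v * np.sqrt(2.0 * n)
    p = float(stats.norm.sf(u))
    return CircResult(mean_angle=mean_angle, resultant_length=r, statistic=float(u),
                      p=min(max(p, np.finfo(float).tiny), 1.0), n=n, test="v")


def phase_similarity(x, y):
    """|cos(delta/2)|: 1 for identical angles, 0 for opposition."""
    return np.abs(np.cos(phase_difference(x, y) / 2.0))


def group_phase_similarity(target_angles, competitor_angles, intrusion_scores,
                           seed=None):
    """Within-participant target/competitor phase similarity and an
    intrusion-split group comparison.

    The similarity is the length of the circular mean of the two unit
    vectors, ``|cos(delta/2)|``.  Participants are split at the intrusion
    median into low/high groups (equal n, random removal from the larger
    group, seeded) and compared with a Wilcoxon signed-rank test on the
    rank-ordered similarities.
    """
    t = np.asarray(target_angles, dtype=float)
    c = np.asarray(competitor_angles, dtype=float)
    scores = np.asarray(intrusion_scores, dtype=float)
    sim = phase_similarity(t, c)

    rng = np.random.default_rng(seed)
    order = np.argsort(scores, kind="stable")
    half = scores.size // 2
    low = order[:half]
    high = order[half:]
    if high.size > low.size:
        drop = rng.integers(high.size)
        high = np.delete(high, drop)
    if low.size < 3:
        raise ValueError("group size < 3")
    lo_sorted = np.sort(sim[low])
    hi_sorted = np.sort(sim[high])
    if np.allclose(lo_sorted, hi_sorted):
        stat, p = 0.0, 1.0
    else:
        res = stats.wilcoxon(lo_sorted, hi_sorted)
        stat, p = float(res.statistic), float(res.pvalue)
    return {
        "similarity": sim,
        "low_group": low,
        "high_group": high,
        "statistic": stat,
        "p": p,
    }
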
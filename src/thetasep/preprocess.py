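"""Deterministic signal conditioning.

Masked robust polynomial detrending, MAD-based trial/channel rejection,
Gaussian smoothing, baseline correction and zero-phase band filtering.
All operations are shape-preserving.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import ndimage, signal

from .containers import TrialSet

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def robust_detrend(x, event_mask=None, orders=(1, 30)):
    """Sequentially fit and remove polynomials, ignoring masked samples.

    Parameters
    ----------
    x
        Signal(s); the last axis is samples.
    event_mask
        Boolean array over samples; True marks event samples excluded from
        the fit (the polynomial is still subtracted there).
    orders
        Polynomial degrees applied in sequence (default first-order then
        30th-order, fitted on a Legendre basis for conditioning).
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if event_mask is None:
        keep = np.ones(n, dtype=bool)
    else:
        keep = ~np.asarray(event_mask, dtype=bool)
        if keep.size != n:
            raise ValueError("event_mask length must match the sample axis")
    max_order = max(orders)
    if keep.sum() < max_order + 1:
        raise ValueError(
            f"only {int(keep.sum())} unmasked samples for a degree-{max_order} fit"
        )
    t = np.linspace(-1.0, 1.0, n)
    flat = x.reshape(-1, n)
    out = flat.copy()
    for order in orders:
        basis = np.polynomial.legendre.legvander(t, order)
        coef, *_ = np.linalg.lstsq(basis[keep], out[:, keep].T, rcond=None)
        out -= (basis @ coef).T
    return out.reshape(x.shape)


def mad_reject(scores, k):
    """Keep mask: item kept iff ``|score - median| <= k * MAD``.

    If the MAD is zero with non-identical scores, only items equal to the
    median are kept; all-identical scores are all kept.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 3:
        raise ValueError("need at least 3 items")
    med = np.median(scores)
    mad = np.median(np.abs(scores - med))
    if mad == 0:
        return np.abs(scores - med) == 0
    return np.abs(scores - med) <= k * mad


def smooth_gaussian(x, fwhm_ms, fs, axis=-1):
    """Convolve with a unit-sum Gaussian of the given FWHM (reflect edges)."""
    if fwhm_ms <= 0:
        raise ValueError("fwhm_ms must be > 0")
    x = np.asarray(x, dtype=float)
    sigma = fwhm_ms / 1000.0 * fs * _FWHM_TO_SIGMA
    kernel_len = 2 * int(4.0 * sigma + 0.5) + 1
    if x.shape[axis] < kernel_len:
        raise ValueError("series shorter than the smoothing kernel")
    return ndimage.gaussian_filter1d(x, sigma, axis=axis, mode="reflect")


def baseline_correct(trials: TrialSet, window=(-400.0, -50.0)) -> TrialSet:
    """Subtract the per-trial, per-channel mean over the baseline window."""
    lo, hi = window
    if lo < trials.times[0] or hi > trials.times[-1]:
        raise IndexError("baseline window outside the epoch")
    sel = (trials.times >= lo) & (trials.times <= hi)
    base = trials.data[:, :, sel].mean(axis=-1, keepdims=True)
    return replace(trials, data=trials.data - base)


def bandpass(x, fs, band, zero_phase=True, order=3, axis=-1):
    """Zero-phase (two-pass) Butterworth band-pass filter."""
    low, high = band
    if not 0 < low < high < fs / 2.0:
        raise ValueError("band must satisfy 0 < low < high < fs/2")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    x = np.asarray(x, dtype=float)
    if zero_phase:
        return signal.sosfiltfilt(sos, x, axis=axis)
    return signal.sosfilt(sos, x, axis=axis)


def highpass(x, fs, cutoff, order=4, axis=-1):
    """Zero-phase Butterworth high-pass (used for rejection scores)."""
    if not 0 < cutoff < fs / 2.0:
        raise ValueError("cutoff must satisfy 0 < cutoff < fs/2")
    sos = signal.butter(order, cutoff, btype="highpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=axis)


def trial_rejection_scores(trials: TrialSet, hp_hz=100.0) -> np.ndarray:
    """Per-trial max |amplitude| after high-pass filtering.

    The amplitude statistic (max vs variance) is a configurable choice;
    max |amplitude| targets the high-frequency bursts the rejection step
    is meant to catch.
    """
    hp = highpass(trials.data, trials.fs, hp_hz)
    return np.max(np.abs(hp), axis=(1, 2))


def channel_rejection_scores(trials: TrialSet, band=(1.0, 100.0)) -> np.ndarray:
    """Per-channel max |amplitude| after band-pass filtering."""
    bp = bandpass(trials.data, trials.fs, band)
    return np.max(np.abs(bp), axis=(0, 2))


def reject_trials(trials: TrialSet, k=4.0, hp_hz=100.0):
    """Drop trials whose amplitude exceeds ``k`` MADs; returns (set, keep)."""
    keep = mad_reject(trial_rejection_scores(trials, hp_hz), k)
    return trials.select(keep), keep


def grid_layout(n_channels: int) -> np.ndarray:
    """Synthetic 2-D sensor layout (square-ish grid) for interpolation."""
    side = int(np.ceil(np.sqrt(n_channels)))
    xy = np.array([(i % side, i // side) for i in range(n_channels)], dtype=float)
    return xy


def interpolate_channels(data, bad, layout=None, k=4):
    """Replace bad channels by the mean of the k nearest good sensors."""
    data = np.array(data, dtype=float)
    n_ch = data.shape[1]
    bad = np.asarray(bad, dtype=int)
    if layout is None:
        layout = grid_layout(n_ch)
    good = np.setdiff1d(np.arange(n_ch), bad)
    if good.size == 0:
        raise ValueError("no good channels left to interpolate from")
    for b in bad:
        d = np.linalg.norm(layout[good] - layout[b], axis=1)
        nearest = good[np.argsort(d)[: min(k, good.size)]]
        data[:, b, :] = data[:, nearest, :].mean(axis=1)
    return data


def detrend_trials(trials: TrialSet, orders=(1, 30), mask_window=(0.0, None)) -> TrialSet:
    """Trial-masked robust detrending on epoched data.

    Each trial/channel series is reflection-padded by one epoch length on
    both sides (a stand-in for the continuous context around the epoch),
    the cognitively relevant window is masked out of the fit, and the
    fitted polynomials are subtracted everywhere before cropping back.
    """
    t0, t1 = mask_window
    t1 = trials.times[-1] if t1 is None else t1
    n = trials.n_samples
    padded_times = np.concatenate(
        [trials.times[0] - (trials.times[::-1] - trials.times[0])[:-1],
         trials.times,
         trials.times[-1] + (trials.times[-1] - trials.times[::-1])[1:]]
    )
    mask = (padded_times >= t0) & (padded_times <= t1)
    pad = np.concatenate(
        [trials.data[:, :, -1:0:-1], trials.data, trials.data[:, :, -2::-1]], axis=-1
    )
    out = robust_detrend(pad, event_mask=mask, orders=orders)
    return replace(trials, data=out[:, :, n - 1 : 2 * n - 1])
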
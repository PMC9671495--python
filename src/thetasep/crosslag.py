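"""Sliding-window cross-correlation between target and competitor
fidelity timecourses at the dominant slow frequency.

Each window spans one oscillation period (330 ms at 3 Hz, rounded to the
nearest odd sample count), so lags map onto phase angles in roughly
[-180, 180] degrees; positive lag means the competitor timecourse lags
the target.  Surrogate (label-shuffled) lag maps provide elementwise
z-scoring, and a Hilbert phase-difference timecourse gives an independent
per-timepoint estimate of the same angular lag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import hilbert

from .containers import FidelityCourse
from .phase import circ_mean, phase_difference
from .preprocess import bandpass

logger = logging.getLogger(__name__)


@dataclass
class LagMap:
    """Window-centre times x lag (degrees) map of correlations or z."""

    values: np.ndarray  # n_centres x n_lags
    lag_deg: np.ndarray
    times: np.ndarray  # ms, window centres
    window_ms: float
    freq: float

    def peak_lag(self) -> float:
        """Lag (degrees) of the maximum of the time-averaged map."""
        return float(self.lag_deg[np.argmax(self.values.mean(axis=0))])


def _as_trials(x):
    if isinstance(x, FidelityCourse):
        return x.values, x.times
    return np.atleast_2d(np.asarray(x, dtype=float)), None


def sliding_xcorr(
    target,
    competitor,
    fs=None,
    times=None,
    freq=3.0,
    window_ms=None,
    span=(500.0, 3000.0),
    prefiltered=False,
    band_halfwidth=1.0,
) -> LagMap:
    """Normalised sliding-window cross-correlation across phase lags.

    Both inputs (trials x samples, or :class:`FidelityCourse`) are
    band-filtered at ``freq`` unless ``prefiltered``; the correlation is
    computed per trial and averaged.  Lags run to ± half a period,
    converted to degrees via ``deg = 360 * lag_s * freq``.
    """
    tgt, t_times = _as_trials(target)
    cmp_, c_times = _as_trials(competitor)
    if tgt.shape != cmp_.shape:
        raise ValueError("target and competitor must share trial/time axes")
    if times is None:
        times = t_times if t_times is not None else c_times
    if times is None:
        raise ValueError("times required for array input")
    times = np.asarray(times, dtype=float)
    if fs is None:
        fs = 1000.0 / (times[1] - times[0])

    if not prefiltered:
        tgt = bandpass(tgt, fs, (freq - band_halfwidth, freq + band_halfwidth))
        cmp_ = bandpass(cmp_, fs, (freq - band_halfwidth, freq + band_halfwidth))

    if window_ms is None:
        window_ms = 1000.0 / freq
    wlen = int(round(window_ms / 1000.0 * fs))
    if wlen % 2 == 0:
        wlen += 1  # nearest odd sample count, centred windows
    half = wlen // 2
    max_lag = int(np.floor(fs / (2.0 * freq)))
    lags = np.arange(-max_lag, max_lag + 1)

    n = times.size
    centres = np.where((times >= span[0]) & (times <= span[1]))[0]
    centres = centres[(centres - half - max_lag >= 0) & (centres + half + max_lag < n)]
    if centres.size == 0:
        raise ValueError("window plus lags exceed the available samples")

    # z-scored windows of both series at every possible start index
    tw = sliding_window_view(tgt, wlen, axis=-1)  # trials x starts x wlen
    cw = sliding_window_view(cmp_, wlen, axis=-1)

    def _zscore(w):
        mu = w.mean(axis=-1, keepdims=True)
        sd = w.std(axis=-1, keepdims=True)
        sd[sd == 0] = np.inf  # flat window -> zero correlation
        return (w - mu) / sd

    tz = _zscore(tw)
    cz = _zscore(cw)
    starts = centres - half
    out = np.empty((centres.size, lags.size))
    base = tz[:, starts, :]
    for j, lag in enumerate(lags):
        out[:, j] = np.einsum("tcw,tcw->c", base, cz[:, starts + lag, :]) / (
            wlen * tgt.shape[0]
        )
    return LagMap(values=out, lag_deg=lags / fs * freq * 360.0, times=times[centres],
                  window_ms=wlen / fs * 1000.0, freq=freq)


def xcorr_zmap(real: LagMap, surrogates) -> LagMap:
    """Elementwise z of the real map against its surrogate maps."""
    if len(surrogates) < 2:
        raise ValueError("need at least 2 surrogate maps")
    stack = np.stack([s.values for s in surrogates])
    mu = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        logger.warning("masking %d cells with zero surrogate sd", int(zero.sum()))
        sd[zero] = np.inf
    z = (real.values - mu) / sd
    z[zero] = np.nan
    return LagMap(values=z, lag_deg=real.lag_deg, times=real.times,
                  window_ms=real.window_ms, freq=real.freq)


def lag_cluster_test(zmaps, n_perm=1000, cluster_alpha=0.05, forming_alpha=0.05,
                     tail="greater", seed=None):
    """Group cluster permutation test over the time x lag z maps."""
    from .clusterstats import cluster_permutation

    data = np.stack([m.values for m in zmaps])
    return cluster_permutation(data, design="one_sample", forming_alpha=forming_alpha,
                               tail=tail, n_perm=n_perm, cluster_alpha=cluster_alpha,
                               seed=seed)


def phase_diff_timecourse(target_avg, competitor_avg, fs, freq=3.0,
                          edge_cycles=1.0):
    """Per-timepoint target-minus-competitor phase angle, per participant.

    Inputs are participant-averaged fidelity courses (participants x
    samples).  Each is band-filtered at ``freq``, Hilbert-transformed, and
    ``theta(t) = phase(target) - phase(competitor)`` (wrapped) is returned
    together with the group circular mean per timepoint.  Samples within
    ``edge_cycles`` periods of either end are NaN (filter + Hilbert
    transients).
    """
    t = np.atleast_2d(np.asarray(target_avg, dtype=float))
    c = np.atleast_2d(np.asarray(competitor_avg, dtype=float))
    if t.shape != c.shape:
        raise ValueError("inputs must share participant/time axes")
    bt = bandpass(t, fs, (freq - 1.0, freq + 1.0))
    bc = bandpass(c, fs, (freq - 1.0, freq + 1.0))
    pt = np.angle(hilbert(bt, axis=-1))
    pc = np.angle(hilbert(bc, axis=-1))
    theta = phase_difference(pt, pc)
    margin = int(round(edge_cycles * fs / freq))
    n = theta.shape[-1]
    margin = min(margin, n)
    theta[:, :margin] = np.nan
    theta[:, n - margin:] = np.nan

    group = np.full(n, np.nan)
    for j in range(n):
        col = theta[:, j]
        if np.isfinite(col).any():
            group[j], _ = circ_mean(col)
    return theta, group
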
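"""Core in-memory containers shared across the pipeline.

A study is a collection of participants; each participant carries a
:class:`TrialSet` (epoched multichannel trial data with behavioural
metadata) and a single-channel phase-reference timecourse standing in for
a source-localised hippocampal signal.  Time-resolved decoding turns a
TrialSet into a :class:`FidelityCourse` of signed classifier decision
values (d-values), the substrate of every downstream phase analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: subordinate -> superordinate category map
CATEGORY_OF = {
    "animate": "object",
    "inanimate": "object",
    "indoor": "scene",
    "outdoor": "scene",
}

#: superordinate -> (subordinate, subordinate)
SUBCATEGORIES = {
    "object": ("animate", "inanimate"),
    "scene": ("indoor", "outdoor"),
}

CONDITIONS = ("NC1", "NC2", "CC")

#: columns every behavioural/trial metadata table must carry
METADATA_COLUMNS = (
    "participant",
    "trial",
    "condition",
    "repetition",
    "target_category",
    "target_sub",
    "competitor_sub",
    "resp_supra",
    "resp_sub",
    "correct_q1",
    "correct_q2",
    "rt_ms",
)


@dataclass
class TrialSet:
    """Epoched trial data: ``data`` is trials x channels x samples.

    Parameters
    ----------
    data
        Sensor amplitudes, shape ``(n_trials, n_channels, n_samples)``.
    fs
        Sampling rate in Hz.
    times
        Sample times in ms relative to cue onset, length ``n_samples``,
        uniformly spaced at ``1000 / fs``.
    metadata
        One row per trial with the behavioural/condition columns listed in
        :data:`METADATA_COLUMNS` (extra columns are allowed).
    participant
        Participant identifier.
    """

    data: np.ndarray
    fs: float
    times: np.ndarray
    metadata: pd.DataFrame
    participant: str = "p00"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if self.data.shape[2] != self.times.size:
            raise ValueError("times length does not match the sample axis")
        dt = np.diff(self.times)
        if dt.size and not np.allclose(dt, 1000.0 / self.fs, atol=1e-6):
            raise ValueError("times must be uniformly spaced at 1000/fs ms")
        if len(self.metadata) != self.data.shape[0]:
            raise ValueError("metadata rows do not match the trial axis")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def time_index(self, t_ms: float) -> int:
        """Index of the sample closest to ``t_ms``."""
        return int(np.argmin(np.abs(self.times - t_ms)))

    def select(self, mask: np.ndarray) -> "TrialSet":
        """Sub-TrialSet of the trials where ``mask`` is True."""
        mask = np.asarray(mask)
        return replace(
            self,
            data=self.data[mask],
            metadata=self.metadata.loc[np.asarray(mask)].reset_index(drop=True),
        )


@dataclass
class FidelityCourse:
    """Single-trial, time-resolved signed classifier decision values.

    Positive values are evidence for the designated memory's true
    subcategory on that trial.
    """

    values: np.ndarray  # trials x timepoints
    times: np.ndarray  # ms
    designation: str  # 'target' | 'competitor' | 'self'
    alignment: str = "cue"  # 'cue' | 'response'
    metadata: pd.DataFrame | None = None
    step_ms: float = field(default=8.0)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.times = np.asarray(self.times, dtype=float)
        if self.values.shape[1] != self.times.size:
            raise ValueError("times length does not match the time axis")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    def mean_course(self) -> np.ndarray:
        """Trial-averaged fidelity timecourse."""
        return np.nanmean(self.values, axis=0)

    def crop(self, window: tuple[float, float]) -> "FidelityCourse":
        keep = (self.times >= window[0]) & (self.times <= window[1])
        return replace(self, values=self.values[:, keep], times=self.times[keep])
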
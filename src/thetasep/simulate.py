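"""Synthetic studies with planted phase-coding ground truth.

The generator emulates a cued-recall interference experiment recorded with
gradiometer-like sensors: each retrieval trial is 1/f background noise on
every channel, plus a fixed category-specific spatial pattern whose
amplitude is modulated by a slow (default 3 Hz) oscillation at a planted
preferred phase.  In the competitive condition (CC) a second, competitor
pattern rides on the same oscillation at ``target_pref_phase +
planted_lag``, so every downstream stage (decoding, rhythmicity detection,
phase binning, lag estimation) can be tested by parameter recovery.  A
behavioural table realises configurable per-condition accuracies with
competitor-biased errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CATEGORY_OF, CONDITIONS, SUBCATEGORIES, TrialSet

_TWO_PI = 2.0 * math.pi


def _wrap(angle):
    """Wrap angles to (-pi, pi]."""
    return np.angle(np.exp(1j * np.asarray(angle, dtype=float)))


@dataclass
class SimConfig:
    """Conditions of a simulated study.

    ``n_trials_per_condition`` counts cue–associate pairs per condition;
    each association is recalled three times (repetitions 1–3), so each
    condition contributes three times that many retrieval trials.  Defaults
    mirror the recorded study this generator emulates: 21 participants, 48
    associations per condition, 204 gradiometer channels at 250 Hz over a
    −1000…+3000 ms epoch, with a 3 Hz modulating oscillation.  The planted
    effect sizes (``modulation_depth``, ``pattern_snr``) are not reported
    quantities; they are chosen, and exposed, as recovery-test settings.
    """

    n_participants: int = 21
    n_trials_per_condition: int = 48
    fs: float = 250.0
    n_channels: int = 204
    epoch_window: tuple[float, float] = (-1000.0, 3000.0)
    background_exponent: float = 1.0
    osc_freq: float = 3.0
    modulation_depth: float = 0.6
    target_pref_phase: float = 0.0
    planted_lag: float = math.radians(34.0)
    pattern_snr: float = 1.0
    ref_snr: float = 5.0
    activation_window: tuple[float, float] = (500.0, 3000.0)
    accuracy: dict = field(
        default_factory=lambda: {"NC1": 0.5771, "NC2": 0.7888, "CC": 0.5318}
    )
    intrusion_bias: float = 0.85
    no_memory_rate: float = 0.1
    rt_mean_ms: float = 2100.0
    rt_sd_ms: float = 400.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.modulation_depth <= 1.0:
            raise ValueError("modulation_depth must lie in [0, 1]")
        if not -math.pi < self.planted_lag <= math.pi:
            raise ValueError("planted_lag must lie in (-pi, pi]")
        if self.background_exponent < 0:
            raise ValueError("background_exponent must be >= 0")
        for cond in CONDITIONS:
            acc = self.accuracy.get(cond)
            if acc is None or not 0.0 <= acc <= 1.0:
                raise ValueError(f"accuracy[{cond!r}] must lie in [0, 1]")
        if not 0.0 <= self.intrusion_bias <= 1.0:
            raise ValueError("intrusion_bias must lie in [0, 1]")
        n = (self.epoch_window[1] - self.epoch_window[0]) * self.fs / 1000.0
        if abs(n - round(n)) > 1e-9:
            raise ValueError("epoch length must be an integral number of samples")

    @property
    def n_samples(self) -> int:
        t0, t1 = self.epoch_window
        return int(round((t1 - t0) * self.fs / 1000.0)) + 1

    @property
    def times(self) -> np.ndarray:
        t0 = self.epoch_window[0]
        return t0 + np.arange(self.n_samples) * (1000.0 / self.fs)


@dataclass
class Participant:
    """One simulated participant: trials, phase reference, ground truth."""

    trials: TrialSet
    reference: np.ndarray  # trials x samples
    ground_truth: dict


@dataclass
class SimulatedStudy:
    config: SimConfig
    participants: list
    ground_truth: dict

    @property
    def behaviour_table(self) -> pd.DataFrame:
        return pd.concat(
            [p.trials.metadata for p in self.participants], ignore_index=True
        )


def pink_noise(n_channels, n_samples, fs, exponent, seed=None):
    """Scale-free noise with expected log–log PSD slope ``-exponent``.

    White noise is shaped in the frequency domain (amplitude ∝
    f**(-exponent/2)); the DC bin is zeroed so every channel has exactly
    zero mean, and each channel is rescaled to unit standard deviation so
    planted pattern amplitudes are interpretable as SNR ratios.
    """
    if n_samples < 16:
        raise ValueError("n_samples must be >= 16")
    if exponent < 0:
        raise ValueError("exponent must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, n=n_samples, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def phase_modulated_gain(phase_series, depth, pref_phase):
    """Gain ``g(t) = 1 + depth * cos(phase(t) - pref_phase)``.

    ``g`` lies in ``[1 - depth, 1 + depth]`` and averages to exactly 1 over
    a uniformly sampled oscillation cycle.
    """
    if not 0.0 <= depth <= 1.0:
        raise ValueError("depth must lie in [0, 1]")
    return 1.0 + depth * np.cos(np.asarray(phase_series, dtype=float) - pref_phase)


def _assoc_table(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Cue–associate assignments: balanced categories and subcategories."""
    rows = []
    for cond in CONDITIONS:
        sub_counter = {"object": 0, "scene": 0}
        for i in range(cfg.n_trials_per_condition):
            target_cat = "object" if i % 2 == 0 else "scene"
            target_sub = SUBCATEGORIES[target_cat][sub_counter[target_cat] % 2]
            sub_counter[target_cat] += 1
            if cond == "CC":
                comp_cat = "scene" if target_cat == "object" else "object"
                comp_sub = SUBCATEGORIES[comp_cat][rng.integers(2)]
            else:
                comp_sub = ""
            rows.append((cond, target_cat, target_sub, comp_sub))
    return pd.DataFrame(
        rows, columns=["condition", "target_category", "target_sub", "competitor_sub"]
    )


def _behaviour(row, acc, bias, no_mem_rate, rng):
    """Simulated responses to the supra- and subordinate questions."""
    target_cat, target_sub = row.target_category, row.target_sub
    other_cat = "scene" if target_cat == "object" else "object"
    if rng.random() < acc:
        return target_cat, target_sub
    if rng.random() < no_mem_rate:
        return "no_memory", ""
    # error: supraordinate response flipped to the other category
    resp_supra = other_cat
    subs = SUBCATEGORIES[other_cat]
    if row.condition == "CC" and rng.random() < bias:
        resp_sub = row.competitor_sub
    else:
        resp_sub = subs[rng.integers(2)]
    return resp_supra, resp_sub


def simulate_participant(cfg: SimConfig, participant: str, seed) -> Participant:
    """Generate one participant's trials, reference channel and truth."""
    rng = np.random.default_rng(seed)
    times = cfg.times
    t_sec = times / 1000.0
    n = cfg.n_samples

    patterns = {}
    for cat, subs in SUBCATEGORIES.items():
        for sub in subs:
            v = rng.standard_normal(cfg.n_channels)
            patterns[sub] = v / np.linalg.norm(v)

    assoc = _assoc_table(cfg, rng)
    trials = assoc.loc[assoc.index.repeat(3)].reset_index(drop=True)
    trials["repetition"] = np.tile([1, 2, 3], len(assoc))
    trials = trials.sample(frac=1.0, random_state=rng.integers(2**31 - 1)).reset_index(
        drop=True
    )

    act = (times >= cfg.activation_window[0]) & (times <= cfg.activation_window[1])
    act = act.astype(float)
    comp_pref = _wrap(cfg.target_pref_phase + cfg.planted_lag)

    data = np.empty((len(trials), cfg.n_channels, n))
    reference = np.empty((len(trials), n))
    phase0 = rng.uniform(-math.pi, math.pi, size=len(trials))
    meta_rows = []
    for i, row in enumerate(trials.itertuples(index=False)):
        noise = pink_noise(cfg.n_channels, n, cfg.fs, cfg.background_exponent, rng)
        phase = _wrap(_TWO_PI * cfg.osc_freq * t_sec + phase0[i])
        g_t = phase_modulated_gain(phase, cfg.modulation_depth, cfg.target_pref_phase)
        x = noise + cfg.pattern_snr * np.outer(patterns[row.target_sub], g_t * act)
        if row.condition == "CC":
            g_c = phase_modulated_gain(phase, cfg.modulation_depth, comp_pref)
            x += cfg.pattern_snr * np.outer(patterns[row.competitor_sub], g_c * act)
        data[i] = x
        ref_noise = rng.standard_normal(n) / cfg.ref_snr if cfg.ref_snr > 0 else 0.0
        reference[i] = np.cos(_TWO_PI * cfg.osc_freq * t_sec + phase0[i]) + ref_noise

        resp_supra, resp_sub = _behaviour(
            row, cfg.accuracy[row.condition], cfg.intrusion_bias, cfg.no_memory_rate, rng
        )
        rt = float(np.clip(rng.normal(cfg.rt_mean_ms, cfg.rt_sd_ms), 600.0, 2800.0))
        meta_rows.append(
            {
                "participant": participant,
                "trial": i,
                "condition": row.condition,
                "repetition": int(row.repetition),
                "target_category": row.target_category,
                "target_sub": row.target_sub,
                "competitor_sub": row.competitor_sub,
                "resp_supra": resp_supra,
                "resp_sub": resp_sub,
                "correct_q1": resp_supra == row.target_category,
                "correct_q2": resp_supra == row.target_category
                and resp_sub == row.target_sub,
                "rt_ms": rt,
            }
        )

    metadata = pd.DataFrame(meta_rows)
    trialset = TrialSet(data=data, fs=cfg.fs, times=times, metadata=metadata,
                        participant=participant)
    truth = {
        "patterns": patterns,
        "phase0": phase0,
        "target_pref_phase": cfg.target_pref_phase,
        "competitor_pref_phase": float(comp_pref),
        "planted_lag": cfg.planted_lag,
        "modulation_depth": cfg.modulation_depth,
        "osc_freq": cfg.osc_freq,
    }
    return Participant(trials=trialset, reference=reference, ground_truth=truth)


def generate_study(config: SimConfig) -> SimulatedStudy:
    """Generate a full study; bit-identical for identical config and seed.

    Memory scales with ``n_participants * n_trials * n_channels *
    n_samples``; at the default (recorded-study scale) configuration each
    participant occupies several hundred MB, so desk-scale work should
    reduce trial/channel counts via the config.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_participants)
    participants = [
        simulate_participant(config, f"p{i:02d}", seeds[i])
        for i in range(config.n_participants)
    ]
    truth = {
        "target_pref_phase": config.target_pref_phase,
        "planted_lag": config.planted_lag,
        "modulation_depth": config.modulation_depth,
        "osc_freq": config.osc_freq,
        "seed": config.seed,
    }
    return SimulatedStudy(config=config, participants=participants, ground_truth=truth)
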
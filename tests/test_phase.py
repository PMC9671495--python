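"""Phase-coupling tests: phase extraction conventions, binning, the
modulation index, preferred phases and circular statistics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from thetasep.containers import FidelityCourse
from thetasep.phase import (
    PhaseCourse,
    bin_fidelity_by_phase,
    circ_mean,
    extract_phase,
    mi_null_threshold,
    modulation_index,
    phase_difference,
    phase_similarity,
    preferred_phase_per_participant,
    group_phase_similarity,
    rayleigh_test,
    v_test,
    wrap_angle,
)

FS = 250.0


def _times(n):
    return np.arange(n) * 1000.0 / FS


class TestExtractPhase:
    n = 1500

    def test_cosine_peak_has_zero_phase(self):
        t = np.arange(self.n) / FS
        x = np.cos(2 * np.pi * 3.0 * t)
        for method in ("wavelet", "hilbert"):
            ph = extract_phase(x, FS, 3.0, method).phases[0]
            peaks = np.where(np.isclose(np.cos(2 * np.pi * 3.0 * t), 1.0, atol=1e-4))[0]
            interior = peaks[(peaks > 200) & (peaks < self.n - 200)]
            assert np.max(np.abs(ph[interior])) < 0.1

    def test_sine_lags_cosine_by_half_pi(self):
        t = np.arange(self.n) / FS
        x = np.sin(2 * np.pi * 3.0 * t)
        ph = extract_phase(x, FS, 3.0, "hilbert").phases[0]
        peaks = np.where(np.isclose(np.cos(2 * np.pi * 3.0 * t), 1.0, atol=1e-4))[0]
        interior = peaks[(peaks > 200) & (peaks < self.n - 200)]
        err = wrap_angle(ph[interior] + np.pi / 2.0)
        assert np.max(np.abs(err)) < 0.1

    def test_wavelet_and_hilbert_agree_on_clean_signal(self):
        t = np.arange(self.n) / FS
        x = np.cos(2 * np.pi * 3.0 * t + 0.8)
        pw = extract_phase(x, FS, 3.0, "wavelet").phases[0]
        ph = extract_phase(x, FS, 3.0, "hilbert").phases[0]
        sel = slice(300, self.n - 300)
        diff = np.abs(wrap_angle(pw[sel] - ph[sel]))
        assert np.percentile(diff, 95) < 0.15

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            extract_phase(np.zeros(100), FS, 3.0, "fourier")


class TestBinning:
    def _pair(self, phases, values):
        times = _times(phases.shape[-1])
        fid = FidelityCourse(values=values, times=times, designation="target")
        ph = PhaseCourse(phases=np.atleast_2d(phases), times=times, freq=3.0,
                         method="synthetic")
        return fid, ph

    def test_cosine_coupled_fidelity_peaks_at_zero_bin(self):
        rng = np.random.default_rng(0)
        phases = rng.uniform(-np.pi, np.pi, (20, 400))
        values = 1.0 + np.cos(phases)
        fid, ph = self._pair(phases, values)
        prof = bin_fidelity_by_phase(fid, ph, window=(0.0, 1e9))
        assert prof.bin_edges[prof.max_bin - 1] <= 0.0 < prof.bin_edges[prof.max_bin]
        assert prof.preferred_phase == pytest.approx(np.pi / 10.0, abs=1e-9)

    def test_edge_conventions(self):
        phases = np.array([[-np.pi, np.pi, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]])
        values = np.ones_like(phases)
        fid, ph = self._pair(phases, values)
        prof = bin_fidelity_by_phase(fid, ph, window=(0.0, 1e9), strict=False)
        assert prof.bin_counts[0] == 1  # -pi -> bin 1
        assert prof.bin_counts[-1] == 1  # +pi -> bin 10

    def test_empty_bin_raises_with_counts(self):
        phases = np.zeros((1, 50))
        values = np.ones_like(phases)
        fid, ph = self._pair(phases, values)
        with pytest.raises(ValueError, match="counts"):
            bin_fidelity_by_phase(fid, ph, window=(0.0, 1e9))

    def test_uncoupled_mi_below_null_threshold(self):
        """No planted coupling: the MI stays below the surrogate 95th
        percentile in most simulations."""
        hits = 0
        n_sims = 100
        for i in range(n_sims):
            rng = np.random.default_rng(10_000 + i)
            phases = rng.uniform(-np.pi, np.pi, (10, 300))
            values = rng.standard_normal((10, 300))
            fid, ph = self._pair(phases, values)
            real = bin_fidelity_by_phase(fid, ph, window=(0.0, 1e9)).mi
            null = []
            for s in range(99):
                perm = rng.permutation(values.ravel()).reshape(values.shape)
                fid2, _ = self._pair(phases, perm)
                null.append(bin_fidelity_by_phase(fid2, ph, window=(0.0, 1e9)).mi)
            hits += real > mi_null_threshold(null, 95)
        assert hits <= 0.10 * n_sims


class TestModulationIndex:
    def test_uniform_is_zero(self):
        assert modulation_index(np.full(10, 0.4)) == pytest.approx(0.0, abs=1e-12)

    def test_delta_is_one(self):
        means = np.zeros(10)
        means[3] = 2.0
        assert modulation_index(means) == pytest.approx(1.0)

    def test_direct_entropy_oracle(self):
        # p = (2,1,...,1)/11 over 10 bins, H evaluated directly:
        # H = ln(11) - (2/11) ln(2) = 2.2718666;
        # MI = (ln10 - H)/ln10 = 0.0133400
        means = np.array([2.0] + [1.0] * 9)
        p = means / means.sum()
        h = -np.sum(p * np.log(p))
        expected = (np.log(10) - h) / np.log(10)
        assert expected == pytest.approx(0.0133400, abs=1e-6)
        assert modulation_index(means) == pytest.approx(expected, rel=1e-12)

    def test_all_zero_after_shift_errors(self):
        with pytest.raises(ValueError):
            modulation_index(np.full(10, -1.0))

    @given(scale=st.floats(0.1, 50.0))
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(5)
        means = rng.standard_normal(10)  # signed d-values
        assert modulation_index(scale * means) == pytest.approx(
            modulation_index(means), rel=1e-9
        )


class TestMiNullThreshold:
    def test_percentile_of_uniform_grid(self):
        null = np.arange(1, 101) / 100.0
        thr = mi_null_threshold(null, 95)
        assert thr == pytest.approx(np.percentile(null, 95))
        assert np.mean(null > thr) <= 0.05

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            mi_null_threshold([])


class TestPreferredPhase:
    def test_identical_angles(self):
        ang, r = preferred_phase_per_participant(np.full(8, 0.314))
        assert ang == pytest.approx(0.314)
        assert r == pytest.approx(1.0)

    def test_symmetric_pair_averages_to_zero(self):
        ang, _ = preferred_phase_per_participant(np.array([0.6, -0.6]))
        assert ang == pytest.approx(0.0, abs=1e-12)

    def test_uniform_angles_flagged_by_small_resultant(self):
        angles = np.linspace(-np.pi, np.pi, 12, endpoint=False)
        _, r = preferred_phase_per_participant(angles)
        assert r < 1e-12


class TestPhaseDifference:
    def test_identity(self):
        assert phase_difference(1.2, 1.2) == pytest.approx(0.0)

    def test_wrapping(self):
        x, y = np.deg2rad(170.0), np.deg2rad(-170.0)
        assert np.rad2deg(phase_difference(x, y)) == pytest.approx(-20.0)

    @given(x=st.floats(-np.pi, np.pi), y=st.floats(-np.pi, np.pi))
    def test_antisymmetry(self, x, y):
        d1, d2 = phase_difference(x, y), phase_difference(y, x)
        if not (np.isclose(abs(d1), np.pi, atol=1e-9)):
            assert d1 == pytest.approx(-d2, abs=1e-9)


class TestCircularTests:
    def test_rayleigh_identical_angles(self):
        res = rayleigh_test(np.full(21, 0.5))
        assert res.resultant_length == pytest.approx(1.0)
        assert res.statistic == pytest.approx(21.0)
        assert res.p < 0.001

    def test_rayleigh_perfectly_uniform(self):
        angles = np.linspace(-np.pi, np.pi, 10, endpoint=False)
        res = rayleigh_test(angles)
        assert res.resultant_length < 1e-12
        assert res.p > 0.99

    def test_v_test_at_mu(self):
        res = v_test(np.full(10, 0.7), mu=0.7)
        assert res.statistic == pytest.approx(np.sqrt(20.0))
        assert res.p < 0.01

    def test_v_test_opposite_mu(self):
        res = v_test(np.full(10, 0.7 + np.pi), mu=0.7)
        assert res.p > 0.99

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            rayleigh_test([0.1, 0.2])
        with pytest.raises(ValueError):
            v_test([0.1, 0.2], 0.0)

    def test_type_one_error_calibration(self):
        """Rayleigh false-positive rate near nominal alpha under uniform
        angles (scaled-down Monte-Carlo)."""
        rng = np.random.default_rng(0)
        hits = sum(
            rayleigh_test(rng.uniform(-np.pi, np.pi, 15)).p < 0.05
            for _ in range(400)
        )
        assert abs(hits / 400 - 0.05) < 0.03


class TestGroupPhaseSimilarity:
    def test_similarity_closed_form(self):
        assert phase_similarity(0.3, 0.3) == pytest.approx(1.0)
        assert phase_similarity(0.0, np.pi) == pytest.approx(0.0, abs=1e-12)
        assert phase_similarity(np.deg2rad(57.0), 0.0) == pytest.approx(
            np.cos(np.deg2rad(28.5))
        )

    def test_group_split_and_test(self, rng):
        n = 11
        tgt = rng.uniform(-np.pi, np.pi, n)
        comp = tgt + rng.normal(0, 0.3, n)
        scores = rng.uniform(0.5, 1.0, n)
        out = group_phase_similarity(tgt, comp, scores, seed=0)
        assert len(out["low_group"]) == len(out["high_group"]) == n // 2
        assert 0.0 <= out["p"] <= 1.0

    def test_small_group_errors(self):
        with pytest.raises(ValueError):
            group_phase_similarity([0.1] * 4, [0.1] * 4, [0.2] * 4, seed=0)


def test_circ_mean_requires_finite_angles():
    with pytest.raises(ValueError):
        circ_mean([np.nan, np.nan])
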
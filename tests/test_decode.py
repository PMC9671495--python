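"""Decoding tests: LDA geometry, cross-validation hygiene, fidelity sign
conventions, response realignment and surrogate nulls."""

import numpy as np
import pytest

from thetasep.containers import CATEGORY_OF, FidelityCourse
from thetasep.decode import (
    accuracy_course,
    cv_accuracy,
    cv_decision_values,
    decode_target_competitor,
    fidelity_timecourses,
    realign_to_response,
    surrogate_fidelities,
    train_lda,
)


class TestTrainLDA:
    def test_separable_classes_perfect_heldout_accuracy(self, rng):
        X = np.concatenate([rng.normal(-1, 0.01, (20, 1)), rng.normal(1, 0.01, (20, 1))])
        y = np.repeat([0, 1], 20)
        assert cv_accuracy(X, y, n_folds=5, n_repeats=1) == 1.0

    def test_boundary_at_midpoint_in_1d(self):
        # closed-form LDA: equal class variances put the boundary at the
        # midpoint of the class means
        X = np.array([[0.0], [0.2], [1.0], [1.2]])
        y = np.array([0, 0, 1, 1])
        model = train_lda(X, y, shrinkage=0.0)
        boundary = -model.b / model.w[0]
        assert boundary == pytest.approx((0.1 + 1.1) / 2.0, abs=1e-8)

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            train_lda(np.zeros((4, 2)), np.zeros(4))

    def test_translation_invariance(self, rng):
        X = rng.standard_normal((30, 10))
        y = np.repeat([0, 1], 15)
        shift = rng.standard_normal(10) * 5
        d0 = train_lda(X, y).decision(X)
        d1 = train_lda(X + shift, y).decision(X + shift)
        np.testing.assert_allclose(d0, d1, atol=1e-8)

    def test_matches_sklearn_reference(self, rng):
        # independent route: sklearn's lsqr/auto-shrinkage discriminant
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X = rng.standard_normal((60, 12))
        y = np.repeat([0, 1], 30)
        X[y == 1] += 0.4
        d_own = train_lda(X, y).decision(X)
        d_sk = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto").fit(
            X, y
        ).decision_function(X)
        assert np.corrcoef(d_own, d_sk)[0, 1] > 0.95
        assert np.mean((d_own > 0) == (d_sk > 0)) > 0.9

    def test_shuffled_labels_give_chance_accuracy(self):
        # small-scale calibration; the full version runs in acceptance
        accs = []
        for i in range(20):
            r = np.random.default_rng(i)
            X = r.standard_normal((40, 30))
            y = r.permutation(np.repeat([0, 1], 20))
            accs.append(cv_accuracy(X, y, seed=i))
        assert abs(np.mean(accs) - 0.5) < 0.05


def test_cv_no_train_test_overlap(rng):
    X = rng.standard_normal((40, 5))
    y = np.repeat([0, 1], 20)
    _, folds = cv_decision_values(X, y, n_folds=10, n_repeats=5)
    for train_idx, test_idx in folds:
        assert np.intersect1d(train_idx, test_idx).size == 0
    # every trial is tested exactly once per repeat
    tested = np.concatenate([t for _, t in folds])
    assert np.bincount(tested, minlength=40).tolist() == [5] * 40


class TestStudyDecoding:
    def test_target_fidelity_positive_at_group_level(self, small_study):
        means = []
        for part in small_study.participants:
            cc = part.trials.select(
                (part.trials.metadata["condition"] == "CC").to_numpy()
            )
            tgt, _ = decode_target_competitor(part.trials, cc, window=(500, 3000))
            means.append(np.nanmean(tgt.values))
        assert np.mean(means) > 0

    def test_designations_use_distinct_classifiers(self, small_study):
        """Target and competitor d-values on the same trial come from the
        classifiers of *different* superordinate categories."""
        part = small_study.participants[0]
        cc = part.trials.select((part.trials.metadata["condition"] == "CC").to_numpy())
        tgt, comp = decode_target_competitor(part.trials, cc, window=(1000, 1100))
        t_cat = tgt.metadata["target_sub"].map(CATEGORY_OF)
        c_cat = comp.metadata["competitor_sub"].map(CATEGORY_OF)
        assert (t_cat != c_cat).all()
        assert not np.allclose(tgt.values, comp.values, equal_nan=True)

    def test_cv_mode_matches_metadata(self, small_study):
        part = small_study.participants[0]
        course = fidelity_timecourses(part.trials, window=(1000, 1100))
        assert course.designation == "self"
        assert (course.metadata["condition"].isin(["NC1", "NC2"])).all()
        acc = accuracy_course(course)
        assert np.all((acc >= 0) & (acc <= 1))


class TestRealignToResponse:
    def _course(self):
        times = np.arange(-500.0, 3001.0, 8.0)
        values = np.tile(times, (3, 1))  # value equals cue time
        import pandas as pd

        meta = pd.DataFrame({"rt_ms": [1000.0, 300.0, 2000.0]})
        return FidelityCourse(values=values, times=times, designation="target",
                              metadata=meta)

    def test_zero_maps_to_response_time(self):
        out = realign_to_response(self._course())
        j = np.argmin(np.abs(out.times))
        assert out.values[0, j] == pytest.approx(1000.0, abs=8.0)
        assert out.alignment == "response"

    def test_early_response_excluded(self):
        out = realign_to_response(self._course())
        assert out.n_trials == 2
        assert 300.0 not in out.metadata["rt_ms"].to_numpy()

    def test_constant_course_means_unchanged(self):
        course = self._course()
        course.values[:] = 3.14
        out = realign_to_response(course)
        assert np.allclose(np.nanmean(out.values, axis=1), 3.14)

    def test_no_survivors_error(self):
        course = self._course()
        course.metadata["rt_ms"] = 100.0
        with pytest.raises(ValueError):
            realign_to_response(course)


def test_surrogates_deterministic_and_near_zero(small_study):
    part = small_study.participants[0]
    cc = part.trials.select((part.trials.metadata["condition"] == "CC").to_numpy())
    kw = dict(window=(1000, 1200))
    s1 = surrogate_fidelities(part.trials, cc, "target", n_iter=3, seed=9, **kw)
    s2 = surrogate_fidelities(part.trials, cc, "target", n_iter=3, seed=9, **kw)
    for a, b in zip(s1, s2):
        np.testing.assert_array_equal(a.values, b.values)
    # the permutations differ between iterations
    assert not np.allclose(s1[0].values, s1[1].values)


def test_snr_monotonicity_of_group_fidelity():
    """Increasing planted pattern SNR never decreases group-mean target
    fidelity (median over simulations, three SNR levels)."""
    from thetasep.simulate import SimConfig, generate_study

    levels = [0.0, 0.7, 1.4]
    med = []
    for snr in levels:
        vals = []
        for sim in range(3):
            cfg = SimConfig(n_participants=2, n_trials_per_condition=4,
                            n_channels=12, pattern_snr=snr, modulation_depth=0.3,
                            seed=100 + sim)
            study = generate_study(cfg)
            for part in study.participants:
                cc = part.trials.select(
                    (part.trials.metadata["condition"] == "CC").to_numpy()
                )
                tgt, _ = decode_target_competitor(part.trials, cc,
                                                  window=(1000, 1200))
                vals.append(np.nanmean(tgt.values))
        med.append(np.median(vals))
    assert med[0] <= med[1] <= med[2]
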
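"""Time-resolved binary decoding of memory reinstatement.

Shrinkage-regularised linear discriminant analysis is trained per
timepoint on the sensor pattern (one feature per channel), producing
single-trial signed decision values ("fidelity" or d-values).  Target and
competitor reinstatement on the same competitive trial are read out by
*different* classifiers (one per superordinate category, each trained on
the non-competitive trials of that category), so the two fidelity
timecourses are independent read-outs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import RepeatedStratifiedKFold

from .containers import CATEGORY_OF, FidelityCourse, TrialSet
from .preprocess import smooth_gaussian


@dataclass
class LDAModel:
    """Linear discriminant ``d(x) = w @ x + b``; d > 0 favours classes[1]."""

    w: np.ndarray
    b: float
    classes: np.ndarray
    shrinkage_: float = float("nan")

    def decision(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.w + self.b


def ledoit_wolf_shrinkage(X_centered) -> float:
    """Analytic (Ledoit–Wolf) shrinkage intensity toward a scaled identity.

    ``X_centered`` holds already-centred observations (rows); the returned
    lambda in [0, 1] minimises the expected Frobenius loss of
    ``(1 - lambda) * S + lambda * (tr(S)/p) * I``.
    """
    X = np.asarray(X_centered, dtype=float)
    n, p = X.shape
    S = X.T @ X / n
    m = np.trace(S) / p
    d2 = np.sum((S - m * np.eye(p)) ** 2) / p
    if d2 == 0:
        return 0.0
    sq_norms = np.einsum("ij,ij->i", X, X)
    b2 = (np.sum(sq_norms**2) - n * np.sum(S**2)) / (n**2 * p)
    b2 = min(max(b2, 0.0), d2)
    return float(b2 / d2)


def train_lda(X, y, shrinkage="auto") -> LDAModel:
    """Fit a binary LDA with shrinkage-regularised pooled covariance.

    ``shrinkage="auto"`` uses the analytic Ledoit–Wolf intensity toward a
    scaled identity; a float in [0, 1] fixes the intensity.  The decision
    value is oriented to the second (sorted) class, with equal priors.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("exactly two classes are required")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 items")
    mu0 = X[y == classes[0]].mean(axis=0)
    mu1 = X[y == classes[1]].mean(axis=0)
    Xc = X.copy()
    Xc[y == classes[0]] -= mu0
    Xc[y == classes[1]] -= mu1
    lam = ledoit_wolf_shrinkage(Xc) if shrinkage == "auto" else float(shrinkage)
    n, p = X.shape
    S = Xc.T @ Xc / n
    sigma = (1.0 - lam) * S + lam * (np.trace(S) / p) * np.eye(p)
    w = np.linalg.solve(sigma, mu1 - mu0)
    b = -float(w @ (mu0 + mu1)) / 2.0
    return LDAModel(w=w, b=b, classes=classes, shrinkage_=lam)


def cv_decision_values(X, y, n_folds=10, n_repeats=5, seed=0, shrinkage="auto"):
    """Out-of-fold decision values, averaged over CV repeats.

    Returns ``(d, folds)`` where ``d`` is oriented to the second (sorted)
    class and ``folds`` records the (train, test) index arrays of every
    split for cross-validation bookkeeping.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    cv = RepeatedStratifiedKFold(n_splits=n_folds, n_repeats=n_repeats,
                                 random_state=seed)
    d = np.zeros(len(y))
    folds = []
    for train_idx, test_idx in cv.split(X, y):
        model = train_lda(X[train_idx], y[train_idx], shrinkage)
        d[test_idx] += model.decision(X[test_idx])
        folds.append((train_idx, test_idx))
    return d / n_repeats, folds


def cv_accuracy(X, y, n_folds=10, n_repeats=5, seed=0) -> float:
    """Mean held-out accuracy of the shrinkage LDA (chance = 0.5)."""
    d, _ = cv_decision_values(X, y, n_folds, n_repeats, seed)
    classes = np.unique(y)
    return float(np.mean((d > 0) == (y == classes[1])))


def _designated_sub(metadata: pd.DataFrame, designation: str) -> pd.Series:
    if designation == "target":
        return metadata["target_sub"]
    if designation == "competitor":
        return metadata["competitor_sub"]
    raise ValueError("designation must be 'target' or 'competitor'")


def _orient(d, true_labels, classes):
    """Flip signs so positive d = evidence for the trial's true label."""
    sign = np.where(np.asarray(true_labels) == classes[1], 1.0, -1.0)
    return d * sign


def _time_grid(times, window, step_ms):
    lo = max(window[0], times[0])
    hi = min(window[1], times[-1])
    sel = np.where((times >= lo) & (times <= hi))[0]
    dt = times[1] - times[0]
    stride = max(1, int(round(step_ms / dt)))
    return sel[::stride]


def fidelity_timecourses(
    train: TrialSet,
    test: TrialSet | None = None,
    designation: str = "target",
    step_ms: float = 8.0,
    fwhm_ms: float = 40.0,
    window: tuple[float, float] = (-500.0, 3000.0),
    correct_only: bool = True,
    n_folds: int = 10,
    n_repeats: int = 5,
    seed: int = 0,
    _permute_rng: np.random.Generator | None = None,
) -> FidelityCourse:
    """Single-trial fidelity timecourses for the designated memory.

    When ``test`` is None (or is ``train``), decoding is within-set and
    stratified 10-fold cross-validation repeated 5 times supplies
    out-of-fold d-values; otherwise the classifier of each superordinate
    category is trained on the non-competitive trials of ``train`` and
    applied to the ``test`` trials whose designated subcategory belongs to
    that category.  Features are the channel amplitudes at each timepoint
    after 40 ms FWHM Gaussian smoothing of the trial time series.
    """
    cv_mode = test is None or test is train
    test = train if cv_mode else test

    train_sm = smooth_gaussian(train.data, fwhm_ms, train.fs)
    test_sm = train_sm if test is train else smooth_gaussian(test.data, fwhm_ms, test.fs)

    t_idx = _time_grid(test.times, window, step_ms)
    times = test.times[t_idx]

    meta = test.metadata
    if cv_mode:
        test_mask = np.asarray(meta["condition"].isin(["NC1", "NC2"]))
    else:
        sub = _designated_sub(meta, designation)
        test_mask = np.asarray(sub != "")
        if correct_only:
            test_mask &= np.asarray(meta["correct_q1"] & meta["correct_q2"])
    if not test_mask.any():
        raise ValueError("empty test set")

    out_meta = meta.loc[test_mask].reset_index(drop=True)
    values = np.full((int(test_mask.sum()), t_idx.size), np.nan)
    pos = np.cumsum(test_mask) - 1  # row in `values` per original trial

    for category in ("object", "scene"):
        if cv_mode:
            grp = test_mask & np.asarray(meta["target_category"] == category)
            if not grp.any():
                continue
            labels = np.asarray(meta.loc[grp, "target_sub"])
            if np.unique(labels).size < 2:
                raise ValueError(f"single-class training set for {category}")
            if _permute_rng is not None:
                labels = _permute_rng.permutation(labels)
            _check_balance(labels)
            rows = pos[grp]
            for j, ti in enumerate(t_idx):
                d, _ = cv_decision_values(
                    train_sm[grp][:, :, ti], labels, n_folds, n_repeats, seed
                )
                classes = np.unique(labels)
                values[rows, j] = _orient(d, np.asarray(meta.loc[grp, "target_sub"]),
                                          classes)
        else:
            tr_mask = np.asarray(
                train.metadata["condition"].isin(["NC1", "NC2"])
                & (train.metadata["target_category"] == category)
            )
            if not tr_mask.any():
                raise ValueError(f"no non-competitive training trials for {category}")
            labels = np.asarray(train.metadata.loc[tr_mask, "target_sub"])
            if np.unique(labels).size < 2:
                raise ValueError(f"single-class training set for {category}")
            if _permute_rng is not None:
                labels = _permute_rng.permutation(labels)
            _check_balance(labels)
            sub = _designated_sub(meta, designation)
            grp = test_mask & np.asarray(sub.map(lambda s: CATEGORY_OF.get(s)) == category)
            if not grp.any():
                continue
            rows = pos[grp]
            true = np.asarray(sub[grp])
            Xtr_all = train_sm[tr_mask]
            Xte_all = test_sm[grp]
            for j, ti in enumerate(t_idx):
                model = train_lda(Xtr_all[:, :, ti], labels)
                d = model.decision(Xte_all[:, :, ti])
                values[rows, j] = _orient(d, true, model.classes)

    return FidelityCourse(
        values=values,
        times=times,
        designation="self" if cv_mode else designation,
        alignment="cue",
        metadata=out_meta,
        step_ms=step_ms,
    )


def decode_target_competitor(
    train: TrialSet,
    test: TrialSet,
    step_ms: float = 8.0,
    fwhm_ms: float = 40.0,
    window: tuple[float, float] = (-500.0, 3000.0),
    correct_only: bool = True,
    _permute_rng: np.random.Generator | None = None,
):
    """Target and competitor fidelity courses for the same CC trials.

    The object and scene classifiers (trained once per timepoint on the
    non-competitive trials of ``train``) are shared between the two
    designations — never the same classifier for both memories of a trial:
    an object-target/scene-competitor trial is scored by the object
    classifier for its target and by the scene classifier for its
    competitor.
    """
    train_sm = smooth_gaussian(train.data, fwhm_ms, train.fs)
    test_sm = smooth_gaussian(test.data, fwhm_ms, test.fs)
    t_idx = _time_grid(test.times, window, step_ms)
    times = test.times[t_idx]

    meta = test.metadata
    test_mask = np.asarray(meta["competitor_sub"] != "")
    if correct_only:
        test_mask &= np.asarray(meta["correct_q1"] & meta["correct_q2"])
    if not test_mask.any():
        raise ValueError("empty test set")
    out_meta = meta.loc[test_mask].reset_index(drop=True)
    n_out = int(test_mask.sum())
    pos = np.cumsum(test_mask) - 1

    courses = {
        "target": np.full((n_out, t_idx.size), np.nan),
        "competitor": np.full((n_out, t_idx.size), np.nan),
    }
    for category in ("object", "scene"):
        tr_mask = np.asarray(
            train.metadata["condition"].isin(["NC1", "NC2"])
            & (train.metadata["target_category"] == category)
        )
        if not tr_mask.any():
            raise ValueError(f"no non-competitive training trials for {category}")
        labels = np.asarray(train.metadata.loc[tr_mask, "target_sub"])
        if np.unique(labels).size < 2:
            raise ValueError(f"single-class training set for {category}")
        if _permute_rng is not None:
            labels = _permute_rng.permutation(labels)
        _check_balance(labels)
        Xtr = train_sm[tr_mask]

        groups = {}
        for designation in ("target", "competitor"):
            sub = _designated_sub(meta, designation)
            grp = test_mask & np.asarray(
                sub.map(lambda s: CATEGORY_OF.get(s)) == category
            )
            if grp.any():
                groups[designation] = (pos[grp], test_sm[grp], np.asarray(sub[grp]))
        for j, ti in enumerate(t_idx):
            model = train_lda(Xtr[:, :, ti], labels)
            for designation, (rows, Xte, true) in groups.items():
                d = model.decision(Xte[:, :, ti])
                courses[designation][rows, j] = _orient(d, true, model.classes)

    return tuple(
        FidelityCourse(values=courses[des], times=times, designation=des,
                       alignment="cue", metadata=out_meta, step_ms=step_ms)
        for des in ("target", "competitor")
    )


def _check_balance(labels, tolerance=0.2):
    _, counts = np.unique(labels, return_counts=True)
    if abs(counts[0] - counts[1]) / counts.sum() > tolerance:
        warnings.warn("class imbalance exceeds tolerance", stacklevel=3)


def accuracy_course(course: FidelityCourse) -> np.ndarray:
    """Per-timepoint fraction of trials with positive (correct) d-values."""
    return np.nanmean(course.values > 0, axis=0)


def realign_to_response(
    course: FidelityCourse,
    rt_ms=None,
    window: tuple[float, float] = (-500.0, 200.0),
    min_rt_ms: float = 500.0,
    tail_ms: float = 200.0,
) -> FidelityCourse:
    """Shift each trial's timeline so 0 = button press.

    Trials responding within the first ``min_rt_ms`` or the last
    ``tail_ms`` of the epoch are excluded.
    """
    if rt_ms is None:
        if course.metadata is None:
            raise ValueError("rt_ms required when the course has no metadata")
        rt_ms = np.asarray(course.metadata["rt_ms"], dtype=float)
    rt_ms = np.asarray(rt_ms, dtype=float)
    t_end = course.times[-1]
    keep = (rt_ms >= min_rt_ms) & (rt_ms <= t_end - tail_ms)
    if not keep.any():
        raise ValueError("no trials survive the response-time exclusion")

    dt = course.times[1] - course.times[0]
    new_times = np.arange(window[0], window[1] + dt / 2, dt)
    vals = np.full((int(keep.sum()), new_times.size), np.nan)
    for out_i, trial_i in enumerate(np.where(keep)[0]):
        cue_times = rt_ms[trial_i] + new_times
        idx = np.round((cue_times - course.times[0]) / dt).astype(int)
        ok = (idx >= 0) & (idx < course.times.size)
        vals[out_i, ok] = course.values[trial_i, idx[ok]]
    meta = None
    if course.metadata is not None:
        meta = course.metadata.loc[keep].reset_index(drop=True)
    return FidelityCourse(values=vals, times=new_times, designation=course.designation,
                          alignment="response", metadata=meta, step_ms=dt)


def surrogate_fidelities(
    train: TrialSet,
    test: TrialSet | None,
    designation: str = "target",
    n_iter: int = 15,
    seed: int = 0,
    **kwargs,
):
    """Label-shuffled null decodings: a fresh training-label permutation
    per iteration, otherwise identical to :func:`fidelity_timecourses`."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    return [
        fidelity_timecourses(train, test, designation, _permute_rng=rng, **kwargs)
        for _ in range(n_iter)
    ]
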
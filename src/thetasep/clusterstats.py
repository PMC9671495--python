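"""Non-parametric cluster-based permutation testing for 1-D and 2-D maps.

Per-cell t statistics are thresholded at a forming alpha, contiguous
suprathreshold cells (1-D adjacency / 2-D 4-connectivity) are summed into
cluster masses, and the observed masses are compared with the permutation
distribution of the maximal cluster mass under sign flipping (one-sample /
paired designs).  Reported p-values are permutation-exact:
``p = (1 + #{perm mass >= observed}) / (n_perm + 1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats


@dataclass
class Cluster:
    mask: np.ndarray
    mass: float
    p: float

    @property
    def size(self) -> int:
        return int(self.mask.sum())


@dataclass
class ClusterResult:
    clusters: list
    t_map: np.ndarray
    forming_threshold: float
    n_permutations: int
    cluster_alpha: float
    tail: str
    null_max_mass: np.ndarray = field(repr=False, default=None)

    @property
    def significant(self) -> list:
        return [c for c in self.clusters if c.p < self.cluster_alpha]

    @property
    def any_significant(self) -> bool:
        return len(self.significant) > 0


def _clusters_from_t(t, thresh, tail, structure, min_size):
    """(mask, signed mass) pairs of suprathreshold clusters."""
    out = []
    masks = []
    if tail in ("two-sided", "greater"):
        masks.append(t >= thresh)
    if tail in ("two-sided", "less"):
        masks.append(t <= -thresh)
    for m in masks:
        labels, n_lab = ndimage.label(m, structure=structure)
        for lab in range(1, n_lab + 1):
            mask = labels == lab
            if mask.sum() >= min_size:
                out.append((mask, float(t[mask].sum())))
    return out


def cluster_permutation(
    data,
    design="one_sample",
    data2=None,
    popmean=0.0,
    forming_alpha=0.05,
    tail="two-sided",
    n_perm=1000,
    cluster_alpha=0.05,
    min_size=1,
    seed=None,
) -> ClusterResult:
    """Cluster-based permutation test on participant maps.

    Parameters
    ----------
    data
        Array ``(n_participants, *map_shape)`` with a 1-D or 2-D map.
    design
        ``"one_sample"`` tests against ``popmean``; ``"paired"`` tests
        ``data - data2`` against zero.  Both reduce to sign-flip
        permutations of per-participant difference maps.
    forming_alpha, tail
        Cluster-forming threshold: critical t of a ``tail`` test at
        ``forming_alpha`` (default two-sided 0.05).
    """
    data = np.asarray(data, dtype=float)
    if design == "paired":
        if data2 is None:
            raise ValueError("paired design requires data2")
        diff = data - np.asarray(data2, dtype=float)
    elif design == "one_sample":
        diff = data - popmean
    else:
        raise ValueError(f"unknown design {design!r}")
    n = diff.shape[0]
    if n < 5:
        raise ValueError("need at least 5 participants")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives very coarse p-values", stacklevel=2)
    if tail not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown tail {tail!r}")

    shape = diff.shape[1:]
    if len(shape) not in (1, 2):
        raise ValueError("maps must be 1-D or 2-D")
    structure = ndimage.generate_binary_structure(len(shape), 1)

    flat = diff.reshape(n, -1)
    sumsq = np.sum(flat**2, axis=0)

    def _tmap(means):
        var = (sumsq - n * means**2) / (n - 1)
        bad = var <= 0
        var[bad] = np.inf  # degenerate-variance cells masked (t = 0)
        return means / np.sqrt(var / n)

    t_obs = _tmap(flat.mean(axis=0)).reshape(shape)
    if tail == "two-sided":
        t_crit = float(stats.t.isf(forming_alpha / 2.0, n - 1))
    else:
        t_crit = float(stats.t.isf(forming_alpha, n - 1))
    t_signed = -t_obs if tail == "less" else t_obs
    obs_tail = "greater" if tail == "less" else tail
    observed = _clusters_from_t(t_signed, t_crit, obs_tail, structure, min_size)

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    perm_means = signs @ flat / n
    null_max = np.zeros(n_perm)
    for i in range(n_perm):
        t_perm = _tmap(perm_means[i]).reshape(shape)
        if tail == "less":
            t_perm = -t_perm
        cl = _clusters_from_t(t_perm, t_crit, obs_tail, structure, min_size)
        if cl:
            null_max[i] = max(abs(m) for _, m in cl)

    clusters = []
    for mask, mass in observed:
        p = (1.0 + np.sum(null_max >= abs(mass))) / (n_perm + 1.0)
        clusters.append(Cluster(mask=mask, mass=mass, p=float(p)))
    clusters.sort(key=lambda c: c.p)
    return ClusterResult(clusters=clusters, t_map=t_obs,
                         forming_threshold=t_crit, n_permutations=n_perm,
                         cluster_alpha=cluster_alpha, tail=tail,
                         null_max_mass=null_max)
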
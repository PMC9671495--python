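"""Behavioural derived measures.

Accuracy requires both follow-up questions correct; the interference
score is NC1 minus CC accuracy; the intrusion score is, among
supraordinate errors on competitive trials, the fraction of subordinate
choices matching the competitor's subcategory (chance reference 50%).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CONDITIONS


def score_behaviour(table: pd.DataFrame) -> pd.DataFrame:
    """Per-participant accuracies, interference and intrusion scores.

    "No-memory" responses count as incorrect for accuracy and are excluded
    from the intrusion denominator.  Participants without any CC
    supraordinate error get an undefined (NaN) intrusion score.
    """
    if len(table) == 0:
        raise ValueError("empty behaviour table")
    rows = []
    for pid, grp in table.groupby("participant", sort=True):
        correct = grp["correct_q1"].astype(bool) & grp["correct_q2"].astype(bool)
        acc = {}
        for cond in CONDITIONS:
            sel = grp["condition"] == cond
            acc[cond] = float(correct[sel].mean()) if sel.any() else np.nan

        cc = grp[grp["condition"] == "CC"]
        errors = cc[
            (cc["resp_supra"] != cc["target_category"])
            & (cc["resp_supra"] != "no_memory")
        ]
        if len(errors):
            intrusion = float((errors["resp_sub"] == errors["competitor_sub"]).mean())
        else:
            intrusion = np.nan
        rows.append(
            {
                "participant": pid,
                "acc_NC1": acc["NC1"],
                "acc_NC2": acc["NC2"],
                "acc_CC": acc["CC"],
                "interference": acc["NC1"] - acc["CC"],
                "intrusion": intrusion,
                "n_cc_errors": len(errors),
            }
        )
    return pd.DataFrame(rows)


def accuracy_by_repetition(table: pd.DataFrame, condition="CC") -> pd.DataFrame:
    """participants x repetitions (1-3) accuracy matrix for slope tests."""
    sel = table[table["condition"] == condition]
    correct = sel["correct_q1"].astype(bool) & sel["correct_q2"].astype(bool)
    out = (
        sel.assign(correct=correct)
        .groupby(["participant", "repetition"])["correct"]
        .mean()
        .unstack("repetition")
    )
    return out.reindex(columns=[1, 2, 3])


def slope_test(values) -> dict:
    """Per-participant least-squares slope over repetitions 1-3 and a
    group Wilcoxon signed-rank test of the slopes against zero.

    Returns ``{"slopes", "statistic", "p"}``; all-zero slopes are a
    degenerate case reported with p = 1.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] != 3:
        raise ValueError("values must be participants x 3 repetitions")
    x = np.array([1.0, 2.0, 3.0])
    xc = x - x.mean()
    slopes = (values - values.mean(axis=1, keepdims=True)) @ xc / (xc @ xc)
    if np.allclose(slopes, 0.0):
        return {"slopes": slopes, "statistic": np.nan, "p": 1.0}
    res = stats.wilcoxon(slopes)
    return {"slopes": slopes, "statistic": float(res.statistic),
            "p": float(res.pvalue)}
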
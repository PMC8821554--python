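"""Beat-by-beat blood-pressure responses around stimulus trains.

Beat index 1 is the first stimulated cardiac cycle; changes are expressed
relative to the mean of the 8 pre-stimulus beats (-8..-1), mirroring the
MSNA control window.  Group contrasts (Inhibitors vs Non-inhibitors) use
the two-sided Wilcoxon rank-sum test at post-stimulus cardiac interval 6
(the expected latency between a missing sympathetic burst and its maximal
BP effect), with exact enumeration for small samples; heart rate and pulse
pressure are screened beat-by-beat over beats 1-15.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

BASELINE_BEATS = np.arange(-8, 0)
MEASURES = ("map", "sbp", "dbp", "hr", "pulse_pressure")


@dataclass
class GroupComparison:
    statistic: float
    p_value: float
    beat: int
    measure: str
    n_groups: tuple[int, int]
    method: str  # "exact" | "asymptotic"


def align_beats(bp_table, include_subjects=None):
    """Trial-averaged change-from-baseline per subject and beat.

    ``bp_table`` is the long-format table written by the generator
    (columns: subject, group, trial, beat, map, sbp, dbp, hr,
    pulse_pressure).  Trials missing any baseline beat are dropped with a
    warning.  Returns a DataFrame indexed by (subject, beat) with change
    columns per measure plus the group label; the baseline-window mean
    change is 0 by construction.
    """
    df = bp_table
    if include_subjects is not None:
        df = df[df["subject"].isin(include_subjects)]
    key = ["subject", "trial"]
    n_base = (df[df["beat"].isin(BASELINE_BEATS)]
              .groupby(key)["beat"].nunique())
    complete = n_base[n_base == len(BASELINE_BEATS)].index
    n_dropped = df.groupby(key).ngroups - len(complete)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} trials with missing baseline "
                      "beats", stacklevel=2)
    df = df.set_index(key).loc[complete].reset_index()
    if df.empty:
        raise ValueError("no usable trials")
    base = (df[df["beat"].isin(BASELINE_BEATS)]
            .groupby(key)[list(MEASURES)].mean())
    delta = df.copy()
    delta[list(MEASURES)] = (df[list(MEASURES)].to_numpy()
                             - base.reindex(
                                 pd.MultiIndex.from_frame(df[key]))
                             .to_numpy())
    beats = (delta.groupby(["subject", "beat"], sort=True)
             .agg({**{m: "mean" for m in MEASURES}, "group": "first"})
             .reset_index())
    return beats


def rank_sum(x, y, exact_max_n: int = 20) -> tuple[float, float, str]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when the combined sample is <= ``exact_max_n`` and
    tie-free; otherwise the normal approximation with tie correction and
    continuity correction.  An all-tied sample yields p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values tied; rank-sum p set to 1", stacklevel=2)
        return 0.0, 1.0, "degenerate"
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if method == "exact" else "asymptotic")
    return float(res.statistic), float(res.pvalue), method


def compare_groups(beats, beat: int = 6, measure: str = "map",
                   group_a: str = "Non-inhibitor",
                   group_b: str = "Inhibitor") -> GroupComparison:
    """Rank-sum contrast of the change at one post-stimulus beat."""
    sel = beats[beats["beat"] == beat]
    x = sel.loc[sel["group"] == group_a, measure].to_numpy()
    y = sel.loc[sel["group"] == group_b, measure].to_numpy()
    stat, p, method = rank_sum(x, y)
    return GroupComparison(statistic=stat, p_value=p, beat=beat,
                           measure=measure, n_groups=(len(x), len(y)),
                           method=method)


def screen_beats(beats, beat_range=range(1, 16),
                 measures=("hr", "pulse_pressure")) -> list:
    """One rank-sum test per beat per measure over the visible-difference
    range.  No multiplicity correction is applied when every raw p >= 0.05
    (none is then needed); significant raw values should be corrected by
    the caller before interpretation."""
    return [compare_groups(beats, beat=b, measure=m)
            for m in measures for b in beat_range]


def correlate_inhibition_bp(inhibition, beats, beat: int = 6,
                            measure: str = "map"):
    """Spearman correlation between subject inhibition (%) and the BP
    change at the given beat.  ``inhibition`` maps subject -> percent."""
    sel = beats[beats["beat"] == beat].set_index("subject")[measure]
    subjects = [s for s in sel.index if s in inhibition]
    if len(subjects) < 3:
        raise ValueError("need >= 3 paired subjects")
    x = np.array([inhibition[s] for s in subjects], dtype=float)
    y = sel.loc[subjects].to_numpy(dtype=float)
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
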
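"""ROI cortical-thickness statistics against MSNA inhibition.

Thickness tables arrive as one row per subject with mean cortical
thickness (mm) per ROI label (a Qdec-style ROI export).  The bilateral
rostral-ACC estimate is the mean of the left and right labels.  Each of
the three pre-selected ROIs (rostral ACC, insula, Rolandic) is tested with
a Spearman correlation against inhibition, Bonferroni-corrected for the
three comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats

N_PRESELECTED_ROIS = 3
#: exact-permutation Spearman p up to this n; t-approximation above
EXACT_PERM_MAX_N = 8


@dataclass
class RoiCorrelation:
    roi: str
    r: float
    p_raw: float
    p_adjusted: float  # Bonferroni x n_rois, capped at 1
    n: int


def bilateral_racc(table) -> np.ndarray:
    """Per-subject bilateral rostral-ACC thickness: mean of left and right
    hemisphere labels.  A missing hemisphere is an error, never a silent
    single-side fallback."""
    for col in ("rACC_left", "rACC_right"):
        if col not in table.columns:
            raise KeyError(f"thickness table missing column {col!r}")
        if table[col].isna().any():
            raise ValueError(f"missing values in {col!r}")
    return 0.5 * (table["rACC_left"].to_numpy(dtype=float)
                  + table["rACC_right"].to_numpy(dtype=float))


def spearman(x, y, exact_max_n: int = EXACT_PERM_MAX_N) -> tuple[float, float]:
    """Spearman rho with mid-ranks for ties; two-sided p by exact
    permutation enumeration for n <= ``exact_max_n``, t-approximation
    above."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 3:
        raise ValueError("need >= 3 paired observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        raise ValueError("constant input: ranks undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        count = 0
        total = 0
        for perm in permutations(ry):
            total += 1
            rp = float(np.corrcoef(rx, np.asarray(perm))[0, 1])
            if abs(rp) >= abs(r) - 1e-12:
                count += 1
        p = count / total
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return r, p


def thickness_correlation(thickness_values, inhibition, roi: str = "rACC",
                          n_rois: int = N_PRESELECTED_ROIS) -> RoiCorrelation:
    """Spearman correlation of ROI thickness vs inhibition with Bonferroni
    adjustment over the pre-selected ROIs."""
    x = np.asarray(thickness_values, dtype=float)
    y = np.asarray(inhibition, dtype=float)
    if len(x) < 5:
        raise ValueError("need >= 5 paired subjects")
    r, p = spearman(x, y)
    return RoiCorrelation(roi=roi, r=r, p_raw=p,
                          p_adjusted=min(1.0, n_rois * p), n=len(x))


def roi_thickness_report(table, inhibition) -> list:
    """Correlations for the three pre-selected ROI estimates: bilateral
    rACC, insula (both unilateral sides and their mean, one test counted),
    and Rolandic."""
    inh = np.asarray(inhibition, dtype=float)
    results = [thickness_correlation(bilateral_racc(table), inh, roi="rACC")]
    insula = 0.5 * (table["insula_left"].to_numpy(dtype=float)
                    + table["insula_right"].to_numpy(dtype=float))
    results.append(thickness_correlation(insula, inh, roi="insula"))
    results.append(thickness_correlation(
        table["rolandic"].to_numpy(dtype=float), inh, roi="rolandic"))
    return results
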
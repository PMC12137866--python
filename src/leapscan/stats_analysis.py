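"""Statistical summaries: quadrant count ratio and condition comparisons."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["quadrant_count_ratio", "compare_conditions", "ComparisonResult"]


def quadrant_count_ratio(points) -> float:
    """Quadrant count ratio of a bivariate point set, in [-1, 1].

    Quadrants are defined by the medians of the two coordinates (quadrant I:
    both above their medians, numbered counter-clockwise); points lying exactly
    on a median line are excluded.  QCR = ((n_I + n_III) - (n_II + n_IV)) / N'
    with N' the number of off-median points — a robust sign-of-association
    statistic: +1 for a strictly increasing diagonal, -1 for a decreasing one,
    0 for one point per quadrant.  Being median-based it is invariant under
    strictly increasing transforms of either axis.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 1:
        raise ValueError("points must be an (N, 2) array with N >= 1")
    if not np.isfinite(pts).all():
        raise ValueError("points must be finite")
    u, v = pts[:, 0], pts[:, 1]
    mu, mv = np.median(u), np.median(v)
    off = (u != mu) & (v != mv)
    n_used = int(off.sum())
    if n_used < 4:
        raise ValueError(f"only {n_used} points off the median lines; need >= 4")
    concordant = ((u > mu) & (v > mv)) | ((u < mu) & (v < mv))
    n13 = int((concordant & off).sum())
    return (2 * n13 - n_used) / n_used


@dataclass
class ComparisonResult:
    """Pairwise two-sample tests plus per-group one-sample tests against a set value."""

    pairwise: pd.DataFrame
    one_sample: pd.DataFrame
    alpha: float = 0.05


def _ttest_1samp_safe(x: np.ndarray, popmean: float) -> tuple[float, float]:
    x = np.asarray(x, dtype=np.float64)
    if np.allclose(x, popmean) and x.std(ddof=1) == 0:
        return 0.0, 1.0
    t, p = sps.ttest_1samp(x, popmean)
    return float(t), float(p)


def compare_conditions(groups: dict[str, np.ndarray], alpha: float = 0.05,
                       equal_var: bool = True, set_value: float = 1.0) -> ComparisonResult:
    """Two-tailed t-tests between all pairs of condition groups (alpha = 5%).

    Pooled-variance tests by default (``equal_var=False`` for Welch).  Also
    tests each group against ``set_value`` (default 1, the natural reference
    for metric ratios normalised to a reference condition).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=np.float64) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.ndim != 1 or len(v) < 2:
            raise ValueError(f"group {k!r} needs at least 2 values")

    names = list(arrays)
    rows = []
    for i, ka in enumerate(names):
        for kb in names[i + 1:]:
            a, b = arrays[ka], arrays[kb]
            if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
                t, p = 0.0, 1.0
            else:
                t, p = sps.ttest_ind(a, b, equal_var=equal_var)
            rows.append({"group_a": ka, "group_b": kb,
                         "mean_a": a.mean(), "mean_b": b.mean(),
                         "mean_diff": a.mean() - b.mean(),
                         "t": float(t), "p": float(p),
                         "significant": bool(p < alpha)})
    ones = []
    for k, v in arrays.items():
        t, p = _ttest_1samp_safe(v, set_value)
        ones.append({"group": k, "mean": v.mean(), "set_value": set_value,
                     "t": t, "p": p, "significant": bool(p < alpha)})
    return ComparisonResult(pairwise=pd.DataFrame(rows),
                            one_sample=pd.DataFrame(ones), alpha=alpha)
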
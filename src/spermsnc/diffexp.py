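"""Rank-based differential expression between the H-GQE and L-GQE groups.

Features are tested per class (tsRNA / rsRNA / miRNA separately) with a
two-sided Mann-Whitney rank-sum test on RPM values — exact when the
smaller group has <= 8 samples and there are no ties, otherwise the normal
approximation with continuity correction — followed by Benjamini-Hochberg
step-up correction within the class. Effect size is the log2 fold change
of group mean RPM (L-GQE over H-GQE) with a pseudocount. A paired Wilcoxon
signed-rank variant is available for equal-size paired designs.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .quantify import GROUP_HIGH, GROUP_LOW

EXACT_MAX_N = 8


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of x, p).

    Exact enumeration when min(n) <= 8 and the pooled values have no ties;
    otherwise the mid-rank normal approximation with tie correction and
    continuity correction. Completely tied data (all values identical)
    gives p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if min(len(x), len(y)) < 2:
        raise ValidationError("both groups need at least 2 values")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return len(x) * len(y) / 2.0, 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(x), len(y)) <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def signed_rank_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Paired two-sided Wilcoxon signed-rank test (requires equal sizes)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError(
            "signed-rank test requires paired (equal-size) groups; "
            "use the rank-sum test for independent groups"
        )
    d = x - y
    if np.all(d == 0):
        return 0.0, 1.0
    res = stats.wilcoxon(x, y)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log2_fold_change(mean_l: float, mean_h: float, pseudocount: float = 1.0) -> float:
    """log2((mean_L + pc) / (mean_H + pc)); positive = up in L-GQE."""
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    return float(np.log2((mean_l + pseudocount) / (mean_h + pseudocount)))


def differential_features(
    rpm: pd.DataFrame,
    groups: pd.Series,
    class_labels: pd.Series | None = None,
    fdr: float = 0.05,
    min_abs_log2fc: float = 1.0,
    pseudocount: float = 1.0,
    test: str = "rank_sum",
) -> pd.DataFrame:
    """Per-feature differential expression between H-GQE and L-GQE.

    ``rpm`` is features x samples (already past the expression floor,
    typically restricted to one class); ``groups`` maps sample id to group
    label (samples labelled neither H-GQE nor L-GQE are dropped).
    Returns a DataFrame sorted by adjusted p with columns: feature, class,
    mean_rpm_H, mean_rpm_L, log2fc, stat, p, p_adj, direction, significant.
    """
    groups = groups.reindex(rpm.columns)
    h_samples = groups.index[groups == GROUP_HIGH]
    l_samples = groups.index[groups == GROUP_LOW]
    if min(len(h_samples), len(l_samples)) < 2:
        raise ValidationError("each group needs at least 2 samples")
    test_fn = {"rank_sum": rank_sum_test, "signed_rank": signed_rank_test}.get(test)
    if test_fn is None:
        raise ValidationError(f"unknown test {test!r}")

    rows = []
    for feature, vals in rpm.iterrows():
        xl = vals[l_samples].to_numpy(dtype=float)
        xh = vals[h_samples].to_numpy(dtype=float)
        stat, p = test_fn(xl, xh)
        lfc = log2_fold_change(xl.mean(), xh.mean(), pseudocount)
        rows.append(
            {
                "feature": feature,
                "class": class_labels[feature] if class_labels is not None else "",
                "mean_rpm_H": xh.mean(),
                "mean_rpm_L": xl.mean(),
                "log2fc": lfc,
                "stat": stat,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    if len(out) == 0:
        return out
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out["direction"] = np.where(out["log2fc"] >= 0, "up", "down")
    out["significant"] = (out["p_adj"] < fdr) & (out["log2fc"].abs() >= min_abs_log2fc)
    return out.sort_values(["p_adj", "p", "feature"]).reset_index(drop=True)
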
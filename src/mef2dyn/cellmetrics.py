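"""Differentiation and transcription-activity metrics.

Myotube differentiation is quantified by the fusion index — the fraction of
nuclei residing in myocytes with two or more nuclei within a visual field.
Transcription activity of each variant comes from a dual-reporter assay:
the luciferase signal is normalized to the co-transfected galactosidase
signal sample-by-sample, expressed as a percentage of the in-batch
wild-type mean, and pooled across experiments.  Group comparisons use a
two-sided two-sample t-test against the wild type, or one-way ANOVA with
Bonferroni-Holm-adjusted pairwise post-hoc tests.  The relation between
beta-domain dynamics and activity is summarised by a rank correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "fusion_index",
    "pooled_fusion_index",
    "normalize_activity",
    "compare_groups",
    "dynamics_activity_correlation",
    "weighted_mean_se",
]


def fusion_index(multinucleated: int, total: int) -> float:
    """Nuclei in ≥2-nucleus myocytes divided by all nuclei in the field."""
    if total <= 0:
        raise ValueError("total nucleus count must be positive")
    if not 0 <= multinucleated <= total:
        raise ValueError("multinucleated count outside [0, total]")
    return multinucleated / total


def pooled_fusion_index(counts: pd.DataFrame) -> float:
    """Fusion index over pooled fields.

    ``counts`` needs columns ``multinucleated`` and ``total``; pooling sums
    the raw counts, which equals the total-weighted mean of the per-field
    indices.
    """
    total = int(counts["total"].sum())
    return fusion_index(int(counts["multinucleated"].sum()), total)


def weighted_mean_se(means: np.ndarray, weights: np.ndarray
                     ) -> tuple[float, float]:
    """Weighted mean and weighted standard error of group-level means.

    Weights are sample counts (the convention for pooling replicate
    experiments of unequal size): SE is the square root of the weighted
    variance of the means divided by the number of groups.
    """
    means = np.asarray(means, dtype=float)
    w = np.asarray(weights, dtype=float)
    if means.size != w.size or means.size == 0:
        raise ValueError("means and weights must be equal-length, non-empty")
    wm = float(np.average(means, weights=w))
    if means.size == 1:
        return wm, float("nan")
    var = float(np.average((means - wm) ** 2, weights=w))
    return wm, float(np.sqrt(var / means.size))


def normalize_activity(readings: pd.DataFrame, wt_label: str = "wt"
                       ) -> pd.DataFrame:
    """Reporter activity as percentage of the in-batch wild-type mean.

    ``readings`` needs columns ``variant``, ``experiment``, ``luciferase``
    and ``galactosidase``.  Per sample, activity = luciferase/galactosidase;
    each batch (experiment) is scaled so the wild-type mean ratio is 100 %.
    Batches without a wild-type sample are excluded with a warning.  The
    returned frame adds a ``pct_of_wt`` column; summarise with
    :func:`summarize_activity`.
    """
    required = {"variant", "experiment", "luciferase", "galactosidase"}
    missing = required - set(readings.columns)
    if missing:
        raise ValueError(f"readings missing columns: {sorted(missing)}")
    if np.any(readings["luciferase"] <= 0) or np.any(readings["galactosidase"] <= 0):
        raise ValueError("reporter signals must be positive")
    out = []
    for batch, grp in readings.groupby("experiment", sort=True):
        ratios = grp["luciferase"] / grp["galactosidase"]
        wt_ratio = ratios[grp["variant"] == wt_label]
        if wt_ratio.empty:
            warnings.warn(f"experiment {batch!r} has no {wt_label!r} sample; "
                          "batch excluded", stacklevel=2)
            continue
        grp = grp.copy()
        grp["pct_of_wt"] = 100.0 * ratios / wt_ratio.mean()
        out.append(grp)
    if not out:
        raise ValueError("no batch contained the wild-type label")
    return pd.concat(out, ignore_index=True)


def summarize_activity(normalized: pd.DataFrame, wt_label: str = "wt"
                       ) -> pd.DataFrame:
    """Per-variant mean ± SE of the normalized activity, with t-test vs wt.

    Returns a frame indexed by variant with columns ``mean_pct``, ``se``,
    ``n`` and ``p_vs_wt`` (NaN for the wild type itself).
    """
    wt_vals = normalized.loc[normalized["variant"] == wt_label, "pct_of_wt"]
    rows = {}
    for variant, grp in normalized.groupby("variant", sort=True):
        vals = grp["pct_of_wt"].to_numpy()
        se = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan
        if variant == wt_label:
            p = np.nan
        else:
            p = float(stats.ttest_ind(vals, wt_vals).pvalue)
        rows[variant] = dict(mean_pct=float(vals.mean()), se=float(se),
                             n=int(vals.size), p_vs_wt=p)
    return pd.DataFrame(rows).T.astype({"n": int})


def compare_groups(groups: Mapping[str, np.ndarray], reference: str,
                   method: str = "t_test") -> pd.DataFrame:
    """Group comparisons against a reference group.

    ``t_test``: two-sided two-sample t-tests, one per non-reference group.
    ``anova_bh``: one-way ANOVA over all groups, then pairwise t-tests vs
    the reference with Bonferroni-Holm adjustment.  Groups with degenerate
    (zero) variance are flagged in the ``degenerate`` column.

    Returns a frame indexed by group with ``p_raw``, ``p_adj`` and
    ``degenerate``; for ``anova_bh`` the ANOVA p-value is in
    ``frame.attrs['anova_p']``.
    """
    if reference not in groups:
        raise KeyError(f"reference group {reference!r} absent")
    ref = np.asarray(groups[reference], dtype=float)
    others = [k for k in groups if k != reference]
    if ref.size < 2 or any(np.asarray(groups[k]).size < 2 for k in others):
        raise ValueError("each group needs at least 2 observations")
    p_raw, degenerate = [], []
    for k in others:
        vals = np.asarray(groups[k], dtype=float)
        degen = vals.std(ddof=1) == 0 and ref.std(ddof=1) == 0
        degenerate.append(degen)
        if degen and np.allclose(vals.mean(), ref.mean()):
            p_raw.append(1.0)
        else:
            p_raw.append(float(stats.ttest_ind(vals, ref).pvalue))
    if method == "t_test":
        frame = pd.DataFrame({"p_raw": p_raw, "p_adj": p_raw,
                              "degenerate": degenerate}, index=others)
    elif method == "anova_bh":
        anova = stats.f_oneway(*[np.asarray(groups[k], dtype=float)
                                 for k in groups])
        adj = multipletests(p_raw, method="holm")[1] if others else []
        frame = pd.DataFrame({"p_raw": p_raw, "p_adj": adj,
                              "degenerate": degenerate}, index=others)
        frame.attrs["anova_p"] = float(anova.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return frame


def dynamics_activity_correlation(mean_p_d: Sequence[float],
                                  activity: Sequence[float],
                                  method: str = "spearman"
                                  ) -> tuple[float, float]:
    """Correlation between beta-domain disorder and transcription activity.

    Rank (Spearman) correlation by default — the claimed relation is
    monotone, not linear; ``method="pearson"`` is available.  Returns
    (coefficient, p-value).  Raises on fewer than 3 variants or constant
    input, where the coefficient is undefined.
    """
    x = np.asarray(mean_p_d, dtype=float)
    y = np.asarray(activity, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired (p_D, activity) points")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for constant input")
    if method == "spearman":
        res = stats.spearmanr(x, y)
    elif method == "pearson":
        res = stats.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)
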
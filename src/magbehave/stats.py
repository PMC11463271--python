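"""Statistical comparisons used across the pipeline.

Group contrasts use the two-tailed unpaired t test with Welch's correction
(Welch-Satterthwaite degrees of freedom); associations between readouts use
Pearson's correlation with the t-transform p value.  One-way ANOVA with
Tukey's HSD is wrapped for multi-group in vitro data.  Per-contrast p values
are reported without multiplicity adjustment by default, matching common
reporting practice; an optional Holm adjustment is available.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = ["welch_t", "paired_t", "pearson_r", "anova_tukey", "holm_adjust"]


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's two-sample t test (two-tailed, unpaired).

    Returns ``(t, df, p)`` with Welch-Satterthwaite degrees of freedom.
    Requires n >= 2 per group and nonzero variance in at least one group.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("zero variance in both groups; t undefined")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def paired_t(a, b) -> tuple[float, float, float]:
    """Paired two-tailed t test (for within-animal baseline-vs-stimulation
    contrasts).  Returns (t, df, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("paired test needs equal-length groups, n >= 2")
    res = sps.ttest_rel(a, b)
    return float(res.statistic), float(len(a) - 1), float(res.pvalue)


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-tailed p (t transform,
    n - 2 df).  Requires n >= 3 and non-constant inputs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length x and y with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input; correlation undefined")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def anova_tukey(groups: list[np.ndarray]) -> dict:
    """One-way ANOVA plus Tukey's HSD across >= 3 groups."""
    if len(groups) < 3:
        raise ValueError("anova_tukey expects three or more groups")
    f, p = sps.f_oneway(*groups)
    tukey = sps.tukey_hsd(*groups)
    return {
        "name": "anova_tukey",
        "F": float(f),
        "p": float(p),
        "tukey_pvalues": np.asarray(tukey.pvalue).tolist(),
    }


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p values (optional, off by default upstream)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues, float), method="holm")[1]
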
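"""Two-group comparisons used for the thickness distributions.

Free vs docked thickness groups are compared with a one-tailed unpaired
t-test; matched within-membrane comparisons (interface vs free part of
the same membrane) use the Wilcoxon matched-pairs signed-ranks test.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .datatypes import GroupTestResult

__all__ = ["compare_groups"]

_ALTERNATIVES = ("greater", "less", "two-sided")

#: below this combined sample size the unpaired t-test p-value comes
#: from exact enumeration of all group relabelings (<= 12870 splits)
_EXACT_PERMUTATION_MAX_N = 16


class _Result:
    def __init__(self, statistic: float, pvalue: float) -> None:
        self.statistic = statistic
        self.pvalue = pvalue


def _t_stats_all_splits(pooled: np.ndarray, n_a: int) -> np.ndarray:
    """Pooled-variance t statistic of every (n_a, n_b) relabeling."""
    from itertools import combinations

    n = pooled.size
    idx = np.array(list(combinations(range(n), n_a)))
    take = pooled[idx]  # (n_splits, n_a)
    total = pooled.sum()
    total_sq = (pooled ** 2).sum()
    n_b = n - n_a
    sum_a = take.sum(axis=1)
    sq_a = (take ** 2).sum(axis=1)
    mean_a = sum_a / n_a
    mean_b = (total - sum_a) / n_b
    ss_a = sq_a - n_a * mean_a ** 2
    ss_b = (total_sq - sq_a) - n_b * mean_b ** 2
    sp2 = (ss_a + ss_b) / (n - 2)
    denom = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    diff = mean_a - mean_b
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
        # degenerate splits (zero pooled variance): sign carries the verdict
        t = np.where(denom == 0, np.sign(diff) * np.inf, t)
        t = np.where((denom == 0) & (diff == 0), 0.0, t)
    return t


def _exact_permutation_p(a: np.ndarray, b: np.ndarray, alternative: str) -> float:
    """One-tailed mid-p from full enumeration of group relabelings.

    Ties with the observed t count half, so the p-value is exactly 0.5
    under the symmetric null (a == b) and within 1/(2 n_splits) of the
    conventional tie-inclusive enumeration otherwise.
    """
    t_all = _t_stats_all_splits(np.concatenate([a, b]), a.size)
    t_obs = t_all[0]  # identity split is the first combination
    tol = 1e-12 * max(1.0, abs(t_obs))
    if alternative == "greater":
        extreme, ties = t_all > t_obs + tol, np.abs(t_all - t_obs) <= tol
    elif alternative == "less":
        extreme, ties = t_all < t_obs - tol, np.abs(t_all - t_obs) <= tol
    else:
        extreme = np.abs(t_all) > abs(t_obs) + tol
        ties = np.abs(np.abs(t_all) - abs(t_obs)) <= tol
    return float((extreme.sum() + 0.5 * ties.sum()) / t_all.size)


def compare_groups(
    a,
    b,
    test: str = "t",
    alternative: str = "greater",
    paired: bool = False,
    alpha: float = 0.05,
) -> GroupTestResult:
    """Compare two samples.

    test='t': unpaired Student t-test (equal variances); test='wilcoxon':
    matched-pairs signed-ranks test (requires ``paired=True``), exact
    null distribution where scipy supports it. ``alternative`` states
    the direction for sample ``a`` relative to ``b``.

    All-zero paired differences make the signed-rank statistic
    undefined; by convention the result then carries p=1 and is flagged.
    A zero-variance pooled t-test is an error.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two observations per group")
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")

    if test == "t":
        if paired:
            raise ValueError("the t comparison here is the unpaired test")
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            raise ValueError("zero variance in both samples: t undefined")
        if a.size + b.size <= _EXACT_PERMUTATION_MAX_N:
            stat = float(sps.ttest_ind(a, b, equal_var=True).statistic)
            pval = _exact_permutation_p(a, b, alternative)
            res = _Result(stat, pval)
        else:
            res = sps.ttest_ind(a, b, equal_var=True, alternative=alternative)
        return GroupTestResult(
            test="one-tailed unpaired t" if alternative != "two-sided" else "unpaired t",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            alternative=alternative,
            n_a=a.size,
            n_b=b.size,
            alpha=alpha,
        )
    if test == "wilcoxon":
        if not paired:
            raise ValueError("the Wilcoxon comparison here is matched-pairs")
        if a.size != b.size:
            raise ValueError("paired samples must have equal length")
        d = a - b
        if np.all(d == 0):
            return GroupTestResult(
                test="Wilcoxon matched-pairs signed-ranks",
                statistic=float("nan"),
                p_value=1.0,
                alternative=alternative,
                n_a=a.size,
                n_b=b.size,
                alpha=alpha,
                flagged=True,
            )
        res = sps.wilcoxon(a, b, alternative=alternative, method="auto")
        return GroupTestResult(
            test="Wilcoxon matched-pairs signed-ranks",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            alternative=alternative,
            n_a=a.size,
            n_b=b.size,
            alpha=alpha,
        )
    raise ValueError("test must be 't' or 'wilcoxon'")
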
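"""Group-comparison statistics: pooled-variance t-test and normality screening."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _scistats
from statsmodels.stats.diagnostic import lilliefors as _lilliefors


@dataclass
class TestResult:
    statistic: float
    p_value: float
    df: float | None
    mean_a: float | None = None
    sd_a: float | None = None
    mean_b: float | None = None
    sd_b: float | None = None
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def ttest_two_sample(a, b, alpha: float = 0.05) -> TestResult:
    """Two-sided Student's t-test with pooled variance (df = n_a + n_b - 2).

    Degenerate zero-variance inputs are resolved by continuity: equal means
    give p = 1, unequal means p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample must contain at least 2 values")
    df = len(a) + len(b) - 2
    common = dict(
        df=df,
        mean_a=float(np.mean(a)),
        sd_a=float(np.std(a, ddof=1)),
        mean_b=float(np.mean(b)),
        sd_b=float(np.std(b, ddof=1)),
        alpha=alpha,
    )
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return TestResult(statistic=0.0, p_value=1.0, **common)
        sign = 1.0 if np.mean(a) > np.mean(b) else -1.0
        return TestResult(statistic=sign * np.inf, p_value=0.0, **common)
    t, p = _scistats.ttest_ind(a, b, equal_var=True)
    return TestResult(statistic=float(t), p_value=float(p), **common)


def ks_normality(sample, alpha: float = 0.05) -> TestResult:
    """Kolmogorov-Smirnov normality check with estimated parameters.

    Because the null mean and SD are estimated from the sample, the naive KS
    null distribution would be anti-conservative; the Lilliefors-corrected
    table is used instead.  The statistic is affine-invariant.
    """
    sample = np.asarray(sample, dtype=float)
    if len(sample) < 5:
        raise ValueError("need at least 5 observations")
    if np.std(sample) == 0:
        raise ValueError("constant sample: normality test undefined")
    stat, p = _lilliefors(sample, dist="norm", pvalmethod="table")
    return TestResult(
        statistic=float(stat),
        p_value=float(min(max(p, 0.0), 1.0)),
        df=None,
        mean_a=float(np.mean(sample)),
        sd_a=float(np.std(sample, ddof=1)),
        alpha=alpha,
    )
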
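"""Statistical comparisons between treatment strategies.

Paired t-tests for DVH indices; McNemar's test for goal achievement rates
(exact binomial for few discordant pairs, chi-square asymptotics otherwise),
both at the 0.05 significance level.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

ALPHA = 0.05
#: switch from the exact binomial to the chi-square form at this many
#: discordant pairs
MCNEMAR_EXACT_LIMIT = 25


@dataclass
class TestResult:
    statistic: float
    p_value: float
    note: str = ""

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def paired_t_test(values_a, values_b) -> TestResult:
    """Classical paired t-test (two-sided), degenerate zero-variance cases
    reported as p = 1 (no difference) or p = 0 (constant nonzero shift)."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two paired 1-D samples of equal length >= 2")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff, 0.0):
            warnings.warn("all paired differences are zero; p = 1")
            return TestResult(0.0, 1.0, "degenerate: zero differences")
        warnings.warn("paired differences constant and nonzero; p -> 0")
        return TestResult(np.sign(diff.mean()) * np.inf, 0.0,
                          "degenerate: constant nonzero differences")
    t, p = sps.ttest_rel(a, b)
    return TestResult(float(t), float(p))


def mcnemar_test(pass_a, pass_b) -> TestResult:
    """McNemar's test on paired pass/fail flags.

    Discordant counts b (A pass, B fail) and c (A fail, B pass); exact
    two-sided binomial p when b + c < 25, otherwise chi-square
    (b - c)^2 / (b + c) with 1 df.
    """
    a = np.asarray(pass_a, bool)
    bb = np.asarray(pass_b, bool)
    if a.shape != bb.shape or a.ndim != 1:
        raise ValueError("need paired 1-D boolean samples of equal length")
    b = int(np.sum(a & ~bb))
    c = int(np.sum(~a & bb))
    if b + c == 0:
        return TestResult(0.0, 1.0, "no discordant pairs")
    table = np.array([[int(np.sum(a & bb)), b], [c, int(np.sum(~a & ~bb))]])
    exact = (b + c) < MCNEMAR_EXACT_LIMIT
    res = _sm_mcnemar(table, exact=exact, correction=False)
    note = "exact binomial" if exact else "chi-square"
    return TestResult(float(res.statistic), float(res.pvalue), note)
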
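"""Two-sample and contingency statistics used throughout the pipeline.

The statistics here are deliberately plain: a pooled-variance Student t-test,
a Mann-Whitney U test with exact small-sample enumeration, the textbook
(uncorrected) 2x2 chi-squared test, and a pseudocounted log2 fold change.
They implement the exact cutoff semantics the downstream analyses rely on,
including the degenerate branches (zero-variance samples, tied ranks, zero
margins) that library wrappers handle inconsistently.  P-values are computed
from the scipy.stats reference distributions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as _st

__all__ = [
    "TestResult",
    "student_t_test",
    "mann_whitney_u",
    "chi_squared_2x2",
    "log2_fold_change",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test.

    Attributes
    ----------
    statistic : float
        The test statistic (t, U, or chi-squared).
    p_value : float
        Two-sided p-value in [0, 1].
    method : str
        Short tag naming the procedure that produced the result.
    sidedness : str
        Always ``"two-sided"`` for the tests exposed here.
    df : float or None
        Degrees of freedom where the reference distribution has them.
    extra : dict
        Method-specific diagnostics (e.g. the 2x2 table, tie counts).
    """

    statistic: float
    p_value: float
    method: str
    sidedness: str = "two-sided"
    df: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _as_float_array(x: Sequence[float], name: str, min_n: int) -> np.ndarray:
    arr = np.asarray(list(x), dtype=float)
    if arr.ndim != 1 or arr.size < min_n:
        raise ValueError(f"{name} must be 1-D with at least {min_n} values")
    if np.isnan(arr).any():
        raise ValueError(f"{name} contains NaN")
    return arr


def student_t_test(
    x: Sequence[float], y: Sequence[float], pooled: bool = True
) -> TestResult:
    """Two-sided unpaired t-test of ``x`` versus ``y``.

    ``pooled=True`` (default) gives the classical Student test with a pooled
    variance estimate; ``pooled=False`` gives Welch's unequal-variance form
    with Welch-Satterthwaite degrees of freedom.

    Degenerate inputs: if both samples have zero variance the test is decided
    by the means alone -- equal means give p = 1, unequal means give p = 0
    (with a warning), since no finite t statistic exists.
    """
    xa = _as_float_array(x, "x", 2)
    ya = _as_float_array(y, "y", 2)
    n1, n2 = xa.size, ya.size
    m1, m2 = xa.mean(), ya.mean()
    v1 = xa.var(ddof=1)
    v2 = ya.var(ddof=1)
    tag = "student-t-pooled" if pooled else "welch-t"

    if v1 == 0.0 and v2 == 0.0:
        if m1 == m2:
            return TestResult(0.0, 1.0, tag, df=float(n1 + n2 - 2))
        warnings.warn(
            "both samples have zero variance with unequal means; p set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        sign = math.copysign(1.0, m1 - m2)
        return TestResult(sign * math.inf, 0.0, tag, df=float(n1 + n2 - 2))

    if pooled:
        df = float(n1 + n2 - 2)
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    else:
        se2_1, se2_2 = v1 / n1, v2 / n2
        se = math.sqrt(se2_1 + se2_2)
        df = (se2_1 + se2_2) ** 2 / (
            se2_1**2 / (n1 - 1) + se2_2**2 / (n2 - 1)
        )
    t = (m1 - m2) / se
    p = 2.0 * _st.t.sf(abs(t), df)
    return TestResult(float(t), float(min(p, 1.0)), tag, df=df)


def _u_statistic(ranks: np.ndarray, idx: Sequence[int], n1: int) -> float:
    return float(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0)


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], exact_threshold: int = 12
) -> TestResult:
    """Two-sided Mann-Whitney U test.

    The U statistic is computed for sample ``x`` from midranks of the pooled
    data (ties allowed).  When ``n1 + n2 <= exact_threshold`` the p-value is
    obtained by full enumeration of all C(n1+n2, n1) rank assignments (exact
    even under ties, conditional on the observed tie pattern); otherwise a
    normal approximation with tie and continuity corrections is used.
    """
    xa = _as_float_array(x, "x", 1)
    ya = _as_float_array(y, "y", 1)
    n1, n2 = xa.size, ya.size
    n = n1 + n2
    pooled = np.concatenate([xa, ya])
    ranks = _st.rankdata(pooled)
    u_obs = _u_statistic(ranks, range(n1), n1)
    mu = n1 * n2 / 2.0

    if n <= exact_threshold:
        dev = abs(u_obs - mu)
        hits = total = 0
        for idx in combinations(range(n), n1):
            total += 1
            if abs(_u_statistic(ranks, idx, n1) - mu) >= dev - 1e-9:
                hits += 1
        return TestResult(
            u_obs, hits / total, "mwu-exact", extra={"n1": n1, "n2": n2}
        )

    # normal approximation; tie correction subtracts sum(t^3 - t) mass
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    sigma2 = (n1 * n2 / 12.0) * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0.0:
        return TestResult(u_obs, 1.0, "mwu-normal", extra={"all_tied": True})
    # continuity correction: shrink the deviation by 0.5 toward the mean
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(sigma2)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * _st.norm.sf(z))
    return TestResult(u_obs, p, "mwu-normal", extra={"tie_term": tie_term})


def chi_squared_2x2(
    a: float, b: float, c: float, d: float, yates: bool = False
) -> TestResult:
    """Chi-squared test of independence for the 2x2 table [[a, b], [c, d]].

    Uses the closed form chi2 = N(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)), df = 1.
    ``yates=True`` applies the continuity correction |ad - bc| -> |ad-bc| - N/2
    (floored at zero), which can only reduce the statistic.
    """
    cells = [a, b, c, d]
    if any(v < 0 for v in cells):
        raise ValueError("all cells must be non-negative")
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) <= 0:
        raise ValueError("zero margin in 2x2 table")
    n = r1 + r2
    cross = a * d - b * c
    if yates:
        cross = max(abs(cross) - n / 2.0, 0.0)
    stat = n * cross**2 / (r1 * r2 * c1 * c2)
    p = float(_st.chi2.sf(stat, 1))
    return TestResult(
        float(stat),
        p,
        "chi2-yates" if yates else "chi2",
        df=1.0,
        extra={"table": ((a, b), (c, d))},
    )


def log2_fold_change(a: float, b: float, pseudocount: float = 1.0) -> float:
    """log2((a + pseudocount) / (b + pseudocount)) for non-negative a, b."""
    if a < 0 or b < 0:
        raise ValueError("inputs must be non-negative")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return math.log2((a + pseudocount) / (b + pseudocount))
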
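"""Small statistical helpers used across analyses."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p_value: float


def welch_t_test(a, b) -> WelchResult:
    """Two-sided Welch's t-test for unequal-variance group means.

    Computed from the closed form: ``t = (m1 - m2) / sqrt(v1/n1 + v2/n2)``
    with Welch-Satterthwaite degrees of freedom.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    m1, m2 = a.mean(), b.mean()
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    if se2 == 0:
        return WelchResult(t=0.0, df=float(n1 + n2 - 2), p_value=1.0)
    t = (m1 - m2) / math.sqrt(se2)
    df = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1)))
    p = 2.0 * _sps.t.sf(abs(t), df)
    return WelchResult(t=float(t), df=float(df), p_value=float(p))


def paired_one_sided_t(x, y) -> tuple[float, float]:
    """Paired t-test of H1: mean(x) > mean(y). Returns ``(t, p)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        return (math.inf if d.mean() > 0 else -math.inf, 0.0 if d.mean() > 0 else 1.0)
    t = d.mean() / (sd / math.sqrt(n))
    p = float(_sps.t.sf(t, n - 1))
    return (float(t), p)


def standard_error(x) -> float | None:
    """Standard error of the mean; None for fewer than 2 observations."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        return None
    return float(x.std(ddof=1) / math.sqrt(len(x)))
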
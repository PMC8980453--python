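"""Prevalence estimators for direct and list questioning.

Direct questioning (DQ) is an ordinary binomial proportion. The list
estimator is the difference in mean item counts between the five-card and
four-card arms, with an unpooled (Welch-style) variance — the arms have
unequal size by design, and the five-card count carries the extra
Bernoulli variance of the sensitive item.

Wald (normal) intervals are used throughout; ``se_from_ci`` inverts them
to recover the standard error behind a printed interval, which is the
entry point for reanalysing published results.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

from .survey_model import PrevalenceEstimate

__all__ = ["dq_prevalence", "lre_prevalence", "se_from_ci", "z_value"]


def z_value(level: float) -> float:
    """Standard-normal quantile for a symmetric two-sided interval."""
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must lie in (0, 1), got {level}")
    return float(norm.ppf(0.5 + level / 2.0))


def dq_prevalence(
    responses, level: float = 0.95, method: str = "DQ"
) -> PrevalenceEstimate:
    """Sample proportion of sensitive-item endorsements with a Wald CI."""
    x = np.asarray(responses, dtype=float)
    if x.size == 0:
        raise ValueError("dq_prevalence requires a nonempty response vector")
    if np.any((x != 0) & (x != 1)):
        raise ValueError("responses must be binary 0/1")
    n = x.size
    p = float(x.mean())
    se = float(np.sqrt(p * (1.0 - p) / n))
    z = z_value(level)
    return PrevalenceEstimate(
        method=method,
        estimate=p,
        se=se,
        ci_low=p - z * se,
        ci_high=p + z * se,
        level=level,
        n=int(n),
    )


def lre_prevalence(
    treatment_counts, control_counts, level: float = 0.95
) -> PrevalenceEstimate:
    """Difference-in-means list estimator (five-card mean minus four-card mean).

    ``se = sqrt(s_t^2/n_t + s_c^2/n_c)`` with n-1 sample variances. The
    point estimate may fall below zero by sampling noise; it is not
    truncated.
    """
    t = np.asarray(treatment_counts, dtype=float)
    c = np.asarray(control_counts, dtype=float)
    if t.size == 0 or c.size == 0:
        raise ValueError("both list arms must be nonempty")
    est = float(t.mean() - c.mean())
    var_t = float(t.var(ddof=1)) if t.size > 1 else 0.0
    var_c = float(c.var(ddof=1)) if c.size > 1 else 0.0
    se = float(np.sqrt(var_t / t.size + var_c / c.size))
    z = z_value(level)
    return PrevalenceEstimate(
        method="LRE",
        estimate=est,
        se=se,
        ci_low=est - z * se,
        ci_high=est + z * se,
        level=level,
        n=int(t.size + c.size),
    )


def se_from_ci(
    lower: float, upper: float, level: float = 0.95, z: float | None = None
) -> float:
    """Recover a standard error from a symmetric interval's full width.

    Published intervals are typically rounded; using the full width rather
    than one half-width is robust to asymmetric rounding. Pass ``z=1.96``
    to match hand-rounded published arithmetic exactly.
    """
    if lower > upper:
        raise ValueError(f"inverted interval [{lower}, {upper}]")
    zq = z_value(level) if z is None else float(z)
    return float((upper - lower) / (2.0 * zq))
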
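"""Design-quality diagnostics for the list experiment.

Two checks matter for a fielded list design:

* the **additional-item test** — adding the sensitive card should not
  change how respondents answer the control items. The two direct-question
  arms make this testable: compare the distribution of endorsed control
  items between the four-card and five-card versions with a two-sample
  Kolmogorov–Smirnov test;
* **floor/ceiling rates** — respondents endorsing none or all items lose
  their anonymity, so the control list should keep both rates rare.

The KS engine computes the ECDF supremum over the observed support, which
is well defined under ties (counts are small integers). The asymptotic
p-value uses the limiting Kolmogorov distribution with the usual
two-sample effective size ``n_x n_y / (n_x + n_y)``; it is conservative
under heavy ties, so an exact permutation option (full enumeration for
small pooled samples, random permutations otherwise) is provided as the
small-sample reference.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import comb, kolmogorov

from .survey_model import (
    ARM_DQ4,
    ARM_DQ5,
    DEFAULT_DESIGN,
    ListDesign,
    RespondentRecord,
)

__all__ = [
    "KSResult",
    "AdditionalItemResult",
    "ks_two_sample",
    "additional_item_test",
    "floor_ceiling_rates",
]

_EXACT_LIMIT = 20  # full enumeration up to this pooled size


@dataclass(frozen=True)
class KSResult:
    """Two-sample Kolmogorov–Smirnov comparison."""

    d_statistic: float
    p_value: float
    method: str  # "asymptotic" or "exact-permutation"
    n_x: int
    n_y: int


def _ks_distance(x: np.ndarray, y: np.ndarray) -> float:
    grid = np.unique(np.concatenate([x, y]))
    fx = np.searchsorted(np.sort(x), grid, side="right") / x.size
    fy = np.searchsorted(np.sort(y), grid, side="right") / y.size
    return float(np.abs(fx - fy).max())


def ks_two_sample(
    x,
    y,
    method: str = "auto",
    n_permutations: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> KSResult:
    """Two-sample KS test on numeric vectors (ties allowed).

    ``method`` is ``"asymptotic"``, ``"exact"`` or ``"auto"`` (exact when
    the pooled sample is small enough to enumerate). The exact p-value is
    the permutation tail probability ``P(D* >= D_obs)`` over all splits of
    the pooled sample — enumerated completely when ``n_x + n_y <= 20``,
    otherwise estimated from random permutations with an add-one
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    d = _ks_distance(x, y)
    nx, ny = int(x.size), int(y.size)
    if method == "auto":
        method = "exact" if nx + ny <= _EXACT_LIMIT else "asymptotic"
    if method == "asymptotic":
        en = nx * ny / (nx + ny)
        p = float(kolmogorov(np.sqrt(en) * d))
        return KSResult(d, min(max(p, 0.0), 1.0), "asymptotic", nx, ny)
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")

    pooled = np.sort(np.concatenate([x, y]))
    tol = 1e-12
    if nx + ny <= _EXACT_LIMIT:
        total = int(comb(nx + ny, nx, exact=True))
        hits = 0
        idx_all = range(nx + ny)
        for subset in itertools.combinations(idx_all, nx):
            mask = np.zeros(nx + ny, dtype=bool)
            mask[list(subset)] = True
            if _ks_distance(pooled[mask], pooled[~mask]) >= d - tol:
                hits += 1
        p = hits / total
    else:
        rng = (
            rng
            if isinstance(rng, np.random.Generator)
            else np.random.default_rng(rng)
        )
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            if _ks_distance(perm[:nx], perm[nx:]) >= d - tol:
                hits += 1
        p = (hits + 1) / (n_permutations + 1)
    return KSResult(d, float(p), "exact-permutation", nx, ny)


@dataclass(frozen=True)
class AdditionalItemResult:
    """Outcome of the additional-item (design independence) check."""

    ks: KSResult
    alpha: float

    @property
    def passed(self) -> bool:
        return self.ks.p_value > self.alpha


def additional_item_test(
    records: Sequence[RespondentRecord],
    design: ListDesign = DEFAULT_DESIGN,
    alpha: float = 0.05,
    include_sensitive: bool = False,
    method: str = "asymptotic",
) -> AdditionalItemResult:
    """KS comparison of endorsed-item counts between the two direct arms.

    By default the five-card arm's sensitive response is excluded, so both
    samples live on the 0–4 control scale and the test targets
    contamination of the non-sensitive items; ``include_sensitive=True``
    compares the raw totals instead.
    """
    dq4 = [r for r in records if r.arm == ARM_DQ4]
    dq5 = [r for r in records if r.arm == ARM_DQ5]
    for arm, group in ((ARM_DQ4, dq4), (ARM_DQ5, dq5)):
        if not group:
            raise ValueError(f"additional-item test requires respondents in arm {arm}")
    x = np.array([sum(r.dq_item_responses[:4]) for r in dq4], dtype=float)
    upto = 5 if include_sensitive else 4
    y = np.array([sum(r.dq_item_responses[:upto]) for r in dq5], dtype=float)
    ks = ks_two_sample(x, y, method=method)
    return AdditionalItemResult(ks, alpha)


def floor_ceiling_rates(counts, k: int) -> tuple[float, float]:
    """Fractions of counts equal to 0 (floor) and to ``k`` (ceiling)."""
    c = np.asarray(counts, dtype=int)
    if c.size == 0:
        raise ValueError("counts must be nonempty")
    if c.min() < 0 or c.max() > k:
        raise ValueError(f"counts must lie in [0, {k}]")
    return float(np.mean(c == 0)), float(np.mean(c == k))
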
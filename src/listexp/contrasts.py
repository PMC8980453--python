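"""Contrasts of prevalence estimates and subgroup report tables.

Every p-value in the analysis comes from the same primitive: an unpaired
z contrast of two prevalence estimates treated as independent normals,
``z = (p1 - p2) / sqrt(se1^2 + se2^2)``. Respondents differ across arms
by randomisation, so independence holds even for the direct-vs-list
contrast within a subgroup. No multiple-testing correction is applied;
tables report raw p-values.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .estimators import dq_prevalence, lre_prevalence, se_from_ci
from .survey_model import (
    ARM_DQ5,
    ARM_LRE4,
    ARM_LRE5,
    COVARIATES,
    ContrastResult,
    PrevalenceEstimate,
    RespondentRecord,
)

__all__ = [
    "DegenerateContrastError",
    "contrast_estimates",
    "contrast_from_cis",
    "method_comparison_table",
    "interaction_table",
    "normative_flag",
    "tabulate_reasons",
    "format_p",
]


class DegenerateContrastError(ValueError):
    """Both estimates are exact (se = 0) but differ: no z-scale exists."""


def contrast_estimates(
    e1: PrevalenceEstimate, e2: PrevalenceEstimate
) -> ContrastResult:
    """Unpaired z contrast of two estimates (``e1 - e2``).

    The result carries both the upper-tail one-sided p (tests
    ``e1 > e2``) and the two-sided p ``2 * min(tail probabilities)``.
    """
    diff = e1.estimate - e2.estimate
    se = float(np.hypot(e1.se, e2.se))
    if se == 0.0:
        if diff == 0.0:
            return ContrastResult(0.0, 0.0, 0.0, 0.5, 1.0)
        raise DegenerateContrastError(
            "both estimates have zero standard error but differ"
        )
    z = diff / se
    upper = float(norm.sf(z))
    lower = float(norm.cdf(z))
    return ContrastResult(diff, se, z, upper, min(2.0 * min(upper, lower), 1.0))


def contrast_from_cis(
    estimate1: float,
    ci1: tuple[float, float],
    estimate2: float,
    ci2: tuple[float, float],
    level: float = 0.95,
    z: float | None = 1.96,
) -> ContrastResult:
    """Contrast two published estimates given only their printed intervals.

    Standard errors are recovered as full CI width / (2 z); the default
    ``z = 1.96`` matches hand-rounded published arithmetic. This is the
    reanalysis path for results where only estimates and CIs are printed.
    """
    e1 = PrevalenceEstimate("published", estimate1, se_from_ci(*ci1, level, z), *ci1, level)
    e2 = PrevalenceEstimate("published", estimate2, se_from_ci(*ci2, level, z), *ci2, level)
    return contrast_estimates(e1, e2)


def _complete(records, covariates) -> list[RespondentRecord]:
    """Listwise-complete subset for the given covariates."""
    kept = [
        r for r in records if all(getattr(r, c) is not None for c in covariates)
    ]
    dropped = len(records) - len(kept)
    if dropped:
        warnings.warn(
            f"excluded {dropped} record(s) with missing {'/'.join(covariates)}",
            stacklevel=3,
        )
    return kept


def _arm_estimates(
    records: Sequence[RespondentRecord], level: float
) -> tuple[PrevalenceEstimate | None, PrevalenceEstimate | None]:
    """(DQ, LRE) estimates from a record subset, None when an arm is empty."""
    dq5 = [r.dq_item_responses[-1] for r in records if r.arm == ARM_DQ5]
    lre5 = [r.lre_count for r in records if r.arm == ARM_LRE5]
    lre4 = [r.lre_count for r in records if r.arm == ARM_LRE4]
    dq = dq_prevalence(dq5, level) if dq5 else None
    lre = lre_prevalence(lre5, lre4, level) if (lre5 and lre4) else None
    return dq, lre


def method_comparison_table(
    records: Sequence[RespondentRecord],
    level: float = 0.95,
    subgroups: Sequence[tuple[str, str | None, str | None]] | None = None,
) -> pd.DataFrame:
    """Direct-vs-list comparison for the whole sample and each subgroup.

    One row per subgroup (label, covariate, level) — defaulting to "all"
    plus every covariate level — with subgroup N over all four arms, both
    estimates with standard errors, the one-sided p for list > direct and
    the two-sided p for list != direct.
    """
    if subgroups is None:
        subgroups = [("all", None, None)] + [
            (f"{cov}:{lvl}", cov, lvl)
            for cov, levels in COVARIATES.items()
            for lvl in levels
        ]
    rows = []
    for label, cov, lvl in subgroups:
        subset = (
            list(records)
            if cov is None
            else [r for r in _complete(records, [cov]) if getattr(r, cov) == lvl]
        )
        dq, lre = _arm_estimates(subset, level)
        row = {
            "subgroup": label,
            "n": len(subset),
            "dq_estimate": np.nan,
            "dq_se": np.nan,
            "lre_estimate": np.nan,
            "lre_se": np.nan,
            "p_lre_greater": np.nan,
            "p_two_sided": np.nan,
        }
        if dq is not None:
            row["dq_estimate"], row["dq_se"] = dq.estimate, dq.se
        if lre is not None:
            row["lre_estimate"], row["lre_se"] = lre.estimate, lre.se
        if dq is not None and lre is not None:
            res = contrast_estimates(lre, dq)
            row["p_lre_greater"] = res.p_one_sided
            row["p_two_sided"] = res.p_two_sided
        else:
            warnings.warn(f"subgroup {label!r}: an arm is empty, p-values omitted")
        rows.append(row)
    return pd.DataFrame(rows)


def interaction_table(
    records: Sequence[RespondentRecord],
    factor_a: str,
    factor_b: str,
    level: float = 0.95,
    method: str = "LRE",
    min_arm_n: int = 2,
) -> pd.DataFrame:
    """List-estimate comparison of ``factor_b`` levels within ``factor_a``.

    For each level of ``factor_a``: list-arm cell sizes and list estimates
    for the two levels of ``factor_b``, plus the two-sided contrast
    p-value. Cells with fewer than ``min_arm_n`` respondents in either
    list arm are reported as missing.
    """
    if method != "LRE":
        raise NotImplementedError("only the list estimator is supported")
    for f in (factor_a, factor_b):
        if f not in COVARIATES:
            raise KeyError(f"unknown covariate {f!r}")
    complete = _complete(records, [factor_a, factor_b])
    b1, b2 = COVARIATES[factor_b]
    rows = []
    for la in COVARIATES[factor_a]:
        row: dict[str, object] = {"factor_a": factor_a, "level_a": la, "factor_b": factor_b}
        ests = {}
        for tag, lb in (("1", b1), ("2", b2)):
            cell = [
                r
                for r in complete
                if getattr(r, factor_a) == la and getattr(r, factor_b) == lb
            ]
            lre5 = [r.lre_count for r in cell if r.arm == ARM_LRE5]
            lre4 = [r.lre_count for r in cell if r.arm == ARM_LRE4]
            row[f"level_b{tag}"] = lb
            row[f"n{tag}"] = len(lre5) + len(lre4)
            if min(len(lre5), len(lre4)) >= min_arm_n:
                est = lre_prevalence(lre5, lre4, level)
                ests[tag] = est
                row[f"estimate{tag}"], row[f"se{tag}"] = est.estimate, est.se
            else:
                row[f"estimate{tag}"] = row[f"se{tag}"] = np.nan
                warnings.warn(
                    f"cell {factor_a}={la}, {factor_b}={lb}: too few list-arm "
                    "respondents, estimate omitted"
                )
        if len(ests) == 2:
            try:
                row["p_two_sided"] = contrast_estimates(ests["1"], ests["2"]).p_two_sided
            except DegenerateContrastError:
                row["p_two_sided"] = np.nan
                warnings.warn(
                    f"cell pair {factor_a}={la}: degenerate contrast (both se = 0)"
                )
        else:
            row["p_two_sided"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def normative_flag(estimate: PrevalenceEstimate | float) -> bool:
    """True iff strictly more than half of the subgroup holds the view."""
    value = estimate.estimate if isinstance(estimate, PrevalenceEstimate) else estimate
    return bool(value > 0.5)


def tabulate_reasons(records: Sequence[RespondentRecord]) -> pd.DataFrame:
    """Frequency table of stated justifications among direct endorsers.

    Counts each stated reason label of five-card direct-arm respondents
    who endorsed the sensitive item; percentages are over all stated
    labels (respondents may give up to three), so they sum to 100.
    """
    labels: list[str] = []
    for r in records:
        if (
            r.arm == ARM_DQ5
            and r.dq_item_responses is not None
            and r.dq_item_responses[-1] == 1
            and r.stated_reasons
        ):
            labels.extend(r.stated_reasons)
    if not labels:
        return pd.DataFrame(columns=["category", "count", "percent"])
    counts = pd.Series(labels).value_counts()
    return pd.DataFrame(
        {
            "category": counts.index,
            "count": counts.values,
            "percent": 100.0 * counts.values / counts.sum(),
        }
    ).reset_index(drop=True)


def format_p(p: float) -> str:
    """Report-style p formatting: 3 decimals below 0.01, else 2."""
    if np.isnan(p):
        return ""
    return f"{p:.3f}" if p < 0.01 else f"{p:.2f}"
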
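"""Domain types and I/O for a four-arm list-experiment survey.

The design crosses two questioning modes with two list lengths:

* ``DQ4`` / ``DQ5`` — direct questioning, each card answered yes/no,
  with (``DQ5``) or without (``DQ4``) the sensitive card;
* ``LRE4`` / ``LRE5`` — list questioning, the respondent reports only
  *how many* cards they endorse, again with or without the sensitive card.

The sensitive card, when present, is always the last item, so direct-arm
response vectors store the four control answers first and the sensitive
answer in position 5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ARMS",
    "DQ_ARMS",
    "LIST_ARMS",
    "COVARIATES",
    "CSV_COLUMNS",
    "ListDesign",
    "RespondentRecord",
    "PrevalenceEstimate",
    "ContrastResult",
    "ReadResult",
    "ValidationReport",
    "SchemaError",
    "DEFAULT_DESIGN",
    "read_respondents",
    "write_respondents",
    "validate_design",
    "record_violations",
]

ARM_DQ4 = "DQ4"
ARM_DQ5 = "DQ5"
ARM_LRE4 = "LRE4"
ARM_LRE5 = "LRE5"

ARMS: tuple[str, ...] = (ARM_DQ4, ARM_DQ5, ARM_LRE4, ARM_LRE5)
DQ_ARMS: tuple[str, ...] = (ARM_DQ4, ARM_DQ5)
LIST_ARMS: tuple[str, ...] = (ARM_LRE4, ARM_LRE5)

#: Covariates collected for every respondent, with their admissible levels
#: (ordering matters: it is the row order used in subgroup tables).
COVARIATES: Mapping[str, tuple[str, str]] = {
    "gender": ("male", "female"),
    "age_group": ("young", "older"),
    "education": ("low", "high"),
    "wealth": ("high", "low"),
    "decision_making": ("male_only", "joint"),
}

CSV_COLUMNS: tuple[str, ...] = (
    "id",
    "arm",
    "gender",
    "age_group",
    "education",
    "wealth",
    "decision_making",
    "item_1",
    "item_2",
    "item_3",
    "item_4",
    "item_5",
    "lre_count",
    "reasons",
)


class SchemaError(ValueError):
    """A respondent CSV is structurally unusable (e.g. a column is missing)."""


@dataclass(frozen=True)
class ListDesign:
    """The item list: four control cards plus an optional sensitive card."""

    control_items: tuple[str, str, str, str]
    sensitive_item: str | None = None

    def __post_init__(self) -> None:
        items = tuple(self.control_items)
        if len(items) != 4:
            raise ValueError(f"exactly 4 control items required, got {len(items)}")
        if len(set(items)) != 4:
            raise ValueError("control item labels must be distinct")
        labels = items + ((self.sensitive_item,) if self.sensitive_item else ())
        for lab in labels:
            if not isinstance(lab, str) or not lab:
                raise ValueError(f"item labels must be non-empty strings, got {lab!r}")
        object.__setattr__(self, "control_items", items)

    @property
    def arm_labels(self) -> tuple[str, ...]:
        """The arms this design supports; 5-card arms need a sensitive item."""
        if self.sensitive_item is None:
            return (ARM_DQ4, ARM_LRE4)
        return ARMS

    def n_items(self, arm: str) -> int:
        if arm not in self.arm_labels:
            raise ValueError(f"unknown arm {arm!r} for this design")
        return 5 if arm.endswith("5") else 4


#: The card list used in the 2017 Arsi Oromo survey: one unpopular item
#: (early marriage), one popular item (schooling), an incompatible pair
#: (work in the city / live close to home), and the sensitive card.
DEFAULT_DESIGN = ListDesign(
    ("early_marriage", "schooling", "work_in_city", "live_close_to_home"),
    sensitive_item="beaten_by_husband",
)


@dataclass(frozen=True)
class RespondentRecord:
    """One surveyed individual.

    Exactly one of ``dq_item_responses`` / ``lre_count`` is populated,
    matching the arm family. Covariates may be ``None`` (missing); such
    records are excluded listwise from subgroup analyses that use them.
    """

    id: str
    arm: str
    gender: str | None = None
    age_group: str | None = None
    education: str | None = None
    wealth: str | None = None
    decision_making: str | None = None
    dq_item_responses: tuple[int, ...] | None = None
    lre_count: int | None = None
    stated_reasons: tuple[str, ...] | None = None

    def covariate(self, name: str) -> str | None:
        if name not in COVARIATES:
            raise KeyError(f"unknown covariate {name!r}")
        return getattr(self, name)

    @property
    def profile(self) -> dict[str, str | None]:
        return {c: getattr(self, c) for c in COVARIATES}

    def control_count(self, design: ListDesign) -> int:
        """Number of endorsed control (non-sensitive) items.

        For list arms the sensitive endorsement is not separable, so the
        reported count is returned as-is for ``LRE4`` and is undefined for
        ``LRE5`` (raises)."""
        if self.arm in DQ_ARMS:
            assert self.dq_item_responses is not None
            return int(sum(self.dq_item_responses[:4]))
        if self.arm == ARM_LRE4:
            assert self.lre_count is not None
            return int(self.lre_count)
        raise ValueError("control count is not observable in the LRE5 arm")


def record_violations(rec: RespondentRecord, design: ListDesign) -> list[str]:
    """Invariant checks for one record; empty list means valid."""
    out: list[str] = []
    if rec.arm not in design.arm_labels:
        out.append(f"unknown arm {rec.arm!r}")
        return out
    has_dq = rec.dq_item_responses is not None
    has_count = rec.lre_count is not None
    if has_dq == has_count:
        out.append("exactly one of dq_item_responses / lre_count must be populated")
        return out
    k = design.n_items(rec.arm)
    if rec.arm in DQ_ARMS:
        if not has_dq:
            out.append("dq_item_responses required in a DQ arm")
        else:
            if len(rec.dq_item_responses) != k:
                out.append(
                    f"dq_item_responses length {len(rec.dq_item_responses)} != {k}"
                )
            elif any(v not in (0, 1) for v in rec.dq_item_responses):
                out.append("dq_item_responses entries must be 0/1")
    else:
        if not has_count:
            out.append("lre_count required in a list arm")
        elif not 0 <= rec.lre_count <= k:
            out.append(f"lre_count out of range [0, {k}]")
    if rec.stated_reasons is not None:
        endorsed = (
            rec.arm == ARM_DQ5
            and rec.dq_item_responses is not None
            and len(rec.dq_item_responses) == 5
            and rec.dq_item_responses[-1] == 1
        )
        if not endorsed:
            out.append("stated_reasons only allowed for DQ5 sensitive-item endorsers")
    for cov, levels in COVARIATES.items():
        val = getattr(rec, cov)
        if val is not None and val not in levels:
            out.append(f"{cov} level {val!r} not in {levels}")
    return out


@dataclass(frozen=True)
class ReadResult:
    """Validated records plus row-level rejections (1-based data row numbers)."""

    records: list[RespondentRecord]
    rejections: list[tuple[int, str]]

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _parse_int(token: str, what: str) -> int:
    try:
        return int(token)
    except ValueError as exc:
        raise ValueError(f"{what} is not an integer: {token!r}") from exc


def read_respondents(
    source: str | Path | IO[str], design: ListDesign = DEFAULT_DESIGN
) -> ReadResult:
    """Read respondent records from CSV, rejecting malformed rows.

    Raises :class:`SchemaError` if a mandatory column is absent; individual
    malformed rows are reported (with their data-row number) rather than
    aborting the read.
    """
    frame = pd.read_csv(source, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    records: list[RespondentRecord] = []
    rejections: list[tuple[int, str]] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            rec = _row_to_record(row, design)
        except ValueError as exc:
            rejections.append((i, str(exc)))
            continue
        probs = record_violations(rec, design)
        if probs:
            rejections.append((i, "; ".join(probs)))
        else:
            records.append(rec)
    return ReadResult(records, rejections)


def _row_to_record(row, design: ListDesign) -> RespondentRecord:
    get = lambda col: getattr(row, col).strip()  # noqa: E731
    arm = get("arm")
    if arm not in design.arm_labels:
        raise ValueError(f"unknown arm {arm!r}")
    k = design.n_items(arm)
    dq: tuple[int, ...] | None = None
    count: int | None = None
    if arm in DQ_ARMS:
        vals = []
        for j in range(1, k + 1):
            tok = get(f"item_{j}")
            if tok == "":
                raise ValueError(f"item_{j} missing in arm {arm}")
            vals.append(_parse_int(tok, f"item_{j}"))
        dq = tuple(vals)
    else:
        tok = get("lre_count")
        if tok == "":
            raise ValueError(f"lre_count missing in arm {arm}")
        count = _parse_int(tok, "lre_count")
    reasons_tok = get("reasons")
    reasons = tuple(t for t in reasons_tok.split(";") if t) if reasons_tok else None
    return RespondentRecord(
        id=get("id"),
        arm=arm,
        **{c: (get(c) or None) for c in COVARIATES},
        dq_item_responses=dq,
        lre_count=count,
        stated_reasons=reasons,
    )


def write_respondents(
    records: Iterable[RespondentRecord], sink: str | Path | IO[str]
) -> None:
    """Write records as CSV with the canonical column order (re-readable)."""
    rows = []
    for rec in records:
        row = {c: "" for c in CSV_COLUMNS}
        row["id"] = rec.id
        row["arm"] = rec.arm
        for cov in COVARIATES:
            row[cov] = getattr(rec, cov) or ""
        if rec.dq_item_responses is not None:
            for j, v in enumerate(rec.dq_item_responses, start=1):
                row[f"item_{j}"] = str(int(v))
        if rec.lre_count is not None:
            row["lre_count"] = str(int(rec.lre_count))
        if rec.stated_reasons:
            row["reasons"] = ";".join(rec.stated_reasons)
        rows.append(row)
    frame = pd.DataFrame(rows, columns=list(CSV_COLUMNS), dtype=str)
    frame.to_csv(sink, index=False)


@dataclass
class ValidationReport:
    """Structural summary of a respondent collection against a design."""

    n_records: int
    arm_counts: dict[str, int]
    covariate_completeness: dict[str, float]
    violations: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.violations

    def to_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "arm_counts": dict(self.arm_counts),
            "covariate_completeness": dict(self.covariate_completeness),
            "violations": list(self.violations),
            "passed": self.passed,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def to_text(self) -> str:
        lines = [f"records: {self.n_records}"]
        lines.append(
            "arm counts: "
            + ", ".join(f"{a}={n}" for a, n in sorted(self.arm_counts.items()))
        )
        for cov, frac in self.covariate_completeness.items():
            lines.append(f"completeness {cov}: {frac:.1%}")
        if self.violations:
            lines.append(f"violations ({len(self.violations)}):")
            lines.extend(f"  - {v}" for v in self.violations)
        else:
            lines.append("violations: none")
        lines.append("status: " + ("PASS" if self.passed else "FAIL"))
        return "\n".join(lines)


def validate_design(
    records: Sequence[RespondentRecord],
    design: ListDesign = DEFAULT_DESIGN,
    require_all_arms: bool = True,
) -> ValidationReport:
    """Per-arm counts, covariate completeness and invariant violations.

    The report passes iff there are zero violations. With
    ``require_all_arms`` (the default for this four-arm design), an arm
    with no respondents is itself a violation — estimation would be
    impossible downstream.
    """
    arm_counts = {arm: 0 for arm in design.arm_labels}
    violations: list[str] = []
    for rec in records:
        if rec.arm in arm_counts:
            arm_counts[rec.arm] += 1
        for v in record_violations(rec, design):
            violations.append(f"record {rec.id}: {v}")
    completeness = {}
    n = len(records)
    for cov in COVARIATES:
        have = sum(1 for r in records if getattr(r, cov) is not None)
        completeness[cov] = have / n if n else 0.0
    if require_all_arms:
        for arm, cnt in arm_counts.items():
            if cnt == 0:
                violations.append(f"arm {arm}: no respondents")
    return ValidationReport(n, arm_counts, completeness, violations)


@dataclass(frozen=True)
class PrevalenceEstimate:
    """A method-tagged prevalence with normal-theory uncertainty.

    List-difference estimates may legitimately fall slightly below zero by
    sampling noise; nothing is truncated here. Use :meth:`truncated` when
    formatting for a report that wants CI endpoints clipped to [0, 1].
    """

    method: str  # "DQ" or "LRE"
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    n: int = 0

    def truncated(self) -> "PrevalenceEstimate":
        return replace(
            self,
            ci_low=min(max(self.ci_low, 0.0), 1.0),
            ci_high=min(max(self.ci_high, 0.0), 1.0),
        )


@dataclass(frozen=True)
class ContrastResult:
    """Unpaired z-contrast between two prevalence estimates."""

    diff: float
    se_diff: float
    z: float
    p_one_sided: float  # upper tail: P(Z >= z)
    p_two_sided: float
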
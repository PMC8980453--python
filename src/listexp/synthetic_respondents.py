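"""Synthetic respondent generator for the four-arm list experiment.

The generator encodes the statistical structure the analysis assumes:

* every respondent carries a latent support indicator ``Z ~ Bernoulli(pi)``
  for the sensitive attitude, where ``pi`` may depend on their covariate
  profile;
* list-arm responses are fully truthful — the five-card count is the
  control count plus ``Z`` ("no liars"), and the sensitive card never
  alters control-item behaviour (design independence holds by
  construction);
* under direct questioning, social desirability acts only on the
  sensitive card: a supporter admits support with probability ``r`` and a
  non-supporter falsely endorses with probability ``f``.

Control items follow a model engineered against floor/ceiling effects:
one rarely endorsed item, one almost universally endorsed item, and a
mutually incompatible pair drawn from a three-way categorical (first /
second / neither), so that a count of 4 is impossible and a count of 0
requires three independently unlikely events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .survey_model import (
    ARM_DQ4,
    ARM_DQ5,
    ARM_LRE4,
    ARM_LRE5,
    COVARIATES,
    DEFAULT_DESIGN,
    ListDesign,
    RespondentRecord,
)

__all__ = [
    "ControlItemModel",
    "AdditiveRateModel",
    "JointCellSpec",
    "GeneratorConfig",
    "ConfigurationError",
    "largest_remainder",
    "assign_arms",
    "arm_allocation",
    "simulate_control_items",
    "simulate_response",
    "simulate_list_counts",
    "concealment_params",
    "calibrate_from_table",
    "generate_population",
    "DEFAULT_COVARIATE_COUNTS",
    "DEFAULT_REASON_WEIGHTS",
]


class ConfigurationError(ValueError):
    """The generator configuration is internally inconsistent."""


# Marginal subgroup sizes of the 2017 Arsi survey (n = 809).
DEFAULT_COVARIATE_COUNTS: dict[str, dict[str, int]] = {
    "gender": {"male": 403, "female": 406},
    "age_group": {"young": 245, "older": 564},
    "education": {"low": 440, "high": 369},
    "wealth": {"high": 289, "low": 520},
    "decision_making": {"male_only": 354, "joint": 455},
}

# Stated justification categories among direct-question endorsers.
DEFAULT_REASON_WEIGHTS: dict[str, float] = {
    "resource_inequality": 0.44,
    "gender_norm_transgression": 0.375,
    "perpetrator_characteristics": 0.105,
    "other": 0.08,
}


@dataclass(frozen=True)
class ControlItemModel:
    """Endorsement model for the four control items.

    Items 1 and 2 are independent Bernoulli draws (rare and popular);
    items 3 and 4 are incompatible and drawn from a categorical over
    {endorse item 3, endorse item 4, endorse neither}.

    The defaults are a repository calibration chosen so that the expected
    control count sits near the 2.2–2.4 band observed in the field data
    while keeping the combined floor/ceiling probability far below 1%.
    """

    p_rare: float = 0.40
    p_popular: float = 0.95
    w_first: float = 0.60
    w_second: float = 0.37
    w_neither: float = 0.03

    def __post_init__(self) -> None:
        for name in ("p_rare", "p_popular", "w_first", "w_second", "w_neither"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        s = self.w_first + self.w_second + self.w_neither
        if abs(s - 1.0) > 1e-9:
            raise ConfigurationError(f"pair weights sum to {s}, expected 1")

    @property
    def mean_count(self) -> float:
        """Closed-form expected control count."""
        return self.p_rare + self.p_popular + self.w_first + self.w_second

    @property
    def floor_probability(self) -> float:
        return (1 - self.p_rare) * (1 - self.p_popular) * self.w_neither

    @property
    def ceiling_probability(self) -> float:
        # all four items requires both incompatible items — impossible.
        return 0.0

    def sample(self, rng: np.random.Generator, size: int | None = None):
        """Draw endorsement vectors; shape (4,) or (size, 4) uint8."""
        n = 1 if size is None else int(size)
        out = np.empty((n, 4), dtype=np.uint8)
        out[:, 0] = rng.random(n) < self.p_rare
        out[:, 1] = rng.random(n) < self.p_popular
        cat = rng.choice(3, size=n, p=(self.w_first, self.w_second, self.w_neither))
        out[:, 2] = cat == 0
        out[:, 3] = cat == 1
        return out[0] if size is None else out


def simulate_control_items(
    model: ControlItemModel, rng: np.random.Generator, size: int | None = None
):
    """Draw four binary control-item endorsements (vectorised with ``size``)."""
    return model.sample(rng, size)


@dataclass(frozen=True)
class AdditiveRateModel:
    """Probability that varies over covariate profiles additively.

    ``rate(profile) = clip(baseline + sum of effects[(covariate, level)])``.

    Marginal subgroup tables only identify one effect per covariate level;
    centring each covariate's effects on its population mean makes the
    model reproduce every printed marginal in expectation (up to the
    internal inconsistency of the published rounding and to clipping).
    """

    baseline: float
    effects: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.baseline <= 1.0:
            raise ConfigurationError(f"baseline {self.baseline} outside [0, 1]")

    def rate(self, profile: Mapping[str, str | None]) -> float:
        total = self.baseline
        for (cov, level), delta in self.effects.items():
            if cov not in profile:
                raise ConfigurationError(
                    f"profile missing covariate {cov!r} required by rate model"
                )
            if profile[cov] == level:
                total += delta
        return float(min(max(total, 0.0), 1.0))


def concealment_params(dq: float, lre: float) -> tuple[float, float, float]:
    """Latent-support and reporting parameters implied by a (DQ, LRE) pair.

    Returns ``(pi, r, f)``: latent support probability, supporters'
    admission rate under direct questioning, and non-supporters' false
    endorsement rate. Understatement (DQ < LRE) is modelled as concealment
    (``r < 1``); overstatement (DQ > LRE) as false endorsement (``f > 0``).
    Either way the expected direct-question "yes" rate equals ``dq``.
    """
    if dq < 0 or lre < 0 or dq > 1 or lre > 1:
        raise ConfigurationError(f"proportions outside [0, 1]: dq={dq}, lre={lre}")
    pi = lre
    if dq <= pi:
        r = dq / pi if pi > 0 else 1.0
        f = 0.0
    else:
        r = 1.0
        f = (dq - pi) / (1.0 - pi) if pi < 1 else 0.0
    return pi, r, f


@dataclass(frozen=True)
class JointCellSpec:
    """Fixed two-way cell counts for one covariate pair within the list arms.

    Published interaction tables report cell sizes among list-arm
    respondents only, so the cells here are list-family counts; the
    direct-question arms receive the complementary margins with a
    rounded-product joint fill.
    """

    factor_a: str
    factor_b: str
    cells: Mapping[tuple[str, str], int]

    def __post_init__(self) -> None:
        for f in (self.factor_a, self.factor_b):
            if f not in COVARIATES:
                raise ConfigurationError(f"unknown covariate {f!r}")
        expect = {
            (a, b) for a in COVARIATES[self.factor_a] for b in COVARIATES[self.factor_b]
        }
        if set(self.cells) != expect:
            raise ConfigurationError("joint cells must cover all 2x2 level pairs")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterisation of the synthetic survey population."""

    n_total: int = 809
    dq_fraction: float = 0.20
    covariate_counts: Mapping[str, Mapping[str, int]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_COVARIATE_COUNTS.items()
        }
    )
    pi: AdditiveRateModel = AdditiveRateModel(0.28)
    dq_prob: AdditiveRateModel = AdditiveRateModel(0.18)
    control_model: ControlItemModel = ControlItemModel()
    reason_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REASON_WEIGHTS)
    )
    joint_cells: JointCellSpec | None = None
    design: ListDesign = DEFAULT_DESIGN
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_total < 0:
            raise ConfigurationError("n_total must be nonnegative")
        if not 0.0 <= self.dq_fraction <= 1.0:
            raise ConfigurationError("dq_fraction must lie in [0, 1]")
        for cov, counts in self.covariate_counts.items():
            if cov not in COVARIATES:
                raise ConfigurationError(f"unknown covariate {cov!r}")
            if set(counts) != set(COVARIATES[cov]):
                raise ConfigurationError(f"levels for {cov!r} must be {COVARIATES[cov]}")
            if sum(counts.values()) != self.n_total:
                raise ConfigurationError(
                    f"{cov} counts sum to {sum(counts.values())}, expected {self.n_total}"
                )
        wsum = sum(self.reason_weights.values())
        if self.reason_weights and abs(wsum - 1.0) > 1e-9:
            raise ConfigurationError(f"reason weights sum to {wsum}, expected 1")

    def uniform(self, pi: float, dq: float | None = None) -> "GeneratorConfig":
        """Copy of this config with profile-independent support/report rates."""
        from dataclasses import replace

        return replace(
            self,
            pi=AdditiveRateModel(pi),
            dq_prob=AdditiveRateModel(pi if dq is None else dq),
        )


def largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    """Apportion ``n`` seats to ``fractions`` by the largest-remainder rule.

    Ties in the fractional remainders are broken by position (first label
    wins), so ``largest_remainder(647, (0.5, 0.5)) == [324, 323]``.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    fr = [float(f) for f in fractions]
    if any(f < 0 or f > 1 for f in fr):
        raise ValueError("fractions must lie in [0, 1]")
    if abs(sum(fr) - 1.0) > 1e-9:
        raise ValueError(f"fractions sum to {sum(fr)}, expected 1")
    quotas = [n * f for f in fr]
    base = [math.floor(q) for q in quotas]
    leftover = n - sum(base)
    order = sorted(range(len(fr)), key=lambda i: (-(quotas[i] - base[i]), i))
    for i in order[:leftover]:
        base[i] += 1
    return base


def assign_arms(
    n: int,
    fractions: Sequence[float],
    rng: np.random.Generator | int | None,
    labels: Sequence[str] | None = None,
) -> np.ndarray:
    """Randomly assign ``n`` individuals to arms with exact quota counts.

    Counts follow largest-remainder rounding of ``n * fraction``; the
    mapping of individuals to arms is a seeded random permutation.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    counts = largest_remainder(n, fractions)
    if labels is None:
        labels = [f"arm{i}" for i in range(len(counts))]
    if len(labels) != len(counts):
        raise ValueError("labels and fractions must have equal length")
    pool = np.repeat(np.asarray(labels, dtype=object), counts)
    return rng.permutation(pool)


def arm_allocation(n_total: int, dq_fraction: float) -> dict[str, int]:
    """Four-arm counts: family split first, then 50/50 within each family."""
    n_dq, n_lre = largest_remainder(n_total, (dq_fraction, 1.0 - dq_fraction))
    dq4, dq5 = largest_remainder(n_dq, (0.5, 0.5))
    lre4, lre5 = largest_remainder(n_lre, (0.5, 0.5))
    return {ARM_DQ4: dq4, ARM_DQ5: dq5, ARM_LRE4: lre4, ARM_LRE5: lre5}


@dataclass(frozen=True)
class _Response:
    dq_item_responses: tuple[int, ...] | None
    lre_count: int | None
    endorsed_sensitive: bool | None  # observable only under DQ5


def simulate_response(
    profile: Mapping[str, str | None],
    arm: str,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> _Response:
    """Draw one respondent's observed response for their assigned arm."""
    pi_i = config.pi.rate(profile)
    dq_i = config.dq_prob.rate(profile)
    pi, r, f = concealment_params(dq_i, pi_i)
    controls = config.control_model.sample(rng)
    z = bool(rng.random() < pi)
    if arm == ARM_LRE4:
        return _Response(None, int(controls.sum()), None)
    if arm == ARM_LRE5:
        return _Response(None, int(controls.sum()) + int(z), None)
    if arm == ARM_DQ4:
        return _Response(tuple(int(v) for v in controls), None, None)
    if arm == ARM_DQ5:
        admit = rng.random() < (r if z else f)
        vec = tuple(int(v) for v in controls) + (int(admit),)
        return _Response(vec, None, bool(admit))
    raise ValueError(f"unknown arm {arm!r}")


def simulate_list_counts(
    pi: float,
    n_treatment: int,
    n_control: int,
    model: ControlItemModel,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised draw of five-card and four-card list counts.

    A fast path for Monte-Carlo work at a profile-independent support
    probability; the five-card count is control count + Bernoulli(pi).
    """
    treat = model.sample(rng, n_treatment).sum(axis=1) + (
        rng.random(n_treatment) < pi
    )
    ctrl = model.sample(rng, n_control).sum(axis=1)
    return treat.astype(np.int64), ctrl.astype(np.int64)


def calibrate_from_table(
    rows: Iterable[Mapping[str, object]],
    covariate_counts: Mapping[str, Mapping[str, int]] | None = None,
    **config_kwargs,
) -> GeneratorConfig:
    """Build a generator config whose arms reproduce a published subgroup table.

    ``rows`` are mappings with keys ``covariate``, ``level``, ``dq``,
    ``lre``; the overall row uses ``covariate='all'``. Latent support is
    set to the list estimate and the direct-question reporting process to
    the direct estimate, per subgroup: understatement becomes concealment
    (admission rate ``r = min(1, dq/lre)``), overstatement becomes false
    endorsement (``f = (dq - lre)/(1 - lre)``).

    With more than one stratifying covariate the subgroup values are
    combined additively around each covariate's population-weighted mean,
    so each printed marginal is matched in expectation.
    """
    counts = covariate_counts or DEFAULT_COVARIATE_COUNTS
    base_lre = base_dq = None
    by_cov: dict[str, dict[str, tuple[float, float]]] = {}
    for row in rows:
        cov = str(row["covariate"])
        dq, lre = float(row["dq"]), float(row["lre"])
        if min(dq, lre) < 0 or max(dq, lre) > 1:
            raise ConfigurationError(f"table proportions outside [0, 1]: {row}")
        if cov == "all":
            base_dq, base_lre = dq, lre
        else:
            if cov not in COVARIATES:
                raise ConfigurationError(f"unknown covariate {cov!r} in table")
            by_cov.setdefault(cov, {})[str(row["level"])] = (dq, lre)

    if base_lre is None:
        raise ConfigurationError("table must include an 'all' row")

    pi_eff: dict[tuple[str, str], float] = {}
    dq_eff: dict[tuple[str, str], float] = {}
    for cov, levels in by_cov.items():
        if set(levels) != set(COVARIATES[cov]):
            raise ConfigurationError(f"table rows for {cov!r} must cover both levels")
        total = sum(counts[cov].values())
        w = {
            lvl: (counts[cov][lvl] / total if total else 1.0 / len(levels))
            for lvl in levels
        }
        mean_dq = sum(w[lvl] * levels[lvl][0] for lvl in levels)
        mean_lre = sum(w[lvl] * levels[lvl][1] for lvl in levels)
        for lvl, (dq, lre) in levels.items():
            dq_eff[(cov, lvl)] = dq - mean_dq
            pi_eff[(cov, lvl)] = lre - mean_lre

    return GeneratorConfig(
        covariate_counts=counts,
        pi=AdditiveRateModel(base_lre, pi_eff),
        dq_prob=AdditiveRateModel(base_dq, dq_eff),
        **config_kwargs,
    )


def _exact_marginal_levels(
    counts: Mapping[str, int], rng: np.random.Generator
) -> np.ndarray:
    pool = np.repeat(np.asarray(list(counts.keys()), dtype=object), list(counts.values()))
    return rng.permutation(pool)


def _dq_joint_fill(
    row_margins: dict[str, int], col_margins: dict[str, int], n: int, spec: JointCellSpec
) -> dict[tuple[str, str], int]:
    """2x2 joint fill for the direct-question family given both margins."""
    (a1, a2) = tuple(row_margins)
    (b1, b2) = tuple(col_margins)
    c11 = round(row_margins[a1] * col_margins[b1] / n) if n else 0
    cells = {
        (a1, b1): c11,
        (a1, b2): row_margins[a1] - c11,
        (a2, b1): col_margins[b1] - c11,
        (a2, b2): n - row_margins[a1] - col_margins[b1] + c11,
    }
    if any(v < 0 for v in cells.values()):
        raise ConfigurationError(
            "joint cells infeasible: direct-question complement has a negative cell"
        )
    return cells


def generate_population(
    config: GeneratorConfig, seed: int | None = None
) -> list[RespondentRecord]:
    """Generate the full synthetic survey (one record per respondent).

    Covariate marginals are matched exactly (stratified assignment with a
    seeded shuffle for the joint structure); arms follow the
    largest-remainder allocation; responses are drawn per respondent in id
    order from a single seeded stream, so identical seed + config yields
    identical records.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n = config.n_total
    alloc = arm_allocation(n, config.dq_fraction)

    covs: dict[str, np.ndarray] = {}
    if config.joint_cells is None:
        arms = rng.permutation(
            np.repeat(np.asarray(list(alloc.keys()), dtype=object), list(alloc.values()))
        )
        for cov in COVARIATES:
            covs[cov] = _exact_marginal_levels(dict(config.covariate_counts[cov]), rng)
    else:
        arms, covs = _joint_structured_assignment(config, alloc, rng)

    records: list[RespondentRecord] = []
    width = max(4, len(str(max(n, 1))))
    reason_labels = list(config.reason_weights)
    reason_p = np.asarray(list(config.reason_weights.values()), dtype=float)
    for i in range(n):
        profile = {cov: covs[cov][i] for cov in COVARIATES}
        resp = simulate_response(profile, arms[i], config, rng)
        reasons = None
        if resp.endorsed_sensitive and reason_labels:
            reasons = (str(rng.choice(reason_labels, p=reason_p)),)
        records.append(
            RespondentRecord(
                id=f"r{i + 1:0{width}d}",
                arm=str(arms[i]),
                **profile,
                dq_item_responses=resp.dq_item_responses,
                lre_count=resp.lre_count,
                stated_reasons=reasons,
            )
        )
    return records


def _joint_structured_assignment(
    config: GeneratorConfig, alloc: dict[str, int], rng: np.random.Generator
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Arm + covariate assignment with fixed list-family two-way cells."""
    spec = config.joint_cells
    assert spec is not None
    n = config.n_total
    n_lre = alloc[ARM_LRE4] + alloc[ARM_LRE5]
    n_dq = alloc[ARM_DQ4] + alloc[ARM_DQ5]
    if sum(spec.cells.values()) != n_lre:
        raise ConfigurationError(
            f"joint cells sum to {sum(spec.cells.values())}, expected list family {n_lre}"
        )

    lre_a = {
        lvl: sum(v for (a, _), v in spec.cells.items() if a == lvl)
        for lvl in COVARIATES[spec.factor_a]
    }
    lre_b = {
        lvl: sum(v for (_, b), v in spec.cells.items() if b == lvl)
        for lvl in COVARIATES[spec.factor_b]
    }
    dq_a = {
        lvl: config.covariate_counts[spec.factor_a][lvl] - lre_a[lvl]
        for lvl in lre_a
    }
    dq_b = {
        lvl: config.covariate_counts[spec.factor_b][lvl] - lre_b[lvl]
        for lvl in lre_b
    }
    if any(v < 0 for v in (*dq_a.values(), *dq_b.values())):
        raise ConfigurationError(
            "joint cells exceed the population marginal for some level"
        )
    dq_cells = _dq_joint_fill(dq_a, dq_b, n_dq, spec)

    fam = []
    a_lv = []
    b_lv = []
    for (a, b), cnt in spec.cells.items():
        fam += ["LRE"] * cnt
        a_lv += [a] * cnt
        b_lv += [b] * cnt
    for (a, b), cnt in dq_cells.items():
        fam += ["DQ"] * cnt
        a_lv += [a] * cnt
        b_lv += [b] * cnt
    fam_arr = np.asarray(fam, dtype=object)
    a_arr = np.asarray(a_lv, dtype=object)
    b_arr = np.asarray(b_lv, dtype=object)

    arms = np.empty(n, dtype=object)
    dq_pool = rng.permutation(
        np.repeat(np.asarray([ARM_DQ4, ARM_DQ5], dtype=object), [alloc[ARM_DQ4], alloc[ARM_DQ5]])
    )
    lre_pool = rng.permutation(
        np.repeat(
            np.asarray([ARM_LRE4, ARM_LRE5], dtype=object), [alloc[ARM_LRE4], alloc[ARM_LRE5]]
        )
    )
    arms[fam_arr == "DQ"] = dq_pool
    arms[fam_arr == "LRE"] = lre_pool

    covs: dict[str, np.ndarray] = {spec.factor_a: a_arr, spec.factor_b: b_arr}
    for cov in COVARIATES:
        if cov not in covs:
            covs[cov] = _exact_marginal_levels(dict(config.covariate_counts[cov]), rng)

    perm = rng.permutation(n)
    arms = arms[perm]
    covs = {cov: vals[perm] for cov, vals in covs.items()}
    return arms, covs
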
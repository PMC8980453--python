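"""Generator: allocation, control-item model, concealment and calibration."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from listexp.survey_model import COVARIATES
from listexp.synthetic_respondents import (
    AdditiveRateModel,
    ConfigurationError,
    ControlItemModel,
    GeneratorConfig,
    JointCellSpec,
    arm_allocation,
    assign_arms,
    calibrate_from_table,
    concealment_params,
    generate_population,
    largest_remainder,
    simulate_control_items,
    simulate_list_counts,
    simulate_response,
)

TABLE_NS = {
    ("gender", "male"): 403,
    ("gender", "female"): 406,
    ("age_group", "young"): 245,
    ("age_group", "older"): 564,
    ("education", "low"): 440,
    ("education", "high"): 369,
    ("wealth", "high"): 289,
    ("wealth", "low"): 520,
    ("decision_making", "male_only"): 354,
    ("decision_making", "joint"): 455,
}


class TestAllocation:
    def test_study_allocation(self):
        assert largest_remainder(809, (0.2, 0.8)) == [162, 647]
        assert largest_remainder(162, (0.5, 0.5)) == [81, 81]
        assert largest_remainder(647, (0.5, 0.5)) == [324, 323]
        assert arm_allocation(809, 0.2) == {
            "DQ4": 81,
            "DQ5": 81,
            "LRE4": 324,
            "LRE5": 323,
        }

    @given(
        n=st.integers(0, 2000),
        raw=st.lists(st.floats(0.01, 1.0), min_size=2, max_size=5),
    )
    def test_largest_remainder_sums_and_bounds(self, n, raw):
        fractions = [r / sum(raw) for r in raw]
        counts = largest_remainder(n, fractions)
        assert sum(counts) == n
        for c, f in zip(counts, fractions):
            assert np.floor(n * f) <= c <= np.ceil(n * f)

    def test_assign_arms_exact_counts_and_reproducibility(self):
        labels = ("DQ", "LRE")
        a1 = assign_arms(809, (0.2, 0.8), rng=7, labels=labels)
        a2 = assign_arms(809, (0.2, 0.8), rng=7, labels=labels)
        assert Counter(a1) == {"DQ": 162, "LRE": 647}
        assert list(a1) == list(a2)

    def test_bad_parameters_raise(self):
        with pytest.raises(ValueError):
            largest_remainder(-1, (0.5, 0.5))
        with pytest.raises(ValueError):
            largest_remainder(10, (0.7, 0.7))


class TestControlItems:
    def test_degenerate_model_always_count_two(self, rng):
        model = ControlItemModel(
            p_rare=0.0, p_popular=1.0, w_first=1.0, w_second=0.0, w_neither=0.0
        )
        draws = simulate_control_items(model, rng, size=200)
        assert np.array_equal(np.unique(draws, axis=0), [[0, 1, 1, 0]])

    def test_mean_matches_closed_form_and_floor_ceiling_rare(self, rng):
        model = ControlItemModel()
        draws = simulate_control_items(model, rng, size=100_000)
        counts = draws.sum(axis=1)
        sd = counts.std()
        assert counts.mean() == pytest.approx(
            model.mean_count, abs=4 * sd / np.sqrt(counts.size)
        )
        assert np.mean((counts == 0) | (counts == 4)) < 0.01
        # incompatible pair: items 3 and 4 never endorsed together
        assert not np.any((draws[:, 2] == 1) & (draws[:, 3] == 1))

    def test_invalid_weights_rejected(self):
        with pytest.raises(ConfigurationError):
            ControlItemModel(w_first=0.5, w_second=0.5, w_neither=0.5)


class TestConcealment:
    @pytest.mark.parametrize(
        "dq,lre,expected",
        [
            (0.16, 0.40, (0.40, 0.40, 0.0)),
            (0.20, 0.17, (0.17, 1.0, 0.03 / 0.83)),
            (0.0, 0.0, (0.0, 1.0, 0.0)),
        ],
    )
    def test_examples(self, dq, lre, expected):
        pi, r, f = concealment_params(dq, lre)
        assert (pi, r, f) == pytest.approx(expected)

    @given(dq=st.floats(0, 1), lre=st.floats(0, 1))
    def test_expected_dq_rate_is_preserved(self, dq, lre):
        pi, r, f = concealment_params(dq, lre)
        assert pi * r + (1 - pi) * f == pytest.approx(dq, abs=1e-12)
        assert 0 <= r <= 1 and 0 <= f <= 1


class TestSimulateResponse:
    PROFILE = {c: COVARIATES[c][0] for c in COVARIATES}

    def test_certain_supporter_always_endorses(self, default_config, rng):
        config = default_config.uniform(pi=1.0, dq=1.0)
        for _ in range(20):
            dq5 = simulate_response(self.PROFILE, "DQ5", config, rng)
            assert dq5.dq_item_responses[-1] == 1
            lre5 = simulate_response(self.PROFILE, "LRE5", config, rng)
            assert 1 <= lre5.lre_count <= 4  # control count (<= 3) plus one

    def test_pi_zero_makes_arms_identical(self, default_config, rng):
        config = default_config.uniform(pi=0.0, dq=0.0)
        treat, ctrl = simulate_list_counts(
            0.0, 20_000, 20_000, config.control_model, rng
        )
        assert treat.max() <= 3  # the sensitive item never adds a count
        assert treat.mean() == pytest.approx(ctrl.mean(), abs=0.02)

    def test_unknown_profile_names_missing_covariate(self, default_config, rng):
        with pytest.raises(ConfigurationError, match="missing covariate"):
            simulate_response({"gender": "male"}, "LRE4", default_config, rng)


class TestUnbiasednessAndMonotonicity:
    @pytest.mark.parametrize("pi", [0.0, 0.1, 0.28, 0.5, 1.0])
    def test_list_difference_recovers_pi(self, pi, rng):
        model = ControlItemModel()
        reps = 200
        ests = np.empty(reps)
        for i in range(reps):
            t, c = simulate_list_counts(pi, 324, 323, model, rng)
            ests[i] = t.mean() - c.mean()
        mc_se = ests.std(ddof=1) / np.sqrt(reps) if ests.std() > 0 else 1e-9
        assert abs(ests.mean() - pi) < 4 * mc_se + 1e-9

    def test_concealment_lowers_dq_but_not_lre(self, default_config, rng):
        open_cfg = default_config.uniform(pi=0.28, dq=0.28)
        hidden_cfg = default_config.uniform(pi=0.28, dq=0.14)
        n = 30_000
        dq_yes = {}
        lre_mean = {}
        for name, cfg in (("open", open_cfg), ("hidden", hidden_cfg)):
            profile = TestSimulateResponse.PROFILE
            yes = sum(
                simulate_response(profile, "DQ5", cfg, rng).dq_item_responses[-1]
                for _ in range(2000)
            )
            dq_yes[name] = yes / 2000
            t, c = simulate_list_counts(0.28, n, n, cfg.control_model, rng)
            lre_mean[name] = t.mean() - c.mean()
        assert dq_yes["hidden"] < dq_yes["open"] - 0.08
        assert lre_mean["hidden"] == pytest.approx(lre_mean["open"], abs=0.02)


class TestGeneratePopulation:
    def test_sample_composition_matches_study(self, default_population):
        assert len(default_population) == 809
        for (cov, level), n in TABLE_NS.items():
            assert sum(1 for r in default_population if getattr(r, cov) == level) == n

    def test_same_seed_reproduces_records(self, default_config):
        a = generate_population(default_config, seed=99)
        b = generate_population(default_config, seed=99)
        assert a == b

    def test_different_seed_differs(self, default_config):
        a = generate_population(default_config, seed=99)
        b = generate_population(default_config, seed=100)
        assert a != b

    def test_infeasible_marginals_rejected(self):
        counts = {k: dict(v) for k, v in GeneratorConfig().covariate_counts.items()}
        counts["gender"]["male"] += 1
        with pytest.raises(ConfigurationError):
            GeneratorConfig(covariate_counts=counts)


class TestCalibration:
    def test_marginal_expectations_track_table(self, default_config, default_population):
        # mean latent support among low-education respondents should sit
        # near the published 0.40 (up to rounding inconsistency of the
        # printed marginals, absorbed by centring)
        rates = [
            default_config.pi.rate(r.profile)
            for r in default_population
            if r.education == "low"
        ]
        assert np.mean(rates) == pytest.approx(0.40, abs=0.03)
        overall = [default_config.pi.rate(r.profile) for r in default_population]
        assert np.mean(overall) == pytest.approx(0.28, abs=0.03)

    def test_requires_all_row(self):
        with pytest.raises(ConfigurationError, match="all"):
            calibrate_from_table(
                [{"covariate": "gender", "level": "male", "dq": 0.1, "lre": 0.2}]
            )

    def test_single_row_table_gives_uniform_rates(self):
        cfg = calibrate_from_table(
            [{"covariate": "all", "level": "all", "dq": 0.18, "lre": 0.28}]
        )
        profile = {c: COVARIATES[c][0] for c in COVARIATES}
        assert cfg.pi.rate(profile) == 0.28
        assert cfg.dq_prob.rate(profile) == 0.18


class TestJointCells:
    CELLS = {
        ("male", "low"): 119,
        ("male", "high"): 202,
        ("female", "low"): 234,
        ("female", "high"): 92,
    }

    def test_list_family_cells_reproduced_exactly(self, default_config):
        from dataclasses import replace

        cfg = replace(
            default_config,
            joint_cells=JointCellSpec("gender", "education", self.CELLS),
        )
        records = generate_population(cfg, seed=5)
        lre = [r for r in records if r.arm in ("LRE4", "LRE5")]
        for (g, e), n in self.CELLS.items():
            got = sum(1 for r in lre if r.gender == g and r.education == e)
            assert got == n, (g, e)
        # marginals of the full population are still exact
        for (cov, level), n in TABLE_NS.items():
            assert sum(1 for r in records if getattr(r, cov) == level) == n

    def test_cells_must_sum_to_list_family(self, default_config):
        from dataclasses import replace

        bad = dict(self.CELLS)
        bad[("male", "low")] += 1
        cfg = replace(
            default_config, joint_cells=JointCellSpec("gender", "education", bad)
        )
        with pytest.raises(ConfigurationError, match="sum"):
            generate_population(cfg, seed=5)
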
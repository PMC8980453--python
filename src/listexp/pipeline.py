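"""End-to-end orchestration: simulate, validate, estimate, diagnose, report.

A run is fully determined by a configuration file and a seed; identical
inputs produce byte-identical numeric outputs. Outputs are plain text
(CSV/TSV/JSON) plus a manifest recording the configuration hash, seed and
per-stage record counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib import metadata, resources
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import contrasts, diagnostics, estimators, survey_model, synthetic_respondents
from .survey_model import ARM_LRE4, ARM_LRE5, ListDesign
from .synthetic_respondents import (
    ConfigurationError,
    ControlItemModel,
    GeneratorConfig,
    JointCellSpec,
    calibrate_from_table,
)

__all__ = [
    "DEFAULT_CONFIG_NAME",
    "PipelineError",
    "ValidationFailure",
    "load_config_file",
    "load_generator_config",
    "load_published_results",
    "run_pipeline",
]

log = logging.getLogger("listexp")

DEFAULT_CONFIG_NAME = "arsi_2017.yaml"

#: Interaction grids reported alongside the subgroup table: gender crossed
#: with every other trait, then education crossed with every other trait.
TABLE2_FACTORS = ("gender", ("education", "age_group", "wealth", "decision_making"))
TABLE3_FACTORS = ("education", ("gender", "age_group", "wealth", "decision_making"))


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage


class ValidationFailure(PipelineError):
    pass


def _default_config_text() -> str:
    return (
        resources.files("listexp").joinpath(f"data/{DEFAULT_CONFIG_NAME}").read_text()
    )


def load_config_file(path: str | Path | None = None) -> dict:
    """Parse a run configuration; ``None`` loads the packaged default."""
    text = _default_config_text() if path is None else Path(path).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "generator" not in doc:
        raise ConfigurationError("configuration must contain a 'generator' section")
    doc["_raw_text"] = text
    return doc


def _design_from_doc(doc: Mapping) -> ListDesign:
    d = doc.get("design")
    if d is None:
        return survey_model.DEFAULT_DESIGN
    return ListDesign(tuple(d["control_items"]), d.get("sensitive_item"))


def load_generator_config(path: str | Path | None = None) -> GeneratorConfig:
    """Build a :class:`GeneratorConfig` from a YAML configuration file."""
    doc = load_config_file(path)
    gen = doc["generator"]
    design = _design_from_doc(doc)
    control = ControlItemModel(**gen.get("control_items", {}))
    covariates = {
        cov: dict(levels) for cov, levels in gen["covariates"].items()
    }
    joint = gen.get("joint_cells")
    joint_spec = None
    if joint:
        cells = {
            (a, b): int(nn)
            for a, row in joint["cells"].items()
            for b, nn in row.items()
        }
        joint_spec = JointCellSpec(joint["factor_a"], joint["factor_b"], cells)
    return calibrate_from_table(
        gen["calibration"],
        covariate_counts=covariates,
        n_total=int(gen["n_total"]),
        dq_fraction=float(gen["dq_fraction"]),
        control_model=control,
        reason_weights=dict(gen.get("reasons", {})),
        joint_cells=joint_spec,
        design=design,
    )


def load_published_results(path: str | Path | None = None) -> dict:
    """The published summary statistics (estimates, CIs, reanalysis cases)."""
    doc = load_config_file(path)
    if "published" not in doc:
        raise ConfigurationError("configuration has no 'published' section")
    return doc["published"]


def reanalyze_published(path: str | Path | None = None) -> pd.DataFrame:
    """Recompute every published contrast whose inputs are printed.

    For each case, standard errors are recovered from the printed 95% CIs
    (full width / (2 x 1.96)) and the two-sided contrast of equal
    proportions recomputed. Both the recomputed and the printed p-value
    are reported; agreement is evaluated at the printed precision.
    """
    cases = load_published_results(path)["reanalysis_cases"]
    rows = []
    for case in cases:
        res = contrasts.contrast_from_cis(
            case["estimate1"],
            tuple(case["ci1"]),
            case["estimate2"],
            tuple(case["ci2"]),
        )
        dec = int(case["printed_decimals"])
        rows.append(
            {
                "case": case["id"],
                "recomputed_p": res.p_two_sided,
                "recomputed_p_rounded": round(res.p_two_sided, dec),
                "printed_p": case["printed_p"],
                "matches_printed": round(res.p_two_sided, dec) == case["printed_p"],
            }
        )
    return pd.DataFrame(rows)


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(
    config_path: str | Path | None = None,
    seed: int = 0,
    out_dir: str | Path = "run",
    level: float = 0.95,
    alpha: float = 0.05,
) -> dict:
    """Simulate, validate, analyse and report; returns the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    doc = load_config_file(config_path)
    config = load_generator_config(config_path)
    design = config.design

    log.info("simulate: n_total=%d seed=%d", config.n_total, seed)
    records = synthetic_respondents.generate_population(config, seed=seed)

    report = survey_model.validate_design(records, design)
    log.info(
        "validate: %d records, %d violations", report.n_records, len(report.violations)
    )
    (out / "validation.json").write_text(report.to_json())
    if not report.passed:
        raise ValidationFailure("validate", f"{len(report.violations)} violation(s)")

    survey_model.write_respondents(records, out / "respondents.csv")

    dq, lre = contrasts._arm_estimates(records, level)
    assert dq is not None and lre is not None
    overall = contrasts.contrast_estimates(lre, dq)
    est_frame = pd.DataFrame(
        [
            {
                "method": e.method,
                "estimate": e.estimate,
                "se": e.se,
                "ci_low": e.truncated().ci_low,
                "ci_high": e.truncated().ci_high,
                "level": e.level,
                "n": e.n,
            }
            for e in (dq, lre)
        ]
    )
    _write_tsv(est_frame, out / "estimates.tsv")
    log.info(
        "estimate: DQ=%.3f (se %.3f), LRE=%.3f (se %.3f), two-sided p=%.3f",
        dq.estimate,
        dq.se,
        lre.estimate,
        lre.se,
        overall.p_two_sided,
    )

    add_item = diagnostics.additional_item_test(records, design, alpha=alpha)
    lre4_counts = [r.lre_count for r in records if r.arm == ARM_LRE4]
    lre5_counts = [r.lre_count for r in records if r.arm == ARM_LRE5]
    fc4 = diagnostics.floor_ceiling_rates(lre4_counts, 4)
    fc5 = diagnostics.floor_ceiling_rates(lre5_counts, 5)
    diag = {
        "additional_item": {
            "d_statistic": add_item.ks.d_statistic,
            "p_value": add_item.ks.p_value,
            "method": add_item.ks.method,
            "alpha": alpha,
            "passed": add_item.passed,
        },
        "floor_ceiling": {
            "LRE4": {"floor": fc4[0], "ceiling": fc4[1]},
            "LRE5": {"floor": fc5[0], "ceiling": fc5[1]},
        },
        "contrast_lre_vs_dq": {
            "diff": overall.diff,
            "z": overall.z,
            "p_one_sided": overall.p_one_sided,
            "p_two_sided": overall.p_two_sided,
        },
    }
    (out / "diagnostics.json").write_text(json.dumps(diag, indent=2, sort_keys=True))

    table1 = contrasts.method_comparison_table(records, level)
    _write_tsv(table1, out / "table1.tsv")
    table2 = pd.concat(
        [
            contrasts.interaction_table(records, TABLE2_FACTORS[0], fb, level)
            for fb in TABLE2_FACTORS[1]
        ],
        ignore_index=True,
    )
    _write_tsv(table2, out / "table2.tsv")
    table3 = pd.concat(
        [
            contrasts.interaction_table(records, TABLE3_FACTORS[0], fb, level)
            for fb in TABLE3_FACTORS[1]
        ],
        ignore_index=True,
    )
    _write_tsv(table3, out / "table3.tsv")
    reasons = contrasts.tabulate_reasons(records)
    _write_tsv(reasons, out / "reasons.tsv")

    try:
        version = metadata.version("listexp")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    manifest = {
        "config": str(config_path) if config_path else f"packaged:{DEFAULT_CONFIG_NAME}",
        "config_sha256": hashlib.sha256(doc["_raw_text"].encode()).hexdigest(),
        "seed": seed,
        "listexp_version": version,
        "stages": {
            "simulate": {"respondents": len(records)},
            "validate": {
                "violations": len(report.violations),
                "arm_counts": report.arm_counts,
            },
            "estimate": {"rows": int(len(est_frame))},
            "diagnose": {"additional_item_passed": add_item.passed},
            "report": {
                "table1_rows": int(len(table1)),
                "table2_rows": int(len(table2)),
                "table3_rows": int(len(table3)),
                "reason_categories": int(len(reasons)),
            },
        },
        "outputs": sorted(
            p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
        ),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
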
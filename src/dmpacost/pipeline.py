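"""End-to-end orchestration: generate, estimate, cost, simulate, break even.

``run_pipeline`` drives the whole analysis from one validated
configuration and writes every intermediate as plain CSV/JSON so that all
reported numbers are re-derivable: the synthetic cohort, per-arm
transition matrices, continuation/hazard summaries, Monte-Carlo Markov
metric summaries, the two comparison tables (provider-administered
DMPA-SC vs DMPA-IM; community vs facility), the per-option steady-state
cost breakdown, break-even curves per location, and a run manifest
(seed, config hash, version) that fully determines the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .breakeven import find_breakeven, threshold_vs_observed
from .cohort import (
    CohortParams,
    default_study_params,
    generate_cohort,
    write_cohort_csv,
)
from .costs import (
    CostSchedule,
    ResourceInventory,
    build_cost_schedule,
    default_inventory,
    inventory_from_dict,
    inventory_to_dict,
)
from .estimation import (
    EVENT_METHOD_CHANGE,
    EstimationError,
    cumulative_incidence_si,
    estimate_transition_matrix,
    hazard_ratio,
    km_continuation,
    logrank_test,
    mean_days_to_switch,
)
from .markov import compare_cohorts, round_half_away, run_monte_carlo
from .states import ARMS, COMMUNITY, FACILITY, IM, LOCATIONS, PA_SC, SI

logger = logging.getLogger(__name__)

MINUS = "−"


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass(frozen=True)
class EngineConfig:
    n0: float = 100_000.0
    n_cycles: int = 4
    n_replicates: int = 1000
    failure_rate_annual: float = 0.0
    beta_concentration: float = 300.0
    beta_fixed: bool = False

    def __post_init__(self):
        if self.n0 <= 0 or self.n_cycles < 1 or self.n_replicates < 1:
            raise ConfigError("engine sizes must be positive")
        if not 0.0 <= self.failure_rate_annual < 1.0:
            raise ConfigError("failure_rate_annual must lie in [0, 1)")


@dataclass(frozen=True)
class BreakevenConfig:
    grid_step: float = 0.01
    locations: tuple[str, ...] = LOCATIONS
    mode: str = "visit"
    observed_si_share: float = 0.64  # lower end of the observed service-statistics range

    def __post_init__(self):
        if not 0.0 < self.grid_step <= 0.5:
            raise ConfigError("grid_step must lie in (0, 0.5]")
        for loc in self.locations:
            if loc not in LOCATIONS:
                raise ConfigError(f"unknown breakeven location {loc!r}")


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration for the full pipeline."""

    cohort: CohortParams = field(default_factory=default_study_params)
    inventory: ResourceInventory = field(default_factory=default_inventory)
    engine: EngineConfig = field(default_factory=EngineConfig)
    breakeven: BreakevenConfig = field(default_factory=BreakevenConfig)
    seed: int = 0


def _from_section(cls, section: dict, name: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in section {name!r}: {sorted(unknown)}")
    try:
        return cls(**section)
    except (TypeError, ValueError) as err:
        raise ConfigError(f"invalid section {name!r}: {err}") from err


def config_from_dict(cfg: dict) -> PipelineConfig:
    known = {"cohort", "inventory", "engine", "breakeven", "seed"}
    unknown = set(cfg) - known
    if unknown:
        raise ConfigError(f"unknown configuration section(s): {sorted(unknown)}")
    seed = int(cfg.get("seed", 0))
    cohort_section = dict(cfg.get("cohort", {}))
    if cohort_section:
        cohort_section.setdefault("seed", seed)
        for key in ("n_per_arm", "hazard_change", "p_transition_si", "p_community"):
            if key in cohort_section and isinstance(cohort_section[key], list):
                cohort_section[key] = tuple(cohort_section[key])
        cohort = _from_section(CohortParams, cohort_section, "cohort")
    else:
        cohort = default_study_params(seed=seed)
    inventory = (
        inventory_from_dict(cfg["inventory"]) if "inventory" in cfg else default_inventory()
    )
    engine = _from_section(EngineConfig, dict(cfg.get("engine", {})), "engine")
    brk_section = dict(cfg.get("breakeven", {}))
    if "locations" in brk_section:
        brk_section["locations"] = tuple(brk_section["locations"])
    breakeven = _from_section(BreakevenConfig, brk_section, "breakeven")
    return PipelineConfig(
        cohort=cohort, inventory=inventory, engine=engine, breakeven=breakeven, seed=seed
    )


def load_config(path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def config_to_dict(config: PipelineConfig) -> dict:
    return {
        "seed": config.seed,
        "cohort": dataclasses.asdict(config.cohort),
        "inventory": inventory_to_dict(config.inventory),
        "engine": dataclasses.asdict(config.engine),
        "breakeven": dataclasses.asdict(config.breakeven),
    }


# ---------------------------------------------------------------------------
# report formatting
# ---------------------------------------------------------------------------

def format_relative_difference(a: float, b: float) -> str:
    """Signed percent difference of b vs a, one decimal, typographic minus."""
    if a == 0:
        raise ValueError("relative difference undefined for a zero reference")
    pct = round_half_away(100.0 * (b - a) / a, 1)
    sign = MINUS if pct < 0 else "+"
    return f"{sign}{abs(pct):.1f}%"


def format_money(x: float) -> str:
    return f"{x:,.2f}"


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    out_dir: Path
    files: dict[str, Path]
    estimates: dict
    metric_summary: pd.DataFrame
    comparisons: dict[str, pd.DataFrame]
    cost_breakdown: pd.DataFrame
    breakeven_thresholds: dict[str, float | None]


def _metric_rows(label: str, result) -> list[dict]:
    rows = []
    for name, metric in result.metrics().items():
        rows.append(
            {
                "cohort": label,
                "metric": name,
                "mean": metric.mean,
                "p5": metric.p5,
                "p95": metric.p95,
            }
        )
    return rows


def _start_distribution(records) -> dict[str, float]:
    counts: dict[str, float] = {}
    for rec in records:
        counts[rec.arm] = counts.get(rec.arm, 0.0) + 1.0
    return counts


def run_pipeline(config: PipelineConfig, out_dir) -> PipelineResult:
    """Run every stage and write the full report bundle to ``out_dir``."""
    t0 = time.perf_counter()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    def stage(name: str):
        logger.info("stage %-18s %6.2fs", name, time.perf_counter() - t0)

    # 1. synthetic cohort -----------------------------------------------------
    try:
        records = generate_cohort(config.cohort)
        files["cohort"] = out / "cohort.csv"
        write_cohort_csv(records, files["cohort"])
    except Exception as err:
        raise RuntimeError(f"stage simulate-cohort failed: {err}") from err
    stage("simulate-cohort")

    # 2. estimation -----------------------------------------------------------
    try:
        matrices = {arm: estimate_transition_matrix(records, arm) for arm in ARMS}
        for arm, tm in matrices.items():
            path = out / f"transition_matrix_{arm}.csv"
            tm.to_frame().to_csv(path)
            files[f"matrix_{arm}"] = path
        hr_pasc = hazard_ratio(records, PA_SC, IM)
        hr_si = hazard_ratio(records, SI, IM)
        ci_pasc = cumulative_incidence_si(records, PA_SC)
        ci_im = cumulative_incidence_si(records, IM)
        lr_stat, lr_p = logrank_test(
            [r for r in records if r.arm == PA_SC],
            [r for r in records if r.arm == IM],
        )
        estimates = {
            "hr_method_change_pasc_vs_im": {
                "hr": hr_pasc.hr,
                "ci": [hr_pasc.ci_low, hr_pasc.ci_high],
            },
            "hr_method_change_si_vs_im": {
                "hr": hr_si.hr,
                "ci": [hr_si.ci_low, hr_si.ci_high],
            },
            "cumulative_si_12mo_pasc": {
                "estimate": ci_pasc.estimate,
                "ci": [ci_pasc.ci_low, ci_pasc.ci_high],
            },
            "cumulative_si_12mo_im": {
                "estimate": ci_im.estimate,
                "ci": [ci_im.ci_low, ci_im.ci_high],
            },
            "logrank_pasc_vs_im": {"statistic": lr_stat, "p_value": lr_p},
        }
        for arm, key in ((PA_SC, "mean_days_to_si_pasc"), (IM, "mean_days_to_si_im")):
            try:
                estimates[key] = mean_days_to_switch(records, arm, config.cohort.cycle_days)
            except EstimationError:
                estimates[key] = None  # no switchers in this cohort realisation
        files["estimates"] = out / "estimates.json"
        files["estimates"].write_text(json.dumps(estimates, indent=2), encoding="utf-8")
        for arm, event in ((IM, EVENT_METHOD_CHANGE), (PA_SC, EVENT_METHOD_CHANGE)):
            curve = km_continuation([r for r in records if r.arm == arm], event)
            path = out / f"km_{event}_{arm}.csv"
            curve.to_frame().to_csv(path, index=False)
            files[f"km_{arm}"] = path
    except Exception as err:
        raise RuntimeError(f"stage estimate failed: {err}") from err
    stage("estimate")

    # 3. costing + Markov simulation -------------------------------------------
    try:
        schedule = build_cost_schedule(config.inventory)
        eng = config.engine
        mc = dict(
            n0=eng.n0,
            n_cycles=eng.n_cycles,
            failure_rate_annual=eng.failure_rate_annual,
            n_replicates=eng.n_replicates,
            concentration=np.inf if eng.beta_fixed else eng.beta_concentration,
        )
        results = {}
        # arm comparison at facility costs (almost all arm enrolment is facility-based)
        results["im_cohort"] = run_monte_carlo(
            matrices[IM], schedule, start=IM, location=FACILITY,
            seed=config.seed * 2 + 1, **mc,
        )
        results["pasc_cohort"] = run_monte_carlo(
            matrices[PA_SC], schedule, start=PA_SC, location=FACILITY,
            seed=config.seed * 2 + 2, **mc,
        )
        # location comparison on location-specific subcohorts
        for loc_i, loc in enumerate(LOCATIONS):
            subset = [r for r in records if r.location == loc]
            tm = estimate_transition_matrix(subset)
            results[f"{loc}_cohort"] = run_monte_carlo(
                tm, schedule, start=_start_distribution(subset), location=loc,
                seed=config.seed * 2 + 10 + loc_i, **mc,
            )
        rows = []
        for label, res in results.items():
            rows.extend(_metric_rows(label, res))
        metric_summary = pd.DataFrame(rows)
        files["metrics"] = out / "metric_summary.csv"
        metric_summary.to_csv(files["metrics"], index=False, float_format="%.6f")
        for label, res in results.items():
            path = out / f"occupancy_{label}.csv"
            res.occupancy_frame().to_csv(path, float_format="%.6f")
            files[f"occupancy_{label}"] = path

        comparisons = {
            "pasc_vs_im": compare_cohorts(
                results["im_cohort"], results["pasc_cohort"], "DMPA-IM", "PA DMPA-SC"
            ),
            "community_vs_facility": compare_cohorts(
                results["facility_cohort"],
                results["community_cohort"],
                "facility",
                "community",
            ),
        }
        for name, df in comparisons.items():
            path = out / f"comparison_{name}.csv"
            df.to_csv(path, float_format="%.6f")
            files[f"comparison_{name}"] = path

        # per-option steady-state cost breakdown by location
        breakdown_rows = []
        for state, label in ((IM, "DMPA-IM"), (PA_SC, "PA DMPA-SC"), (SI, "Self-injection")):
            fac = schedule.cost_per_person_year(state, FACILITY)
            com = schedule.cost_per_person_year(state, COMMUNITY)
            breakdown_rows.append(
                {
                    "option": label,
                    "facility": round(fac, 2),
                    "community": round(com, 2),
                    "pct_difference": format_relative_difference(fac, com),
                }
            )
        cost_breakdown = pd.DataFrame(breakdown_rows).set_index("option")
        files["cost_breakdown"] = out / "cost_breakdown_per_py.csv"
        cost_breakdown.to_csv(files["cost_breakdown"])
    except Exception as err:
        raise RuntimeError(f"stage simulate failed: {err}") from err
    stage("simulate")

    # 4. break-even -------------------------------------------------------------
    try:
        thresholds: dict[str, float | None] = {}
        for loc in config.breakeven.locations:
            curve = find_breakeven(
                schedule,
                matrices[PA_SC],
                location=loc,
                grid_step=config.breakeven.grid_step,
                mode=config.breakeven.mode,
            )
            thresholds[loc] = curve.threshold
            path = out / f"breakeven_{loc}.csv"
            curve.to_frame().to_csv(path, index=False, float_format="%.6f")
            files[f"breakeven_{loc}"] = path
            verdict = threshold_vs_observed(
                curve.threshold, config.breakeven.observed_si_share
            )
            logger.info(
                "break-even (%s): threshold=%s observed=%.2f cost_saving=%s",
                loc,
                curve.threshold,
                config.breakeven.observed_si_share,
                verdict.cost_saving,
            )
    except Exception as err:
        raise RuntimeError(f"stage breakeven failed: {err}") from err
    stage("breakeven")

    # 5. manifest ---------------------------------------------------------------
    cfg_dict = config_to_dict(config)
    cfg_json = json.dumps(cfg_dict, sort_keys=True)
    manifest = {
        "package": "dmpacost",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "config": cfg_dict,
        "outputs": {k: str(v.name) for k, v in sorted(files.items())},
    }
    files["manifest"] = out / "manifest.json"
    files["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
    stage("manifest")

    return PipelineResult(
        out_dir=out,
        files=files,
        estimates=estimates,
        metric_summary=metric_summary,
        comparisons=comparisons,
        cost_breakdown=cost_breakdown,
        breakeven_thresholds=thresholds,
    )


def comparison_report(df: pd.DataFrame, label_a: str, label_b: str) -> str:
    """Plain-text comparison table with formatted relative differences."""
    wa = max(16, len(label_a) + 2)
    wb = max(16, len(label_b) + 2)
    lines = [f"{'metric':<16}{label_a:>{wa}}{label_b:>{wb}}{'comparison':>12}"]
    for metric, row in df.iterrows():
        lines.append(
            f"{metric:<16}{format_money(row[label_a]):>{wa}}"
            f"{format_money(row[label_b]):>{wb}}"
            f"{format_relative_difference(row[label_a], row[label_b]):>12}"
        )
    return "\n".join(lines)
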
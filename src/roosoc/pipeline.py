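"""End-to-end orchestration: simulate/load -> group -> associate -> metrics ->
spatial null -> permutation GLMMs, with a reproducible run manifest.

All randomness flows from one root seed through named substreams per stage so
stages can be re-run independently; the manifest records seeds, thresholds and
per-period filter counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .associations import association_matrix, filter_eligible
from .grouping import group_observations
from .inference import ModelSpec, PermutationConfig, PermutationEngine
from .lifehistory import build_records
from .metrics import metrics_table
from .periods import Period, annual_periods, observed_years, window_periods
from .spatial_null import estimate_uds, preferred_associates, simulate_null_surveys
from .synthetic import OutcomeConfig, PopulationConfig, simulate_dataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline configuration (thresholds default to the field protocol)."""

    design: str = "both"                   # approach1 | approach2 | both
    observations_path: str | None = None   # None -> simulate
    gps_path: str | None = None
    out_dir: str = "roosoc_out"
    seed: int = 0
    chain_threshold: float = 15.0
    min_sightings: int = 10
    min_fixes: int = 50
    max_gap_months: int = 2
    preferred_quantile: float = 0.975
    n_sim: int = 200
    swaps_per_step: int = 100
    burn_in_steps: int = 200
    kept_steps: int = 1000
    tail: str = "two-sided"
    population: PopulationConfig | None = None
    outcomes: OutcomeConfig | None = None

    def __post_init__(self) -> None:
        if self.design not in ("approach1", "approach2", "both"):
            raise ValueError(f"invalid design {self.design!r}")
        for v in (self.chain_threshold, self.min_sightings, self.min_fixes,
                  self.max_gap_months, self.n_sim):
            if v <= 0:
                raise ValueError("thresholds must be positive")


@dataclass
class DesignResult:
    design: str
    periods: list[Period]
    eligible: dict[str, list[str]]
    metrics: pd.DataFrame
    records: pd.DataFrame
    models: dict
    preferred: dict[str, pd.DataFrame] = field(default_factory=dict)


@dataclass
class RunResult:
    config: RunConfig
    observations: pd.DataFrame
    grouped: pd.DataFrame
    designs: dict[str, DesignResult]
    manifest: dict


def _analyse_design(config: RunConfig, design: str, observations, grouped, gps_fixes):
    years = observed_years(observations)
    periods = annual_periods(years) if design == "approach1" else window_periods(years)
    dates = pd.to_datetime(grouped["date"])
    eligible: dict[str, list[str]] = {}
    matrices = {}
    preferred = {}
    pref_counts = {}
    for period in periods:
        elig = filter_eligible(
            observations, gps_fixes, design, period,
            config.min_sightings, config.min_fixes, config.max_gap_months,
        )
        grouped_p = grouped[dates.dt.year.isin(period.years)]
        ids = sorted(elig & set(grouped_p["female_id"]))
        eligible[period.label] = ids
        matrices[period.label] = association_matrix(grouped_p, ids=ids)
        if design == "approach2":
            uds = estimate_uds(
                gps_fixes, years=list(period.years), min_fixes=config.min_fixes
            )
            uds = {f: u for f, u in uds.items() if f in elig}
            null = simulate_null_surveys(
                uds, grouped_p[grouped_p["female_id"].isin(ids)],
                n_sim=config.n_sim, seed=config.seed + 1000 + ord(period.label),
                threshold=config.chain_threshold,
            )
            dyads, counts = preferred_associates(null, config.preferred_quantile)
            preferred[period.label] = dyads
            pref_counts[period.label] = counts

    session_periods = {}
    for sid, year in zip(grouped["session_id"], dates.dt.year):
        labs = [p.label for p in periods if year in p.years]
        session_periods[sid] = labs
    metrics = metrics_table(matrices, grouped, periods, session_periods)
    if design == "approach2":
        metrics["n_preferred"] = [
            int(pref_counts[row.period].get(row.female_id, 0))
            for row in metrics.itertuples(index=False)
        ]
    records = build_records(observations, metrics, periods, design)
    logger.info("%s: %d model rows, %d females", design, len(records),
                records["female_id"].nunique() if len(records) else 0)
    if records.empty or len(records) < 4:
        raise RuntimeError(f"{design}: too few model rows after filtering")
    engine = PermutationEngine(grouped, metrics, records, periods, design, eligible)
    pconfig = PermutationConfig(
        config.swaps_per_step, config.burn_in_steps, config.kept_steps,
        seed=config.seed + 2000,
    )
    specs = [ModelSpec(r, design) for r in ("lpy", "pep", "wean")]
    models = engine.run(specs, pconfig, tail=config.tail)
    return DesignResult(design, periods, eligible, metrics, records, models, preferred)


def run_pipeline(config: RunConfig, write: bool = True) -> RunResult:
    """Run the configured analysis end to end; deterministic given the seed."""
    if config.observations_path:
        from .io import read_gps_fixes, read_observations

        observations = read_observations(config.observations_path)
        gps_fixes = read_gps_fixes(config.gps_path) if config.gps_path else None
        truth = None
    else:
        pop_cfg = config.population or PopulationConfig(seed=config.seed)
        ds = simulate_dataset(pop_cfg, config.outcomes)
        observations, gps_fixes, truth = ds.observations, ds.gps_fixes, ds
    grouped = group_observations(observations, config.chain_threshold)

    designs = {}
    design_names = (
        ["approach1", "approach2"] if config.design == "both" else [config.design]
    )
    for design in design_names:
        try:
            designs[design] = _analyse_design(
                config, design, observations, grouped, gps_fixes
            )
        except Exception:
            logger.exception("stage failed: %s", design)
            raise RuntimeError(f"pipeline stage failed: {design}") from None

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": {
            k: v for k, v in asdict(config).items()
            if not isinstance(v, (dict,)) and k not in ("population", "outcomes")
        },
        "n_observations": int(len(observations)),
        "n_sessions": int(observations["session_id"].nunique()),
        "filters": {
            d: {p.label: len(r.eligible[p.label]) for p in r.periods}
            for d, r in designs.items()
        },
        "model_rows": {d: int(len(r.records)) for d, r in designs.items()},
    }

    result = RunResult(config, observations, grouped, designs, manifest)
    if write:
        _write_outputs(result, truth)
    return result


def _write_outputs(result: RunResult, truth=None) -> None:
    from .io import write_model_table, write_observations

    out = Path(result.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_observations(result.observations, out / "observations.csv")
    result.grouped[["session_id", "group_id", "female_id"]].to_csv(
        out / "grouped_sessions.csv", index=False
    )
    for design, dr in result.designs.items():
        dr.metrics.to_csv(out / f"metrics_{design}.csv", index=False)
        dr.records.to_csv(out / f"records_{design}.csv", index=False)
        for resp, model in dr.models.items():
            write_model_table(model, out / f"model_{design}_{resp}")
        for label, dyads in dr.preferred.items():
            dyads.to_csv(out / f"preferred_dyads_{label}.csv", index=False)
    if truth is not None:
        (out / "ground_truth.json").write_text(truth.ground_truth_json())
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1))
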
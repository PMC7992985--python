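"""Scenario batch runner: presets, seeded replications, publication-style tables.

Scenario comparisons use common random numbers: replication *i* of every
scenario runs with the same seed, so that paired policy contrasts are not
drowned in arrival-stream noise.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .config import ScenarioConfig, ScenarioError
from .engine import CaseLog, run_replication
from .kpi import CIReport, KPIReport, aggregate_replications, compute_kpis
from .patient_generation import Calibration, default_calibration
from .scheduling import MasterSurgerySchedule, default_mss

__all__ = [
    "preset_experiments",
    "replication_seeds",
    "run_scenario",
    "run_experiments",
]

_SEED_MOD = 2_147_483_647  # keep every derived seed below 2**31


def replication_seeds(base_seed: int, replications: int) -> List[int]:
    return [(int(base_seed) + i) % _SEED_MOD for i in range(replications)]


def preset_experiments(
    replications: int = 30,
    horizon_weeks: int = 52,
    warmup_weeks: int = 4,
    base_seed: int = 20_210_324,
) -> List[ScenarioConfig]:
    """The bundled scenario battery: Base Case, buffer-hour sweep (1-4 h),
    parallel induction with 0-3 extra anesthesia teams, shortest-first and
    longest-first sequencing, and closing the dedicated emergency room."""
    common = dict(
        replications=replications,
        horizon_weeks=horizon_weeks,
        warmup_weeks=warmup_weeks,
        base_seed=base_seed,
    )
    scenarios = [ScenarioConfig(name="base", **common)]
    for h in (1, 2, 3, 4):
        scenarios.append(ScenarioConfig(name=f"buffer_{h}h", buffer_hours=float(h), **common))
    for k in (0, 1, 2, 3):
        scenarios.append(
            ScenarioConfig(name=f"parallel_{k}team", parallel_induction=True, extra_teams=k, **common)
        )
    scenarios.append(ScenarioConfig(name="sequencing_sf", sequencing="SF", **common))
    scenarios.append(ScenarioConfig(name="sequencing_lf", sequencing="LF", **common))
    scenarios.append(ScenarioConfig(name="no_emergency_or", dedicated_emergency_or=False, **common))
    return scenarios


def run_scenario(
    scenario: ScenarioConfig,
    calibration: Optional[Calibration] = None,
    mss: Optional[MasterSurgerySchedule] = None,
    keep_logs: bool = False,
):
    """Run all replications of one scenario; returns (reports, logs or None)."""
    calibration = calibration or default_calibration()
    mss = mss or default_mss()
    reports: List[KPIReport] = []
    logs: List[CaseLog] = []
    for seed in replication_seeds(scenario.base_seed, scenario.replications):
        log = run_replication(scenario, calibration, mss, seed)
        reports.append(compute_kpis(log))
        if keep_logs:
            logs.append(log)
    return reports, (logs if keep_logs else None)


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh) or {}
    return dict(config)


def run_experiments(config, outdir=None, keep_logs: bool = False) -> pd.DataFrame:
    """Run a batch of scenarios from a config file or dict.

    The config may list explicit ``scenarios`` (dicts of ScenarioConfig
    fields) and/or ``presets: true`` to include the bundled battery; shared
    run parameters (``replications``, ``horizon_weeks``, ``warmup_weeks``,
    ``base_seed``) apply to every scenario.  Outputs: one per-replication KPI
    CSV per scenario, a cross-scenario CI summary (CSV + JSON) and a run
    manifest with config hash and seeds.
    """
    cfg = _load_config(config)
    common = {
        k: cfg[k]
        for k in ("replications", "horizon_weeks", "warmup_weeks", "base_seed")
        if k in cfg
    }
    calibration = (
        Calibration.from_dict(cfg["calibration"]) if cfg.get("calibration") else default_calibration()
    )
    mss = (
        MasterSurgerySchedule.from_csv(cfg["mss"]) if cfg.get("mss") else default_mss()
    )
    scenarios: List[ScenarioConfig] = []
    if cfg.get("presets"):
        scenarios.extend(preset_experiments(**common) if common else preset_experiments())
    for sdict in cfg.get("scenarios", []):
        scenarios.append(ScenarioConfig.from_dict({**common, **sdict}))
    if not scenarios:
        raise ScenarioError("config defines no scenarios (set presets: true or list scenarios)")
    names = [s.name for s in scenarios]
    if len(set(names)) != len(names):
        raise ScenarioError(f"duplicate scenario names: {names}")

    outdir = Path(outdir or cfg.get("outdir", "ortheater_results"))
    outdir.mkdir(parents=True, exist_ok=True)

    ci_rows = []
    manifest: Dict = {
        "version": __version__,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "scenarios": {},
    }
    for scen in scenarios:
        reports, logs = run_scenario(scen, calibration, mss, keep_logs=keep_logs)
        rep_df = pd.DataFrame([r.to_dict() for r in reports])
        rep_df.insert(0, "replication", range(len(reports)))
        rep_df.insert(0, "scenario", scen.name)
        rep_df.to_csv(outdir / f"kpi_{scen.name}.csv", index=False)
        if keep_logs and logs:
            for i, log in enumerate(logs):
                log.to_csv(outdir / f"caselog_{scen.name}_rep{i}.csv")
        ci = aggregate_replications(reports)
        for kpi, row in ci.table.iterrows():
            ci_rows.append({"scenario": scen.name, "kpi": kpi, **row.to_dict()})
        manifest["scenarios"][scen.name] = {
            "config": scen.to_dict(),
            "seeds": replication_seeds(scen.base_seed, scen.replications),
        }

    summary = pd.DataFrame(ci_rows)
    summary.to_csv(outdir / "ci_summary.csv", index=False)
    summary.to_json(outdir / "ci_summary.json", orient="records", indent=2)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return summary


def reaggregate(outdir) -> pd.DataFrame:
    """Rebuild the CI summary from previously written per-replication KPI CSVs."""
    outdir = Path(outdir)
    ci_rows = []
    for path in sorted(outdir.glob("kpi_*.csv")):
        df = pd.read_csv(path)
        name = df["scenario"].iloc[0]
        reports = [
            KPIReport(**{k: row[k] for k in KPIReport().to_dict()}) for _, row in df.iterrows()
        ]
        ci = aggregate_replications(reports)
        for kpi, row in ci.table.iterrows():
            ci_rows.append({"scenario": name, "kpi": kpi, **row.to_dict()})
    summary = pd.DataFrame(ci_rows)
    summary.to_csv(outdir / "ci_summary.csv", index=False)
    return summary
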
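"""Experiment orchestration: strategy grids, sensitivity sweeps and
roster calibration.

``run_experiment`` executes a list of named strategies for a fixed
number of replications each, with per-trial seeds derived
deterministically from a master seed, and writes tidy per-trial and
summary CSVs plus a JSON manifest.  ``sensitivity_sweep`` re-runs a base
strategy over a parameter grid.  ``calibrate_roster`` tunes staff
availability (and optionally the imaging prep time) so the simulated
standard-care annual overspill matches an external audit figure.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .config import ConfigError, ScenarioConfig
from .metrics import METRICS
from .model import ClinicModel, SimulationResults
from .presets import preset


@dataclass
class ExperimentSpec:
    """A named list of strategies plus the replication settings."""

    strategies: list[ScenarioConfig]
    n_trials: int = 150
    master_seed: int = 0
    paired_seeds: bool = False  # common random numbers across strategies
    output_dir: str | None = None

    def validate(self) -> "ExperimentSpec":
        if self.n_trials < 1:
            raise ConfigError("n_trials must be at least 1")
        names = [s.name for s in self.strategies]
        if len(set(names)) != len(names):
            raise ConfigError("strategy names must be unique")
        if not names:
            raise ConfigError("experiment needs at least one strategy")
        for s in self.strategies:
            s.validate()
        return self

    @classmethod
    def from_dict(cls, data: Mapping) -> "ExperimentSpec":
        data = dict(data)
        strategies = []
        for item in data.pop("strategies", []):
            if isinstance(item, str):
                strategies.append(preset(item))
            else:
                strategies.append(ScenarioConfig.from_dict(item))
        known = {f.name for f in dataclasses.fields(cls)} - {"strategies"}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown experiment field(s): {sorted(unknown)}")
        return cls(strategies=strategies, **data).validate()

    @classmethod
    def from_yaml(cls, path) -> "ExperimentSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _config_hash(spec: ExperimentSpec) -> str:
    payload = json.dumps(
        {"strategies": [s.to_dict() for s in spec.strategies],
         "n_trials": spec.n_trials, "master_seed": spec.master_seed,
         "paired_seeds": spec.paired_seeds},
        sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def summary_table(results: Mapping[str, SimulationResults]) -> pd.DataFrame:
    """Audit-style wide table: one row per strategy, mean (95% CI) columns."""
    rows = []
    for name, res in results.items():
        s = res.summary()
        row: dict = {"strategy": name, "n_trials": res.n_trials}
        for metric in METRICS:
            row[metric] = s.loc[metric, "mean"]
            row[f"{metric}_ci_low"] = s.loc[metric, "ci_low"]
            row[f"{metric}_ci_high"] = s.loc[metric, "ci_high"]
        rows.append(row)
    return pd.DataFrame(rows).set_index("strategy")


def run_experiment(spec: ExperimentSpec, progress: bool = False,
                   ) -> dict[str, SimulationResults]:
    """Run every strategy; optionally write CSVs + manifest to output_dir.

    Per-trial seeds derive from (master seed, strategy name, trial index),
    or from (master seed, "paired", trial index) for every strategy when
    ``paired_seeds`` is set (common random numbers).
    """
    spec.validate()
    results: dict[str, SimulationResults] = {}
    for cfg in spec.strategies:
        label = "paired" if spec.paired_seeds else cfg.name
        if progress:
            print(f"strategy {cfg.name}: {spec.n_trials} trials")
        results[cfg.name] = ClinicModel(cfg).simulate(
            n_trials=spec.n_trials, seed=spec.master_seed,
            seed_label=label, progress=progress)

    if spec.output_dir is not None:
        out = Path(spec.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.concat([r.trials() for r in results.values()],
                  ignore_index=True).to_csv(out / "trials.csv", index=False)
        summary_table(results).to_csv(out / "summary.csv")
        manifest = {
            "config_hash": _config_hash(spec),
            "master_seed": spec.master_seed,
            "n_trials": spec.n_trials,
            "paired_seeds": spec.paired_seeds,
            "strategies": [s.name for s in spec.strategies],
            "versions": {"python": platform.python_version(),
                         "numpy": np.__version__, "pandas": pd.__version__},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return results


# ---------------------------------------------------------------------------
# sensitivity sweeps
# ---------------------------------------------------------------------------

def _set_path(cfg: ScenarioConfig, path: str, value) -> ScenarioConfig:
    """Return a copy of ``cfg`` with the dotted parameter path replaced."""
    parts = path.split(".")
    def rebuild(obj, parts):
        name = parts[0]
        if not hasattr(obj, name):
            raise ConfigError(f"unknown parameter {path!r}")
        if len(parts) == 1:
            return dataclasses.replace(obj, **{name: value})
        child = rebuild(getattr(obj, name), parts[1:])
        return dataclasses.replace(obj, **{name: child})
    return rebuild(cfg, parts)


#: Secondary-analysis axes: GP override up to 50%, non-cancer delayed
#: returns up to 50%, and a 10% demand increase.
SWEEP_PRESETS: dict[str, list[float]] = {
    "triage.gp_override_probability": [0.2, 0.3, 0.4, 0.5],
    "triage.delayed_return_probability_noncancer": [0.1, 0.25, 0.5],
    "arrivals.demand_multiplier": [1.0, 1.10],
}


def sensitivity_sweep(base: ScenarioConfig, grid: Mapping[str, Sequence],
                      n_trials: int = 150, master_seed: int = 0,
                      progress: bool = False) -> pd.DataFrame:
    """One-at-a-time sweep of each grid axis around the base strategy.

    Returns a long frame (parameter, value, metric, mean, ci_low,
    ci_high).  Duplicate values on an axis are deduplicated; unknown
    parameter paths are rejected before any simulation.
    """
    base.validate()
    axes: dict[str, list] = {}
    for param, values in grid.items():
        _set_path(base, param, list(values)[0])  # path check up front
        deduped = list(dict.fromkeys(values))
        axes[param] = deduped

    records = []
    for param, values in axes.items():
        for value in values:
            cfg = _set_path(base, param, value)
            cfg = cfg.replace(name=f"{base.name}[{param}={value}]").validate()
            res = ClinicModel(cfg).simulate(n_trials=n_trials, seed=master_seed,
                                            seed_label=cfg.name, progress=progress)
            s = res.summary()
            for metric in METRICS:
                records.append({
                    "parameter": param, "value": value, "metric": metric,
                    "mean": s.loc[metric, "mean"],
                    "ci_low": s.loc[metric, "ci_low"],
                    "ci_high": s.loc[metric, "ci_high"]})
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# roster calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    config: ScenarioConfig
    params: dict[str, float]
    achieved: float
    target: float
    trace: list = field(default_factory=list)
    converged: bool = False


def _apply_calibration_param(cfg: ScenarioConfig, name: str, value: float,
                             ) -> ScenarioConfig:
    if name == "availability":
        roster = dataclasses.replace(
            cfg.roster, availability={r: value for r in cfg.roster.availability})
        return cfg.replace(roster=roster)
    if name == "prep_minutes":
        return cfg.replace(durations=dataclasses.replace(
            cfg.durations, prep_minutes=value))
    raise ConfigError(f"unknown calibration parameter {name!r}")


def calibrate_roster(target: float,
                     base: ScenarioConfig | None = None,
                     tunables: Mapping[str, tuple[float, float]] | None = None,
                     n_trials: int = 20,
                     master_seed: int = 0,
                     max_evals: int = 40,
                     tolerance: float = 0.10,
                     objective: Callable[[ScenarioConfig], float] | None = None,
                     ) -> CalibrationResult:
    """Tune availability / prep time until the simulated mean annual
    overspill matches ``target`` (an external audit figure).

    Coordinate bisection: each tunable is searched in turn over its
    bounds, exploiting the monotone response of overspill to capacity
    (decreasing in availability, increasing in prep time).  Evaluations
    use ``n_trials`` replications with seeds fixed across evaluations
    (common random numbers), so the whole procedure is deterministic
    given the master seed.  Failure to come within ``tolerance``
    (relative) of the target is reported via ``converged=False``, never
    silently accepted.
    """
    if base is None:
        base = preset("standard_care")
    if tunables is None:
        tunables = {"availability": (0.5, 1.0)}
    if not tunables:
        raise ConfigError("no tunables supplied")

    def default_objective(cfg: ScenarioConfig) -> float:
        res = ClinicModel(cfg).simulate(n_trials=n_trials, seed=master_seed,
                                        seed_label="calibration")
        return float(res.mean["overspill_appointments"])

    f = objective if objective is not None else default_objective
    # overspill falls as capacity rises
    direction = {"availability": -1.0, "prep_minutes": +1.0}

    params = {}
    for name, (lo, hi) in tunables.items():
        if name not in direction:
            raise ConfigError(f"unknown calibration parameter {name!r}")
        if not lo < hi:
            raise ConfigError(f"bad bounds for {name!r}: ({lo}, {hi})")
        params[name] = 0.5 * (lo + hi)

    def build(p: dict[str, float]) -> ScenarioConfig:
        cfg = base
        for name, value in p.items():
            cfg = _apply_calibration_param(cfg, name, value)
        return cfg.replace(name=base.name).validate()

    trace: list = []
    evals = 0
    best = (np.inf, dict(params), np.nan)

    def evaluate(p) -> float:
        nonlocal evals, best
        value = f(build(p))
        evals += 1
        trace.append({**p, "overspill": value})
        resid = abs(value - target)
        if resid < best[0]:
            best = (resid, dict(p), value)
        return value

    for sweep in range(2):  # two coordinate passes
        if best[0] <= 0.25 * tolerance * target:
            break
        for name, (lo, hi) in tunables.items():
            a, b = lo, hi
            sign = direction[name]
            while evals < max_evals and (b - a) > 1e-3 * (hi - lo):
                mid = 0.5 * (a + b)
                params[name] = mid
                value = evaluate(params)
                if abs(value - target) <= 0.25 * tolerance * target:
                    break
                # keep the half-interval containing the root of the
                # monotone response (sign = d overspill / d parameter)
                if (value - target) * sign < 0:
                    a = mid
                else:
                    b = mid
            params[name] = best[1][name]
            if evals >= max_evals:
                break
        if evals >= max_evals:
            break

    achieved = best[2]
    converged = bool(abs(achieved - target) <= tolerance * target)
    return CalibrationResult(config=build(best[1]), params=best[1],
                             achieved=achieved, target=target,
                             trace=trace, converged=converged)
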
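"""Factorial simulation experiment: strategies x fields x error conditions
x repetitions, with order-independent seed management.

Every trial owns a seed derived from the experiment's base seed and the
trial's coordinates in the design, so the result table is reproducible
bit-exactly regardless of execution order.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .fields import SensitivityField
from .grid import TestGrid, build_24_2
from .observer import ERROR_CONDITIONS, ErrorCondition, ObserverConfig
from .strategy import StrategyConfig, preset, run_trial

__all__ = [
    "ExperimentPlan",
    "ExperimentTable",
    "ExperimentError",
    "plan_trial_count",
    "trial_seed",
    "run_experiment",
    "study_plan",
]


@dataclass(frozen=True)
class ExperimentPlan:
    """The full factorial design of a simulation experiment."""

    strategies: tuple[tuple[str, StrategyConfig], ...]
    fields: tuple[SensitivityField, ...]
    conditions: tuple[ErrorCondition, ...]
    repetitions: int
    base_seed: int
    observer_base: ObserverConfig = ObserverConfig()

    def __post_init__(self):
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        names = [name for name, _ in self.strategies]
        if len(set(names)) != len(names):
            raise ValueError("strategy arm names must be unique")
        fids = [f.field_id for f in self.fields]
        if len(set(fids)) != len(fids):
            raise ValueError("field ids must be unique (they key the trial seeds)")
        clabels = [c.label for c in self.conditions]
        if len(set(clabels)) != len(clabels):
            raise ValueError("condition labels must be unique (they key the trial seeds)")


def study_plan(
    fields,
    base_seed: int,
    repetitions: int = 1000,
    strategies=("aize", "nonweighted", "fixedweighted"),
    conditions=ERROR_CONDITIONS,
    observer_base: ObserverConfig = ObserverConfig(),
) -> ExperimentPlan:
    """The study design: three arms, five error conditions.

    repetitions=1000 is the full design (100,000 trials per arm with the
    20-field cohort); pass repetitions=100 for a desk-scale run.
    """
    arms = tuple(
        (name, preset(name)) if isinstance(name, str) else tuple(name) for name in strategies
    )
    return ExperimentPlan(
        strategies=arms,
        fields=tuple(fields),
        conditions=tuple(conditions),
        repetitions=repetitions,
        base_seed=base_seed,
        observer_base=observer_base,
    )


def plan_trial_count(plan: ExperimentPlan) -> int:
    """Scheduled trials per strategy arm: fields x conditions x repetitions."""
    return len(plan.fields) * len(plan.conditions) * plan.repetitions


def _coord_key(value) -> int:
    """Stable non-negative integer key for a design coordinate.

    Strings hash via CRC32 so a trial's seed depends on the arm / field /
    condition identity, not its position in the plan: reordering the plan
    cannot change any trial's result.
    """
    if isinstance(value, str):
        return zlib.crc32(value.encode())
    return int(value)


def trial_seed(base_seed: int, arm, field, condition, rep: int) -> np.random.SeedSequence:
    """Collision-free per-trial seed from the trial's design coordinates."""
    return np.random.SeedSequence(
        entropy=base_seed,
        spawn_key=(_coord_key(arm), _coord_key(field), _coord_key(condition), int(rep)),
    )


class ExperimentError(RuntimeError):
    """Raised after an experiment when one or more trials failed."""

    def __init__(self, failures):
        self.failures = failures
        keys = ", ".join(str(k) for k, _ in failures[:5])
        super().__init__(f"{len(failures)} trial(s) failed (first keys: {keys})")


@dataclass
class ExperimentTable:
    """Long-format experiment results.

    `trials` has one row per trial (strategy, field_id, field_label,
    condition, fp, fn, rep, total_presentations); `estimates` and
    `presentations` are aligned (n_trials, n_locations) arrays; `truths`
    maps field_id to its true-sensitivity array.
    """

    trials: pd.DataFrame
    estimates: np.ndarray
    presentations: np.ndarray
    grid: TestGrid
    truths: dict = dc_field(default_factory=dict)
    field_labels: dict = dc_field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trials)

    def estimates_frame(self) -> pd.DataFrame:
        """Per-location estimates in long format (one row per trial x location)."""
        n_loc = len(self.grid)
        rep = self.trials.loc[self.trials.index.repeat(n_loc)].reset_index(drop=True)
        rep["location"] = np.tile(np.arange(n_loc), len(self.trials))
        rep["x_deg"] = np.tile([loc.x for loc in self.grid], len(self.trials))
        rep["y_deg"] = np.tile([loc.y for loc in self.grid], len(self.trials))
        rep["estimate_db"] = self.estimates.ravel()
        rep["presentations"] = self.presentations.ravel()
        return rep

    def to_csv(self, trials_path, estimates_path=None) -> None:
        self.trials.to_csv(trials_path, index=False)
        if estimates_path is not None:
            self.estimates_frame().to_csv(estimates_path, index=False)

    @classmethod
    def from_csv(cls, trials_path, estimates_path, fields, grid: TestGrid | None = None):
        """Rebuild a table from `to_csv` output plus the true fields."""
        grid = grid or build_24_2()
        trials = pd.read_csv(trials_path)
        est_long = pd.read_csv(estimates_path)
        n_loc = len(grid)
        if len(est_long) != len(trials) * n_loc:
            raise ValueError("estimates file does not match trials file / grid size")
        estimates = est_long["estimate_db"].to_numpy().reshape(len(trials), n_loc)
        presentations = est_long["presentations"].to_numpy().reshape(len(trials), n_loc)
        truths = {f.field_id: np.asarray(f.sensitivity) for f in fields}
        labels = {f.field_id: f.label for f in fields}
        missing = set(trials["field_id"]) - set(truths)
        if missing:
            raise ValueError(f"true fields missing for: {sorted(missing)}")
        return cls(trials, estimates, presentations, grid, truths, labels)

    def manifest(self, plan: ExperimentPlan) -> dict:
        return {
            "base_seed": plan.base_seed,
            "strategies": [name for name, _ in plan.strategies],
            "fields": [f.field_id for f in plan.fields],
            "conditions": [c.label for c in plan.conditions],
            "repetitions": plan.repetitions,
            "n_trials": len(self.trials),
        }


def run_experiment(plan: ExperimentPlan, progress=None, grid: TestGrid | None = None) -> ExperimentTable:
    """Execute every scheduled trial and assemble the result table.

    Per-trial failures are recorded with the trial key and re-raised
    together at the end; `progress`, if given, is called with
    (done, total) after each trial.
    """
    grid = grid or (plan.fields[0].grid if plan.fields else build_24_2())
    rows = []
    estimates = []
    presentations = []
    failures = []
    truths = {f.field_id: np.asarray(f.sensitivity) for f in plan.fields}
    labels = {f.field_id: f.label for f in plan.fields}
    total = plan_trial_count(plan) * len(plan.strategies)
    done = 0
    for arm_name, cfg in plan.strategies:
        for fld in plan.fields:
            for cond in plan.conditions:
                obs = plan.observer_base.with_errors(cond.fp, cond.fn)
                for rep in range(plan.repetitions):
                    seed = trial_seed(plan.base_seed, arm_name, fld.field_id, cond.label, rep)
                    key = (arm_name, fld.field_id, cond.label, rep)
                    try:
                        res = run_trial(fld, grid, cfg, obs, seed)
                    except Exception as exc:  # noqa: BLE001 - collected, re-raised
                        failures.append((key, exc))
                        continue
                    rows.append(
                        {
                            "strategy": arm_name,
                            "field_id": fld.field_id,
                            "field_label": fld.label,
                            "condition": cond.label,
                            "fp": cond.fp,
                            "fn": cond.fn,
                            "rep": rep,
                            "total_presentations": res.total_presentations,
                        }
                    )
                    estimates.append(res.estimates)
                    presentations.append(res.presentations + res.verification_presentations)
                    done += 1
                    if progress is not None:
                        progress(done, total)
    table = ExperimentTable(
        trials=pd.DataFrame(rows),
        estimates=np.array(estimates) if estimates else np.empty((0, len(grid))),
        presentations=np.array(presentations) if presentations else np.empty((0, len(grid)), int),
        grid=grid,
        truths=truths,
        field_labels=labels,
    )
    if failures:
        raise ExperimentError(failures)
    return table


def write_manifest(path, plan: ExperimentPlan, table: ExperimentTable) -> None:
    with open(path, "w") as fh:
        json.dump(table.manifest(plan), fh, indent=2)
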
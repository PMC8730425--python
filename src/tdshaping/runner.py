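"""Scenario execution, CSV/JSON trace output, and run summaries.

A run request names a built-in scenario (``fig1``..``fig4``), optionally
overrides its parameters, and points at an output directory.  Executing it
produces:

* ``values.csv`` — per-trial value snapshots of the first run (columns
  ``arm, trial, state_label, value``; trials are 1-based),
* ``deltas.csv`` — per-step prediction errors of the first run (columns
  ``arm, trial, step, from_state, to_state, delta``),
* ``average_values.csv`` — across-run mean values (same schema as values.csv),
* ``scenario.json`` — the problem, potential and configuration actually run,
* ``summary.json`` — final averaged values, analytic targets from the exact
  matrix solution, the worst-state compensation error ``max |(V + phi) - V*|``,
  and the trials-to-90% speed metric.

Every quantity in the summary can be recomputed from the emitted files alone
(:func:`summarize_directory` is that independent reader).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .markov import PredictionProblem, solve_values
from .scenarios import SCENARIO_NAMES, Scenario, get_scenario
from .td import (
    LearningTrace,
    PotentialFunction,
    TDConfig,
    TraceAverager,
    run_experiment,
)

__all__ = [
    "RunRequest",
    "ArmSummary",
    "RunSummary",
    "run_scenario",
    "trials_to_90_percent",
    "compare_runs",
    "summarize_directory",
    "read_values_csv",
]

logger = logging.getLogger(__name__)

#: Targets smaller than this are treated as zero: 90% of nothing is reached
#: immediately, so the speed metric is flagged undefined instead.
_ZERO_TARGET_TOL = 1e-12


@dataclasses.dataclass
class RunRequest:
    """What to run and where to put the outputs.

    ``alpha``, ``trials`` and ``runs`` default to the scenario's own values
    when left as ``None``; ``T`` and ``p`` override the chain geometry.
    """

    scenario: str
    out_dir: Path | str = "."
    alpha: float | None = None
    trials: int | None = None
    runs: int | None = None
    seed: int = 0
    T: int | None = None
    p: float | None = None

    def validate(self) -> None:
        if self.scenario not in SCENARIO_NAMES:
            raise KeyError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIO_NAMES}"
            )
        if self.alpha is not None and not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha override must lie in (0, 1]")
        if self.trials is not None and self.trials < 1:
            raise ValueError("trials override must be at least 1")
        if self.runs is not None and self.runs < 1:
            raise ValueError("runs override must be at least 1")
        if self.T is not None and self.T < 2:
            raise ValueError("T override must be at least 2")
        if self.p is not None and not 0.0 <= self.p <= 1.0:
            raise ValueError("p override must lie in [0, 1]")


@dataclasses.dataclass
class ArmSummary:
    """Summary of one experimental arm (one problem/potential pair)."""

    final_values: dict[str, float]
    targets: dict[str, float]
    max_compensation_error: float
    trials_to_90: int | None
    target_defined: bool
    asymptote_target: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, doc: dict) -> "ArmSummary":
        return cls(**doc)


@dataclasses.dataclass
class RunSummary:
    """Summary of a whole scenario run, derivable from the emitted CSVs."""

    scenario: str
    alpha: float
    n_trials: int
    n_runs: int
    seeds: list[int]
    start_state: int
    arms: dict[str, ArmSummary]

    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        doc["arms"] = {k: v.to_dict() for k, v in self.arms.items()}
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "RunSummary":
        arms = {k: ArmSummary.from_dict(v) for k, v in doc["arms"].items()}
        return cls(**{**doc, "arms": arms})


def trials_to_90_percent(v0_by_trial: np.ndarray, target: float) -> int | None:
    """First (1-based) trial at which the averaged start-state value reaches
    90% of its analytic asymptote; ``None`` (undefined) for a zero target."""
    if abs(target) < _ZERO_TARGET_TOL:
        return None
    sign = 1.0 if target > 0 else -1.0
    hits = np.nonzero(sign * np.asarray(v0_by_trial) >= 0.9 * abs(target))[0]
    return int(hits[0]) + 1 if hits.size else None


def _summarise_arm(
    problem: PredictionProblem,
    phi: PotentialFunction,
    averaged: LearningTrace,
    start_state: int,
) -> ArmSummary:
    targets = solve_values(problem)
    final = averaged.final_values
    comp_err = float(np.max(np.abs(final + phi.phi - targets)))
    target0 = float(targets[start_state])
    labels = averaged.labels
    return ArmSummary(
        final_values={labels[i]: float(final[i]) for i in range(len(labels))},
        targets={labels[i]: float(targets[i]) for i in range(len(labels))},
        max_compensation_error=comp_err,
        trials_to_90=trials_to_90_percent(
            averaged.state_values(start_state), target0
        ),
        target_defined=abs(target0) >= _ZERO_TARGET_TOL,
        asymptote_target=target0,
    )


def run_scenario(request: RunRequest) -> RunSummary:
    """Execute a scenario: run every arm ``runs`` times with seeds ``seed,
    seed + 1, ...``, write the output files, and return the summary."""
    request.validate()
    scenario = get_scenario(request.scenario, p=request.p, T=request.T)
    alpha = scenario.default_alpha if request.alpha is None else request.alpha
    n_trials = scenario.default_trials if request.trials is None else request.trials
    n_runs = scenario.default_runs if request.runs is None else request.runs
    out_dir = Path(request.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not out_dir.is_dir():
        raise NotADirectoryError(f"{out_dir} is not a writable directory")
    seeds = [request.seed + k for k in range(n_runs)]
    logger.info(
        "scenario=%s alpha=%g trials=%d runs=%d seed=%d out=%s",
        scenario.name, alpha, n_trials, n_runs, request.seed, out_dir,
    )
    t0 = time.perf_counter()
    values_frames, deltas_frames, avg_frames = [], [], []
    arms: dict[str, ArmSummary] = {}
    scenario_doc: dict = {
        "scenario": scenario.name,
        "alpha": alpha,
        "n_trials": n_trials,
        "n_runs": n_runs,
        "seeds": seeds,
        "start_state": scenario.start_state,
        "arms": {},
    }
    for arm_name, (problem, phi) in scenario.arms.items():
        averager = TraceAverager()
        first_trace: LearningTrace | None = None
        for seed in seeds:
            cfg = TDConfig(alpha=alpha, n_trials=n_trials, seed=seed)
            trace = run_experiment(
                problem, phi, cfg, scenario.start_state, scenario=scenario.name
            )
            if first_trace is None:
                first_trace = trace
            averager.add(trace)
        averaged = averager.result()
        assert first_trace is not None
        for frames, trace in ((values_frames, first_trace), (avg_frames, averaged)):
            frame = trace.to_values_frame()
            frame.insert(0, "arm", arm_name)
            frames.append(frame)
        dframe = first_trace.to_deltas_frame()
        dframe.insert(0, "arm", arm_name)
        deltas_frames.append(dframe)
        arms[arm_name] = _summarise_arm(problem, phi, averaged, scenario.start_state)
        scenario_doc["arms"][arm_name] = {
            "problem": problem.to_dict(),
            "phi": phi.phi.tolist(),
        }
    summary = RunSummary(
        scenario=scenario.name,
        alpha=alpha,
        n_trials=n_trials,
        n_runs=n_runs,
        seeds=seeds,
        start_state=scenario.start_state,
        arms=arms,
    )
    pd.concat(values_frames).to_csv(out_dir / "values.csv", index=False)
    pd.concat(deltas_frames).to_csv(out_dir / "deltas.csv", index=False)
    pd.concat(avg_frames).to_csv(out_dir / "average_values.csv", index=False)
    (out_dir / "scenario.json").write_text(json.dumps(scenario_doc, indent=2))
    (out_dir / "summary.json").write_text(json.dumps(summary.to_dict(), indent=2))
    logger.info("finished %s in %.2fs", scenario.name, time.perf_counter() - t0)
    return summary


def read_values_csv(path: Path | str) -> dict[str, tuple[tuple[str, ...], np.ndarray]]:
    """Re-parse a values table into per-arm ``(labels, values_by_trial)``
    pairs, inverting :meth:`LearningTrace.to_values_frame` exactly."""
    frame = pd.read_csv(path)
    out: dict[str, tuple[tuple[str, ...], np.ndarray]] = {}
    for arm, group in frame.groupby("arm", sort=False):
        labels = tuple(group["state_label"].unique())
        n_trials = group["trial"].max()
        values = (
            group.pivot(index="trial", columns="state_label", values="value")
            .loc[np.arange(1, n_trials + 1), list(labels)]
            .to_numpy()
        )
        out[str(arm)] = (labels, values)
    return out


def summarize_directory(run_dir: Path | str) -> RunSummary:
    """Recompute a run's summary from its emitted files alone.

    Reads ``average_values.csv`` and ``scenario.json`` (never
    ``summary.json``), re-derives the analytic targets by the matrix solution
    and re-measures the summary quantities; an independent check that the
    stored summary is faithful to the stored traces.
    """
    run_dir = Path(run_dir)
    doc = json.loads((run_dir / "scenario.json").read_text())
    averages = read_values_csv(run_dir / "average_values.csv")
    start_state = int(doc["start_state"])
    arms: dict[str, ArmSummary] = {}
    for arm_name, arm_doc in doc["arms"].items():
        problem = PredictionProblem.from_dict(arm_doc["problem"])
        phi = PotentialFunction(np.asarray(arm_doc["phi"], dtype=float))
        labels, values_by_trial = averages[arm_name]
        trace = LearningTrace(
            values_by_trial=values_by_trial,
            deltas_by_trial=[],
            alpha=float(doc["alpha"]),
            seed=int(doc["seeds"][0]),
            start_state=start_state,
            labels=labels,
            scenario=doc["scenario"],
            n_runs=int(doc["n_runs"]),
        )
        arms[arm_name] = _summarise_arm(problem, phi, trace, start_state)
    return RunSummary(
        scenario=doc["scenario"],
        alpha=float(doc["alpha"]),
        n_trials=int(doc["n_trials"]),
        n_runs=int(doc["n_runs"]),
        seeds=[int(s) for s in doc["seeds"]],
        start_state=start_state,
        arms=arms,
    )


def compare_runs(summaries: Sequence[RunSummary]) -> pd.DataFrame:
    """Order runs by learning speed (trials to 90% of the start-state
    asymptote).

    Returns one row per (scenario, arm) with the asymptote target, the final
    learned start-state value, the speed metric, its rank (ties share a rank
    and are marked), and an ``undefined`` flag for zero-asymptote arms where
    the metric does not exist.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two summaries to compare")
    start_states = {s.start_state for s in summaries}
    if len(start_states) != 1:
        raise ValueError("summaries are incomparable: different start states")
    rows = []
    for s in summaries:
        for arm_name, arm in s.arms.items():
            label = s.scenario if len(s.arms) == 1 else f"{s.scenario}/{arm_name}"
            start_label = list(arm.targets)[s.start_state]
            rows.append(
                {
                    "run": label,
                    "asymptote_target": arm.asymptote_target,
                    "final_value": arm.final_values[start_label],
                    "trials_to_90": arm.trials_to_90,
                    "undefined": not arm.target_defined,
                }
            )
    table = pd.DataFrame(rows)
    defined = table.loc[~table["undefined"], "trials_to_90"].astype(float)
    table["rank"] = defined.rank(method="min").reindex(table.index)
    counts = table.loc[~table["undefined"]].groupby("trials_to_90")["run"].transform("size")
    table["tie"] = counts.reindex(table.index).fillna(1).gt(1) & ~table["undefined"]
    return table.sort_values(
        ["undefined", "trials_to_90"], na_position="last"
    ).reset_index(drop=True)
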
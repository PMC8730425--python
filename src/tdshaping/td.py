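"""Tabular TD(0) value learning with potential-based reward shaping.

The learner estimates the values of an episodic Markov prediction problem
from sampled trajectories.  The shaped prediction error on the transition
``s -> s'`` with reward ``r`` is

    delta = r + [phi(s') - phi(s)] + V(s') - V(s)

with ``phi`` a shaping potential over nonterminal states (the terminal
potential and value are identically 0); with ``phi == 0`` this is the plain
TD(0) error.  Updates are online and undiscounted: ``V(s) <- V(s) + alpha *
delta`` applied in temporal order within each episode, so a delta computed
later in an episode sees values already updated earlier in the same episode.

Because the potential enters only in difference form, its net effect around
any cycle of states is zero, so shaping steers the transient of learning
without moving the asymptote: the across-run mean of ``V + phi`` converges to
the true values, and learning with potential ``phi`` from zero initial values
is step-for-step equivalent to unshaped learning initialised at ``phi``
(Wiewiora's initialization equivalence), which :func:`shaping_as_initialization`
exposes.
"""

from __future__ import annotations

import dataclasses
from bisect import bisect_right
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .markov import (
    TERMINAL,
    DegenerateProblemError,
    PredictionProblem,
    Trajectory,
)

__all__ = [
    "PotentialFunction",
    "TDConfig",
    "TrialDeltas",
    "LearningTrace",
    "td_error",
    "run_trial",
    "run_experiment",
    "average_traces",
    "TraceAverager",
    "run_averaged_experiment",
    "shaping_as_initialization",
]


@dataclasses.dataclass(frozen=True)
class PotentialFunction:
    """Shaping potential ``phi`` over nonterminal states.

    The terminal potential is identically 0 and is not stored; only the
    nonterminal vector is representable, which enforces the invariant by
    construction.
    """

    phi: np.ndarray

    def __post_init__(self) -> None:
        phi = np.atleast_1d(np.asarray(self.phi, dtype=float))
        if phi.ndim != 1:
            raise ValueError("phi must be a vector over nonterminal states")
        if not np.all(np.isfinite(phi)):
            raise ValueError("phi must be finite")
        object.__setattr__(self, "phi", phi)

    @classmethod
    def zeros(cls, n_states: int) -> "PotentialFunction":
        return cls(np.zeros(n_states))

    @property
    def n_states(self) -> int:
        return self.phi.shape[0]

    def __getitem__(self, state: int) -> float:
        """Potential of ``state``; the terminal marker maps to 0."""
        if state == TERMINAL:
            return 0.0
        return float(self.phi[state])

    def is_zero(self) -> bool:
        return bool(np.all(self.phi == 0.0))


@dataclasses.dataclass(frozen=True)
class TDConfig:
    """Learning configuration: rate ``alpha`` in (0, 1], episode count,
    optional initial values (default all-zero) and the RNG seed."""

    alpha: float
    n_trials: int
    initial_values: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if self.n_trials < 1:
            raise ValueError("n_trials must be at least 1")
        if self.initial_values is not None:
            v0 = np.asarray(self.initial_values, dtype=float)
            if v0.ndim != 1 or not np.all(np.isfinite(v0)):
                raise ValueError("initial_values must be a finite vector")
            object.__setattr__(self, "initial_values", v0)

    def resolve_initial_values(self, n_states: int) -> np.ndarray:
        if self.initial_values is None:
            return np.zeros(n_states)
        if self.initial_values.shape != (n_states,):
            raise ValueError(
                f"initial_values has length {self.initial_values.shape[0]}, "
                f"problem has {n_states} states"
            )
        return self.initial_values.copy()


@dataclasses.dataclass(frozen=True)
class TrialDeltas:
    """Prediction errors of one episode, in temporal order.

    ``to_states[t] == TERMINAL`` marks the absorbing transition.
    """

    from_states: np.ndarray
    to_states: np.ndarray
    deltas: np.ndarray


@dataclasses.dataclass
class LearningTrace:
    """Record of one TD run (or the elementwise mean of several).

    ``values_by_trial[k]`` is the full value vector after episode ``k``;
    ``deltas_by_trial[k]`` holds that episode's prediction errors.  Averaged
    traces (``n_runs > 1``) carry per-(trial, step) delta means and the count
    of runs in which each step occurred, instead of per-episode records.
    """

    values_by_trial: np.ndarray
    deltas_by_trial: list[TrialDeltas]
    alpha: float
    seed: int
    start_state: int
    labels: tuple[str, ...]
    scenario: str | None = None
    n_runs: int = 1
    delta_means: np.ndarray | None = None
    delta_counts: np.ndarray | None = None

    @property
    def n_trials(self) -> int:
        return self.values_by_trial.shape[0]

    @property
    def n_states(self) -> int:
        return self.values_by_trial.shape[1]

    @property
    def final_values(self) -> np.ndarray:
        return self.values_by_trial[-1]

    def state_values(self, state: int) -> np.ndarray:
        """Per-trial trajectory of one state's value."""
        return self.values_by_trial[:, state]

    def delta_matrix(self) -> np.ndarray:
        """Deltas as an ``(n_trials, max_steps)`` array, NaN-padded where an
        episode ended before a given within-trial step index."""
        if self.delta_means is not None:
            out = self.delta_means.copy()
            if self.delta_counts is not None:
                out[self.delta_counts == 0] = np.nan
            return out
        width = max((d.deltas.shape[0] for d in self.deltas_by_trial), default=0)
        out = np.full((len(self.deltas_by_trial), width), np.nan)
        for k, d in enumerate(self.deltas_by_trial):
            out[k, : d.deltas.shape[0]] = d.deltas
        return out

    # -- tabular export (trial indices are 1-based in the tables) ----------

    def to_values_frame(self) -> pd.DataFrame:
        n_trials, n_states = self.values_by_trial.shape
        return pd.DataFrame(
            {
                "trial": np.repeat(np.arange(1, n_trials + 1), n_states),
                "state_label": list(self.labels) * n_trials,
                "value": self.values_by_trial.ravel(),
            }
        )

    def to_deltas_frame(self) -> pd.DataFrame:
        rows: dict[str, list] = {
            "trial": [],
            "step": [],
            "from_state": [],
            "to_state": [],
            "delta": [],
        }
        if self.deltas_by_trial:
            for k, d in enumerate(self.deltas_by_trial, start=1):
                m = d.deltas.shape[0]
                rows["trial"].extend([k] * m)
                rows["step"].extend(range(m))
                rows["from_state"].extend(self.labels[s] for s in d.from_states)
                rows["to_state"].extend(
                    "terminal" if s == TERMINAL else self.labels[s] for s in d.to_states
                )
                rows["delta"].extend(d.deltas.tolist())
        else:  # averaged trace: step means, no state identity across runs
            mat, counts = self.delta_means, self.delta_counts
            if mat is not None:
                for k in range(mat.shape[0]):
                    for t in range(mat.shape[1]):
                        if counts is not None and counts[k, t] == 0:
                            continue
                        rows["trial"].append(k + 1)
                        rows["step"].append(t)
                        rows["from_state"].append("")
                        rows["to_state"].append("")
                        rows["delta"].append(mat[k, t])
        return pd.DataFrame(rows)

    def metadata(self) -> dict:
        return {
            "scenario": self.scenario,
            "alpha": self.alpha,
            "seed": self.seed,
            "n_trials": self.n_trials,
            "n_runs": self.n_runs,
            "start_state": self.start_state,
            "labels": list(self.labels),
        }


def td_error(
    reward: float,
    phi_from: float,
    phi_to: float,
    v_from: float,
    v_to: float,
) -> float:
    """Shaped TD(0) prediction error for a single transition.

    For a transition into the terminal state pass ``phi_to = 0`` and
    ``v_to = 0``.
    """
    return reward + (phi_to - phi_from) + v_to - v_from


def run_trial(
    values: np.ndarray,
    trajectory: Trajectory,
    phi: PotentialFunction,
    alpha: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one episode of online TD updates along a sampled trajectory.

    Walks the trajectory in temporal order; each delta is computed from the
    *current* values (including updates made earlier in this same episode) and
    immediately applied to the source state.  Returns the updated values
    (a copy) and the ordered delta sequence.  The terminal state is never
    updated.
    """
    values = np.asarray(values, dtype=float).copy()
    if phi.n_states != values.shape[0]:
        raise ValueError("phi and values disagree on the number of states")
    deltas = np.empty(trajectory.n_steps)
    for t in range(trajectory.n_steps):
        s = trajectory.states[t]
        nxt = trajectory.states[t + 1]
        v_to = 0.0 if nxt == TERMINAL else float(values[nxt])
        d = td_error(trajectory.rewards[t], phi[s], phi[nxt], float(values[s]), v_to)
        values[s] += alpha * d
        deltas[t] = d
    return values, deltas


def run_experiment(
    problem: PredictionProblem,
    phi: PotentialFunction,
    config: TDConfig,
    start_state: int = 0,
    scenario: str | None = None,
) -> LearningTrace:
    """Run ``config.n_trials`` episodes of shaped TD learning on ``problem``.

    Each episode is sampled from the run's random stream and learned online
    (equivalent to :func:`markov.sample_trajectory` followed by
    :func:`run_trial`, fused into one pass over the episode); the returned
    trace holds a post-episode value snapshot and the delta sequence of every
    trial.  Bit-reproducible given ``config.seed``.
    """
    n = problem.n_states
    if phi.n_states != n:
        raise ValueError("phi and problem disagree on the number of states")
    if not 0 <= start_state < n:
        raise ValueError(f"start_state {start_state} out of range")
    rng = np.random.default_rng(config.seed)
    values = config.resolve_initial_values(n).tolist()
    phi_l = phi.phi.tolist()
    trans = problem.transitions
    cum_rows = np.cumsum(trans, axis=1).tolist()
    rewards = problem.transition_rewards.tolist()
    term_rewards = problem.terminal_rewards.tolist()
    # Per-state dispatch: TERMINAL for certain absorption, a successor index
    # for a deterministic move (neither consumes the random stream), or None.
    det_next: list[int | None] = []
    for s in range(n):
        row_total = cum_rows[s][-1]
        if row_total <= 0.0:
            det_next.append(TERMINAL)
        elif row_total >= 1.0 and np.count_nonzero(trans[s]) == 1:
            det_next.append(int(np.argmax(trans[s])))
        else:
            det_next.append(None)
    alpha = config.alpha
    step_cap = problem.step_cap
    random = rng.random
    snapshots = np.empty((config.n_trials, n))
    deltas_by_trial: list[TrialDeltas] = []
    for trial in range(config.n_trials):
        s = start_state
        froms: list[int] = []
        tos: list[int] = []
        ds: list[float] = []
        for _ in range(step_cap):
            nxt = det_next[s]
            if nxt is None:
                row = cum_rows[s]
                u = random()
                nxt = TERMINAL if u >= row[-1] else bisect_right(row, u)
            if nxt == TERMINAL:
                d = term_rewards[s] - phi_l[s] - values[s]
            else:
                d = rewards[s][nxt] + phi_l[nxt] - phi_l[s] + values[nxt] - values[s]
            values[s] += alpha * d
            froms.append(s)
            tos.append(nxt)
            ds.append(d)
            if nxt == TERMINAL:
                break
            s = nxt
        else:
            raise DegenerateProblemError(
                f"episode exceeded {step_cap} steps; problem appears non-absorbing"
            )
        snapshots[trial] = values
        deltas_by_trial.append(
            TrialDeltas(
                from_states=np.asarray(froms, dtype=np.int64),
                to_states=np.asarray(tos, dtype=np.int64),
                deltas=np.asarray(ds),
            )
        )
    return LearningTrace(
        values_by_trial=snapshots,
        deltas_by_trial=deltas_by_trial,
        alpha=alpha,
        seed=config.seed,
        start_state=start_state,
        labels=problem.state_labels,
        scenario=scenario,
    )


class TraceAverager:
    """Streaming elementwise mean of learning traces.

    Values are averaged per (trial, state); deltas per (trial, within-trial
    step index), counting only the runs in which that step occurred.  Lets
    many-run averages be computed without holding every trace in memory.
    """

    def __init__(self) -> None:
        self._n = 0
        self._template: LearningTrace | None = None
        self._value_sum: np.ndarray | None = None
        self._delta_sum = np.empty((0, 0))
        self._delta_count = np.empty((0, 0), dtype=np.int64)

    def add(self, trace: LearningTrace) -> None:
        if self._template is None:
            self._template = trace
            self._value_sum = np.zeros_like(trace.values_by_trial)
        else:
            t = self._template
            if (
                trace.values_by_trial.shape != t.values_by_trial.shape
                or trace.scenario != t.scenario
                or trace.start_state != t.start_state
            ):
                raise ValueError("traces to average must share scenario and shape")
        self._value_sum += trace.values_by_trial
        mat = trace.delta_matrix()
        occupied = ~np.isnan(mat)
        if mat.shape[1] > self._delta_sum.shape[1] or self._delta_sum.shape[0] == 0:
            new_shape = (mat.shape[0], max(mat.shape[1], self._delta_sum.shape[1]))
            for name in ("_delta_sum", "_delta_count"):
                old = getattr(self, name)
                grown = np.zeros(new_shape, dtype=old.dtype)
                grown[: old.shape[0], : old.shape[1]] = old
                setattr(self, name, grown)
        w = mat.shape[1]
        self._delta_sum[:, :w][occupied] += mat[occupied]
        self._delta_count[:, :w][occupied] += 1
        self._n += 1

    def result(self) -> LearningTrace:
        if self._template is None or self._value_sum is None:
            raise ValueError("no traces to average")
        counts = self._delta_count
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0, self._delta_sum / np.maximum(counts, 1), np.nan)
        t = self._template
        return LearningTrace(
            values_by_trial=self._value_sum / self._n,
            deltas_by_trial=[],
            alpha=t.alpha,
            seed=t.seed,
            start_state=t.start_state,
            labels=t.labels,
            scenario=t.scenario,
            n_runs=self._n,
            delta_means=means,
            delta_counts=counts,
        )


def average_traces(traces: Sequence[LearningTrace] | Iterable[LearningTrace]) -> LearningTrace:
    """Elementwise mean of traces sharing a scenario, trial count and state
    count (their seeds differ); delta steps are aligned by within-trial time
    index, averaging only over runs in which the step occurred."""
    avg = TraceAverager()
    for trace in traces:
        avg.add(trace)
    return avg.result()


def run_averaged_experiment(
    problem: PredictionProblem,
    phi: PotentialFunction,
    config: TDConfig,
    n_runs: int,
    start_state: int = 0,
    scenario: str | None = None,
) -> LearningTrace:
    """Across-run mean trace of ``n_runs`` independent experiments with seeds
    ``config.seed, config.seed + 1, ...`` (streamed, one run in memory at a
    time)."""
    if n_runs < 1:
        raise ValueError("n_runs must be at least 1")
    avg = TraceAverager()
    for k in range(n_runs):
        cfg = dataclasses.replace(config, seed=config.seed + k)
        avg.add(run_experiment(problem, phi, cfg, start_state, scenario))
    return avg.result()


def shaping_as_initialization(
    problem: PredictionProblem,
    phi: PotentialFunction,
    config: TDConfig,
) -> TDConfig:
    """Config for the unshaped run equivalent to shaping with ``phi``: same
    settings, initial values set to ``phi`` (for use with a zero potential)."""
    if phi.n_states != problem.n_states:
        raise ValueError("phi and problem disagree on the number of states")
    if phi.is_zero():
        return config
    return dataclasses.replace(config, initial_values=phi.phi.copy())
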
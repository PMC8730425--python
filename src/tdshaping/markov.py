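"""Episodic Markov reward processes and exact / Monte-Carlo value solutions.

The processes modelled here are undiscounted and absorbing: a set of
nonterminal states, an implicit terminal state ``s*``, a transition matrix
``T`` restricted to nonterminal pairs (the probability mass missing from each
row goes to ``s*``), and rewards attached to transitions, delivered on arrival
at the destination state.  The value of a state is the expected total reward
collected on the transitions taken from that state until absorption, so the
terminal value is identically 0 and ``V = (I - T)^{-1} r`` with ``r`` the
one-step expected reward vector.

The matrix solution (:func:`solve_values`) and the sampling estimate
(:func:`monte_carlo_values`) are deliberately independent routes to the same
quantity; the latter serves as an oracle for the former and for the asymptotes
of temporal-difference learning.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "TERMINAL",
    "DegenerateProblemError",
    "PredictionProblem",
    "Trajectory",
    "expected_immediate_reward",
    "solve_values",
    "monte_carlo_values",
    "sample_trajectory",
    "generate_random_problem",
]

#: Sentinel index for the terminal state in trajectories.
TERMINAL: int = -1

_ROW_TOL = 1e-9
#: Runaway guard for episode sampling: generous multiple of any plausible
#: absorption time for a valid (absorbing) problem.
_STEP_CAP_PER_STATE = 10_000


class DegenerateProblemError(ValueError):
    """Raised when a problem is not absorbing (terminal state unreachable)."""


@dataclasses.dataclass(frozen=True)
class PredictionProblem:
    """An episodic Markov reward process over nonterminal states.

    Parameters
    ----------
    transitions
        ``(n, n)`` matrix with ``transitions[s, s']`` the probability of
        moving from nonterminal state ``s`` to nonterminal state ``s'``.
        Row sums must lie in ``[0, 1]``; the remainder of each row is the
        probability of absorbing into the terminal state.
    transition_rewards
        ``(n, n)`` matrix of rewards delivered on the transition ``s -> s'``
        (received on arrival at ``s'``).
    terminal_rewards
        Length-``n`` vector of rewards delivered on the transition from each
        state directly to the terminal state.
    labels
        Optional per-state names (defaults to ``s0, s1, ...``).
    """

    transitions: np.ndarray
    transition_rewards: np.ndarray
    terminal_rewards: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        T = np.atleast_2d(np.asarray(self.transitions, dtype=float))
        R = np.atleast_2d(np.asarray(self.transition_rewards, dtype=float))
        r_term = np.atleast_1d(np.asarray(self.terminal_rewards, dtype=float))
        n = T.shape[0]
        if T.shape != (n, n):
            raise ValueError(f"transitions must be square, got {T.shape}")
        if R.shape != (n, n):
            raise ValueError(
                f"transition_rewards must match transitions, got {R.shape}"
            )
        if r_term.shape != (n,):
            raise ValueError(f"terminal_rewards must have length {n}")
        if np.any(T < -_ROW_TOL) or np.any(T > 1 + _ROW_TOL):
            raise ValueError("transition probabilities must lie in [0, 1]")
        row_sums = T.sum(axis=1)
        if np.any(row_sums > 1 + _ROW_TOL):
            raise ValueError("transition rows must sum to at most 1")
        if not (np.all(np.isfinite(R)) and np.all(np.isfinite(r_term))):
            raise ValueError("all rewards must be finite")
        # Absorption with probability one <=> spectral radius of T below 1.
        if n > 0 and np.max(np.abs(np.linalg.eigvals(T))) >= 1 - 1e-9:
            raise DegenerateProblemError(
                "terminal state is not reached with probability 1 "
                "(spectral radius of the transition matrix is not < 1)"
            )
        labels = self.labels
        if labels is not None:
            labels = tuple(str(x) for x in labels)
            if len(labels) != n:
                raise ValueError(f"labels must have length {n}")
        object.__setattr__(self, "transitions", T)
        object.__setattr__(self, "transition_rewards", R)
        object.__setattr__(self, "terminal_rewards", r_term)
        object.__setattr__(self, "labels", labels)

    @property
    def n_states(self) -> int:
        return self.transitions.shape[0]

    @property
    def termination(self) -> np.ndarray:
        """Per-state probability of absorbing into the terminal state."""
        return np.clip(1.0 - self.transitions.sum(axis=1), 0.0, 1.0)

    @property
    def state_labels(self) -> tuple[str, ...]:
        if self.labels is not None:
            return self.labels
        return tuple(f"s{i}" for i in range(self.n_states))

    @property
    def step_cap(self) -> int:
        return _STEP_CAP_PER_STATE * max(self.n_states, 1)

    # -- JSON round-trip ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_states": self.n_states,
            "transitions": self.transitions.tolist(),
            "transition_rewards": self.transition_rewards.tolist(),
            "terminal_rewards": self.terminal_rewards.tolist(),
            "labels": list(self.state_labels),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "PredictionProblem":
        problem = cls(
            transitions=np.asarray(doc["transitions"], dtype=float),
            transition_rewards=np.asarray(doc["transition_rewards"], dtype=float),
            terminal_rewards=np.asarray(doc["terminal_rewards"], dtype=float),
            labels=tuple(doc["labels"]) if doc.get("labels") else None,
        )
        if "n_states" in doc and int(doc["n_states"]) != problem.n_states:
            raise ValueError("n_states does not match the transition matrix")
        return problem

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PredictionProblem":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))


@dataclasses.dataclass(frozen=True)
class Trajectory:
    """One sampled episode: visited states (ending in ``TERMINAL``) and the
    reward received on each transition.

    ``states`` has one more element than ``rewards`` is short by: with ``k``
    nonterminal states visited, ``states`` has length ``k + 1`` (the terminal
    marker closes it) and ``rewards`` has length ``k`` (one reward per
    transition, counting the arrival at the terminal state).
    """

    states: tuple[int, ...]
    rewards: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.states) < 2 or self.states[-1] != TERMINAL:
            raise ValueError("trajectory must end with the terminal marker")
        if any(s == TERMINAL for s in self.states[:-1]):
            raise ValueError("terminal marker may only appear last")
        if len(self.rewards) != len(self.states) - 1:
            raise ValueError("need exactly one reward per transition")

    @property
    def n_steps(self) -> int:
        return len(self.rewards)

    @property
    def total_reward(self) -> float:
        return float(sum(self.rewards))


def expected_immediate_reward(problem: PredictionProblem) -> np.ndarray:
    """One-step expected reward ``r[s] = E[reward on the transition out of s]``.

    Maps the per-transition reward convention onto the per-state reward vector
    of the value recursion: ``r[s] = sum_s' T[s,s'] R[s,s'] + term[s] R_term[s]``.
    """
    return (
        (problem.transitions * problem.transition_rewards).sum(axis=1)
        + problem.termination * problem.terminal_rewards
    )


def solve_values(problem: PredictionProblem) -> np.ndarray:
    """Exact state values ``V = (I - T)^{-1} r`` of the undiscounted episodic
    recursion ``V = r + T V``.

    ``V[s]`` is the expected total reward collected on transitions taken from
    ``s`` until absorption.  Raises :class:`DegenerateProblemError` if the
    linear solve fails (non-absorbing chain).
    """
    n = problem.n_states
    r = expected_immediate_reward(problem)
    try:
        return np.linalg.solve(np.eye(n) - problem.transitions, r)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded upstream
        raise DegenerateProblemError("I - T is singular") from exc


def sample_trajectory(
    problem: PredictionProblem,
    start_state: int,
    rng: np.random.Generator,
) -> Trajectory:
    """Sample one episode from ``start_state`` until absorption.

    Consumes the supplied random stream deterministically: one uniform draw per
    visited state whose outgoing distribution is non-degenerate (deterministic
    successors take no draw).
    """
    n = problem.n_states
    if not 0 <= start_state < n:
        raise ValueError(f"start_state {start_state} out of range")
    cum = np.cumsum(problem.transitions, axis=1)
    states = [start_state]
    rewards: list[float] = []
    s = start_state
    for _ in range(problem.step_cap):
        row_total = cum[s, -1] if n else 0.0
        if row_total <= 0.0:
            nxt = TERMINAL
        elif row_total >= 1.0 and np.count_nonzero(problem.transitions[s]) == 1:
            nxt = int(np.argmax(problem.transitions[s]))
        else:
            u = rng.random()
            nxt = TERMINAL if u >= row_total else int(np.searchsorted(cum[s], u, side="right"))
        if nxt == TERMINAL:
            rewards.append(float(problem.terminal_rewards[s]))
            states.append(TERMINAL)
            return Trajectory(tuple(states), tuple(rewards))
        rewards.append(float(problem.transition_rewards[s, nxt]))
        states.append(nxt)
        s = nxt
    raise DegenerateProblemError(
        f"episode exceeded {problem.step_cap} steps; problem appears non-absorbing"
    )


def monte_carlo_values(
    problem: PredictionProblem,
    n_episodes: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Sampling estimate of the state values, with standard errors.

    For every start state, averages the total episode reward over
    ``n_episodes`` independently sampled episodes.  Returns ``(values,
    standard_errors)``; reproducible given ``seed``.
    """
    if n_episodes < 1:
        raise ValueError("n_episodes must be at least 1")
    rng = np.random.default_rng(seed)
    n = problem.n_states
    values = np.empty(n)
    stderr = np.empty(n)
    for s in range(n):
        totals = np.fromiter(
            (sample_trajectory(problem, s, rng).total_reward for _ in range(n_episodes)),
            dtype=float,
            count=n_episodes,
        )
        values[s] = totals.mean()
        stderr[s] = totals.std(ddof=1) / np.sqrt(n_episodes) if n_episodes > 1 else 0.0
    return values, stderr


def generate_random_problem(
    n_states: int,
    seed: int,
    min_termination: float = 0.05,
    max_reward: float = 1.0,
) -> PredictionProblem:
    """Random absorbing problem for property tests.

    Every state terminates with probability at least ``min_termination`` (so
    absorption is certain); transition and terminal rewards are drawn
    uniformly in ``[-max_reward, max_reward]``.  Reproducible given ``seed``.
    """
    if n_states < 1:
        raise ValueError("n_states must be at least 1")
    if not min_termination > 0:
        raise ValueError("min_termination must be positive")
    rng = np.random.default_rng(seed)
    raw = rng.random((n_states, n_states))
    termination = rng.uniform(min_termination, 1.0, size=n_states)
    T = raw / raw.sum(axis=1, keepdims=True) * (1.0 - termination)[:, None]
    return PredictionProblem(
        transitions=T,
        transition_rewards=rng.uniform(-max_reward, max_reward, (n_states, n_states)),
        terminal_rewards=rng.uniform(-max_reward, max_reward, n_states),
    )
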
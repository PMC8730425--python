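"""Built-in experiments: branching chains and flavour–nutrient conditioning.

Four canonical settings are provided, all built on the same chain topology:
a start state ``s0`` that either absorbs immediately (probability ``1 - p``)
or enters a serial chain ``s1 -> s2 -> ... -> sT -> terminal`` — a complete
serial compound representation in which every time step after the triggering
event (the "morsel of food") is a distinct state.

* ``fig1`` — the unshaped chain: ``p = 0.3``, ``T = 10``, unit reward on
  arrival at ``sT`` (the delayed "digestive" report).  Learning is slow: the
  reward must propagate backwards one state per chain visit.
* ``fig2`` — the same chain with the ideal hedonic potential (1 on
  ``s1..s(T-1)``, 0 at ``sT``): the "taste" signal announces the delayed
  reward the moment the chain is entered, so within-chain prediction errors
  vanish from trial one and the start-state value is acquired much faster.
* ``fig3`` — a partial potential that decays linearly from 1 to 0 along a
  ``T = 15`` chain, with the unit reward spread equally over the last five
  arrivals: the premature decay of the hedonic signal transiently suppresses
  the start-state value before the true reward propagates back and restores it.
* ``fig4`` — flavour–nutrient conditioning: three deterministic chains whose
  orosensory ("liking", the potential level) and nutritive ("wanting", the
  terminal reward) qualities are orthogonalised — red (phi 0, reward 2),
  green (phi 2, reward 0), blue (phi 1, reward 1) — learned at ``alpha = 0.4``.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from .markov import PredictionProblem
from .td import LearningTrace, PotentialFunction, TDConfig, run_experiment

__all__ = [
    "ChainSpec",
    "FlavourSpec",
    "Scenario",
    "build_chain",
    "perfect_shaping",
    "linear_decay_shaping",
    "build_flavour_problem",
    "run_flavour_experiment",
    "STANDARD_FLAVOURS",
    "SCENARIO_NAMES",
    "get_scenario",
]


@dataclasses.dataclass(frozen=True)
class ChainSpec:
    """Branching serial chain: from ``s0``, enter ``s1`` with probability
    ``p`` (absorb otherwise), then advance deterministically to ``sT``.

    ``reward_schedule`` maps an arrival-state index ``tau`` (1-based, in
    ``1..T``) to the reward delivered on the transition *into* ``s_tau``.
    """

    p: float
    T: int
    reward_schedule: Mapping[int, float]
    label: str = "chain"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if self.T < 1:
            raise ValueError("T must be at least 1")
        for tau, r in self.reward_schedule.items():
            if not 1 <= tau <= self.T:
                raise ValueError(f"schedule key {tau} outside 1..{self.T}")
            if not np.isfinite(r):
                raise ValueError("schedule rewards must be finite")
        object.__setattr__(self, "reward_schedule", dict(self.reward_schedule))

    @property
    def total_reward(self) -> float:
        return float(sum(self.reward_schedule.values()))


@dataclasses.dataclass(frozen=True)
class FlavourSpec:
    """One flavour in the conditioning paradigm: an orosensory potential level
    held on the post-ingestion states and a nutritive reward delivered at the
    end of the (deterministic) chain."""

    name: str
    phi_level: float
    nutritive_reward: float
    T: int = 10

    def __post_init__(self) -> None:
        if self.T < 2:
            raise ValueError("T must be at least 2")
        if not (np.isfinite(self.phi_level) and np.isfinite(self.nutritive_reward)):
            raise ValueError("phi_level and nutritive_reward must be finite")


#: The three flavours with orthogonalised sweetness and nutritive value.
STANDARD_FLAVOURS: tuple[FlavourSpec, ...] = (
    FlavourSpec("red", phi_level=0.0, nutritive_reward=2.0),
    FlavourSpec("green", phi_level=2.0, nutritive_reward=0.0),
    FlavourSpec("blue", phi_level=1.0, nutritive_reward=1.0),
)


def build_chain(spec: ChainSpec) -> PredictionProblem:
    """Materialise a :class:`ChainSpec` as a prediction problem with
    ``T + 1`` nonterminal states ``s0 .. sT``."""
    n = spec.T + 1
    trans = np.zeros((n, n))
    rewards = np.zeros((n, n))
    trans[0, 1] = spec.p
    for tau in range(1, spec.T):
        trans[tau, tau + 1] = 1.0
    for tau, r in spec.reward_schedule.items():
        rewards[tau - 1, tau] = r
    return PredictionProblem(
        transitions=trans,
        transition_rewards=rewards,
        terminal_rewards=np.zeros(n),
        labels=tuple(f"s{i}" for i in range(n)),
    )


def perfect_shaping(T: int, level: float = 1.0) -> PotentialFunction:
    """Ideal potential for a length-``T`` chain with reward on arrival at
    ``sT``: ``level`` on ``s1 .. s(T-1)``, zero at ``s0`` and ``sT``.

    The potential steps up on entering the chain (announcing the delayed
    reward) and steps down exactly where the reward arrives, so every shaped
    within-chain prediction error is zero from the first trial.
    """
    if T < 2:
        raise ValueError("T must be at least 2")
    phi = np.zeros(T + 1)
    phi[1:T] = level
    return PotentialFunction(phi)


def linear_decay_shaping(T: int) -> PotentialFunction:
    """Partial potential that decays linearly along the chain:
    ``phi[s_tau] = 1 - (tau - 1) / (T - 1)`` for ``tau = 1..T`` (1 at ``s1``,
    0 at ``sT``), zero at ``s0`` — a hedonic signal that fades before the
    delayed reward is reported."""
    if T < 2:
        raise ValueError("T must be at least 2")
    phi = np.zeros(T + 1)
    tau = np.arange(1, T + 1)
    phi[1:] = 1.0 - (tau - 1) / (T - 1)
    return PotentialFunction(phi)


def build_flavour_problem(spec: FlavourSpec) -> tuple[PredictionProblem, PotentialFunction]:
    """Deterministic chain for one flavour plus its orosensory potential.

    The chain is entered with certainty (``p = 1``); the nutritive reward is
    delivered on arrival at ``sT``; the potential sits at ``spec.phi_level``
    on ``s1 .. s(T-1)`` and at zero on ``s0`` and ``sT``.
    """
    problem = build_chain(
        ChainSpec(
            p=1.0,
            T=spec.T,
            reward_schedule={spec.T: spec.nutritive_reward},
            label=spec.name,
        )
    )
    return problem, perfect_shaping(spec.T, level=spec.phi_level)


def run_flavour_experiment(
    specs: Sequence[FlavourSpec] = STANDARD_FLAVOURS,
    config: TDConfig | None = None,
) -> dict[str, LearningTrace]:
    """Learn each flavour independently and return its trace.

    The learned "flavour value" is the start-state value ``V[s0]`` (read it
    off a trace with ``trace.state_values(0)``): the value assigned to the
    flavour before any within-episode hedonic increment.  With deterministic
    chains the outcome does not depend on the seed.
    """
    if config is None:
        config = TDConfig(alpha=0.4, n_trials=1000)
    traces: dict[str, LearningTrace] = {}
    for spec in specs:
        problem, phi = build_flavour_problem(spec)
        traces[spec.name] = run_experiment(
            problem, phi, config, start_state=0, scenario=spec.name
        )
    return traces


# ---------------------------------------------------------------------------
# Scenario registry (drives the CLI and the experiment runner)


@dataclasses.dataclass(frozen=True)
class Scenario:
    """A named, ready-to-run experiment: one or more (problem, potential)
    pairs with the default learning configuration."""

    name: str
    arms: dict[str, tuple[PredictionProblem, PotentialFunction]]
    default_alpha: float
    default_trials: int
    default_runs: int
    start_state: int = 0

    def default_config(self, seed: int = 0) -> TDConfig:
        return TDConfig(alpha=self.default_alpha, n_trials=self.default_trials, seed=seed)


def _fig1_arm(p: float, T: int) -> tuple[PredictionProblem, PotentialFunction]:
    problem = build_chain(ChainSpec(p=p, T=T, reward_schedule={T: 1.0}, label="fig1"))
    return problem, PotentialFunction.zeros(T + 1)


def _fig3_arm(p: float, T: int) -> tuple[PredictionProblem, PotentialFunction]:
    # Total unit reward spread equally over the last five arrivals.
    schedule = {tau: 0.2 for tau in range(T - 4, T + 1)}
    problem = build_chain(ChainSpec(p=p, T=T, reward_schedule=schedule, label="fig3"))
    return problem, linear_decay_shaping(T)


def get_scenario(name: str, p: float | None = None, T: int | None = None) -> Scenario:
    """Look up a built-in scenario by name (``fig1 | fig2 | fig3 | fig4``),
    optionally overriding the branch probability ``p`` or chain length ``T``."""
    if name == "fig1":
        problem, phi = _fig1_arm(0.3 if p is None else p, 10 if T is None else T)
        return Scenario(name, {"chain": (problem, phi)}, 0.1, 3000, 1000)
    if name == "fig2":
        T_ = 10 if T is None else T
        problem, _ = _fig1_arm(0.3 if p is None else p, T_)
        return Scenario(name, {"chain": (problem, perfect_shaping(T_))}, 0.1, 3000, 1000)
    if name == "fig3":
        problem, phi = _fig3_arm(0.3 if p is None else p, 15 if T is None else T)
        return Scenario(name, {"chain": (problem, phi)}, 0.1, 3000, 1000)
    if name == "fig4":
        if p is not None:
            raise ValueError("fig4 transitions are deterministic; p cannot be overridden")
        arms = {
            spec.name: build_flavour_problem(
                spec if T is None else dataclasses.replace(spec, T=T)
            )
            for spec in STANDARD_FLAVOURS
        }
        return Scenario("fig4", arms, 0.4, 1000, 1)
    raise KeyError(f"unknown scenario {name!r}; expected one of {sorted(SCENARIO_NAMES)}")


SCENARIO_NAMES: tuple[str, ...] = ("fig1", "fig2", "fig3", "fig4")
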
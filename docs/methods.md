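# Methods

## Model

The simulator works with undiscounted, absorbing Markov prediction problems.
A problem is a set of `n` nonterminal states, a substochastic transition
matrix `T` over those states (row deficits absorb into an implicit terminal
state `s*`), a matrix `R` of per-transition rewards plus a vector `R*` of
rewards on direct absorption, and optional state labels. Validity requires
row sums in `[0, 1]`, finite rewards, and a spectral radius of `T` strictly
below 1, which guarantees absorption with probability one and makes `I − T`
invertible.

**Reward convention.** Rewards attach to transitions and are received on
arrival at the destination; the value of a state is the expected total reward
collected strictly after leaving it, so the terminal value is identically 0
and `V = (I − T)⁻¹ r` with `r_s = Σ_s' T_ss' R_ss' + T̃_s R*_s`. This
convention is what makes the package's quantitative claims consistent with
each other: the branching chain's start-state value equals `p`, the ideal
potential silences all post-ingestion learning (those values stay exactly 0),
and `V + φ` converges to the true long-run reward. The alternative
convention, in which a state's own reward is included in its value, breaks
the second of these and is not implemented.

**Learning.** Tabular TD(0) with a fixed learning rate `α ∈ (0, 1]`, no
discounting, no eligibility traces, and online within-episode updates: each
prediction error uses the values as they stand at that step, including
updates made earlier in the same episode. The within-trial order is applied
forwards in time (standard TD(0) practice). The shaped error on a transition
`s → s'` with reward `r` is `δ = r + [φ(s') − φ(s)] + V(s') − V(s)`, with
`φ(s*) = V(s*) = 0`. Initial values default to zero — the shaping story
presumes the successor's value has not yet been learned.

`run_experiment` fuses episode sampling and learning into one pass for speed;
the fused loop consumes the random stream exactly as `sample_trajectory`
followed by `run_trial` would (deterministic successors take no draw), and a
test asserts step-for-step identity between the two routes.

## Shaping invariants

Three properties anchor the implementation and are tested directly:

* **Cycle neutrality** — potential differences telescope, so their sum around
  any ordered cycle is zero; shaping cannot move the asymptote.
* **Initialization equivalence** — on identical trajectory streams,
  `V_shaped(s) + φ(s) = V_init(s)` after every update, where the second
  learner is unshaped but starts at `φ`. The two update forms associate
  floating-point operations differently, so equality is asserted to `1e−10`,
  not bitwise.
* **Asymptotic compensation** — the across-run mean of `V + φ` approaches the
  exact matrix solution: whatever the potential gets wrong, learning pays
  back.

## Scenarios and their parameters

All four built-in experiments share one topology: a start state `s0` that
either absorbs (probability `1 − p`) or enters a serial chain
`s1 → … → sT → s*`, a complete serial compound representation of the
post-ingestion interval.

| scenario | p | T | reward schedule | potential | α | trials | runs |
|---|---|---|---|---|---|---|---|
| fig1 | 0.3 | 10 | 1 on arrival at s10 | none | 0.1 | 3,000 | 1,000 |
| fig2 | 0.3 | 10 | 1 on arrival at s10 | 1 on s1..s9, 0 at s10 | 0.1 | 3,000 | 1,000 |
| fig3 | 0.3 | 15 | 0.2 on each of s11..s15 | linear 1→0 over s1..s15 | 0.1 | 3,000 | 1,000 |
| fig4 | 1.0 | 10 | flavour reward at s10 | flavour level on s1..s9 | 0.4 | 1,000 | 1 |

Choices the scenario definitions had to make:

* The fig3 unit reward is split equally (0.2 × 5) over the last five
  arrivals; the split's weighting is otherwise unconstrained, and equal
  weights are the neutral choice.
* The fig3 potential decays linearly from `φ(s1) = 1` to `φ(sT) = 0` with
  equal steps of `1/(T−1)`, continuing through the reward-delivery window;
  only the endpoints are pinned down, and a single linear ramp is the
  simplest curve through them.
* The fig4 chains reuse `T = 10` for consistency with figs 1–2; the flavour
  value reported per trial is `V(s0)`, the value held before any
  within-episode hedonic increment — this choice reproduces the intended
  asymptotes (green → 0, red → 2, blue → 1) and the green early peak.
* Trial counts per scenario are conventions (3,000 at α = 0.1 leaves the
  slowest scenario's averaged values within a few hundredths of their
  asymptotes; 1,000 at α = 0.4 converges the deterministic flavours to
  machine precision); averaged curves use 1,000 runs with seeds
  `seed, seed+1, …` fanned out per run.

## Numerical choices

* Exact values come from `numpy.linalg.solve` on `I − T`; a singular system
  raises a degenerate-problem error rather than returning garbage.
* With a fixed (non-decaying) α the values fluctuate forever at the stochastic
  branch, so convergence claims are stated for across-run means with
  tolerances: 0.05 for stochastic scenarios at 1,000 runs (residual
  fluctuation of the mean scales with `α` and branch variance), `1e−3` after
  1,000 trials for deterministic scenarios.
* Episode sampling carries a runaway guard of `10,000 × n` steps; exceeding
  it reports a non-absorbing problem. The random-problem generator enforces a
  minimum termination probability (default 0.05) so absorption is certain by
  construction.
* Trace averaging aligns prediction errors by within-trial step index; runs
  whose episode ended before a given index contribute nothing at that index.
  Averaged traces therefore store per-(trial, step) means and occurrence
  counts. Note the averager stores the *signed* mean of δ; quantities like
  the asymptotic mean |δ| are accumulated from individual runs, since at the
  stochastic branch positive and negative errors cancel in the signed mean.
* The trials-to-90% speed metric is the first trial at which the across-run
  mean of `V(s0)` reaches 90% of its analytic target; for a zero target the
  metric is undefined and flagged as such rather than reported as 0.
* Problems round-trip through JSON as decimal arrays; round-trip agreement is
  guaranteed to `1e−12`, not bit-exactness.

## What the simulations do and do not show

The generator and scenarios are deliberately abstract: deterministic timing
between ingestion and the nutritive report, a fixed potential (no hedonic
shift learning), a single stochastic branch, prediction only (no action
selection), and no gastric dynamics. Passing tests show that the shaping
mechanism has the claimed properties in this idealised setting — acceleration
under a good potential, transient distortion and exact pay-back under a bad
one, dissociation of fast hedonic acquisition from slow nutritive
revaluation. They do not show that real orosensory signals are potentials,
nor anything about the timing noise, partial observability or motivational
modulation present in real conditioning data.

## Known limitations

* No TD(λ), function approximation, actor–critic choice, or discounting.
* The averaged-δ CSV loses per-run state identity (only step indices align
  across runs).
* `compare_runs` orders by a single scalar (trials-to-90% at the start
  state); it does not attempt curve-shape comparisons.
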
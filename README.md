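# boundedplan

Information-theoretic analysis of concurrent motor planning in a
delayed-response task (DRT), built around a bounded-rational
decision-making model with explicit capacity limits for memory and
action planning.

## The problem

In the DRT a cue stimulus `s1` shows a set of potential target
locations spread over four response panels; after a delay, a go-signal
`s2` (a half-frame over part of one panel) reveals which target is the
real one, and the subject responds with a 2-, 3- or 4-step button-press
sequence `a` that moves a cursor to the target `w`. Twelve conditions
cross the target multiplicity (`'1'`, `'11'`, `'2'`, `'4'`) with the
sequence length (2, 3, 4). The scientific question is what happens
*during the delay*: does the brain merely hold the cue in memory and
postpone planning until the go-signal (delayed planning, H0), or does
it prepare an action plan for every possible go-signal concurrently
(prospective planning, H1)? The two strategies predict different
condition profiles of information processing, which can be regressed
against condition-level estimates of delay-period brain activity.

## The model

The decision-maker maximizes expected utility subject to information
constraints on two channels — memory formation `p(m|s1)` and action
selection `p(a|m,s2)`:

```
max  E[U] − (1/β1) I(M;S1) − (1/β2) ( I(A;M) + I(A;S2|M) )
```

with a 0/1 utility (`U(w,a) = 1` iff sequence `a` reaches target `w`),
so that `E[U] = 1 − error rate`. The inverse temperatures β1, β2 set
the channel capacities; β → ∞ approaches the Bayes-optimal decision
maker. The optimum satisfies coupled softmax/marginal fixed-point
equations which the package iterates to convergence
(Blahut–Arimoto-style alternating maximization).

From a solved policy, per-condition information costs are computed in
bits: `I1(c)`, the KL cost of memory formation (shared by both
hypotheses), and `I2(c)`, the cost of action-uncertainty reduction —
via the memory-conditioned action marginal `p(a|m)` for H0, or summed
over all anticipated go-signals with plan-count multipliers
N = 1, 4, 4, 16 for H1. Synthetic subjects are generated as
`activity(c) = α0 + α1·f(I1(c)) + α2·f(I2(c)) + noise` for a link `f`
(linear, quadratic, logarithmic, sigmoidal), and recovered with
non-negative multilinear regression, capacity grid search, nested
F-tests, leave-one-out cross-validation, paired group statistics and a
behavioral-prediction regression of `1 − error rate` on predicted
`E[U]`.

## Worked example

```python
from boundedplan import build_task, solve
from boundedplan.information import Hypothesis, condition_information

task = build_task()              # |W|=40, |A|=80, |S2|=8, |S1|=|M|=820
policy = solve(task, 500.0, 500.0)
h0 = condition_information(policy, task, Hypothesis.H0_DELAYED)
h1 = condition_information(policy, task, Hypothesis.H1_PROSPECTIVE)
print(f"EU={h0.EU:.3f}  EI1={h0.EI1:.3f}  "
      f"EI2(H0)={h0.EI2:.3f}  EI2(H1)={h1.EI2:.3f}")
```

prints

```
EU=1.000  EI1=4.801  EI2(H0)=2.633  EI2(H1)=32.823
```

At maximal capacity (β1 = β2 = 500) the agent always hits the target
(`EU = 1.000`, i.e. zero predicted error rate). Forming the memory of
the cue costs on average 4.801 bits per trial. If planning is delayed
(H0), reducing action uncertainty during the delay costs a further
2.633 bits on average; planning prospectively for every possible
go-signal (H1) costs 32.823 bits — an order of magnitude more, and the
gap widens with the number of potential targets. It is this difference
in condition profiles that lets the downstream regression distinguish
the two strategies.

The same numbers are available from the command line, along with the
full pipeline (task → grid → synthetic cohort → fits → group
statistics → behavior correlation):

```
boundedplan solve --beta1 500 --beta2 500
boundedplan run --preset smoke --out runs/smoke
```

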
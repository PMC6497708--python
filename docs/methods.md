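# Methods

## The game

Pairs of connected players repeatedly play an asymmetric battle of the sexes:
both earn by choosing the same action, but they rank the two coordinated
outcomes oppositely. With actions `A` ("blue") and `B` ("yellow"), a player
whose preferred action is matched earns `v_pref`, a player matched on the
other action earns `v_other`, and miscoordination earns `v_mis`, with
`v_pref > v_other > v_mis >= 0`. Two presets are built in: the theoretical
2/1/0 stakes and the laboratory 10/8/0 stakes. The experimental stakes make
coordinating on the non-preferred action only slightly worse than on the
preferred one, so players have a genuine incentive to give in rather than
miscoordinate.

On a network each node chooses one action per round and plays it against all
neighbors; its round payoff is the sum of the pairwise payoffs and the
per-round payment divides that sum by the node's degree ("points per
opponent"). Because the pairwise game is anonymous, a node's incentives
depend only on the *count* of neighbors on each action. This yields the
local-majority structure: a node of degree `d` profits from its preferred
action as soon as `v_pref * n >= v_other * (d - n)` like-minded neighbors
support it. With 10/8 stakes this threshold equals the strict self-inclusive
majority `ceil(d/2)` for every degree up to 8 (the experiment's relevant
range) and first diverges at degree 9, where 4 of 9 suffice. Even-degree
nodes therefore need only 50% of their neighbors on their side, odd-degree
nodes strictly more — the "even-degree advantage" the analysis probes.

Payoff ties are resolved toward the player's own preferred action. This
matches the self-inclusive majority counting above and the salience of one's
own preference; the first round, where nodes have no history, plays the
preferred action outright.

## Model dynamics

The simulator implements myopic-best-response reinforcement. Each node keeps
a probability `p` of playing its preferred action, initialized at 1. After
every round, `p` interpolates toward the indicator of whether the preferred
action would have been the best reply to the neighbors' just-observed
actions:

    p <- p + lambda * (target - p),    target = 1{best reply = preferred}

with learning rate `lambda` in (0, 1], default 0.5. Updates are synchronous;
all randomness flows from one integer seed, and batch runs derive
per-replicate child seeds deterministically from a master seed.

The exact functional form of the update is a reconstruction: the linear
interpolation is the simplest rule consistent with "update the probability
toward last round's best choice", and its rate is exposed as a parameter.
Two boundary behaviors characterize it. At `lambda = 1` the rule is plain
deterministic best response, and a dyad with opposite preferences alternates
`A/B -> B/A` forever without coordinating. At fractional rates the
stochastic draws break that symmetry: at `lambda = 0.5` the dyad is
coordinated in round 20 in about 93% of replicates (measured against an
independently coded dyad simulator at 2 x 10^5 replicates). This trap-escape
property is why the default is fractional.

Convergence of a finished trace is assessed per node over the last `w`
rounds (default 5): a node converged if one action accounts for at least
`w - 1` of its last `w` choices, and the network converged if all nodes did.
The `(w-1)/w` criterion deliberately tolerates a single exploratory switch,
since occasional switching inside an equilibrium is expected; both the
window and the criterion are parameters, as any such rule is a judgment
call.

## Network classes

Three generator families at the experiment's scale — 20 nodes, 38 edges,
density 38/190 = 0.2:

* **random** — uniform G(n, m) graphs conditioned on connectedness
  (resampled up to 1000 times); low clustering, narrow degree spread.
* **clustered** — Watts–Strogatz: ring lattice with 4 neighbors per node,
  each edge rewired with probability 0.1; high clustering, short paths.
* **centralized** — Barabási–Albert growth attaching each new node to 2
  existing ones in proportion to degree; a few hubs, many peripheral nodes.

The classic generators do not hit an exact edge count, so outputs are
adjusted to the target by removing uniformly chosen non-bridge edges or
adding uniformly chosen absent edges, preserving connectedness. Exactness
matters because the density of the experimental networks is a design
constant, and connectedness because every subject must actually play. The
lattice-neighbor count, rewiring probability and attachment count are not
dictated by the study design; the defaults (4, 0.1, 2) reproduce the
qualitative class signatures at n = 20 — verified as seed-averaged
orderings: small-world clustering exceeds random clustering, and
preferential-attachment maximum degree exceeds random maximum degree, each
by more than two standard errors over 100 seeds — and are overridable in the
run configuration.

## Synthetic subjects

The session generator stands in for human participants and is intentionally
a *different* process from the model: an ε-noisy myopic best responder.
Round 1 expresses the assigned preference; each later round plays the best
reply to the previous round, and every decision is flipped to the other
action with probability ε (default 0.04, anchored to the observed ~96%
best-response rate in human play of iterated games of this type). Round-1
noise is on by default (subjects occasionally deviate immediately) and can
be disabled. Keeping model and "data" distinct means the model-data match
score measures genuine predictive agreement between two different behavioral
processes, not a self-comparison.

A full synthetic study mirrors the experimental design: 12 sessions, each
playing all three network classes in per-session permuted order, 20 rounds
per network, types reassigned at random (balanced, 10 per type) before each
network's first round. Fresh networks are drawn per session, so the study
samples the network classes rather than three fixed instances; a fixed
master seed makes the whole study reproducible file for file.

What the generator does **not** emulate: deliberate signaling (persistently
playing one's preference to pull neighbors along), inertia or stubbornness
heterogeneity across subjects, learning of the noise level itself, and any
session-level context effects. Passing tests on synthetic sessions therefore
show that the pipeline recovers the behavior of noisy best responders —
they quantify the statistics' behavior under the design's assumptions, not
the behavior of humans.

## Statistics

**Match score.** Model and session behavior matrices with identical starting
conditions (same network, same preference assignment) are compared decision
by decision: each agreement contributes +1, each disagreement −1, averaged
over all N x R decisions, giving `r` in [−1, 1]. This is a match score, not
a Pearson correlation — the mapping `percent correct = 100 (r + 1) / 2`
(reported rounded to integer) only holds for the ±1 scoring. Because the
model is stochastic, it is rerun (default 100 replicates) and the median
score is reported; the median of the two middle values for even counts, with
the full distribution retained because it is often strongly skewed (a run
converging to the opposite equilibrium contributes r near −1). Scores are
computed both over all rounds and over the last five, the latter capturing
converged behavior.

**Heterogeneity.** For the last `k` rounds (default 5, to smooth out
occasional switching), `p_blue` is the proportion of blue choices pooled
over all N x k decisions and `h = p_blue (1 − p_blue)` is its variance: 0
when behavior is homogeneous, 0.25 at an even split. Pooling over the window
is one of two defensible readings (the other averages per-round variances);
pooling is the default and the per-round variant is available as an option.
A one-way ANOVA compares session-level `h` across the three network classes
(k − 1, n − k degrees of freedom; (2, 33) for the default 12-session
design). The ANOVA is computed from the classical sums of squares so the
zero-within-variance boundary returns a flagged infinite F rather than
failing; post hoc pairwise comparisons are delegated to standard libraries
and not re-implemented.

**Decision model.** Every subject-round decision becomes a record with a
binary played-preferred outcome, the subject's degree and an even-degree
indicator, and a pooled logistic regression (maximum likelihood, Newton
iterations, tolerance 1e−8) estimates both effects. Pooling ignores the
subject- and network-level nesting of the data; a random-effects multilevel
fit is out of scope, and the exported decision table retains session and
subject identifiers so such a model can be fit externally. Separation and
non-convergence are detected and reported as errors rather than returning
unstable estimates.

**Community agreement.** For clustered topologies, mean pairwise same-action
rates are compared within versus between partition blocks (greedy-modularity
partition with deterministic tie-breaking, or any user partition) over the
last-rounds window.

## Qualitative replication, problem sizes, and what is checked

The human-data headline numbers (the published medians, regression
coefficients, F value) are functions of the human sessions and cannot be
recomputed here. What the default synthetic study (12 sessions x 3 network
classes, 100 model replicates per session-network, master seed 1) is
expected to — and does — reproduce are the *orderings* those numbers
express: the model predicts centralized networks better than random ones;
clustered networks end more heterogeneous than centralized ones; and degree
and even degree both carry positive coefficients in the pooled decision
model. The full battery runs in well under a minute on one CPU thanks to a
vectorized best-reply step (an adjacency matrix-vector product per round);
the test suite uses the full 12-session design, and the scaled demonstration
in `examples/replication_study.py` uses 3 sessions with 20 replicates.

## Numerical and degenerate-input conventions

* Probabilities stay in [0, 1] by construction (linear interpolation of a
  bounded variable toward {0, 1}).
* Seeds: every stochastic entry point takes one integer seed; batches and
  the experiment generator derive child seeds below 2^31 from it.
* Degree-0 nodes: normalized payoff is undefined and raises; generators
  never produce isolated nodes (connectedness is enforced).
* Edge-count adjustment refuses to disconnect a graph (bridge edges are
  never removed) and raises when reduction is impossible.
* Empty round subsets, windows longer than the trace, unbalanced
  preference requests on odd-sized networks, and malformed edge-list or
  session files raise typed errors naming the offending parameter, line or
  row.

## Known limitations

* The update rule is a reconstruction (see above); other rules consistent
  with the verbal description (e.g. discrete win-stay/lose-shift variants)
  would change quantitative rates such as the dyad's 93% coordination.
* Synthetic subjects are memory-one and homogeneous; none of the richer
  behaviors listed above are modeled.
* The pooled logistic understates standard errors relative to a multilevel
  fit; coefficient signs, which the qualitative checks use, are unaffected
  in the synthetic design.
* Generated networks sample the classes; they are not the three specific
  instances human subjects played, so session-level numbers are comparable
  only in distribution.
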
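"""Iterated-game simulator: reinforcement learning toward the myopic best reply.

Each node starts by playing its preferred action with probability one.  After
every round a node looks at what its neighbors just played and moves its
probability of playing the preferred action toward the indicator of whether
the preferred action would have been the best reply:

    p[t] = p[t-1] + lambda * (target - p[t-1]),   target in {0, 1}

with learning rate ``lambda`` in (0, 1].  Updates are synchronous and one
decision per round is played against all neighbors.  With ``lambda = 1`` this
degenerates to deterministic myopic best response (a dyad with opposite
preferences then alternates forever); fractional rates let the stochastic
draws break such symmetric traps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter

import numpy as np

from .game import (
    ACTION_A,
    ACTION_B,
    PayoffScheme,
    PreferenceAssignment,
    ValidationError,
)
from .networks import Network, ParameterError


@dataclass
class Trace:
    """Node x round action matrix from one simulation run.

    ``actions[i, t]`` is node ``i``'s action (``'A'``/``'B'``) in round
    ``t + 1``; the first column always equals the preference vector.
    """

    actions: np.ndarray
    preferences: PreferenceAssignment
    network: Network
    seed: int
    learning_rate: float
    scheme: PayoffScheme

    @property
    def n_nodes(self) -> int:
        return self.actions.shape[0]

    @property
    def rounds(self) -> int:
        return self.actions.shape[1]

    def actions01(self) -> np.ndarray:
        """Actions coded 0 = A, 1 = B."""
        return (self.actions == ACTION_B).astype(np.int8)


def _validate_inputs(network: Network, prefs: PreferenceAssignment) -> None:
    if network.n_nodes == 0:
        raise ValidationError("empty network")
    missing = [n for n in network.nodes if n not in prefs.prefs]
    if missing:
        raise ValidationError(f"nodes without an assigned preference: {missing}")


def best_response_is_pref(
    adjacency: np.ndarray, actions01: np.ndarray, pref01: np.ndarray, scheme: PayoffScheme
) -> np.ndarray:
    """Vectorized myopic best reply for all nodes at once.

    Returns a boolean array: True where the node's preferred action (weakly)
    maximizes the summed pairwise payoff against ``actions01``, i.e. the same
    tie-toward-preference rule as :func:`netcoord.game.best_response`.
    """
    deg = adjacency.sum(axis=1)
    n_playing_b = adjacency @ actions01
    n_pref = np.where(pref01 == 1, n_playing_b, deg - n_playing_b)
    pay_pref = scheme.v_pref * n_pref + scheme.v_mis * (deg - n_pref)
    pay_other = scheme.v_other * (deg - n_pref) + scheme.v_mis * n_pref
    return pay_pref >= pay_other


def simulate(
    network: Network,
    prefs: PreferenceAssignment,
    scheme: PayoffScheme,
    rounds: int = 20,
    learning_rate: float = 0.5,
    seed: int = 0,
) -> Trace:
    """Run one replicate of the reinforcement-learning dynamics.

    Round 1 is the preference vector; in later rounds node ``i`` plays its
    preferred action with its current probability ``p_i``, updated after each
    round toward the best-reply indicator.  All randomness comes from
    ``seed``.
    """
    if rounds < 1:
        raise ParameterError("rounds must be >= 1")
    if not 0 < learning_rate <= 1:
        raise ParameterError("learning_rate must be in (0, 1]")
    _validate_inputs(network, prefs)

    n = network.n_nodes
    adj = network.adjacency()
    pref01 = (prefs.vector() == ACTION_B).astype(np.int8)
    rng = np.random.default_rng(seed)

    acts = np.empty((n, rounds), dtype=np.int8)
    acts[:, 0] = pref01  # preferred behavior with probability one
    p_pref = np.ones(n)
    for t in range(1, rounds):
        target = best_response_is_pref(adj, acts[:, t - 1], pref01, scheme).astype(float)
        p_pref = p_pref + learning_rate * (target - p_pref)
        plays_pref = rng.random(n) < p_pref
        acts[:, t] = np.where(plays_pref, pref01, 1 - pref01)

    letters = np.where(acts == 1, ACTION_B, ACTION_A).astype("<U1")
    return Trace(letters, prefs, network, seed, learning_rate, scheme)


def replicate_seeds(seed: int, replicates: int) -> list[int]:
    """Deterministic per-replicate child seeds below 2**31."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31, size=replicates)]


def batch_simulate(
    network: Network,
    prefs: PreferenceAssignment,
    scheme: PayoffScheme,
    rounds: int = 20,
    learning_rate: float = 0.5,
    replicates: int = 100,
    seed: int = 0,
) -> list[Trace]:
    """Run ``replicates`` independent traces with seeds derived from ``seed``."""
    if replicates < 1:
        raise ParameterError("replicates must be >= 1")
    return [
        simulate(network, prefs, scheme, rounds, learning_rate, child)
        for child in replicate_seeds(seed, replicates)
    ]


def is_converged(
    trace: Trace, window: int = 5
) -> tuple[bool, dict[int, str], dict[int, bool]]:
    """Terminal-window stability check.

    A node counts as converged when it played a single action in at least
    ``window - 1`` of the last ``window`` rounds; the network is converged
    when every node is.  Returns the network flag, each node's modal action
    in the window (ties toward ``'A'``) and the per-node flags.
    """
    if window < 2:
        raise ParameterError("window must be >= 2")
    if window > trace.rounds:
        raise ParameterError("window cannot exceed the number of rounds")
    tail = trace.actions[:, -window:]
    modal: dict[int, str] = {}
    per_node: dict[int, bool] = {}
    for i in range(trace.n_nodes):
        counts = Counter(tail[i])
        top = max(counts.values())
        modal[i] = ACTION_A if counts.get(ACTION_A, 0) == top else ACTION_B
        per_node[i] = top >= window - 1
    return all(per_node.values()), modal, per_node
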
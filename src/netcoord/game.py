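"""Payoff structure of the asymmetric battle of the sexes on a network.

Two actions, ``A`` and ``B`` (shown to subjects as "blue" and "yellow").
Each player has a preferred action: coordinating on it pays ``v_pref``,
coordinating on the other action pays ``v_other`` and miscoordinating pays
``v_mis``, with ``v_pref > v_other > v_mis >= 0``.  A player facing several
neighbors plays one action against all of them and earns the sum of the
pairwise payoffs; the per-round payment in the experiment divides that sum by
the number of neighbors.

Because the pairwise game is anonymous, a player's best reply to its
neighborhood depends only on how many neighbors chose each action, which
yields the local-majority thresholds computed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .networks import Network, ParameterError

ACTION_A = "A"
ACTION_B = "B"
ACTIONS = (ACTION_A, ACTION_B)

#: Display labels: A is "blue" (the row players' preferred color), B "yellow".
ACTION_COLOR = {ACTION_A: "blue", ACTION_B: "yellow"}
COLOR_ACTION = {c: a for a, c in ACTION_COLOR.items()}

ROW = "row"
COLUMN = "column"


class ValidationError(ValueError):
    """Inconsistent game inputs (missing neighbors, unknown nodes, ...)."""


def _check_action(action: str) -> None:
    if action not in ACTIONS:
        raise ValidationError(f"action must be one of {ACTIONS}, got {action!r}")


@dataclass(frozen=True)
class PayoffScheme:
    """Asymmetric-coordination payoffs ``v_pref > v_other > v_mis >= 0``."""

    v_pref: float
    v_other: float
    v_mis: float = 0.0

    def __post_init__(self) -> None:
        if not (self.v_pref > self.v_other > self.v_mis >= 0):
            raise ParameterError(
                f"require v_pref > v_other > v_mis >= 0, got "
                f"({self.v_pref}, {self.v_other}, {self.v_mis})"
            )


#: 2/1/0 scheme used in the theoretical payoff tables.
THEORY = PayoffScheme(2, 1, 0)
#: 10/8/0 scheme used in the laboratory sessions.
EXPERIMENT = PayoffScheme(10, 8, 0)


@dataclass
class PreferenceAssignment:
    """Per-node preferred action; A-preferring nodes are the row players."""

    prefs: dict[int, str]

    def __post_init__(self) -> None:
        for node, pref in self.prefs.items():
            if pref not in ACTIONS:
                raise ValidationError(f"node {node}: preference must be in {ACTIONS}")

    def __getitem__(self, node: int) -> str:
        return self.prefs[node]

    def __len__(self) -> int:
        return len(self.prefs)

    @property
    def nodes(self) -> list[int]:
        return sorted(self.prefs)

    def type_of(self, node: int) -> str:
        """``row`` for A-preferring (blue) nodes, ``column`` otherwise."""
        return ROW if self.prefs[node] == ACTION_A else COLUMN

    def vector(self) -> np.ndarray:
        """Preferences in node-id order as an array of ``A``/``B``."""
        return np.array([self.prefs[n] for n in self.nodes], dtype="<U1")

    def counts(self) -> dict[str, int]:
        vec = self.vector()
        return {a: int((vec == a).sum()) for a in ACTIONS}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"node": self.nodes, "pref": [self.prefs[n] for n in self.nodes]})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PreferenceAssignment":
        df = pd.read_csv(path)
        return cls(dict(zip(df["node"].astype(int), df["pref"].astype(str))))


def pairwise_payoff(
    my_action: str, other_action: str, my_pref: str, scheme: PayoffScheme
) -> float:
    """Payoff of one pairwise interaction.

    ``v_mis`` on miscoordination; ``v_pref`` when both chose my preferred
    action; ``v_other`` when both chose the action I do not prefer.
    """
    for a in (my_action, other_action, my_pref):
        _check_action(a)
    if my_action != other_action:
        return scheme.v_mis
    return scheme.v_pref if my_action == my_pref else scheme.v_other


def neighborhood_payoff(
    node: int,
    action: str,
    neighbor_actions: Mapping[int, str],
    pref: str,
    scheme: PayoffScheme,
    network: Network | None = None,
) -> float:
    """Sum of pairwise payoffs of playing ``action`` against all neighbors.

    If ``network`` is given, ``neighbor_actions`` must cover exactly the
    node's neighbors.
    """
    if network is not None:
        expected = set(network.neighbors(node))
        got = set(neighbor_actions)
        if expected != got:
            missing = sorted(expected - got)
            extra = sorted(got - expected)
            raise ValidationError(
                f"node {node}: neighbor actions mismatch (missing {missing}, extra {extra})"
            )
    return sum(
        pairwise_payoff(action, other, pref, scheme) for other in neighbor_actions.values()
    )


def normalized_payoff(total: float, degree: int) -> float:
    """Accumulated payoff divided by the number of opponents."""
    if degree < 1:
        raise ParameterError("normalized payoff is undefined for degree 0")
    return total / degree


def best_response(
    node: int,
    neighbor_actions: Mapping[int, str],
    pref: str,
    scheme: PayoffScheme,
    network: Network | None = None,
) -> str:
    """Myopic best response to the neighbors' (previous-round) actions.

    Maximizes :func:`neighborhood_payoff` over the two actions; payoff ties
    resolve toward the player's own preferred action.
    """
    _check_action(pref)
    other = ACTION_B if pref == ACTION_A else ACTION_A
    pay_pref = neighborhood_payoff(node, pref, neighbor_actions, pref, scheme, network)
    pay_other = neighborhood_payoff(node, other, neighbor_actions, pref, scheme, network)
    return pref if pay_pref >= pay_other else other


def majority_threshold(degree: int) -> tuple[int, int]:
    """Neighbors needed for a local majority of one's own choice.

    Counting the node itself, a strict majority among ``degree + 1`` choices
    needs ``ceil(degree / 2)`` like-minded neighbors.  Returns the count and
    the percentage of neighbors it represents (rounded to integer percent).
    Even-degree nodes need only 50%; odd-degree nodes need more.
    """
    if degree < 1:
        raise ParameterError("degree must be >= 1")
    needed = math.ceil(degree / 2)
    return needed, round(100 * needed / degree)


def payoff_threshold(degree: int, scheme: PayoffScheme) -> int:
    """Smallest number of preferred-action neighbors making the preferred
    action a (weak) best response.

    The smallest ``n`` with ``v_pref * n >= v_other * (degree - n)``; ties
    resolve toward the preferred action, matching :func:`best_response`.
    With the 10/8 experimental stakes this coincides with the local-majority
    count for degrees up to 8 and first diverges at degree 9.
    """
    if degree < 1:
        raise ParameterError("degree must be >= 1")
    for n in range(degree + 1):
        if scheme.v_pref * n >= scheme.v_other * (degree - n):
            return n
    return degree  # unreachable: n = degree always satisfies the inequality


def assign_preferences(network: Network, per_type: int, seed: int) -> PreferenceAssignment:
    """Uniformly random balanced assignment: ``per_type`` nodes prefer each action."""
    n = network.n_nodes
    if 2 * per_type != n:
        raise ParameterError(
            f"balanced assignment needs 2 * per_type == N, got per_type={per_type}, N={n}"
        )
    rng = np.random.default_rng(seed)
    nodes = network.nodes
    a_nodes = set(rng.choice(nodes, size=per_type, replace=False).tolist())
    return PreferenceAssignment(
        {node: (ACTION_A if node in a_nodes else ACTION_B) for node in nodes}
    )
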
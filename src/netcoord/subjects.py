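"""Synthetic experimental sessions: noisy myopic best responders.

Earlier work on iterated battle-of-the-sexes play found that about 96% of
human decisions follow a myopic best-response pattern, so the synthetic
subject plays the best reply to its neighbors' previous-round choices with
probability ``1 - noise_rate`` (default noise 0.04) and the other action
otherwise.  This is deliberately a different process from the
reinforcement-learning model in :mod:`netcoord.dynamics`, so that comparing
model traces against synthetic sessions exercises a genuine model-vs-data
comparison rather than a self-match.

Session tables use the experiment's feedback structure: one record per
subject per round with the chosen color, the accumulated round payoff and
the payoff normalized by the number of opponents.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import NETWORK_CLASSES, RunConfig
from .dynamics import best_response_is_pref
from .game import (
    ACTION_A,
    ACTION_B,
    ACTION_COLOR,
    COLOR_ACTION,
    COLUMN,
    ROW,
    PayoffScheme,
    PreferenceAssignment,
    ValidationError,
    assign_preferences,
)
from .networks import (
    Network,
    ParameterError,
    generate_preferential,
    generate_random,
    generate_small_world,
)

SESSION_COLUMNS = [
    "session_id",
    "network_label",
    "node_id",
    "subject_type",
    "round",
    "choice",
    "round_payoff",
    "normalized_payoff",
]

CHOICES = tuple(ACTION_COLOR.values())  # ("blue", "yellow")


class SchemaError(ValidationError):
    """A session table violating the record schema."""


class BalanceWarning(UserWarning):
    """Session without the balanced 10/10 type split."""


@dataclass
class SessionData:
    """One session on one network: the table plus its generating objects."""

    session_id: int
    network_label: str
    network: Network
    prefs: PreferenceAssignment
    table: pd.DataFrame
    seed: int
    order_index: int = 0


def generate_session(
    network: Network,
    prefs: PreferenceAssignment,
    scheme: PayoffScheme,
    rounds: int = 20,
    noise_rate: float = 0.04,
    seed: int = 0,
    session_id: int = 1,
    network_label: str | None = None,
    round1_noise: bool = True,
) -> pd.DataFrame:
    """Simulate one session of noisy myopic best responders.

    Round 1 expresses the assigned preference; every later round plays the
    best reply to the previous round, each decision flipped to the other
    action with probability ``noise_rate`` (round-1 noise can be disabled).
    Payoffs follow the game: the round payoff sums the pairwise interactions
    and the normalized payoff divides by the subject's degree.
    """
    if not 0 <= noise_rate <= 1:
        raise ParameterError("noise_rate must be in [0, 1]")
    if rounds < 1:
        raise ParameterError("rounds must be >= 1")
    if network.n_nodes == 0:
        raise ValidationError("empty network")
    missing = [n for n in network.nodes if n not in prefs.prefs]
    if missing:
        raise ValidationError(f"nodes without an assigned preference: {missing}")
    if network_label is None:
        network_label = network.class_label

    n = network.n_nodes
    adj = network.adjacency()
    deg = adj.sum(axis=1)
    pref01 = (prefs.vector() == ACTION_B).astype(np.int8)
    rng = np.random.default_rng(seed)

    acts = np.empty((n, rounds), dtype=np.int8)
    flip = rng.random(n) < noise_rate if round1_noise else np.zeros(n, dtype=bool)
    acts[:, 0] = np.where(flip, 1 - pref01, pref01)
    for t in range(1, rounds):
        br_pref = best_response_is_pref(adj, acts[:, t - 1], pref01, scheme)
        br = np.where(br_pref, pref01, 1 - pref01)
        flip = rng.random(n) < noise_rate
        acts[:, t] = np.where(flip, 1 - br, br)

    records = []
    for t in range(rounds):
        a = acts[:, t]
        n_playing_b = adj @ a
        n_same = np.where(a == 1, n_playing_b, deg - n_playing_b)
        coord_value = np.where(a == pref01, scheme.v_pref, scheme.v_other)
        round_pay = n_same * coord_value + (deg - n_same) * scheme.v_mis
        for i in range(n):
            records.append(
                (
                    session_id,
                    network_label,
                    i,
                    ROW if pref01[i] == 0 else COLUMN,
                    t + 1,
                    ACTION_COLOR[ACTION_A if a[i] == 0 else ACTION_B],
                    float(round_pay[i]),
                    float(round_pay[i] / deg[i]) if deg[i] > 0 else 0.0,
                )
            )
    return pd.DataFrame.from_records(records, columns=SESSION_COLUMNS)


def _build_network(label: str, config: RunConfig, seed: int) -> Network:
    if label == "random":
        return generate_random(config.n_nodes, config.target_edges, seed)
    if label == "clustered":
        return generate_small_world(
            config.n_nodes,
            config.sw_lattice_neighbors,
            config.sw_rewire_prob,
            config.target_edges,
            seed,
        )
    if label == "centralized":
        return generate_preferential(
            config.n_nodes, config.ba_attach_count, config.target_edges, seed
        )
    raise ParameterError(f"unknown network class {label!r}")


def generate_experiment(config: RunConfig, seed: int | None = None) -> list[SessionData]:
    """Generate the full synthetic study: sessions x network classes.

    Per session the order of the three network classes is permuted, a fresh
    network of each class is generated, and types are reassigned at random
    (balanced) before its first round.  All child seeds derive
    deterministically from the master seed.
    """
    if seed is None:
        seed = config.seed
    master = np.random.default_rng(seed)
    out: list[SessionData] = []
    for sid in range(1, config.sessions + 1):
        order = [NETWORK_CLASSES[i] for i in master.permutation(len(NETWORK_CLASSES))]
        for pos, label in enumerate(order):
            net_seed, pref_seed, sess_seed = (
                int(s) for s in master.integers(0, 2**31, size=3)
            )
            network = _build_network(label, config, net_seed)
            prefs = assign_preferences(network, config.per_type, pref_seed)
            table = generate_session(
                network,
                prefs,
                config.scheme,
                rounds=config.rounds,
                noise_rate=config.noise_rate,
                seed=sess_seed,
                session_id=sid,
                network_label=label,
                round1_noise=config.round1_noise,
            )
            out.append(SessionData(sid, label, network, prefs, table, sess_seed, pos))
    return out


def best_response_fraction(
    table: pd.DataFrame, network: Network, prefs: PreferenceAssignment, scheme: PayoffScheme
) -> float:
    """Fraction of round >= 2 decisions that are myopic best replies.

    The diagnostic the noise level is anchored to: with noise ``eps`` the
    long-run fraction approaches ``1 - eps``.
    """
    adj = network.adjacency()
    pref01 = (prefs.vector() == ACTION_B).astype(np.int8)
    acts = session_actions01(table, network.n_nodes)
    hits = 0
    total = 0
    for t in range(1, acts.shape[1]):
        br_pref = best_response_is_pref(adj, acts[:, t - 1], pref01, scheme)
        br = np.where(br_pref, pref01, 1 - pref01)
        hits += int((acts[:, t] == br).sum())
        total += acts.shape[0]
    return hits / total if total else float("nan")


def session_actions01(table: pd.DataFrame, n_nodes: int) -> np.ndarray:
    """Node x round matrix of choices coded 0 = blue, 1 = yellow."""
    pivot = table.pivot(index="node_id", columns="round", values="choice")
    pivot = pivot.reindex(index=range(n_nodes), columns=sorted(pivot.columns))
    if pivot.isna().any().any():
        raise SchemaError("session table does not cover every node x round cell")
    return (pivot.to_numpy() == ACTION_COLOR[ACTION_B]).astype(np.int8)


def write_sessions(tables: pd.DataFrame | list[pd.DataFrame], path: str | Path) -> None:
    """Write one or several session tables to a single CSV."""
    if isinstance(tables, list):
        tables = pd.concat([s.table if isinstance(s, SessionData) else s for s in tables])
    tables.to_csv(path, index=False)


def validate_sessions(table: pd.DataFrame, rounds: int | None = None) -> None:
    """Schema validation; raises :class:`SchemaError` naming column and row."""
    for col in SESSION_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"missing column {col!r}")
    bad = ~table["choice"].isin(CHOICES)
    if bad.any():
        row = int(table.index[bad][0])
        raise SchemaError(f"column 'choice', row {row}: value not in {CHOICES}")
    bad = ~table["subject_type"].isin((ROW, COLUMN))
    if bad.any():
        row = int(table.index[bad][0])
        raise SchemaError(f"column 'subject_type', row {row}: value not in (row, column)")
    if rounds is not None:
        bad = (table["round"] < 1) | (table["round"] > rounds)
        if bad.any():
            row = int(table.index[bad][0])
            raise SchemaError(
                f"column 'round', row {row}: value {table.loc[row, 'round']} "
                f"outside 1..{rounds}"
            )
    for (sid, label), grp in table.groupby(["session_id", "network_label"]):
        first = grp[grp["round"] == grp["round"].min()]
        n_row = int((first["subject_type"] == ROW).sum())
        n_col = int((first["subject_type"] == COLUMN).sum())
        if n_row != n_col:
            warnings.warn(
                f"session {sid} / {label}: unbalanced types ({n_row} row, {n_col} column)",
                BalanceWarning,
                stacklevel=2,
            )


def read_sessions(path: str | Path, rounds: int | None = None) -> pd.DataFrame:
    """Read and validate a session CSV written by :func:`write_sessions`."""
    table = pd.read_csv(path)
    validate_sessions(table, rounds=rounds)
    table["session_id"] = table["session_id"].astype(int)
    table["node_id"] = table["node_id"].astype(int)
    table["round"] = table["round"].astype(int)
    return table
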
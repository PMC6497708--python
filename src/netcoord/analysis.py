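"""Statistics for comparing model dynamics with (synthetic) session data.

The central quantity is a match score between two node x round behavior
matrices with the same starting conditions (same network, same preference
assignment): every decision pair contributes +1 on agreement and -1 on
disagreement, averaged over all N x R decisions, giving a score in [-1, 1].
The fraction of correctly predicted decisions is then 100 * (r + 1) / 2.
Because the model is stochastic it is run many times (default 100) and the
median score is reported, with the full distribution retained since it can be
strongly skewed.

Further measures: behavioral heterogeneity h = p(1 - p) of the proportion
choosing "blue" over the last rounds of a session; a one-way ANOVA of h
across network conditions; and a pooled logistic regression of
played-preferred decisions on degree centrality and even degree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .dynamics import Trace, simulate, replicate_seeds
from .game import (
    ACTION_B,
    ACTION_COLOR,
    PayoffScheme,
    PreferenceAssignment,
    ValidationError,
)
from .networks import Network, ParameterError
from .subjects import SessionData, session_actions01


class FitError(RuntimeError):
    """Logistic fit did not converge or the data are separated."""


# ---------------------------------------------------------------------------
# match score


@dataclass
class MatchScore:
    r: float
    rounds_used: str
    n_decisions: int

    @property
    def percent(self) -> int:
        return percent_correct(self.r)


def _behavior_matrix(obj: Trace | pd.DataFrame) -> tuple[np.ndarray, list[str] | None]:
    """0/1 behavior matrix (1 = yellow/B) plus per-node type labels if known."""
    if isinstance(obj, Trace):
        types = [obj.preferences.type_of(n) for n in sorted(obj.preferences.nodes)]
        return obj.actions01(), types
    if isinstance(obj, SessionData):
        types = [obj.prefs.type_of(n) for n in obj.prefs.nodes]
        return session_actions01(obj.table, obj.network.n_nodes), types
    if isinstance(obj, pd.DataFrame):
        n = int(obj["node_id"].max()) + 1
        first = obj[obj["round"] == obj["round"].min()].sort_values("node_id")
        types = list(first["subject_type"])
        return session_actions01(obj, n), types
    raise TypeError(f"cannot extract behavior from {type(obj).__name__}")


def match_score(
    model: Trace | pd.DataFrame,
    observed: Trace | pd.DataFrame,
    rounds_subset: Iterable[int] | None = None,
) -> MatchScore:
    """Agreement-minus-disagreement score between two behavior matrices.

    Both sources must share starting conditions: equal node count and the
    same type (preference) vector.  ``rounds_subset`` selects 1-based rounds
    (e.g. the last five); by default all rounds are compared.  The score is
    symmetric in its two arguments.
    """
    a, types_a = _behavior_matrix(model)
    b, types_b = _behavior_matrix(observed)
    if a.shape != b.shape:
        raise ValidationError(f"behavior shapes differ: {a.shape} vs {b.shape}")
    if types_a is not None and types_b is not None and types_a != types_b:
        raise ValidationError("mismatched starting conditions: preference vectors differ")
    if rounds_subset is None:
        cols = list(range(a.shape[1]))
        label = "all"
    else:
        cols = [r - 1 for r in rounds_subset]
        if not cols:
            raise ParameterError("rounds_subset must be nonempty")
        if min(cols) < 0 or max(cols) >= a.shape[1]:
            raise ParameterError("rounds_subset outside the available rounds")
        label = f"subset[{len(cols)}]"
    sel_a, sel_b = a[:, cols], b[:, cols]
    n_dec = sel_a.size
    agree = int((sel_a == sel_b).sum())
    r = (agree - (n_dec - agree)) / n_dec
    return MatchScore(r, label, n_dec)


def last_k_rounds(rounds: int, k: int = 5) -> list[int]:
    """The 1-based indices of the final ``k`` rounds."""
    if k > rounds:
        raise ParameterError("k cannot exceed the number of rounds")
    return list(range(rounds - k + 1, rounds + 1))


def percent_correct(r: float) -> int:
    """Percentage of decisions correctly predicted, implied by score ``r``.

    Each agreement contributes +1 and each disagreement -1, so the agreement
    fraction is (r + 1) / 2; reported rounded to the nearest integer percent.
    """
    if not -1 <= r <= 1:
        raise ParameterError(f"score must be in [-1, 1], got {r}")
    return round(100 * (r + 1) / 2)


@dataclass
class MedianMatch:
    median_r: float
    scores: np.ndarray
    rounds_used: str

    @property
    def percent_of_median(self) -> int:
        return percent_correct(self.median_r)

    @property
    def mean_percent(self) -> float:
        return float(np.mean([percent_correct(r) for r in self.scores]))


def median_match(
    network: Network,
    prefs: PreferenceAssignment,
    scheme: PayoffScheme,
    observed: Trace | pd.DataFrame,
    replicates: int = 100,
    rounds_subset: Iterable[int] | None = None,
    learning_rate: float = 0.5,
    rounds: int | None = None,
    seed: int = 0,
) -> MedianMatch:
    """Median model-data match over stochastic model replicates.

    Reruns the reinforcement-learning model ``replicates`` times from the
    observed session's starting conditions and reports the median of the
    per-replicate scores (mean of the middle pair for even counts) together
    with the full distribution.
    """
    if replicates < 1:
        raise ParameterError("replicates must be >= 1")
    obs_matrix, _ = _behavior_matrix(observed)
    if rounds is None:
        rounds = obs_matrix.shape[1]
    rounds_subset = list(rounds_subset) if rounds_subset is not None else None
    scores = np.array(
        [
            match_score(
                simulate(network, prefs, scheme, rounds, learning_rate, child),
                observed,
                rounds_subset,
            ).r
            for child in replicate_seeds(seed, replicates)
        ]
    )
    label = "all" if rounds_subset is None else f"subset[{len(rounds_subset)}]"
    return MedianMatch(float(np.median(scores)), scores, label)


# ---------------------------------------------------------------------------
# heterogeneity


@dataclass
class HeterogeneityResult:
    p_blue: float
    h: float
    window: int


def heterogeneity(
    source: Trace | pd.DataFrame, last_k: int = 5, per_round: bool = False
) -> HeterogeneityResult:
    """Variance of the proportion choosing blue over the last ``last_k`` rounds.

    ``h = p_blue * (1 - p_blue)`` is 0 for homogeneous behavior and maximal
    (0.25) at an even split.  ``p_blue`` pools all N x last_k decisions by
    default; ``per_round=True`` instead averages the per-round variances.
    """
    mat, _ = _behavior_matrix(source)  # 1 = yellow
    if last_k > mat.shape[1]:
        raise ParameterError("last_k cannot exceed the number of rounds")
    tail = mat[:, -last_k:]
    if per_round:
        p_rounds = 1 - tail.mean(axis=0)
        h = float(np.mean(p_rounds * (1 - p_rounds)))
        p_blue = float(np.mean(p_rounds))
    else:
        p_blue = float(1 - tail.mean())
        h = p_blue * (1 - p_blue)
    return HeterogeneityResult(p_blue, h, last_k)


# ---------------------------------------------------------------------------
# ANOVA


@dataclass
class AnovaResult:
    f: float
    df: tuple[int, int]
    p: float
    infinite_f: bool = False


def one_way_anova(groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]]) -> AnovaResult:
    """Classical one-way ANOVA (between / within mean-square ratio).

    Accepts a mapping label -> values or a sequence of groups.  A zero
    within-group variance with distinct group means yields an infinite F,
    flagged rather than raised.
    """
    if isinstance(groups, Mapping):
        data = [np.asarray(v, dtype=float) for v in groups.values()]
    else:
        data = [np.asarray(v, dtype=float) for v in groups]
    k = len(data)
    if k < 2 or any(len(g) < 2 for g in data):
        raise ParameterError("need >= 2 groups with >= 2 values each")
    n = sum(len(g) for g in data)
    grand = float(np.concatenate(data).mean())
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in data)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in data)
    df = (k - 1, n - k)
    ms_between = ss_between / df[0]
    ms_within = ss_within / df[1]
    if ms_within == 0:
        if ms_between == 0:
            return AnovaResult(float("nan"), df, float("nan"), infinite_f=False)
        return AnovaResult(float("inf"), df, 0.0, infinite_f=True)
    f = ms_between / ms_within
    p = float(scipy.stats.f.sf(f, *df))
    return AnovaResult(float(f), df, p)


# ---------------------------------------------------------------------------
# decision table + pooled logistic regression


def build_decision_table(sessions: Sequence[SessionData] | SessionData) -> pd.DataFrame:
    """One record per subject-round decision.

    Columns: ``played_preferred`` (1 when the chosen color is the subject's
    preferred one), ``degree``, ``even_degree``, plus identifiers.  The
    subject id is unique within a session (subjects keep their seat across
    that session's networks).
    """
    if isinstance(sessions, SessionData):
        sessions = [sessions]
    frames = []
    for s in sessions:
        degrees = dict(s.network.graph.degree())
        unknown = set(s.table["node_id"]) - set(degrees)
        if unknown:
            raise ValidationError(f"session {s.session_id}: unknown nodes {sorted(unknown)}")
        t = s.table[["session_id", "network_label", "node_id", "round", "choice"]].copy()
        pref_color = {n: ACTION_COLOR[s.prefs[n]] for n in s.prefs.nodes}
        t["played_preferred"] = (
            t["choice"] == t["node_id"].map(pref_color)
        ).astype(int)
        t["degree"] = t["node_id"].map(degrees).astype(int)
        t["even_degree"] = (t["degree"] % 2 == 0).astype(int)
        t["subject_id"] = (t["session_id"] - 1) * s.network.n_nodes + t["node_id"]
        frames.append(t.drop(columns=["choice"]))
    return pd.concat(frames, ignore_index=True)


def fit_preference_model(
    table: pd.DataFrame, predictors: Sequence[str] = ("degree", "even_degree")
) -> pd.DataFrame:
    """Pooled logistic regression of played-preferred on the predictors.

    Maximum-likelihood Newton fit with tolerance 1e-8; returns a coefficient
    table (estimate, standard error, p) indexed by ``const`` plus the
    predictors.  Non-convergence or (quasi-)separation raises
    :class:`FitError` with a diagnostic.
    """
    if not predictors:
        raise ParameterError("need at least one predictor")
    y = table["played_preferred"].to_numpy()
    if set(np.unique(y)) - {0, 1}:
        raise ParameterError("outcome must be binary 0/1")
    X = sm.add_constant(table[list(predictors)].astype(float), has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
            fit = sm.Logit(y, X).fit(method="newton", tol=1e-8, maxiter=100, disp=0)
    except (sm.tools.sm_exceptions.PerfectSeparationError,
            sm.tools.sm_exceptions.PerfectSeparationWarning) as exc:
        raise FitError(f"separation detected: {exc}") from exc
    if not fit.mle_retvals.get("converged", False):
        raise FitError("logistic fit did not converge")
    if not np.all(np.isfinite(fit.params)) or not np.all(np.isfinite(fit.bse)):
        raise FitError("separation detected: non-finite estimates")
    return pd.DataFrame(
        {"estimate": fit.params, "std_err": fit.bse, "p_value": fit.pvalues}
    )


# ---------------------------------------------------------------------------
# within- vs between-community agreement


def within_cluster_homogeneity(
    source: Trace | pd.DataFrame,
    partition: Sequence[Sequence[int]],
    last_k: int = 5,
) -> tuple[float, float]:
    """Mean pairwise same-action rate inside vs across partition blocks.

    Agreement is averaged over the last ``last_k`` rounds and over node
    pairs.  With a single block the between-block rate is undefined (NaN,
    with a warning); with only singleton blocks the within rate is.
    """
    mat, _ = _behavior_matrix(source)
    if last_k > mat.shape[1]:
        raise ParameterError("last_k cannot exceed the number of rounds")
    tail = mat[:, -last_k:]
    block_of: dict[int, int] = {}
    for b, block in enumerate(partition):
        for node in block:
            if node in block_of:
                raise ParameterError(f"node {node} appears in two blocks")
            block_of[node] = b
    if set(block_of) != set(range(mat.shape[0])):
        raise ParameterError("partition must cover exactly the nodes 0..N-1")
    within, between = [], []
    n = mat.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            rate = float((tail[i] == tail[j]).mean())
            (within if block_of[i] == block_of[j] else between).append(rate)
    w = float(np.mean(within)) if within else float("nan")
    b = float(np.mean(between)) if between else float("nan")
    if not within:
        warnings.warn("within-block agreement undefined (all blocks singletons)", stacklevel=2)
    if not between:
        warnings.warn("between-block agreement undefined (single block)", stacklevel=2)
    return w, b
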
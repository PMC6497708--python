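import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from netcoord import EXPERIMENT, PreferenceAssignment
from netcoord.analysis import (
    FitError,
    build_decision_table,
    fit_preference_model,
    heterogeneity,
    last_k_rounds,
    match_score,
    median_match,
    one_way_anova,
    percent_correct,
    within_cluster_homogeneity,
)
from netcoord.game import ValidationError, assign_preferences
from netcoord.networks import ParameterError, generate_random
from netcoord.subjects import SessionData, generate_session
from conftest import build_network, make_trace


# ---------------------------------------------------------------------------
# match score


def test_match_score_extremes():
    x = make_trace([list("AABB"), list("BBAA")], {0: "A", 1: "B"})
    assert match_score(x, x).r == 1.0
    assert percent_correct(match_score(x, x).r) == 100
    flipped = make_trace(
        np.where(x.actions == "A", "B", "A"), {0: "A", 1: "B"}, network=x.network
    )
    assert match_score(x, flipped).r == -1.0


def test_match_score_hand_example():
    # 2 nodes x 2 rounds, 3 of 4 decisions agree: r = (3 - 1) / 4
    a = make_trace([["A", "A"], ["B", "B"]], {0: "A", 1: "B"})
    b = make_trace([["A", "A"], ["B", "A"]], {0: "A", 1: "B"}, network=a.network)
    score = match_score(a, b)
    assert score.r == 0.5
    assert score.n_decisions == 4


def test_match_score_symmetric_and_brute_force():
    rng = np.random.default_rng(31)
    for _ in range(20):
        n, r = int(rng.integers(2, 6)), int(rng.integers(2, 8))
        prefs = {i: "A" if i % 2 == 0 else "B" for i in range(n)}
        a = make_trace(rng.choice(["A", "B"], size=(n, r)), prefs)
        b = make_trace(rng.choice(["A", "B"], size=(n, r)), prefs, network=a.network)
        expected = sum(
            1 if a.actions[i, t] == b.actions[i, t] else -1
            for i in range(n)
            for t in range(r)
        ) / (n * r)
        assert match_score(a, b).r == pytest.approx(expected)
        assert match_score(b, a).r == match_score(a, b).r


def test_match_score_rounds_subset():
    a = make_trace([list("AAAB")], {0: "A"})
    b = make_trace([list("BBAB")], {0: "A"}, network=a.network)
    assert match_score(a, b, rounds_subset=[3, 4]).r == 1.0
    assert match_score(a, b, rounds_subset=[1, 2]).r == -1.0
    with pytest.raises(ParameterError):
        match_score(a, b, rounds_subset=[5])


def test_match_score_requires_same_starting_conditions():
    a = make_trace([["A"], ["B"]], {0: "A", 1: "B"})
    b = make_trace([["A"], ["B"]], {0: "B", 1: "A"}, network=a.network)
    with pytest.raises(ValidationError, match="starting conditions"):
        match_score(a, b)


@pytest.mark.parametrize("r,expected", [
    (0.92, 96),
    (0.44, 72),
    (-1.0, 0),
    (1.0, 100),
    (0.0, 50),
])
def test_percent_correct(r, expected):
    assert percent_correct(r) == expected


def test_percent_correct_consistent_with_published_score_pairs():
    # printed (score, percent) pairs satisfy percent = 50(r+1) within rounding
    pairs = [(0.13, 56), (0.18, 59), (0.44, 72), (0.51, 76), (0.74, 87), (0.92, 96)]
    for r, pct in pairs:
        assert abs(percent_correct(r) - pct) <= 1


def test_percent_correct_rejects_out_of_range():
    with pytest.raises(ParameterError):
        percent_correct(1.2)


def test_median_match_deterministic_case():
    """When every replicate produces the same trace, the median is that score."""
    network = build_network(2, [(0, 1)])
    prefs = PreferenceAssignment({0: "A", 1: "A"})
    observed = generate_session(network, prefs, EXPERIMENT, rounds=10, noise_rate=0.0, seed=0)
    sd = SessionData(1, "custom", network, prefs, observed, 0)
    result = median_match(network, prefs, EXPERIMENT, sd, replicates=10, seed=4)
    assert result.median_r == 1.0
    assert set(result.scores) == {1.0}


# ---------------------------------------------------------------------------
# heterogeneity


def test_heterogeneity_extremes_and_arithmetic():
    all_blue = make_trace([["A"] * 5] * 4, {i: "A" for i in range(4)})
    res = heterogeneity(all_blue, last_k=5)
    assert res.p_blue == 1.0 and res.h == 0.0

    half = make_trace([["A"] * 5] * 2 + [["B"] * 5] * 2, {i: "A" for i in range(4)})
    assert heterogeneity(half, last_k=5).h == 0.25

    # 1 of 5 nodes blue: p = 0.2, h = 0.16
    fifth = make_trace([["A"] * 5] + [["B"] * 5] * 4, {i: "A" for i in range(5)})
    res = heterogeneity(fifth, last_k=5)
    assert res.p_blue == pytest.approx(0.2)
    assert res.h == pytest.approx(0.16)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.integers(0, 2**31 - 1))
def test_heterogeneity_color_relabel_invariance(seed):
    rng = np.random.default_rng(seed)
    acts = rng.choice(["A", "B"], size=(6, 8))
    prefs = {i: "A" for i in range(6)}
    base = make_trace(acts, prefs)
    swapped = make_trace(np.where(acts == "A", "B", "A"), prefs, network=base.network)
    assert heterogeneity(base).h == pytest.approx(heterogeneity(swapped).h)


def test_heterogeneity_window_validation():
    trace = make_trace([["A"] * 3], {0: "A"})
    with pytest.raises(ParameterError):
        heterogeneity(trace, last_k=4)


# ---------------------------------------------------------------------------
# ANOVA


def test_anova_df_structure():
    rng = np.random.default_rng(0)
    groups = {c: rng.normal(size=12) for c in "abc"}
    assert one_way_anova(groups).df == (2, 33)


def test_anova_equal_means_zero_f():
    res = one_way_anova([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
    assert res.f == pytest.approx(0.0)


def test_anova_zero_within_variance_flagged():
    res = one_way_anova([[0.0, 0.0], [1.0, 1.0]])
    assert res.infinite_f and math.isinf(res.f) and res.p == 0.0


def test_anova_matches_scipy():
    rng = np.random.default_rng(5)
    groups = [rng.normal(loc=m, size=10) for m in (0.0, 0.4, 1.0)]
    ours = one_way_anova(groups)
    ref = scipy.stats.f_oneway(*groups)
    assert ours.f == pytest.approx(ref.statistic)
    assert ours.p == pytest.approx(ref.pvalue)


def test_anova_degenerate_inputs_rejected():
    with pytest.raises(ParameterError):
        one_way_anova([[1.0, 2.0]])
    with pytest.raises(ParameterError):
        one_way_anova([[1.0], [2.0, 3.0]])


# ---------------------------------------------------------------------------
# decision table + logistic


def _session_data(seed=0, rounds=20):
    network = generate_random(20, 38, seed)
    prefs = assign_preferences(network, 10, seed + 1)
    table = generate_session(network, prefs, EXPERIMENT, rounds=rounds, seed=seed + 2)
    return SessionData(1, "random", network, prefs, table, seed)


def test_decision_table_schema():
    sd = _session_data()
    table = build_decision_table(sd)
    assert len(table) == 400
    degrees = dict(sd.network.graph.degree())
    assert (table["degree"] == table["node_id"].map(degrees)).all()
    assert (table["even_degree"] == (table["degree"] % 2 == 0).astype(int)).all()
    assert set(table["played_preferred"]) <= {0, 1}
    # round-1 no-noise decisions are exactly the preferred plays
    noiseless = generate_session(
        sd.network, sd.prefs, EXPERIMENT, rounds=5, noise_rate=0.0, seed=1
    )
    t0 = build_decision_table(SessionData(1, "random", sd.network, sd.prefs, noiseless, 0))
    assert (t0.loc[t0["round"] == 1, "played_preferred"] == 1).all()


def test_logistic_slope_equals_log_odds_ratio():
    """Single binary predictor: the MLE slope is the 2x2 log odds ratio."""
    rng = np.random.default_rng(12)
    x = rng.integers(0, 2, size=4000)
    p = np.where(x == 1, 0.7, 0.45)
    y = (rng.random(4000) < p).astype(int)
    table = pd.DataFrame({"played_preferred": y, "x": x})
    coefs = fit_preference_model(table, predictors=["x"])
    n11 = ((x == 1) & (y == 1)).sum()
    n10 = ((x == 1) & (y == 0)).sum()
    n01 = ((x == 0) & (y == 1)).sum()
    n00 = ((x == 0) & (y == 0)).sum()
    log_or = math.log((n11 / n10) / (n01 / n00))
    assert coefs.loc["x", "estimate"] == pytest.approx(log_or, abs=1e-6)


def test_logistic_null_predictor_rarely_significant():
    rng = np.random.default_rng(77)
    hits = 0
    for _ in range(100):
        x = rng.integers(0, 2, size=1000)
        y = rng.integers(0, 2, size=1000)
        table = pd.DataFrame({"played_preferred": y, "x": x})
        coefs = fit_preference_model(table, predictors=["x"])
        hits += coefs.loc["x", "p_value"] > 0.05
    assert hits >= 90


def test_logistic_separation_detected():
    table = pd.DataFrame({"played_preferred": [0, 0, 1, 1] * 10, "x": [0, 0, 1, 1] * 10})
    with pytest.raises(FitError, match="separation"):
        fit_preference_model(table, predictors=["x"])


def test_logistic_requires_predictors_and_binary_outcome():
    table = pd.DataFrame({"played_preferred": [0, 1, 2], "x": [0.0, 1.0, 2.0]})
    with pytest.raises(ParameterError):
        fit_preference_model(table, predictors=[])
    with pytest.raises(ParameterError):
        fit_preference_model(table, predictors=["x"])


# ---------------------------------------------------------------------------
# within / between agreement


def test_within_cluster_homogeneity_trivial_cases():
    prefs = {i: "A" for i in range(4)}
    constant = make_trace([["A"] * 5] * 4, prefs)
    assert within_cluster_homogeneity(constant, [[0, 1], [2, 3]]) == (1.0, 1.0)

    opposite = make_trace([["A"] * 5, ["A"] * 5, ["B"] * 5, ["B"] * 5], prefs)
    assert within_cluster_homogeneity(opposite, [[0, 1], [2, 3]]) == (1.0, 0.0)


def test_within_cluster_homogeneity_degenerate_partitions():
    prefs = {i: "A" for i in range(3)}
    trace = make_trace([["A"] * 5] * 3, prefs)
    with pytest.warns(UserWarning, match="single block"):
        _, between = within_cluster_homogeneity(trace, [[0, 1, 2]])
    assert math.isnan(between)
    with pytest.warns(UserWarning, match="singleton"):
        within, _ = within_cluster_homogeneity(trace, [[0], [1], [2]])
    assert math.isnan(within)
    with pytest.raises(ParameterError):
        within_cluster_homogeneity(trace, [[0, 1]])


def test_last_k_rounds():
    assert last_k_rounds(20, 5) == [16, 17, 18, 19, 20]
    with pytest.raises(ParameterError):
        last_k_rounds(4, 5)
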
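import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from bambooclim import niche_model as nm


# ---------------------------------------------------------------- oracles


def auc_brute(scores, labels):
    """O(n^2) average over all presence/absence pairs, half credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def youden_brute(scores, labels):
    """Exhaustive scan of every candidate cutoff; smallest tau on J ties."""
    best_tau, best_j = None, -math.inf
    for tau in nm.youden_candidates(scores):
        pred = scores >= tau
        tp = np.sum(pred & (labels == 1))
        fn = np.sum(~pred & (labels == 1))
        tn = np.sum(~pred & (labels == 0))
        fp = np.sum(pred & (labels == 0))
        j = tp / (tp + fn) + tn / (tn + fp) - 1.0
        if j > best_j + 1e-12:
            best_tau, best_j = tau, j
    return best_tau, best_j


# ---------------------------------------------------------------- fitting


def test_intercept_only_is_logit_of_prevalence():
    y = np.array([1] * 116 + [0] * 29)
    m = nm.fit_logistic(pd.DataFrame(index=range(145)), y)
    assert m.coefficients["intercept"] == pytest.approx(math.log(116 / 29), abs=1e-6)
    assert m.k_params == 1


def test_null_slope_recovery():
    rng = np.random.default_rng(0)
    n = 10_000
    X = pd.DataFrame({"noise": rng.normal(size=n)})
    y = rng.binomial(1, 0.5, size=n)
    m = nm.fit_logistic(X, y)
    se = m.standard_errors()["noise"]
    assert abs(m.coefficients["noise"]) < 3 * se


def test_true_coefficient_recovery(world):
    spec, table, truth = world
    from bambooclim.synthetic_data import SyntheticWorldSpec, make_stations
    from bambooclim.cli_io import station_summaries

    big, _ = make_stations(SyntheticWorldSpec(n_stations=5000, seed=11))
    s = station_summaries(big)
    m = nm.fit_logistic(s[["mean_annual_temp", "radiation"]], s["presence"])
    se = m.standard_errors()
    b = spec.true_coefficients
    assert abs(m.coefficients["intercept"] - b[0]) < 3 * se["intercept"]
    assert abs(m.coefficients["mean_annual_temp"] - b[1]) < 3 * se["mean_annual_temp"]
    assert abs(m.coefficients["radiation"] - b[2]) < 3 * se["radiation"]


def test_separation_flagged_with_predictor_name():
    x = np.linspace(-1, 1, 50)
    y = (x > 0).astype(int)
    X = pd.DataFrame({"benign": np.cos(37.0 * x), "culprit": x})
    with pytest.raises(nm.SeparationError) as err:
        nm.fit_logistic(X, y)
    assert err.value.predictor == "culprit"


def test_structural_errors():
    y = np.array([0, 1] * 10)
    with pytest.raises(nm.ModelStructureError):
        nm.fit_logistic(pd.DataFrame({"const": np.ones(20)}), y)
    x = np.arange(20.0)
    with pytest.raises(nm.ModelStructureError):
        nm.fit_logistic(pd.DataFrame({"a": x, "b": 2 * x + 1}), y)  # rank deficient
    with pytest.raises(nm.ModelStructureError):
        nm.fit_logistic(pd.DataFrame({"a": x}), y + 1)  # non-binary


# ---------------------------------------------------------------- AICc


def test_aicc_spot_value():
    assert nm.aicc(-40.0, 3, 145) == pytest.approx(86.0 + 24 / 141)


def test_aicc_limits_and_domain():
    assert nm.aicc(-40.0, 0, 145) == pytest.approx(80.0)
    assert nm.aicc(-40.0, 3, 10**9) == pytest.approx(86.0, abs=1e-4)
    with pytest.raises(nm.ModelStructureError):
        nm.aicc(-40.0, 3, 4)


def test_aicc_monotonicity():
    assert nm.aicc(-39.0, 3, 145) < nm.aicc(-40.0, 3, 145)
    assert nm.aicc(-40.0, 4, 145) > nm.aicc(-40.0, 3, 145)


# ---------------------------------------------------------------- dredge


def test_dredge_counts_and_best_delta(summaries):
    table = nm.dredge_subsets(
        ("mean_annual_temp", "radiation"), summaries, "presence"
    )
    assert len(table) == 4  # 2^2 subsets
    assert table["deltaAICc"].iloc[0] == 0.0
    four = nm.dredge_subsets(
        ("mean_annual_temp", "radiation", "forest_ratio", "annual_precip"),
        summaries,
        "presence",
    )
    assert len(four) == 16


def test_dredge_finds_true_predictor():
    rng = np.random.default_rng(5)
    n = 5000
    x = rng.normal(size=n)
    noise = rng.normal(size=n)
    y = rng.binomial(1, expit(1.5 * x))
    data = pd.DataFrame({"signal": x, "noise": noise, "presence": y})
    table = nm.dredge_subsets(("signal", "noise"), data)
    assert "signal" in table["terms"].iloc[0]


def test_two_stage_selection_ranks_pooled_union(summaries):
    pooled = nm.two_stage_selection(summaries)
    assert pooled["deltaAICc"].iloc[0] == 0.0
    # temperature carries the signal in the synthetic world: the best model
    # should include a temperature-related term
    assert any(t in pooled["terms"].iloc[0] for t in nm.TEMPERATURE_VARS)
    # union over 10 dredges of 6 terms, deduplicated
    assert len(pooled) > 64


# ---------------------------------------------------------------- LOOCV


def test_loocv_order_equivariance(summaries):
    data = summaries.head(60).reset_index(drop=True)
    scores = nm.loocv_scores(["mean_annual_temp"], data)
    rng = np.random.default_rng(1)
    perm = rng.permutation(len(data))
    permuted = nm.loocv_scores(["mean_annual_temp"], data.iloc[perm].reset_index(drop=True))
    np.testing.assert_allclose(permuted, scores[perm], rtol=1e-10)


def test_loocv_counts_one_fit_per_record(summaries, monkeypatch):
    data = summaries.head(12).reset_index(drop=True)
    calls = []
    original = nm.fit_logistic
    monkeypatch.setattr(nm, "fit_logistic", lambda *a, **k: calls.append(1) or original(*a, **k))
    nm.loocv_scores(["mean_annual_temp"], data)
    assert len(calls) == 12


def test_loocv_auc_close_to_resubstitution(summaries):
    data = summaries.head(200).reset_index(drop=True)
    terms = ["mean_annual_temp", "radiation"]
    loocv = nm.loocv_scores(terms, data)
    m = nm.fit_logistic(data[terms], data["presence"])
    resub = m.predict_proba(data[terms])
    y = data["presence"].to_numpy()
    assert abs(nm.roc_auc(loocv, y) - nm.roc_auc(resub, y)) < 0.02


# ---------------------------------------------------------------- AUC / Youden


def test_auc_trivial_cases():
    assert nm.roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0
    assert nm.roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5
    with pytest.raises(nm.ModelStructureError):
        nm.roc_auc([0.1, 0.9], [1, 1])


def test_auc_matches_pairwise_oracle():
    rng = np.random.default_rng(7)
    for _ in range(50):
        n = rng.integers(4, 40)
        scores = rng.choice([0.1, 0.25, 0.5, 0.8], size=n)  # force ties
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            continue
        assert nm.roc_auc(scores, labels) == pytest.approx(
            auc_brute(scores, labels), abs=1e-12
        )


def test_youden_toy_and_degenerate():
    assert nm.youden_threshold(
        np.array([0.8, 0.9, 0.1, 0.2]), np.array([1, 1, 0, 0])
    ) == pytest.approx(0.5)
    # all scores equal: J = 0 everywhere, smallest candidate (-inf) wins
    assert nm.youden_threshold(np.ones(5), np.array([1, 0, 1, 0, 1])) == -np.inf


def test_youden_matches_exhaustive_scan():
    rng = np.random.default_rng(8)
    for _ in range(50):
        n = int(rng.integers(4, 30))
        scores = np.round(rng.random(n), 2)
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            continue
        tau = nm.youden_threshold(scores, labels)
        tau_b, j_b = youden_brute(scores, labels)
        assert tau == tau_b
        c = nm.confusion(scores, labels, tau)
        rep = nm.metrics(c)
        assert rep.informedness == pytest.approx(j_b, abs=1e-12)


# ---------------------------------------------------------------- confusion / metrics


def test_confusion_sentinels_and_hand_count():
    scores = np.array([0.9, 0.7, 0.4, 0.2, 0.6])
    labels = np.array([1, 0, 1, 0, 1])
    assert nm.confusion(scores, labels, -np.inf) == nm.ConfusionCounts(3, 2, 0, 0)
    assert nm.confusion(scores, labels, np.inf) == nm.ConfusionCounts(0, 0, 3, 2)
    assert nm.confusion(scores, labels, 0.5) == nm.ConfusionCounts(2, 1, 1, 1)


def test_metrics_printed_values_example():
    rep = nm.metrics(nm.ConfusionCounts(tp=112, fp=6, fn=4, tn=23))
    assert round(rep.mcc, 3) == 0.780
    assert round(rep.informedness, 3) == 0.759
    assert round(rep.accuracy, 3) == 0.931


def test_metrics_perfect_and_label_flip():
    perfect = nm.metrics(nm.ConfusionCounts(10, 0, 0, 10))
    assert perfect.mcc == 1.0 and perfect.accuracy == 1.0 and perfect.informedness == 1.0
    a = nm.metrics(nm.ConfusionCounts(8, 3, 2, 7))
    flipped = nm.metrics(nm.ConfusionCounts(2, 7, 8, 3))  # predictions inverted
    assert flipped.mcc == pytest.approx(-a.mcc)
    assert flipped.informedness == pytest.approx(-a.informedness)


def test_metrics_undefined_denominator_is_nan_not_zero():
    with pytest.warns(UserWarning):
        rep = nm.metrics(nm.ConfusionCounts(tp=0, fp=0, fn=5, tn=5))
    assert math.isnan(rep.ppv)
    assert not math.isnan(rep.accuracy)


def test_solve_confusion():
    assert nm.solve_confusion(116, 29, 0.931, 0.759) == nm.ConfusionCounts(
        tp=112, fp=6, fn=4, tn=23
    )
    assert nm.solve_confusion(10, 10, 1.0, 1.0) == nm.ConfusionCounts(10, 0, 0, 10)
    with pytest.raises(nm.ModelStructureError):
        nm.solve_confusion(10, 10, 0.0, 1.0)  # infeasible combination


# ---------------------------------------------------------------- collinearity


def test_collinearity_screen():
    rng = np.random.default_rng(9)
    x = rng.normal(size=10_000)
    df = pd.DataFrame(
        {
            "a": x,
            "dup": x,
            "neg": -x,
            "indep": rng.normal(size=10_000),
            "flat": np.ones(10_000),
        }
    )
    report = nm.collinearity_screen(df)
    flagged = {
        frozenset((r.var_a, r.var_b)) for r in report.pairs.itertuples()
    }
    assert frozenset(("a", "dup")) in flagged
    assert frozenset(("a", "neg")) in flagged
    assert not any("indep" in pair for pair in flagged)
    assert report.zero_variance == ("flat",)
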
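"""Tests of the beta-binomial likelihood, MLE fitting, AICc and bootstrap."""

import numpy as np
import pytest
from scipy import stats

from sexcost import (
    PairedFrequency,
    aicc,
    akaike_weights,
    betabinom_logpmf,
    bootstrap_confidence_set,
    bootstrap_param_ci,
    candidate_models,
    fit_model,
    neg_loglik,
    next_frequency,
    select_models,
)

MODELS = {m.id: m for m in candidate_models(["2012", "2013", "2014", "2015"])}


# ---------------------------------------------------------------------------
# beta-binomial pmf


def test_betabinom_single_trial_mean():
    assert betabinom_logpmf(1, 1, 0.3, 5.0) == pytest.approx(np.log(0.3), abs=1e-12)


def test_betabinom_matches_scipy_oracle():
    """Cross-check against the independent scipy parameterization
    (alpha = q*theta, beta = (1-q)*theta)."""
    for q in (0.05, 0.3, 0.7):
        for theta in (0.5, 7.0, 80.0):
            for n in (1, 10, 73):
                k = np.arange(n + 1)
                expected = stats.betabinom.logpmf(k, n, q * theta, (1 - q) * theta)
                got = betabinom_logpmf(k, n, q, theta)
                assert np.allclose(got, expected, atol=1e-10)


def test_betabinom_normalizes():
    for n in (1, 17, 200):
        for q in (0.1, 0.5, 0.93):
            for theta in (0.7, 12.0, 300.0):
                k = np.arange(n + 1)
                total = np.exp(betabinom_logpmf(k, n, q, theta)).sum()
                assert total == pytest.approx(1.0, abs=1e-10)


def test_betabinom_large_theta_is_binomial():
    k = np.arange(51)
    got = betabinom_logpmf(k, 50, 0.4, 1e8)
    assert np.allclose(got, stats.binom.logpmf(k, 50, 0.4), atol=1e-4)


def test_betabinom_no_overflow_large_n():
    value = betabinom_logpmf(5000, 10_000, 0.5, 40.0)
    assert np.isfinite(value)


@pytest.mark.parametrize(
    "k, n, q, theta", [(-1, 5, 0.5, 1.0), (6, 5, 0.5, 1.0), (2, 5, 0.0, 1.0),
                       (2, 5, 1.0, 1.0), (2, 5, 0.5, 0.0)]
)
def test_betabinom_domain_errors(k, n, q, theta):
    with pytest.raises(ValueError):
        betabinom_logpmf(k, n, q, theta)


# ---------------------------------------------------------------------------
# likelihood composition and fitting


def _pair(q_t, k, n, year="2012", mid="M1"):
    return PairedFrequency(q_t=q_t, offspring_k=k, offspring_n=n,
                           year=year, mesocosm_id=mid)


def test_neg_loglik_is_sum_of_logpmf():
    data = [_pair(0.3, 35, 70)]
    nll = neg_loglik(MODELS["two_fold"], {"theta": 12.0}, data)
    expected = -betabinom_logpmf(35, 70, next_frequency(0.3, 2.0), 12.0)
    assert nll == pytest.approx(expected, rel=1e-12)


def test_neg_loglik_empty_data():
    assert neg_loglik(MODELS["two_fold"], {"theta": 5.0}, []) == 0.0


def test_neg_loglik_invalid_cost_is_infinite():
    data = [_pair(0.3, 35, 70, year="2013")]
    params = {"theta": 10.0, "c0": 1.0, "d_2013": -1.5, "d_2014": 0.0,
              "d_2015": 0.0}
    assert neg_loglik(MODELS["mle_by_year"], params, data) == np.inf


def _noiseless_data(c, n=70, n_reps=24):
    """Offspring counts fixed at their exact expectation under cost c."""
    rng = np.random.default_rng(7)
    data = []
    years = ["2012", "2013", "2014", "2015"]
    for i in range(n_reps):
        q = float(rng.uniform(0.1, 0.6))
        k = n * next_frequency(q, c)  # fractional pseudo-count
        data.append(
            {"q_t": q, "offspring_k": k, "offspring_n": n,
             "year": years[i % 4], "mesocosm_id": f"M{i}"}
        )
    import pandas as pd

    return pd.DataFrame(data)


def test_fit_recovers_cost_from_noiseless_data():
    df = _noiseless_data(c=2.0)
    fit = fit_model(MODELS["mle"], df, seed=0)
    assert fit.converged
    assert fit.estimates["c"] == pytest.approx(2.0, abs=1e-2)


def test_nested_models_agree_under_null():
    """Data generated with c = 1: the free-cost fit collapses onto no-cost."""
    from sexcost import SyntheticConfig, generate_experiment, paired_frequencies

    records, _ = generate_experiment(SyntheticConfig(seed=11, true_c=1.0))
    pairs, _ = paired_frequencies(records)
    free = fit_model(MODELS["mle"], pairs, seed=0)
    null = fit_model(MODELS["no_cost"], pairs, seed=0)
    assert free.estimates["c"] == pytest.approx(1.0, abs=0.15)
    assert abs(free.logL - null.logL) < 1.0
    # nesting: the free model's optimum cannot be worse
    assert free.logL >= null.logL - 1e-6


def test_fit_requires_enough_replicates():
    with pytest.raises(ValueError, match="replicates"):
        fit_model(MODELS["mle_by_year"], [_pair(0.3, 35, 70)])


# ---------------------------------------------------------------------------
# information criteria


@pytest.mark.parametrize(
    "logL, k, expected",
    [(-100.78, 1, 203.74), (-86.27, 1, 174.73), (-85.16, 5, 183.65)],
)
def test_aicc_selection_table_arithmetic(logL, k, expected):
    """Selection-table AICc values follow from logL with n = 24 replicates
    (the year-indexed model counts five parameters)."""
    assert aicc(logL, k, 24) == pytest.approx(expected, abs=0.01)


def test_aicc_reduces_to_aic_for_large_n():
    assert aicc(-50.0, 3, 10**9) == pytest.approx(-2 * -50.0 + 6, abs=1e-6)


def test_aicc_domain():
    with pytest.raises(ValueError):
        aicc(-10.0, 5, 6)


def test_akaike_weights_worked_row():
    w = akaike_weights([29.01, 0.00, 1.98, 8.93])
    assert w.sum() == pytest.approx(1.0)
    assert round(w[1], 2) == 0.72
    assert round(w[2], 2) == 0.27
    assert round(w[0], 2) == 0.00


def test_akaike_weights_edge_cases():
    assert akaike_weights([0.0]) == pytest.approx([1.0])
    assert akaike_weights([0.0, 0.0]) == pytest.approx([0.5, 0.5])
    with pytest.raises(ValueError):
        akaike_weights([])


def test_akaike_weights_shift_invariant():
    deltas = np.array([0.0, 1.3, 5.2])
    assert np.allclose(akaike_weights(deltas), akaike_weights(deltas + 17.0))


# ---------------------------------------------------------------------------
# model selection and bootstrap


def test_select_models_ranking(paper_like_pairs):
    results = select_models(paper_like_pairs, seed=0)
    ids = [r.model_id for r in results]
    assert set(ids) == set(MODELS)
    assert results[0].delta_aicc == 0.0
    assert sum(r.akaike_weight for r in results) == pytest.approx(1.0)
    aiccs = [r.aicc for r in results]
    assert aiccs == sorted(aiccs)
    # true two-fold cost: the no-cost model should rank behind both
    # cost-bearing single-cost models
    assert ids.index("no_cost") > ids.index("two_fold")
    assert ids.index("no_cost") > ids.index("mle")
    weights = {r.model_id: r.akaike_weight for r in results}
    assert weights["no_cost"] < 0.05


def test_bootstrap_identity_resample(paper_like_pairs):
    """With the identity resample the delta-AICc limit is the focal model's
    actual delta."""
    idx = np.arange(len(paper_like_pairs))
    conf = bootstrap_confidence_set(
        paper_like_pairs, indices=[idx], focal_model="two_fold", seed=None, B=1
    )
    assert conf.B == 1
    assert conf.delta_limit == pytest.approx(
        conf.actual_delta["two_fold"], abs=5e-4
    )
    assert "two_fold" in conf.confidence_set


def test_bootstrap_seed_mandatory(paper_like_pairs):
    with pytest.raises(ValueError, match="seed"):
        bootstrap_confidence_set(paper_like_pairs, B=2)
    with pytest.raises(ValueError, match="seed"):
        bootstrap_param_ci(paper_like_pairs, MODELS["mle"], B=2)


def test_bootstrap_param_ci_degenerate_data():
    """24 copies of one replicate: every resample is the same dataset, so
    the percentile interval collapses."""
    data = [_pair(0.3, 40, 70, mid=f"M{i}") for i in range(24)]
    ci = bootstrap_param_ci(data, MODELS["mle"], B=20, seed=5)
    lo, hi = ci["c"]
    assert hi - lo < 1e-6


def test_bootstrap_param_ci_reproducible(paper_like_pairs):
    a = bootstrap_param_ci(paper_like_pairs, MODELS["mle"], B=30, seed=9)
    b = bootstrap_param_ci(paper_like_pairs, MODELS["mle"], B=30, seed=9)
    assert a == b
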
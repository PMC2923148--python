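import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aacost.expression import (
    IMPORTANCE_CAP,
    RankDeficientDesignError,
    compute_features,
    fit_expression_model,
    log_scale_column,
    prepare_features,
    prune_interactions,
    transform_and_scale,
    variable_importance,
)
from aacost.synth import ExpressionSimSpec, simulate_expression


@pytest.fixture(scope="module")
def abs_cost():
    from aacost.compendium import load_compendium
    return load_compendium().column("abs_glc")


# -- features ----------------------------------------------------------------


def test_homopolymer_mean_equals_residue_value(properties, abs_cost):
    weight = properties.column("mol_weight")
    rec = compute_features("MMM", 0.5, properties, weight)
    assert rec.mean_cost == pytest.approx(149.2)


def test_mean_sulphur_counts_cys_and_met(properties, abs_cost):
    rec = compute_features("ACD", 0.5, properties, abs_cost)
    assert rec.mean_sulphur == pytest.approx(1 / 3)
    rec = compute_features("ACM", 0.5, properties, abs_cost)
    assert rec.mean_sulphur == pytest.approx(2 / 3)


def test_trailing_stop_is_stripped(properties, abs_cost):
    with_stop = compute_features("MKV*", 0.5, properties, abs_cost)
    without = compute_features("MKV", 0.5, properties, abs_cost)
    assert with_stop.length == without.length == 3
    assert with_stop.mean_cost == pytest.approx(without.mean_cost)


def test_empty_sequence_rejected(properties, abs_cost):
    with pytest.raises(ValueError, match="empty"):
        compute_features("", 0.5, properties, abs_cost)


def test_unknown_residue_rejected(properties, abs_cost):
    with pytest.raises(ValueError, match="unknown residue"):
        compute_features("MKO", 0.5, properties, abs_cost)


def test_cai_domain_enforced(properties, abs_cost):
    with pytest.raises(ValueError, match="CAI"):
        compute_features("MKV", 1.5, properties, abs_cost)


# -- scaling -----------------------------------------------------------------


def test_log_scale_closed_form():
    out = transform_and_scale([1.0, np.e, np.e ** 2], log_first=True)
    expected = np.array([0.0, 1.0, 2.0])
    expected = (expected - 1.0) / np.sqrt(np.mean((expected - 1.0) ** 2))
    assert np.allclose(out, expected, atol=1e-12)


def test_constant_column_rejected():
    with pytest.raises(ValueError, match="zero-variance"):
        transform_and_scale([3.0, 3.0, 3.0])


def test_log_requires_positive():
    with pytest.raises(ValueError, match="strictly positive"):
        transform_and_scale([1.0, 0.0, 2.0], log_first=True)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_scaled_output_has_zero_mean_unit_rms(seed):
    rng = np.random.default_rng(seed)
    x = rng.lognormal(size=rng.integers(5, 200))
    out = transform_and_scale(x, log_first=True)
    assert abs(out.mean()) < 1e-12
    assert abs(np.sqrt(np.mean(out ** 2)) - 1.0) < 1e-12


def test_pseudocount_only_when_zeros_present():
    x = np.array([1.0, 2.0, 4.0])
    assert np.allclose(log_scale_column(x),
                       transform_and_scale(x, log_first=True))
    with_zero = log_scale_column(np.array([0.0, 1.0, 2.0, 4.0]))
    assert np.isfinite(with_zero).all()


# -- regression --------------------------------------------------------------


def test_coefficient_recovery_single_driver(properties, abs_cost):
    spec = ExpressionSimSpec(n_genes=2000, coefficients={"cai": 2.0},
                             noise_sd=0.5, seed=42)
    data, _ = simulate_expression(spec, properties, abs_cost)
    report = fit_expression_model(data)
    assert report.params["cai"] == pytest.approx(2.0, abs=0.05)
    for name in ("cost", "trna", "carbon", "nitrogen", "sulphur"):
        se = report.result.bse[name]
        assert abs(report.params[name]) <= 3 * se


def test_noiseless_linear_response_has_unit_adjusted_r2(properties, abs_cost):
    spec = ExpressionSimSpec(n_genes=200, coefficients={"cai": 1.0,
                                                        "cost": -0.5},
                             noise_sd=0.0, seed=1)
    data, _ = simulate_expression(spec, properties, abs_cost)
    report = fit_expression_model(data)
    assert report.adj_r2 == pytest.approx(1.0, abs=1e-10)


def test_adjusted_r2_matches_closed_form(properties, abs_cost):
    spec = ExpressionSimSpec(n_genes=400, coefficients={"cai": 1.0},
                             noise_sd=1.0, seed=3)
    data, _ = simulate_expression(spec, properties, abs_cost)
    report = fit_expression_model(data)
    res = report.result
    n = int(res.nobs)
    p = len(res.params) - 1
    oracle = 1 - (1 - res.rsquared) * (n - 1) / (n - p - 1)
    assert report.adj_r2 == pytest.approx(oracle, abs=1e-12)


def test_duplicated_predictor_raises_rank_error(properties, abs_cost):
    spec = ExpressionSimSpec(n_genes=100, seed=5)
    data, _ = simulate_expression(spec, properties, abs_cost)
    data["dup"] = data["cai"]
    with pytest.raises(RankDeficientDesignError, match="dup|cai"):
        fit_expression_model(
            data, predictors=("cost", "cai", "dup", "trna"))


def test_parameter_recovery_coverage_over_replicates(properties, abs_cost):
    """Fitted coefficients fall within 3 SE of truth in >= 95% of replicates."""
    truth = {"cai": 2.0, "cost": -0.5, "trna": 0.0, "carbon": 0.0,
             "nitrogen": 0.0, "sulphur": 0.0}
    n_reps = 200
    hits = 0
    for rep in range(n_reps):
        spec = ExpressionSimSpec(n_genes=120,
                                 coefficients={"cai": 2.0, "cost": -0.5},
                                 noise_sd=0.5, seed=50_000 + rep,
                                 min_length=50, max_length=200)
        data, _ = simulate_expression(spec, properties, abs_cost)
        report = fit_expression_model(data)
        ok = all(abs(report.params[k] - v) <= 3 * report.result.bse[k]
                 for k, v in truth.items())
        hits += ok
    assert hits / n_reps >= 0.95


# -- stepwise pruning and importance ----------------------------------------


def test_spurious_interactions_all_removed(properties, abs_cost):
    spec = ExpressionSimSpec(n_genes=1200, coefficients={"cai": 2.0},
                             conditions=("a", "b", "c"), noise_sd=0.5, seed=9)
    data, _ = simulate_expression(spec, properties, abs_cost)
    report = fit_expression_model(data, condition_cols=("condition",))
    pruned = prune_interactions(report)
    assert pruned.retained_interactions == ()


def test_true_interaction_retained(properties, abs_cost):
    spec = ExpressionSimSpec(n_genes=1500, coefficients={"cai": 2.0},
                             conditions=("a", "b"),
                             interaction_effects={("cai", "b"): 1.0},
                             noise_sd=0.5, seed=11)
    data, _ = simulate_expression(spec, properties, abs_cost)
    report = fit_expression_model(data, condition_cols=("condition",))
    pruned = prune_interactions(report)
    assert "cai:C(condition)" in pruned.retained_interactions


def test_model_without_interactions_unchanged(properties, abs_cost):
    spec = ExpressionSimSpec(n_genes=300, seed=13)
    data, _ = simulate_expression(spec, properties, abs_cost)
    report = fit_expression_model(data, interactions=())
    pruned = prune_interactions(report)
    assert pruned.retained_interactions == ()
    assert pruned.aic == pytest.approx(report.aic, abs=1e-9)


def test_importance_dominated_by_true_driver(properties, abs_cost):
    spec = ExpressionSimSpec(n_genes=2000, coefficients={"cai": 2.0,
                                                         "cost": -0.2},
                             noise_sd=0.5, seed=17)
    data, _ = simulate_expression(spec, properties, abs_cost)
    report = variable_importance(fit_expression_model(data))
    imp = report.importance
    assert imp.idxmax() == "cai"
    # half an order of magnitude above the runner-up, at least
    runner_up = imp.drop("cai").max()
    assert imp["cai"] > max(10.0, 3 * abs(runner_up))


def test_useless_predictors_have_nonpositive_importance(properties, abs_cost):
    spec = ExpressionSimSpec(n_genes=1000, coefficients={}, noise_sd=1.0,
                             seed=19)
    data, _ = simulate_expression(spec, properties, abs_cost)
    report = variable_importance(fit_expression_model(data))
    # dropping a useless parameter lowers AIC by up to 2 per parameter
    assert (report.importance <= 2.0).all()


def test_perfect_fit_importance_capped(properties, abs_cost):
    spec = ExpressionSimSpec(n_genes=200, coefficients={"cai": 1.0},
                             noise_sd=0.0, seed=23)
    data, _ = simulate_expression(spec, properties, abs_cost)
    report = variable_importance(fit_expression_model(data))
    assert report.importance_capped["cai"]
    assert report.importance["cai"] == IMPORTANCE_CAP


def test_prepare_features_scales_raw_table(properties, abs_cost):
    rng = np.random.default_rng(29)
    n = 80
    raw = pd.DataFrame({
        "cost": rng.uniform(0.5, 2.5, n), "cai": rng.uniform(0.1, 0.9, n),
        "trna": rng.uniform(5, 20, n), "carbon": rng.uniform(4, 6, n),
        "nitrogen": rng.uniform(1, 2, n),
        "sulphur": rng.uniform(0.0, 0.1, n),
        "response": rng.lognormal(5, 1, n),
    })
    prepared = prepare_features(raw, response_kind="protein")
    for col in ("response", "cai", "cost", "sulphur"):
        assert abs(prepared[col].mean()) < 1e-12
        assert np.sqrt(np.mean(prepared[col] ** 2)) == pytest.approx(1.0,
                                                                     abs=1e-12)
    # protein response is log-transformed before scaling: monotone in the raw
    order = np.argsort(raw["response"].to_numpy())
    assert (np.diff(prepared["response"].to_numpy()[order]) > 0).all()
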
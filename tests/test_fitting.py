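import numpy as np
import pytest

from focikit import (DatasetSuite, ExperimentKind, FitProblem, FociDataset,
                     OptimizerConfig, ParameterSet, TLKRegressor, fit_ensemble,
                     fit_model, generate_suite, get_variant, objective,
                     study_bounds, suite_to_xy, weights_from_suite)
from focikit.data import default_design
from focikit.fitting import ResidualEvaluator


def _mini_dataset(eid, means, kind=ExperimentKind.GAMMAH2AX_TIMECOURSE,
                  role="fit"):
    n = len(means)
    return FociDataset(
        experiment_id=eid, kind=kind, doses=np.full(n, 2.0),
        times=np.linspace(0.1, 1.0, n), means=np.asarray(means, float),
        sems=np.zeros(n), n_cells=np.full(n, 10), role=role,
    )


def test_weights_are_inverse_experiment_means():
    suite = DatasetSuite([
        _mini_dataset("a", [2.0, 4.0]),
        _mini_dataset("b", [1.0, 1.0, 1.0]),
    ])
    w = weights_from_suite(suite)
    assert w["a"] == pytest.approx(1.0 / 3.0)
    assert w["b"] == pytest.approx(1.0)
    # order preserved and one weight per fitted experiment
    assert list(w) == ["a", "b"]


def test_zero_mean_experiment_rejected():
    suite = DatasetSuite([_mini_dataset("z", [0.0, 0.0])])
    with pytest.raises(ValueError, match="non-positive mean"):
        weights_from_suite(suite)


def test_objective_zero_at_ground_truth(noisefree_suite, truth):
    variant, params = truth
    problem = FitProblem(noisefree_suite, variant,
                         bounds=study_bounds(variant))
    ssr = objective(params.to_vector(variant), problem)
    assert ssr == pytest.approx(0.0, abs=1e-8)


def test_objective_hand_arithmetic(truth):
    """Residuals (+1, -1) under weight 0.5 give SSR = 1."""
    variant, params = truth
    suite = generate_suite(variant, params, seed=0, noise=False)
    e = suite.fit_experiments[0]
    perturbed = e.means.copy()
    perturbed[0] += 1.0
    perturbed[1] -= 1.0
    e.means[:] = perturbed
    problem = FitProblem(
        DatasetSuite([e]), variant, weights={e.experiment_id: 0.5},
        rtol=1e-8, atol=1e-10)  # same solver tolerance the means used
    ssr = ResidualEvaluator(problem)(np.asarray(params.to_vector(variant)))
    assert ssr == pytest.approx(0.5 * 2.0, abs=1e-6)


def test_objective_invariant_to_experiment_order(suite50, truth):
    variant, params = truth
    theta = params.to_vector(variant)
    fwd = FitProblem(suite50, variant)
    rev = FitProblem(DatasetSuite(list(suite50)[::-1]), variant)
    assert ResidualEvaluator(fwd)(theta) == pytest.approx(
        ResidualEvaluator(rev)(theta))


def test_objective_rejects_out_of_bounds_theta(suite50, truth):
    variant, params = truth
    problem = FitProblem(suite50, variant, bounds=study_bounds(variant))
    theta = np.asarray(params.to_vector(variant))
    theta[0] = 1e9
    with pytest.raises(ValueError, match="bounds"):
        objective(theta, problem)


def test_collapsed_bounds_return_that_point(suite50, truth):
    variant, params = truth
    from focikit import parameter_names

    point = {n: (v, v) for n, v in
             zip(parameter_names(variant), params.to_vector(variant))}
    problem = FitProblem(suite50, variant, bounds=point)
    res = fit_model(problem, OptimizerConfig(population=4, generations=2,
                                             polish=False), seed=0)
    np.testing.assert_allclose(res.params.to_vector(variant),
                               params.to_vector(variant), rtol=1e-9)
    # log10-space round-trip costs a few ulps in the parameters
    assert res.ssr == pytest.approx(
        ResidualEvaluator(problem)(np.asarray(params.to_vector(variant))),
        rel=1e-6)


def test_fit_recovers_first_order_rates_noise_free(truth):
    """Fitting the simplest no-protein model to its own noise-free data
    recovers the fast and slow repair rates within 5%."""
    v7 = get_variant(7)
    gt = ParameterSet(kDSB=8.0, c=0.1, k1=3.0, k3=0.3, kTAF=0.8, T0=0.5,
                      B=1.0)
    suite = generate_suite(v7, gt, default_design(n_cells=50), seed=0,
                           noise=False)
    problem = FitProblem(suite, v7, bounds=study_bounds(v7))
    res = fit_model(problem, OptimizerConfig(budget_scale=0.15,
                                             polish_maxfev=600,
                                             polish_top=1), seed=2)
    assert res.params.get("k1") == pytest.approx(3.0, rel=0.05)
    assert res.params.get("k3") == pytest.approx(0.3, rel=0.05)
    assert res.n == 49 and res.k == 7


def test_fit_is_deterministic_under_seed(suite50):
    v7 = get_variant(7)
    problem = FitProblem(suite50, v7, bounds=study_bounds(v7))
    cfg = OptimizerConfig(population=6, generations=20, polish_maxfev=100,
                          polish_top=1, polish_restarts=1)
    a = fit_model(problem, cfg, seed=11)
    b = fit_model(problem, cfg, seed=11)
    assert a.ssr == b.ssr
    assert a.params.to_dict() == b.params.to_dict()


def test_richer_model_never_beaten_by_nested_submodel(suite50, truth):
    """A model containing the cross-term channel can emulate its nested
    submodel by sending kcross to the bound, so its attainable SSR is no
    larger."""
    v8, v6 = get_variant(8), get_variant(6)  # v6 = v8 + kcross
    p8 = FitProblem(suite50, v8, bounds=study_bounds(v8))
    res8 = fit_model(p8, OptimizerConfig(budget_scale=0.1,
                                         polish_maxfev=300,
                                         polish_top=1,
                                         polish_restarts=1), seed=3)
    theta6 = dict(res8.params.to_dict())
    theta6["kcross"] = 1e-6  # lower bound of the study box
    p6 = FitProblem(suite50, v6, bounds=study_bounds(v6))
    emb = ResidualEvaluator(p6)(
        np.asarray(ParameterSet(**theta6).to_vector(v6)))
    assert emb <= res8.ssr * (1.0 + 1e-3)


def test_ensemble_results_order_independent(suite50):
    variants = [get_variant(7), get_variant(8)]
    cfg = OptimizerConfig(population=5, generations=10, polish=False)
    fwd = fit_ensemble(suite50, variants, cfg, seed=4,
                       bounds=None)
    rev = fit_ensemble(suite50, variants[::-1], cfg, seed=4,
                       bounds=None)
    by_id_fwd = {r.variant.variant_id: r.ssr for r in fwd}
    by_id_rev = {r.variant.variant_id: r.ssr for r in rev}
    assert by_id_fwd == by_id_rev


def test_sklearn_estimator_contract(suite50):
    X, y = suite_to_xy(suite50)
    est = TLKRegressor(variant_id=7, population=5, generations=10,
                       polish=False, random_state=0,
                       bounds=study_bounds(get_variant(7)))
    est.fit(X, y)
    assert hasattr(est, "params_") and est.k_ == 7 and est.n_ == 49
    yhat = est.predict(X)
    assert yhat.shape == y.shape
    assert np.all(np.isfinite(yhat))
    # get_params/set_params round-trip (sklearn clone compatibility)
    from sklearn.base import clone

    cloned = clone(est)
    assert cloned.get_params()["variant_id"] == 7
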
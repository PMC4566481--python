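import numpy as np
import pytest
from scipy.stats import f as f_dist

from focikit import (OptimizerConfig, ParameterSet,
                     classify_identifiability, cross_validate, get_variant,
                     lhs_robustness, sigma_sim)
from focikit.fitting import FitProblem, study_bounds
from focikit.validation import (CrossValReport, LikelihoodProfile,
                                f_ratio_threshold, prediction_error)


# -- cross-validation ------------------------------------------------------

def test_average_error_is_mean_of_runs():
    runs = [{"held_out": str(i), "error": e}
            for i, e in enumerate([10.0, 20.0, 30.0, 40.0, 50.0])]
    rep = CrossValReport(10, runs, float(np.mean([r["error"] for r in runs])))
    assert rep.average_error == 30.0


def test_prediction_error_zero_for_exact_prediction(noisefree_suite, truth):
    variant, params = truth
    held = noisefree_suite.get("gH2AX_tc_2.5Gy")
    from focikit.fitting import FitResult

    fit = FitResult(variant=variant, params=params, ssr=0.0, n=49,
                    k=variant.k)
    assert prediction_error(fit, held) == pytest.approx(0.0, abs=1e-8)


def test_taf_experiments_never_held_out(suite50):
    """Hold-out candidates exclude TAF series: they carry the only
    information about the persistent-damage parameters."""
    eligible = [e for e in suite50.fit_experiments if not e.kind.is_taf]
    assert len(eligible) == 5
    assert all("TAF" not in e.experiment_id for e in eligible)


def test_true_model_predicts_held_out_data_better_than_misspecified(truth):
    """Cross-validated prediction error of the generating structure beats
    the linear-dose first-order one on the same data."""
    variant, params = truth
    from focikit import generate_suite
    from focikit.data import default_design

    design = [d for d in default_design(n_cells=50)
              if d.experiment_id in ("gH2AX_tc_2.5Gy", "gH2AX_tc_10Gy",
                                     "gH2AX_dr_1d", "TAF_dr_1d")]
    suite = generate_suite(variant, params, design, seed=4)
    cfg = OptimizerConfig(population=8, generations=60, polish_maxfev=250,
                          polish_top=1, polish_restarts=1)
    cv10 = cross_validate(suite, get_variant(10), cfg, seed=0,
                          bounds=study_bounds(get_variant(10)))
    cv7 = cross_validate(suite, get_variant(7), cfg, seed=0,
                         bounds=study_bounds(get_variant(7)))
    assert len(cv10.runs) == 3
    assert cv10.average_error < cv7.average_error


# -- profile likelihood ----------------------------------------------------

def _toy_profile(n=49, k=10, s=0.3, theta_hat=1.0, ssr_min=40.0,
                 n_points=2001, span=1.0):
    """Quadratic log-likelihood toy with known threshold crossings."""
    F = f_dist.ppf(0.95, 1, n - k)
    grid = np.geomspace(theta_hat * 10 ** -span, theta_hat * 10 ** span,
                        n_points)
    ssr = ssr_min * (1.0 + ((grid - theta_hat) / s) ** 2 * F / (n - k))
    return LikelihoodProfile(
        parameter="toy", values=grid, ssr=ssr, fitted_value=theta_hat,
        ssr_min=ssr_min, threshold=f_ratio_threshold(ssr_min, n, k), n=n,
        k=k,
    )


def test_quadratic_profile_crosses_threshold_at_known_points():
    prof = _toy_profile()
    lo, hi = prof.confidence_interval()
    assert lo == pytest.approx(1.0 - 0.3, rel=1e-3)
    assert hi == pytest.approx(1.0 + 0.3, rel=1e-3)
    assert classify_identifiability(prof) == "practical"


def test_monotone_profile_classifies_one_sided():
    prof = _toy_profile()
    ssr = prof.ssr.copy()
    ssr[prof.values < prof.fitted_value] = prof.ssr_min  # flat left branch
    prof.ssr = ssr
    assert classify_identifiability(prof) == "one_sided"


def test_flat_profile_classifies_non_identifiable():
    prof = _toy_profile()
    prof.ssr = np.full_like(prof.ssr, prof.ssr_min * (1 + 1e-9))
    assert classify_identifiability(prof) == "non_identifiable"


def test_bounded_but_uncrossed_profile_classifies_structural():
    prof = _toy_profile()
    prof.ssr = np.minimum(prof.ssr, prof.threshold * 0.99)
    assert classify_identifiability(prof) == "structural"


def test_structurally_silent_parameter_has_flat_profile(truth):
    """With no complex breaks in the ground truth (c = 0), the
    complex-repair rate ks has no observable effect and its profile is
    flat."""
    v10 = get_variant(10)
    params = ParameterSet(kDSB=25.0, c=0.0, k1=0.4, k3=0.07, kTAF=0.8,
                          T0=0.5, B=1.0, kcross=0.0, kf=12.0, ks=1.0)
    from focikit import generate_suite
    from focikit.data import default_design

    design = [d for d in default_design(n_cells=50)
              if d.experiment_id in ("gH2AX_tc_2.5Gy", "TAF_dr_1d")]
    suite = generate_suite(v10, params, design, seed=0, noise=False)
    problem = FitProblem(suite, v10, bounds=study_bounds(v10))
    # scan ks without re-optimization noise: evaluate the raw objective
    from focikit.fitting import ResidualEvaluator

    ev = ResidualEvaluator(problem)
    grid = np.geomspace(0.1, 10.0, 9)
    ssrs = []
    for val in grid:
        theta = params.to_dict()
        theta["ks"] = val
        ssrs.append(ev(np.asarray(ParameterSet(**theta).to_vector(v10))))
    assert np.ptp(ssrs) < 1e-10  # ks cannot move the observables


# -- sigma_sim and LHS robustness -----------------------------------------

def test_sigma_sim_identical_ensemble_is_zero():
    opt = np.array([10.0, 8.0, 6.0])
    ens = np.tile(opt, (5, 1))
    np.testing.assert_allclose(sigma_sim(ens, opt), 0.0)


def test_sigma_sim_single_member_scale():
    opt = np.array([10.0, 20.0])
    ens = 1.1 * opt[None, :]
    np.testing.assert_allclose(sigma_sim(ens, opt), 0.1)


def test_sigma_sim_two_member_hand_example():
    assert sigma_sim(np.array([[8.0], [12.0]]),
                     np.array([10.0]))[0] == pytest.approx(0.2)


def test_sigma_sim_permutation_invariant():
    rng = np.random.default_rng(0)
    opt = rng.uniform(5, 15, size=7)
    ens = opt[None, :] * rng.uniform(0.8, 1.2, size=(6, 7))
    a = sigma_sim(ens, opt)
    b = sigma_sim(ens[::-1], opt)
    np.testing.assert_allclose(a, b)


def test_sigma_sim_undefined_at_zero_optimum():
    with pytest.raises(ValueError, match="zero"):
        sigma_sim(np.ones((2, 2)), np.array([1.0, 0.0]))


def test_zero_width_perturbation_degenerates(truth):
    variant, params = truth
    rep = lhs_robustness(params, variant, doses=(2.5,), rel_width=0.0,
                         n_samples=5, seed=0,
                         times=np.geomspace(0.05, 30.0, 25))
    assert rep.max_sigma(2.5) == 0.0
    row = rep.tau.iloc[0]
    assert row["tau_mean"] == pytest.approx(row["tau_optimal"])
    assert row["tau_sd"] == 0.0


def test_sigma_envelope_grows_with_dose(truth):
    variant, params = truth
    rep = lhs_robustness(params, variant, doses=(2.5, 10.0, 20.0),
                         rel_width=0.2, n_samples=100, seed=1,
                         times=np.geomspace(0.05, 60.0, 30))
    m25, m10, m20 = (rep.max_sigma(d) for d in (2.5, 10.0, 20.0))
    assert m25 < m10 < m20
    # the band contains the generating trajectory
    for dose in (2.5, 10.0, 20.0):
        q05 = rep.quantiles[dose]["q05"].to_numpy()
        q95 = rep.quantiles[dose]["q95"].to_numpy()
        opt = rep.optimal[dose].to_numpy()
        inside = (q05 <= opt + 1e-9) & (opt <= q95 + 1e-9)
        assert inside.mean() > 0.9
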
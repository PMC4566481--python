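import pytest

from focikit import (OptimizerConfig, default_design, default_ground_truth,
                     generate_suite, get_variant)


@pytest.fixture(scope="session")
def truth():
    """Canonical synthetic ground truth (variant, parameters)."""
    return default_ground_truth()


@pytest.fixture(scope="session")
def suite50(truth):
    """Default-noise suite: 49 fitted points, 50 cells per point."""
    variant, params = truth
    return generate_suite(variant, params, default_design(n_cells=50),
                          seed=1)


@pytest.fixture(scope="session")
def suite200(truth):
    """Low-noise suite: 49 fitted points, 200 cells per point."""
    variant, params = truth
    return generate_suite(variant, params, default_design(n_cells=200),
                          seed=1)


@pytest.fixture(scope="session")
def noisefree_suite(truth):
    """Suite whose means are the exact model values (no sampling)."""
    variant, params = truth
    return generate_suite(variant, params, default_design(n_cells=50),
                          seed=0, noise=False)


@pytest.fixture(scope="session")
def recovery_fit(suite200):
    """Variant-10 fit of the low-noise suite at reduced optimizer budget.

    Session-scoped: the parameter-recovery and identifiability checks all
    interrogate this single fit.
    """
    from focikit import FitProblem, fit_model, study_bounds

    v10 = get_variant(10)
    problem = FitProblem(suite200, v10, bounds=study_bounds(v10))
    result = fit_model(problem, OptimizerConfig(budget_scale=0.2), seed=1)
    return problem, result
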
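"""Scikit-learn style estimators for damage-kinetics model fitting.

:class:`TLKRegressor` fits one candidate model to foci measurements by
weighted least squares with the evolutionary-programming search.  The
tabular interface follows the sklearn contract: ``X`` is a DataFrame (or
record array) with columns ``experiment_id``, ``kind``, ``dose_Gy`` and
``time_days`` identifying each measurement, and ``y`` holds the measured
mean foci per cell.  Fitted state lives in trailing-underscore attributes
and the estimator composes with sklearn model-selection utilities (grouped
by ``experiment_id``).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .data import DatasetSuite, ExperimentKind, FociDataset
from .optimize import OptimizerConfig, minimize_ep
from .variants import ParameterSet, get_variant

__all__ = ["TLKRegressor", "suite_to_xy"]

_X_COLUMNS = ("experiment_id", "kind", "dose_Gy", "time_days")


def suite_to_xy(suite: DatasetSuite, fit_only: bool = True):
    """Flatten a suite into the (X, y) pair the estimators consume."""
    df = suite.to_frame()
    if fit_only:
        df = df[df["role"] == "fit"]
    X = df[list(_X_COLUMNS)].reset_index(drop=True)
    y = df["mean"].to_numpy(float)
    return X, y


def _xy_to_suite(X, y) -> DatasetSuite:
    df = pd.DataFrame(X, columns=list(_X_COLUMNS)) if not isinstance(
        X, pd.DataFrame) else X.copy()
    missing = [c for c in _X_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"X is missing columns {missing}")
    df = df.reset_index(drop=True)
    y = np.asarray(y, float)
    if len(y) != len(df):
        raise ValueError("X and y have inconsistent lengths")
    experiments = []
    for eid in df["experiment_id"].unique():
        m = df["experiment_id"] == eid
        sub = df[m]
        experiments.append(FociDataset(
            experiment_id=str(eid),
            kind=ExperimentKind(sub["kind"].iloc[0]),
            doses=sub["dose_Gy"].to_numpy(float),
            times=sub["time_days"].to_numpy(float),
            means=y[m.to_numpy()],
            sems=np.zeros(int(m.sum())),
            n_cells=np.ones(int(m.sum()), dtype=int),
        ))
    return DatasetSuite(experiments)


class TLKRegressor(RegressorMixin, BaseEstimator):
    """Weighted least-squares fit of one extended-TLK model variant.

    Parameters
    ----------
    variant_id : int, default=10
        Which of the 20 candidate model structures to fit.
    bounds : dict or None
        Per-parameter ``(low, high)`` search bounds; unset parameters fall
        back to the package-wide defaults.
    weights : dict or None
        Per-experiment weights; ``None`` uses the inverse of each fitted
        series' mean (recomputed from the data being fitted).
    population, generations, budget_scale, polish, polish_maxfev
        Evolutionary-search budget; see
        :class:`focikit.optimize.OptimizerConfig`.
    warm_starts : tuple of parameter vectors
        Vectors injected into the initial population.
    rtol, atol : float
        ODE solver tolerances used during fitting.
    random_state : int or None
        Seed for the stochastic search; fits are reproducible given it.

    Attributes
    ----------
    params_ : ParameterSet          fitted parameters
    ssr_ : float                    weighted sum of squared residuals
    n_ : int                        number of fitted data points
    k_ : int                        number of free parameters
    weights_ : dict                 per-experiment weights actually used
    optimizer_result_ : OptimizerResult
    """

    def __init__(
        self,
        variant_id: int = 10,
        bounds: Optional[dict] = None,
        weights: Optional[dict] = None,
        population: Optional[int] = None,
        generations: Optional[int] = None,
        budget_scale: float = 1.0,
        polish: bool = True,
        polish_maxfev: Optional[int] = None,
        warm_starts: tuple = (),
        rtol: float = 1e-6,
        atol: float = 1e-9,
        random_state: Optional[int] = None,
    ):
        self.variant_id = variant_id
        self.bounds = bounds
        self.weights = weights
        self.population = population
        self.generations = generations
        self.budget_scale = budget_scale
        self.polish = polish
        self.polish_maxfev = polish_maxfev
        self.warm_starts = warm_starts
        self.rtol = rtol
        self.atol = atol
        self.random_state = random_state

    # -- construction helpers -------------------------------------------

    @classmethod
    def from_problem(cls, problem, optimizer_config=None, seed=None):
        cfg = optimizer_config or OptimizerConfig()
        return cls(
            variant_id=problem.variant.variant_id,
            bounds=problem.bounds, weights=problem.weights,
            population=cfg.population, generations=cfg.generations,
            budget_scale=cfg.budget_scale, polish=cfg.polish,
            polish_maxfev=cfg.polish_maxfev,
            warm_starts=tuple(tuple(w) for w in cfg.warm_starts),
            rtol=problem.rtol, atol=problem.atol, random_state=seed,
        )

    def _optimizer_config(self) -> OptimizerConfig:
        return OptimizerConfig(
            population=self.population, generations=self.generations,
            budget_scale=self.budget_scale, polish=self.polish,
            polish_maxfev=self.polish_maxfev,
            warm_starts=tuple(self.warm_starts),
        )

    # -- fitting --------------------------------------------------------

    def fit_suite(self, suite: DatasetSuite) -> "TLKRegressor":
        """Fit directly from a :class:`DatasetSuite` (fit-role experiments)."""
        from .fitting import FitProblem, FitResult, ResidualEvaluator

        variant = get_variant(self.variant_id)
        problem = FitProblem(
            suite, variant, bounds=self.bounds, weights=self.weights,
            rtol=self.rtol, atol=self.atol,
        )
        evaluator = ResidualEvaluator(problem)
        lo, hi = problem.bounds_arrays()
        opt = minimize_ep(
            evaluator, lo, hi, self._optimizer_config(),
            seed=self.random_state,
        )
        if not np.isfinite(opt.fun):
            raise RuntimeError(
                f"no feasible evaluation for variant {variant.variant_id}: "
                f"all {opt.nfev} simulations failed"
            )
        self.variant_ = variant
        self.problem_ = problem
        self.params_ = ParameterSet.from_vector(variant, opt.x)
        self.ssr_ = float(opt.fun)
        self.n_ = problem.n_points
        self.k_ = variant.k
        self.weights_ = dict(problem.weights)
        self.optimizer_result_ = opt
        return self

    def fit(self, X, y) -> "TLKRegressor":
        """Fit from tabular measurements (see module docstring for schema)."""
        return self.fit_suite(_xy_to_suite(X, y))

    # -- prediction -----------------------------------------------------

    def predict(self, X) -> np.ndarray:
        """Model-predicted observable for each row of *X*."""
        from .data import model_observable

        check_is_fitted(self, "params_")
        df = pd.DataFrame(X, columns=list(_X_COLUMNS)) if not isinstance(
            X, pd.DataFrame) else X
        out = np.empty(len(df))
        for kind in df["kind"].unique():
            m = (df["kind"] == kind).to_numpy()
            out[m] = model_observable(
                self.variant_, self.params_, ExperimentKind(kind),
                df.loc[m, "dose_Gy"].to_numpy(float),
                df.loc[m, "time_days"].to_numpy(float),
                rtol=self.rtol, atol=self.atol,
            )
        return out

    def to_fit_result(self):
        from .fitting import FitResult

        check_is_fitted(self, "params_")
        opt = self.optimizer_result_
        return FitResult(
            variant=self.variant_, params=self.params_, ssr=self.ssr_,
            n=self.n_, k=self.k_, seed=self.random_state, nfev=opt.nfev,
            n_failures=opt.n_failures, optimizer=opt,
        )
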
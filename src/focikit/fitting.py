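"""Weighted least-squares fitting of damage-kinetics models to foci data.

The objective is the weighted sum of squared residuals over all fitted
experiments, with each experiment weighted by the inverse of the mean of
its data values, so time courses spanning very different focus counts
contribute comparably.  gammaH2AX experiments are compared against the
total focus count Ft, TAF experiments against the TAF pool.

The user-facing fitting surface is the sklearn-style
:class:`focikit.estimators.TLKRegressor`; the functions here operate on
:class:`FitProblem`/:class:`FitResult` and delegate to it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .data import DatasetSuite, ExperimentKind
from .optimize import OptimizerConfig, OptimizerResult
from .simulate import DoseProtocol, simulate
from .variants import ModelVariant, ParameterSet, parameter_names

__all__ = [
    "FitProblem",
    "FitResult",
    "DEFAULT_BOUNDS",
    "study_bounds",
    "weights_from_suite",
    "objective",
    "fit_model",
    "fit_ensemble",
]

#: Catch-all default search box (model units): rates and coefficients span
#: many orders of magnitude, so the box is deliberately wide; the complex
#: fraction c is a fraction and is bounded by 1.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {"c": (1e-4, 1.0)}
_WIDE = (1e-6, 1e3)

#: Search box informed by the scale of the data (foci counts of order
#: 1-100, repair half-lives of hours to days); the box used throughout the
#: synthetic parameter-recovery studies.
STUDY_BOUNDS: dict[str, tuple[float, float]] = {
    "kDSB": (1.0, 200.0),
    "c": (1e-3, 0.5),
    "k1": (1e-3, 50.0),
    "k3": (1e-3, 50.0),
    "kTAF": (1e-2, 10.0),
    "T0": (1e-2, 10.0),
    "B": (1e-2, 10.0),
    "kcross": (1e-6, 1.0),
    "kf": (1e-2, 50.0),
    "ks": (1e-2, 50.0),
    "k2": (1e-3, 50.0),
    "k4": (1e-3, 50.0),
    "P_total": (1.0, 200.0),
}


def _bounds_for(variant: ModelVariant, bounds: dict | None) -> dict:
    out = {}
    for name in parameter_names(variant):
        if bounds and name in bounds:
            out[name] = tuple(bounds[name])
        elif name in DEFAULT_BOUNDS:
            out[name] = DEFAULT_BOUNDS[name]
        else:
            out[name] = _WIDE
    for name, (lo, hi) in out.items():
        if not (0 < lo <= hi and np.isfinite(hi)):
            raise ValueError(f"bounds for {name} must be finite and positive")
    return out


def study_bounds(variant: ModelVariant) -> dict[str, tuple[float, float]]:
    """Data-scale-informed bounds for every free parameter of *variant*."""
    return {n: STUDY_BOUNDS[n] for n in parameter_names(variant)}


def weights_from_suite(suite: DatasetSuite) -> dict[str, float]:
    """Per-experiment weights: inverse of the mean of each fitted series."""
    weights = {}
    for e in suite.fit_experiments:
        m = float(np.mean(e.means))
        if m <= 0:
            raise ValueError(
                f"experiment {e.experiment_id} has non-positive mean; "
                "its inverse-mean weight is undefined"
            )
        weights[e.experiment_id] = 1.0 / m
    return weights


@dataclass
class FitProblem:
    """One variant, the data it is fitted to, bounds and weights."""

    suite: DatasetSuite
    variant: ModelVariant
    bounds: Optional[dict] = None
    weights: Optional[dict[str, float]] = None
    rtol: float = 1e-6
    atol: float = 1e-9

    def __post_init__(self) -> None:
        self.bounds = _bounds_for(self.variant, self.bounds)
        if self.weights is None:
            self.weights = weights_from_suite(self.suite)
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("weights must be strictly positive")

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return parameter_names(self.variant)

    @property
    def n_points(self) -> int:
        return self.suite.n_fit_points

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.bounds[n][0] for n in self.parameter_names])
        hi = np.array([self.bounds[n][1] for n in self.parameter_names])
        return lo, hi


class ResidualEvaluator:
    """Weighted-SSR evaluation with one ODE solve per unique dose.

    All fitted experiments sharing an irradiation dose are read off a
    single simulation over the union of their sampling times.
    """

    def __init__(self, problem: FitProblem):
        self.problem = problem
        slots = []  # (dose, time, is_taf, sqrt_weight, y)
        for e in problem.suite.fit_experiments:
            if e.kind is ExperimentKind.PERCENTTAF_TIMECOURSE:
                raise ValueError(
                    f"{e.experiment_id}: percent-TAF series are "
                    "prediction-only and cannot carry the fit role"
                )
            w = problem.weights[e.experiment_id]
            for d, t, y in zip(e.doses, e.times, e.means):
                slots.append((float(d), float(t), e.kind.is_taf,
                              np.sqrt(w), float(y)))
        self._doses = np.array([s[0] for s in slots])
        self._times = np.array([s[1] for s in slots])
        self._is_taf = np.array([s[2] for s in slots])
        self._sqw = np.array([s[3] for s in slots])
        self.y = np.array([s[4] for s in slots])
        # per unique dose: sorted union of times and slot indices
        self._groups = []
        for dose in np.unique(self._doses):
            idx = np.nonzero(self._doses == dose)[0]
            order = np.argsort(self._times[idx], kind="stable")
            self._groups.append((dose, idx[order]))

    def predict(self, params: ParameterSet) -> np.ndarray:
        """Model value for every fitted data point (natural order)."""
        p = self.problem
        out = np.empty(len(self.y))
        for dose, idx in self._groups:
            times = self._times[idx]
            uniq, inv = np.unique(times, return_inverse=True)
            sim = simulate(p.variant, params, DoseProtocol.acute(dose),
                           uniq, rtol=p.rtol, atol=p.atol)
            vals = np.where(self._is_taf[idx], sim.TAF[inv], sim.Ft[inv])
            out[idx] = vals
        return out

    def weighted_ssr(self, params: ParameterSet) -> float:
        r = (self.predict(params) - self.y) * self._sqw
        return float(r @ r)

    def __call__(self, theta: np.ndarray) -> float:
        params = ParameterSet.from_vector(self.problem.variant, theta)
        return self.weighted_ssr(params)


def objective(theta, problem: FitProblem) -> float:
    """Weighted SSR of parameter vector *theta* (variant's canonical order)."""
    theta = np.asarray(theta, float)
    lo, hi = problem.bounds_arrays()
    if np.any(theta < lo) or np.any(theta > hi):
        raise ValueError("theta outside problem bounds")
    return ResidualEvaluator(problem)(theta)


@dataclass
class FitResult:
    """Best-fit parameters with the quantities model ranking needs."""

    variant: ModelVariant
    params: ParameterSet
    ssr: float
    n: int
    k: int
    seed: Optional[int] = None
    nfev: int = 0
    n_failures: int = 0
    optimizer: Optional[OptimizerResult] = None

    def to_dict(self) -> dict:
        return {
            "variant_id": self.variant.variant_id,
            "theta": self.params.to_dict(),
            "ssr": self.ssr, "n": self.n, "k": self.k,
            "seed": self.seed, "nfev": self.nfev,
            "n_failures": self.n_failures,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def fit_model(
    problem: FitProblem,
    optimizer_config: OptimizerConfig | None = None,
    seed: int | None = None,
) -> FitResult:
    """Fit one variant to the suite; deterministic for a fixed seed."""
    from .estimators import TLKRegressor  # avoid circular import

    est = TLKRegressor.from_problem(problem, optimizer_config, seed)
    est.fit_suite(problem.suite)
    return est.to_fit_result()


def variant_seed(master_seed, variant_id: int) -> int:
    """Deterministic per-variant sub-seed, independent of fit order."""
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, variant_id])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def fit_ensemble(
    suite: DatasetSuite,
    variants: Sequence[ModelVariant],
    optimizer_config: OptimizerConfig | None = None,
    seed: int | None = 0,
    bounds: dict | None = None,
    warm_starts: dict[int, ParameterSet] | None = None,
    weights: dict[str, float] | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> list[FitResult | None]:
    """Fit every variant independently; per-variant failures yield ``None``.

    Sub-seeds derive deterministically from (master seed, variant_id), so
    results do not depend on the order variants are listed in.
    ``warm_starts`` maps variant_id to a parameter set injected into that
    variant's initial population (e.g. its fit to the unresampled data).
    """
    if not variants:
        raise ValueError("variants must be non-empty")
    results: list[FitResult | None] = []
    for variant in variants:
        cfg = optimizer_config or OptimizerConfig()
        if warm_starts and variant.variant_id in warm_starts:
            ws = warm_starts[variant.variant_id].to_vector(variant)
            cfg = OptimizerConfig(
                population=cfg.population, generations=cfg.generations,
                budget_scale=cfg.budget_scale, polish=cfg.polish,
                polish_maxfev=cfg.polish_maxfev, init_sigma=cfg.init_sigma,
                warm_starts=tuple(cfg.warm_starts) + (tuple(ws),),
            )
        problem = FitProblem(suite, variant, bounds=bounds, weights=weights,
                             rtol=rtol, atol=atol)
        try:
            results.append(fit_model(
                problem, cfg, seed=variant_seed(seed or 0, variant.variant_id)
            ))
        except Exception:
            results.append(None)
    return results
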
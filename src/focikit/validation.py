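"""Predictive validation, identifiability, and robustness analysis.

Three complementary checks of a fitted damage-kinetics model:

* leave-one-experiment-out cross-validation of predictive power (TAF
  experiments stay in every training set — they are the only information
  constraining the persistent-damage parameters);
* profile-likelihood identifiability: scan one parameter, re-optimize the
  rest, and compare the SSR profile against an F-ratio 95% threshold;
* Latin-hypercube robustness: perturb all fitted parameters within a
  relative box (default +/-20%), simulate the ensemble and summarize the
  spread (quantile bands, relative standard deviation sigma_sim(t), and
  the distribution of the repair time tau).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import f as f_dist
from scipy.stats import qmc

from .data import DatasetSuite
from .fitting import (FitProblem, FitResult, ResidualEvaluator, fit_model)
from .optimize import OptimizerConfig, _LogSpace
from .simulate import DoseProtocol, repair_time, simulate
from .variants import ModelVariant, ParameterSet, parameter_names

__all__ = [
    "CrossValReport",
    "cross_validate",
    "LikelihoodProfile",
    "profile_likelihood",
    "classify_identifiability",
    "RobustnessReport",
    "lhs_robustness",
    "sigma_sim",
]


# --------------------------------------------------------------------------
# cross-validation

@dataclass
class CrossValReport:
    variant_id: int
    runs: list[dict]          # held_out, error (or error=None on failure)
    average_error: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "variant_id": self.variant_id, "runs": self.runs,
                "average_error": self.average_error,
            }, fh, indent=2, default=float)


def prediction_error(
    fit: FitResult, held_out, weight: float | None = None
) -> float:
    """Weighted SSR of the fitted model's prediction on one experiment."""
    from .data import model_observable

    w = weight if weight is not None else 1.0 / float(np.mean(held_out.means))
    yhat = model_observable(fit.variant, fit.params, held_out.kind,
                            held_out.doses, held_out.times)
    r = yhat - held_out.means
    return float(w * (r @ r))


def cross_validate(
    suite: DatasetSuite,
    variant: ModelVariant,
    optimizer_config: OptimizerConfig | None = None,
    seed: int = 0,
    bounds: dict | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> CrossValReport:
    """Average prediction error over leave-one-experiment-out runs.

    Every fitted non-TAF experiment is held out once; the model is
    retrained on the rest and scored on the held-out series with its
    inverse-mean weight.  Per-run failures are recorded with a null error
    and excluded from the average.
    """
    eligible = [e for e in suite.fit_experiments if not e.kind.is_taf]
    if len(eligible) < 2:
        raise ValueError("need at least two hold-out-eligible experiments")
    runs = []
    errors = []
    for i, held in enumerate(eligible):
        training = suite.drop(held.experiment_id)
        run_seed = int(np.random.SeedSequence(
            [int(seed) & 0x7FFFFFFF, i]).generate_state(1)[0] & 0x7FFFFFFF)
        try:
            fit = fit_model(
                FitProblem(training, variant, bounds=bounds, rtol=rtol,
                           atol=atol),
                optimizer_config, seed=run_seed,
            )
            err = prediction_error(fit, held)
            runs.append({"held_out": held.experiment_id, "error": err})
            errors.append(err)
        except Exception as exc:
            runs.append({"held_out": held.experiment_id, "error": None,
                         "failure": str(exc)})
    if not errors:
        raise RuntimeError("all cross-validation runs failed")
    return CrossValReport(variant.variant_id, runs,
                          float(np.mean(errors)))


# --------------------------------------------------------------------------
# profile likelihood

@dataclass
class LikelihoodProfile:
    parameter: str
    values: np.ndarray        # scanned parameter values
    ssr: np.ndarray           # re-optimized SSR at each (nan where failed)
    fitted_value: float
    ssr_min: float
    threshold: float          # SSR* from the F-ratio test
    n: int
    k: int

    @property
    def has_gaps(self) -> bool:
        return bool(np.any(~np.isfinite(self.ssr)))

    def confidence_interval(self) -> tuple[float, float]:
        """95% CI from the threshold crossings (inf where uncrossed)."""
        lo, hi = -math.inf, math.inf
        v, s = self.values, self.ssr
        below = s <= self.threshold
        ctr = int(np.nanargmin(np.abs(np.log(v / self.fitted_value))))
        # walk outward until the profile exceeds the threshold
        for j in range(ctr, 0, -1):
            if np.isfinite(s[j - 1]) and not below[j - 1] and below[j]:
                lo = self._crossing(v[j], s[j], v[j - 1], s[j - 1])
                break
        else:
            if below[0]:
                lo = -math.inf
        for j in range(ctr, len(v) - 1):
            if np.isfinite(s[j + 1]) and not below[j + 1] and below[j]:
                hi = self._crossing(v[j], s[j], v[j + 1], s[j + 1])
                break
        else:
            if below[-1]:
                hi = math.inf
        return lo, hi

    def _crossing(self, v_in, s_in, v_out, s_out) -> float:
        """Threshold crossing between a below- and an above-threshold grid
        point.

        Near its minimum the profile is approximately quadratic in
        log-parameter, so sqrt(SSR - SSR_min) is approximately linear
        there; interpolating in that space locates the crossing far more
        accurately than linear-in-SSR interpolation when the outer grid
        point is already far beyond the threshold.
        """
        z_in = math.sqrt(max(s_in - self.ssr_min, 0.0))
        z_out = math.sqrt(max(s_out - self.ssr_min, 0.0))
        z_thr = math.sqrt(max(self.threshold - self.ssr_min, 0.0))
        t = 0.5 if z_out == z_in else (z_thr - z_in) / (z_out - z_in)
        t = min(max(t, 0.0), 1.0)
        return float(math.exp(
            math.log(v_in) + t * (math.log(v_out) - math.log(v_in))
        ))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": self.parameter, "value": self.values,
            "ssr": self.ssr,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def f_ratio_threshold(ssr_min: float, n: int, k: int,
                      confidence: float = 0.95, df: int = 1) -> float:
    """SSR* = SSR_min * (1 + df * F(confidence; df, n-k) / (n-k))."""
    if n <= k:
        raise ValueError("threshold undefined for n <= k")
    return ssr_min * (1.0 + df * f_dist.ppf(confidence, df, n - k) / (n - k))


def profile_likelihood(
    fit: FitResult,
    problem: FitProblem,
    parameter: str,
    n_points: int = 41,
    span_decades: float = 2.0,
    optimizer_config: OptimizerConfig | None = None,
    seed: int = 0,
    confidence: float = 0.95,
    simultaneous: bool = False,
) -> LikelihoodProfile:
    """Profile the weighted SSR along one parameter of a fitted model.

    The parameter is scanned over ``n_points`` log-spaced values spanning
    ``+/-span_decades`` around the fitted value (clipped to the bounds);
    at each value the remaining parameters are re-optimized by a simplex
    search warm-started from the neighbouring grid point, marching outward
    from the fit.  The threshold uses the pointwise 1-df F-ratio test by
    default (``simultaneous=True`` switches to the k-df version).
    """
    names = list(problem.parameter_names)
    if parameter not in names:
        raise ValueError(
            f"{parameter!r} is not a free parameter of variant "
            f"{problem.variant.variant_id}"
        )
    p_idx = names.index(parameter)
    theta_hat = np.array(fit.params.to_vector(problem.variant), float)
    evaluator = ResidualEvaluator(problem)
    lo, hi = problem.bounds_arrays()

    center = theta_hat[p_idx]
    g_lo = max(lo[p_idx], center * 10.0 ** -span_decades)
    g_hi = min(hi[p_idx], center * 10.0 ** span_decades)
    grid = np.unique(np.concatenate([
        np.geomspace(g_lo, g_hi, n_points), [center]
    ]))

    others = [i for i in range(len(names)) if i != p_idx]
    space = _LogSpace(lo[others], hi[others])
    cfg = optimizer_config or OptimizerConfig()
    maxfev = cfg.polish_maxfev or 150 * max(1, len(others))

    def reopt(fixed_value, u_start):
        def obj(u):
            theta = np.empty(len(names))
            theta[p_idx] = fixed_value
            theta[others] = space.to_natural(np.clip(u, 0, 1))
            try:
                return evaluator(theta)
            except Exception:
                return math.inf
        res = minimize(obj, u_start, method="Nelder-Mead",
                       options={"maxfev": maxfev, "xatol": 1e-6,
                                "fatol": 1e-10})
        return (float(res.fun), np.clip(res.x, 0, 1))

    ssr = np.full(len(grid), np.nan)
    ctr = int(np.argmin(np.abs(grid - center)))
    u_hat = space.to_unit(theta_hat[others])
    # march outward in both directions, warm-starting from the neighbour
    for direction in (range(ctr, len(grid)), range(ctr - 1, -1, -1)):
        u = u_hat.copy()
        for j in direction:
            val, u = reopt(grid[j], u)
            if math.isfinite(val):
                ssr[j] = val

    ssr_min = float(min(fit.ssr, np.nanmin(ssr)))
    df = problem.variant.k if simultaneous else 1
    threshold = f_ratio_threshold(ssr_min, problem.n_points,
                                  problem.variant.k, confidence, df)
    return LikelihoodProfile(
        parameter=parameter, values=grid, ssr=ssr, fitted_value=center,
        ssr_min=ssr_min, threshold=threshold, n=problem.n_points,
        k=problem.variant.k,
    )


def classify_identifiability(
    profile: LikelihoodProfile, flat_tol: float = 1e-6
) -> str:
    """Classify a profile as ``practical``, ``one_sided``, ``structural``
    or ``non_identifiable``.

    practical: the profile exceeds the threshold on both sides of the fit;
    one_sided: on exactly one side; structural: never exceeds it but is
    not flat; non_identifiable: flat within ``flat_tol * SSR_min``.
    """
    s = profile.ssr[np.isfinite(profile.ssr)]
    if len(s) < 3:
        raise ValueError("profile has too few finite points to classify")
    v = profile.values[np.isfinite(profile.ssr)]
    left = s[v < profile.fitted_value]
    right = s[v > profile.fitted_value]
    crosses_left = bool(len(left)) and bool(np.any(left > profile.threshold))
    crosses_right = bool(len(right)) and bool(
        np.any(right > profile.threshold))
    if crosses_left and crosses_right:
        return "practical"
    if crosses_left or crosses_right:
        return "one_sided"
    if s.max() - s.min() < flat_tol * max(profile.ssr_min,
                                          np.finfo(float).tiny):
        return "non_identifiable"
    return "structural"


# --------------------------------------------------------------------------
# robustness

def sigma_sim(ensemble: np.ndarray, optimal: np.ndarray) -> np.ndarray:
    """Relative standard deviation of an ensemble around the optimum.

    ``sigma_sim(t) = sqrt(mean_j (y_j(t) - y_opt(t))^2) / y_opt(t)``;
    undefined (raises) where the optimal trajectory is zero.
    """
    ensemble = np.atleast_2d(np.asarray(ensemble, float))
    optimal = np.asarray(optimal, float)
    if ensemble.shape[1] != len(optimal):
        raise ValueError("ensemble and optimal trajectory are misaligned")
    if np.any(optimal == 0):
        raise ValueError(
            "sigma_sim undefined where the optimal trajectory is zero"
        )
    dev = ensemble - optimal[None, :]
    return np.sqrt(np.mean(dev * dev, axis=0)) / optimal


@dataclass
class RobustnessReport:
    doses: list[float]
    times: np.ndarray
    quantiles: dict[float, pd.DataFrame]  # dose -> columns q05, q50, q95
    sigma: pd.DataFrame                   # index time, one column per dose
    optimal: pd.DataFrame                 # optimal Ft per dose
    tau: pd.DataFrame                     # per-dose tau samples summary
    n_samples: int
    n_failed: int

    def to_csv(self, path) -> None:
        rows = []
        for dose in self.doses:
            q = self.quantiles[dose]
            for i, t in enumerate(self.times):
                rows.append({
                    "dose_Gy": dose, "time_days": t,
                    "q05": q["q05"].iloc[i], "q50": q["q50"].iloc[i],
                    "q95": q["q95"].iloc[i],
                    "optimal": self.optimal[dose].iloc[i],
                    "sigma_sim": self.sigma[dose].iloc[i],
                })
        pd.DataFrame(rows).to_csv(path, index=False)

    def max_sigma(self, dose: float) -> float:
        return float(self.sigma[dose].max())


def lhs_robustness(
    theta_hat: ParameterSet,
    variant: ModelVariant,
    doses: Sequence[float] = (2.5, 10.0, 20.0),
    rel_width: float = 0.2,
    n_samples: int = 1000,
    seed: int = 0,
    times: Optional[np.ndarray] = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> RobustnessReport:
    """Perturb all fitted parameters in a +/-``rel_width`` box by Latin
    hypercube sampling and summarize the simulated spread per dose.

    Induction parameters are perturbed along with the rate constants, so
    initial conditions (which are parameter-derived) vary too.  Draws whose
    simulation fails are excluded and counted.
    """
    names = parameter_names(variant)
    base = np.array(theta_hat.to_vector(variant), float)
    if np.any(base < 0):
        raise ValueError("theta_hat entries must be non-negative")
    if times is None:
        times = np.unique(np.concatenate([
            np.geomspace(1.0 / 24.0, 14.0, 40), np.linspace(15.0, 120.0, 20)
        ]))
    times = np.asarray(times, float)

    if rel_width > 0 and n_samples > 0:
        sampler = qmc.LatinHypercube(d=len(base), seed=seed)
        factors = 1.0 - rel_width + 2.0 * rel_width * sampler.random(n_samples)
    else:
        factors = np.ones((max(n_samples, 1), len(base)))
    draws = base[None, :] * factors
    # c is a fraction; the perturbation box must stay within [0, 1]
    if "c" in names:
        draws[:, names.index("c")] = np.clip(
            draws[:, names.index("c")], 0.0, 1.0)

    quantiles, sigma_cols, optimal_cols, tau_rows = {}, {}, {}, []
    n_failed = 0
    for dose in doses:
        protocol = DoseProtocol.acute(float(dose))
        opt_sim = simulate(variant, theta_hat, protocol, times,
                           rtol=rtol, atol=atol)
        y_opt = opt_sim.Ft
        tau_opt = repair_time(opt_sim)
        ys, taus = [], []
        for row in draws:
            p = ParameterSet.from_vector(variant, row)
            try:
                sim = simulate(variant, p, protocol, times,
                               rtol=rtol, atol=atol)
            except Exception:
                n_failed += 1
                continue
            ys.append(sim.Ft)
            taus.append(repair_time(sim))
        ys = np.array(ys)
        q = np.percentile(ys, [5, 50, 95], axis=0)
        quantiles[dose] = pd.DataFrame(
            {"q05": q[0], "q50": q[1], "q95": q[2]})
        sigma_cols[dose] = sigma_sim(ys, y_opt)
        optimal_cols[dose] = y_opt
        taus = np.asarray(taus, float)
        reached = taus[np.isfinite(taus)]
        tau_rows.append({
            "dose_Gy": dose, "tau_optimal": tau_opt,
            "tau_mean": float(reached.mean()) if len(reached) else math.nan,
            "tau_sd": float(reached.std(ddof=1)) if len(reached) > 1 else 0.0,
            "n_not_reached": int(np.sum(~np.isfinite(taus))),
        })
    return RobustnessReport(
        doses=[float(d) for d in doses], times=times, quantiles=quantiles,
        sigma=pd.DataFrame(sigma_cols, index=times),
        optimal=pd.DataFrame(optimal_cols, index=times),
        tau=pd.DataFrame(tau_rows), n_samples=n_samples, n_failed=n_failed,
    )
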
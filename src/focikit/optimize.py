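"""Global parameter search by self-adaptive evolutionary programming.

A (mu+lambda) evolution strategy without recombination: each individual
carries per-coordinate log-normal self-adapting mutation scales; parents
and offspring compete jointly for survival.  The search runs in a unit
hypercube mapped log-uniformly onto the parameter bounds (rates span
orders of magnitude), with an optional derivative-free simplex polish of
the best individual afterwards.

The default budget is population = 10 * n_parameters and generations =
10 * population; ``budget_scale`` shrinks both proportionally for
desk-scale runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import minimize

__all__ = ["OptimizerConfig", "OptimizerResult", "minimize_ep"]


@dataclass
class OptimizerConfig:
    """Budget and behaviour of the evolutionary search.

    ``population``/``generations`` of ``None`` mean the defaults
    (10*d and 10*population) scaled by ``budget_scale``.  ``warm_starts``
    are parameter vectors (natural units) injected into the initial
    population, e.g. a previous fit of the same model.
    """

    population: Optional[int] = None
    generations: Optional[int] = None
    budget_scale: float = 1.0
    polish: bool = True
    polish_maxfev: Optional[int] = None
    polish_top: int = 2
    polish_restarts: int = 3
    init_sigma: float = 0.15
    warm_starts: Sequence[Sequence[float]] = field(default_factory=tuple)

    def resolve(self, n_params: int) -> tuple[int, int]:
        pop = self.population
        if pop is None:
            pop = max(2, round(10 * n_params * self.budget_scale))
        gen = self.generations
        if gen is None:
            gen = max(1, round(10 * pop))
        return int(pop), int(gen)


@dataclass
class OptimizerResult:
    x: np.ndarray          # best parameters, natural units
    fun: float             # objective at x
    nfev: int
    n_failures: int        # evaluations that raised / returned non-finite
    population: int
    generations: int
    polished: bool


class _LogSpace:
    """Bijection between the unit cube and log-uniform parameter bounds."""

    def __init__(self, lower, upper):
        self.lo = np.log10(np.asarray(lower, float))
        self.hi = np.log10(np.asarray(upper, float))
        if np.any(~np.isfinite(self.lo)) or np.any(~np.isfinite(self.hi)):
            raise ValueError("bounds must be finite and strictly positive")
        if np.any(self.hi < self.lo):
            raise ValueError("upper bounds must be >= lower bounds")
        self.span = self.hi - self.lo

    def to_natural(self, u: np.ndarray) -> np.ndarray:
        return 10.0 ** (self.lo + np.clip(u, 0.0, 1.0) * self.span)

    def to_unit(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        with np.errstate(divide="ignore"):
            lx = np.log10(x)
        u = np.where(self.span > 0, (lx - self.lo) / np.where(
            self.span > 0, self.span, 1.0), 0.5)
        return np.clip(u, 0.0, 1.0)


def minimize_ep(
    objective: Callable[[np.ndarray], float],
    lower: Sequence[float],
    upper: Sequence[float],
    config: OptimizerConfig | None = None,
    seed=None,
) -> OptimizerResult:
    """Minimize *objective* over box bounds with the evolutionary search.

    The objective receives parameters in natural units; evaluations that
    raise or return non-finite values count as failures and are treated as
    +inf.  Fully deterministic for a fixed *seed*.
    """
    config = config or OptimizerConfig()
    space = _LogSpace(lower, upper)
    d = len(space.lo)
    rng = np.random.default_rng(seed)
    pop_size, n_gen = config.resolve(d)

    n_failures = 0
    nfev = 0

    def evaluate(u: np.ndarray) -> float:
        nonlocal n_failures, nfev
        nfev += 1
        try:
            val = float(objective(space.to_natural(u)))
        except Exception:
            n_failures += 1
            return math.inf
        if not math.isfinite(val):
            n_failures += 1
            return math.inf
        return val

    # initial population: log-uniform draws, plus any warm starts
    genomes = rng.random((pop_size, d))
    for i, ws in enumerate(config.warm_starts[:pop_size]):
        genomes[i] = space.to_unit(np.asarray(ws, float))
    sigmas = np.full((pop_size, d), config.init_sigma)
    fitness = np.array([evaluate(g) for g in genomes])

    tau_g = 1.0 / math.sqrt(2.0 * d)          # global learning rate
    tau_c = 1.0 / math.sqrt(2.0 * math.sqrt(d))  # per-coordinate
    sigma_floor = 1e-4

    for _ in range(n_gen):
        g_noise = rng.standard_normal(pop_size)[:, None]
        c_noise = rng.standard_normal((pop_size, d))
        child_sig = np.maximum(
            sigmas * np.exp(tau_g * g_noise + tau_c * c_noise), sigma_floor
        )
        children = np.clip(
            genomes + child_sig * rng.standard_normal((pop_size, d)), 0.0, 1.0
        )
        child_fit = np.array([evaluate(c) for c in children])
        all_g = np.vstack([genomes, children])
        all_s = np.vstack([sigmas, child_sig])
        all_f = np.concatenate([fitness, child_fit])
        keep = np.argsort(all_f, kind="stable")[:pop_size]
        genomes, sigmas, fitness = all_g[keep], all_s[keep], all_f[keep]

    best_u, best_f = genomes[0].copy(), float(fitness[0])

    polished = False
    if config.polish and math.isfinite(best_f):
        maxfev = config.polish_maxfev or 200 * d
        # polish the leading distinct survivors; restart the simplex from
        # its own result until it stops improving (fresh simplexes escape
        # collapsed geometry from the previous run)
        starts, seen = [], []
        for g in genomes:
            if all(np.max(np.abs(g - s)) > 0.02 for s in seen):
                seen.append(g)
                starts.append(g.copy())
            if len(starts) >= max(1, config.polish_top):
                break
        for u0 in starts:
            f_prev = math.inf
            for _ in range(max(1, config.polish_restarts)):
                res = minimize(
                    evaluate, u0, method="Nelder-Mead",
                    options={"maxfev": maxfev, "xatol": 1e-7,
                             "fatol": 1e-12},
                )
                if not math.isfinite(res.fun):
                    break
                u0 = np.clip(res.x, 0.0, 1.0)
                if res.fun < best_f:
                    best_u, best_f = u0.copy(), float(res.fun)
                if f_prev - res.fun < 1e-6 * max(1.0, abs(res.fun)):
                    break
                f_prev = float(res.fun)
        polished = True

    return OptimizerResult(
        x=space.to_natural(best_u), fun=best_f, nfev=nfev,
        n_failures=n_failures, population=pop_size, generations=n_gen,
        polished=polished,
    )
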
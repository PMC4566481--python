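"""Model ranking by small-sample-corrected AIC and selection robustness.

Candidate fits are ranked by AICc computed from the Gaussian log-likelihood
including its constants,

    AICc = n ln(SSR/n) + n ln(2*pi) + n + 2k + 2k(k+1)/(n-k-1),

normalized into Akaike weights ``w_i = exp(-Delta_i/2)/sum_j exp(-Delta_j/2)``
with ``Delta_i = AICc_i - AICc_min``.  Models with weight above a cutoff
(0.125 by default) are flagged as most probable candidates.  The
constant-free form ``n ln(SSR/n) + 2k + correction`` does NOT reproduce the
published reference ranking and is deliberately not offered.

Ranking stability under measurement noise is assessed by a Poisson
resampling Monte Carlo: each replicate redraws every fitted data point
from Poisson(mean), refits the whole ensemble and re-ranks it.
"""

from __future__ import annotations

import importlib.resources
import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data import DatasetSuite, poisson_resample
from .fitting import FitResult, fit_ensemble, weights_from_suite
from .optimize import OptimizerConfig
from .variants import ModelVariant, ParameterSet

__all__ = [
    "aicc",
    "akaike_weights",
    "SelectionTable",
    "build_selection_table",
    "ResamplingReport",
    "mc_model_selection",
    "load_reference_ranking",
    "AIC_WEIGHT_CUTOFF",
]

#: Akaike-weight threshold above which a model counts as a most probable
#: candidate.
AIC_WEIGHT_CUTOFF = 0.125


def aicc(ssr: float, k: int, n: int) -> float:
    """Small-sample-corrected AIC from a least-squares fit.

    Uses the full Gaussian log-likelihood (constants included); requires
    ``n > k + 1`` for the finite-sample correction term.
    """
    if ssr <= 0:
        raise ValueError(f"ssr must be positive, got {ssr}")
    if n <= k + 1:
        raise ValueError(
            f"small-sample correction undefined for n={n}, k={k} "
            "(needs n > k + 1)"
        )
    return (
        n * math.log(ssr / n) + n * math.log(2.0 * math.pi) + n
        + 2 * k + 2 * k * (k + 1) / (n - k - 1)
    )


def akaike_weights(aicc_values) -> np.ndarray:
    """Normalized evidence weights exp(-Delta/2) over an ensemble."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size == 0 or not np.all(np.isfinite(a)):
        raise ValueError("aicc values must be a non-empty finite list")
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


@dataclass
class SelectionTable:
    """Ranked AICc/Akaike-weight table over an ensemble of fits."""

    table: pd.DataFrame  # rank, variant_id, k, n, ssr, aicc, aicw, within_cutoff
    cutoff: float = AIC_WEIGHT_CUTOFF

    @property
    def best_variant_id(self) -> int:
        return int(self.table.iloc[0]["variant_id"])

    def rank_of(self, variant_id: int) -> int:
        row = self.table[self.table["variant_id"] == variant_id]
        if row.empty:
            raise KeyError(variant_id)
        return int(row["rank"].iloc[0])

    def accepted_variant_ids(self) -> list[int]:
        return [int(v) for v in
                self.table.loc[self.table["within_cutoff"], "variant_id"]]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"cutoff": self.cutoff,
                 "rows": self.table.to_dict(orient="records")},
                fh, indent=2, default=float,
            )


def build_selection_table(
    fit_results: Sequence[FitResult],
    cutoff: float = AIC_WEIGHT_CUTOFF,
) -> SelectionTable:
    """Rank fitted variants by AICc and attach Akaike weights.

    Ties in AICc are broken parsimony-first (lower k, then lower
    variant_id) so the ranking is deterministic.
    """
    results = [r for r in fit_results if r is not None]
    if not results:
        raise ValueError("need at least one successful fit result")
    ids = [r.variant.variant_id for r in results]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate variant_ids in fit results")
    rows = [{
        "variant_id": r.variant.variant_id, "k": r.k, "n": r.n,
        "ssr": r.ssr, "aicc": aicc(r.ssr, r.k, r.n),
    } for r in results]
    df = pd.DataFrame(rows).sort_values(
        ["aicc", "k", "variant_id"], kind="stable"
    ).reset_index(drop=True)
    df["aicw"] = akaike_weights(df["aicc"].to_numpy())
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    df["within_cutoff"] = df["aicw"] > cutoff
    return SelectionTable(df[["rank", "variant_id", "k", "n", "ssr",
                              "aicc", "aicw", "within_cutoff"]], cutoff)


@dataclass
class ResamplingReport:
    """Rank frequencies and weight histograms over resampled refits."""

    variant_ids: list[int]
    n_replicates: int
    n_failed: int
    rank_frequency: pd.DataFrame     # index variant_id, columns rank 1..m
    weight_histograms: pd.DataFrame  # index variant_id, columns weight bins
    weight_bin_edges: np.ndarray

    def rank1_fraction(self, variant_id: int) -> float:
        ok = self.n_replicates - self.n_failed
        return float(self.rank_frequency.loc[variant_id, 1]) / ok

    def to_csv(self, path_prefix: str) -> None:
        self.rank_frequency.to_csv(f"{path_prefix}_rank_frequency.csv")
        self.weight_histograms.to_csv(f"{path_prefix}_weight_histograms.csv")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "variant_ids": self.variant_ids,
                "n_replicates": self.n_replicates,
                "n_failed": self.n_failed,
                "rank_frequency": self.rank_frequency.to_dict(),
                "weight_histograms": self.weight_histograms.to_dict(),
                "weight_bin_edges": list(self.weight_bin_edges),
            }, fh, indent=2, default=float)


def mc_model_selection(
    suite: DatasetSuite,
    variants: Sequence[ModelVariant],
    n_replicates: int = 200,
    optimizer_config: OptimizerConfig | None = None,
    seed: int = 0,
    bounds: dict | None = None,
    cutoff: float = AIC_WEIGHT_CUTOFF,
    warm_start: bool = True,
    recompute_weights: bool = True,
    replicate_config: OptimizerConfig | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> ResamplingReport:
    """Monte-Carlo assessment of ranking robustness by Poisson resampling.

    Each replicate redraws every fitted data point from Poisson(mean),
    recomputes the inverse-mean experiment weights (unless
    ``recompute_weights=False``), refits all variants and ranks them.  With
    ``warm_start=True`` the variants are first fitted to the unresampled
    suite and those solutions seed every replicate's initial population,
    which lets the per-replicate budget (``replicate_config``, default a
    tenth of the main budget) stay small.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    cfg = optimizer_config or OptimizerConfig()

    warm: dict[int, ParameterSet] | None = None
    if warm_start:
        base = fit_ensemble(suite, variants, cfg, seed=seed, bounds=bounds,
                            rtol=rtol, atol=atol)
        warm = {r.variant.variant_id: r.params for r in base
                if r is not None}
    if replicate_config is not None:
        rep_cfg = replicate_config
    elif warm_start:
        # replicates start from the unresampled-data solution, so a tenth
        # of the main budget suffices
        rep_cfg = OptimizerConfig(
            population=cfg.population, generations=cfg.generations,
            budget_scale=cfg.budget_scale * 0.1,
            polish=cfg.polish, polish_maxfev=cfg.polish_maxfev,
            polish_top=1, polish_restarts=1,
        )
    else:
        rep_cfg = cfg

    m = len(variants)
    ids = [v.variant_id for v in variants]
    rank_freq = pd.DataFrame(0, index=ids,
                             columns=pd.RangeIndex(1, m + 1, name="rank"))
    rank_freq.index.name = "variant_id"
    bin_edges = np.round(np.arange(0.0, 1.0 + 1e-9, 0.1), 10)
    hist_cols = [f"[{a:.1f},{b:.1f})" for a, b in
                 zip(bin_edges[:-1], bin_edges[1:])]
    weight_hist = pd.DataFrame(0, index=pd.Index(ids, name="variant_id"),
                               columns=hist_cols)
    n_failed = 0
    for rep in range(n_replicates):
        rep_seed = int(np.random.SeedSequence(
            [int(seed) & 0x7FFFFFFF, 1000 + rep]).generate_state(1)[0]
            & 0x7FFFFFFF)
        replica = poisson_resample(suite, rep_seed)
        fixed_weights = (None if recompute_weights
                         else weights_from_suite(suite))
        try:
            fits = fit_ensemble(replica, variants, rep_cfg, seed=rep_seed,
                                bounds=bounds, warm_starts=warm,
                                weights=fixed_weights, rtol=rtol, atol=atol)
            if any(f is None for f in fits):
                raise RuntimeError("per-variant fit failure")
            table = build_selection_table(fits, cutoff=cutoff)
        except Exception:
            n_failed += 1
            continue
        for _, row in table.table.iterrows():
            vid = int(row["variant_id"])
            rank_freq.loc[vid, int(row["rank"])] += 1
            b = min(int(row["aicw"] / 0.1), len(hist_cols) - 1)
            weight_hist.iloc[weight_hist.index.get_loc(vid), b] += 1
    return ResamplingReport(
        variant_ids=ids, n_replicates=n_replicates, n_failed=n_failed,
        rank_frequency=rank_freq, weight_histograms=weight_hist,
        weight_bin_edges=bin_edges,
    )


def load_reference_ranking() -> pd.DataFrame:
    """Published reference fit statistics for the 20-model family.

    Columns: rank, variant_id, n, k, ssr plus the printed AICc, Akaike
    weight and cutoff flag, as reported for the original experimental
    compilation.  Used for ranking demonstrations and regression checks.
    """
    with importlib.resources.files("focikit").joinpath(
        "data/reference_ranking.csv"
    ).open() as fh:
        return pd.read_csv(fh)
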
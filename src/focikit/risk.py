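"""Excess relative risk of secondary leukemia from persistent damage foci.

The predictor is deliberately simple: the excess relative risk (ERR) after
radiotherapy is the simulated radiation-induced telomere-associated focus
count, corrected for the basal background signal,

    ERR(D) = T_AF+(D) - B,

where ``T_AF+`` excludes the pre-existing background TAF (T0).  For a
fractionated schedule two accumulation rules are offered: ``cumulative``
applies the dose map to the total dose (the default — risk is plotted
against cumulative dose as one smooth curve), ``per_fraction`` sums the
per-fraction inductions.  Which rule the square-root map should use for
fractionated schedules is a genuine modelling choice; both are exposed and
recorded in every output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .simulate import DoseProtocol, dose_map_value
from .variants import DoseMap, ParameterSet

__all__ = [
    "taf_plus",
    "ErrPrediction",
    "err_predict",
    "err_r2",
    "err_band",
    "read_observations",
]

_RULES = ("cumulative", "per_fraction")


def taf_plus(
    protocol: DoseProtocol,
    params: ParameterSet,
    dose_map: DoseMap = DoseMap.SQRT,
    rule: str = "cumulative",
) -> float:
    """Radiation-induced TAF (foci) excluding the background level T0."""
    if rule not in _RULES:
        raise ValueError(f"rule must be one of {_RULES}, got {rule!r}")
    kTAF = params.get("kTAF")
    if not protocol.fractions:
        return 0.0
    if rule == "cumulative":
        return kTAF * dose_map_value(protocol.total_dose, dose_map)
    return kTAF * sum(dose_map_value(d, dose_map)
                      for _, d in protocol.fractions)


@dataclass
class ErrPrediction:
    doses: np.ndarray        # cumulative Gy
    err_mean: np.ndarray
    err_lo: Optional[np.ndarray]
    err_hi: Optional[np.ndarray]
    rule: str
    dose_map: DoseMap
    kTAF: float
    B: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"dose_Gy": self.doses, "err_mean": self.err_mean})
        if self.err_lo is not None:
            df["err_lo"] = self.err_lo
            df["err_hi"] = self.err_hi
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def zero_crossing_dose(self) -> float:
        """Cumulative dose at which predicted ERR becomes positive
        (closed form for the cumulative rule)."""
        kTAF, B = self.kTAF, self.B
        if kTAF <= 0:
            return float("inf")
        if DoseMap(self.dose_map) is DoseMap.SQRT:
            return (B / kTAF) ** 2
        return B / kTAF


def _protocol_for(dose: float, n_fractions: int) -> DoseProtocol:
    if n_fractions <= 1:
        return DoseProtocol.acute(dose)
    per = dose / n_fractions
    return DoseProtocol(tuple((float(i), per) for i in range(n_fractions)))


def err_predict(
    doses: Sequence[float],
    params: ParameterSet,
    rule: str = "cumulative",
    dose_map: DoseMap = DoseMap.SQRT,
    n_fractions: int = 1,
    band: Optional[tuple] = None,
) -> ErrPrediction:
    """Predicted ERR at each cumulative dose: ``T_AF+ - B``.

    ``n_fractions`` splits each cumulative dose into equal daily fractions
    (only relevant under the per-fraction rule).  ``band`` optionally holds
    precomputed (lo, hi) arrays from :func:`err_band`.
    """
    kTAF, B = params.get("kTAF"), params.get("B")
    doses = np.asarray(doses, float)
    err = np.array([
        taf_plus(_protocol_for(float(D), n_fractions), params, dose_map,
                 rule) - B
        for D in doses
    ])
    lo, hi = (band if band is not None else (None, None))
    return ErrPrediction(doses=doses, err_mean=err, err_lo=lo, err_hi=hi,
                         rule=rule, dose_map=DoseMap(dose_map),
                         kTAF=kTAF, B=B)


def err_r2(predicted, observed) -> float:
    """Coefficient of determination of matched ERR predictions.

    ``R^2 = 1 - SS_res / SS_tot`` with the total sum of squares taken
    around the observed mean; undefined for constant observations.
    """
    predicted = np.asarray(predicted, float)
    observed = np.asarray(observed, float)
    if predicted.shape != observed.shape or observed.size < 2:
        raise ValueError("need >= 2 matched (predicted, observed) pairs")
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined: observations are constant")
    ss_res = float(np.sum((observed - predicted) ** 2))
    return 1.0 - ss_res / ss_tot


def err_band(
    params: ParameterSet,
    kTAF_interval: tuple[float, float],
    B_interval: tuple[float, float],
    doses: Sequence[float],
    n_samples: int = 2000,
    seed: int = 0,
    rule: str = "cumulative",
    dose_map: DoseMap = DoseMap.SQRT,
    n_fractions: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """95% band of the ERR curve from uncertainty in kTAF and B.

    kTAF and B are sampled independently and uniformly within their given
    intervals (e.g. profile-likelihood 95% CIs); the 2.5/97.5 percentiles
    of the resulting ERR are returned per dose.  Degenerate (zero-width)
    intervals collapse the band onto the mean curve.
    """
    rng = np.random.default_rng(seed)
    doses = np.asarray(doses, float)
    kt = rng.uniform(*sorted(kTAF_interval), size=n_samples)
    bb = rng.uniform(*sorted(B_interval), size=n_samples)
    f = np.array([
        taf_plus(_protocol_for(float(D), n_fractions),
                 ParameterSet(kTAF=1.0), dose_map, rule)
        for D in doses
    ])  # induction per unit kTAF
    sims = kt[:, None] * f[None, :] - bb[:, None]
    lo, hi = np.percentile(sims, [2.5, 97.5], axis=0)
    return lo, hi


def read_observations(path) -> pd.DataFrame:
    """Read observed (dose_Gy, err) pairs, e.g. digitized registry
    estimates, from CSV."""
    df = pd.read_csv(path)
    for col in ("dose_Gy", "err"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if (df["dose_Gy"] < 0).any():
        raise ValueError(f"{path}: negative dose")
    return df[["dose_Gy", "err"]]
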
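"""Synthetic foci datasets with the statistical structure of counting assays.

Per-cell focus counts are modelled as Poisson draws whose means follow the
kinetic model; an experiment reports the sample mean and SEM over
``n_cells`` cells.  The default design emulates the published study layout:
six fitted experiments totalling 49 data points (gammaH2AX time courses at
2.5, 10 and 20 Gy, gammaH2AX dose-responses at 1 and 3 days, a TAF
dose-response at 1 day and a TAF time course at 20 Gy) plus a
prediction-only percent-TAF series at 20 Gy.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .simulate import DoseProtocol, simulate
from .variants import ModelVariant, ParameterSet

__all__ = [
    "default_ground_truth",
    "ExperimentKind",
    "FociDataset",
    "DatasetSuite",
    "default_design",
    "generate_suite",
    "sample_counts",
    "poisson_resample",
    "read_dataset",
    "write_dataset",
    "interpolate_dose_point",
]


class ExperimentKind(str, enum.Enum):
    GAMMAH2AX_TIMECOURSE = "gammaH2AX_timecourse"
    GAMMAH2AX_DOSERESPONSE = "gammaH2AX_doseresponse"
    TAF_DOSERESPONSE = "TAF_doseresponse"
    TAF_TIMECOURSE = "TAF_timecourse"
    PERCENTTAF_TIMECOURSE = "percentTAF_timecourse"

    @property
    def is_taf(self) -> bool:
        return self in (ExperimentKind.TAF_DOSERESPONSE,
                        ExperimentKind.TAF_TIMECOURSE)

    @property
    def is_dose_response(self) -> bool:
        return self in (ExperimentKind.GAMMAH2AX_DOSERESPONSE,
                        ExperimentKind.TAF_DOSERESPONSE)


@dataclass
class FociDataset:
    """One experiment: mean +/- SEM foci per cell along time or dose.

    For time courses ``doses`` holds a single repeated dose; for
    dose-responses ``times`` holds a single repeated sampling time.
    ``role`` is ``"fit"`` for calibration data and ``"predict"`` for series
    used only to test predictions.
    """

    experiment_id: str
    kind: ExperimentKind
    doses: np.ndarray        # Gy, one per data point
    times: np.ndarray        # days, one per data point
    means: np.ndarray        # foci per cell (or % for percent-TAF)
    sems: np.ndarray
    n_cells: np.ndarray      # cells counted per data point
    role: str = "fit"

    def __post_init__(self) -> None:
        self.kind = ExperimentKind(self.kind)
        for name in ("doses", "times", "means", "sems", "n_cells"):
            setattr(self, name, np.asarray(getattr(self, name)))
        n = len(self.means)
        for name in ("doses", "times", "sems", "n_cells"):
            if len(getattr(self, name)) != n:
                raise ValueError(
                    f"{self.experiment_id}: {name} length differs from means"
                )
        if np.any(self.means < 0) or np.any(self.sems < 0):
            raise ValueError(f"{self.experiment_id}: negative mean or SEM")
        if self.role not in ("fit", "predict"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.kind is ExperimentKind.PERCENTTAF_TIMECOURSE and np.any(
            self.means > 100
        ):
            raise ValueError("percent-TAF values must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.means)


@dataclass
class DatasetSuite:
    """Ordered collection of experiments fitted jointly."""

    experiments: list[FociDataset]

    def __post_init__(self) -> None:
        ids = [e.experiment_id for e in self.experiments]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate experiment_id in suite")

    def __iter__(self):
        return iter(self.experiments)

    def __len__(self) -> int:
        return len(self.experiments)

    @property
    def fit_experiments(self) -> list[FociDataset]:
        return [e for e in self.experiments if e.role == "fit"]

    @property
    def n_fit_points(self) -> int:
        return sum(len(e) for e in self.fit_experiments)

    def get(self, experiment_id: str) -> FociDataset:
        for e in self.experiments:
            if e.experiment_id == experiment_id:
                return e
        raise KeyError(experiment_id)

    def drop(self, experiment_id: str) -> "DatasetSuite":
        self.get(experiment_id)  # raise if absent
        return DatasetSuite(
            [e for e in self.experiments if e.experiment_id != experiment_id]
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.experiments:
            for d, t, m, s, n in zip(e.doses, e.times, e.means, e.sems,
                                     e.n_cells):
                rows.append({
                    "experiment_id": e.experiment_id, "kind": e.kind.value,
                    "dose_Gy": d, "time_days": t, "mean": m, "sem": s,
                    "n_cells": int(n), "role": e.role,
                })
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class DesignPoint:
    experiment_id: str
    kind: ExperimentKind
    doses: tuple[float, ...]
    times: tuple[float, ...]
    n_cells: int = 50
    role: str = "fit"


_H = 1.0 / 24.0  # one hour in days


def default_ground_truth():
    """Canonical synthetic ground truth: the best-supported model structure
    (protein binding with a fixed pool, second-order channel, square-root
    dose maps) with parameters set once from the field's qualitative
    anchors: ~2% of induced DSBs complex, ~1 background focus per cell,
    simple-repair half-life of hours and complex-repair of half a day to a
    day, and a TAF induction coefficient placing the radiation-induced TAF
    excess above background near 1.6 Gy cumulative dose.

    Returns ``(variant, params)``.
    """
    from .variants import get_variant

    variant = get_variant(10)
    params = ParameterSet(
        kDSB=25.0,   # induced DSB foci per sqrt-Gy
        c=0.02,      # complex fraction
        k1=0.4,      # simple-DSB protein-binding coefficient (per focus/day)
        k3=0.07,     # complex-DSB protein-binding coefficient
        kTAF=0.8,    # TAF induced per sqrt-Gy
        T0=0.5,      # background TAF (foci)
        B=1.0,       # basal non-DSB background (foci)
        kcross=0.002,  # binary-misrepair coefficient (per focus/day)
        kf=12.0,     # repair of protein-bound simple DSBs (1/day)
        ks=1.0,      # repair of protein-bound complex DSBs (1/day)
    )
    return variant, params


def default_design(n_cells: int = 50) -> list[DesignPoint]:
    """The study-layout design: 49 fitted points over 7 experiments plus a
    prediction-only percent-TAF series."""
    tc_short = (_H, 6 * _H, 1.0, 2.0, 3.0, 7.0, 10.0, 14.0)
    tc_long = (_H, 6 * _H, 1.0, 2.0, 3.0, 7.0, 14.0, 28.0, 56.0, 84.0,
               105.0, 120.0)
    taf_tc = (1.0, 3.0, 7.0, 14.0, 28.0, 56.0, 120.0)
    dr_doses = (1.0, 2.5, 5.0, 10.0, 20.0)
    K = ExperimentKind
    return [
        DesignPoint("gH2AX_tc_2.5Gy", K.GAMMAH2AX_TIMECOURSE, (2.5,), tc_short,
                    n_cells),
        DesignPoint("gH2AX_tc_10Gy", K.GAMMAH2AX_TIMECOURSE, (10.0,), tc_short,
                    n_cells),
        DesignPoint("gH2AX_tc_20Gy", K.GAMMAH2AX_TIMECOURSE, (20.0,), tc_long,
                    n_cells),
        DesignPoint("gH2AX_dr_1d", K.GAMMAH2AX_DOSERESPONSE, dr_doses, (1.0,),
                    n_cells),
        DesignPoint("gH2AX_dr_3d", K.GAMMAH2AX_DOSERESPONSE,
                    (1.0, 5.0, 10.0, 20.0), (3.0,), n_cells),
        DesignPoint("TAF_dr_1d", K.TAF_DOSERESPONSE, dr_doses, (1.0,),
                    n_cells),
        DesignPoint("TAF_tc_20Gy", K.TAF_TIMECOURSE, (20.0,), taf_tc, n_cells),
        DesignPoint("pctTAF_tc_20Gy", K.PERCENTTAF_TIMECOURSE, (20.0,), taf_tc,
                    n_cells, role="predict"),
    ]


def sample_counts(mean: float, n_cells: int, rng) -> dict:
    """Draw ``n_cells`` Poisson per-cell counts and summarize them.

    Returns the raw counts, their sample mean and the SEM (sample standard
    deviation / sqrt(n)).  With a single cell the SEM is undefined and is
    reported as 0 with ``sem_defined=False``.
    """
    if mean < 0:
        raise ValueError(f"Poisson mean must be >= 0, got {mean}")
    if n_cells < 1:
        raise ValueError(f"n_cells must be >= 1, got {n_cells}")
    rng = np.random.default_rng(rng)
    counts = rng.poisson(mean, size=int(n_cells))
    sem_defined = n_cells > 1
    sem = float(counts.std(ddof=1) / math.sqrt(n_cells)) if sem_defined else 0.0
    return {
        "counts": counts,
        "mean": float(counts.mean()),
        "sem": sem,
        "sem_defined": sem_defined,
    }


def _expand_grid(dp: DesignPoint):
    """Per-point (dose, time) pairs for one design entry."""
    if len(dp.doses) > 1 and len(dp.times) > 1:
        raise ValueError(
            f"{dp.experiment_id}: design must vary dose or time, not both"
        )
    if len(dp.doses) == 1:
        doses = [dp.doses[0]] * len(dp.times)
        times = list(dp.times)
    else:
        doses = list(dp.doses)
        times = [dp.times[0]] * len(dp.doses)
    return doses, times


def model_observable(
    variant: ModelVariant,
    params: ParameterSet,
    kind: ExperimentKind,
    doses,
    times,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Model-predicted observable at matched (dose, time) points.

    gammaH2AX experiments read the total focus count Ft, TAF experiments
    the TAF pool, percent-TAF the ratio 100*TAF/Ft.
    """
    doses = np.asarray(doses, float)
    times = np.asarray(times, float)
    kind = ExperimentKind(kind)
    out = np.empty(len(doses))
    for dose in np.unique(doses):
        mask = doses == dose
        ts = times[mask]
        order = np.argsort(ts)
        sim = simulate(variant, params, DoseProtocol.acute(dose),
                       ts[order], rtol=rtol, atol=atol)
        if kind is ExperimentKind.PERCENTTAF_TIMECOURSE:
            vals = sim.percent_taf
        elif kind.is_taf:
            vals = sim.TAF
        else:
            vals = sim.Ft
        tmp = np.empty(len(ts))
        tmp[order] = vals
        out[mask] = tmp
    return out


def generate_suite(
    variant: ModelVariant,
    params: ParameterSet,
    design: list[DesignPoint] | None = None,
    seed=0,
    noise: bool = True,
    censor_at: float | None = None,
) -> DatasetSuite:
    """Generate a suite of experiments from a ground-truth model.

    Each design point's model mean seeds Poisson per-cell counts
    (``noise=False`` records the exact model means with SEM
    ``sqrt(mean/n_cells)`` instead).  Percent-TAF series are derived from
    the TAF and total-count means rather than sampled per cell.  Counts can
    optionally be right-censored at ``censor_at`` to mimic saturation of
    focus counting at high damage loads.
    """
    design = design if design is not None else default_design()
    rng = np.random.default_rng(seed)
    experiments = []
    for dp in design:
        doses, times = _expand_grid(dp)
        mu = model_observable(variant, params, dp.kind, doses, times)
        means, sems = [], []
        if dp.kind is ExperimentKind.PERCENTTAF_TIMECOURSE:
            means = list(mu)
            sems = [0.0] * len(mu)
        else:
            for m in mu:
                if noise:
                    stats = sample_counts(m, dp.n_cells, rng)
                    counts = stats["counts"]
                    if censor_at is not None:
                        counts = np.minimum(counts, censor_at)
                        stats = {
                            "mean": float(counts.mean()),
                            "sem": float(counts.std(ddof=1)
                                         / math.sqrt(dp.n_cells)),
                        }
                    means.append(stats["mean"])
                    sems.append(stats["sem"])
                else:
                    means.append(float(m))
                    sems.append(math.sqrt(m / dp.n_cells))
        experiments.append(FociDataset(
            experiment_id=dp.experiment_id, kind=dp.kind,
            doses=np.array(doses), times=np.array(times),
            means=np.array(means), sems=np.array(sems),
            n_cells=np.full(len(means), dp.n_cells), role=dp.role,
        ))
    return DatasetSuite(experiments)


def poisson_resample(suite: DatasetSuite, seed) -> DatasetSuite:
    """One Monte-Carlo replicate of the suite.

    Every fitted data point's mean y is replaced by a single draw from
    Poisson(y); shapes, SEMs and roles are preserved and prediction-only
    experiments are left untouched.
    """
    rng = np.random.default_rng(seed)
    experiments = []
    for e in suite:
        if e.role != "fit":
            experiments.append(replace(e))
            continue
        new_means = rng.poisson(e.means).astype(float)
        experiments.append(replace(e, means=new_means, sems=e.sems.copy()))
    return DatasetSuite(experiments)


_CSV_COLUMNS = ["experiment_id", "kind", "dose_Gy", "time_days", "mean",
                "sem", "n_cells", "role"]


def write_dataset(suite: DatasetSuite, path) -> None:
    # %.17g keeps IEEE doubles exact so read_dataset round-trips bitwise
    suite.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_dataset(path) -> DatasetSuite:
    """Read a suite from the tidy CSV schema (round-trips write_dataset)."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: no experiments found")
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = df.index[df["mean"] < 0]
    if len(bad):
        raise ValueError(
            f"{path}: negative mean at row(s) {[int(i) + 2 for i in bad]}"
        )
    experiments = []
    for eid in df["experiment_id"].unique():
        sub = df[df["experiment_id"] == eid]
        try:
            kind = ExperimentKind(sub["kind"].iloc[0])
        except ValueError:
            raise ValueError(
                f"{path}: unknown kind {sub['kind'].iloc[0]!r} "
                f"in experiment {eid}"
            ) from None
        experiments.append(FociDataset(
            experiment_id=str(eid), kind=kind,
            doses=sub["dose_Gy"].to_numpy(float),
            times=sub["time_days"].to_numpy(float),
            means=sub["mean"].to_numpy(float),
            sems=sub["sem"].to_numpy(float),
            n_cells=sub["n_cells"].to_numpy(int),
            role=str(sub["role"].iloc[0]),
        ))
    return DatasetSuite(experiments)


def interpolate_dose_point(
    dose: float, dose_lo: float, y_lo: float, dose_hi: float, y_hi: float
) -> float:
    """Linear interpolation of a dose-response value between two doses
    (data-preparation utility for filling an unmeasured dose)."""
    if not dose_lo <= dose <= dose_hi or dose_hi <= dose_lo:
        raise ValueError("dose must lie within [dose_lo, dose_hi]")
    w = (dose - dose_lo) / (dose_hi - dose_lo)
    return float((1 - w) * y_lo + w * y_hi)
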
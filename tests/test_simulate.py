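import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from focikit import (DoseProtocol, ParameterSet, dose_map_value, get_variant,
                     initial_state, protein_depletion_diagnostic, repair_time,
                     simulate)
from focikit.simulate import STATE_NAMES, SimulationResult
from focikit.variants import DoseMap


def _p7(**kw):
    base = dict(kDSB=25.0, c=0.02, k1=3.0, k3=0.3, kTAF=0.8, T0=0.5, B=1.0)
    base.update(kw)
    return ParameterSet(**base)


def _p10(**kw):
    base = dict(kDSB=25.0, c=0.02, k1=0.4, k3=0.07, kTAF=0.8, T0=0.5,
                B=1.0, kcross=0.002, kf=12.0, ks=1.0)
    base.update(kw)
    return ParameterSet(**base)


@pytest.mark.parametrize("dose, dmap, expected", [
    (0.0, DoseMap.SQRT, 0.0),
    (4.0, DoseMap.SQRT, 2.0),
    (4.0, DoseMap.LINEAR, 4.0),
])
def test_dose_map_value(dose, dmap, expected):
    assert dose_map_value(dose, dmap) == expected


def test_negative_dose_rejected():
    with pytest.raises(ValueError):
        dose_map_value(-1.0, DoseMap.LINEAR)


def test_initial_state_partitions_induced_damage():
    p = _p10(kDSB=10.0, kTAF=1.0)
    y0 = initial_state(get_variant(10), p, dose=4.0)
    assert y0[STATE_NAMES.index("Si")] == pytest.approx(19.6)
    assert y0[STATE_NAMES.index("Ci")] == pytest.approx(0.4)
    assert y0[STATE_NAMES.index("TAF")] == pytest.approx(2.5)
    assert y0[STATE_NAMES.index("S")] == 0 and y0[STATE_NAMES.index("C")] == 0
    assert y0[STATE_NAMES.index("P")] == 20.0


def test_zero_dose_induces_nothing():
    for vid in (7, 10):
        p = _p10() if vid == 10 else _p7()
        y0 = initial_state(get_variant(vid), p, dose=0.0)
        assert y0[0] == 0 and y0[1] == 0
        assert y0[STATE_NAMES.index("TAF")] == p.get("T0")


def test_linear_vs_sqrt_dose_scaling():
    y_lin = initial_state(get_variant(9), _p10(), dose=9.0)
    y_sq = initial_state(get_variant(10), _p10(), dose=9.0)
    assert y_lin[0] / y_sq[0] == pytest.approx(3.0)


def test_zero_dose_trajectory_is_flat_background():
    p = _p7(T0=0.0)
    sim = simulate(get_variant(7), p, DoseProtocol.acute(0.0),
                   np.linspace(0, 10, 11))
    assert np.allclose(sim.Ft, p.get("B"), atol=1e-12)


def test_first_order_variant_matches_biexponential_closed_form():
    """Variant without protein binding or cross terms is two uncoupled
    exponentials; the integrator must match the closed form to 1e-6."""
    p = _p7()
    times = np.linspace(0.0, 5.0, 41)
    sim = simulate(get_variant(7), p, DoseProtocol.acute(4.0), times)
    Si0 = 25.0 * 0.98 * 4.0
    Ci0 = 25.0 * 0.02 * 4.0
    exact = Si0 * np.exp(-3.0 * times) + Ci0 * np.exp(-0.3 * times)
    num = sim.pool("Si") + sim.pool("Ci")
    rel = np.abs(num - exact) / exact
    assert rel.max() < 1e-6


def test_protein_conservation_across_dose_sweep():
    v10 = get_variant(10)
    times = np.geomspace(1e-3, 120.0, 60)
    for dose in (1.0, 2.5, 5.0, 10.0, 20.0):
        sim = simulate(v10, _p10(), DoseProtocol.acute(dose), times)
        total = sim.pool("P") + sim.pool("S") + sim.pool("C")
        assert np.max(np.abs(total - 20.0)) < 1e-6 * 20.0


def test_taf_constant_and_repair_monotone_between_fractions():
    sim = simulate(get_variant(10), _p10(), DoseProtocol.acute(10.0),
                   np.linspace(0, 30, 200))
    assert np.ptp(sim.TAF) < 1e-9
    repairable = sim.states[:, :4].sum(axis=1)
    assert np.all(np.diff(repairable) <= 1e-9)
    # percent TAF rises as repairable damage clears
    assert np.all(np.diff(sim.percent_taf) >= -1e-9)


def test_trajectory_approaches_background_asymptote():
    p = _p10()
    sim = simulate(get_variant(10), p, DoseProtocol.acute(20.0),
                   np.array([0.1, 400.0]))
    floor = p.get("B") + sim.TAF[-1]
    assert sim.Ft[-1] == pytest.approx(floor, rel=1e-6)


def test_fractionated_protocol_accumulates_taf():
    p = _p10()
    proto = DoseProtocol(((0.0, 5.0), (1.0, 5.0), (2.0, 5.0)))
    sim = simulate(get_variant(10), p, proto, np.array([0.0, 0.5, 1.5, 2.5]))
    # sqrt map applied per fraction: T0 + 3 * kTAF * sqrt(5)
    assert sim.TAF[-1] == pytest.approx(0.5 + 3 * 0.8 * math.sqrt(5.0))
    assert sim.TAF[0] == pytest.approx(0.5 + 0.8 * math.sqrt(5.0))


@settings(max_examples=20, deadline=None, derandomize=True)
@given(scale=st.floats(0.25, 4.0))
def test_linear_first_order_variant_obeys_superposition(scale):
    """For the linear-dose, first-order, no-protein variant the repairable
    signal scales proportionally with dose."""
    p = _p7(T0=0.0, B=0.0, kTAF=0.0)
    times = np.linspace(0.0, 3.0, 7)
    v7 = get_variant(7)
    base = simulate(v7, p, DoseProtocol.acute(2.0), times).Ft
    scaled = simulate(v7, p, DoseProtocol.acute(2.0 * scale), times).Ft
    np.testing.assert_allclose(scaled, scale * base, rtol=1e-6, atol=1e-9)


def test_simulation_result_serializes_tidy_csv(tmp_path):
    sim = simulate(get_variant(10), _p10(), DoseProtocol.acute(2.5),
                   np.linspace(0, 14, 8))
    path = tmp_path / "sim.csv"
    sim.to_csv(path)
    import pandas as pd

    df = pd.read_csv(path)
    assert list(df.columns) == ["time_days", "Si", "Ci", "S", "C", "P",
                                "TAF", "Ft", "percent_taf"]
    np.testing.assert_allclose(
        df["Ft"], df[["Si", "Ci", "S", "C", "TAF"]].sum(axis=1) + 1.0)


# -- repair time -----------------------------------------------------------

def _toy_sim(times, ft_minus_b, B=3.0):
    """Synthetic SimulationResult with Si carrying the decaying signal."""
    states = np.zeros((len(times), 6))
    states[:, 0] = ft_minus_b
    p = ParameterSet(kDSB=1.0, c=0.5, k1=1.0, k3=1.0, kTAF=0.0, T0=0.0, B=B)
    return SimulationResult(get_variant(7), p, np.asarray(times), states)


def test_repair_time_closed_form_crossing():
    times = np.arange(0.0, 5.0, 1e-3)
    sim = _toy_sim(times, 17.0 * np.exp(-times))
    assert repair_time(sim) == pytest.approx(math.log(17.0 / 1.5), abs=1e-6)


def test_repair_time_degenerate_cases():
    times = np.linspace(0, 5, 6)
    already_below = _toy_sim(times, np.full(6, 1.0))
    assert repair_time(already_below) == 0.0
    never = _toy_sim(times, np.full(6, 10.0))
    assert math.isnan(repair_time(never))


# -- protein depletion ------------------------------------------------------

def test_small_damage_leaves_protein_pool_free():
    # induced damage well below the pool of 20 focus equivalents
    sim = simulate(get_variant(10), _p10(kDSB=2.0), DoseProtocol.acute(0.25),
                   np.linspace(0, 5, 20))
    diag = protein_depletion_diagnostic(sim)
    assert diag["min_free_fraction"] > 0.9
    assert not diag["saturated"]


def test_overwhelming_damage_saturates_pool_with_linear_decay():
    # damage far above the pool, fast binding, slow bound-repair
    p = _p10(kDSB=500.0, k1=5.0, k3=5.0, kf=0.5, ks=0.5, kcross=0.0)
    times = np.linspace(0.0, 2.0, 41)
    sim = simulate(get_variant(12), p, DoseProtocol.acute(16.0), times)
    diag = protein_depletion_diagnostic(sim)
    assert diag["saturated"]
    # while saturated the total foci decay is ~linear (constant rate)
    ft = sim.Ft
    slopes = np.diff(ft) / np.diff(times)
    mid = slopes[5:25]
    assert np.ptp(mid) < 0.1 * abs(mid.mean())


def test_depletion_diagnostic_undefined_without_protein():
    sim = simulate(get_variant(7), _p7(), DoseProtocol.acute(1.0),
                   np.linspace(0, 2, 5))
    with pytest.raises(ValueError, match="no-protein"):
        protein_depletion_diagnostic(sim)


def test_dose_protocol_validation():
    with pytest.raises(ValueError):
        DoseProtocol(((0.0, 1.0), (0.0, 1.0)))
    with pytest.raises(ValueError):
        DoseProtocol(((0.0, -1.0),))
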
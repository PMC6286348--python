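"""Functional-model fits: exact noiseless recovery, identities, noisy recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from symport import (EphysSimSpec, fit_hill_activation, fit_inhibition_ki,
                     fit_qv_boltzmann, ki_from_qmax_series,
                     normalize_to_reference, simulate_measurements)
from symport.kinetics import boltzmann_charge, hill_current, qmax_suppression


def _hill_table(i_max, k_half, n_h, grid=None, reps=1, noise=0.0, seed=0):
    grid = np.geomspace(k_half / 20, k_half * 20, 8) if grid is None else grid
    return simulate_measurements(EphysSimSpec(
        "hill_activation", {"i_max": i_max, "k_half": k_half, "n_h": n_h},
        grid, replicates=reps, noise_sigma=noise, seed=seed))


# ---------------------------------------------------------------------------
# Hill activation
# ---------------------------------------------------------------------------

@settings(max_examples=25, derandomize=True, deadline=None)
@given(i_max=st.floats(0.2, 50.0), k_half=st.floats(0.05, 80.0),
       n_h=st.floats(0.6, 3.5))
def test_hill_noiseless_round_trip_is_exact(i_max, k_half, n_h):
    fit = fit_hill_activation(_hill_table(i_max, k_half, n_h))
    assert fit.converged
    assert fit.i_max == pytest.approx(i_max, rel=1e-6)
    assert fit.k_half == pytest.approx(k_half, rel=1e-6)
    assert fit.n_h == pytest.approx(n_h, rel=1e-6)


def test_hill_midpoint_identity():
    fit = fit_hill_activation(_hill_table(1.7, 0.9, 1.61))
    assert fit.predict(fit.k_half) == pytest.approx(fit.i_max / 2, rel=1e-9)


def test_hill_fit_invariant_to_rescaling():
    """Positive rescaling only scales I_max; K_0.5 and n_H are unchanged."""
    tbl = _hill_table(1.0, 0.9, 1.61, reps=3, noise=0.03, seed=5)
    fit_a = fit_hill_activation(tbl)
    scaled = tbl.copy()
    scaled["response"] *= 7.5
    fit_b = fit_hill_activation(scaled)
    assert fit_b.k_half == pytest.approx(fit_a.k_half, rel=1e-6)
    assert fit_b.n_h == pytest.approx(fit_a.n_h, rel=1e-6)
    assert fit_b.i_max == pytest.approx(7.5 * fit_a.i_max, rel=1e-6)


def test_hill_normalization_preprocessing():
    tbl = _hill_table(2.0, 0.9, 1.6, grid=np.array([0.1, 0.5, 1, 5, 10, 20.0]))
    normed = normalize_to_reference(tbl, 10.0)
    assert normed.loc[normed["x"] == 10.0, "response"].mean() == pytest.approx(1.0)
    fit = fit_hill_activation(normed)
    assert fit.k_half == pytest.approx(0.9, rel=1e-6)


def test_hill_noisy_recovery_of_wildtype_sugar_parameters():
    """Seeded 5% noise, wild-type sugar affinity and Hill slope within 10%."""
    tbl = _hill_table(1.0, 0.9, 1.61, grid=np.geomspace(0.05, 50, 8),
                      reps=5, noise=0.05, seed=101)
    fit = fit_hill_activation(tbl)
    assert fit.k_half == pytest.approx(0.9, rel=0.10)
    assert fit.n_h == pytest.approx(1.61, rel=0.10)


def test_hill_requires_enough_concentrations():
    with pytest.raises(ValueError, match="4 distinct"):
        fit_hill_activation(_hill_table(1, 1, 1, grid=np.array([0.5, 1, 2.0])))


def test_hill_flags_k_outside_grid_window():
    """A series far below its K_0.5 is flagged (K outside range x [0.01, 100])."""
    grid = np.geomspace(1e-4, 1e-3, 6)   # K true = 100, grid max * 100 = 0.1
    fit = fit_hill_activation(_hill_table(1.0, 100.0, 1.0, grid=grid))
    assert fit.flags


# ---------------------------------------------------------------------------
# inhibition + competitive correction
# ---------------------------------------------------------------------------

def _inhibition_table(i_0, ic50, grid=None, reps=1, noise=0.0, seed=0):
    grid = np.geomspace(ic50 / 50, ic50 * 50, 8) if grid is None else grid
    return simulate_measurements(EphysSimSpec(
        "inhibition", {"i_0": i_0, "ic50": ic50}, grid,
        replicates=reps, noise_sigma=noise, seed=seed))


def test_cheng_prusoff_at_midpoint_substrate():
    """At S = K_0.5 the correction is exactly a factor of two."""
    fit = fit_inhibition_ki(_inhibition_table(1.0, 2.0), substrate=0.9,
                            substrate_k_half=0.9)
    assert fit.ic50 == pytest.approx(2.0, rel=1e-6)
    assert fit.k_i == pytest.approx(1.0, rel=1e-6)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(i_0=st.floats(0.2, 10.0), k_i=st.floats(0.005, 50.0),
       s_over_k=st.floats(0.2, 5.0))
def test_inhibition_noiseless_round_trip(i_0, k_i, s_over_k):
    ic50 = k_i * (1 + s_over_k)
    fit = fit_inhibition_ki(_inhibition_table(i_0, ic50),
                            substrate=s_over_k, substrate_k_half=1.0)
    assert fit.k_i == pytest.approx(k_i, rel=1e-6)
    assert fit.i_0 == pytest.approx(i_0, rel=1e-6)


def test_ki_never_exceeds_ic50():
    fit = fit_inhibition_ki(_inhibition_table(1.0, 1.0), substrate=2.0,
                            substrate_k_half=1.0)
    assert fit.k_i <= fit.ic50


def test_inhibition_noisy_recovery_of_wildtype_phlorizin_ki():
    """Wild-type phlorizin K_i (0.22 uM) at S = K_0.5 within 15%."""
    k_i = 0.22
    tbl = _inhibition_table(1.0, 2 * k_i, grid=np.geomspace(0.01, 10, 8),
                            reps=5, noise=0.05, seed=202)
    fit = fit_inhibition_ki(tbl, substrate=0.9, substrate_k_half=0.9)
    assert fit.k_i == pytest.approx(k_i, rel=0.15)


def test_flat_inhibition_series_rejected():
    tbl = pd.DataFrame({"x": [0.1, 1, 10, 100], "response": [1.0] * 4})
    with pytest.raises(ValueError, match="no inhibition signal"):
        fit_inhibition_ki(tbl, substrate=1.0, substrate_k_half=1.0)


# ---------------------------------------------------------------------------
# Boltzmann Q-V
# ---------------------------------------------------------------------------

def _qv_table(q_offset, q_max, v_half, z, grid=None, noise=0.0, seed=0,
              reps=1):
    grid = np.arange(-180.0, 60.0, 20.0) if grid is None else grid
    return simulate_measurements(EphysSimSpec(
        "boltzmann_qv",
        {"q_offset": q_offset, "q_max": q_max, "v_half": v_half, "z": z},
        grid, replicates=reps, noise_sigma=noise, seed=seed))


@settings(max_examples=20, derandomize=True, deadline=None)
@given(q_offset=st.floats(-1.0, 1.0), q_max=st.floats(0.3, 5.0),
       v_half=st.floats(-80.0, -10.0), z=st.floats(0.4, 2.0))
def test_boltzmann_noiseless_round_trip(q_offset, q_max, v_half, z):
    fit = fit_qv_boltzmann(_qv_table(q_offset, q_max, v_half, z))
    assert fit.q_offset == pytest.approx(q_offset, rel=1e-6, abs=1e-8)
    assert fit.q_max == pytest.approx(q_max, rel=1e-6)
    assert fit.v_half == pytest.approx(v_half, rel=1e-6)
    assert fit.z == pytest.approx(z, rel=1e-6)


def test_boltzmann_symmetric_data_recovers_v_half_exactly():
    v_half = -50.0
    grid = v_half + np.array([-75, -50, -25, 0, 25, 50, 75.0])
    fit = fit_qv_boltzmann(_qv_table(0.0, 1.0, v_half, 1.0, grid=grid))
    assert fit.v_half == pytest.approx(v_half, rel=1e-9)


def test_boltzmann_midpoint_identity():
    fit = fit_qv_boltzmann(_qv_table(-0.2, 1.4, -45.0, 1.1))
    assert fit.predict(fit.v_half) == pytest.approx(
        fit.q_offset + fit.q_max / 2, rel=1e-9)


def test_boltzmann_saturates_at_hyperpolarization():
    fit = fit_qv_boltzmann(_qv_table(0.1, 1.0, -40.0, 1.0))
    assert fit.predict(-1e4) == pytest.approx(fit.q_offset + fit.q_max,
                                              rel=1e-6)


def test_boltzmann_needs_six_voltages():
    with pytest.raises(ValueError, match="6 voltages"):
        fit_qv_boltzmann(_qv_table(0, 1, -40, 1, grid=np.array([-80, -40, 0.0])))


# ---------------------------------------------------------------------------
# K_i from Q_max suppression
# ---------------------------------------------------------------------------

def test_qmax_midpoint_identity():
    assert qmax_suppression(0.3, 2.0, 0.3) == pytest.approx(1.0)


@settings(max_examples=20, derandomize=True, deadline=None)
@given(q0=st.floats(0.5, 5.0), k_i=st.floats(0.01, 3.0))
def test_qmax_series_noiseless_round_trip(q0, k_i):
    grid = np.concatenate([[0.0], np.geomspace(k_i / 10, k_i * 10, 6)])
    pairs = [(i, float(qmax_suppression(i, q0, k_i))) for i in grid]
    fit = ki_from_qmax_series(pairs)
    assert fit.k_i == pytest.approx(k_i, rel=1e-6)
    assert fit.q_max0 == pytest.approx(q0, rel=1e-6)


def test_qmax_noisy_recovery_of_d268h_dapagliflozin_ki():
    """Q_max suppression with the D268H dapagliflozin constant, within 15%."""
    k_i, q0 = 0.035, 1.0
    grid = np.concatenate([[0.0], np.geomspace(0.005, 1.0, 7)])
    rng = np.random.default_rng(7)
    pairs = [(i, float(qmax_suppression(i, q0, k_i)) + rng.normal(0, 0.02))
             for i in grid]
    fit = ki_from_qmax_series(pairs)
    assert fit.k_i == pytest.approx(k_i, rel=0.15)


def test_qmax_series_requirements():
    with pytest.raises(ValueError, match="4 inhibitor"):
        ki_from_qmax_series([(0, 1.0), (1, 0.5), (2, 0.3)])
    with pytest.raises(ValueError, match="i=0"):
        ki_from_qmax_series([(1, 1.0), (2, 0.5), (3, 0.4), (4, 0.3)])


def test_qmax_non_decreasing_series_flagged():
    pairs = [(0, 1.0), (0.1, 1.1), (1.0, 1.2), (10.0, 1.3)]
    fit = ki_from_qmax_series(pairs)
    assert any("non-decreasing" in f for f in fit.flags)
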
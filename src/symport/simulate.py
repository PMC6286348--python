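"""Simulated oocyte-style electrophysiology tables.

Statistical stand-ins for two-electrode voltage-clamp recordings: each
generator evaluates one of the functional models on a concentration or
voltage grid and adds seeded Gaussian noise, producing the tidy replicate
table the fitting routines consume (columns ``construct, model, x,
replicate, response, unit``).

Noise conventions: current-type models (``hill_activation``, ``inhibition``)
use multiplicative noise, response * (1 + N(0, sigma)), matching the roughly
proportional scatter of oocyte currents; charge (``boltzmann_qv``) and
reversal-potential (``vrev_series``) models use additive noise in the units
of the measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import kinetics
from .stoichiometry import ThermoContext, predict_vrev

__all__ = ["EphysSimSpec", "simulate_measurements", "MODELS"]

MODELS = ("hill_activation", "inhibition", "boltzmann_qv", "vrev_series")

_RELATIVE_NOISE_MODELS = {"hill_activation", "inhibition"}

_UNITS = {
    "hill_activation": "normalized_current",
    "inhibition": "normalized_current",
    "boltzmann_qv": "normalized_charge",
    "vrev_series": "mV",
}


@dataclass
class EphysSimSpec:
    """One simulated protocol.

    ``grid`` holds concentrations (mM or µM, positive) for concentration
    models, membrane voltages in mV for ``boltzmann_qv``, and external sugar
    concentrations for ``vrev_series``.  ``params`` are the generating model
    parameters (see the corresponding fit model in :mod:`symport.kinetics` /
    :mod:`symport.stoichiometry`).
    """

    model: str
    params: dict
    grid: Sequence[float]
    replicates: int = 1
    noise_sigma: float = 0.0
    seed: int = 0
    construct: str = "synthetic"
    thermo: ThermoContext = field(default_factory=ThermoContext)

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; one of {MODELS}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        grid = np.asarray(self.grid, dtype=float)
        if grid.size == 0:
            raise ValueError("grid must be non-empty")
        if self.model in ("hill_activation", "vrev_series") and np.any(grid <= 0):
            raise ValueError(
                f"{self.model} requires strictly positive concentrations")
        if self.model == "inhibition" and np.any(grid < 0):
            raise ValueError("inhibitor concentrations must be non-negative")


def _evaluate(spec: EphysSimSpec, grid: np.ndarray) -> np.ndarray:
    p = spec.params
    if spec.model == "hill_activation":
        return kinetics.hill_current(grid, p["i_max"], p["k_half"], p["n_h"])
    if spec.model == "inhibition":
        return kinetics.inhibition_current(grid, p["i_0"], p["ic50"])
    if spec.model == "boltzmann_qv":
        return kinetics.boltzmann_charge(
            grid, p["q_offset"], p["q_max"], p["v_half"], p["z"],
            spec.thermo.temperature_k)
    # vrev_series
    return np.array([
        predict_vrev(p["n"], p["na_o"], p["na_i"], s_o, p["s_i"], spec.thermo)
        for s_o in grid])


def simulate_measurements(spec: EphysSimSpec) -> pd.DataFrame:
    """Simulate a tidy replicate table for one protocol.

    One row per (grid point, replicate).  With ``noise_sigma == 0`` every row
    equals the model value at its grid point; noise is seeded and bit-exact
    reproducible for a given spec.
    """
    grid = np.asarray(spec.grid, dtype=float)
    clean = _evaluate(spec, grid)
    rng = np.random.default_rng(spec.seed)
    rows = []
    for rep in range(1, spec.replicates + 1):
        if spec.noise_sigma == 0:
            noisy = clean
        elif spec.model in _RELATIVE_NOISE_MODELS:
            noisy = clean * (1.0 + rng.normal(0.0, spec.noise_sigma, clean.shape))
        else:
            noisy = clean + rng.normal(0.0, spec.noise_sigma, clean.shape)
        for x, resp in zip(grid, noisy):
            rows.append((spec.construct, spec.model, x, rep, resp,
                         _UNITS[spec.model]))
    return pd.DataFrame(
        rows, columns=["construct", "model", "x", "replicate", "response",
                       "unit"])
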
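"""Fits for electrogenic-cotransporter functional data.

Four steady-state / pre-steady-state models cover the standard two-electrode
voltage-clamp protocols used to characterize Na+/glucose symporters expressed
in oocytes:

* **Hill activation** — substrate- or Na+-dependence of the inward current,
  ``I(S) = I_max * S^n / (K_0.5^n + S^n)``.  ``K_0.5`` is the apparent affinity
  (concentration of half-maximal current) and ``n_H`` the Hill coefficient, a
  lower bound on the number of cooperating binding sites.
* **Inhibition dose-response** — suppression of the substrate-evoked current by
  increasing inhibitor, ``I(i) = I_0 / (1 + i/IC50)``, with the competitive
  (Cheng-Prusoff) correction ``K_i = IC50 / (1 + S/K_0.5)``.  When the assay is
  run at a substrate concentration equal to its own K_0.5, ``K_i = IC50/2``.
* **Boltzmann Q-V** — voltage dependence of the pre-steady-state charge moved
  by voltage steps, ``Q(V) = Q_offset + Q_max / (1 + exp(zF(V - V_0.5)/RT))``;
  charge saturates at ``Q_offset + Q_max`` for hyperpolarizing potentials.
* **Q_max suppression** — inhibitor locking of the outward-facing state reduces
  the mobile charge as ``Q_max(i) = Q_max0 / (1 + i/K_i)``, giving a second,
  sugar-independent route to K_i.

All fits are unweighted least squares on replicate means with deterministic
initialization, so repeated fits of the same table give identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .constants import FARADAY, GAS_CONSTANT, TEMPERATURE_K

__all__ = [
    "HillFit",
    "InhibitionFit",
    "BoltzmannFit",
    "QmaxKiFit",
    "hill_current",
    "inhibition_current",
    "boltzmann_charge",
    "qmax_suppression",
    "fit_hill_activation",
    "fit_inhibition_ki",
    "fit_qv_boltzmann",
    "ki_from_qmax_series",
    "normalize_to_reference",
]


# ---------------------------------------------------------------------------
# model functions
# ---------------------------------------------------------------------------

def hill_current(s, i_max, k_half, n_h):
    """Hill activation: I(S) = I_max * S^n / (K^n + S^n)."""
    s = np.asarray(s, dtype=float)
    sn = np.power(s, n_h)
    return i_max * sn / (np.power(k_half, n_h) + sn)


def inhibition_current(i, i_0, ic50):
    """Single-site inhibition isotherm: I(i) = I_0 / (1 + i/IC50)."""
    i = np.asarray(i, dtype=float)
    return i_0 / (1.0 + i / ic50)


def boltzmann_charge(v_mv, q_offset, q_max, v_half_mv, z,
                     temperature_k=TEMPERATURE_K):
    """Two-state Boltzmann Q-V curve.

    Q saturates at ``q_offset + q_max`` as V -> -inf (hyperpolarization) and at
    ``q_offset`` as V -> +inf, for z > 0.
    """
    v_mv = np.asarray(v_mv, dtype=float)
    rt_f_mv = 1000.0 * GAS_CONSTANT * temperature_k / FARADAY
    return q_offset + q_max / (1.0 + np.exp(z * (v_mv - v_half_mv) / rt_f_mv))


def qmax_suppression(i, q_max0, k_i):
    """Q_max(i) = Q_max,0 / (1 + i/K_i)."""
    i = np.asarray(i, dtype=float)
    return q_max0 / (1.0 + i / k_i)


# ---------------------------------------------------------------------------
# fit results
# ---------------------------------------------------------------------------

@dataclass
class HillFit:
    i_max: float
    k_half: float
    n_h: float
    i_max_se: float
    k_half_se: float
    n_h_se: float
    converged: bool = True
    flags: list[str] = field(default_factory=list)

    def predict(self, s):
        return hill_current(s, self.i_max, self.k_half, self.n_h)


@dataclass
class InhibitionFit:
    i_0: float
    ic50: float
    k_i: float
    i_0_se: float
    ic50_se: float
    k_i_se: float
    substrate: float
    substrate_k_half: float
    converged: bool = True
    flags: list[str] = field(default_factory=list)

    def predict(self, i):
        return inhibition_current(i, self.i_0, self.ic50)


@dataclass
class BoltzmannFit:
    q_offset: float
    q_max: float
    v_half: float
    z: float
    q_offset_se: float
    q_max_se: float
    v_half_se: float
    z_se: float
    temperature_k: float = TEMPERATURE_K
    converged: bool = True
    flags: list[str] = field(default_factory=list)

    def predict(self, v_mv):
        return boltzmann_charge(v_mv, self.q_offset, self.q_max, self.v_half,
                                self.z, self.temperature_k)


@dataclass
class QmaxKiFit:
    q_max0: float
    k_i: float
    q_max0_se: float
    k_i_se: float
    converged: bool = True
    flags: list[str] = field(default_factory=list)

    def predict(self, i):
        return qmax_suppression(i, self.q_max0, self.k_i)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _replicate_means(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Collapse replicate rows to per-x means, sorted by x."""
    if not {"x", "response"}.issubset(table.columns):
        raise ValueError("table must have 'x' and 'response' columns")
    g = table.groupby("x", sort=True)["response"].mean()
    return g.index.to_numpy(dtype=float), g.to_numpy(dtype=float)


def _se_from_cov(pcov: np.ndarray) -> np.ndarray:
    d = np.diag(pcov)
    return np.sqrt(np.where(np.isfinite(d) & (d >= 0), d, np.nan))


def _half_max_crossing(x: np.ndarray, y: np.ndarray, half: float) -> float:
    """Log-linear interpolation of the first half-maximum crossing.

    Used only for initialization; falls back to the geometric median of the
    grid when the data never cross half-max.
    """
    above = y >= half
    for j in range(1, len(x)):
        if above[j] != above[0]:
            x0, x1 = x[j - 1], x[j]
            y0, y1 = y[j - 1], y[j]
            if y1 == y0:
                return float(np.sqrt(x0 * x1))
            f = (half - y0) / (y1 - y0)
            return float(np.exp(np.log(x0) + f * (np.log(x1) - np.log(x0))))
    return float(np.exp(np.median(np.log(x))))


def normalize_to_reference(table: pd.DataFrame, x_ref: float) -> pd.DataFrame:
    """Normalize responses to the mean response at a reference grid point.

    Mirrors the common oocyte convention of expressing currents relative to the
    current at a fixed substrate concentration (e.g. 10 mM sugar).
    """
    ref_rows = table.loc[np.isclose(table["x"].astype(float), x_ref)]
    if ref_rows.empty:
        raise ValueError(f"reference x={x_ref} not present in table")
    ref = ref_rows["response"].mean()
    if ref == 0:
        raise ValueError("reference response is zero; cannot normalize")
    out = table.copy()
    out["response"] = out["response"] / ref
    return out


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------

def fit_hill_activation(table: pd.DataFrame) -> HillFit:
    """Fit the Hill activation model to a dose-response table.

    Parameters
    ----------
    table
        Tidy table with columns ``x`` (concentration, mM) and ``response``
        (current); replicate rows are averaged per concentration.

    Initialization: I_max = max mean response, K_0.5 from the log-linear
    half-max crossing, n_H = 1.
    """
    x, y = _replicate_means(table)
    if len(x) < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if np.any(x <= 0):
        raise ValueError("concentrations must be positive")
    if np.any(y < 0):
        raise ValueError("responses must be non-negative")
    i_max0 = float(np.max(y))
    k0 = _half_max_crossing(x, y, i_max0 / 2.0)
    p0 = (i_max0, k0, 1.0)
    flags: list[str] = []
    converged = True
    try:
        popt, pcov = curve_fit(hill_current, x, y, p0=p0, maxfev=20000)
    except RuntimeError:
        converged = False
        flags.append("non-convergence")
        popt, pcov = np.asarray(p0), np.full((3, 3), np.nan)
    se = _se_from_cov(pcov)
    k_fit = float(popt[1])
    if not (0.01 * x.min() <= k_fit <= 100.0 * x.max()):
        flags.append("k_half outside tested range x [0.01, 100]")
    return HillFit(float(popt[0]), k_fit, float(popt[2]),
                   float(se[0]), float(se[1]), float(se[2]),
                   converged=converged, flags=flags)


def fit_inhibition_ki(table: pd.DataFrame, substrate: float,
                      substrate_k_half: float) -> InhibitionFit:
    """Fit the inhibition isotherm and apply the competitive K_i correction.

    ``substrate`` is the assay substrate concentration S and
    ``substrate_k_half`` its independently measured K_0.5; then
    K_i = IC50 / (1 + S/K_0.5).  At S = K_0.5 this is exactly IC50/2.
    """
    if substrate <= 0 or substrate_k_half <= 0:
        raise ValueError("substrate and its K_0.5 must be positive")
    x, y = _replicate_means(table)
    if np.ptp(y) == 0:
        raise ValueError("no inhibition signal: all responses are equal")
    i_00 = float(np.max(y))
    pos = x > 0
    ic50_0 = _half_max_crossing(x[pos], y[pos], i_00 / 2.0) if pos.sum() > 1 \
        else float(np.median(x[pos]))
    flags: list[str] = []
    converged = True
    try:
        popt, pcov = curve_fit(inhibition_current, x, y, p0=(i_00, ic50_0),
                               maxfev=20000)
    except RuntimeError:
        converged = False
        flags.append("non-convergence")
        popt, pcov = np.asarray((i_00, ic50_0)), np.full((2, 2), np.nan)
    se = _se_from_cov(pcov)
    correction = 1.0 + substrate / substrate_k_half
    ic50 = float(popt[1])
    return InhibitionFit(
        i_0=float(popt[0]), ic50=ic50, k_i=ic50 / correction,
        i_0_se=float(se[0]), ic50_se=float(se[1]),
        k_i_se=float(se[1]) / correction,
        substrate=substrate, substrate_k_half=substrate_k_half,
        converged=converged, flags=flags)


def fit_qv_boltzmann(table: pd.DataFrame,
                     temperature_k: float = TEMPERATURE_K) -> BoltzmannFit:
    """Fit the two-state Boltzmann to a charge-voltage table (x in mV)."""
    v, q = _replicate_means(table)
    if len(v) < 6:
        raise ValueError("need at least 6 voltages")
    q_off0 = float(np.min(q))
    q_max0 = float(np.max(q) - np.min(q))
    if q_max0 == 0:
        raise ValueError("charge is flat across voltages")
    # V_0.5 guess: voltage nearest half saturation
    half = q_off0 + q_max0 / 2.0
    v_half0 = float(v[np.argmin(np.abs(q - half))])
    p0 = (q_off0, q_max0, v_half0, 1.0)

    def model(vv, q_offset, q_max, v_half, z):
        return boltzmann_charge(vv, q_offset, q_max, v_half, z, temperature_k)

    flags: list[str] = []
    converged = True
    try:
        popt, pcov = curve_fit(model, v, q, p0=p0, maxfev=20000)
    except RuntimeError:
        converged = False
        flags.append("non-convergence")
        popt, pcov = np.asarray(p0), np.full((4, 4), np.nan)
    se = _se_from_cov(pcov)
    return BoltzmannFit(float(popt[0]), float(popt[1]), float(popt[2]),
                        float(popt[3]), float(se[0]), float(se[1]),
                        float(se[2]), float(se[3]),
                        temperature_k=temperature_k,
                        converged=converged, flags=flags)


def ki_from_qmax_series(pairs) -> QmaxKiFit:
    """K_i from suppression of Q_max by inhibitor.

    ``pairs`` is a sequence of (inhibitor concentration, fitted Q_max) with at
    least 4 concentrations including 0.  A series in which Q_max does not
    decrease with inhibitor is inconsistent with the binding model and is
    flagged.
    """
    arr = np.asarray(sorted(pairs), dtype=float)
    if arr.shape[0] < 4:
        raise ValueError("need at least 4 inhibitor concentrations")
    if not np.any(arr[:, 0] == 0):
        raise ValueError("series must include the uninhibited point (i=0)")
    i, q = arr[:, 0], arr[:, 1]
    flags: list[str] = []
    if np.all(np.diff(q) >= 0):
        flags.append("Q_max non-decreasing in inhibitor")
    q00 = float(q[i == 0].mean())
    pos = i > 0
    ki0 = _half_max_crossing(i[pos], q[pos], q00 / 2.0) if pos.sum() > 1 \
        else float(np.median(i[pos]))
    converged = True
    try:
        popt, pcov = curve_fit(qmax_suppression, i, q, p0=(q00, ki0),
                               maxfev=20000)
    except RuntimeError:
        converged = False
        flags.append("non-convergence")
        popt, pcov = np.asarray((q00, ki0)), np.full((2, 2), np.nan)
    se = _se_from_cov(pcov)
    return QmaxKiFit(float(popt[0]), float(popt[1]),
                     float(se[0]), float(se[1]),
                     converged=converged, flags=flags)
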
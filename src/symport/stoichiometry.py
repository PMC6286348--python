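"""Coupling stoichiometry of electrogenic Na+/sugar cotransport.

At the reversal potential the net electrochemical driving force on one
transport cycle vanishes.  For inward cotransport of ``n`` Na+ ions (charge +1
each) with one neutral sugar molecule,

    n * (RT ln(Na_o/Na_i) + F V) + RT ln(S_o/S_i) = 0  at V = V_rev

so

    V_rev = -(RT/F) [ ln(Na_o/Na_i) + (1/n) ln(S_o/S_i) ] * (-1)
          = (RT/F) [ ln(Na_o/Na_i) + (1/n) ln(S_o/S_i) ]

with the membrane potential defined as inside relative to outside and the
transporter moving cargo inward.  Holding the Na+ gradient fixed and varying
only the external sugar concentration, V_rev is linear in ln(S_o) with slope
RT/(nF): the coupling ratio is read off as n = (RT/F)/slope.  A 2:1
transporter therefore shows half the ln-sugar slope of a 1:1 transporter.

The Na+ term only shifts the intercept; it carries no information about n in
this protocol.  The Na+-activation Hill coefficient provides a corroborating
lower-bound estimate of the same quantity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .constants import FARADAY, GAS_CONSTANT, TEMPERATURE_K, rt_over_f_mv

__all__ = [
    "ThermoContext",
    "CouplingEstimate",
    "predict_vrev",
    "coupling_ratio_from_vrev",
    "coupling_from_hill",
]


@dataclass(frozen=True)
class ThermoContext:
    """Thermodynamic constants used by the reversal-potential analysis."""

    gas_constant: float = GAS_CONSTANT
    temperature_k: float = TEMPERATURE_K
    faraday: float = FARADAY

    def __post_init__(self):
        if self.temperature_k <= 0:
            raise ValueError("temperature must be positive")

    @property
    def rt_f_mv(self) -> float:
        """RT/F in mV."""
        return 1000.0 * self.gas_constant * self.temperature_k / self.faraday


@dataclass
class CouplingEstimate:
    n: float
    n_se: float
    slope_mv: float
    slope_se_mv: float
    intercept_mv: float
    method: str = "reversal_potential"
    note: str = ""


def predict_vrev(n: float, na_o: float, na_i: float, s_o: float, s_i: float,
                 ctx: ThermoContext | None = None) -> float:
    """Reversal potential (mV) for n Na+ : 1 neutral-sugar cotransport.

    V_rev = (RT/F) [ ln(Na_o/Na_i) + (1/n) ln(S_o/S_i) ].  With equal inner
    and outer sugar this reduces to the Na+ Nernst potential, independent
    of n.
    """
    if n <= 0:
        raise ValueError("coupling ratio n must be positive")
    for name, c in (("na_o", na_o), ("na_i", na_i), ("s_o", s_o), ("s_i", s_i)):
        if c <= 0:
            raise ValueError(f"concentration {name} must be positive")
    ctx = ctx or ThermoContext()
    return ctx.rt_f_mv * (np.log(na_o / na_i) + np.log(s_o / s_i) / n)


def coupling_ratio_from_vrev(s_o_mm, v_rev_mv,
                             ctx: ThermoContext | None = None) -> CouplingEstimate:
    """Coupling ratio from a series of (S_o, V_rev) at fixed Na+ gradient.

    Ordinary least squares of V_rev on ln(S_o); n = (RT/F)/slope with the
    standard error propagated from the slope SE: se(n) = (RT/F) se(b)/b^2.
    Replicate rows are allowed (each point enters the regression).
    """
    s_o = np.asarray(s_o_mm, dtype=float)
    v = np.asarray(v_rev_mv, dtype=float)
    if s_o.shape != v.shape:
        raise ValueError("s_o and v_rev must have the same length")
    if np.any(s_o <= 0):
        raise ValueError("sugar concentrations must be positive")
    if len(np.unique(s_o)) < 3:
        raise ValueError("need at least 3 distinct sugar concentrations")
    ctx = ctx or ThermoContext()
    res = stats.linregress(np.log(s_o), v)
    b = res.slope
    if not np.isfinite(b) or b <= 0:
        raise ValueError(f"non-physical slope {b!r}: no positive coupling ratio")
    rt_f = ctx.rt_f_mv
    n = rt_f / b
    n_se = rt_f * res.stderr / b**2
    return CouplingEstimate(n=float(n), n_se=float(n_se), slope_mv=float(b),
                            slope_se_mv=float(res.stderr),
                            intercept_mv=float(res.intercept))


def coupling_from_hill(na_fit) -> CouplingEstimate:
    """Corroborating stoichiometry estimate from a Na+-activation Hill fit.

    The Hill coefficient underestimates the true number of transported ions
    unless binding is infinitely cooperative, so the returned estimate is
    labelled a lower bound.
    """
    return CouplingEstimate(n=float(na_fit.n_h), n_se=float(na_fit.n_h_se),
                            slope_mv=float("nan"), slope_se_mv=float("nan"),
                            intercept_mv=float("nan"),
                            method="hill_coefficient",
                            note="Hill-based, lower bound")
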
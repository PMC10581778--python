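"""Channel gating models used by the synthetic recording generator.

Two families are provided:

* :class:`PiecewiseQ10Params` — a phenomenological model in which the
  magnitude of the current follows exact Q10 (exponential-in-temperature)
  growth on up to three temperature bands separated by an activation
  threshold and an optional saturation breakpoint.  Because this model is the
  exact inverse of the Q10 formula applied downstream, it yields well-posed
  parameter-recovery targets.
* :class:`TwoStateParams` — a mechanistic two-state (closed/open) model whose
  open probability follows the van't Hoff form
  ``Po(T) = 1 / (1 + exp((dH - T*dS) / (R*T)))`` with a large opening
  enthalpy, optionally combined with a Boltzmann voltage dependence for
  simulating current-voltage experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

__all__ = [
    "GAS_CONSTANT",
    "CELSIUS_OFFSET",
    "PiecewiseQ10Params",
    "TwoStateParams",
    "ChannelParams",
    "current_piecewise",
    "open_probability",
    "current_two_state",
]

#: Molar gas constant, J / (mol K).
GAS_CONSTANT = 8.314
#: 0 °C in kelvin.
CELSIUS_OFFSET = 273.15


@dataclass(frozen=True)
class PiecewiseQ10Params:
    """Piecewise-Q10 description of a heat-activated current.

    ``i_ref`` is the current (nA, sign as recorded; inward negative) at the
    reference temperature ``t_ref`` (°C).  Below ``threshold`` the magnitude
    grows with ``q10_baseline`` per 10 °C; between ``threshold`` and
    ``second_breakpoint`` with ``q10_activation``; above the second
    breakpoint (open probability saturated, remaining temperature dependence
    from ion diffusion through the open pore) with ``q10_supra``.
    """

    i_ref: float
    t_ref: float
    q10_baseline: float
    threshold: float
    q10_activation: float
    second_breakpoint: Optional[float] = None
    q10_supra: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.i_ref) or self.i_ref == 0:
            raise ValueError("i_ref must be finite and non-zero")
        for name in ("q10_baseline", "q10_activation", "q10_supra"):
            if getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be >= 1")
        if self.second_breakpoint is not None and not (
            self.threshold < self.second_breakpoint
        ):
            raise ValueError("threshold must lie below second_breakpoint")


@dataclass(frozen=True)
class TwoStateParams:
    """Two-state thermodynamic gating with optional voltage dependence.

    ``delta_h`` (J/mol) and ``delta_s`` (J/(mol K)) are the enthalpy and
    entropy of channel opening; for a heat-activated channel both are
    positive and the gating midpoint is at ``T = delta_h / delta_s`` kelvin.
    ``g_max`` is the effective maximal conductance (number of channels times
    unitary conductance), µS; ``e_rev`` the reversal potential, mV.  When
    ``v50``/``v_slope`` (mV) are given, open probability is multiplied by a
    Boltzmann voltage term ``1 / (1 + exp((v50 - V) / v_slope))``.
    """

    delta_h: float
    delta_s: float
    g_max: float
    e_rev: float = 0.0
    v50: Optional[float] = None
    v_slope: Optional[float] = None

    def __post_init__(self) -> None:
        if self.g_max <= 0:
            raise ValueError("g_max must be positive")
        if np.sign(self.delta_h) != np.sign(self.delta_s):
            raise ValueError(
                "delta_h and delta_s must share a sign for monotone Po(T)"
            )
        if (self.v50 is None) != (self.v_slope is None):
            raise ValueError("v50 and v_slope must be given together")
        if self.v_slope is not None and self.v_slope == 0:
            raise ValueError("v_slope must be non-zero")

    @property
    def midpoint_K(self) -> float:
        """Gating midpoint temperature (Po = 1/2), kelvin."""
        return self.delta_h / self.delta_s


ChannelParams = Union[PiecewiseQ10Params, TwoStateParams]


def current_piecewise(T, p: PiecewiseQ10Params):
    """Current (nA) of a piecewise-Q10 channel at temperature ``T`` (°C).

    The magnitude is

    ``|i_ref| * q10_baseline**((min(T, thr) - t_ref)/10)
             * q10_activation**((clip(T, thr, bp2) - thr)/10)
             * q10_supra**(max(T - bp2, 0)/10)``

    which is continuous in ``T``; the sign of ``i_ref`` is preserved.
    Accepts scalars or arrays.
    """
    T = np.asarray(T, float)
    bp2 = p.second_breakpoint if p.second_breakpoint is not None else np.inf
    base_exp = (np.minimum(T, p.threshold) - p.t_ref) / 10.0
    act_exp = (np.clip(T, p.threshold, bp2) - p.threshold) / 10.0
    mag = abs(p.i_ref) * p.q10_baseline**base_exp * p.q10_activation**act_exp
    if np.isfinite(bp2):
        sup_exp = np.maximum(T - bp2, 0.0) / 10.0
        mag = mag * p.q10_supra**sup_exp
    out = np.sign(p.i_ref) * mag
    return out if out.ndim else float(out)


def open_probability(T, p: TwoStateParams):
    """Two-state open probability at temperature ``T`` (°C)."""
    T_K = np.asarray(T, float) + CELSIUS_OFFSET
    if np.any(T_K <= 0):
        raise ValueError("temperature must exceed absolute zero")
    z = (p.delta_h - T_K * p.delta_s) / (GAS_CONSTANT * T_K)
    po = 1.0 / (1.0 + np.exp(z))
    return po if po.ndim else float(po)


def current_two_state(T, V, p: TwoStateParams):
    """Current (nA) of a two-state channel at ``T`` (°C) and ``V`` (mV).

    ``I = g_max * Po(T) * Pv(V) * (V - e_rev)`` with ``g_max`` in µS and
    voltages in mV, giving nA.  ``Pv`` is 1 when no voltage dependence is
    configured.
    """
    V = np.asarray(V, float)
    po = open_probability(T, p)
    if p.v50 is not None:
        pv = 1.0 / (1.0 + np.exp((p.v50 - V) / p.v_slope))
    else:
        pv = 1.0
    out = p.g_max * po * pv * (V - p.e_rev)
    return out if np.ndim(out) else float(out)
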
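"""Current-voltage extraction and Boltzmann voltage-dependence fitting.

Steady-state currents are read from the tail of each voltage-step episode,
converted to chord conductances ``G = I / (V - E_rev)``, and fitted with a
Boltzmann function

    G(V) = g_max / (1 + exp((V50 - V) / s))

where ``V50`` is the half-activation potential (also reported as EC50 in
dose-response language) and ``s`` the slope factor in mV.  The reversal
potential defaults to 0 mV for a nonselective cation conductance and points
too close to it are excluded from the conversion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .protocols import StimulusProtocol
from .traces import Recording

__all__ = [
    "IVCurve",
    "BoltzmannFit",
    "ProtocolMismatchError",
    "extract_iv",
    "fit_boltzmann",
]


class ProtocolMismatchError(ValueError):
    """Recording length is inconsistent with the step protocol."""


@dataclass
class IVCurve:
    """Steady-state current per step potential at one bath temperature."""

    voltages: np.ndarray
    steady_currents: np.ndarray
    temperature: float
    cell_id: Optional[str] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.voltages, float)
        if v.size != np.asarray(self.steady_currents).size:
            raise ValueError("one current per voltage required")
        if np.any(np.diff(v) <= 0):
            raise ValueError("voltages must be strictly increasing")

    def __len__(self) -> int:
        return len(self.voltages)


@dataclass
class BoltzmannFit:
    """Boltzmann fit of the conductance-voltage relation.

    ``g_leak`` is the fitted voltage-independent (ohmic) conductance
    offset; oocyte recordings always carry some leak, and leaving it out
    of the model biases ``v50`` whenever the channel conductance is not
    much larger than the leak.
    """

    v50: float
    slope_factor: float
    g_max: float
    e_rev: float
    rss: float
    converged: bool
    voltage_dependent: bool
    g_leak: float = 0.0
    v50_se: Optional[float] = None
    n_points: int = 0


def extract_iv(
    rec: Recording,
    protocol: StimulusProtocol,
    tail_fraction: float = 0.2,
) -> IVCurve:
    """Extract the I-V curve from a voltage-step recording.

    Episodes are located from the protocol timing (step then tail pulse,
    back to back); the steady-state current of each step is the mean over
    the final ``tail_fraction`` of the test-step portion.  Raises
    :class:`ProtocolMismatchError` when the sample count does not match the
    protocol.
    """
    if not 0 < tail_fraction <= 1:
        raise ValueError("tail_fraction must lie in (0, 1]")
    fs = rec.sample_rate
    n_step = int(round(protocol.step_duration * fs))
    n_tail = int(round(protocol.tail_duration * fs))
    ep_len = n_step + n_tail
    n_ep = protocol.n_steps
    if len(rec) != ep_len * n_ep:
        raise ProtocolMismatchError(
            f"recording has {len(rec)} samples; protocol implies "
            f"{n_ep} episodes x {ep_len} samples"
        )
    n_avg = max(1, int(round(tail_fraction * n_step)))
    currents = np.empty(n_ep)
    for i in range(n_ep):
        start = i * ep_len
        window = rec.current[start + n_step - n_avg : start + n_step]
        currents[i] = window.mean()
    return IVCurve(
        voltages=np.asarray(protocol.step_voltages, float),
        steady_currents=currents,
        temperature=float(np.mean(rec.temperature)),
        cell_id=str(rec.metadata.get("cell_id", "")) or None,
    )


def _boltzmann(v, g_max, v50, slope, g_leak=0.0):
    return g_leak + g_max / (1.0 + np.exp((v50 - v) / slope))


def fit_boltzmann(
    iv: IVCurve,
    e_rev: float = 0.0,
    *,
    fit_offset: bool = True,
    exclusion_mV: float = 5.0,
    bootstrap_reps: int = 0,
    seed: Optional[int] = None,
) -> BoltzmannFit:
    """Fit ``G = g_leak + g_max / (1 + exp((V50 - V)/s))`` to the G-V relation.

    Conductances are ``I / (V - e_rev)`` excluding points within
    ``exclusion_mV`` of the reversal potential.  The constant ``g_leak``
    term absorbs the ohmic leak conductance every oocyte recording carries
    (set ``fit_offset=False`` for the bare sigmoid).  The fit is bounded
    nonlinear least squares started from a deterministic grid of
    (V50, slope) values; ``converged`` is False when no start converges.
    ``voltage_dependent`` is False when the fitted sigmoid barely moves
    across the tested voltage span (e.g. a purely ohmic leak).  An optional
    seeded bootstrap over points gives a V50 standard error.
    """
    V = np.asarray(iv.voltages, float)
    I = np.asarray(iv.steady_currents, float)
    keep = np.abs(V - e_rev) >= exclusion_mV
    V, I = V[keep], I[keep]
    if V.size < 6:
        raise ValueError("at least 6 usable points are required")
    G = I / (V - e_rev)

    span = V.max() - V.min()
    starts = [
        (v50, s)
        for v50 in np.linspace(V.min(), V.max(), 5)
        for s in (5.0, 15.0, 30.0)
    ]
    g_scale = max(abs(G).max(), 1e-12)
    lo = [0.0, V.min() - 2 * span, 0.5]
    hi = [10 * g_scale + 1e-9, V.max() + 2 * span, 300.0]
    if fit_offset:
        lo.append(-g_scale)
        hi.append(10 * g_scale + 1e-9)
    bounds = (lo, hi)

    best = None
    for v50_0, s_0 in starts:
        g0 = np.clip(2 * np.median(np.abs(G)), 1e-9, hi[0])
        x0 = [g0, v50_0, s_0] + ([float(np.min(np.abs(G)))] if fit_offset else [])
        try:
            res = least_squares(
                lambda p: _boltzmann(V, *p) - G,
                x0=x0,
                bounds=bounds,
                method="trf",
            )
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        return BoltzmannFit(
            v50=np.nan,
            slope_factor=np.nan,
            g_max=np.nan,
            e_rev=e_rev,
            rss=np.nan,
            converged=False,
            voltage_dependent=False,
            n_points=int(V.size),
        )
    g_max, v50, slope = best.x[:3]
    g_leak = float(best.x[3]) if fit_offset else 0.0
    rss = float(2 * best.cost)
    pv_lo = 1.0 / (1.0 + np.exp((v50 - V.min()) / slope))
    pv_hi = 1.0 / (1.0 + np.exp((v50 - V.max()) / slope))
    voltage_dependent = bool((pv_hi - pv_lo) > 0.3 and g_max > 1e-9)

    v50_se = None
    if bootstrap_reps > 0:
        rng = np.random.default_rng(seed)
        draws = []
        idx_all = np.arange(V.size)
        for _ in range(bootstrap_reps):
            idx = np.sort(rng.choice(idx_all, size=V.size, replace=True))
            vv, gg = V[idx], G[idx]
            x0 = list(best.x)
            try:
                res = least_squares(
                    lambda p: _boltzmann(vv, *p) - gg,
                    x0=x0,
                    bounds=bounds,
                    method="trf",
                )
            except Exception:
                continue
            if res.success:
                draws.append(res.x[1])
        if len(draws) > 1:
            v50_se = float(np.std(draws, ddof=1))

    return BoltzmannFit(
        v50=float(v50),
        slope_factor=float(slope),
        g_max=float(g_max),
        e_rev=e_rev,
        rss=rss,
        converged=True,
        voltage_dependent=voltage_dependent,
        g_leak=g_leak,
        v50_se=v50_se,
        n_points=int(V.size),
    )
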
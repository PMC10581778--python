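"""Diagnostic figures: van't Hoff curves with fitted segments, and G-V fits."""

from __future__ import annotations

import numpy as np

from .iv import BoltzmannFit, IVCurve
from .vanthoff import SegmentedVantHoffFit, VantHoffCurve

__all__ = ["plot_vanthoff", "plot_gv"]


def plot_vanthoff(curve: VantHoffCurve, fit: SegmentedVantHoffFit | None = None, ax=None):
    """Scatter the van't Hoff curve and overlay the segmented fit."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve.inv_T, curve.log_abs_I, ".", ms=2, alpha=0.5, label="data")
    if fit is not None:
        xs = np.linspace(fit.inv_T_min, fit.inv_T_max, 400)
        ax.plot(xs, fit.predict(xs), "r-", lw=1.5,
                label=f"{fit.n_breakpoints}-breakpoint fit")
        for bp in fit.breakpoints:
            ax.axvline(bp, color="k", ls=":", lw=0.8)
    ax.set_xlabel("1 / T  (K$^{-1}$)")
    ax.set_ylabel("log |I|")
    if curve.cell_id:
        ax.set_title(f"{curve.cell_id} activation {curve.activation_index}")
    ax.legend(frameon=False)
    return ax


def plot_gv(iv: IVCurve, fit: BoltzmannFit | None = None, ax=None):
    """Conductance-voltage relation with the Boltzmann fit."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    e_rev = fit.e_rev if fit is not None else 0.0
    keep = np.abs(iv.voltages - e_rev) >= 5.0
    G = iv.steady_currents[keep] / (iv.voltages[keep] - e_rev)
    ax.plot(iv.voltages[keep], G, "o", label="data")
    if fit is not None and fit.converged:
        vs = np.linspace(iv.voltages.min(), iv.voltages.max(), 200)
        ax.plot(vs, fit.g_max / (1 + np.exp((fit.v50 - vs) / fit.slope_factor)),
                "r-", label=f"V50 = {fit.v50:.1f} mV")
    ax.set_xlabel("V (mV)")
    ax.set_ylabel("G (µS)")
    ax.legend(frameon=False)
    return ax
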
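"""Calibrated study-condition generator settings.

Each function returns a ``(CellPopulationSpec, StimulusProtocol)`` pair (or
a bath temperature as well, for voltage-step conditions) whose parameters
are the published control or treatment estimates for the two Antarctic
notothenioid channels characterized by oocyte voltage clamp:

* ``trpa1b_control`` — dragonfish TRPA1b under control conditions:
  activation Q10 11.09 above a 22.91 °C threshold, baseline Q10 1.59, a
  saturation breakpoint at 34.46 °C with supra-breakpoint Q10 3.26
  (12 cells).
* ``trpv1a_control`` — *Notothenia coriiceps* TRPV1a: first-activation Q10
  20.48 above a 32.11 °C threshold, baseline Q10 1.43, no saturation
  breakpoint within the tested range, and strong desensitization of the
  activation Q10 on repeated heating (3.95 then 2.70 on activations 2-3)
  (21 cells).
* ``water_control`` — water-injected oocytes: leak only, Q10 1.24
  (9 cells).
* ``mbc_treated`` — cholesterol depletion by methyl-β-cyclodextrin:
  TRPA1b threshold lowered to 15.1 °C (19 cells).
* ``h2o2_treated`` — 1 mM extracellular H2O2: TRPA1b threshold lowered to
  16.97 °C (8 cells).
* ``staurosporine_iv`` / ``control_iv`` — voltage-step conditions for the
  Boltzmann analysis: half-activation at −35.8 mV (staurosporine, 25 °C,
  7 cells) versus −17.22 mV (control, 30 °C).

Published ``±`` dispersions are used as between-cell standard deviations;
measurement noise (2 nA at the 2 kHz acquisition rate) and the reference
current are generator choices documented in the methods note.  The
sub-threshold temperature dependence of the simulated trace (channel
baseline plus endogenous/leak currents, which the voltage clamp cannot
separate) is carried by the channel term's baseline Q10, so the explicit
leak conductance is zero in channel-expressing conditions and nonzero only
for water controls.
"""

from __future__ import annotations

from dataclasses import replace

from .gating import PiecewiseQ10Params, TwoStateParams
from .protocols import StimulusProtocol, default_temp_protocol, default_voltage_protocol
from .simulate import ActivationSchedule, CellPopulationSpec

__all__ = [
    "trpa1b_control",
    "trpv1a_control",
    "water_control",
    "mbc_treated",
    "h2o2_treated",
    "staurosporine_iv",
    "control_iv",
]

# shared acquisition settings
NOISE_SD_NA = 2.0
BETWEEN_CELL_CV = 0.3
I_REF_NA = -25.0
HOLD_TEMP_C = 6.0

TRPA1B = PiecewiseQ10Params(
    i_ref=I_REF_NA,
    t_ref=HOLD_TEMP_C,
    q10_baseline=1.59,
    threshold=22.91,
    q10_activation=11.09,
    second_breakpoint=34.46,
    q10_supra=3.26,
)

TRPV1A = PiecewiseQ10Params(
    i_ref=I_REF_NA,
    t_ref=HOLD_TEMP_C,
    q10_baseline=1.43,
    threshold=32.11,
    q10_activation=20.48,
    second_breakpoint=None,
)

#: Activation-segment Q10 on successive heatings of TRPV1a (desensitization).
TRPV1A_Q10_BY_ACTIVATION = (20.48, 3.95, 2.70, 2.31, 1.92, 1.49, 1.45)


def _protocol(**overrides) -> StimulusProtocol:
    return default_temp_protocol(hold_temp=HOLD_TEMP_C, **overrides)


def trpa1b_control(seed: int = 0, n_cells: int = 12):
    spec = CellPopulationSpec(
        n_cells=n_cells,
        channel_params=TRPA1B,
        between_cell_cv=BETWEEN_CELL_CV,
        threshold_sd_C=1.31,
        noise_sd=NOISE_SD_NA,
        seed=seed,
        condition="control",
        construct="TRPA1b",
        rna_ng=(78.0, 100.0),
    )
    return spec, _protocol()


def trpv1a_control(seed: int = 0, n_cells: int = 21):
    q1 = TRPV1A_Q10_BY_ACTIVATION[0]
    factors = tuple(q / q1 for q in TRPV1A_Q10_BY_ACTIVATION[:3])
    spec = CellPopulationSpec(
        n_cells=n_cells,
        channel_params=TRPV1A,
        between_cell_cv=BETWEEN_CELL_CV,
        threshold_sd_C=0.637,
        schedule=ActivationSchedule(
            q10_factors=factors,
            leak_factors=(1.0, 1.0, 1.0),
            threshold_lost=(False, False, False),
        ),
        noise_sd=NOISE_SD_NA,
        seed=seed,
        condition="control",
        construct="TRPV1a",
        rna_ng=(21.0, 100.0),
    )
    return spec, _protocol()


def water_control(seed: int = 0, n_cells: int = 9):
    spec = CellPopulationSpec(
        n_cells=n_cells,
        channel_params=None,
        between_cell_cv=BETWEEN_CELL_CV,
        leak_g=0.5,  # µS: ~-30 nA at the -60 mV hold
        leak_q10=1.24,
        leak_t_ref=HOLD_TEMP_C,
        noise_sd=NOISE_SD_NA,
        seed=seed,
        condition="water",
        construct="",
    )
    return spec, _protocol()


def mbc_treated(seed: int = 0, n_cells: int = 19):
    spec, proto = trpa1b_control(seed=seed, n_cells=n_cells)
    spec = replace(
        spec,
        channel_params=replace(TRPA1B, threshold=15.1),
        threshold_sd_C=1.41,
        condition="MBC",
    )
    return spec, proto


def h2o2_treated(seed: int = 0, n_cells: int = 8):
    spec, proto = trpa1b_control(seed=seed, n_cells=n_cells)
    spec = replace(
        spec,
        channel_params=replace(TRPA1B, threshold=16.97),
        threshold_sd_C=1.92,
        condition="H2O2_1mM",
    )
    return spec, proto


# --- voltage-step conditions -------------------------------------------------

# Two-state gating with its midpoint at the saturation breakpoint region
# (~35 °C) and a large opening enthalpy, so Po rises steeply with heat.
_DELTA_H = 200_000.0  # J/mol
_T_MID_K = 273.15 + 35.0

TRPA1B_IV_CONTROL = TwoStateParams(
    delta_h=_DELTA_H,
    delta_s=_DELTA_H / _T_MID_K,
    g_max=10.0,  # µS
    e_rev=0.0,
    v50=-17.22,
    v_slope=15.0,
)

TRPA1B_IV_STAUROSPORINE = replace(TRPA1B_IV_CONTROL, v50=-35.8)


def _iv_spec(params, condition, seed, n_cells):
    return CellPopulationSpec(
        n_cells=n_cells,
        channel_params=params,
        between_cell_cv=BETWEEN_CELL_CV,
        leak_g=0.05,
        leak_q10=1.24,
        leak_t_ref=HOLD_TEMP_C,
        noise_sd=NOISE_SD_NA,
        seed=seed,
        condition=condition,
        construct="TRPA1b",
    )


def control_iv(seed: int = 0, n_cells: int = 7):
    """Control I-V condition; bath temperature 30 °C."""
    return _iv_spec(TRPA1B_IV_CONTROL, "control", seed, n_cells), default_voltage_protocol(), 30.0


def staurosporine_iv(seed: int = 0, n_cells: int = 7):
    """Staurosporine I-V condition; bath temperature 25 °C."""
    return (
        _iv_spec(TRPA1B_IV_STAUROSPORINE, "staurosporine", seed, n_cells),
        default_voltage_protocol(),
        25.0,
    )
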
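"""Synthetic two-electrode voltage-clamp recordings with known ground truth.

The generator emulates oocyte temperature-activation experiments: repeated
heating cycles from a cool hold to ~40 °C while clamped at −60 mV, a
heat-activated channel current (piecewise-Q10 or two-state), a
temperature-dependent ohmic leak, per-activation
sensitization/desensitization schedules, between-cell parameter variation,
and gaussian measurement noise.  Every recording carries a ``truth`` sidecar
with the realized per-cell parameters so downstream fits can be scored by
parameter recovery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

from .gating import (
    ChannelParams,
    PiecewiseQ10Params,
    TwoStateParams,
    current_piecewise,
    current_two_state,
)
from .protocols import (
    InvalidProtocolError,
    StimulusProtocol,
    make_temperature_protocol,
    temperature_cycle_ids,
)
from .traces import Recording

__all__ = [
    "ActivationSchedule",
    "CellPopulationSpec",
    "SimulatedRecording",
    "ConfigurationError",
    "simulate_cell_population",
    "simulate_voltage_steps",
]


class ConfigurationError(ValueError):
    """Raised when a population spec is inconsistent with its protocol."""


@dataclass(frozen=True)
class ActivationSchedule:
    """Per-activation multiplicative modifiers.

    ``q10_factors[k]`` scales the activation-segment Q10 on activation
    ``k+1`` (desensitization when < 1), ``leak_factors[k]`` scales the leak
    conductance (run-up when > 1), and ``threshold_lost[k]`` marks
    activations on which the channel no longer shows a distinct threshold
    (already open at the hold temperature): the activation-band Q10 then
    applies from the reference temperature upward.
    """

    q10_factors: Sequence[float] = (1.0, 1.0, 1.0)
    leak_factors: Sequence[float] = (1.0, 1.0, 1.0)
    threshold_lost: Sequence[bool] = (False, False, False)

    def __len__(self) -> int:
        return min(len(self.q10_factors), len(self.leak_factors), len(self.threshold_lost))

    @staticmethod
    def flat(n: int) -> "ActivationSchedule":
        return ActivationSchedule((1.0,) * n, (1.0,) * n, (False,) * n)


@dataclass(frozen=True)
class CellPopulationSpec:
    """Generator truth for a population of cells under one condition.

    ``between_cell_cv`` is a fractional coefficient of variation applied as
    a lognormal scale factor to magnitude-type parameters (reference current
    / maximal conductance); ``threshold_sd_C`` is a normal SD applied to the
    activation threshold in °C (piecewise model only).  ``leak_g`` (µS) is
    an ohmic leak with temperature coefficient ``leak_q10`` referenced to
    ``leak_t_ref`` °C and reversal ``leak_e_rev`` mV.  ``noise_sd`` is the
    per-sample gaussian current noise (nA) at the synthesis rate.
    ``rna_ng`` may be a scalar or a ``(lo, hi)`` range sampled uniformly per
    cell.
    """

    n_cells: int
    channel_params: Optional[ChannelParams]
    between_cell_cv: float = 0.0
    threshold_sd_C: float = 0.0
    leak_g: float = 0.0
    leak_q10: float = 1.24
    leak_e_rev: float = 0.0
    leak_t_ref: float = 6.0
    schedule: ActivationSchedule = field(default_factory=lambda: ActivationSchedule.flat(3))
    noise_sd: float = 0.0
    seed: int = 0
    condition: str = "control"
    construct: str = ""
    rna_ng: Union[float, tuple, None] = None

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ConfigurationError("n_cells must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.between_cell_cv < 0 or self.threshold_sd_C < 0:
            raise ConfigurationError("between-cell variation must be >= 0")


@dataclass
class SimulatedRecording:
    """A synthetic recording plus the realized parameters that produced it."""

    recording: Recording
    truth: dict


def _cell_rng(spec: CellPopulationSpec, cell_index: int) -> np.random.Generator:
    # deterministic per-cell substream: master seed plus cell index
    return np.random.default_rng(int(spec.seed) + cell_index)


def _realize_cell(spec: CellPopulationSpec, cell_index: int, rng: np.random.Generator) -> dict:
    """Draw one cell's realized parameters (lognormal magnitudes, normal threshold)."""
    truth: dict = {"cell_index": cell_index}
    cv = spec.between_cell_cv
    if cv > 0:
        sigma = float(np.sqrt(np.log1p(cv**2)))
        scale = float(rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))
    else:
        scale = 1.0
    truth["magnitude_scale"] = scale
    params = spec.channel_params
    if isinstance(params, PiecewiseQ10Params):
        thr = params.threshold
        if spec.threshold_sd_C > 0:
            thr = float(rng.normal(params.threshold, spec.threshold_sd_C))
        bp2 = params.second_breakpoint
        if bp2 is not None and thr >= bp2:
            thr = bp2 - 0.5  # keep the bands ordered for extreme draws
        params = replace(params, i_ref=params.i_ref * scale, threshold=thr)
    elif isinstance(params, TwoStateParams):
        params = replace(params, g_max=params.g_max * scale)
    truth["channel_params"] = dataclasses.asdict(params) if params is not None else None
    if isinstance(spec.rna_ng, tuple):
        truth["rna_ng"] = float(rng.uniform(*spec.rna_ng))
    elif spec.rna_ng is not None:
        truth["rna_ng"] = float(spec.rna_ng)
    else:
        truth["rna_ng"] = None
    truth["_params"] = params
    return truth


def _leak_current(spec: CellPopulationSpec, temp: np.ndarray, voltage, factor: float) -> np.ndarray:
    if spec.leak_g == 0:
        return np.zeros_like(temp)
    g = spec.leak_g * factor * spec.leak_q10 ** ((temp - spec.leak_t_ref) / 10.0)
    return g * (np.asarray(voltage, float) - spec.leak_e_rev)


def _channel_current_cycle(
    params: Optional[ChannelParams],
    temp: np.ndarray,
    hold_voltage: float,
    q10_factor: float,
    threshold_lost: bool,
) -> np.ndarray:
    if params is None:
        return np.zeros_like(temp)
    if isinstance(params, PiecewiseQ10Params):
        p = params
        if q10_factor != 1.0:
            q10 = max(1.0, p.q10_activation * q10_factor)
            p = replace(p, q10_activation=q10)
        if threshold_lost:
            # channels already open at the hold: the activation-band Q10
            # applies from the reference temperature, continuous at i_ref
            thr = p.t_ref
            bp2 = p.second_breakpoint
            if bp2 is not None and thr >= bp2:
                bp2 = thr + 0.5
            p = replace(p, threshold=thr, second_breakpoint=bp2)
        return np.asarray(current_piecewise(temp, p))
    return np.asarray(current_two_state(temp, hold_voltage, params))


def simulate_cell_population(
    spec: CellPopulationSpec, protocol: StimulusProtocol
) -> list[SimulatedRecording]:
    """Simulate ``spec.n_cells`` recordings under a temperature protocol.

    Per sample, the current is the channel current at the instantaneous
    temperature (and holding potential), modified by the per-activation
    schedule for the cycle the sample falls in, plus the temperature-
    dependent leak and gaussian noise.  Identical spec and seed give
    bit-identical output.
    """
    if protocol.kind not in ("temp_cycles", "subzero_probe"):
        raise InvalidProtocolError("temperature protocol required")
    n_cycles = protocol.n_cycles if protocol.kind == "temp_cycles" else 3
    if len(spec.schedule) < n_cycles:
        raise ConfigurationError(
            f"activation schedule covers {len(spec.schedule)} cycles, "
            f"protocol has {n_cycles}"
        )
    time, temp = make_temperature_protocol(protocol)
    cycle_ids = temperature_cycle_ids(protocol, temp.size)
    out: list[SimulatedRecording] = []
    for i in range(spec.n_cells):
        rng = _cell_rng(spec, i)
        truth = _realize_cell(spec, i, rng)
        params = truth.pop("_params")
        current = np.zeros_like(temp)
        for c in range(int(cycle_ids.max()) + 1):
            mask = cycle_ids == c
            current[mask] = _channel_current_cycle(
                params,
                temp[mask],
                protocol.hold_voltage,
                spec.schedule.q10_factors[c],
                bool(spec.schedule.threshold_lost[c]),
            )
            current[mask] += _leak_current(
                spec, temp[mask], protocol.hold_voltage, spec.schedule.leak_factors[c]
            )
        if spec.noise_sd > 0:
            current = current + rng.normal(0.0, spec.noise_sd, size=current.size)
        cell_id = f"{spec.condition}_{i:03d}"
        metadata = {
            "cell_id": cell_id,
            "construct": spec.construct,
            "condition": spec.condition,
        }
        if truth["rna_ng"] is not None:
            metadata["rna_ng"] = truth["rna_ng"]
        rec = Recording(
            time=time.copy(),
            temperature=temp.copy(),
            current=current,
            voltage=np.full_like(temp, protocol.hold_voltage),
            sample_rate=protocol.sample_rate,
            metadata=metadata,
        )
        truth["cell_id"] = cell_id
        truth["spec"] = {
            k: v
            for k, v in dataclasses.asdict(spec).items()
            if k != "channel_params"
        }
        out.append(SimulatedRecording(recording=rec, truth=truth))
    return out


def simulate_voltage_steps(
    spec: CellPopulationSpec, protocol: StimulusProtocol, T: float
) -> list[SimulatedRecording]:
    """Simulate voltage-step recordings at a fixed bath temperature ``T`` °C.

    Episodes (test step then tail pulse) are concatenated back to back; the
    channel current follows the two-state model at the commanded potential
    (steady state; capacitive transients are out of scope).  Requires
    channel params with voltage dependence.
    """
    if protocol.kind != "voltage_steps":
        raise InvalidProtocolError("voltage_steps protocol required")
    params = spec.channel_params
    if not isinstance(params, TwoStateParams) or params.v50 is None:
        raise ConfigurationError(
            "voltage-step simulation requires TwoStateParams with v50/v_slope"
        )
    fs = protocol.sample_rate
    n_step = int(round(protocol.step_duration * fs))
    n_tail = int(round(protocol.tail_duration * fs))
    volt_ep = []
    for v in protocol.step_voltages:
        volt_ep.append(np.concatenate([np.full(n_step, float(v)), np.full(n_tail, protocol.tail_voltage)]))
    voltage = np.concatenate(volt_ep)
    time = np.arange(voltage.size) / fs
    temp = np.full_like(voltage, float(T))
    out: list[SimulatedRecording] = []
    for i in range(spec.n_cells):
        rng = _cell_rng(spec, i)
        truth = _realize_cell(spec, i, rng)
        p = truth.pop("_params")
        current = np.asarray(current_two_state(float(T), voltage, p))
        current = current + _leak_current(spec, temp, voltage, 1.0)
        if spec.noise_sd > 0:
            current = current + rng.normal(0.0, spec.noise_sd, size=current.size)
        cell_id = f"{spec.condition}_iv_{i:03d}"
        rec = Recording(
            time=time.copy(),
            temperature=temp.copy(),
            current=current,
            voltage=voltage.copy(),
            sample_rate=fs,
            metadata={
                "cell_id": cell_id,
                "construct": spec.construct,
                "condition": spec.condition,
                "bath_temp_C": float(T),
            },
        )
        truth["cell_id"] = cell_id
        out.append(SimulatedRecording(recording=rec, truth=truth))
    return out
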
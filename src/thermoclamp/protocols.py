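"""Stimulus protocols for temperature-clamp and voltage-step experiments.

Two families of stimulus are modelled:

* ``temp_cycles`` — repeated triangular heating/cooling excursions from a cool
  holding temperature (typically 5-9 °C) to a peak near 40 °C, each cycle
  lasting about a minute, as used to probe heat activation of TRP channels
  expressed in oocytes.
* ``voltage_steps`` — a family of 100 ms voltage steps (−90 to +40 mV in
  10 mV increments) followed by a fixed tail pulse, used to measure
  current-voltage relationships at a fixed bath temperature.
* ``subzero_probe`` — a near-freezing variant: the bath is held at 0-1 °C, a
  5 °C solution is applied for 10-20 s, and expression is then verified with
  two ordinary heating cycles.

The exact ramp shape of the heating hardware is not modelled; cycles are
piecewise-linear (triangle) ramps with a configurable hold plateau.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "StimulusProtocol",
    "InvalidProtocolError",
    "make_temperature_protocol",
    "temperature_waveform",
    "default_temp_protocol",
    "default_voltage_protocol",
]


class InvalidProtocolError(ValueError):
    """Raised when a stimulus protocol is internally inconsistent."""


@dataclass(frozen=True)
class StimulusProtocol:
    """Declarative description of one stimulus protocol.

    Parameters
    ----------
    kind:
        ``"temp_cycles"``, ``"voltage_steps"`` or ``"subzero_probe"``.
    hold_temp:
        Holding (baseline) bath temperature, °C.
    peak_temp:
        Peak temperature of each heating excursion, °C.
    n_cycles:
        Number of heating/cooling cycles.
    cycle_duration:
        Duration of one full cycle, s (hold plateau + up ramp + down ramp).
    sample_rate:
        Acquisition rate, Hz.
    hold_fraction:
        Fraction of each cycle spent on the hold plateau before the up ramp;
        the remainder is split equally between up and down ramps.
    hold_voltage:
        Command potential during temperature protocols, mV.
    step_voltages:
        Strictly increasing step potentials for ``voltage_steps``, mV.
    step_duration / tail_duration:
        Durations of the test step and the tail pulse, s.
    tail_voltage:
        Tail-pulse potential, mV.
    excursion_temp / excursion_duration:
        For ``subzero_probe``: temperature and duration of the warm-solution
        application from the near-freezing hold.
    """

    kind: str = "temp_cycles"
    hold_temp: float = 6.0
    peak_temp: float = 40.0
    n_cycles: int = 3
    cycle_duration: float = 60.0
    sample_rate: float = 2000.0
    hold_fraction: float = 1.0 / 6.0
    hold_voltage: float = -60.0
    step_voltages: Sequence[float] = field(
        default_factory=lambda: tuple(np.arange(-90.0, 41.0, 10.0))
    )
    step_duration: float = 0.100
    tail_duration: float = 0.100
    tail_voltage: float = -50.0
    excursion_temp: float = 5.0
    excursion_duration: float = 15.0

    def __post_init__(self) -> None:
        if self.kind not in ("temp_cycles", "voltage_steps", "subzero_probe"):
            raise InvalidProtocolError(f"unknown protocol kind {self.kind!r}")
        if self.sample_rate <= 0:
            raise InvalidProtocolError("sample_rate must be positive")
        if self.kind in ("temp_cycles", "subzero_probe"):
            if self.n_cycles < 1:
                raise InvalidProtocolError("n_cycles must be >= 1")
            if self.cycle_duration <= 0:
                raise InvalidProtocolError("cycle_duration must be positive")
            if self.peak_temp <= self.hold_temp:
                raise InvalidProtocolError("peak_temp must exceed hold_temp")
            if not 0.0 <= self.hold_fraction < 1.0:
                raise InvalidProtocolError("hold_fraction must lie in [0, 1)")
        if self.kind == "subzero_probe" and self.excursion_duration <= 0:
            raise InvalidProtocolError("excursion_duration must be positive")
        if self.kind == "voltage_steps":
            v = np.asarray(self.step_voltages, float)
            if v.size < 2 or np.any(np.diff(v) <= 0):
                raise InvalidProtocolError("step_voltages must be strictly increasing")
            if self.step_duration <= 0 or self.tail_duration <= 0:
                raise InvalidProtocolError("step durations must be positive")

    @property
    def n_steps(self) -> int:
        return len(self.step_voltages)


def _triangle_cycle(proto: StimulusProtocol, n_samp: int) -> np.ndarray:
    """Temperature waveform of one hold+up+down cycle, ``n_samp`` samples."""
    t = np.arange(n_samp) / proto.sample_rate
    hold_t = proto.hold_fraction * proto.cycle_duration
    ramp_t = 0.5 * (proto.cycle_duration - hold_t)
    temp = np.full(n_samp, proto.hold_temp, float)
    up = (t >= hold_t) & (t < hold_t + ramp_t)
    down = t >= hold_t + ramp_t
    span = proto.peak_temp - proto.hold_temp
    temp[up] = proto.hold_temp + span * (t[up] - hold_t) / ramp_t
    temp[down] = proto.peak_temp - span * (t[down] - hold_t - ramp_t) / ramp_t
    return temp


def make_temperature_protocol(proto: StimulusProtocol) -> tuple[np.ndarray, np.ndarray]:
    """Build the programmed temperature waveform for a protocol.

    Returns ``(time_s, temp_C)``.  For ``temp_cycles`` the waveform is
    ``n_cycles`` consecutive triangle cycles starting and ending at
    ``hold_temp`` and reaching ``peak_temp`` once per cycle.  For
    ``subzero_probe`` it is an initial hold at ``hold_temp`` (0-1 °C),
    a triangular excursion to ``excursion_temp`` lasting
    ``excursion_duration``, a return hold, and two verification cycles to
    ``peak_temp``.
    """
    if proto.kind == "voltage_steps":
        raise InvalidProtocolError("voltage_steps protocols carry no temperature ramp")
    fs = proto.sample_rate
    if proto.kind == "temp_cycles":
        per = int(round(proto.cycle_duration * fs))
        if per < 4:
            raise InvalidProtocolError("cycle too short for the sample rate")
        one = _triangle_cycle(proto, per)
        temp = np.tile(one, proto.n_cycles)
    else:  # subzero_probe
        hold_n = int(round(10.0 * fs))
        exc_n = int(round(proto.excursion_duration * fs))
        t_exc = np.arange(exc_n) / fs
        half = proto.excursion_duration / 2.0
        exc = np.where(
            t_exc < half,
            proto.hold_temp + (proto.excursion_temp - proto.hold_temp) * t_exc / half,
            proto.excursion_temp
            - (proto.excursion_temp - proto.hold_temp) * (t_exc - half) / half,
        )
        verify = StimulusProtocol(
            kind="temp_cycles",
            hold_temp=5.0,
            peak_temp=proto.peak_temp,
            n_cycles=2,
            cycle_duration=proto.cycle_duration,
            sample_rate=fs,
            hold_fraction=proto.hold_fraction,
        )
        _, vwave = make_temperature_protocol(verify)
        temp = np.concatenate(
            [np.full(hold_n, proto.hold_temp), exc, np.full(hold_n, proto.hold_temp), vwave]
        )
    time = np.arange(temp.size) / fs
    return time, temp


def temperature_cycle_ids(proto: StimulusProtocol, n_samples: int) -> np.ndarray:
    """0-based heating-cycle index for each sample of a temp_cycles waveform.

    For ``subzero_probe`` the excursion and the two verification cycles are
    numbered 0, 1, 2 in order of occurrence.
    """
    fs = proto.sample_rate
    if proto.kind == "temp_cycles":
        per = int(round(proto.cycle_duration * fs))
        ids = np.minimum(np.arange(n_samples) // per, proto.n_cycles - 1)
        return ids.astype(int)
    if proto.kind == "subzero_probe":
        hold_n = int(round(10.0 * fs))
        exc_n = int(round(proto.excursion_duration * fs))
        per = int(round(proto.cycle_duration * fs))
        ids = np.zeros(n_samples, int)
        start_verify = hold_n + exc_n + hold_n
        rel = np.arange(n_samples) - start_verify
        in_verify = rel >= 0
        ids[in_verify] = 1 + np.minimum(rel[in_verify] // per, 1)
        return ids
    raise InvalidProtocolError("cycle ids are defined for temperature protocols only")


# convenience synonym used throughout the docs
temperature_waveform = make_temperature_protocol


def default_temp_protocol(**overrides) -> StimulusProtocol:
    """The standard heating protocol: 3 x 60 s cycles, 6 -> 40 °C, 2 kHz."""
    return StimulusProtocol(**{"kind": "temp_cycles", **overrides})


def default_voltage_protocol(**overrides) -> StimulusProtocol:
    """The standard I-V protocol: -90..+40 mV in 10 mV steps, 100 ms + tail."""
    return StimulusProtocol(**{"kind": "voltage_steps", **overrides})
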
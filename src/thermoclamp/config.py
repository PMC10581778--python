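"""TOML run configuration for the command-line workflow.

A run config has ``[protocol]``, ``[channel]``, ``[population]``,
``[schedule]``, ``[analysis]`` and ``[stats]`` tables.  Example::

    [protocol]
    kind = "temp_cycles"
    hold_temp = 6.0
    peak_temp = 40.0
    n_cycles = 3
    cycle_duration = 60.0
    sample_rate = 2000.0

    [channel]
    model = "piecewise"            # or "two_state", or "none" (leak only)
    i_ref = -25.0
    t_ref = 6.0
    q10_baseline = 1.59
    threshold = 22.91
    q10_activation = 11.09
    second_breakpoint = 34.46      # omit for a single-breakpoint channel
    q10_supra = 3.26

    [population]
    n_cells = 12
    between_cell_cv = 0.3
    threshold_sd_C = 1.31
    noise_sd = 2.0
    seed = 1
    condition = "control"

    [schedule]
    q10_factors = [1.0, 1.0, 1.0]
    leak_factors = [1.0, 1.0, 1.0]
    threshold_lost = [false, false, false]

    [analysis]
    downsample_to = 100.0
    q10_floor = 3.0

    [stats]
    alpha = 0.05

Schema violations raise :class:`ConfigError` naming the offending field.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path

from .gating import PiecewiseQ10Params, TwoStateParams
from .pipeline import AnalysisOptions
from .protocols import StimulusProtocol
from .simulate import ActivationSchedule, CellPopulationSpec

__all__ = ["ConfigError", "RunConfig", "load_config"]


class ConfigError(ValueError):
    """A run configuration failed schema validation."""


@dataclass
class RunConfig:
    protocol: StimulusProtocol
    population: CellPopulationSpec
    analysis: AnalysisOptions
    alpha: float = 0.05
    bath_temp_C: float = 25.0
    raw: dict = field(default_factory=dict)


def _build(cls, section: dict, name: str, **extra):
    allowed = {f.name for f in fields(cls)}
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"[{name}]: unknown fields {sorted(unknown)}")
    try:
        return cls(**{**section, **extra})
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"[{name}]: {exc}") from exc


def _build_channel(section: dict):
    model = section.get("model", "piecewise")
    params = {k: v for k, v in section.items() if k != "model"}
    if model == "none":
        if params:
            raise ConfigError("[channel]: model 'none' takes no parameters")
        return None
    if model == "piecewise":
        return _build(PiecewiseQ10Params, params, "channel")
    if model == "two_state":
        return _build(TwoStateParams, params, "channel")
    raise ConfigError(f"[channel]: unknown model {model!r}")


def load_config(path) -> RunConfig:
    """Load and validate a TOML run configuration."""
    path = Path(path)
    with path.open("rb") as fh:
        raw = tomllib.load(fh)
    proto_sec = dict(raw.get("protocol", {}))
    if "step_voltages" in proto_sec:
        proto_sec["step_voltages"] = tuple(float(v) for v in proto_sec["step_voltages"])
    try:
        protocol = _build(StimulusProtocol, proto_sec, "protocol")
    except ConfigError:
        raise
    except ValueError as exc:
        raise ConfigError(f"[protocol]: {exc}") from exc

    channel = _build_channel(dict(raw.get("channel", {})))

    sched_sec = dict(raw.get("schedule", {}))
    if sched_sec:
        schedule = _build(ActivationSchedule, sched_sec, "schedule")
    else:
        n = protocol.n_cycles if protocol.kind != "voltage_steps" else 1
        schedule = ActivationSchedule.flat(max(n, 3))

    pop_sec = dict(raw.get("population", {}))
    if "rna_ng" in pop_sec and isinstance(pop_sec["rna_ng"], list):
        pop_sec["rna_ng"] = tuple(pop_sec["rna_ng"])
    population = _build(
        CellPopulationSpec, pop_sec, "population",
        channel_params=channel, schedule=schedule,
    )

    analysis = _build(AnalysisOptions, dict(raw.get("analysis", {})), "analysis")

    stats_sec = dict(raw.get("stats", {}))
    alpha = float(stats_sec.get("alpha", 0.05))
    if not 0 < alpha < 1:
        raise ConfigError("[stats]: alpha must lie in (0, 1)")

    bath = float(raw.get("bath_temp_C", 25.0))
    return RunConfig(
        protocol=protocol,
        population=population,
        analysis=analysis,
        alpha=alpha,
        bath_temp_C=bath,
        raw=raw,
    )
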
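"""Shared fixtures: small noiseless and noisy synthetic recordings."""

from __future__ import annotations

import pytest

from thermoclamp import scenarios
from thermoclamp.protocols import default_temp_protocol
from thermoclamp.simulate import CellPopulationSpec, simulate_cell_population
from thermoclamp.traces import segment_activations


@pytest.fixture(scope="session")
def small_protocol():
    """One 30 s heating cycle, 6 -> 40 degC, 100 Hz (no downsampling needed)."""
    return default_temp_protocol(n_cycles=1, cycle_duration=30.0, sample_rate=100.0)


@pytest.fixture(scope="session")
def noiseless_trpa1b_segment(small_protocol):
    """A single noiseless, zero-variance TRPA1b-like heating segment."""
    spec = CellPopulationSpec(
        n_cells=1,
        channel_params=scenarios.TRPA1B,
        between_cell_cv=0.0,
        threshold_sd_C=0.0,
        noise_sd=0.0,
        seed=0,
    )
    rec = simulate_cell_population(spec, small_protocol)[0].recording
    (seg,) = segment_activations(rec)
    return seg


@pytest.fixture(scope="session")
def noisy_trpa1b_recordings():
    """Three noisy TRPA1b-like cells at the full 2 kHz acquisition rate."""
    spec, proto = scenarios.trpa1b_control(seed=42, n_cells=3)
    return [s.recording for s in simulate_cell_population(spec, proto)], proto
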
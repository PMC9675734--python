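"""Synthetic telegraph-noise blink traces.

A two-state continuous-time Markov chain (exponential dwell times in both
states) is simulated event-driven and then rasterized onto a uniform time
grid, which preserves exact dwell statistics.  The in-blink current level
sits ``G * G0 * V_bias`` above the baseline; Gaussian read noise is added
per sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ..constants import blink_amplitude_nA
from ..datatypes import CurrentTrace
from ..exceptions import ConfigurationError


@dataclass
class BlinkGenConfig:
    baseline_current: float = 0.33  # nA
    blink_conductance: float = 4.3e-6  # multiples of G0
    bias_voltage: float = 0.8  # V
    mean_blink_lifetime: float = 0.05  # s
    mean_interblink_time: float = 0.25  # s (np.inf -> no blinks)
    sampling_rate: float = 10_000.0  # Hz
    trace_duration: float = 10.0  # s
    noise_sd: float = 0.01  # nA
    seed: int | None = None

    def __post_init__(self):
        if self.mean_blink_lifetime <= 0 or self.mean_interblink_time <= 0:
            raise ConfigurationError("dwell-time means must be positive")
        if self.sampling_rate <= 0 or self.trace_duration <= 0:
            raise ConfigurationError("sampling rate and duration must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise s.d. must be non-negative")
        if self.blink_conductance < 0:
            raise ConfigurationError("blink conductance must be non-negative")
        if self.sampling_rate * self.mean_blink_lifetime < 10:
            warnings.warn(
                "fewer than 10 samples per mean blink lifetime: blinks will "
                "be poorly resolved",
                stacklevel=2,
            )


def gen_blink_trace(config: BlinkGenConfig) -> CurrentTrace:
    """Simulate one feedback-off current-time trace with telegraph blinks.

    The ground-truth event list (onset, lifetime) and the ideal blink
    amplitude are stored in ``trace.metadata``.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.trace_duration * config.sampling_rate))
    t = np.arange(n) / config.sampling_rate
    amplitude = blink_amplitude_nA(config.blink_conductance, config.bias_voltage)

    events: list[tuple[float, float]] = []
    state_on = np.zeros(n, dtype=bool)
    clock = 0.0
    while clock < config.trace_duration:
        if not np.isfinite(config.mean_interblink_time):
            break
        clock += rng.exponential(config.mean_interblink_time)
        if clock >= config.trace_duration:
            break
        lifetime = rng.exponential(config.mean_blink_lifetime)
        onset = clock
        end = min(onset + lifetime, config.trace_duration)
        i0 = int(np.ceil(onset * config.sampling_rate))
        i1 = int(np.ceil(end * config.sampling_rate))
        state_on[i0:i1] = True
        events.append((onset, lifetime))
        clock += lifetime

    current = config.baseline_current + amplitude * state_on
    if config.noise_sd > 0:
        current = current + config.noise_sd * rng.standard_normal(n)

    return CurrentTrace(
        time=t,
        current=current,
        bias_voltage=config.bias_voltage,
        current_setpoint=config.baseline_current,
        sampling_rate=config.sampling_rate,
        metadata={
            "events_true": events,
            "amplitude_true": amplitude,
            "conductance_true": config.blink_conductance,
            "baseline_true": config.baseline_current,
        },
    )
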
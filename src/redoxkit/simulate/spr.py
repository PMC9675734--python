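"""Synthetic SPR sensograms under the closed-form 1:1 Langmuir model.

Association phase:  R(t) = R_eq(C) * (1 - exp(-(kon*C + koff) t))
with R_eq(C) = Rmax * C / (C + koff/kon); dissociation phase: exponential
decay at rate koff from the response reached at the end of association.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..datatypes import Sensogram
from ..exceptions import ConfigurationError


@dataclass
class SPRGenConfig:
    kon: float = 6.54e3  # 1/(M s)
    koff: float = 3.18e-3  # 1/s
    rmax: float = 100.0  # RU
    concentrations: list[float] = field(default_factory=lambda: [5e-6, 2.5e-6])
    association_duration: float = 300.0  # s
    dissociation_duration: float = 600.0  # s
    time_step: float = 1.0  # s
    noise_sd: float = 0.0  # RU
    seed: int | None = None

    def __post_init__(self):
        if min(self.kon, self.koff, self.rmax) <= 0:
            raise ConfigurationError("kon, koff and rmax must be positive")
        if not self.concentrations or any(c <= 0 for c in self.concentrations):
            raise ConfigurationError("concentrations must be positive")
        if self.association_duration <= 0 or self.dissociation_duration < 0:
            raise ConfigurationError("phase durations must be positive")
        if self.time_step <= 0 or self.noise_sd < 0:
            raise ConfigurationError("invalid time step or noise level")


def langmuir_response(
    t: np.ndarray,
    concentration: float,
    kon: float,
    koff: float,
    rmax: float,
    association_end: float,
) -> np.ndarray:
    """Closed-form 1:1 binding response, both phases, noiseless."""
    t = np.asarray(t, dtype=float)
    k_obs = kon * concentration + koff
    r_eq = rmax * concentration / (concentration + koff / kon)
    r = np.where(
        t <= association_end,
        r_eq * (1.0 - np.exp(-k_obs * t)),
        r_eq * (1.0 - np.exp(-k_obs * association_end))
        * np.exp(-koff * np.clip(t - association_end, 0, None)),
    )
    return r


def gen_sensogram(config: SPRGenConfig) -> list[Sensogram]:
    """Generate one sensogram per configured analyte concentration."""
    rng = np.random.default_rng(config.seed)
    t = np.arange(
        0.0,
        config.association_duration + config.dissociation_duration + config.time_step / 2,
        config.time_step,
    )
    out = []
    for c in config.concentrations:
        r = langmuir_response(
            t, c, config.kon, config.koff, config.rmax, config.association_duration
        )
        if config.noise_sd > 0:
            r = r + config.noise_sd * rng.standard_normal(t.size)
        out.append(
            Sensogram(
                time=t.copy(),
                response=r,
                concentration=c,
                association_end=config.association_duration,
                metadata={
                    "kon_true": config.kon,
                    "koff_true": config.koff,
                    "rmax_true": config.rmax,
                },
            )
        )
    return out
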
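"""Synthetic force-separation retraction curves with unbinding events.

Each curve is a flat (zero-force) retraction trace with, optionally, one
adhesive sawtooth: the pulling force ramps linearly at the effective
stiffness until the bond ruptures at a force drawn from the configured
rupture model, then snaps back to the baseline.  Rupture forces can be
drawn from a Gaussian (near-equilibrium behaviour) or from the
first-passage distribution of a single sharp barrier under a constant
loading rate r = k_eff * v (kinetic regime):

    p(F) = (k0/r) * exp(x F / kBT) * exp[-(k0 kBT/(x r)) (exp(x F/kBT) - 1)]

sampled exactly through its analytic inverse CDF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..constants import thermal_energy_pn_nm
from ..datatypes import ForceCurve
from ..exceptions import ConfigurationError


@dataclass
class GaussianRupture:
    """Gaussian rupture-force statistics (truncated at F > 0)."""

    center: float  # pN
    width: float  # pN

    def __post_init__(self):
        if self.center <= 0 or self.width < 0:
            raise ConfigurationError("Gaussian rupture needs center > 0, width >= 0")


@dataclass
class BellEvansRupture:
    """Single-barrier rupture kinetics: zero-force rate k0_u and barrier
    distance x_u, producing loading-rate-dependent rupture forces."""

    k0_u: float  # 1/s
    x_u: float  # nm
    temperature: float = 298.0  # K

    def __post_init__(self):
        if self.k0_u <= 0 or self.x_u <= 0 or self.temperature <= 0:
            raise ConfigurationError("Bell-Evans parameters must be positive")


def sample_bell_evans_forces(
    k0_u: float,
    x_u: float,
    loading_rate: float,
    n: int,
    temperature: float = 298.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw rupture forces (pN) from the single-barrier first-passage
    distribution at constant loading rate via the analytic inverse CDF.

    With a = x_u/kBT and c = k0_u*kBT/(x_u*r), the survival function is
    S(F) = exp[-c (e^{aF} - 1)], so F = ln(1 - ln(U)/c) / a for U~U(0,1).
    """
    if min(k0_u, x_u, loading_rate, temperature) <= 0 or n < 0:
        raise ConfigurationError("all Bell-Evans sampling arguments must be positive")
    rng = np.random.default_rng() if rng is None else rng
    kbt = thermal_energy_pn_nm(temperature)
    a = x_u / kbt
    c = k0_u * kbt / (x_u * loading_rate)
    u = rng.uniform(size=n)
    return np.log1p(-np.log(u) / c) / a


@dataclass
class ForceGenConfig:
    rupture_model: GaussianRupture | BellEvansRupture = field(
        default_factory=lambda: GaussianRupture(center=55.0, width=17.0)
    )
    pulling_velocity: float = 1.0  # µm/s
    effective_stiffness: float = 56.0  # pN/nm
    tether_contour_length: float = 0.0  # nm; 0 = direct attachment
    rupture_length_distribution: tuple[float, float] = (12.0, 4.0)  # (center, width) nm
    fraction_with_event: float = 1.0
    n_curves: int = 200
    retraction_span: float = 30.0  # nm
    points_per_curve: int = 2000
    noise_sd: float = 5.0  # pN
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.fraction_with_event <= 1.0:
            raise ConfigurationError("fraction_with_event must be in [0, 1]")
        if self.pulling_velocity <= 0 or self.effective_stiffness <= 0:
            raise ConfigurationError("loading rate k_eff*v must be positive")
        if self.retraction_span <= 0 or self.points_per_curve < 10:
            raise ConfigurationError("invalid retraction geometry")
        if self.noise_sd < 0 or self.tether_contour_length < 0:
            raise ConfigurationError("noise and tether length must be non-negative")

    @property
    def loading_rate(self) -> float:
        """Nominal loading rate k_eff * v in pN/s."""
        return self.effective_stiffness * self.pulling_velocity * 1e3


def _draw_rupture_force(
    model: GaussianRupture | BellEvansRupture,
    loading_rate: float,
    rng: np.random.Generator,
) -> float:
    if isinstance(model, GaussianRupture):
        f = -1.0
        while f <= 0:  # truncate at positive force
            f = model.center + model.width * rng.standard_normal()
        return f
    return float(
        sample_bell_evans_forces(
            model.k0_u, model.x_u, loading_rate, 1, model.temperature, rng
        )[0]
    )


def gen_force_curves(config: ForceGenConfig) -> list[ForceCurve]:
    """Generate an ensemble of retraction force curves.

    Adhesive (pulling) forces are negative; the ground-truth rupture
    force/length of each curve (if any) is stored in its metadata.
    """
    rng = np.random.default_rng(config.seed)
    s = np.linspace(0.0, config.retraction_span, config.points_per_curve)
    lr_center, lr_width = config.rupture_length_distribution

    curves = []
    for i in range(config.n_curves):
        force = np.zeros_like(s)
        meta: dict = {"has_event": False}
        if rng.uniform() < config.fraction_with_event:
            f_r = _draw_rupture_force(config.rupture_model, config.loading_rate, rng)
            l_r = -1.0
            while l_r <= config.tether_contour_length or l_r <= 1.0:
                l_r = lr_center + lr_width * rng.standard_normal()
            l_r = min(l_r, config.retraction_span * 0.8)
            # bond loads at k_eff from s_start so that |F| reaches F_r at l_r
            s_start = max(0.0, l_r - f_r / config.effective_stiffness)
            loading = (s >= s_start) & (s < l_r)
            force[loading] = -config.effective_stiffness * (s[loading] - s_start)
            meta = {"has_event": True, "rupture_force_true": f_r,
                    "rupture_length_true": l_r,
                    "loading_rate_true": config.loading_rate}
        if config.noise_sd > 0:
            force = force + config.noise_sd * rng.standard_normal(s.size)
        curves.append(
            ForceCurve(
                separation=s.copy(),
                force=force,
                pulling_velocity=config.pulling_velocity,
                cantilever_stiffness=config.effective_stiffness,
                metadata={**meta, "curve_id": i},
            )
        )
    return curves
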
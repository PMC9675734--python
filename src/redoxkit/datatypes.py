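"""Core data containers shared by the generators and the analysis models.

These are thin, validated dataclasses around numpy arrays; heavier
behaviour (fitting, detection) lives in the analysis modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .constants import G0_SIEMENS
from .exceptions import ConfigurationError


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ConfigurationError(f"{name} must be one-dimensional")
    return arr


@dataclass
class ProbeRetractionCurve:
    """One feedback-off I-z recording during probe retraction.

    ``z`` is the retraction distance in nm, monotone non-decreasing from 0
    at the current set point; ``current`` is the probe current in nA.
    ``sample_potential`` (U_S) and ``probe_potential`` (U_P) are given vs
    the reference electrode; the electrochemical gate is -U_S at fixed
    bias U_P - U_S.
    """

    z: np.ndarray
    current: np.ndarray
    sample_potential: float = np.nan
    probe_potential: float = np.nan
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        self.z = _as_1d(self.z, "z")
        self.current = _as_1d(self.current, "current")
        if self.z.size != self.current.size:
            raise ConfigurationError("z and current must have equal length")
        if self.z.size < 2:
            raise ConfigurationError("curve needs at least 2 points")
        if self.z[0] != 0:
            raise ConfigurationError("z must start at 0 (the set point)")
        if np.any(np.diff(self.z) < 0):
            raise ConfigurationError("z must be monotone non-decreasing")
        if not np.all(np.isfinite(self.current)):
            raise ConfigurationError("currents must be finite")

    @property
    def bias(self) -> float:
        """Bias U_P - U_S in V."""
        return self.probe_potential - self.sample_potential

    @property
    def gate(self) -> float:
        """Electrochemical gate potential, -U_S, in V."""
        return -self.sample_potential


@dataclass
class CurrentTrace:
    """Uniformly sampled feedback-off current-time trace."""

    time: np.ndarray
    current: np.ndarray
    bias_voltage: float
    current_setpoint: float = np.nan
    sampling_rate: float | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        self.time = _as_1d(self.time, "time")
        self.current = _as_1d(self.current, "current")
        if self.time.size != self.current.size:
            raise ConfigurationError("time and current must have equal length")
        if self.time.size >= 2:
            dt = np.diff(self.time)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
                raise ConfigurationError("sampling must be uniform")
            if self.sampling_rate is None:
                self.sampling_rate = 1.0 / dt[0]


@dataclass
class BlinkEvent:
    """A single telegraph excursion in a current-time trace."""

    onset: float  # s
    lifetime: float  # s
    blink_current: float  # nA, baseline-subtracted plateau
    baseline_current: float  # nA, local baseline at onset
    bias_voltage: float  # V

    @property
    def conductance_g0(self) -> float:
        """G = I_blink / V_bias, in multiples of G0."""
        return (self.blink_current * 1e-9 / self.bias_voltage) / G0_SIEMENS


@dataclass
class BlinkMap:
    """2D histogram of blink samples (time since onset x current)."""

    time_axis: np.ndarray  # bin edges, s, origin 0
    current_axis: np.ndarray  # bin edges, nA
    counts: np.ndarray  # normalized so that the maximum bin = 100
    n_events: int


@dataclass
class ForceCurve:
    """Force-separation retraction trace from a pulling experiment."""

    separation: np.ndarray  # nm
    force: np.ndarray  # pN, adhesive (pulling) forces negative
    pulling_velocity: float  # µm/s
    cantilever_stiffness: float  # pN/nm (effective)
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        self.separation = _as_1d(self.separation, "separation")
        self.force = _as_1d(self.force, "force")
        if self.separation.size != self.force.size:
            raise ConfigurationError("separation and force must match in length")
        if self.pulling_velocity <= 0:
            raise ConfigurationError("pulling velocity must be positive")

    @property
    def nominal_loading_rate(self) -> float:
        """k_eff * v in pN/s (velocity µm/s = 1000 nm/s)."""
        return self.cantilever_stiffness * self.pulling_velocity * 1e3


@dataclass
class RuptureEvent:
    """Unbinding event extracted from a force curve."""

    rupture_force: float  # pN, positive
    rupture_length: float  # nm
    loading_rate: float  # pN/s
    curve_id: int | str | None = None


@dataclass
class Sensogram:
    """SPR response vs time for one analyte concentration."""

    time: np.ndarray  # s
    response: np.ndarray  # RU
    concentration: float  # M
    association_end: float  # s
    reference_subtracted: bool = True
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        self.time = _as_1d(self.time, "time")
        self.response = _as_1d(self.response, "response")
        if self.time.size != self.response.size:
            raise ConfigurationError("time and response must match in length")
        if self.concentration <= 0:
            raise ConfigurationError("analyte concentration must be positive")
        if not (self.time.min() <= self.association_end <= self.time.max()):
            raise ConfigurationError("association_end outside the time range")

    @property
    def association_mask(self) -> np.ndarray:
        return self.time <= self.association_end

    @property
    def dissociation_mask(self) -> np.ndarray:
        return self.time > self.association_end


@dataclass
class IonTrajectory:
    """Ion coordinate frames (Å) inside a rectangular box."""

    frames: list[np.ndarray]  # each (N_i, 3), Å
    box_dimensions: tuple[float, float, float]  # Å
    ion_charge: float = 1.0  # e
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.frames) < 1:
            raise ConfigurationError("need at least one frame")
        box = np.asarray(self.box_dimensions, dtype=float)
        if box.shape != (3,) or np.any(box <= 0):
            raise ConfigurationError("box dimensions must be a positive triplet")
        clean = []
        for i, f in enumerate(self.frames):
            arr = np.asarray(f, dtype=float).reshape(-1, 3)
            if arr.size and (np.any(arr < -1e-9) or np.any(arr > box + 1e-9)):
                raise ConfigurationError(f"frame {i} has coordinates outside the box")
            clean.append(arr)
        self.frames = clean
        self.box_dimensions = tuple(box)

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class DensityGrid:
    """Voxelized time-averaged molarity map."""

    origin: np.ndarray  # Å
    voxel_edge: float  # Å
    values: np.ndarray  # (nx, ny, nz), mol/L
    n_frames_averaged: int = 1

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ConfigurationError("density values must be a 3D array")
        if np.any(self.values < 0):
            raise ConfigurationError("densities must be non-negative")

    @property
    def voxel_volume_L(self) -> float:
        return (self.voxel_edge**3) * 1e-27  # Å^3 -> L


@dataclass
class PrismSpec:
    """Axis-aligned rectangular prism used for region-averaged molarity.

    Edge lengths are in Å (grid units of 1 Å), so a 15 x 43 x 20 prism has
    a volume of 12.9 nm^3.
    """

    center: tuple[float, float, float]  # Å
    edge_lengths: tuple[float, float, float]  # Å

    def __post_init__(self):
        edges = np.asarray(self.edge_lengths, dtype=float)
        if np.any(edges <= 0):
            raise ConfigurationError("prism edges must be positive")
        self.edge_lengths = tuple(edges)
        self.center = tuple(np.asarray(self.center, dtype=float))

    @property
    def volume_nm3(self) -> float:
        return float(np.prod(self.edge_lengths)) / 1000.0

    @property
    def bounds(self) -> np.ndarray:
        """(2, 3) array of lower/upper corners in Å."""
        c = np.asarray(self.center)
        e = np.asarray(self.edge_lengths)
        return np.stack([c - e / 2, c + e / 2])


@dataclass
class PotentialField:
    """Screened electrostatic potential on a voxel grid, in kT/e units."""

    origin: np.ndarray  # Å
    voxel_edge: float  # Å
    values: np.ndarray  # (nx, ny, nz), kT/e
    debye_length_nm: float
    contour_spacing: float = 0.2  # kT/e

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ConfigurationError("potential values must be a 3D array")

    def contour_levels(self, vmin: float = -1.0, vmax: float = 1.0) -> np.ndarray:
        """Equipotential levels at the configured spacing, spanning [vmin, vmax]."""
        n = int(np.floor((vmax - vmin) / self.contour_spacing))
        return vmin + self.contour_spacing * np.arange(n + 1)


@dataclass
class RateCurve:
    """Association rate vs reaction-distance criterion."""

    reaction_distances: np.ndarray  # nm, sorted ascending
    rates: np.ndarray  # M^-1 s^-1
    rate_errors: np.ndarray | None = None  # Monte-Carlo s.e.

    def __post_init__(self):
        self.reaction_distances = _as_1d(self.reaction_distances, "reaction_distances")
        self.rates = _as_1d(self.rates, "rates")
        order = np.argsort(self.reaction_distances)
        self.reaction_distances = self.reaction_distances[order]
        self.rates = self.rates[order]
        if self.rate_errors is not None:
            self.rate_errors = _as_1d(self.rate_errors, "rate_errors")[order]

    def rate_at(self, distance_nm: float) -> float:
        """Rate at a given criterion distance (log-interpolated)."""
        return float(
            np.exp(
                np.interp(
                    distance_nm, self.reaction_distances, np.log(self.rates)
                )
            )
        )

    @property
    def k_on_at_contact(self) -> float:
        """Association rate at the 0.6 nm contact criterion."""
        return self.rate_at(0.6)

    @property
    def k_trigger(self) -> float:
        """Association rate at the 2.5 nm electron-transfer trigger distance."""
        return self.rate_at(2.5)
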
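"""Synthetic monovalent-ion coordinate frames.

Ions are placed by rejection sampling with Boltzmann weight
exp(-q * phi(x)) where phi is the linearized (Debye-Hückel) potential of
a set of fixed point charges in a dielectric continuum — a statistical
stand-in for explicit-solvent molecular dynamics.  The number of ions
per frame is set by the bulk concentration and the box volume; with no
fixed charges the sampler is exactly uniform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..constants import AVOGADRO, ROOM_TEMPERATURE, WATER_EPS_R
from ..datatypes import IonTrajectory
from ..exceptions import ConfigurationError, PathologicalField
from ..ionfield import DEFAULT_CORE_RADIUS_NM, dh_potential_at


@dataclass
class IonGenConfig:
    box_dimensions: tuple[float, float, float] = (6.0, 6.0, 6.0)  # nm
    bulk_concentration: float = 0.05  # M
    site_charges: list[tuple[tuple[float, float, float], float]] = field(
        default_factory=lambda: [((3.0, 3.0, 1.4), 1.0), ((3.0, 3.0, 4.6), 1.0)]
    )  # ((x, y, z) nm, charge e); default: two +1 sites 3.2 nm apart
    ion_charge: float = 1.0  # e (monovalent cation)
    temperature: float = ROOM_TEMPERATURE  # K
    relative_permittivity: float = WATER_EPS_R
    core_radius_nm: float = DEFAULT_CORE_RADIUS_NM
    n_frames: int = 50
    seed: int | None = None

    def __post_init__(self):
        box = np.asarray(self.box_dimensions, dtype=float)
        if box.shape != (3,) or np.any(box <= 0):
            raise ConfigurationError("box dimensions must be a positive nm triplet")
        self.box_dimensions = tuple(box)
        if self.bulk_concentration < 0:
            raise ConfigurationError("bulk concentration must be non-negative")
        if self.n_frames < 1:
            raise ConfigurationError("need at least one frame")
        if self.temperature <= 0 or self.relative_permittivity <= 0:
            raise ConfigurationError("temperature and permittivity must be positive")


def _weight_bound(config: IonGenConfig) -> float:
    """Upper bound on the Boltzmann weight, from a probe grid plus margin.

    The potential is core-clamped so the weight is bounded; a dense probe
    grid finds its maximum to within a small margin.
    """
    box = np.asarray(config.box_dimensions)
    spacing = min(0.1, config.core_radius_nm / 2)
    # evaluating a full fine grid is wasteful: probe coarsely everywhere
    # and finely within 1 nm of each site
    coarse = [np.linspace(spacing / 2, b - spacing / 2, 15) for b in box]
    pts = [np.stack(np.meshgrid(*coarse, indexing="ij"), -1).reshape(-1, 3)]
    for pos, _ in config.site_charges:
        pos = np.asarray(pos)
        local = [
            np.arange(max(0, p - 1.0), min(b, p + 1.0) + spacing / 2, spacing)
            for p, b in zip(pos, box)
        ]
        pts.append(np.stack(np.meshgrid(*local, indexing="ij"), -1).reshape(-1, 3))
    probe = np.concatenate(pts)
    phi = dh_potential_at(
        probe,
        config.site_charges,
        config.bulk_concentration,
        config.temperature,
        config.relative_permittivity,
        config.core_radius_nm,
    )
    w = np.exp(-config.ion_charge * phi)
    return float(w.max()) * 1.25


def gen_ion_frames(config: IonGenConfig) -> IonTrajectory:
    """Generate Boltzmann-distributed ion frames (coordinates in Å).

    Raises :class:`PathologicalField` if the rejection-sampling acceptance
    rate falls below 1% (field too extreme for this sampler).
    """
    rng = np.random.default_rng(config.seed)
    box = np.asarray(config.box_dimensions, dtype=float)
    volume_L = float(np.prod(box)) * 1e-24  # nm^3 -> L
    n_ions = int(round(config.bulk_concentration * AVOGADRO * volume_L))

    frames: list[np.ndarray] = []
    if n_ions == 0:
        frames = [np.empty((0, 3)) for _ in range(config.n_frames)]
        return IonTrajectory(
            frames=frames,
            box_dimensions=tuple(box * 10.0),
            ion_charge=config.ion_charge,
            metadata={"config": config, "n_ions_per_frame": 0},
        )

    uniform = len(config.site_charges) == 0
    bound = 1.0 if uniform else _weight_bound(config)

    n_accepted = 0
    n_proposed = 0
    for _ in range(config.n_frames):
        coords = np.empty((0, 3))
        while coords.shape[0] < n_ions:
            need = n_ions - coords.shape[0]
            batch = max(4 * need, 64)
            cand = rng.uniform(size=(batch, 3)) * box
            n_proposed += batch
            if uniform:
                keep = cand[:need]
            else:
                phi = dh_potential_at(
                    cand,
                    config.site_charges,
                    config.bulk_concentration,
                    config.temperature,
                    config.relative_permittivity,
                    config.core_radius_nm,
                )
                w = np.exp(-config.ion_charge * phi)
                accept = rng.uniform(size=batch) * bound < w
                keep = cand[accept][:need]
            n_accepted += keep.shape[0]
            coords = np.vstack([coords, keep])
            if not uniform and n_proposed > 10_000 and n_accepted / n_proposed < 0.01:
                raise PathologicalField(
                    "rejection-sampling acceptance rate below 1%"
                )
        frames.append(coords * 10.0)  # nm -> Å

    return IonTrajectory(
        frames=frames,
        box_dimensions=tuple(box * 10.0),
        ion_charge=config.ion_charge,
        metadata={
            "config": config,
            "n_ions_per_frame": n_ions,
            "acceptance_rate": (n_accepted / n_proposed) if n_proposed else 1.0,
        },
    )
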
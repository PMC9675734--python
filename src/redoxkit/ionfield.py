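"""Ionic-environment analysis: voxelized concentration maps, prism
averages, linearized-screening (Debye-Hückel) potential fields, and
diffusion-limited association rates from centrosymmetric Brownian
dynamics.

Geometry convention: voxel grids and ion coordinates are in Å (the grid
unit of the concentration maps); the screened-Coulomb helpers take
distances in nm internally.  Potentials are expressed in thermal units
kT/e, so the Boltzmann factor of an ion of charge q (in e) is simply
exp(-q * phi).
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy import integrate

from .constants import (
    AVOGADRO,
    ROOM_TEMPERATURE,
    WATER_EPS_R,
    bjerrum_length_nm,
    debye_length_nm,
)
from .datatypes import DensityGrid, IonTrajectory, PotentialField, PrismSpec, RateCurve
from .exceptions import ConfigurationError, InvalidGrid, OutOfBounds, StepTooLarge

#: Minimum approach distance (nm) of an ion to a point charge; below it the
#: potential is evaluated at the core radius (finite ion size).
DEFAULT_CORE_RADIUS_NM = 0.3


# ---------------------------------------------------------------------------
# concentration maps
# ---------------------------------------------------------------------------

def density_map(traj: IonTrajectory, voxel_edge: float = 1.0) -> DensityGrid:
    """Average ion occupancy per voxel over frames, as molarity.

    c_voxel = <N_voxel> / (N_A * V_voxel), with V_voxel in litres.  The
    map conserves the mean ion count: sum(c * V * N_A) equals the mean
    number of ions per frame.
    """
    box = np.asarray(traj.box_dimensions, dtype=float)
    if voxel_edge <= 0 or voxel_edge > box.min():
        raise InvalidGrid("voxel edge must be positive and fit inside the box")
    nbins = np.maximum(np.ceil(box / voxel_edge).astype(int), 1)
    edges = [np.arange(nb + 1) * voxel_edge for nb in nbins]
    counts = np.zeros(tuple(nbins), dtype=float)
    for frame in traj.frames:
        if frame.size == 0:
            continue
        h, _ = np.histogramdd(frame, bins=edges)
        counts += h
    mean_counts = counts / traj.n_frames
    voxel_volume_L = (voxel_edge**3) * 1e-27
    values = mean_counts / (AVOGADRO * voxel_volume_L)
    return DensityGrid(
        origin=np.zeros(3),
        voxel_edge=voxel_edge,
        values=values,
        n_frames_averaged=traj.n_frames,
    )


def prism_average(grid: DensityGrid, prism: PrismSpec) -> float:
    """Volume-weighted mean molarity over a rectangular prism.

    Voxels partially covered by the prism contribute in proportion to
    their overlap volume.
    """
    lo, hi = prism.bounds
    grid_lo = grid.origin
    grid_hi = grid.origin + np.array(grid.values.shape) * grid.voxel_edge
    if np.any(lo < grid_lo - 1e-9) or np.any(hi > grid_hi + 1e-9):
        raise OutOfBounds("prism extends beyond the density grid")

    weights = []
    for axis in range(3):
        n = grid.values.shape[axis]
        starts = grid.origin[axis] + grid.voxel_edge * np.arange(n)
        ends = starts + grid.voxel_edge
        overlap = np.clip(np.minimum(ends, hi[axis]) - np.maximum(starts, lo[axis]), 0, None)
        weights.append(overlap)
    w = np.einsum("i,j,k->ijk", *weights)
    total = w.sum()
    if total <= 0:
        raise OutOfBounds("prism has zero overlap with the grid")
    return float((w * grid.values).sum() / total)


# ---------------------------------------------------------------------------
# linearized screening
# ---------------------------------------------------------------------------

def dh_potential_at(
    points_nm: np.ndarray,
    charges: Sequence[tuple[Sequence[float], float]],
    ionic_strength_M: float,
    temperature: float = ROOM_TEMPERATURE,
    eps_r: float = WATER_EPS_R,
    core_radius_nm: float = DEFAULT_CORE_RADIUS_NM,
) -> np.ndarray:
    """Superposition of screened Coulomb (Yukawa) potentials, in kT/e.

    phi(x) = sum_i q_i * l_B * exp(-r_i / lambda_D) / r_i  with r_i in nm,
    the Bjerrum length l_B, and the Debye length lambda_D of a 1:1
    electrolyte.  Distances below ``core_radius_nm`` are clamped to it.
    """
    pts = np.atleast_2d(np.asarray(points_nm, dtype=float))
    lam = debye_length_nm(ionic_strength_M, temperature, eps_r)
    lb = bjerrum_length_nm(temperature, eps_r)
    phi = np.zeros(pts.shape[0])
    for pos, q in charges:
        r = np.linalg.norm(pts - np.asarray(pos, dtype=float), axis=1)
        r = np.maximum(r, core_radius_nm)
        if np.isinf(lam):
            phi += q * lb / r
        else:
            phi += q * lb * np.exp(-r / lam) / r
    return phi


def dh_field(
    charges: Sequence[tuple[Sequence[float], float]],
    ionic_strength_M: float,
    temperature: float = ROOM_TEMPERATURE,
    eps_r: float = WATER_EPS_R,
    origin: Sequence[float] = (0.0, 0.0, 0.0),
    shape: Sequence[int] = (60, 60, 60),
    voxel_edge: float = 1.0,
    contour_spacing: float = 0.2,
    core_radius_nm: float = DEFAULT_CORE_RADIUS_NM,
) -> PotentialField:
    """Debye-Hückel potential on a voxel grid (geometry in Å).

    Charge positions are given in Å; voxels closer to a charge than the
    core radius are flagged with NaN (the potential diverges at a point
    charge and those voxels are excluded from contouring).
    """
    if ionic_strength_M < 0:
        raise ConfigurationError("ionic strength must be non-negative")
    origin = np.asarray(origin, dtype=float)
    shape = tuple(int(s) for s in shape)
    ax = [origin[i] + voxel_edge * (np.arange(shape[i]) + 0.5) for i in range(3)]
    xx, yy, zz = np.meshgrid(*ax, indexing="ij")
    pts_nm = np.stack([xx, yy, zz], axis=-1).reshape(-1, 3) * 0.1  # Å -> nm
    charges_nm = [(np.asarray(pos, dtype=float) * 0.1, q) for pos, q in charges]
    phi = dh_potential_at(
        pts_nm, charges_nm, ionic_strength_M, temperature, eps_r, core_radius_nm
    ).reshape(shape)
    # flag voxels inside the ionic core of any site
    mask = np.zeros(shape, dtype=bool)
    for pos, _ in charges_nm:
        r = np.linalg.norm(pts_nm - pos, axis=1).reshape(shape)
        mask |= r < core_radius_nm
    phi = np.where(mask, np.nan, phi)
    return PotentialField(
        origin=origin,
        voxel_edge=voxel_edge,
        values=phi,
        debye_length_nm=debye_length_nm(ionic_strength_M, temperature, eps_r),
        contour_spacing=contour_spacing,
    )


def boltzmann_consistency_slope(
    traj: IonTrajectory,
    charges: Sequence[tuple[Sequence[float], float]],
    ionic_strength_M: float,
    voxel_edge: float = 2.5,
    phi_window: tuple[float, float] = (-0.5, -0.05),
    n_bins: int = 15,
    temperature: float = ROOM_TEMPERATURE,
    eps_r: float = WATER_EPS_R,
) -> float:
    """Regression slope of ln(c/c_bulk) against q*phi over voxels.

    For ions equilibrated in a field phi the densities should satisfy
    ln(c(x)/c_bulk) = -q phi(x) + const, i.e. a slope of -1.  Voxels are
    aggregated into potential bins (individual voxels are Poisson-noisy)
    and the window excludes both the near-bulk region (no signal) and
    the immediate vicinity of the charges (strong within-voxel field
    variation).  Charge positions are in nm, to match the generator
    configs.
    """
    grid = density_map(traj, voxel_edge=voxel_edge)
    shape = grid.values.shape
    ax = [grid.origin[i] + voxel_edge * (np.arange(shape[i]) + 0.5) for i in range(3)]
    mesh = np.meshgrid(*ax, indexing="ij")
    pts_nm = np.stack(mesh, axis=-1).reshape(-1, 3) * 0.1
    phi = traj.ion_charge * dh_potential_at(
        pts_nm, charges, ionic_strength_M, temperature, eps_r
    )
    c = grid.values.ravel()
    box_volume_L = float(np.prod(traj.box_dimensions)) * 1e-27
    mean_n = float(np.mean([f.shape[0] for f in traj.frames]))
    c_bulk = mean_n / (AVOGADRO * box_volume_L)
    sel = (phi > phi_window[0]) & (phi < phi_window[1])
    if sel.sum() < 2 * n_bins:
        raise ConfigurationError("too few voxels inside the potential window")
    edges = np.quantile(phi[sel], np.linspace(0, 1, n_bins + 1))
    edges[0] -= 1e-9
    idx = np.digitize(phi[sel], edges[1:-1])
    xs, ys = [], []
    for b in range(n_bins):
        m = idx == b
        if m.sum() < 5:
            continue
        cm = c[sel][m].mean()
        if cm <= 0:
            continue
        xs.append(phi[sel][m].mean())
        ys.append(np.log(cm / c_bulk))
    return float(np.polyfit(xs, ys, 1)[0])


# ---------------------------------------------------------------------------
# diffusion-limited association
# ---------------------------------------------------------------------------

def diffusion_limited_rate(
    absorbing_radius_nm: float,
    diffusion_m2_s: float,
    potential: Callable[[np.ndarray], np.ndarray] | None = None,
    far_radius_nm: float | None = None,
) -> float:
    """Steady-state rate constant (M^-1 s^-1) to an absorbing sphere under a
    centrosymmetric potential U(r) (in kT units), by quadrature of

        k = 4 pi D / int_r^inf exp(U(s)) / s^2 ds.

    With U = 0 this is the Smoluchowski rate 4 pi D r N_A.
    """
    if absorbing_radius_nm <= 0 or diffusion_m2_s <= 0:
        raise ConfigurationError("radius and diffusion constant must be positive")
    if potential is None:
        integral_per_nm = 1.0 / absorbing_radius_nm
    else:
        far = far_radius_nm or max(50.0, 10.0 * absorbing_radius_nm)
        val, _ = integrate.quad(
            lambda s: np.exp(potential(np.array([s]))[0]) / s**2,
            absorbing_radius_nm,
            far,
            limit=200,
        )
        integral_per_nm = val + 1.0 / far  # analytic U=0 tail beyond `far`
    k_m3_s = 4 * np.pi * diffusion_m2_s / (integral_per_nm * 1e9)
    return k_m3_s * AVOGADRO * 1e3


def bd_rate_curve(
    potential: Callable[[np.ndarray], np.ndarray] | None,
    diffusion_m2_s: float,
    b_surface_nm: float,
    q_surface_nm: float,
    reaction_distances_nm: Sequence[float],
    n_trajectories: int = 2000,
    seed: int | None = None,
    max_steps: int = 2_000_000,
) -> RateCurve:
    """Association rate vs reaction-distance criterion from Brownian
    trajectories, with the standard b/q-surface truncation correction.

    Trajectories start on the b-surface and run (Euler-Maruyama, adaptive
    step) until they escape past the q-surface; the recombination
    probability P(d) is the fraction that reached separation <= d, and

        k(d) = k_D(b) P(d) / [1 - (1 - P(d)) k_D(b)/k_D(q)]

    with k_D(.) the quadrature rate of :func:`diffusion_limited_rate`.
    ``potential`` maps separation (nm) to energy in kT units (None = free
    diffusion).
    """
    d_arr = np.sort(np.asarray(reaction_distances_nm, dtype=float))
    if d_arr.size == 0 or d_arr[0] <= 0:
        raise ConfigurationError("reaction distances must be positive")
    if not (d_arr[-1] < b_surface_nm < q_surface_nm):
        raise ConfigurationError("need reaction distances < b_surface < q_surface")

    rng = np.random.default_rng(seed)
    d_nm2_s = diffusion_m2_s * 1e18  # nm^2/s
    d_abs = d_arr[0]

    if potential is None:
        u = lambda r: np.zeros_like(r)  # noqa: E731
    else:
        u = potential
    h = 1e-3

    def u_grad(r: np.ndarray) -> np.ndarray:
        return (u(r + h) - u(r - h)) / (2 * h)

    # start on the b sphere (centrosymmetric: any point is equivalent)
    pos = np.zeros((n_trajectories, 3))
    pos[:, 2] = b_surface_nm
    min_r = np.full(n_trajectories, b_surface_nm)
    active = np.ones(n_trajectories, dtype=bool)

    for _ in range(max_steps):
        if not active.any():
            break
        p = pos[active]
        r = np.linalg.norm(p, axis=1)
        grad = u_grad(r)
        # adaptive rms step: shrink near the absorbing surface and where
        # the potential is steep (keep |dU| per step well below kT)
        sigma = np.minimum(0.05 * (r - d_abs) + 0.005, 0.35)
        with np.errstate(divide="ignore"):
            sigma = np.minimum(sigma, 0.5 / np.maximum(np.abs(grad), 1e-12))
        if np.any(sigma < 1e-4):
            raise StepTooLarge(
                "potential too steep for a resolvable Brownian step"
            )
        dt = sigma**2 / (2 * d_nm2_s)
        drift = (-d_nm2_s * grad * dt / r)[:, None] * p
        p = p + drift + sigma[:, None] * rng.standard_normal(p.shape)
        r_new = np.linalg.norm(p, axis=1)
        pos[active] = p
        idx = np.flatnonzero(active)
        min_r[idx] = np.minimum(min_r[idx], r_new)
        done = (r_new <= d_abs) | (r_new >= q_surface_nm)
        active[idx[done]] = False
    else:
        raise StepTooLarge("Brownian trajectories did not terminate")

    k_b = diffusion_limited_rate(b_surface_nm, diffusion_m2_s, potential)
    k_q = diffusion_limited_rate(q_surface_nm, diffusion_m2_s, potential)
    ratio = k_b / k_q

    rates = np.empty_like(d_arr)
    errors = np.empty_like(d_arr)
    for i, d in enumerate(d_arr):
        p_hit = np.mean(min_r <= d)
        denom = 1.0 - (1.0 - p_hit) * ratio
        rates[i] = k_b * p_hit / denom
        se_p = np.sqrt(max(p_hit * (1 - p_hit), 1e-12) / n_trajectories)
        # delta method on k(P)
        dk_dp = k_b * (1.0 - ratio) / denom**2
        errors[i] = abs(dk_dp) * se_p
    return RateCurve(reaction_distances=d_arr, rates=rates, rate_errors=errors)
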
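"""Dynamic force spectroscopy: rupture-event detection and Bell-Evans
unbinding kinetics.

In the Bell-Evans single-barrier picture, a bond pulled at constant
loading rate r ruptures most probably at

    F* = (kBT / x_u) * ln( x_u * r / (k0_u * kBT) ),

so F* is linear in ln r; the slope gives the barrier distance
x_u = kBT/slope and the intercept the zero-force unbinding rate k0_u.
A slope indistinguishable from zero indicates near-equilibrium
unbinding (rebinding outpaces pulling), in which case the kinetic
parameters are undefined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._peakfit import gaussian_peak_fit
from .constants import thermal_energy_pn_nm
from .datatypes import ForceCurve, RuptureEvent
from .exceptions import BaselineUndefined, DomainError, InsufficientData

__all__ = [
    "detect_ruptures",
    "force_distribution",
    "ForceDistribution",
    "most_probable_force",
    "BellEvans",
    "BellEvansResults",
    "bell_evans_fit",
    "classify_regime",
    "rupture_density_map",
]


def detect_ruptures(
    curve: ForceCurve,
    noise_sigmas: float = 3.0,
    max_jump_samples: int = 3,
    slope_window: int = 20,
    min_excursion_samples: int = 4,
    depth_sigmas: float = 5.0,
) -> list[RuptureEvent]:
    """Detect unbinding events in one retraction trace.

    The zero-force baseline and the force noise come from the
    far-retraction tail (last 20% of samples, median / MAD).  A rupture
    is a negative-force (adhesive) excursion that ends in a
    discontinuous jump back to baseline exceeding ``noise_sigmas`` times
    the noise within at most ``max_jump_samples`` samples.  To reject
    single-sample noise dips, the excursion must last at least
    ``min_excursion_samples`` samples and reach ``depth_sigmas`` times
    the noise below baseline.  The rupture force is read from a short
    linear extrapolation of the pre-jump ramp, the rupture length is
    the separation at the jump, and the loading rate is the pre-jump
    |dF/dt| over ``slope_window`` samples.
    """
    n = curve.force.size
    tail = curve.force[int(0.8 * n):]
    if tail.size < 10:
        raise BaselineUndefined("no far-retraction tail to define zero force")
    baseline = float(np.median(tail))
    sigma = 1.4826 * float(np.median(np.abs(tail - baseline)))
    sigma = max(sigma, 1e-12)
    resid = curve.force - baseline
    thr = noise_sigmas * sigma

    below = resid < -thr
    padded = np.concatenate([[False], below, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])  # exclusive

    dt_per_sample = 1.0  # time enters only through the velocity scaling below
    nm_per_sample = float(np.mean(np.diff(curve.separation)))
    v_nm_s = curve.pulling_velocity * 1e3

    events = []
    for a, b in zip(starts, ends):
        if b - a < min_excursion_samples:
            continue  # too brief to be a loading ramp
        if resid[a:b].min() > -depth_sigmas * sigma:
            continue  # too shallow: indistinguishable from noise
        i_end = b - 1  # last sample below threshold = pre-jump sample
        j_max = min(i_end + max_jump_samples, n - 1)
        if j_max <= i_end:
            continue
        post = resid[i_end + 1: j_max + 1].max()
        jump = post - resid[i_end]
        if jump <= thr:
            continue  # smooth recovery, not a rupture
        if post <= -thr:
            continue  # mid-ramp noise spike: force never returned to baseline
        # pre-jump force by short linear extrapolation of the loading ramp
        w0 = max(a, i_end - 9)
        seg = np.arange(w0, i_end + 1)
        if seg.size >= 3:
            coef = np.polyfit(seg.astype(float), resid[seg], 1)
            pre_jump = float(np.polyval(coef, i_end))
        else:
            pre_jump = float(resid[i_end])
        f_r = abs(pre_jump)
        l_r = float(curve.separation[i_end])
        # loading rate from the local slope before the jump
        w1 = max(a, i_end - slope_window + 1)
        seg = np.arange(w1, i_end + 1)
        if seg.size >= 2:
            slope_per_sample = abs(np.polyfit(seg.astype(float), resid[seg], 1)[0])
            loading_rate = slope_per_sample / nm_per_sample * v_nm_s
        else:
            loading_rate = curve.nominal_loading_rate
        events.append(
            RuptureEvent(
                rupture_force=f_r,
                rupture_length=l_r,
                loading_rate=loading_rate,
                curve_id=curve.metadata.get("curve_id"),
            )
        )
    return events


@dataclass
class ForceDistribution:
    """Rupture-force statistics at one pulling velocity."""

    center: float  # pN, Gaussian fit of the main peak
    width: float  # pN
    mean: float  # pN, arithmetic (reported separately: skew)
    n: int
    counts: np.ndarray
    bin_edges: np.ndarray

    def summary(self) -> str:
        return (
            f"Rupture forces (n={self.n}): "
            f"Gaussian center {self.center:.1f} +/- {self.width:.1f} pN, "
            f"mean {self.mean:.1f} pN"
        )


def force_distribution(events: list[RuptureEvent], min_events: int = 30) -> ForceDistribution:
    """Histogram + main-peak Gaussian fit of rupture forces, plus the raw
    arithmetic mean (the distributions can be skewed)."""
    if len(events) < min_events:
        raise InsufficientData(f"need >= {min_events} events, got {len(events)}")
    forces = np.array([ev.rupture_force for ev in events])
    center, width, counts, edges = gaussian_peak_fit(forces)
    return ForceDistribution(
        center=center,
        width=width,
        mean=float(forces.mean()),
        n=forces.size,
        counts=counts,
        bin_edges=edges,
    )


def most_probable_force(
    k0_u: float, x_u: float, loading_rate: float, temperature: float = 298.0
) -> float:
    """Bell-Evans most probable rupture force (pN).

    Returns 0 when the log argument is <= 1 (spontaneous dissociation
    outpaces loading).
    """
    if min(k0_u, x_u, loading_rate, temperature) <= 0:
        raise DomainError("all Bell-Evans arguments must be positive")
    kbt = thermal_energy_pn_nm(temperature)
    arg = x_u * loading_rate / (k0_u * kbt)
    if arg <= 1.0:
        return 0.0
    return (kbt / x_u) * np.log(arg)


@dataclass
class BellEvansResults:
    """Linear dynamic-force-spectroscopy fit F* = a + b ln(r)."""

    slope: float  # pN per ln(pN/s)
    intercept: float  # pN
    slope_stderr: float
    slope_p_value: float
    k0_u: float  # 1/s (nan in the near-equilibrium regime)
    x_u: float  # nm (nan in the near-equilibrium regime)
    temperature: float
    regime: str  # "kinetic" | "near_equilibrium"
    n_rates: int

    def summary(self) -> str:
        lines = [
            "Bell-Evans dynamic force spectroscopy",
            "=" * 42,
            f"slope       {self.slope:10.4f}  pN / ln(pN s^-1)"
            f"  (+/- {self.slope_stderr:.4f}, p={self.slope_p_value:.3g})",
            f"intercept   {self.intercept:10.4f}  pN",
            f"regime      {self.regime}",
        ]
        if self.regime == "kinetic":
            lines += [
                f"k0_u        {self.k0_u:10.4g}  s^-1",
                f"x_u         {self.x_u:10.4f}  nm",
            ]
        return "\n".join(lines)


class BellEvans:
    """Bell-Evans model of most-probable force vs loading rate.

    Parameters are the loading rates (pN/s), the most probable rupture
    forces (pN) and the temperature (K).  ``fit`` inverts the linear
    relation exactly: x_u = kBT/slope and
    k0_u = (1/slope) * exp(-intercept/slope) (in 1/s with slope in pN
    and kBT in pN nm), so a noiseless round trip through
    :func:`most_probable_force` is the identity.
    """

    def __init__(self, loading_rates, forces, temperature: float = 298.0):
        self.loading_rates = np.asarray(loading_rates, dtype=float)
        self.forces = np.asarray(forces, dtype=float)
        if self.loading_rates.size != self.forces.size:
            raise DomainError("rates and forces must have the same length")
        if np.unique(self.loading_rates).size < 3:
            raise InsufficientData("need at least 3 distinct loading rates")
        if np.any(self.loading_rates <= 0):
            raise DomainError("loading rates must be positive")
        self.temperature = temperature

    def fit(self, alpha: float = 0.05) -> BellEvansResults:
        x = np.log(self.loading_rates)
        res = stats.linregress(x, self.forces)
        b, a = res.slope, res.intercept
        p = float(res.pvalue) if np.isfinite(res.pvalue) else 0.0
        kbt = thermal_energy_pn_nm(self.temperature)
        if b > 0:
            x_u = kbt / b
            k0_u = (1.0 / b) * np.exp(-a / b)
        else:
            x_u = np.nan
            k0_u = np.nan
        kinetic = b > 0 and p < alpha
        return BellEvansResults(
            slope=float(b),
            intercept=float(a),
            slope_stderr=float(res.stderr) if np.isfinite(res.stderr) else 0.0,
            slope_p_value=p,
            k0_u=float(k0_u),
            x_u=float(x_u),
            temperature=self.temperature,
            regime="kinetic" if kinetic else "near_equilibrium",
            n_rates=int(np.unique(self.loading_rates).size),
        )


def bell_evans_fit(points, temperature: float = 298.0, alpha: float = 0.05) -> BellEvansResults:
    """Fit (loading rate, most-probable force) pairs to the Bell-Evans line."""
    pts = np.asarray(points, dtype=float)
    return BellEvans(pts[:, 0], pts[:, 1], temperature).fit(alpha=alpha)


def classify_regime(fit: BellEvansResults, alpha: float = 0.05) -> str:
    """``kinetic`` iff the DFS slope is positive and significant at alpha."""
    if fit.n_rates < 3:
        raise InsufficientData("regime classification needs >= 3 loading rates")
    if fit.slope > 0 and fit.slope_p_value < alpha:
        return "kinetic"
    return "near_equilibrium"


def rupture_density_map(
    events: list[RuptureEvent],
    n_grid: int = 80,
):
    """Kernel-density map over (rupture length, rupture force) with Scott
    bandwidth, for contour rendering.

    Returns ``(L, F, density)`` meshgrid arrays.
    """
    if len(events) < 3:
        raise InsufficientData("need at least 3 events for a density map")
    l_r = np.array([ev.rupture_length for ev in events])
    f_r = np.array([ev.rupture_force for ev in events])
    kde = stats.gaussian_kde(np.vstack([l_r, f_r]), bw_method="scott")
    li = np.linspace(l_r.min() - 1, l_r.max() + 1, n_grid)
    fi = np.linspace(f_r.min() - 5, f_r.max() + 5, n_grid)
    L, F = np.meshgrid(li, fi)
    density = kde(np.vstack([L.ravel(), F.ravel()])).reshape(L.shape)
    return L, F, density
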
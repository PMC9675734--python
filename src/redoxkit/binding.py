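"""Global 1:1 Langmuir fitting of SPR sensograms.

The closed-form one-site model is fitted simultaneously to one or more
sensograms recorded at distinct analyte concentrations, sharing kon,
koff and (by default) Rmax across curves:

    association:  R(t) = R_eq(C) (1 - e^{-(kon C + koff) t}),
                  R_eq(C) = Rmax C / (C + koff/kon)
    dissociation: R(t) = R(t_assoc) e^{-koff (t - t_assoc)}

The equilibrium dissociation constant is K_D = koff/kon; smaller K_D
means tighter binding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np

from .datatypes import Sensogram
from .exceptions import DomainError, FitFailure, InitFailure
from .simulate.spr import langmuir_response

__all__ = [
    "LangmuirKinetics",
    "BindingKineticsResults",
    "fit_global_1to1",
    "koff_from_dissociation",
    "compute_kd",
]


def koff_from_dissociation(sensogram: Sensogram, min_points: int = 10) -> float:
    """Off-rate initializer: minus the slope of ln R over the
    dissociation phase.

    Non-positive responses truncate the phase to its positive prefix; a
    constant response yields 0 (flagged to the caller as "no decay").
    """
    mask = sensogram.dissociation_mask
    t = sensogram.time[mask] - sensogram.association_end
    r = sensogram.response[mask]
    pos = r > 0
    if not pos.any():
        raise InitFailure("dissociation phase has no positive responses")
    first_nonpos = np.argmin(pos) if not pos.all() else r.size
    t, r = t[:first_nonpos], r[:first_nonpos]
    if t.size < min_points:
        raise InitFailure(
            f"dissociation phase has only {t.size} usable points (need >= {min_points})"
        )
    slope = np.polyfit(t, np.log(r), 1)[0]
    return max(-float(slope), 0.0)


@dataclass
class BindingKineticsResults:
    """Fitted 1:1 binding kinetics."""

    kon: float  # 1/(M s)
    koff: float  # 1/s
    rmax: float  # RU (shared surface capacity)
    kon_stderr: float | None
    koff_stderr: float | None
    rmax_stderr: float | None
    r_squared: float
    n_sensograms: int
    concentrations: list[float] = field(default_factory=list)

    @property
    def kd(self) -> float:
        """Equilibrium dissociation constant K_D = koff/kon (M)."""
        return compute_kd(self)

    def r_eq(self, concentration: float) -> float:
        """Equilibrium response at a given analyte concentration."""
        return self.rmax * concentration / (concentration + self.kd)

    def summary(self) -> str:
        def fmt(v, se):
            return f"{v:12.4g}" + (f"  (+/- {se:.3g})" if se is not None else "")

        return "\n".join(
            [
                "1:1 Langmuir binding kinetics (global fit)",
                "=" * 46,
                f"n sensograms  {self.n_sensograms}   at "
                + ", ".join(f"{c:.3g} M" for c in self.concentrations),
                f"kon   {fmt(self.kon, self.kon_stderr)}  M^-1 s^-1",
                f"koff  {fmt(self.koff, self.koff_stderr)}  s^-1",
                f"Rmax  {fmt(self.rmax, self.rmax_stderr)}  RU",
                f"K_D   {self.kd:12.4g}  M",
                f"R^2   {self.r_squared:12.6f}",
            ]
        )


class LangmuirKinetics:
    """Global 1:1 binding model over one or more sensograms.

    With more than one curve the analyte concentrations must be
    distinct; kon, koff and (by default) Rmax are shared across curves.
    """

    def __init__(self, sensograms: list[Sensogram], shared_rmax: bool = True):
        if not sensograms:
            raise DomainError("need at least one sensogram")
        concs = [s.concentration for s in sensograms]
        if len(sensograms) > 1 and len(set(concs)) != len(concs):
            raise DomainError("concentrations must be distinct for a global fit")
        self.sensograms = sensograms
        self.shared_rmax = shared_rmax

    def _initial_guesses(self) -> tuple[float, float, float]:
        koff0 = None
        for s in self.sensograms:
            try:
                k = koff_from_dissociation(s)
                if k > 0:
                    koff0 = k
                    break
            except InitFailure:
                continue
        if koff0 is None:
            koff0 = 1e-3
        # k_obs from the association tail: R_eq ~ max response in phase
        kobs, concs, reqs = [], [], []
        for s in self.sensograms:
            mask = s.association_mask
            t, r = s.time[mask], s.response[mask]
            r_eq = r.max()
            if r_eq <= 0:
                continue
            resid = r_eq * 1.02 - r  # 2% headroom keeps the log defined
            good = resid > 0.02 * r_eq
            if good.sum() >= 5:
                slope = -np.polyfit(t[good], np.log(resid[good]), 1)[0]
                if slope > 0:
                    kobs.append(slope)
                    concs.append(s.concentration)
                    reqs.append(r_eq)
        if kobs:
            kon0 = max(
                np.polyfit(concs, kobs, 1)[0] if len(kobs) > 1
                else (kobs[0] - koff0) / concs[0],
                1.0,
            )
            kd0 = koff0 / kon0
            rmax0 = max(reqs[0] * (concs[0] + kd0) / concs[0], reqs[0])
        else:
            kon0, rmax0 = 1e4, max(s.response.max() for s in self.sensograms)
        return kon0, koff0, rmax0

    def fit(self) -> BindingKineticsResults:
        kon0, koff0, rmax0 = self._initial_guesses()
        params = lmfit.Parameters()
        params.add("kon", value=kon0, min=1e-12)
        params.add("koff", value=koff0 if koff0 > 0 else 1e-4, min=1e-12)
        if self.shared_rmax:
            params.add("rmax", value=rmax0, min=1e-12)
        else:
            for i in range(len(self.sensograms)):
                params.add(f"rmax_{i}", value=rmax0, min=1e-12)

        def residual(p):
            out = []
            for i, s in enumerate(self.sensograms):
                rmax = p["rmax"] if self.shared_rmax else p[f"rmax_{i}"]
                model = langmuir_response(
                    s.time, s.concentration, p["kon"].value, p["koff"].value,
                    float(rmax), s.association_end,
                )
                out.append(model - s.response)
            return np.concatenate(out)

        minres = lmfit.minimize(residual, params)
        if not minres.success:
            raise FitFailure(
                f"global 1:1 fit did not converge (init kon={kon0:.3g}, "
                f"koff={koff0:.3g}, rmax={rmax0:.3g}): {minres.message}"
            )
        p = minres.params
        data = np.concatenate([s.response for s in self.sensograms])
        ss_res = float(np.sum(minres.residual**2))
        ss_tot = float(np.sum((data - data.mean()) ** 2))
        rmax_name = "rmax" if self.shared_rmax else "rmax_0"

        def se(name):
            err = p[name].stderr
            return float(err) if err is not None else None

        return BindingKineticsResults(
            kon=float(p["kon"].value),
            koff=float(p["koff"].value),
            rmax=float(p[rmax_name].value),
            kon_stderr=se("kon"),
            koff_stderr=se("koff"),
            rmax_stderr=se(rmax_name),
            r_squared=1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0,
            n_sensograms=len(self.sensograms),
            concentrations=[s.concentration for s in self.sensograms],
        )


def fit_global_1to1(
    sensograms: list[Sensogram], shared_rmax: bool = True
) -> BindingKineticsResults:
    """Globally fit the closed-form 1:1 model to >= 1 sensograms."""
    return LangmuirKinetics(sensograms, shared_rmax=shared_rmax).fit()


def compute_kd(kinetics_or_kon, koff: float | None = None) -> float:
    """K_D = koff / kon, from a results object or a (kon, koff) pair."""
    if koff is None:
        kon, koff = kinetics_or_kon.kon, kinetics_or_kon.koff
    else:
        kon = kinetics_or_kon
    if kon <= 0:
        raise DomainError("kon must be positive to form K_D")
    return koff / kon
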
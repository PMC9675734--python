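"""Distance-decay analysis of tunneling retraction curves.

The measured probe current decays (nearly) exponentially with the
retraction distance z from the set point down to the faradaic leakage
floor:

    I(z) = A * exp(-beta * z) + I_leak.

``ExponentialDecay`` fits one curve and returns the decay factor beta
(nm^-1) with diagnostics; ``BetaMixture`` models a population of beta
values as a 1- or 2-component Gaussian mixture selected by BIC;
``beta_vs_gate`` aggregates beta against the electrochemical gate
potential; ``compare_groups`` is the pooled two-sample t-test used to
compare conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from .datatypes import ProbeRetractionCurve
from .exceptions import FitFailure, InsufficientData, NoDecayRegion

__all__ = [
    "ExponentialDecay",
    "DecayFitResults",
    "fit_decay",
    "BetaMixture",
    "BetaPopulationResults",
    "fit_beta_population",
    "beta_vs_gate",
    "compare_groups",
]


@dataclass
class DecayFitResults:
    """Result of a single-curve exponential decay fit."""

    beta: float  # nm^-1
    amplitude: float  # nA
    leakage: float  # nA
    beta_stderr: float | None
    fit_window: tuple[float, float]  # (z_start, z_end) nm
    r_squared: float
    n_points_used: int
    flagged: bool  # r^2 below the quality threshold

    def summary(self) -> str:
        lines = [
            "Exponential decay fit",
            "=" * 42,
            f"beta           {self.beta:10.4f}  nm^-1"
            + (f"  (+/- {self.beta_stderr:.4f})" if self.beta_stderr else ""),
            f"amplitude      {self.amplitude:10.4f}  nA",
            f"leakage        {self.leakage:10.5f}  nA",
            f"fit window     {self.fit_window[0]:.3f} - {self.fit_window[1]:.3f} nm"
            f"  ({self.n_points_used} points)",
            f"R^2            {self.r_squared:10.4f}"
            + ("  [flagged]" if self.flagged else ""),
        ]
        return "\n".join(lines)


class ExponentialDecay:
    """Model of a single I-z retraction curve.

    Parameters
    ----------
    curve:
        The retraction recording.
    leakage:
        ``"auto"`` (median of the final 10% of points) or a value in nA
        used to initialize the leakage parameter and set the window
        threshold.
    skip_initial:
        Points excluded at the start of the curve (feedback-off
        transient).
    r2_flag_threshold:
        Fits with R^2 below this value are flagged (never dropped).
    """

    def __init__(
        self,
        curve: ProbeRetractionCurve,
        leakage: float | str = "auto",
        skip_initial: int = 2,
        r2_flag_threshold: float = 0.8,
    ):
        self.curve = curve
        self.skip_initial = int(skip_initial)
        self.r2_flag_threshold = r2_flag_threshold
        if leakage == "auto":
            tail = max(5, curve.current.size // 10)
            self.leakage_estimate = float(np.median(curve.current[-tail:]))
        else:
            self.leakage_estimate = float(leakage)

    def _exponential_window(self) -> np.ndarray:
        """Indices of the contiguous run of points above 3x leakage,
        starting after the feedback-off transient."""
        current = self.curve.current
        threshold = 3.0 * max(self.leakage_estimate, 0.0)
        above = current > threshold
        start = self.skip_initial
        if start >= current.size or not above[start]:
            raise NoDecayRegion(
                "no current above 3x the estimated leakage floor"
            )
        end = start
        while end < current.size and above[end]:
            end += 1
        idx = np.arange(start, end)
        if idx.size < 8:
            raise NoDecayRegion(
                f"exponential window has only {idx.size} points (need >= 8)"
            )
        return idx

    def fit(self) -> DecayFitResults:
        idx = self._exponential_window()
        z = self.curve.z[idx]
        current = self.curve.current[idx]
        leak0 = max(self.leakage_estimate, 0.0)

        # log-linear initializer on (I - leakage)
        resid0 = np.clip(current - leak0, 1e-12, None)
        slope, intercept = np.polyfit(z, np.log(resid0), 1)
        beta0 = max(-slope, 1e-3)
        amp0 = max(np.exp(intercept), 1e-9)

        model = lmfit.Model(lambda z, amplitude, beta, leakage:
                            amplitude * np.exp(-beta * z) + leakage)
        params = model.make_params(
            amplitude=dict(value=amp0, min=0),
            beta=dict(value=beta0, min=1e-6),
            leakage=dict(value=leak0, min=0),
        )
        beta_stderr = None
        try:
            res = model.fit(current, params, z=z)
            if not res.success:
                raise FitFailure(res.message)
            beta = float(res.params["beta"].value)
            amplitude = float(res.params["amplitude"].value)
            leakage = float(res.params["leakage"].value)
            beta_stderr = (
                float(res.params["beta"].stderr)
                if res.params["beta"].stderr is not None
                else None
            )
            fitted = res.best_fit
        except FitFailure:
            # fall back to the log-linear regression with leakage fixed
            beta, amplitude, leakage = beta0, amp0, leak0
            fitted = amplitude * np.exp(-beta * z) + leakage

        ss_res = float(np.sum((current - fitted) ** 2))
        ss_tot = float(np.sum((current - current.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        r2 = min(max(r2, 0.0), 1.0)
        return DecayFitResults(
            beta=beta,
            amplitude=amplitude,
            leakage=leakage,
            beta_stderr=beta_stderr,
            fit_window=(float(z[0]), float(z[-1])),
            r_squared=r2,
            n_points_used=idx.size,
            flagged=r2 < self.r2_flag_threshold,
        )


def fit_decay(
    curve: ProbeRetractionCurve, leakage_hint: float | str = "auto", **kwargs
) -> DecayFitResults:
    """Fit I(z) = A exp(-beta z) + I_leak to one retraction curve."""
    return ExponentialDecay(curve, leakage=leakage_hint, **kwargs).fit()


@dataclass
class BetaPopulationResults:
    """Gaussian-mixture model of a beta population."""

    n_components: int
    centers: np.ndarray  # nm^-1, ascending
    widths: np.ndarray  # s.d., nm^-1
    weights: np.ndarray  # sum to 1
    bic_per_model: dict[int, float]

    def summary(self) -> str:
        lines = [
            f"Beta population: {self.n_components} component(s)",
            "=" * 42,
        ]
        for c, w, wt in zip(self.centers, self.widths, self.weights):
            lines.append(
                f"  center {c:6.3f} nm^-1   sd {w:6.3f} nm^-1   weight {wt:5.2f}"
            )
        for k, b in sorted(self.bic_per_model.items()):
            lines.append(f"  BIC[{k} comp] = {b:.2f}")
        return "\n".join(lines)


class BetaMixture:
    """1- vs 2-component Gaussian mixture of per-curve beta values,
    selected by BIC (fitted on the raw values, not a histogram)."""

    def __init__(self, betas, min_n: int = 20):
        self.betas = np.asarray(betas, dtype=float).ravel()
        if self.betas.size < min_n:
            raise InsufficientData(
                f"need at least {min_n} beta values, got {self.betas.size}"
            )

    def fit(self, max_components: int = 2, random_state: int = 0) -> BetaPopulationResults:
        x = self.betas.reshape(-1, 1)
        if np.ptp(self.betas) == 0:
            # degenerate: all values identical
            return BetaPopulationResults(
                n_components=1,
                centers=np.array([self.betas[0]]),
                widths=np.array([0.0]),
                weights=np.array([1.0]),
                bic_per_model={1: -np.inf},
            )
        bics: dict[int, float] = {}
        models: dict[int, GaussianMixture] = {}
        for k in range(1, max_components + 1):
            gm = GaussianMixture(
                n_components=k, n_init=5, random_state=random_state
            ).fit(x)
            bics[k] = float(gm.bic(x))
            models[k] = gm
        best_k = min(bics, key=bics.get)
        gm = models[best_k]
        centers = gm.means_.ravel()
        widths = np.sqrt(gm.covariances_.ravel())
        weights = gm.weights_.ravel()
        order = np.argsort(centers)
        return BetaPopulationResults(
            n_components=best_k,
            centers=centers[order],
            widths=widths[order],
            weights=weights[order],
            bic_per_model=bics,
        )


def fit_beta_population(betas, max_components: int = 2) -> BetaPopulationResults:
    """Mixture-model a collection of beta values (>= 20 required)."""
    return BetaMixture(betas).fit(max_components=max_components)


def beta_vs_gate(
    curves: list[ProbeRetractionCurve],
    leakage: float | str = "auto",
    gate_decimals: int = 6,
) -> pd.DataFrame:
    """Per-gate mean +/- s.d. of per-curve beta.

    Curves are grouped by their gate potential (-U_S); groups with fewer
    than two curves are dropped.  The returned frame is sorted by gate
    and carries the gate of minimum mean beta in ``df.attrs``.
    """
    if not curves:
        raise InsufficientData("no curves supplied")
    rows = []
    for curve in curves:
        fit = fit_decay(curve, leakage_hint=leakage)
        rows.append({"gate": round(curve.gate, gate_decimals), "beta": fit.beta})
    df = pd.DataFrame(rows)
    grouped = (
        df.groupby("gate")["beta"]
        .agg(beta_mean="mean", beta_sd="std", n="count")
        .reset_index()
    )
    grouped = grouped[grouped["n"] >= 2].sort_values("gate").reset_index(drop=True)
    if grouped.empty:
        raise InsufficientData("no gate group has >= 2 curves")
    grouped.attrs["gate_of_min_beta"] = float(
        grouped.loc[grouped["beta_mean"].idxmin(), "gate"]
    )
    return grouped


def compare_groups(a, b) -> tuple[float, int, float]:
    """Student (pooled-variance) two-sample t-test.

    Returns (t statistic, degrees of freedom n_a + n_b - 2, two-sided p).
    With zero variance in both groups and equal means, t = 0 by
    convention.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise InsufficientData("each group needs at least 2 values")
    df = a.size + b.size - 2
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        return np.inf * np.sign(a.mean() - b.mean()), df, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), df, float(p)
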
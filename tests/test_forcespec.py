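"""Force spectroscopy: rupture detection, Bell-Evans closed form and its
exact inversion, regime classification, and Monte-Carlo recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from redoxkit import forcespec
from redoxkit.datatypes import ForceCurve, RuptureEvent
from redoxkit.exceptions import DomainError, InsufficientData
from redoxkit.simulate import ForceGenConfig, GaussianRupture, gen_force_curves


def sawtooth_curve(f_r=55.0, l_r=12.0, k=56.0, span=30.0, n=2000, noise=0.0, seed=0):
    s = np.linspace(0, span, n)
    force = np.zeros_like(s)
    s_start = l_r - f_r / k
    ramp = (s >= s_start) & (s < l_r)
    force[ramp] = -k * (s[ramp] - s_start)
    if noise > 0:
        force += noise * np.random.default_rng(seed).standard_normal(n)
    return ForceCurve(separation=s, force=force, pulling_velocity=1.0,
                      cantilever_stiffness=k)


class TestDetectRuptures:
    def test_single_sawtooth(self):
        events = forcespec.detect_ruptures(sawtooth_curve(noise=0.5))
        assert len(events) == 1
        assert events[0].rupture_force == pytest.approx(55.0, abs=1.5)
        assert events[0].rupture_length == pytest.approx(12.0, abs=0.1)

    def test_smooth_adhesion_ramp_yields_no_events(self):
        s = np.linspace(0, 30, 2000)
        force = -20.0 * np.exp(-((s - 10) / 4.0) ** 2)  # smooth bump, no jump
        curve = ForceCurve(separation=s, force=force, pulling_velocity=1.0,
                           cantilever_stiffness=56.0)
        assert forcespec.detect_ruptures(curve) == []

    def test_median_loading_rate_matches_k_times_v(self):
        cfg = ForceGenConfig(n_curves=100, seed=1)
        events = [
            e for c in gen_force_curves(cfg) for e in forcespec.detect_ruptures(c)
        ]
        median_rate = np.median([e.loading_rate for e in events])
        assert median_rate == pytest.approx(56_000.0, rel=0.05)

    def test_detection_completeness_above_5_sigma(self):
        """Ruptures well above the noise floor are essentially all found,
        with small force error."""
        noise = 4.0
        cfg = ForceGenConfig(
            rupture_model=GaussianRupture(60.0, 8.0), noise_sd=noise,
            n_curves=150, seed=5,
        )
        curves = gen_force_curves(cfg)
        n_true, n_found, errors, l_true, l_found = 0, 0, [], [], []
        for c in curves:
            truth = c.metadata
            events = forcespec.detect_ruptures(c)
            if truth["has_event"]:
                n_true += 1
                l_true.append(truth["rupture_length_true"])
                if events:
                    n_found += 1
                    best = min(
                        events,
                        key=lambda e: abs(e.rupture_force - truth["rupture_force_true"]),
                    )
                    errors.append(best.rupture_force - truth["rupture_force_true"])
                    l_found.append(best.rupture_length)
        assert n_found / n_true >= 0.99
        assert np.median(np.abs(errors)) < noise
        # recovered rupture-length distribution matches the generator truth
        assert stats.ks_2samp(l_true, l_found).pvalue > 0.01


class TestMostProbableForce:
    @pytest.mark.parametrize(
        "rate,expected", [(28_000.0, 50.2), (224_000.0, 77.8)]
    )
    def test_closed_form_values(self, rate, expected):
        f = forcespec.most_probable_force(48.0, 0.31, rate)
        assert f == pytest.approx(expected, abs=0.05)

    def test_spontaneous_regime_returns_zero(self):
        from redoxkit.constants import KBT_298_PN_NM

        r = 48.0 * KBT_298_PN_NM / 0.31  # ln argument exactly 1
        assert forcespec.most_probable_force(48.0, 0.31, r) == pytest.approx(
            0.0, abs=1e-9
        )
        assert forcespec.most_probable_force(48.0, 0.31, r / 2) == 0.0

    def test_non_positive_arguments_rejected(self):
        with pytest.raises(DomainError):
            forcespec.most_probable_force(-1.0, 0.31, 1e4)


class TestBellEvansFit:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        k0=st.floats(0.1, 500.0),
        x_u=st.floats(0.05, 2.0),
        scale=st.floats(0.5, 10.0),
    )
    def test_round_trip_is_identity(self, k0, x_u, scale):
        """bell_evans_fit inverts most_probable_force exactly for any
        parameters producing forces in the kinetic regime."""
        rates = scale * np.array([28_000.0, 56_000.0, 112_000.0, 224_000.0])
        forces = [forcespec.most_probable_force(k0, x_u, r) for r in rates]
        if min(forces) <= 0:
            return  # spontaneous regime: no line to invert
        res = forcespec.bell_evans_fit(list(zip(rates, forces)))
        assert res.k0_u == pytest.approx(k0, rel=1e-8)
        assert res.x_u == pytest.approx(x_u, rel=1e-8)
        assert res.regime == "kinetic"

    def test_flat_forces_classified_near_equilibrium(self):
        pts = [(r, 55.0) for r in (28e3, 56e3, 112e3, 224e3)]
        res = forcespec.bell_evans_fit(pts)
        assert res.regime == "near_equilibrium"

    def test_negative_slope_leaves_parameters_undefined(self):
        pts = [(28e3, 80.0), (56e3, 70.0), (112e3, 60.0), (224e3, 50.0)]
        res = forcespec.bell_evans_fit(pts)
        assert res.regime == "near_equilibrium"
        assert np.isnan(res.k0_u) and np.isnan(res.x_u)

    def test_noisy_recovery_within_20_percent(self):
        """With 2 pN force noise the recovered parameters stay near truth
        in the typical (median over seeds) case; k0 is exponentially
        sensitive to the intercept so its band is wider."""
        rates = np.array([28e3, 56e3, 112e3, 224e3])
        clean = np.array(
            [forcespec.most_probable_force(48.0, 0.31, r) for r in rates]
        )
        x_errs, k_errs = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            forces = clean + 2.0 * rng.standard_normal(4)
            res = forcespec.bell_evans_fit(list(zip(rates, forces)))
            x_errs.append(abs(res.x_u / 0.31 - 1))
            k_errs.append(abs(res.k0_u / 48.0 - 1))
        assert np.median(x_errs) < 0.20
        assert np.median(k_errs) < 0.75

    def test_two_rates_rejected(self):
        with pytest.raises(InsufficientData):
            forcespec.bell_evans_fit([(28e3, 50.0), (56e3, 60.0)])


class TestForceDistribution:
    def test_gaussian_centers_recovered(self):
        for center, width, seed in [(55.0, 17.0, 1), (77.0, 24.0, 3)]:
            cfg = ForceGenConfig(
                rupture_model=GaussianRupture(center, width), n_curves=200, seed=seed
            )
            events = [
                e for c in gen_force_curves(cfg) for e in forcespec.detect_ruptures(c)
            ]
            dist = forcespec.force_distribution(events)
            assert dist.center == pytest.approx(center, rel=0.10)
            assert dist.mean == pytest.approx(center, rel=0.10)

    def test_delta_distribution(self):
        events = [RuptureEvent(100.0, 12.0, 56e3) for _ in range(40)]
        dist = forcespec.force_distribution(events)
        assert dist.center == 100.0
        assert dist.mean == 100.0
        assert dist.width == 0.0

    def test_too_few_events_rejected(self):
        with pytest.raises(InsufficientData):
            forcespec.force_distribution([RuptureEvent(55.0, 12.0, 56e3)] * 10)


class TestRegimeAndMaps:
    def test_classify_regime_matches_fit(self):
        pts = [
            (r, forcespec.most_probable_force(48.0, 0.31, r))
            for r in (28e3, 56e3, 112e3, 224e3)
        ]
        fit = forcespec.bell_evans_fit(pts)
        assert forcespec.classify_regime(fit) == "kinetic"

    def test_density_map_peaks_near_the_data(self):
        rng = np.random.default_rng(0)
        events = [
            RuptureEvent(55 + 5 * rng.standard_normal(), 12 + rng.standard_normal(), 56e3)
            for _ in range(100)
        ]
        L, F, dens = forcespec.rupture_density_map(events)
        imax = np.unravel_index(np.argmax(dens), dens.shape)
        assert L[imax] == pytest.approx(12.0, abs=2.0)
        assert F[imax] == pytest.approx(55.0, abs=6.0)
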
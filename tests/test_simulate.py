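"""Generator-level checks: closed-form values, dwell statistics,
rupture-force sampling, sensogram kinetics, and seeded determinism."""

import numpy as np
import pytest
from scipy import stats

from redoxkit.constants import G0_SIEMENS, KBT_298_PN_NM
from redoxkit.exceptions import ConfigurationError
from redoxkit.simulate import (
    BellEvansRupture,
    BlinkGenConfig,
    ForceGenConfig,
    GaussianRupture,
    IZGenConfig,
    SPRGenConfig,
    gen_blink_trace,
    gen_force_curves,
    gen_iz_ensemble,
    gen_sensogram,
    sample_bell_evans_forces,
)


class TestIZGenerator:
    def test_noiseless_curve_matches_closed_form(self):
        # I(1 nm) = 0.4 e^{-1.3} + 0.002 = 0.1110 nA
        cfg = IZGenConfig(
            beta_components=[(1.3, 1.0)],
            noise_fraction=0.0,
            retraction_length=2.0,
            points_per_curve=3,
            n_curves=1,
            seed=0,
        )
        curve = gen_iz_ensemble(cfg)[0]
        assert curve.z[1] == 1.0
        assert curve.current[1] == pytest.approx(0.4 * np.exp(-1.3) + 0.002, rel=1e-12)
        assert curve.current[1] == pytest.approx(0.1110, abs=5e-5)

    def test_mixture_component_fractions(self):
        cfg = IZGenConfig(
            beta_components=[(1.3, 0.22, 0.2), (3.1, 0.78, 0.4)],
            points_per_curve=16,
            n_curves=2000,
            seed=7,
        )
        comps = np.array([c.metadata["component"] for c in gen_iz_ensemble(cfg)])
        assert np.mean(comps == 0) == pytest.approx(0.22, abs=0.03)

    def test_ground_truth_in_metadata(self):
        curve = gen_iz_ensemble(IZGenConfig(n_curves=1, seed=3))[0]
        assert curve.metadata["beta_true"] > 0
        assert curve.metadata["leakage_true"] == 0.002

    @pytest.mark.parametrize(
        "bad",
        [
            dict(retraction_length=0.0),
            dict(beta_components=[(1.3, 0.5)]),  # weights must sum to 1
            dict(beta_components=[(-1.0, 1.0)]),
            dict(leakage_current=0.5),  # above set point
            dict(points_per_curve=1),
        ],
    )
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            IZGenConfig(**bad)

    def test_seeded_determinism(self):
        a = gen_iz_ensemble(IZGenConfig(n_curves=3, seed=42))
        b = gen_iz_ensemble(IZGenConfig(n_curves=3, seed=42))
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.current, cb.current)


class TestBlinkGenerator:
    def test_blink_amplitude_arithmetic(self):
        # dI = G * G0 * V = 4.3e-6 * 77.5 uS * 0.8 V = 0.267 nA
        trace = gen_blink_trace(BlinkGenConfig(noise_sd=0.0, seed=1))
        amp = trace.metadata["amplitude_true"]
        assert amp == pytest.approx(4.3e-6 * G0_SIEMENS * 0.8 * 1e9, rel=1e-12)
        assert amp == pytest.approx(0.267, abs=1e-3)
        in_blink = trace.current.max()
        assert in_blink == pytest.approx(0.33 + amp, rel=1e-9)

    def test_infinite_interblink_time_gives_flat_trace(self):
        cfg = BlinkGenConfig(mean_interblink_time=np.inf, noise_sd=0.0, seed=0)
        trace = gen_blink_trace(cfg)
        assert trace.metadata["events_true"] == []
        assert np.all(trace.current == 0.33)

    def test_lifetimes_are_exponential_with_configured_mean(self):
        cfg = BlinkGenConfig(trace_duration=120.0, noise_sd=0.0, seed=5)
        trace = gen_blink_trace(cfg)
        lifetimes = np.array([lt for _, lt in trace.metadata["events_true"]])
        assert lifetimes.size > 200
        assert lifetimes.mean() == pytest.approx(
            cfg.mean_blink_lifetime,
            abs=4 * cfg.mean_blink_lifetime / np.sqrt(lifetimes.size),
        )

    def test_undersampled_blinks_warn(self):
        with pytest.warns(UserWarning):
            BlinkGenConfig(sampling_rate=100.0, mean_blink_lifetime=0.01)

    def test_seeded_determinism(self):
        a = gen_blink_trace(BlinkGenConfig(seed=9))
        b = gen_blink_trace(BlinkGenConfig(seed=9))
        np.testing.assert_array_equal(a.current, b.current)


class TestForceGenerator:
    def test_bell_evans_sampling_matches_analytic_distribution(self):
        k0, x_u, r = 48.0, 0.31, 224_000.0
        rng = np.random.default_rng(0)
        forces = sample_bell_evans_forces(k0, x_u, r, 20_000, rng=rng)
        a = x_u / KBT_298_PN_NM
        c = k0 * KBT_298_PN_NM / (x_u * r)
        cdf = lambda f: 1.0 - np.exp(-c * np.expm1(a * np.clip(f, 0, None)))  # noqa: E731
        assert stats.kstest(forces, cdf).pvalue > 0.01
        # mode at the most probable force, 77.8 pN
        f_star = (KBT_298_PN_NM / x_u) * np.log(x_u * r / (k0 * KBT_298_PN_NM))
        assert f_star == pytest.approx(77.8, abs=0.05)
        kde = stats.gaussian_kde(forces)
        grid = np.linspace(forces.min(), forces.max(), 400)
        mode = grid[np.argmax(kde(grid))]
        assert mode == pytest.approx(f_star, abs=3.0)

    def test_gaussian_rupture_sample_mean(self):
        cfg = ForceGenConfig(
            rupture_model=GaussianRupture(55.0, 17.0), n_curves=400, seed=2
        )
        truths = [
            c.metadata["rupture_force_true"]
            for c in gen_force_curves(cfg)
            if c.metadata["has_event"]
        ]
        assert np.mean(truths) == pytest.approx(55.0, abs=3.0)

    def test_fraction_with_event_zero(self):
        cfg = ForceGenConfig(fraction_with_event=0.0, n_curves=20, seed=3)
        assert not any(c.metadata["has_event"] for c in gen_force_curves(cfg))

    def test_loading_rate_is_stiffness_times_velocity(self):
        cfg = ForceGenConfig(pulling_velocity=4.0, effective_stiffness=56.0)
        assert cfg.loading_rate == pytest.approx(224_000.0)

    def test_bell_evans_model_accepted(self):
        cfg = ForceGenConfig(
            rupture_model=BellEvansRupture(48.0, 0.31), n_curves=5, seed=1
        )
        curves = gen_force_curves(cfg)
        assert len(curves) == 5

    def test_seeded_determinism(self):
        a = gen_force_curves(ForceGenConfig(n_curves=3, seed=11))
        b = gen_force_curves(ForceGenConfig(n_curves=3, seed=11))
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.force, cb.force)


class TestSPRGenerator:
    def test_half_saturation_at_kd(self):
        kon, koff = 1.0e4, 3.58e-3
        kd = koff / kon
        cfg = SPRGenConfig(
            kon=kon, koff=koff, rmax=100.0, concentrations=[kd],
            association_duration=20_000.0, dissociation_duration=0.0,
            time_step=10.0, seed=0,
        )
        s = gen_sensogram(cfg)[0]
        assert s.response[s.association_mask][-1] == pytest.approx(50.0, rel=1e-3)

    def test_observed_association_rate(self):
        # k_obs = kon*C + koff = 1.00e4 * 5e-6 + 3.58e-3 = 0.0536 1/s,
        # recovered here by log-linear regression on the association phase
        cfg = SPRGenConfig(kon=1.0e4, koff=3.58e-3, concentrations=[5e-6], seed=0)
        s = gen_sensogram(cfg)[0]
        mask = s.association_mask
        t, r = s.time[mask], s.response[mask]
        r_eq = 100.0 * 5e-6 / (5e-6 + 3.58e-7)
        resid = r_eq - r
        good = resid > 1e-3 * r_eq
        slope = -np.polyfit(t[good], np.log(resid[good]), 1)[0]
        assert slope == pytest.approx(0.0536, abs=2e-4)

    def test_dissociation_decays_to_zero(self):
        cfg = SPRGenConfig(
            dissociation_duration=20_000.0, time_step=20.0, seed=0
        )
        for s in gen_sensogram(cfg):
            assert s.response[-1] < 1e-6 * s.response.max()

    def test_seeded_determinism_with_noise(self):
        a = gen_sensogram(SPRGenConfig(noise_sd=1.0, seed=8))
        b = gen_sensogram(SPRGenConfig(noise_sd=1.0, seed=8))
        np.testing.assert_array_equal(a[0].response, b[0].response)
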
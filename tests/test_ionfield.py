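"""Ion maps, screened electrostatics, Boltzmann-sampled frames, and
Brownian association rates against the quadrature oracle."""

import numpy as np
import pytest

from redoxkit import ionfield
from redoxkit.constants import AVOGADRO, debye_length_nm
from redoxkit.datatypes import DensityGrid, IonTrajectory, PrismSpec
from redoxkit.exceptions import (
    ConfigurationError,
    InvalidGrid,
    OutOfBounds,
    PathologicalField,
    StepTooLarge,
)
from redoxkit.simulate import IonGenConfig, gen_ion_frames

TWO_NEG_SITES = [((3.0, 3.0, 1.4), -1.0), ((3.0, 3.0, 4.6), -1.0)]
BETWEEN_PRISM = PrismSpec(center=(30.0, 30.0, 30.0), edge_lengths=(15.0, 15.0, 20.0))


class TestDensityMap:
    def test_single_pinned_ion_molarity(self):
        # 1 ion always inside one (10 Å)^3 voxel -> 1.661 M there
        traj = IonTrajectory(
            frames=[np.array([[5.0, 5.0, 5.0]])] * 4, box_dimensions=(10, 10, 10)
        )
        grid = ionfield.density_map(traj, voxel_edge=10.0)
        assert grid.values.max() == pytest.approx(1.661, abs=1e-3)
        assert np.count_nonzero(grid.values) == 1

    def test_mean_ion_count_is_conserved(self):
        rng = np.random.default_rng(0)
        frames = [rng.uniform(0, 50, size=(rng.integers(5, 15), 3)) for _ in range(20)]
        traj = IonTrajectory(frames=frames, box_dimensions=(50, 50, 50))
        grid = ionfield.density_map(traj, voxel_edge=5.0)
        total = grid.values.sum() * grid.voxel_volume_L * AVOGADRO
        mean_n = np.mean([f.shape[0] for f in frames])
        assert total == pytest.approx(mean_n, rel=1e-12)

    def test_empty_frames_give_zero_grid(self):
        traj = IonTrajectory(frames=[np.empty((0, 3))] * 3, box_dimensions=(10, 10, 10))
        assert ionfield.density_map(traj, voxel_edge=2.0).values.sum() == 0.0

    def test_oversized_voxel_rejected(self):
        traj = IonTrajectory(frames=[np.empty((0, 3))], box_dimensions=(10, 10, 10))
        with pytest.raises(InvalidGrid):
            ionfield.density_map(traj, voxel_edge=20.0)


class TestPrismAverage:
    def test_printed_prism_volume(self):
        prism = PrismSpec(center=(0, 0, 0), edge_lengths=(15, 43, 20))
        assert prism.volume_nm3 == pytest.approx(12.9)

    def test_uniform_grid_average(self):
        grid = DensityGrid(origin=np.zeros(3), voxel_edge=2.0,
                           values=np.full((10, 10, 10), 0.05))
        assert ionfield.prism_average(grid, PrismSpec((10, 10, 10), (7, 9, 5))) == (
            pytest.approx(0.05)
        )

    def test_single_voxel_prism_returns_voxel_value(self):
        values = np.zeros((4, 4, 4))
        values[1, 2, 3] = 0.7
        grid = DensityGrid(origin=np.zeros(3), voxel_edge=1.0, values=values)
        prism = PrismSpec(center=(1.5, 2.5, 3.5), edge_lengths=(1, 1, 1))
        assert ionfield.prism_average(grid, prism) == pytest.approx(0.7)

    def test_out_of_bounds_prism_rejected(self):
        grid = DensityGrid(origin=np.zeros(3), voxel_edge=1.0, values=np.zeros((4, 4, 4)))
        with pytest.raises(OutOfBounds):
            ionfield.prism_average(grid, PrismSpec((10, 0, 0), (2, 2, 2)))


class TestDebyeHuckel:
    def test_debye_length_at_50_mM(self):
        assert debye_length_nm(0.05) == pytest.approx(1.36, abs=0.01)

    def test_sign_flip_negates_field_exactly(self):
        field_pos = ionfield.dh_field([((30, 30, 30), 1.0)], 0.05, shape=(20, 20, 20))
        field_neg = ionfield.dh_field([((30, 30, 30), -1.0)], 0.05, shape=(20, 20, 20))
        np.testing.assert_allclose(
            np.nan_to_num(field_pos.values), -np.nan_to_num(field_neg.values)
        )

    def test_zero_ionic_strength_reduces_to_coulomb(self):
        pt = np.array([[1.0, 0.0, 0.0]])
        charges = [((0.0, 0.0, 0.0), 1.0)]
        screened = ionfield.dh_potential_at(pt, charges, 1e-14)
        coulomb = ionfield.dh_potential_at(pt, charges, 0.0)
        assert screened[0] == pytest.approx(coulomb[0], rel=1e-6)

    def test_charge_site_voxels_flagged(self):
        field = ionfield.dh_field([((10.0, 10.0, 10.0), 1.0)], 0.05, shape=(20, 20, 20))
        assert np.isnan(field.values).any()

    def test_contour_levels_follow_spacing(self):
        field = ionfield.dh_field([((10.0, 10.0, 10.0), 1.0)], 0.05, shape=(8, 8, 8))
        levels = field.contour_levels(-1.0, 1.0)
        assert np.allclose(np.diff(levels), 0.2)


class TestIonGenerator:
    def test_uniform_sampling_recovers_bulk(self):
        cfg = IonGenConfig(site_charges=[], n_frames=400, seed=1)
        traj = gen_ion_frames(cfg)
        grid = ionfield.density_map(traj, voxel_edge=10.0)
        n = traj.metadata["n_ions_per_frame"]
        expected = n / (AVOGADRO * np.prod(cfg.box_dimensions) * 1e-24)
        assert grid.values.mean() == pytest.approx(expected, rel=0.02)

    def test_zero_bulk_concentration_gives_empty_frames(self):
        traj = gen_ion_frames(IonGenConfig(bulk_concentration=0.0, n_frames=3, seed=0))
        assert all(f.shape == (0, 3) for f in traj.frames)

    def test_depletion_vs_accumulation_between_sites(self):
        """Two like-charged (+1) sites deplete cations in the gap; two
        negative sites accumulate them above bulk."""
        bulk = {}
        for label, q in (("repulsive", 1.0), ("attractive", -1.0)):
            charges = [((3.0, 3.0, 1.4), q), ((3.0, 3.0, 4.6), q)]
            cfg = IonGenConfig(site_charges=charges, n_frames=400, seed=4)
            traj = gen_ion_frames(cfg)
            grid = ionfield.density_map(traj, voxel_edge=5.0)
            n = traj.metadata["n_ions_per_frame"]
            c_bulk = n / (AVOGADRO * np.prod(cfg.box_dimensions) * 1e-24)
            bulk[label] = ionfield.prism_average(grid, BETWEEN_PRISM) / c_bulk
        assert bulk["repulsive"] < 1.0
        assert bulk["attractive"] > 1.0

    def test_boltzmann_consistency_slope(self):
        """ln(c/c_bulk) regresses on q*phi with slope -1 in the
        well-sampled moderate-field region."""
        cfg = IonGenConfig(site_charges=TWO_NEG_SITES, n_frames=4000, seed=3)
        traj = gen_ion_frames(cfg)
        slope = ionfield.boltzmann_consistency_slope(
            traj, TWO_NEG_SITES, cfg.bulk_concentration
        )
        assert slope == pytest.approx(-1.0, abs=0.1)

    def test_pathological_field_raises(self):
        cfg = IonGenConfig(
            site_charges=[((3.0, 3.0, 3.0), -40.0)], n_frames=2, seed=0
        )
        with pytest.raises(PathologicalField):
            gen_ion_frames(cfg)

    def test_seeded_determinism(self):
        a = gen_ion_frames(IonGenConfig(n_frames=3, seed=6))
        b = gen_ion_frames(IonGenConfig(n_frames=3, seed=6))
        for fa, fb in zip(a.frames, b.frames):
            np.testing.assert_array_equal(fa, fb)


class TestBrownianRates:
    D = 1e-9  # m^2/s

    def test_smoluchowski_closed_form(self):
        # k(0.6 nm) = 4 pi D d N_A = 4.54e9 M^-1 s^-1
        k = ionfield.diffusion_limited_rate(0.6, self.D)
        assert k == pytest.approx(4.54e9, rel=1e-3)

    def test_bd_matches_quadrature_oracle_free_diffusion(self):
        distances = [0.6, 1.0, 1.5, 2.5]
        rc = ionfield.bd_rate_curve(
            None, self.D, b_surface_nm=5.0, q_surface_nm=20.0,
            reaction_distances_nm=distances, n_trajectories=1500, seed=4,
        )
        for d, k, se in zip(rc.reaction_distances, rc.rates, rc.rate_errors):
            oracle = ionfield.diffusion_limited_rate(d, self.D)
            assert abs(k - oracle) < 3 * se

    def test_bd_matches_oracle_with_screened_attraction(self):
        def u(r):
            r = np.atleast_1d(np.asarray(r, dtype=float))
            return -2.0 * 0.7 * np.exp(-r / 1.36) / r  # kT units

        rc = ionfield.bd_rate_curve(
            u, self.D, 5.0, 20.0, [0.6, 1.5], n_trajectories=1200, seed=5
        )
        for d, k, se in zip(rc.reaction_distances, rc.rates, rc.rate_errors):
            oracle = ionfield.diffusion_limited_rate(d, self.D, u)
            assert abs(k - oracle) < 3 * se
            # attraction strictly accelerates association
            assert k > ionfield.diffusion_limited_rate(d, self.D)

    def test_rates_non_increasing_with_stricter_criterion(self):
        rc = ionfield.bd_rate_curve(
            None, self.D, 5.0, 15.0, [0.6, 1.0, 2.0], n_trajectories=800, seed=6
        )
        assert np.all(np.diff(rc.rates) >= 0)  # sorted ascending in distance
        assert rc.k_on_at_contact <= rc.k_trigger

    def test_step_too_large_for_singular_potential(self):
        def u(r):
            r = np.atleast_1d(np.asarray(r, dtype=float))
            return -1e6 / r**6

        with pytest.raises(StepTooLarge):
            ionfield.bd_rate_curve(u, self.D, 5.0, 15.0, [0.6], n_trajectories=10, seed=0)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ConfigurationError):
            ionfield.bd_rate_curve(None, self.D, 5.0, 4.0, [0.6], n_trajectories=10)
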
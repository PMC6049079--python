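import numpy as np
import pytest

from conftest import KB, KF_EXPR
from ecsrd.grid import build_grid
from ecsrd.kinetics import RateTerm, Reaction, Species
from ecsrd.solver import PointSource, Simulation, face_coefficient


class TestFaceCoefficient:
    def test_homogeneous_reduction(self):
        assert face_coefficient(0.2, 1.0234, 0.2, 1.0234) == pytest.approx(
            0.2 * 1.0234
        )

    def test_blocked_face(self):
        assert face_coefficient(0.0, 1.0, 0.2, 1.0) == 0.0
        assert face_coefficient(0.2, 0.0, 0.2, 1.0) == 0.0

    def test_harmonic_mean_of_alpha(self):
        got = face_coefficient(0.07, 1.0, 0.2, 1.0)
        assert got == pytest.approx(2 * 0.07 * 0.2 / 0.27)

    def test_symmetry(self):
        assert face_coefficient(0.1, 2.0, 0.3, 0.5) == face_coefficient(
            0.3, 0.5, 0.1, 2.0
        )


class TestDiffusionStep:
    def test_uniform_field_is_fixed_point(self, hetero_grid):
        sim = Simulation(hetero_grid, [Species("k", d=2.62, initial=3.5)],
                         dt=1.0)
        sim.diffusion_step()
        assert np.max(np.abs(sim.by_name["k"].conc - 3.5)) < 1e-13

    def test_uniform_dirichlet_fixed_point(self, hetero_grid):
        sim = Simulation(hetero_grid,
                         [Species("k", d=2.62, initial=3.5, boundary=3.5)],
                         dt=1.0)
        sim.diffusion_step()
        assert np.max(np.abs(sim.by_name["k"].conc - 3.5)) < 1e-13

    def test_neumann_mass_conservation(self, hetero_grid):
        sim = Simulation(
            hetero_grid,
            [Species("k", d=2.62,
                     initial=lambda x, y, z: np.where(x < 50, 25.0, 3.5))],
            dt=1.0,
        )
        m0 = sim.total_mass("k")
        for _ in range(200):
            sim.diffusion_step()
        assert abs(sim.total_mass("k") - m0) / m0 <= 1e-12

    def test_unconditional_stability_beyond_explicit_limit(self):
        """dt at 100x the explicit bound stays bounded and settles.

        On discontinuous data the trapezoidal directional sub-steps produce
        a small bounded transient (under 10% of the jump) that decays; there
        is no blow-up and the field relaxes to the conserved mean."""
        grid = build_grid(0, 0, 0, 210, 210, 210, 10, 0.2, 1.0)
        explicit_limit = 10.0**2 / (6 * 2.62)
        sim = Simulation(
            grid,
            [Species("k", d=2.62,
                     initial=lambda x, y, z: np.where(x < 30, 40.0, 0.0))],
            dt=100 * explicit_limit,
        )
        mean = sim.total_mass("k") / grid.free_volume()
        spreads = []
        for _ in range(60):
            sim.diffusion_step()
            c = sim.by_name["k"].conc
            assert np.all(np.isfinite(c))
            assert c.min() >= -4.0 and c.max() <= 44.0
            spreads.append(np.ptp(c))
        assert spreads[-1] < 0.05 * spreads[0]
        assert np.max(np.abs(sim.by_name["k"].conc - mean)) < 2.0

    def test_symmetry_preserved(self):
        """Mirror-symmetric initial data stays mirror-symmetric."""
        grid = build_grid(0, 0, 0, 90, 30, 30, 10, 0.2, 1.6)
        sim = Simulation(
            grid,
            [Species("k", d=2.62,
                     initial=lambda x, y, z: np.where(
                         np.abs(x - 45.0) < 15.0, 20.0, 1.0))],
            dt=1.0,
        )
        for _ in range(50):
            sim.diffusion_step()
        c = sim.by_name["k"].conc
        assert np.max(np.abs(c - c[::-1])) < 1e-12

    def test_dirichlet_converges_to_boundary_value(self, tiny_grid):
        sim = Simulation(tiny_grid,
                         [Species("k", d=2.62, initial=10.0, boundary=3.5)],
                         dt=5.0)
        dist = np.inf
        for _ in range(400):
            sim.diffusion_step()
            new = np.max(np.abs(sim.by_name["k"].conc - 3.5))
            # monotone decay until the round-off floor
            assert new <= dist + 1e-15 or new < 1e-12
            dist = new
        assert dist < 1e-12

    def test_anisotropic_axis_decoupling(self):
        """With d = (D, 0, 0) a y/z-uniform profile only evolves along x and
        conserves mass."""
        grid = build_grid(0, 0, 0, 100, 40, 40, 10, 0.2, 1.0)
        sim = Simulation(
            grid,
            [Species("k", d=(1.0, 0.0, 0.0),
                     initial=lambda x, y, z: np.where(x < 30, 10.0, 0.0))],
            dt=1.0,
        )
        m0 = sim.total_mass("k")
        for _ in range(30):
            sim.diffusion_step()
        c = sim.by_name["k"].conc
        assert np.ptp(c, axis=1).max() < 1e-13 and np.ptp(c, axis=2).max() < 1e-13
        assert abs(sim.total_mass("k") - m0) / m0 < 1e-12


class TestReactionStep:
    def test_backward_euler_linear_decay(self, tiny_grid):
        sim = Simulation(tiny_grid, [Species("s", initial=1.0)],
                         rate_terms=[RateTerm("s", "-0.1*s")], dt=1.0)
        sim.reaction_step()
        assert sim.by_name["s"].conc[0, 0, 0] == pytest.approx(
            1.0 / 1.1, abs=1e-9
        )

    def test_equilibrium_is_fixed_point(self, tiny_grid):
        # at equilibrium kf*[K][A] = kb*[AK]
        k, a = 20.0, 5.0
        kf = KB / (1.0 + np.exp(-(k - 15.0) / 1.15))
        ak = kf * k * a / KB
        sim = Simulation(
            tiny_grid,
            [Species("k", initial=k), Species("A", initial=a),
             Species("AK", initial=ak)],
            reactions=[Reaction("k + A", "AK", KF_EXPR, KB)],
            dt=1.0,
        )
        before = {s.name: s.conc.copy() for s in sim.species}
        sim.reaction_step()
        for s in sim.species:
            assert np.max(np.abs(s.conc - before[s.name])) < 1e-12

    def test_linear_invariant_preserved(self, tiny_grid, buffer_reaction):
        sim = Simulation(
            tiny_grid,
            [Species("k", initial=30.0), Species("A", initial=10.0),
             Species("AK", initial=2.0)],
            reactions=[buffer_reaction], dt=1.0,
        )
        tot0 = sim.total_mass("k") + sim.total_mass("AK")
        for _ in range(100):
            sim.reaction_step()
        tot = sim.total_mass("k") + sim.total_mass("AK")
        assert abs(tot - tot0) / tot0 <= 1e-12


class TestSources:
    def test_zero_current_no_change(self, tiny_grid):
        sim = Simulation(
            tiny_grid, [Species("k", initial=3.5)],
            sources=[PointSource("k", 15, 15, 15, 0.0)], dt=1.0,
        )
        sim.apply_sources()
        assert np.all(sim.by_name["k"].conc == 3.5)

    def test_steady_influx_bookkeeping(self, tiny_grid):
        """Total mass grows by exactly rate * t under a constant source."""
        q = 2.5e-13  # mmol/ms
        sim = Simulation(
            tiny_grid, [Species("k", d=2.62, initial=3.5)],
            sources=[PointSource("k", 15, 15, 15, q)], dt=1.0,
        )
        m0 = sim.total_mass("k")
        sim.step(50)
        expected = q * 50.0 / 1e-15  # mM*um^3
        assert sim.total_mass("k") - m0 == pytest.approx(expected, rel=1e-12)

    def test_membrane_current_rate(self, tiny_grid):
        """1 mA/cm^2 over 1000 um^2 into one alpha=0.2, dx=10 voxel raises
        its concentration by ~0.518 mM/ms."""
        src = PointSource.from_current("k", 15, 15, 15,
                                       current_density=1.0, area=1000.0)
        sim = Simulation(tiny_grid, [Species("k", initial=0.0)],
                         sources=[src], dt=1.0)
        sim.apply_sources()
        i, j, k = tiny_grid.voxel_of(15, 15, 15)
        assert sim.by_name["k"].conc[i, j, k] == pytest.approx(0.518, rel=1e-3)

    def test_source_outside_domain_rejected(self, tiny_grid):
        with pytest.raises(ValueError):
            Simulation(tiny_grid, [Species("k", initial=0.0)],
                       sources=[PointSource("k", 100, 0, 0, 1.0)])

    def test_time_dependent_rate(self, tiny_grid):
        src = PointSource("k", 15, 15, 15, lambda t: 1e-13 if t < 2 else 0.0)
        sim = Simulation(tiny_grid, [Species("k", initial=0.0)],
                         sources=[src], dt=1.0)
        sim.step(5)
        assert sim.injected_mass["k"] == pytest.approx(2e-13 / 1e-15)


class TestFullStep:
    def test_no_kinetics_equals_pure_diffusion(self, hetero_grid):
        init = lambda x, y, z: np.where(x < 50, 25.0, 3.5)
        a = Simulation(hetero_grid, [Species("k", d=2.62, initial=init)],
                       dt=1.0)
        b = Simulation(hetero_grid, [Species("k", d=2.62, initial=init)],
                       dt=1.0)
        a.step(5)
        for _ in range(5):
            b.diffusion_step()
        assert np.array_equal(a.by_name["k"].conc, b.by_name["k"].conc)

    def test_immobile_species_only_reacts(self, tiny_grid, buffer_reaction):
        sim = Simulation(
            tiny_grid,
            [Species("k", d=0.0, initial=30.0), Species("A", initial=10.0),
             Species("AK", initial=0.0)],
            reactions=[buffer_reaction], dt=1.0,
        )
        sim.step(3)
        # no transport: fields stay uniform
        for s in sim.species:
            assert np.ptp(s.conc) == 0.0

    def test_combined_conservation(self, hetero_grid, buffer_species,
                                   buffer_reaction):
        """Total K (free + buffer-bound) is conserved through full split
        steps with diffusion and buffering."""
        sim = Simulation(hetero_grid, buffer_species,
                         reactions=[buffer_reaction], dt=1.0)
        tot0 = sim.total_mass("k") + sim.total_mass("AK")
        sim.step(100)
        tot = sim.total_mass("k") + sim.total_mass("AK")
        assert abs(tot - tot0) / tot0 <= 1e-12

    def test_strang_splitting_conserves(self, hetero_grid, buffer_species,
                                        buffer_reaction):
        sim = Simulation(hetero_grid, buffer_species,
                         reactions=[buffer_reaction], dt=1.0,
                         splitting="strang")
        tot0 = sim.total_mass("k") + sim.total_mass("AK")
        sim.step(50)
        tot = sim.total_mass("k") + sim.total_mass("AK")
        assert abs(tot - tot0) / tot0 <= 1e-12

    def test_uniform_total_mass_value(self):
        grid = build_grid(-500, -500, -500, 500, 500, 500, 10, 0.2, 1.6)
        sim = Simulation(grid, [Species("k", initial=3.5)])
        assert sim.total_mass("k") == pytest.approx(7e8, rel=1e-12)

    def test_empty_field_zero_mass(self, tiny_grid):
        sim = Simulation(tiny_grid, [Species("k", initial=0.0)])
        assert sim.total_mass("k") == 0.0

    def test_output_clamping(self, tiny_grid):
        sim = Simulation(tiny_grid, [Species("k", initial=1.0)])
        sim.by_name["k"].conc[0, 0, 0] = -1e-13  # sub-tolerance transient
        assert sim.concentration("k").min() == 0.0
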
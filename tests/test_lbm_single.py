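"""Single-phase BGK solver: equilibrium, collision, boundaries, moments."""

import numpy as np
import pytest

from mfsim.fluids import FluidSpec
from mfsim.geometry import (
    FLUID,
    WALL,
    ChannelGeometry,
    build_channel_mask,
)
from mfsim.lbm import ConvergenceMonitor, SinglePhaseSim, equilibrium, tau_from_viscosity
from mfsim.lbm.solver import macroscopic
from mfsim.units import UnitScales


def closed_box(n=12):
    mask = np.full((n, n), FLUID, dtype=np.int8)
    mask[0, :] = mask[-1, :] = mask[:, 0] = mask[:, -1] = WALL
    return mask


def water_sim(mask, u_in=0.0, **kw):
    scales = UnitScales(dx=1e-6, dt=(1 / 6) * 1e-12 / 1e-6, rho_ref=1000.0)  # tau=1
    fluid = FluidSpec(density=1000.0, viscosity=1e-3)
    from mfsim.lbm import make_lattice

    return SinglePhaseSim(mask, make_lattice("D2Q9"), scales, fluid, u_in=u_in, **kw)


class TestEquilibrium:
    def test_rest_state_is_weighted_density(self, d2q9):
        rho = np.full((4, 4), 1.3)
        u = np.zeros((2, 4, 4))
        feq = equilibrium(rho, u, d2q9)
        for i in range(9):
            assert feq[i] == pytest.approx(d2q9.w[i] * 1.3)

    def test_rest_population_at_u01(self, d2q9):
        # f_eq,0 = (4/9)(1 - 1.5 * 0.01) for rho=1, u=(0.1, 0)
        rho = np.ones((1, 1))
        u = np.zeros((2, 1, 1))
        u[0] = 0.1
        feq = equilibrium(rho, u, d2q9)
        assert feq[0, 0, 0] == pytest.approx((4 / 9) * (1 - 0.015), abs=1e-12)
        assert feq[0, 0, 0] == pytest.approx(0.4378, abs=5e-5)

    @pytest.mark.parametrize("seed", range(20))
    def test_moment_identities_random_states(self, d2q9, seed):
        rng = np.random.default_rng(seed)
        rho = rng.uniform(0.5, 2.0, (3, 3))
        u = rng.uniform(-0.1, 0.1, (2, 3, 3))
        feq = equilibrium(rho, u, d2q9)
        assert np.allclose(feq.sum(axis=0), rho, atol=1e-14)
        j0 = np.einsum("i...,i->...", feq, d2q9.c[:, 0].astype(float))
        j1 = np.einsum("i...,i->...", feq, d2q9.c[:, 1].astype(float))
        assert np.allclose(j0, rho * u[0], atol=1e-14)
        assert np.allclose(j1, rho * u[1], atol=1e-14)


class TestCollision:
    def test_tau_one_relaxes_to_equilibrium(self, d2q9):
        sim = water_sim(closed_box())
        sim.initialize()
        rng = np.random.default_rng(0)
        sim.f += rng.uniform(0, 0.01, sim.f.shape)
        rho, u = sim.macroscopic()
        fpost, feq = sim.collide(rho, u)
        assert np.allclose(fpost, feq)  # tau = 1 = dt

    def test_equilibrium_is_fixed_point(self, d2q9):
        sim = water_sim(closed_box())
        sim.initialize()
        rho, u = sim.macroscopic()
        fpost, _ = sim.collide(rho, u)
        assert np.allclose(fpost, sim.f, atol=1e-15)

    @pytest.mark.parametrize("seed", range(30))
    def test_collision_conserves_mass_and_momentum(self, d2q9, seed):
        sim = water_sim(closed_box())
        sim.initialize()
        rng = np.random.default_rng(seed)
        sim.f = rng.uniform(0.01, 0.2, sim.f.shape)
        rho0, u0 = macroscopic(sim.f, d2q9)
        fpost, _ = sim.collide(rho0, u0)
        rho1, u1 = macroscopic(fpost, d2q9)
        assert np.allclose(rho1, rho0, atol=1e-14)
        assert np.allclose(rho1 * u1[0], rho0 * u0[0], atol=1e-14)


class TestMacroscopic:
    def test_inverts_equilibrium(self, d2q9):
        rng = np.random.default_rng(3)
        rho0 = rng.uniform(0.5, 2.0, (5, 5))
        u0 = rng.uniform(-0.05, 0.05, (2, 5, 5))
        rho, u = macroscopic(equilibrium(rho0, u0, d2q9), d2q9)
        assert np.allclose(rho, rho0, atol=1e-14)
        assert np.allclose(u, u0, atol=1e-14)

    def test_moments_equal_explicit_sums(self, d2q9):
        rng = np.random.default_rng(4)
        f = rng.uniform(0, 1, (9, 4, 4))
        rho, u = macroscopic(f, d2q9)
        assert np.allclose(rho, sum(f[i] for i in range(9)))
        jx = sum(d2q9.c[i, 0] * f[i] for i in range(9))
        assert np.allclose(u[0] * rho, jx)


class TestBoundaries:
    def test_closed_box_conserves_mass_exactly(self):
        sim = water_sim(closed_box(10))
        sim.initialize()
        rng = np.random.default_rng(1)
        u0 = rng.uniform(-0.02, 0.02, (2,) + sim.mask.shape)
        sim.initialize(u=u0)
        m0 = sim.f[:, sim.fluid_cells].sum()
        for _ in range(2000):
            sim.step()
        m1 = sim.f[:, sim.fluid_cells].sum()
        assert m1 == pytest.approx(m0, rel=1e-12)

    def test_zero_velocity_inlet_is_plain_bounce_back(self):
        geom = ChannelGeometry(l=8e-6, w=6e-6)
        scales = UnitScales(dx=1e-6, dt=(1 / 6) * 1e-12 / 1e-6, rho_ref=1000.0)
        mask = build_channel_mask(geom, scales, dims=2)
        from mfsim.lbm import make_lattice

        fluid = FluidSpec(density=1000.0, viscosity=1e-3)
        lat = make_lattice("D2Q9")
        a = SinglePhaseSim(mask, lat, scales, fluid, u_in=0.0, p_out=0.0)
        b = SinglePhaseSim(
            np.where(mask == 2, WALL, mask).astype(np.int8), lat, scales, fluid,
            u_in=0.0, p_out=0.0,
        )
        rng = np.random.default_rng(2)
        f0 = rng.uniform(0.01, 0.2, (9,) + mask.shape)
        for sim in (a, b):
            sim.initialize()
            sim.f = f0.copy()
            sim.step()
        assert np.allclose(a.f[:, a.fluid_cells], b.f[:, b.fluid_cells])

    def test_galilean_uniform_flow_fixed_point(self, d2q9):
        # uniform flow in a fully periodic domain must not drift
        mask = np.full((8, 8), FLUID, dtype=np.int8)
        sim = water_sim(mask, periodic=True)
        u0 = np.zeros((2, 8, 8))
        u0[0] = 0.04
        sim.initialize(u=u0)
        for _ in range(50):
            sim.step()
        _, u = sim.macroscopic()
        assert np.allclose(u[0], 0.04, atol=1e-13)
        assert np.allclose(u[1], 0.0, atol=1e-13)


class TestTauAndStrainRate:
    def test_tau_from_viscosity(self):
        assert tau_from_viscosity(1 / 6) == pytest.approx(1.0)

    def test_newtonian_tau_field_uniform(self):
        sim = water_sim(closed_box())
        assert np.ptp(sim.tau) == 0.0

    def test_equilibrium_state_has_zero_strain_rate(self):
        sim = water_sim(closed_box())
        sim.initialize()
        assert np.allclose(sim.strain_rate(), 0.0, atol=1e-14)

    def test_blood_tau_lower_at_wall(self, blood_fluid):
        # converged shear-thinning channel: higher shear at the wall means
        # lower viscosity, hence lower relaxation time than mid-channel
        geom = ChannelGeometry(l=100e-6, w=50e-6, x_m=80e-6)
        nu_max = blood_fluid.nu_bounds()[1]
        scales = UnitScales(dx=5e-6, dt=(1 / 3) * 25e-12 / nu_max, rho_ref=1060.0)
        mask = build_channel_mask(geom, scales, dims=2)
        from mfsim.lbm import make_lattice

        sim = SinglePhaseSim(
            mask, make_lattice("D2Q9"), scales, blood_fluid, u_in=0.01, p_out=0.0
        )
        sim.initialize()
        sim.run_steady(ConvergenceMonitor(window=400, tol=1e-6, check_every=20),
                       max_steps=40000)
        col = geom.measurement_column(scales.dx) + 1
        tau_line = sim.tau[col, 1:-1]
        assert tau_line[0] < tau_line[len(tau_line) // 2]


class TestSteadyState:
    def test_quiescent_problem_converges_immediately(self):
        sim = water_sim(closed_box())
        sim.initialize()
        steps = sim.run_steady(
            ConvergenceMonitor(window=100, tol=1e-5, check_every=10), max_steps=5000
        )
        assert steps <= 300

    def test_poiseuille_parabola_ratio(self, water_fluid):
        geom = ChannelGeometry(l=240e-6, w=40e-6, x_m=200e-6)
        scales = UnitScales(dx=2e-6, dt=(1 / 6) * 4e-12 / 1e-6, rho_ref=1000.0)
        mask = build_channel_mask(geom, scales, dims=2)
        from mfsim.lbm import make_lattice

        sim = SinglePhaseSim(
            mask, make_lattice("D2Q9"), scales, water_fluid, u_in=0.005, p_out=0.0
        )
        u0 = np.zeros((2,) + mask.shape)
        u0[0][sim.fluid_cells] = sim.u_in_lat
        sim.initialize(u=u0)
        sim.run_steady(ConvergenceMonitor(window=500, tol=1e-7, check_every=25),
                       max_steps=60000)
        _, u = sim.macroscopic()
        col = geom.measurement_column(scales.dx) + 1
        prof = u[0, col, 1:-1]
        assert prof.max() / prof.mean() == pytest.approx(1.5, rel=0.01)

    def test_strain_rate_against_finite_differences(self, water_fluid):
        geom = ChannelGeometry(l=120e-6, w=40e-6, x_m=100e-6)
        scales = UnitScales(dx=2e-6, dt=(1 / 6) * 4e-12 / 1e-6, rho_ref=1000.0)
        mask = build_channel_mask(geom, scales, dims=2)
        from mfsim.lbm import make_lattice

        sim = SinglePhaseSim(
            mask, make_lattice("D2Q9"), scales, water_fluid, u_in=0.005, p_out=0.0
        )
        u0 = np.zeros((2,) + mask.shape)
        u0[0][sim.fluid_cells] = sim.u_in_lat
        sim.initialize(u=u0)
        sim.run_steady(ConvergenceMonitor(window=500, tol=1e-7, check_every=25),
                       max_steps=60000)
        gdot = sim.strain_rate()
        _, u = sim.macroscopic()
        col = geom.measurement_column(scales.dx) + 1
        # centered-difference du/dy on the measurement column
        du = np.gradient(u[0, col, :], edge_order=2)
        interior = slice(3, -3)
        fd = np.abs(du)[interior]
        lb = gdot[col, :][interior]
        sel = fd > 0.2 * fd.max()
        assert np.all(np.abs(lb[sel] - fd[sel]) / fd[sel] < 0.05)
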
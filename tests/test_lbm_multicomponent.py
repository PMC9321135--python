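"""Shan–Chen coupling: forces, conservation, symmetry, diffusivity."""

import numpy as np
import pytest

from mfsim.geometry import FLUID, WALL
from mfsim.lbm import TwoComponentSim, shan_chen_force
from mfsim.lbm.multicomponent import (
    ShanChenParams,
    measure_effective_diffusivity,
    species_tau_for_diffusivity,
)
from mfsim.units import CS2, UnitScales

LATTICE_SCALES = UnitScales(dx=1.0, dt=1.0, rho_ref=1.0)


def periodic_sim(alpha, G=0.8, tau=0.9, floor=0.02, u=None):
    from mfsim.lbm import make_lattice

    mask = np.full(alpha.shape, FLUID, dtype=np.int8)
    sim = TwoComponentSim(
        mask, make_lattice("D2Q9"), LATTICE_SCALES,
        ShanChenParams(G=G, tau_a=tau, tau_b=tau, minority_floor=floor),
        periodic=True,
    )
    sim.initialize(alpha, u=u)
    return sim


class TestForce:
    def test_zero_coupling_means_zero_force(self, d2q9):
        rng = np.random.default_rng(0)
        ra, rb = rng.uniform(0.1, 1, (2, 8, 8))
        fa, fb = shan_chen_force(ra, rb, 0.0, d2q9)
        assert np.allclose(fa, 0) and np.allclose(fb, 0)

    def test_uniform_mixture_has_no_force(self, d2q9):
        ra = np.full((8, 8), 0.4)
        rb = np.full((8, 8), 0.6)
        fa, fb = shan_chen_force(ra, rb, 1.1, d2q9)
        assert np.allclose(fa, 0, atol=1e-15)
        assert np.allclose(fb, 0, atol=1e-15)

    def test_flat_interface_antisymmetric_zero_total_momentum(self, d2q9):
        x = np.arange(32)
        ra = np.where((x >= 8) & (x < 24), 0.98, 0.02)[:, None] * np.ones((1, 4))
        rb = 1.0 - ra
        fa, fb = shan_chen_force(ra, rb, 1.1, d2q9)
        # Newton's third law over the periodic domain
        assert abs((fa + fb).sum()) < 1e-12
        # the slab is mirror-symmetric about its center, so the x-force is
        # antisymmetric under that reflection (pushes A toward its bulk on
        # both interfaces)
        assert fa[0].max() > 0 and fa[0].min() < 0
        assert np.allclose(fa[0][::-1, :], -fa[0], atol=1e-13)

    def test_mismatched_grids_rejected(self, d2q9):
        with pytest.raises(ValueError):
            shan_chen_force(np.ones((4, 4)), np.ones((5, 4)), 1.0, d2q9)


class TestConservationAndSymmetry:
    def test_component_masses_conserved_periodic(self):
        rng = np.random.default_rng(5)
        alpha = rng.uniform(0.2, 0.8, (16, 16))
        sim = periodic_sim(alpha)
        ma0, mb0 = sim.component_masses()
        sim.run(500)
        ma1, mb1 = sim.component_masses()
        assert ma1 == pytest.approx(ma0, rel=1e-12)
        assert mb1 == pytest.approx(mb0, rel=1e-12)

    def test_component_swap_maps_alpha_to_one_minus(self):
        x = np.arange(24)
        alpha = 0.5 * (1 + np.tanh((x - 12.0 + 0.5) / 2))[:, None] * np.ones((1, 4))
        a_sim = periodic_sim(alpha.copy())
        b_sim = periodic_sim(alpha.copy())
        # swap the population fields: evolution must commute with the swap
        # bit-for-bit (both components share the same relaxation time)
        b_sim.f = [a_sim.f[1].copy(), a_sim.f[0].copy()]
        a_sim.run(200)
        b_sim.run(200)
        ra, rb = a_sim.densities()
        sb_a, sb_b = b_sim.densities()
        assert np.array_equal(ra, sb_b)
        assert np.array_equal(rb, sb_a)
        assert np.allclose(a_sim.alpha(), 1.0 - b_sim.alpha(), atol=1e-14)

    def test_rest_state_with_balanced_forces_stays_at_rest(self):
        # a symmetric 1D interface at rest: forces balance pairwise, the
        # barycentric velocity stays at machine zero
        x = np.arange(32)
        alpha = np.where((x >= 8) & (x < 24), 0.98, 0.02)[:, None] * np.ones((1, 4))
        sim = periodic_sim(alpha, G=1.1, tau=0.7)
        sim.run(300)
        u = sim.velocity()
        assert np.abs(u[0].mean()) < 1e-12  # no net momentum generated


class TestImmiscibility:
    def test_interface_width_decreases_with_coupling(self):
        widths = []
        for G in (0.9, 1.1, 1.4):
            x = np.arange(48)
            alpha = np.where((x >= 12) & (x < 36), 1.0, 0.0)[:, None] * np.ones((1, 4))
            sim = periodic_sim(alpha, G=G, tau=0.7)
            sim.run(3000)
            a = sim.alpha()[:, 0]
            widths.append(int(np.sum((a > 0.1) & (a < 0.9))))
        assert widths[0] >= widths[1] >= widths[2]


class TestEffectiveDiffusivity:
    def test_ideal_mixture_matches_bgk_diffusivity(self):
        D = measure_effective_diffusivity(0.0, 0.8, n_steps=300)
        assert D == pytest.approx(CS2 * 0.3, rel=0.02)

    def test_coupling_suppresses_diffusion(self):
        d0 = measure_effective_diffusivity(0.0, 1.0, n_steps=300)
        d1 = measure_effective_diffusivity(0.8, 1.0, n_steps=300)
        assert d1 < d0
        # linear-response prediction: cs^2 [(tau-1/2) - tau G rho/2]
        assert d1 == pytest.approx(CS2 * (0.5 - 1.0 * 0.8 / 2), rel=0.05)

    def test_tau_calibration_inverts_the_relation(self):
        for d_target in (1e-3, 5e-3):
            tau = species_tau_for_diffusivity(0.8, d_target)
            pred = CS2 * ((tau - 0.5) - tau * 0.8 / 2)
            assert pred == pytest.approx(d_target, rel=1e-12)
        with pytest.raises(ValueError):
            species_tau_for_diffusivity(2.5, 1e-3)


class TestWalledDomain:
    def test_mass_conserved_with_walls(self):
        mask = np.full((12, 12), FLUID, dtype=np.int8)
        mask[0, :] = mask[-1, :] = mask[:, 0] = mask[:, -1] = WALL
        from mfsim.lbm import make_lattice

        sim = TwoComponentSim(
            mask, make_lattice("D2Q9"), LATTICE_SCALES,
            ShanChenParams(G=1.1, tau_a=0.7, tau_b=0.7, minority_floor=0.02),
        )
        x = np.arange(12)
        alpha = np.where((x > 3) & (x < 9), 0.98, 0.02)[:, None] * np.ones((1, 12))
        sim.initialize(alpha)
        ma0, mb0 = sim.component_masses()
        sim.run(1000)
        ma1, mb1 = sim.component_masses()
        assert ma1 == pytest.approx(ma0, rel=1e-12)
        assert mb1 == pytest.approx(mb0, rel=1e-12)


class TestSingleComponentLimit:
    def test_zero_coupling_total_matches_single_phase(self, d2q9, water_fluid):
        """With G = 0 the component pair is two passive halves of one fluid:
        the total density and momentum evolve exactly like the single-phase
        solver from the same initial state."""
        from mfsim.lbm import SinglePhaseSim
        from mfsim.lbm.solver import macroscopic

        shape = (12, 10)
        mask = np.full(shape, FLUID, dtype=np.int8)
        scales = UnitScales(dx=1e-6, dt=(1 / 6) * 1e-12 / 1e-6, rho_ref=1000.0)
        rng = np.random.default_rng(9)
        u0 = rng.uniform(-0.02, 0.02, (2,) + shape)
        alpha = rng.uniform(0.2, 0.8, shape)

        two = TwoComponentSim(
            mask, d2q9, scales,
            ShanChenParams(G=0.0, tau_a=1.0, tau_b=1.0, minority_floor=0.02),
            periodic=True,
        )
        two.initialize(alpha, u=u0)
        one = SinglePhaseSim(mask, d2q9, scales, water_fluid, periodic=True)
        one.initialize(u=u0)
        for _ in range(60):
            two.step()
            one.step()
        rho_t = sum(two.densities())
        rho_1, u_1 = macroscopic(one.f, d2q9)
        u_t = two.velocity()
        assert np.allclose(rho_t, rho_1, atol=1e-13)
        assert np.allclose(u_t, u_1, atol=1e-13)


class TestMixingDriver:
    def test_identical_inlet_fluids_give_zero_ami(self):
        """Feeding the same fluid through both inlet halves leaves nothing
        to mix: the index vanishes at every station."""
        from mfsim.config import builtin_config
        from mfsim.metrics import absolute_mixing_index, extract_profile
        from mfsim.usecases import build_mixing_sim

        cfg = builtin_config("mix")
        cfg.geometry = type(cfg.geometry)(l=100e-6, w=20e-6, x_m=80e-6)
        sim = build_mixing_sim(cfg, dims=2)
        sim.inlet_alpha = np.ones(sim.mask.shape)
        sim.initialize(np.ones(sim.mask.shape), u=None)
        sim.run(800)
        for col in (20, 50, 80):
            prof = extract_profile(
                sim.alpha(), sim.mask, col, sim.scales, kind="concentration"
            )
            assert absolute_mixing_index(prof) == pytest.approx(0.0, abs=1e-3)

    def test_steady_mass_flux_balance(self):
        """Mass flux in equals mass flux out of the mixing channel."""
        from mfsim.config import builtin_config
        from mfsim.lbm import ConvergenceMonitor
        from mfsim.usecases import build_mixing_sim

        cfg = builtin_config("mix")
        cfg.geometry = type(cfg.geometry)(l=150e-6, w=20e-6, x_m=120e-6)
        sim = build_mixing_sim(cfg, dims=2)
        sim.run(12000, monitor=ConvergenceMonitor(window=500, tol=1e-6, check_every=50))
        rho_t = sum(sim.densities())
        u = sim.velocity()
        fl = sim.fluid_cells
        jin = float((rho_t * u[0])[1][fl[1]].sum())
        jout = float((rho_t * u[0])[-2][fl[-2]].sum())
        assert abs(jin - jout) / jin < 1e-3
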
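"""Mixing index, line extraction, droplet tracking."""

import numpy as np
import pytest

from mfsim.geometry import ChannelGeometry, build_channel_mask
from mfsim.metrics import absolute_mixing_index, droplet_track, extract_profile
from mfsim.mixing import mixing_concentration, mixing_profile_at_line
from mfsim.units import UnitScales


class TestAMI:
    def test_uniform_profile_is_mixed(self):
        for c in (0.2, 0.5, 0.9):
            for m in ("calibrated", "mad", "rms"):
                assert absolute_mixing_index(np.full(40, c), method=m) == 0.0

    def test_perfect_step(self):
        step = np.r_[np.ones(20), np.zeros(20)]
        assert absolute_mixing_index(step, method="mad") == pytest.approx(1.0)
        assert absolute_mixing_index(step, method="rms") == pytest.approx(1.0)
        assert absolute_mixing_index(step) == pytest.approx(1 / np.sqrt(2))

    def test_three_point_example(self):
        # mean 0.5; deviations 0.5, 0, 0.5 -> MAD/mean = 2/3
        assert absolute_mixing_index([1.0, 0.5, 0.0], method="mad") == pytest.approx(2 / 3)

    def test_reorder_invariance(self):
        rng = np.random.default_rng(7)
        a = rng.uniform(0, 1, 64)
        assert absolute_mixing_index(a) == pytest.approx(
            absolute_mixing_index(rng.permutation(a))
        )

    def test_subsampling_stability_smooth_profile(self):
        # halving the sampling resolution barely moves the index for a
        # smooth profile
        fine = (np.arange(80) + 0.5) / 80 - 0.5
        coarse = (np.arange(40) + 0.5) / 40 - 0.5
        full = absolute_mixing_index(mixing_concentration(12.0, fine, 400.0))
        half = absolute_mixing_index(mixing_concentration(12.0, coarse, 400.0))
        assert abs(full - half) < 1e-3

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            absolute_mixing_index(np.zeros(10))


class TestExtractProfile:
    def setup_method(self):
        self.geom = ChannelGeometry(l=20e-6, w=10e-6, x_m=15e-6)
        self.scales = UnitScales(dx=1e-6, dt=2e-6, rho_ref=1000.0)
        self.mask = build_channel_mask(self.geom, self.scales, dims=2)

    def test_uniform_field(self):
        field = np.full(self.mask.shape, 0.02)
        prof = extract_profile(
            field, self.mask, self.geom.measurement_column(1e-6), self.scales,
            kind="concentration",
        )
        assert prof.alpha == pytest.approx(np.full(10, 0.02))
        assert prof.y.size == 10

    def test_velocity_line_sample_count_and_walls(self):
        field = np.zeros(self.mask.shape)
        field[:, 1:-1] = np.linspace(0, 1, 10) * (1 - np.linspace(0, 1, 10))
        prof = extract_profile(
            field, self.mask, 5, self.scales, kind="velocity"
        )
        assert prof.u[0] == 0.0 and prof.u[-1] == 0.0
        assert prof.z.size == 12  # 10 cells + both wall points
        assert np.argmax(prof.u) not in (0, prof.u.size - 1)

    def test_line_outside_domain(self):
        with pytest.raises(ValueError):
            extract_profile(np.zeros(self.mask.shape), self.mask, 1000, self.scales)

    def test_matches_direct_series_evaluation(self):
        # painting the analytic solution onto a grid and extracting the
        # line must equal the direct 1D evaluation to near machine precision
        geom = ChannelGeometry(l=600e-6, w=40e-6, x_m=500e-6)
        scales = UnitScales(dx=1e-6, dt=5e-6, rho_ref=1.0)
        mask = build_channel_mask(geom, scales, dims=2)
        Pe = 0.01 * geom.w / 90e-12
        y = (np.arange(40) + 0.5) / 40 - 0.5
        xs = (np.arange(600) + 0.5) / 40.0  # x~ = x/w per column
        field = np.zeros(mask.shape)
        field[1:-1, 1:-1] = mixing_concentration(xs[:, None], y[None, :], Pe)
        col = geom.measurement_column(1e-6)
        prof = extract_profile(field, mask, col, scales, kind="concentration")
        direct = mixing_concentration((col + 0.5) / 40.0, y, Pe)
        assert np.max(np.abs(prof.alpha - direct)) < 1e-12
        assert absolute_mixing_index(prof) == pytest.approx(
            absolute_mixing_index(direct), abs=1e-12
        )


class TestDropletTrack:
    def test_synthetic_slug_exact_recovery(self):
        alpha = np.zeros((60, 20))
        alpha[10:30, 4:16] = 1.0
        path = np.tile(((np.arange(60) + 0.5) * 1e-6)[:, None], (1, 20))
        s, length, n = droplet_track(alpha, path)
        assert n == 1
        assert s == pytest.approx(10.5e-6)
        assert length == pytest.approx(19e-6)

    def test_two_blobs(self):
        alpha = np.zeros((40, 10))
        alpha[5:10, 3:7] = 1.0
        alpha[20:28, 3:7] = 1.0
        path = np.tile(((np.arange(40) + 0.5) * 1e-6)[:, None], (1, 10))
        _, _, n = droplet_track(alpha, path)
        assert n == 2

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            droplet_track(np.ones((4, 4)), np.zeros((4, 4)), threshold=1.5)

    def test_empty_phase(self):
        with pytest.raises(ValueError, match="empty"):
            droplet_track(np.zeros((4, 4)), np.zeros((4, 4)))
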
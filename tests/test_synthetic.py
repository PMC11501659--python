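"""Confined Brownian simulation, scattered intensity and camera rendering."""

import numpy as np
import pytest

from canta.beam import GaussianBeamField, RadialProfileField
from canta.synthetic import (
    AcquisitionConfig,
    CameraModel,
    ChannelGeometry,
    airy_radius_um,
    apply_shot_noise,
    auto_photon_scale,
    render_frames,
    scattered_intensity,
    simulate_confined_brownian,
)
from canta.transport import ParticleSpec

from conftest import make_acquisition


class UniformField:
    def intensity(self, x, y, z):
        return np.ones_like(np.asarray(x, dtype=float))


class TestConfinedBrownian:
    def test_zero_diffusion_is_static(self, geometry):
        acq = make_acquisition(50)
        traj = simulate_confined_brownian(0.0, geometry, acq, start_xy_um=(1.0, -0.5))
        assert np.all(traj.sub_x == 1.0)
        assert np.all(traj.sub_y == -0.5)
        assert np.all(traj.sub_z == 0.0)

    def test_axial_displacement_variance_matches_theory(self):
        # effectively unconfined: huge channel, check var(dz) over one frame
        geometry = ChannelGeometry(radius_um=1e6, axial_extent_um=1.0)
        acq = make_acquisition(65_000, substeps_per_frame=1, seed=4)
        d_coeff = 2.6
        traj = simulate_confined_brownian(d_coeff, geometry, acq)
        dz = np.diff(traj.sub_z.ravel())
        dt = acq.substep_dt_s
        var = dz.var()
        expected = 2.0 * d_coeff * dt
        stderr = expected * np.sqrt(2.0 / dz.size)
        assert abs(var - expected) < 3.0 * stderr

    def test_confinement_invariant_every_substep(self, geometry):
        acq = make_acquisition(2000, seed=5)
        traj = simulate_confined_brownian(5.0, geometry, acq)
        assert np.hypot(traj.sub_x, traj.sub_y).max() <= geometry.radius_um + 1e-12

    def test_seed_reproducibility(self, geometry):
        acq = make_acquisition(200, seed=6)
        a = simulate_confined_brownian(2.5, geometry, acq)
        b = simulate_confined_brownian(2.5, geometry, acq)
        assert np.array_equal(a.sub_x, b.sub_x)
        assert np.array_equal(a.sub_z, b.sub_z)

    def test_rejects_insufficient_substep_resolution(self):
        tiny = ChannelGeometry(radius_um=0.05, axial_extent_um=1.0)
        with pytest.raises(ValueError, match="substeps"):
            simulate_confined_brownian(5.0, tiny, make_acquisition(10, substeps_per_frame=1))

    def test_rejects_start_outside_channel(self, geometry):
        with pytest.raises(ValueError, match="outside"):
            simulate_confined_brownian(1.0, geometry, make_acquisition(10), start_xy_um=(3.0, 0))


class TestScatteredIntensity:
    def test_uniform_field_constant_series(self, geometry, particle):
        traj = simulate_confined_brownian(2.5, geometry, make_acquisition(300, seed=7))
        series = scattered_intensity(traj, UniformField(), particle)
        assert series == pytest.approx(np.full(300, particle.relative_scattering))

    def test_d6_diameter_scaling(self, geometry):
        traj = simulate_confined_brownian(2.5, geometry, make_acquisition(100, seed=8))
        small = scattered_intensity(traj, UniformField(), ParticleSpec(50.0))
        large = scattered_intensity(traj, UniformField(), ParticleSpec(100.0))
        assert large / small == pytest.approx(np.full(100, 64.0))

    def test_flat_field_series_within_envelope(self, geometry, design_beam, particle):
        """Noise-free intensity variation is bounded by the field's min->max
        envelope along the realised trajectory (closed-form Gaussian-beam
        oracle: axial decay between extreme z plus radial centre-to-edge
        drop)."""
        from canta.beam import axial_decay, radial_flatness

        acq = make_acquisition(5000, seed=9)
        traj = simulate_confined_brownian(2.47, geometry, acq)
        field = GaussianBeamField(design_beam, z_offset_um=geometry.axial_offset_um)
        series = scattered_intensity(traj, field, particle)
        rel_std = series.std() / series.mean()

        z_lo = geometry.axial_offset_um + traj.sub_z.min()
        z_span = traj.sub_z.max() - traj.sub_z.min()
        envelope = axial_decay(design_beam, z_lo, z_span) + radial_flatness(
            design_beam, z_lo, 2.0 * geometry.radius_um
        )
        assert rel_std <= envelope / 2.0
        assert rel_std < 0.05  # flat field: percent-level at most

    def test_shot_noise_preserves_mean(self, geometry, particle, rng):
        traj = simulate_confined_brownian(2.5, geometry, make_acquisition(5000, seed=10))
        series = scattered_intensity(traj, UniformField(), particle)
        camera = CameraModel(photon_scale=auto_photon_scale(particle, UniformField()))
        noisy = apply_shot_noise(series, camera, rng)
        assert noisy.mean() == pytest.approx(series.mean(), rel=0.01)
        assert noisy.std() > 0


class TestRenderFrames:
    def _static_traj(self, geometry, n_frames=3, xy=(0.3, 0.0)):
        return simulate_confined_brownian(
            0.0, geometry, make_acquisition(n_frames), start_xy_um=xy
        )

    def test_zero_intensity_gives_pure_background(self, geometry, camera, rng):
        traj = self._static_traj(geometry, n_frames=5)
        stack = render_frames(traj, np.zeros(5), camera, fov_px=(30, 64), rng=rng)
        assert stack.frames.mean() == pytest.approx(camera.noise_floor, abs=1.0)

    def test_noise_free_peak_at_true_position_with_airy_minimum(self, geometry, camera):
        traj = self._static_traj(geometry, n_frames=1, xy=(0.0, 0.0))
        stack = render_frames(
            traj, np.array([20_000.0]), camera, fov_px=(31, 63), noise=False
        )
        img = stack.frames[0].astype(float) - camera.noise_floor
        peak = np.unravel_index(np.argmax(img), img.shape)
        true_row = traj.x_um[0] / camera.pixel_pitch_um + (31 - 1) / 2
        true_col = traj.z_um[0] / camera.pixel_pitch_um - stack.origin_z_px[0]
        assert peak == (round(true_row), round(true_col))
        # first Airy minimum at 0.61 lambda / NA = 1.30 um for NA 0.25
        r_airy = airy_radius_um(0.25, 0.532)
        assert r_airy == pytest.approx(1.30, abs=0.005)
        cols = np.arange(img.shape[1])
        profile = img[peak[0], :]
        radii = np.abs(cols - true_col) * camera.pixel_pitch_um
        near_min = profile[(radii > r_airy - 0.2) & (radii < r_airy + 0.2)]
        assert near_min.size > 0
        assert near_min.max() < 0.01 * img[peak]

    def test_integrated_signal_linear_in_intensity(self, geometry, camera):
        traj = self._static_traj(geometry, n_frames=3)
        levels = np.array([5_000.0, 10_000.0, 20_000.0])
        stack = render_frames(traj, levels, camera, fov_px=(30, 64), noise=False)
        masses = [
            (frame.astype(float) - camera.noise_floor).sum() for frame in stack.frames
        ]
        assert masses[1] / masses[0] == pytest.approx(2.0, rel=1e-3)
        assert masses[2] / masses[1] == pytest.approx(2.0, rel=1e-3)

    def test_clipping_at_saturation(self, geometry, camera):
        traj = self._static_traj(geometry, n_frames=1)
        stack = render_frames(traj, np.array([1e7]), camera, fov_px=(30, 64), noise=False)
        assert stack.frames.max() == camera.saturation

    def test_rejects_undersampled_psf(self, geometry, camera):
        traj = self._static_traj(geometry, n_frames=1)
        with pytest.raises(ValueError, match="undersampled"):
            render_frames(
                traj, np.array([1000.0]), camera, na=0.9, vacuum_wavelength_um=0.4,
                fov_px=(30, 64), noise=False,
            )

    def test_seeded_frames_reproducible(self, geometry, camera):
        traj = simulate_confined_brownian(2.5, geometry, make_acquisition(20, seed=11))
        series = np.full(20, 10_000.0)
        a = render_frames(traj, series, camera, fov_px=(30, 64),
                         rng=np.random.default_rng(3))
        b = render_frames(traj, series, camera, fov_px=(30, 64),
                         rng=np.random.default_rng(3))
        assert np.array_equal(a.frames, b.frames)

    def test_moving_window_keeps_particle_in_frame(self, camera):
        # long run in a short window: origins must shift, particle stays inside
        geometry = ChannelGeometry(radius_um=2.0, axial_extent_um=30.0)
        traj = simulate_confined_brownian(25.0, geometry, make_acquisition(2000, seed=12))
        series = np.full(2000, 10_000.0)
        stack = render_frames(traj, series, camera, fov_px=(30, 64), noise=False)
        assert stack.origin_z_px.min() != stack.origin_z_px.max()
        rel = traj.z_um / camera.pixel_pitch_um - stack.origin_z_px
        assert rel.min() > 0 and rel.max() < 64
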
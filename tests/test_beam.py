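"""Gaussian-beam design metrics, regime classification and the propagator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from canta.beam import (
    CapillarySpec,
    GaussianBeamSpec,
    LiquidSpec,
    RadialProfileField,
    axial_decay,
    beam_radius,
    capillary_index_profile,
    classify_regime,
    gaussian_field_1d,
    guided_mode_profile,
    intensity,
    plane_wave_field,
    propagate,
    radial_flatness,
    rayleigh_range,
)
from canta.transport import diffusion_length


class TestAnalyticBeam:
    def test_rayleigh_range_reference(self, design_beam):
        # pi * 4.2^2 * 1.46 / 0.532
        assert rayleigh_range(design_beam) == pytest.approx(152.1, abs=0.1)

    def test_rayleigh_range_scalings(self, design_beam):
        doubled_n = GaussianBeamSpec(4.2, 0.532, 2.92)
        assert rayleigh_range(doubled_n) == pytest.approx(2 * rayleigh_range(design_beam))
        doubled_lam = GaussianBeamSpec(4.2, 1.064, 1.46)
        assert rayleigh_range(doubled_lam) == pytest.approx(rayleigh_range(design_beam) / 2)

    def test_intensity_normalisation_and_symmetry(self, design_beam):
        assert intensity(design_beam, 0.0, 0.0) == 1.0
        r = np.linspace(0.1, 5, 7)
        assert intensity(design_beam, r, 300.0) == pytest.approx(
            intensity(design_beam, -r, 300.0)
        )

    def test_radial_flatness_under_2pct_at_1mm(self, design_beam):
        # across the 4 um channel, 1 mm from the waist
        flat = radial_flatness(design_beam, 1000.0, 4.0)
        assert 0 < flat <= 0.02
        assert 1 - intensity(design_beam, 2.0, 1000.0) / intensity(
            design_beam, 0.0, 1000.0
        ) == pytest.approx(flat)

    def test_radial_flatness_degenerate_channel(self, design_beam):
        assert radial_flatness(design_beam, 500.0, 0.0) == 0.0

    def test_radial_flatness_decreases_with_distance(self, design_beam):
        z = np.linspace(100.0, 5000.0, 30)
        vals = [radial_flatness(design_beam, zi, 4.0) for zi in z]
        assert np.all(np.diff(vals) < 0)

    def test_axial_decay_over_diffusion_length(self, design_beam):
        # ~4% drop over one diffusion length starting 1 mm from the waist
        l_dif = diffusion_length(2.86, 65.0)
        decay = axial_decay(design_beam, 1000.0, l_dif)
        assert decay == pytest.approx(0.04, abs=0.005)

    def test_axial_decay_degenerate_and_far_field(self, design_beam):
        assert axial_decay(design_beam, 1000.0, 0.0) == 0.0
        vals = [axial_decay(design_beam, za, 19.0) for za in (1e3, 1e4, 1e5, 1e6)]
        assert np.all(np.diff(vals) < 0)
        assert vals[-1] < 1e-4

    def test_invalid_beam_parameters(self):
        with pytest.raises(ValueError):
            GaussianBeamSpec(-1.0, 0.532, 1.46)
        with pytest.raises(ValueError):
            GaussianBeamSpec(4.2, 0.532, 0.9)


class TestRegime:
    @pytest.mark.parametrize(
        "delta_n,expected",
        [(0.004, "guided"), (-0.004, "leaky"), (0.0, "flat"), (4e-5, "flat")],
    )
    def test_reference_cases(self, delta_n, expected):
        assert classify_regime(delta_n) == expected

    @settings(derandomize=True, max_examples=50)
    @given(delta_n=st.floats(min_value=-0.1, max_value=0.1, allow_nan=False))
    def test_antisymmetry(self, delta_n):
        swap = {"guided": "leaky", "leaky": "guided", "flat": "flat"}
        assert classify_regime(-delta_n) == swap[classify_regime(delta_n)]


def second_moment_radius(x, profile):
    """1/e^2 radius of a Gaussian profile from its second moment (w = 2 sigma)."""
    return 2.0 * np.sqrt(np.sum(profile * x**2) / np.sum(profile))


@pytest.fixture(scope="module")
def wide_grid():
    return np.arange(-204.8, 204.8, 0.05)


@pytest.fixture(scope="module")
def capillary_fields(capillary):
    """End fields after 50 um in the capillary for the three index regimes."""
    x = np.arange(-51.2, 51.2, 0.05)
    beam = GaussianBeamSpec(4.2, 0.532, capillary.cladding_index)
    f0 = gaussian_field_1d(beam, x, 1000.0)
    out = {}
    for dn in (0.004, -0.004, 0.0):
        liquid = LiquidSpec(capillary.cladding_index + dn, 3.3e-3, 293.15)
        profile = capillary_index_profile(x, capillary, liquid)
        out[dn] = propagate(f0, profile, 50.0, step_um=0.25)
    return x, out


class TestPropagator:
    def test_matches_analytic_beam(self, design_beam, wide_grid):
        f0 = gaussian_field_1d(design_beam, wide_grid)
        f1 = propagate(f0, None, 1000.0, step_um=0.5)
        ref = gaussian_field_1d(design_beam, wide_grid, 1000.0)
        c = wide_grid.size // 2
        assert f1.intensity[c] == pytest.approx(ref.intensity[c], rel=0.01)
        assert second_moment_radius(wide_grid, f1.intensity) == pytest.approx(
            second_moment_radius(wide_grid, ref.intensity), rel=0.01
        )

    def test_matches_analytic_beam_to_ten_rayleigh_ranges(self, design_beam, wide_grid):
        zr = rayleigh_range(design_beam)
        f0 = gaussian_field_1d(design_beam, wide_grid)
        f1 = propagate(f0, None, 10 * zr, step_um=1.0)
        ref = gaussian_field_1d(design_beam, wide_grid, 10 * zr)
        c = wide_grid.size // 2
        assert f1.intensity[c] == pytest.approx(ref.intensity[c], rel=0.01)
        assert second_moment_radius(wide_grid, f1.intensity) == pytest.approx(
            second_moment_radius(wide_grid, ref.intensity), rel=0.01
        )

    def test_power_conserved_in_homogeneous_medium(self, design_beam, wide_grid):
        f0 = gaussian_field_1d(design_beam, wide_grid)
        f1 = propagate(f0, None, 1000.0, step_um=0.5)
        assert abs(f1.power / f0.power - 1.0) < 1e-3

    def test_matched_index_stays_flat_across_channel(self, capillary_fields):
        x, fields = capillary_fields
        channel = np.abs(x) <= 2.0
        profile = fields[0.0].intensity[channel]
        assert 1.0 - profile.min() / profile.max() < 0.02

    def test_positive_mismatch_concentrates_light(self, capillary_fields):
        x, fields = capillary_fields
        c = x.size // 2
        wall = np.argmin(np.abs(x - 2.0))
        guided_ratio = fields[0.004].intensity[c] / fields[0.004].intensity[wall]
        flat_ratio = fields[0.0].intensity[c] / fields[0.0].intensity[wall]
        assert guided_ratio > flat_ratio
        assert guided_ratio > 1.5  # clear centre concentration

    def test_negative_mismatch_dissipates_power(self, capillary_fields):
        x, fields = capillary_fields
        c = x.size // 2
        assert fields[-0.004].intensity[c] < 0.7 * fields[0.0].intensity[c]

    def test_rejects_coarse_grid(self, design_beam):
        x = np.arange(-50.0, 50.0, 0.5)  # > lambda/2n
        f0 = gaussian_field_1d(design_beam, x)
        with pytest.raises(ValueError, match="too coarse"):
            propagate(f0, None, 10.0, step_um=0.25)

    def test_rejects_bad_steps(self, design_beam, wide_grid):
        f0 = gaussian_field_1d(design_beam, wide_grid)
        with pytest.raises(ValueError):
            propagate(f0, None, 1.0, step_um=2.0)  # step > distance
        with pytest.raises(ValueError, match="stability"):
            propagate(f0, None, 100.0, step_um=50.0, max_step_um=1.0)

    def test_record_intensity_map(self, design_beam, wide_grid):
        f0 = gaussian_field_1d(design_beam, wide_grid)
        _, zs, frames = propagate(f0, None, 10.0, step_um=0.5, record_every=4)
        assert zs.shape[0] == frames.shape[0] == 5
        assert frames.shape[1] == wide_grid.size

    def test_field_exports(self, design_beam, wide_grid, tmp_path):
        import pandas as pd
        import tifffile

        from canta.beam import write_intensity_tiff, write_profile_csv

        f0 = gaussian_field_1d(design_beam, wide_grid)
        _, _, frames = propagate(f0, None, 10.0, step_um=0.5, record_every=4)
        write_intensity_tiff(tmp_path / "map.tiff", frames)
        loaded = tifffile.imread(tmp_path / "map.tiff")
        assert loaded.dtype == np.float32
        assert loaded.shape == frames.shape
        write_profile_csv(tmp_path / "profile.csv", wide_grid, f0.intensity)
        df = pd.read_csv(tmp_path / "profile.csv")
        assert df["intensity"].to_numpy() == pytest.approx(f0.intensity, rel=1e-6)


class TestIlluminationProfiles:
    def test_guided_profile_contrast(self):
        field = guided_mode_profile(2.0, center_to_edge_ratio=2.5)
        center = field.intensity(0.0, 0.0, 0.0)
        edge = field.intensity(2.0, 0.0, 0.0)
        assert center / edge == pytest.approx(2.5)

    def test_radial_profile_interpolates(self):
        field = RadialProfileField(np.array([0.0, 1.0, 2.0]), np.array([1.0, 0.5, 0.25]))
        assert field.intensity(0.5, 0.0, 0.0) == pytest.approx(0.75)
        # radial symmetry: depends on hypot(x, y)
        assert field.intensity(0.6, 0.8, 0.0) == pytest.approx(field.intensity(1.0, 0.0, 5.0))

    def test_plane_wave_power(self):
        x = np.arange(-10.0, 10.0, 0.05)
        f = plane_wave_field(x, 0.532, 1.46)
        assert f.intensity == pytest.approx(np.ones_like(x))
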
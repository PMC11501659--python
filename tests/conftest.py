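"""Shared fixtures: the reference experiment's parameters."""

import numpy as np
import pytest

from canta import (
    AcquisitionConfig,
    CameraModel,
    CapillarySpec,
    ChannelGeometry,
    GaussianBeamSpec,
    LiquidSpec,
    ParticleSpec,
)


@pytest.fixture(scope="session")
def design_beam() -> GaussianBeamSpec:
    """The design beam: omega_0 = 4.2 um, 532 nm, index 1.46."""
    return GaussianBeamSpec(waist_radius_um=4.2, vacuum_wavelength_um=0.532, medium_index=1.46)


@pytest.fixture(scope="session")
def capillary() -> CapillarySpec:
    return CapillarySpec(channel_diameter_um=4.0, outer_diameter_um=125.0, cladding_index=1.4607)


@pytest.fixture(scope="session")
def liquid() -> LiquidSpec:
    """Index-matched water/DMSO mixture."""
    return LiquidSpec(refractive_index=1.4607, viscosity_pa_s=3.3e-3, temperature_k=293.15)


@pytest.fixture(scope="session")
def particle() -> ParticleSpec:
    return ParticleSpec(diameter_nm=50.0, material="gold")


@pytest.fixture(scope="session")
def geometry() -> ChannelGeometry:
    return ChannelGeometry(radius_um=2.0, axial_extent_um=200.0, axial_offset_um=1000.0)


@pytest.fixture(scope="session")
def camera() -> CameraModel:
    return CameraModel()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_acquisition(n_frames: int, seed: int = 0, **kwargs) -> AcquisitionConfig:
    return AcquisitionConfig(n_frames=n_frames, seed=seed, **kwargs)
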
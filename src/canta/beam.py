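"""Gaussian-beam optics and flat-field illumination design.

The flat-field concept: a nanoparticle diffusing in a liquid-filled capillary
microchannel is illuminated by a freely diffracting Gaussian beam whose waist
is much larger than the channel.  If the liquid refractive index matches the
cladding (Delta_n = n_liquid - n_cladding = 0), no modes form and the particle
sees an essentially position-independent intensity.  A positive mismatch
creates guided modes (centre-concentrated intensity), a negative one leaky
modes (centre-depleted).

This module provides the analytic Gaussian-beam formulas used for the design
metrics (Rayleigh range, radial flatness across the channel, axial decay over
a diffusion length), the mismatch regime classifier, illumination-field
objects consumed by the synthetic-data generator, and a paraxial split-step
scalar beam propagator for the (x, z) plane that reproduces the guided /
leaky / flat phenomenology of the liquid-filled capillary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "GaussianBeamSpec",
    "CapillarySpec",
    "LiquidSpec",
    "rayleigh_range",
    "beam_radius",
    "intensity",
    "radial_flatness",
    "axial_decay",
    "classify_regime",
    "IlluminationField",
    "GaussianBeamField",
    "RadialProfileField",
    "guided_mode_profile",
    "ScalarField2D",
    "gaussian_field_1d",
    "plane_wave_field",
    "capillary_index_profile",
    "propagate",
]

#: Default |Delta_n| tolerance for regime classification: one order of
#: magnitude below the smallest mismatch considered in the design study.
REGIME_TOLERANCE = 5e-5


@dataclass(frozen=True)
class GaussianBeamSpec:
    """A fundamental Gaussian beam in a homogeneous medium.

    Parameters
    ----------
    waist_radius_um : float
        1/e^2 intensity radius omega_0 at the waist, um.
    vacuum_wavelength_um : float
        Vacuum wavelength lambda_0, um.
    medium_index : float
        Refractive index n of the propagation medium (>= 1).
    power : float
        Total beam power in arbitrary units (default 1).
    """

    waist_radius_um: float
    vacuum_wavelength_um: float
    medium_index: float
    power: float = 1.0

    def __post_init__(self) -> None:
        if not self.waist_radius_um > 0:
            raise ValueError("waist_radius_um must be > 0")
        if not self.vacuum_wavelength_um > 0:
            raise ValueError("vacuum_wavelength_um must be > 0")
        if not self.medium_index >= 1:
            raise ValueError("medium_index must be >= 1")


@dataclass(frozen=True)
class CapillarySpec:
    """Silica capillary with a central fluidic hole."""

    channel_diameter_um: float
    outer_diameter_um: float
    cladding_index: float

    def __post_init__(self) -> None:
        if not 0 < self.channel_diameter_um < self.outer_diameter_um:
            raise ValueError("need 0 < channel_diameter_um < outer_diameter_um")
        if not self.cladding_index >= 1:
            raise ValueError("cladding_index must be >= 1")


@dataclass(frozen=True)
class LiquidSpec:
    """Host liquid filling the microchannel (e.g. a water/DMSO mixture)."""

    refractive_index: float
    viscosity_pa_s: float
    temperature_k: float

    def __post_init__(self) -> None:
        if not self.viscosity_pa_s > 0:
            raise ValueError("viscosity_pa_s must be > 0")
        if not self.temperature_k > 0:
            raise ValueError("temperature_k must be > 0")


# ---------------------------------------------------------------------------
# analytic Gaussian-beam formulas
# ---------------------------------------------------------------------------

def rayleigh_range(beam: GaussianBeamSpec) -> float:
    """Rayleigh range z_R = pi omega_0^2 n / lambda_0, um."""
    return float(
        np.pi * beam.waist_radius_um**2 * beam.medium_index / beam.vacuum_wavelength_um
    )


def beam_radius(beam: GaussianBeamSpec, z_um) -> np.ndarray | float:
    """1/e^2 radius omega(z) = omega_0 sqrt(1 + (z/z_R)^2), um."""
    z = np.asarray(z_um, dtype=float)
    w = beam.waist_radius_um * np.sqrt(1.0 + (z / rayleigh_range(beam)) ** 2)
    return float(w) if np.isscalar(z_um) else w


def intensity(beam: GaussianBeamSpec, r_um, z_um) -> np.ndarray | float:
    """Normalised intensity I(r, z) with I(0, 0) = 1.

    I(r, z) = [omega_0/omega(z)]^2 exp(-2 r^2 / omega(z)^2).
    """
    r = np.asarray(r_um, dtype=float)
    w = np.asarray(beam_radius(beam, z_um), dtype=float)
    out = (beam.waist_radius_um / w) ** 2 * np.exp(-2.0 * r**2 / w**2)
    if np.isscalar(r_um) and np.isscalar(z_um):
        return float(out)
    return out


def radial_flatness(beam: GaussianBeamSpec, z_um: float, channel_diameter_um: float) -> float:
    """Fractional centre-to-edge intensity drop across the channel at z.

    Returns 1 - I(D/2, z)/I(0, z) in [0, 1); 0 for a degenerate channel.
    """
    if channel_diameter_um < 0:
        raise ValueError("channel_diameter_um must be >= 0")
    if z_um < 0:
        raise ValueError("z_um must be >= 0")
    if channel_diameter_um == 0:
        return 0.0
    w = beam_radius(beam, z_um)
    return float(1.0 - np.exp(-2.0 * (channel_diameter_um / 2.0) ** 2 / w**2))


def axial_decay(beam: GaussianBeamSpec, z_a_um: float, dz_um: float) -> float:
    """Fractional on-axis intensity decrease over [z_a, z_a + dz].

    On-axis I(0, z) is proportional to 1/(1 + (z/z_R)^2).
    """
    if z_a_um < 0 or dz_um < 0:
        raise ValueError("z_a_um and dz_um must be >= 0")
    zr2 = rayleigh_range(beam) ** 2
    i0 = 1.0 / (1.0 + z_a_um**2 / zr2)
    i1 = 1.0 / (1.0 + (z_a_um + dz_um) ** 2 / zr2)
    return float(1.0 - i1 / i0)


def classify_regime(delta_n: float, tolerance: float = REGIME_TOLERANCE) -> str:
    """Classify the index mismatch Delta_n = n_liquid - n_cladding.

    Returns ``"flat"`` for |Delta_n| <= tolerance, ``"guided"`` for a positive
    mismatch (total internal reflection in the channel) and ``"leaky"`` for a
    negative one (power dissipates transversely).
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if abs(delta_n) <= tolerance:
        return "flat"
    return "guided" if delta_n > 0 else "leaky"


# ---------------------------------------------------------------------------
# illumination fields consumed by the synthetic-data generator
# ---------------------------------------------------------------------------

class IlluminationField:
    """Normalised optical intensity as a function of position in the channel.

    Coordinates: (x, y) transverse, origin on the channel axis; z along the
    channel measured from the start of the tracking region.
    """

    def intensity(self, x_um, y_um, z_um):  # pragma: no cover - interface
        raise NotImplementedError


@dataclass(frozen=True)
class GaussianBeamField(IlluminationField):
    """Freely diffracting Gaussian beam launched ``z_offset_um`` upstream.

    The flat-field illumination of the experiment: the tracking region starts
    a distance z_a from the beam waist, so the local axial coordinate z maps
    to z_a + z in beam coordinates.
    """

    beam: GaussianBeamSpec
    z_offset_um: float = 1000.0

    def intensity(self, x_um, y_um, z_um):
        r = np.hypot(np.asarray(x_um, dtype=float), np.asarray(y_um, dtype=float))
        return intensity(self.beam, r, self.z_offset_um + np.asarray(z_um, dtype=float))


@dataclass(frozen=True)
class RadialProfileField(IlluminationField):
    """z-invariant field defined by a sampled radial intensity profile I(r)."""

    r_um: np.ndarray
    profile: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.r_um, dtype=float)
        p = np.asarray(self.profile, dtype=float)
        if r.ndim != 1 or r.shape != p.shape or r.size < 2:
            raise ValueError("r_um and profile must be matching 1D arrays (size >= 2)")
        if np.any(np.diff(r) <= 0):
            raise ValueError("r_um must be strictly increasing")
        object.__setattr__(self, "r_um", r)
        object.__setattr__(self, "profile", p)

    def intensity(self, x_um, y_um, z_um):
        r = np.hypot(np.asarray(x_um, dtype=float), np.asarray(y_um, dtype=float))
        return np.interp(r, self.r_um, self.profile)


def guided_mode_profile(
    channel_radius_um: float, center_to_edge_ratio: float = 2.5, n_points: int = 257
) -> RadialProfileField:
    """Centre-peaked parabolic profile emulating a guided-mode intensity.

    I(r) = 1 - (1 - 1/ratio) (r/R)^2 inside the channel, continued at its edge
    value outside.  ``center_to_edge_ratio=2.5`` mimics the intensity contrast
    a small positive index mismatch (Delta_n ~ +0.004) produces.
    """
    if center_to_edge_ratio <= 0:
        raise ValueError("center_to_edge_ratio must be > 0")
    r = np.linspace(0.0, 2.0 * channel_radius_um, n_points)
    frac = np.clip(r / channel_radius_um, 0.0, 1.0)
    profile = 1.0 - (1.0 - 1.0 / center_to_edge_ratio) * frac**2
    return RadialProfileField(r_um=r, profile=profile)


# ---------------------------------------------------------------------------
# paraxial split-step scalar propagation in the (x, z) plane
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScalarField2D:
    """Complex scalar field sampled on a transverse x grid at one z position.

    A numerical stand-in for full electromagnetic field solutions: the field
    lives in the (x, z) plane and is advanced along z by :func:`propagate`.
    """

    x_um: np.ndarray
    amplitude: np.ndarray
    z_um: float
    vacuum_wavelength_um: float
    reference_index: float

    def __post_init__(self) -> None:
        x = np.asarray(self.x_um, dtype=float)
        a = np.asarray(self.amplitude, dtype=complex)
        if x.ndim != 1 or x.shape != a.shape or x.size < 8:
            raise ValueError("x_um and amplitude must be matching 1D arrays (size >= 8)")
        dx = np.diff(x)
        if not np.allclose(dx, dx[0]) or dx[0] <= 0:
            raise ValueError("x grid must be uniform and increasing")
        if not np.isfinite(a).all():
            raise ValueError("amplitude must be finite")
        object.__setattr__(self, "x_um", x)
        object.__setattr__(self, "amplitude", a)

    @property
    def dx_um(self) -> float:
        return float(self.x_um[1] - self.x_um[0])

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.amplitude) ** 2

    @property
    def power(self) -> float:
        """Integrated |E|^2 dx (arbitrary units)."""
        return float(np.sum(self.intensity) * self.dx_um)


def gaussian_field_1d(
    beam: GaussianBeamSpec, x_um: np.ndarray, z_um: float = 0.0
) -> ScalarField2D:
    """Analytic slab (1D-transverse) Gaussian beam a distance z from its waist.

    E(x, z) = (1 + i z/z_R)^(-1/2) exp(-x^2 / (omega_0^2 (1 + i z/z_R))),
    the exact solution of the paraxial wave equation used by the propagator.
    For a slab beam the on-axis intensity decays as omega_0/omega(z) (one
    transverse dimension spreads) while omega(z) follows the standard
    hyperbolic law.
    """
    x = np.asarray(x_um, dtype=float)
    zr = rayleigh_range(beam)
    q = 1.0 + 1j * z_um / zr
    amp = np.exp(-(x**2) / (beam.waist_radius_um**2 * q)) / np.sqrt(q)
    return ScalarField2D(
        x_um=x,
        amplitude=amp,
        z_um=z_um,
        vacuum_wavelength_um=beam.vacuum_wavelength_um,
        reference_index=beam.medium_index,
    )


def plane_wave_field(
    x_um: np.ndarray, vacuum_wavelength_um: float, medium_index: float
) -> ScalarField2D:
    """Unit-amplitude plane wave on the grid (k along z)."""
    x = np.asarray(x_um, dtype=float)
    return ScalarField2D(
        x_um=x,
        amplitude=np.ones_like(x, dtype=complex),
        z_um=0.0,
        vacuum_wavelength_um=vacuum_wavelength_um,
        reference_index=medium_index,
    )


def capillary_index_profile(
    x_um: np.ndarray, capillary: CapillarySpec, liquid: LiquidSpec
) -> np.ndarray:
    """Step index profile: liquid inside the hole, cladding outside.

    The 125 um outer capillary surface is deliberately ignored: the tracking
    region is chosen to avoid reflections from it, so only the channel /
    cladding step matters for the fields inside the hole.
    """
    x = np.asarray(x_um, dtype=float)
    inside = np.abs(x) <= capillary.channel_diameter_um / 2.0
    return np.where(inside, liquid.refractive_index, capillary.cladding_index)


def _absorber(x: np.ndarray, width_fraction: float) -> np.ndarray:
    """Super-Gaussian edge mask suppressing wrap-around at the grid boundary."""
    half = (x[-1] - x[0]) / 2.0
    x0 = (x[-1] + x[0]) / 2.0
    edge = half * (1.0 - width_fraction)
    d = np.maximum(np.abs(x - x0) - edge, 0.0) / (half * width_fraction)
    return np.exp(-3.0 * d**4)


def propagate(
    field: ScalarField2D,
    index_profile: np.ndarray | None,
    distance_um: float,
    step_um: float = 0.25,
    absorber_fraction: float = 0.1,
    max_step_um: float = 1.0,
    record_every: int | None = None,
) -> ScalarField2D | tuple[ScalarField2D, np.ndarray, np.ndarray]:
    """Advance a scalar field by ``distance_um`` with a split-step method.

    Paraxial beam propagation: each step applies the exact free-space
    diffraction operator in the spatial-frequency domain (reference index
    ``field.reference_index``) and a thin phase screen for the index contrast
    n(x) - n_ref.  A super-Gaussian absorber at the grid edges emulates open
    boundaries (power leaving the window is removed, as for leaky modes).

    Parameters
    ----------
    index_profile : array or None
        Refractive index on ``field.x_um``; ``None`` means homogeneous
        propagation at the reference index.
    record_every : int or None
        If set, also return (z positions, intensity map) sampled every that
        many steps, ordered with z along the first axis.

    Returns
    -------
    ScalarField2D, or (ScalarField2D, z_um array, intensity map) when
    ``record_every`` is given.
    """
    if distance_um <= 0:
        raise ValueError("distance_um must be > 0")
    if step_um <= 0 or step_um > distance_um:
        raise ValueError("need 0 < step_um <= distance_um")
    if step_um > max_step_um:
        raise ValueError(
            f"axial step {step_um} um exceeds the stability bound {max_step_um} um"
        )
    n_max = field.reference_index
    if index_profile is not None:
        index_profile = np.asarray(index_profile, dtype=float)
        if index_profile.shape != field.x_um.shape:
            raise ValueError("index_profile must be sampled on the field grid")
        n_max = max(n_max, float(index_profile.max()))
    if field.dx_um > field.vacuum_wavelength_um / (2.0 * n_max):
        raise ValueError(
            "transverse grid too coarse: dx must resolve half the medium wavelength"
        )

    lam = field.vacuum_wavelength_um
    k0 = 2.0 * np.pi / lam
    kbar = k0 * field.reference_index
    n_steps = int(np.ceil(distance_um / step_um))
    dz = distance_um / n_steps

    kx = 2.0 * np.pi * np.fft.fftfreq(field.x_um.size, d=field.dx_um)
    diffraction = np.exp(-1j * kx**2 * dz / (2.0 * kbar))
    if index_profile is None:
        phase = None
    else:
        phase = np.exp(1j * k0 * (index_profile - field.reference_index) * dz)
    mask = _absorber(field.x_um, absorber_fraction)

    amp = field.amplitude.copy()
    zs, frames = [], []
    for i in range(n_steps):
        amp = np.fft.ifft(np.fft.fft(amp) * diffraction)
        if phase is not None:
            amp = amp * phase
        amp = amp * mask
        if record_every is not None and (i + 1) % record_every == 0:
            zs.append(field.z_um + (i + 1) * dz)
            frames.append(np.abs(amp) ** 2)

    out = replace(field, amplitude=amp, z_um=field.z_um + distance_um)
    if record_every is not None:
        return out, np.asarray(zs), np.asarray(frames)
    return out


def write_intensity_tiff(path, intensity_map: np.ndarray) -> None:
    """Export an |E|^2 map (e.g. from ``propagate(..., record_every=...)``)
    as 32-bit float TIFF."""
    import tifffile

    tifffile.imwrite(path, np.asarray(intensity_map, dtype=np.float32))


def write_profile_csv(path, x_um: np.ndarray, intensity: np.ndarray) -> None:
    """Export a transverse line profile as CSV (x_um, intensity)."""
    import pandas as pd

    pd.DataFrame({"x_um": x_um, "intensity": intensity}).to_csv(path, index=False)
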
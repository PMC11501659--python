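"""Physical-chemistry utilities for nanoparticle tracking analysis.

Stokes-Einstein relations between hydrodynamic diameter and diffusion
coefficient, the diffusion length over a measurement time, hindered-diffusion
corrections for a sphere confined to a cylindrical microchannel, and the
Washburn capillary-filling law.

Unit convention: the public API uses the reporting units of the field
(nm for particle diameters, um and um^2/s for lengths and diffusion
coefficients, Pa*s, K, s); conversions to SI happen internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BOLTZMANN_J_PER_K",
    "ParticleSpec",
    "DiffusionSummary",
    "stokes_einstein_D",
    "stokes_einstein_d",
    "diffusion_length",
    "hindrance_factor",
    "washburn_fill_length",
]

#: Boltzmann constant (exact, SI), J/K.
BOLTZMANN_J_PER_K = 1.380649e-23


@dataclass(frozen=True)
class ParticleSpec:
    """A spherical scatterer.

    Parameters
    ----------
    diameter_nm : float
        Geometric diameter in nm.
    material : str
        Free-text material tag (e.g. ``"gold"``).
    scattering_scale : float or None
        Relative scattered-intensity scale.  ``None`` (default) applies the
        Rayleigh d^6 law, evaluated as ``(diameter_nm / 100)**6`` so that the
        scale is dimensionless and of order one for sub-100 nm particles.
    """

    diameter_nm: float
    material: str = ""
    scattering_scale: float | None = None

    def __post_init__(self) -> None:
        if not self.diameter_nm > 0:
            raise ValueError(f"diameter_nm must be > 0, got {self.diameter_nm}")

    @property
    def relative_scattering(self) -> float:
        """Scattered-intensity scale; d^6 law unless overridden."""
        if self.scattering_scale is not None:
            return self.scattering_scale
        return (self.diameter_nm / 100.0) ** 6


@dataclass(frozen=True)
class DiffusionSummary:
    """Transport numbers characterising one tracking experiment."""

    diffusion_coefficient_um2_s: float
    hydrodynamic_diameter_nm: float
    diffusion_length_um: float
    measurement_time_s: float
    hindrance_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "diffusion_coefficient_um2_s",
            "hydrodynamic_diameter_nm",
            "diffusion_length_um",
            "measurement_time_s",
            "hindrance_factor",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


def _require_positive(**values: float) -> None:
    for name, value in values.items():
        if not np.all(np.asarray(value) > 0):
            raise ValueError(f"{name} must be > 0, got {value}")


def stokes_einstein_D(diameter_nm: float, viscosity_pa_s: float, temperature_k: float) -> float:
    """Free-solution diffusion coefficient of a sphere, in um^2/s.

    D = k_B T / (3 pi eta d).
    """
    _require_positive(
        diameter_nm=diameter_nm, viscosity_pa_s=viscosity_pa_s, temperature_k=temperature_k
    )
    d_m = diameter_nm * 1e-9
    d_m2_s = BOLTZMANN_J_PER_K * temperature_k / (3.0 * np.pi * viscosity_pa_s * d_m)
    return d_m2_s * 1e12  # m^2/s -> um^2/s


def stokes_einstein_d(diffusion_um2_s: float, viscosity_pa_s: float, temperature_k: float) -> float:
    """Hydrodynamic diameter in nm from a diffusion coefficient in um^2/s.

    Exact algebraic inverse of :func:`stokes_einstein_D`.
    """
    _require_positive(
        diffusion_um2_s=diffusion_um2_s,
        viscosity_pa_s=viscosity_pa_s,
        temperature_k=temperature_k,
    )
    d_m2_s = diffusion_um2_s * 1e-12
    d_m = BOLTZMANN_J_PER_K * temperature_k / (3.0 * np.pi * viscosity_pa_s * d_m2_s)
    return d_m * 1e9


def diffusion_length(diffusion_um2_s: float, tau_s: float) -> float:
    """One-dimensional rms diffusion length L = sqrt(2 D tau), in um."""
    if diffusion_um2_s < 0 or tau_s < 0:
        raise ValueError("diffusion coefficient and time must be >= 0")
    return float(np.sqrt(2.0 * diffusion_um2_s * tau_s))


# Centerline hindrance polynomials for a sphere of diameter d in a cylindrical
# pore of diameter D, lam = d/D.  H(lam) multiplies the free-solution D; the
# apparent-size correction factor is R = 1/H >= 1.
def _renkin_H(lam: np.ndarray) -> np.ndarray:
    return (1.0 - lam) ** 2 * (1.0 - 2.104 * lam + 2.09 * lam**3 - 0.95 * lam**5)


def _dechadilok_deen_H(lam: np.ndarray) -> np.ndarray:
    lam = np.asarray(lam, dtype=float)
    out = np.ones_like(lam)
    nz = lam > 0
    ln = np.where(nz, lam, 1.0)
    out = (
        1.0
        + 9.0 / 8.0 * lam * np.where(nz, np.log(ln), 0.0)
        - 1.56034 * lam
        + 0.528155 * lam**2
        + 1.91521 * lam**3
        - 2.81903 * lam**4
        + 0.270788 * lam**5
        + 1.10115 * lam**6
        - 0.435933 * lam**7
    )
    return out


_HINDRANCE_MODELS = {
    "renkin": _renkin_H,
    "dechadilok-deen": _dechadilok_deen_H,
}


def hindrance_factor(diameter_nm: float, channel_diameter_um: float, model: str = "renkin") -> float:
    """Hindered-diffusion correction factor R >= 1 for a confined sphere.

    The channel slows diffusion: D_confined = D_free * H(lam) with
    lam = d / D_channel, so the apparent hydrodynamic size inferred from the
    measured D must be corrected by R = 1/H.  R -> 1 as lam -> 0 (free
    diffusion).

    Parameters
    ----------
    diameter_nm : float
        Particle diameter (nm).
    channel_diameter_um : float
        Cylindrical channel diameter (um).
    model : {"renkin", "dechadilok-deen"}
        Centerline hindrance correlation to use.
    """
    _require_positive(diameter_nm=diameter_nm, channel_diameter_um=channel_diameter_um)
    try:
        H = _HINDRANCE_MODELS[model]
    except KeyError:
        raise ValueError(
            f"unknown hindrance model {model!r}; available: {sorted(_HINDRANCE_MODELS)}"
        ) from None
    lam = diameter_nm * 1e-3 / channel_diameter_um
    if lam >= 1.0:
        raise ValueError("particle does not fit in the channel (d/D >= 1)")
    h = float(H(np.asarray(lam)))
    if not 0 < h <= 1.0 + 1e-12:
        raise ValueError(f"hindrance model {model!r} out of validity range at lam={lam:g}")
    return 1.0 / h


def washburn_fill_length(
    surface_tension_n_m: float,
    contact_angle_rad: float,
    channel_radius_um: float,
    viscosity_pa_s: float,
    t_s: float,
) -> float:
    """Capillary-driven filled length L(t) = sqrt(gamma R cos(theta) t / (2 eta)), in um.

    Describes passive filling of the microchannel by the capillary effect;
    L grows as sqrt(t).
    """
    _require_positive(
        surface_tension_n_m=surface_tension_n_m,
        channel_radius_um=channel_radius_um,
        viscosity_pa_s=viscosity_pa_s,
    )
    if not 0 <= contact_angle_rad < np.pi / 2:
        raise ValueError("contact angle must lie in [0, pi/2) for spontaneous filling")
    if t_s < 0:
        raise ValueError("time must be >= 0")
    r_m = channel_radius_um * 1e-6
    l_m = np.sqrt(
        surface_tension_n_m * r_m * np.cos(contact_angle_rad) * t_s / (2.0 * viscosity_pa_s)
    )
    return float(l_m * 1e6)
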
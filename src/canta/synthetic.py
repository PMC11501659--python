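"""Synthetic optofluidic tracking data: the in-silico stand-in for the experiment.

Generates ground-truth trajectories of a single nanoparticle diffusing in a
liquid-filled cylindrical microchannel, its scattered-intensity time series
under a chosen illumination field, and rendered camera frames (Airy point
spread function, shot noise, read noise, offset, quantisation, saturation).

Default parameters emulate the reference experiment: a 50 nm gold nanosphere
in a 4 um channel filled with a water/DMSO mixture (eta = 3.3 mPa*s,
T = 293.15 K), illuminated at 532 nm by a Gaussian beam (omega_0 = 4.2 um)
1 mm from its waist, imaged at 1 kHz with 0.2 ms exposure on a 16-bit camera
(noise floor ~200 counts, saturation 65,000) with a 30 x 600 px field of view
for 65,000 frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import j1

from .beam import IlluminationField
from .transport import ParticleSpec

__all__ = [
    "ChannelGeometry",
    "AcquisitionConfig",
    "CameraModel",
    "TrajectoryRecord",
    "FrameStack",
    "simulate_confined_brownian",
    "scattered_intensity",
    "apply_shot_noise",
    "airy_radius_um",
    "render_frames",
    "auto_photon_scale",
]


@dataclass(frozen=True)
class ChannelGeometry:
    """Cylindrical fluidic channel, axis along z.

    ``axial_offset_um`` is the distance z_a of the tracking region from the
    illumination beam waist (1 mm in the reference layout).
    """

    radius_um: float = 2.0
    axial_extent_um: float = 200.0
    axial_offset_um: float = 1000.0

    def __post_init__(self) -> None:
        if not self.radius_um > 0:
            raise ValueError("radius_um must be > 0")
        if not self.axial_extent_um > 0:
            raise ValueError("axial_extent_um must be > 0")


@dataclass(frozen=True)
class AcquisitionConfig:
    """Camera timing: frame rate, exposure, frame count, substep resolution.

    Brownian motion is integrated on ``substeps_per_frame`` substeps per frame
    period; the exposure window covers the first ``exposure_s * frame_rate_hz``
    fraction of each period, and the substeps falling inside it carry the
    motion blur.  The default (50 substeps at 1 kHz / 0.2 ms exposure) puts 10
    substeps inside the exposure.
    """

    frame_rate_hz: float = 1000.0
    exposure_s: float = 0.2e-3
    n_frames: int = 65_000
    substeps_per_frame: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.frame_rate_hz > 0:
            raise ValueError("frame_rate_hz must be > 0")
        if not 0 < self.exposure_s <= 1.0 / self.frame_rate_hz:
            raise ValueError("need 0 < exposure_s <= 1/frame_rate_hz")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.substeps_per_frame < 1:
            raise ValueError("substeps_per_frame must be >= 1")

    @property
    def frame_period_s(self) -> float:
        return 1.0 / self.frame_rate_hz

    @property
    def substep_dt_s(self) -> float:
        return self.frame_period_s / self.substeps_per_frame

    @property
    def n_exposure_substeps(self) -> int:
        """Substeps inside the exposure window (at least 1)."""
        return max(1, round(self.exposure_s * self.frame_rate_hz * self.substeps_per_frame))


@dataclass(frozen=True)
class CameraModel:
    """Monochrome scientific camera with a linear response.

    ``photon_scale`` converts scattered-intensity units into peak counts of
    the rendered point-spread function; shot noise is Poisson in counts, read
    noise Gaussian, and the noise floor an additive offset.
    """

    pixel_pitch_um: float = 0.345
    bit_depth: int = 16
    noise_floor: float = 200.0
    saturation: float = 65_000.0
    read_noise: float = 10.0
    photon_scale: float = 1.0

    def __post_init__(self) -> None:
        if not self.pixel_pitch_um > 0:
            raise ValueError("pixel_pitch_um must be > 0")
        if not 0 < self.noise_floor < self.saturation <= 2**self.bit_depth - 1:
            raise ValueError("need 0 < noise_floor < saturation <= 2**bit_depth - 1")
        if self.read_noise < 0 or self.photon_scale <= 0:
            raise ValueError("read_noise must be >= 0 and photon_scale > 0")


@dataclass
class TrajectoryRecord:
    """Ground-truth particle state, frame-sampled and at substep resolution.

    Frame-level positions are exposure averages (what an ideal camera
    localises); the per-substep positions retained in ``sub_x/sub_y/sub_z``
    (shape ``(n_frames, substeps_per_frame)``) allow motion-blur rendering and
    confinement checks at full resolution.  z is unbounded (channel axis),
    (x, y) are confined to the channel disc.
    """

    times_s: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    z_um: np.ndarray
    sub_x: np.ndarray
    sub_y: np.ndarray
    sub_z: np.ndarray
    geometry: ChannelGeometry
    acquisition: AcquisitionConfig
    diffusion_um2_s: float
    intensity: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return self.times_s.size

    def exposure_substeps(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-frame substep positions inside the exposure window."""
        m = self.acquisition.n_exposure_substeps
        return self.sub_x[:, :m], self.sub_y[:, :m], self.sub_z[:, :m]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "t": self.times_s,
                "x": self.x_um,
                "y": self.y_um,
                "z": self.z_um,
            }
        )
        if self.intensity is not None:
            df["I_true"] = self.intensity
        return df


@dataclass
class FrameStack:
    """Rendered image sequence in camera counts.

    ``origin_z_px`` records, per frame, the absolute axial pixel coordinate of
    image column 0 (the rendering window may re-centre to follow the particle;
    ground truth keeps absolute z).  Absolute positions in um:
    x = (row - (height-1)/2) * pitch, z = (origin_z_px + column) * pitch.
    """

    frames: np.ndarray
    pixel_pitch_um: float
    times_s: np.ndarray
    origin_z_px: np.ndarray
    saturation: float

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n, height, width)")
        if self.frames.max(initial=0) > self.saturation:
            raise ValueError("pixel values exceed saturation")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def write_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(path, self.frames, photometric="minisblack")


# ---------------------------------------------------------------------------
# confined Brownian dynamics
# ---------------------------------------------------------------------------

def _reflect_disc_python(x, y, steps_x, steps_y, radius):  # pragma: no cover - numba used
    n = steps_x.shape[0]
    out_x = np.empty(n)
    out_y = np.empty(n)
    for i in range(n):
        x += steps_x[i]
        y += steps_y[i]
        r = (x * x + y * y) ** 0.5
        if r > radius:
            scale = (2.0 * radius - r) / r
            x *= scale
            y *= scale
        out_x[i] = x
        out_y[i] = y
    return out_x, out_y


try:  # the reflection recursion is sequential; JIT it when numba is available
    from numba import njit

    _reflect_disc = njit(_reflect_disc_python)
except ImportError:  # pragma: no cover
    _reflect_disc = _reflect_disc_python


def simulate_confined_brownian(
    diffusion_um2_s: float,
    geometry: ChannelGeometry,
    acquisition: AcquisitionConfig,
    rng: np.random.Generator | None = None,
    start_xy_um: tuple[float, float] = (0.0, 0.0),
) -> TrajectoryRecord:
    """Brownian motion of a point particle confined to the channel disc.

    Each coordinate takes zero-mean Gaussian substeps of standard deviation
    sqrt(2 D dt_sub).  Transverse (x, y) excursions beyond the channel radius
    are reflected specularly (the radial overshoot is folded back, a no-flux
    wall); z is unbounded.  Deterministic given the acquisition seed or an
    explicit ``rng``.
    """
    if diffusion_um2_s < 0:
        raise ValueError("diffusion_um2_s must be >= 0")
    rng = np.random.default_rng(acquisition.seed) if rng is None else rng
    n_sub = acquisition.n_frames * acquisition.substeps_per_frame
    dt = acquisition.substep_dt_s
    sigma = np.sqrt(2.0 * diffusion_um2_s * dt)
    if sigma > geometry.radius_um / 5.0:
        raise ValueError(
            f"substep rms length {sigma:.3g} um exceeds radius/5; increase "
            "substeps_per_frame for adequate wall resolution"
        )
    r0 = float(np.hypot(*start_xy_um))
    if r0 > geometry.radius_um:
        raise ValueError("start position outside the channel")

    if diffusion_um2_s == 0:
        sub_x = np.full(n_sub, start_xy_um[0])
        sub_y = np.full(n_sub, start_xy_um[1])
        sub_z = np.zeros(n_sub)
    else:
        steps = rng.normal(0.0, sigma, size=(3, n_sub))
        sub_x, sub_y = _reflect_disc(
            float(start_xy_um[0]), float(start_xy_um[1]), steps[0], steps[1],
            geometry.radius_um,
        )
        sub_z = np.cumsum(steps[2])

    shape = (acquisition.n_frames, acquisition.substeps_per_frame)
    sub_x = sub_x.reshape(shape)
    sub_y = sub_y.reshape(shape)
    sub_z = sub_z.reshape(shape)
    m = acquisition.n_exposure_substeps
    times = np.arange(acquisition.n_frames) * acquisition.frame_period_s
    return TrajectoryRecord(
        times_s=times,
        x_um=sub_x[:, :m].mean(axis=1),
        y_um=sub_y[:, :m].mean(axis=1),
        z_um=sub_z[:, :m].mean(axis=1),
        sub_x=sub_x,
        sub_y=sub_y,
        sub_z=sub_z,
        geometry=geometry,
        acquisition=acquisition,
        diffusion_um2_s=diffusion_um2_s,
    )


# ---------------------------------------------------------------------------
# scattered intensity
# ---------------------------------------------------------------------------

def scattered_intensity(
    traj: TrajectoryRecord,
    illumination: IlluminationField,
    particle: ParticleSpec,
    prefactor: float = 1.0,
) -> np.ndarray:
    """Noise-free scattered-intensity time series (arbitrary units).

    I_s(t) = prefactor * (d/100 nm)^6 * <I_illum> where the illumination is
    averaged over the substeps inside the exposure window (motion blur).  The
    result is also stored on ``traj.intensity``.
    """
    sx, sy, sz = traj.exposure_substeps()
    illum = np.asarray(illumination.intensity(sx, sy, sz), dtype=float)
    if illum.shape != sx.shape:
        illum = np.broadcast_to(illum, sx.shape)
    series = prefactor * particle.relative_scattering * illum.mean(axis=1)
    traj.intensity = series
    return series


def apply_shot_noise(
    intensities: np.ndarray, camera: CameraModel, rng: np.random.Generator
) -> np.ndarray:
    """Shot-noise-limited intensity measurement in the camera's count units.

    Converts the series to expected counts via ``camera.photon_scale``, draws
    Poisson counts and maps back to intensity units — the fluctuation model of
    an idealised detector that integrates the whole point-spread function.
    """
    counts = np.asarray(intensities, dtype=float) * camera.photon_scale
    if np.any(counts < 0):
        raise ValueError("intensities must be >= 0")
    return rng.poisson(counts).astype(float) / camera.photon_scale


# ---------------------------------------------------------------------------
# camera rendering
# ---------------------------------------------------------------------------

def airy_radius_um(na: float, vacuum_wavelength_um: float) -> float:
    """Radius of the first Airy minimum, 0.61 lambda / NA (um)."""
    if not 0 < na < 1.5:
        raise ValueError("NA out of range")
    return 0.61 * vacuum_wavelength_um / na


def _airy_lut(na: float, wavelength_um: float, r_max_um: float, dr_um: float = 1e-3):
    """Radial lookup table of the Airy intensity pattern, peak normalised to 1."""
    r = np.arange(0.0, r_max_um + dr_um, dr_um)
    v = 2.0 * np.pi * na * r / wavelength_um
    with np.errstate(invalid="ignore", divide="ignore"):
        psf = (2.0 * j1(v) / v) ** 2
    psf[0] = 1.0
    return r, psf


def auto_photon_scale(
    particle: ParticleSpec,
    illumination: IlluminationField,
    target_peak_counts: float = 20_000.0,
    prefactor: float = 1.0,
) -> float:
    """Counts-per-intensity-unit placing a particle at the field centre at
    ``target_peak_counts`` peak counts (mid-range of a 16-bit camera)."""
    i0 = float(np.asarray(illumination.intensity(0.0, 0.0, 0.0)))
    return target_peak_counts / (prefactor * particle.relative_scattering * i0)


def render_frames(
    traj: TrajectoryRecord,
    intensities: np.ndarray,
    camera: CameraModel,
    na: float = 0.25,
    vacuum_wavelength_um: float = 0.532,
    fov_px: tuple[int, int] = (30, 600),
    noise: bool = True,
    rng: np.random.Generator | None = None,
    stamp_radius_px: int | None = None,
    recenter_margin_px: int | None = None,
) -> FrameStack:
    """Render camera frames of the diffusing particle.

    Each frame sums an Airy-disc point-spread function over the exposure
    substeps (motion blur), centred at the projected (x, z) substep positions
    and scaled so the per-frame peak equals ``camera.photon_scale *
    intensities[frame]``; Poisson shot noise on the signal, Gaussian read
    noise, the noise-floor offset, integer quantisation and clipping at
    saturation follow.  Depth (y) defocus is ignored (the reference objective
    depth of field exceeds the channel diameter).

    The axial rendering window re-centres on the particle whenever it comes
    within ``recenter_margin_px`` of an edge; per-frame window origins are
    recorded on the returned :class:`FrameStack` so image coordinates map back
    to absolute z.
    """
    height, width = fov_px
    pitch = camera.pixel_pitch_um
    r_airy = airy_radius_um(na, vacuum_wavelength_um)
    if r_airy / pitch < 1.0:
        raise ValueError("point-spread function undersampled: first Airy minimum < 1 px")
    intensities = np.asarray(intensities, dtype=float)
    if intensities.shape != (traj.n_frames,):
        raise ValueError("intensities must have one value per frame")
    if noise and rng is None:
        rng = np.random.default_rng(traj.acquisition.seed + 1)

    if stamp_radius_px is None:
        stamp_radius_px = int(np.ceil(3.0 * r_airy / pitch))
    if recenter_margin_px is None:
        recenter_margin_px = stamp_radius_px + 4
    r_lut, psf_lut = _airy_lut(na, vacuum_wavelength_um, (stamp_radius_px + 2) * pitch * 1.5)

    sx, _, sz = traj.exposure_substeps()
    n_exp = sx.shape[1]
    x_px = sx / pitch + (height - 1) / 2.0
    z_px_abs = sz / pitch
    if np.any(x_px < 0) or np.any(x_px > height - 1):
        raise ValueError("particle leaves the transverse field of view")

    frames = np.empty((traj.n_frames, height, width), dtype=np.uint16)
    origins = np.empty(traj.n_frames, dtype=np.int64)
    rows = np.arange(height)
    s = stamp_radius_px
    origin = int(round(z_px_abs[0].mean())) - width // 2
    for i in range(traj.n_frames):
        zc = z_px_abs[i].mean()
        if zc - origin < recenter_margin_px or zc - origin > width - 1 - recenter_margin_px:
            origin = int(round(zc)) - width // 2
        origins[i] = origin

        signal = np.zeros((height, width))
        amp = camera.photon_scale * intensities[i] / n_exp
        for k in range(n_exp):
            xi, zi = x_px[i, k], z_px_abs[i, k] - origin
            i0, i1 = max(0, int(xi) - s), min(height, int(xi) + s + 1)
            j0, j1 = max(0, int(zi) - s), min(width, int(zi) + s + 1)
            if i0 >= i1 or j0 >= j1:
                continue
            rr = np.hypot(
                (rows[i0:i1, None] - xi) * pitch,
                (np.arange(j0, j1)[None, :] - zi) * pitch,
            )
            signal[i0:i1, j0:j1] += amp * np.interp(rr, r_lut, psf_lut)

        if noise:
            img = rng.poisson(signal).astype(float)
            img += camera.noise_floor + rng.normal(0.0, camera.read_noise, signal.shape)
        else:
            img = signal + camera.noise_floor
        frames[i] = np.clip(np.rint(img), 0, camera.saturation).astype(np.uint16)

    return FrameStack(
        frames=frames,
        pixel_pitch_um=pitch,
        times_s=traj.times_s.copy(),
        origin_z_px=origins,
        saturation=camera.saturation,
    )
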
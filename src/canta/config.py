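"""Run configuration: TOML-backed parameter sets for all pipeline stages.

Defaults reproduce the reference experiment (50 nm gold nanosphere, 4 um
silica capillary filled with an index-matched water/DMSO mixture, 532 nm
Gaussian-beam illumination 1 mm from the waist, 1 kHz / 0.2 ms acquisition on
a 16-bit camera).  Every section may be omitted; unknown keys raise.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from pathlib import Path
from typing import Any

from .beam import CapillarySpec, GaussianBeamSpec, LiquidSpec
from .flatfield import BinScheme
from .synthetic import AcquisitionConfig, CameraModel, ChannelGeometry
from .tracking import TrackingConfig
from .transport import ParticleSpec

__all__ = ["MSDConfig", "SimulationConfig", "RunConfig"]


@dataclass(frozen=True)
class MSDConfig:
    max_lag: int = 10
    n_lags: int = 2
    n_blocks: int = 20
    hindrance_model: str = "renkin"

    def __post_init__(self) -> None:
        if not 1 <= self.n_lags <= self.max_lag:
            raise ValueError("need 1 <= n_lags <= max_lag")


@dataclass(frozen=True)
class SimulationConfig:
    """Synthetic-run options: field of view, chunking, illumination shape."""

    fov_px: tuple[int, int] = (30, 600)
    chunk_frames: int = 2000
    illumination: str = "gaussian"
    guided_ratio: float = 2.5
    target_peak_counts: float = 20_000.0
    save_frames: bool = False

    def __post_init__(self) -> None:
        if self.illumination not in ("gaussian", "guided", "leaky"):
            raise ValueError("illumination must be gaussian, guided or leaky")
        if self.chunk_frames < 1:
            raise ValueError("chunk_frames must be >= 1")


# section name -> (constructor, {toml key: dataclass field})
_SECTION_KEYS: dict[str, dict[str, str]] = {
    "optics": {
        "waist_radius": "waist_radius_um",
        "wavelength": "vacuum_wavelength_um",
        "medium_index": "medium_index",
        "power": "power",
    },
    "capillary": {
        "channel_diameter": "channel_diameter_um",
        "outer_diameter": "outer_diameter_um",
        "cladding_index": "cladding_index",
    },
    "liquid": {
        "refractive_index": "refractive_index",
        "viscosity": "viscosity_pa_s",
        "temperature": "temperature_k",
    },
    "particle": {
        "diameter": "diameter_nm",
        "material": "material",
        "scattering_scale": "scattering_scale",
    },
    "acquisition": {
        "frame_rate": "frame_rate_hz",
        "exposure": "exposure_s",
        "n_frames": "n_frames",
        "substeps_per_frame": "substeps_per_frame",
        "seed": "seed",
    },
    "camera": {
        "pixel_pitch": "pixel_pitch_um",
        "bit_depth": "bit_depth",
        "noise_floor": "noise_floor",
        "saturation": "saturation",
        "read_noise": "read_noise",
        "photon_scale": "photon_scale",
    },
    "tracking": {
        "spot_diameter": "spot_diameter_px",
        "threshold": "threshold",
        "search_radius": "search_radius_px",
        "memory": "memory_frames",
        "smoothing_sigma": "smoothing_sigma_px",
    },
    "msd": {
        "max_lag": "max_lag",
        "n_lags": "n_lags",
        "n_blocks": "n_blocks",
        "hindrance_model": "hindrance_model",
    },
    "simulation": {
        "fov": "fov_px",
        "chunk_frames": "chunk_frames",
        "illumination": "illumination",
        "guided_ratio": "guided_ratio",
        "target_peak_counts": "target_peak_counts",
        "save_frames": "save_frames",
    },
}


@dataclass(frozen=True)
class RunConfig:
    """Complete, validated configuration of a CaNTA run."""

    beam: GaussianBeamSpec = GaussianBeamSpec(
        waist_radius_um=4.2, vacuum_wavelength_um=0.532, medium_index=1.4607
    )
    capillary: CapillarySpec = CapillarySpec(
        channel_diameter_um=4.0, outer_diameter_um=125.0, cladding_index=1.4607
    )
    liquid: LiquidSpec = LiquidSpec(
        refractive_index=1.4607, viscosity_pa_s=3.3e-3, temperature_k=293.15
    )
    particle: ParticleSpec = ParticleSpec(diameter_nm=50.0, material="gold")
    acquisition: AcquisitionConfig = AcquisitionConfig()
    camera: CameraModel = CameraModel()
    tracking: TrackingConfig = TrackingConfig()
    bins: BinScheme | None = None
    msd: MSDConfig = MSDConfig()
    simulation: SimulationConfig = SimulationConfig()
    z_a_um: float = 1000.0
    seed: int = 0

    @property
    def bin_scheme(self) -> BinScheme:
        if self.bins is not None:
            return self.bins
        return BinScheme.thirds(self.capillary.channel_diameter_um)

    @property
    def geometry(self) -> ChannelGeometry:
        return ChannelGeometry(
            radius_um=self.capillary.channel_diameter_um / 2.0,
            axial_extent_um=self.simulation.fov_px[1] * self.camera.pixel_pitch_um,
            axial_offset_um=self.z_a_um,
        )

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        from dataclasses import replace as dc_replace

        data = dict(data)
        defaults = cls()
        field_names = {
            "optics": "beam",
            "capillary": "capillary",
            "liquid": "liquid",
            "particle": "particle",
            "acquisition": "acquisition",
            "camera": "camera",
            "tracking": "tracking",
            "msd": "msd",
            "simulation": "simulation",
        }
        kwargs: dict[str, Any] = {}
        errors = []
        optics = dict(data.pop("optics", {}))
        kwargs["z_a_um"] = float(optics.pop("z_a", defaults.z_a_um))
        if optics:
            data["optics"] = optics
        if "bins" in data:
            bins = data.pop("bins")
            try:
                kwargs["bins"] = BinScheme(
                    cb=tuple(bins["cb"]), sb=tuple(tuple(i) for i in bins["sb"])
                )
            except (KeyError, TypeError, ValueError) as exc:
                errors.append(f"[bins]: {exc}")
        kwargs["seed"] = int(data.pop("seed", 0))
        for section, section_data in data.items():
            if section not in field_names:
                errors.append(f"unknown section [{section}]")
                continue
            mapping = _SECTION_KEYS[section]
            unknown = set(section_data) - set(mapping)
            if unknown:
                errors.append(f"unknown keys in [{section}]: {sorted(unknown)}")
                continue
            section_kwargs = {mapping[k]: v for k, v in section_data.items()}
            if section == "simulation" and "fov_px" in section_kwargs:
                section_kwargs["fov_px"] = tuple(int(v) for v in section_kwargs["fov_px"])
            try:
                base = getattr(defaults, field_names[section])
                kwargs[field_names[section]] = dc_replace(base, **section_kwargs)
            except (TypeError, ValueError) as exc:
                errors.append(f"[{section}]: {exc}")
        if errors:
            raise ValueError("invalid configuration: " + "; ".join(errors))
        return cls(**kwargs)

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))

    def to_dict(self) -> dict[str, Any]:
        """Lossless echo of every parameter, for run reports."""
        from dataclasses import asdict

        out = {
            "optics": asdict(self.beam) | {"z_a": self.z_a_um},
            "capillary": asdict(self.capillary),
            "liquid": asdict(self.liquid),
            "particle": asdict(self.particle),
            "acquisition": asdict(self.acquisition),
            "camera": asdict(self.camera),
            "tracking": asdict(self.tracking),
            "msd": asdict(self.msd),
            "simulation": asdict(self.simulation),
            "bins": {"cb": list(self.bin_scheme.cb), "sb": [list(i) for i in self.bin_scheme.sb]},
            "seed": self.seed,
        }
        return out
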
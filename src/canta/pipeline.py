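"""Stage orchestration: design report, synthetic run, tracking, statistics.

Ties the modules into reproducible runs: ``run_design`` evaluates the
flat-field design calculus for a configuration; ``run_full`` executes
simulate -> render -> track -> flat-field statistics -> MSD sizing on
synthetic data, streaming the video in chunks so experiment-scale frame counts fit
in memory.  All randomness derives from a single seed via
``numpy.random.SeedSequence``; identical seeds give identical reports.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .beam import (
    GaussianBeamField,
    IlluminationField,
    beam_radius,
    classify_regime,
    guided_mode_profile,
    radial_flatness,
    axial_decay,
    rayleigh_range,
)
from .config import RunConfig
from .flatfield import assign_bins, fit_intensity_histogram, flatfield_metrics
from .msd import compute_msd, d_uncertainty, fit_diffusion, size_particle
from .synthetic import (
    TrajectoryRecord,
    auto_photon_scale,
    render_frames,
    scattered_intensity,
    simulate_confined_brownian,
)
from .tracking import link_trajectories, locate_stack, normalize_intensity
from .transport import diffusion_length, hindrance_factor, stokes_einstein_D

log = logging.getLogger("canta")

__all__ = ["run_design", "run_full", "make_illumination", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message carries the stage tag."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def make_illumination(config: RunConfig) -> IlluminationField:
    """Illumination field for the synthetic run.

    ``gaussian``: the diffracting design beam a distance z_a upstream (the
    flat-field condition).  ``guided``/``leaky``: analytic centre-peaked /
    centre-depleted radial profiles with the configured centre-to-edge
    contrast, emulating a small positive / negative index mismatch.
    """
    sim = config.simulation
    radius = config.capillary.channel_diameter_um / 2.0
    if sim.illumination == "gaussian":
        return GaussianBeamField(beam=config.beam, z_offset_um=config.z_a_um)
    if sim.illumination == "guided":
        return guided_mode_profile(radius, center_to_edge_ratio=sim.guided_ratio)
    # leaky: invert the contrast (centre dimmer than the wall)
    return guided_mode_profile(radius, center_to_edge_ratio=1.0 / sim.guided_ratio)


def run_design(config: RunConfig) -> dict:
    """Flat-field design metrics for a configuration.

    Reports the Rayleigh range, beam radius at the tracking region, radial
    flatness across the channel, free-solution diffusion coefficient and
    diffusion length over the measurement time, the axial intensity decay
    over that length, and the index-mismatch regime.
    """
    beam = config.beam
    tau_m = config.acquisition.n_frames / config.acquisition.frame_rate_hz
    d_dif = stokes_einstein_D(
        config.particle.diameter_nm,
        config.liquid.viscosity_pa_s,
        config.liquid.temperature_k,
    )
    l_dif = diffusion_length(d_dif, tau_m)
    delta_n = config.liquid.refractive_index - config.capillary.cladding_index
    return {
        "rayleigh_range_um": rayleigh_range(beam),
        "beam_radius_at_za_um": float(beam_radius(beam, config.z_a_um)),
        "radial_flatness": radial_flatness(
            beam, config.z_a_um, config.capillary.channel_diameter_um
        ),
        "D_dif_um2_s": d_dif,
        "measurement_time_s": tau_m,
        "L_dif_um": l_dif,
        "axial_decay_over_L_dif": axial_decay(beam, config.z_a_um, l_dif),
        "delta_n": delta_n,
        "regime": classify_regime(delta_n),
    }


def _slice_trajectory(traj: TrajectoryRecord, a: int, b: int) -> TrajectoryRecord:
    """View of frames [a, b) as a standalone trajectory (shared buffers)."""
    acq = replace(traj.acquisition, n_frames=b - a)
    return TrajectoryRecord(
        times_s=traj.times_s[a:b],
        x_um=traj.x_um[a:b],
        y_um=traj.y_um[a:b],
        z_um=traj.z_um[a:b],
        sub_x=traj.sub_x[a:b],
        sub_y=traj.sub_y[a:b],
        sub_z=traj.sub_z[a:b],
        geometry=traj.geometry,
        acquisition=acq,
        diffusion_um2_s=traj.diffusion_um2_s,
        intensity=None if traj.intensity is None else traj.intensity[a:b],
    )


def simulate_stage(config: RunConfig, seed: int | None = None):
    """Simulate trajectory + intensity series; returns (traj, illumination, camera).

    The ground-truth diffusion coefficient is the hindered value
    D_free / R for the configured particle and channel: the generator emulates
    what a confined particle actually exhibits, so the downstream hindrance
    correction is exercised honestly.
    """
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    sim_seed, render_seed = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))

    d_free = stokes_einstein_D(
        config.particle.diameter_nm,
        config.liquid.viscosity_pa_s,
        config.liquid.temperature_k,
    )
    r_hind = hindrance_factor(
        config.particle.diameter_nm,
        config.capillary.channel_diameter_um,
        model=config.msd.hindrance_model,
    )
    acq = replace(config.acquisition, seed=sim_seed)
    traj = simulate_confined_brownian(d_free / r_hind, config.geometry, acq)
    illumination = make_illumination(config)
    scattered_intensity(traj, illumination, config.particle)
    scale = auto_photon_scale(
        config.particle, illumination, target_peak_counts=config.simulation.target_peak_counts
    )
    camera = replace(config.camera, photon_scale=scale)
    return traj, illumination, camera, render_seed


def track_stage(
    config: RunConfig, traj: TrajectoryRecord, camera, render_seed: int
) -> pd.DataFrame:
    """Render frames chunk-by-chunk, detect and link; returns the linked table."""
    rng = np.random.default_rng(render_seed)
    sim = config.simulation
    detections = []
    n = traj.n_frames
    for a in range(0, n, sim.chunk_frames):
        b = min(a + sim.chunk_frames, n)
        chunk = _slice_trajectory(traj, a, b)
        stack = render_frames(
            chunk,
            traj.intensity[a:b],
            camera,
            vacuum_wavelength_um=config.beam.vacuum_wavelength_um,
            fov_px=sim.fov_px,
            rng=rng,
        )
        det = locate_stack(stack, config.tracking)
        if len(det):
            det["frame"] += a
            detections.append(det)
    if not detections:
        raise PipelineError("track", "no detections in any frame")
    detections = pd.concat(detections, ignore_index=True)
    linked = link_trajectories(detections, config.tracking)
    # single-particle experiment: analyse the longest track
    best = linked["track_id"].value_counts().idxmax()
    track = linked[linked["track_id"] == best].sort_values("frame").reset_index(drop=True)
    coverage = len(track) / n
    log.info("track: %d/%d frames covered (%.2f%%)", len(track), n, 100 * coverage)
    if coverage < 0.5:
        raise PipelineError("track", f"longest track covers only {100 * coverage:.1f}% of frames")
    return track


def flatfield_stage(config: RunConfig, track: pd.DataFrame) -> dict:
    """Flat-field statistics on the tracked intensity (mass) series."""
    norm = np.asarray(normalize_intensity(track["mass"]))
    labels = assign_bins(track["x_um"].to_numpy(), config.bin_scheme)
    try:
        fit_cb = fit_intensity_histogram(norm[labels == "CB"])
        fit_sb = fit_intensity_histogram(norm[labels == "SB"])
    except ValueError as exc:
        raise PipelineError("flatfield", str(exc)) from exc
    report = flatfield_metrics(fit_cb, fit_sb, norm)
    return report.to_dict()


def msd_stage(config: RunConfig, track: pd.DataFrame) -> dict:
    """MSD, diffusion fit, hindrance-corrected hydrodynamic size, uncertainty."""
    z = track["z_um"].to_numpy()
    dt = 1.0 / config.acquisition.frame_rate_hz
    try:
        msd = compute_msd(z, dt, max_lag=config.msd.max_lag)
        fit_diffusion(msd, n_lags=config.msd.n_lags)
        r_hind = hindrance_factor(
            config.particle.diameter_nm,
            config.capillary.channel_diameter_um,
            model=config.msd.hindrance_model,
        )
        dh = size_particle(msd.diffusion_um2_s, config.liquid, hindrance=r_hind)
        err = d_uncertainty(
            z,
            dt,
            config.liquid,
            hindrance=r_hind,
            n_blocks=config.msd.n_blocks,
            n_lags=config.msd.n_lags,
        )
    except ValueError as exc:
        raise PipelineError("msd", str(exc)) from exc
    out = msd.to_dict()
    out.update(
        {
            "hindrance_factor": r_hind,
            "d_h_nm": dh,
            "sigma_D_um2_s": err["sigma_D_um2_s"],
            "sigma_d_h_nm": err["sigma_d_h_nm"],
        }
    )
    return out


def run_full(config: RunConfig, seed: int | None = None, outdir=None) -> dict:
    """Execute every stage on synthetic data and return the run report.

    Deterministic given the seed.  When ``outdir`` is given, the ground
    truth, linked trajectory and per-stage reports are written there (CSV /
    JSON); frames are written as multi-page TIFF only when
    ``simulation.save_frames`` is set (an experiment-scale stack is large).
    """
    report: dict = {"version": __version__, "seed": config.seed if seed is None else seed}
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    report["design"] = run_design(config)
    timings["design"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    traj, illumination, camera, render_seed = simulate_stage(config, seed)
    timings["simulate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    track = track_stage(config, traj, camera, render_seed)
    timings["track"] = time.perf_counter() - t0
    report["tracking"] = {
        "n_frames": traj.n_frames,
        "n_linked": int(len(track)),
        "coverage": len(track) / traj.n_frames,
    }

    t0 = time.perf_counter()
    report["flatfield"] = flatfield_stage(config, track)
    timings["flatfield"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    report["msd"] = msd_stage(config, track)
    timings["msd"] = time.perf_counter() - t0

    report["timings_s"] = timings
    report["config"] = config.to_dict()

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        traj.to_dataframe().to_csv(outdir / "truth.csv", index=False)
        track.to_csv(outdir / "trajectory.csv", index=False)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        if config.simulation.save_frames:
            stack = render_frames(
                traj,
                traj.intensity,
                camera,
                vacuum_wavelength_um=config.beam.vacuum_wavelength_um,
                fov_px=config.simulation.fov_px,
                rng=np.random.default_rng(render_seed),
            )
            stack.write_tiff(outdir / "frames.tiff")
    return report
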
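"""Single-particle detection, subpixel localisation and trajectory linking.

Detection: median background subtraction, Gaussian smoothing, local-maximum
candidates above a count threshold.  Subpixel refinement uses the
radial-symmetry centre method (intensity-gradient lines of a radially
symmetric spot intersect at its centre; the least-squares intersection is a
fast, unbiased estimator for Airy- or Gaussian-shaped spots).  Linking is
greedy nearest-neighbour with gap bridging, adequate for the dilute
single-particle regime the microchannel experiment operates in.

Coordinates: pixel centres at integer indices, 0-based; the image short axis
(rows) is the transverse x direction, the long axis (columns) the channel
axis z.  Conversion to um is by the camera pixel pitch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .synthetic import FrameStack

__all__ = [
    "TrackingConfig",
    "locate_spots",
    "locate_stack",
    "link_trajectories",
    "normalize_intensity",
    "radial_symmetry_center",
]

DETECTION_COLUMNS = ["frame", "x_px", "z_px", "mass", "background", "saturated"]


@dataclass(frozen=True)
class TrackingConfig:
    """Detection and linking parameters.

    spot_diameter_px : odd window size enclosing the point-spread-function
    core (>= 3).  threshold : minimum smoothed peak height above background,
    in counts.  search_radius_px : maximum frame-to-frame displacement when
    linking.  memory_frames : number of consecutive missed frames a track
    survives.  smoothing_sigma_px : Gaussian bandpass scale for peak finding.
    """

    spot_diameter_px: int = 11
    threshold: float = 300.0
    search_radius_px: float = 5.0
    memory_frames: int = 1
    smoothing_sigma_px: float = 1.0

    def __post_init__(self) -> None:
        if self.spot_diameter_px < 3 or self.spot_diameter_px % 2 == 0:
            raise ValueError("spot_diameter_px must be odd and >= 3")
        if not self.search_radius_px > 0:
            raise ValueError("search_radius_px must be > 0")
        if self.memory_frames < 0:
            raise ValueError("memory_frames must be >= 0")
        if self.threshold < 0 or self.smoothing_sigma_px <= 0:
            raise ValueError("threshold must be >= 0 and smoothing_sigma_px > 0")


def radial_symmetry_center(window: np.ndarray) -> tuple[float, float]:
    """Centre (row, col) of a radially symmetric spot, in window coordinates.

    Least-squares intersection of the lines through the midpoint-grid points
    along the local intensity-gradient directions (gradients of a radially
    symmetric pattern point at its centre).  Exact for noise-free symmetric
    spots; near the information bound under shot noise.
    """
    w = np.asarray(window, dtype=float)
    if w.ndim != 2 or min(w.shape) < 3:
        raise ValueError("window must be 2D with both sides >= 3")
    # gradients on the half-pixel midpoint grid, via diagonal differences
    du = w[1:, 1:] - w[:-1, :-1]
    dv = w[1:, :-1] - w[:-1, 1:]
    # smooth 3x3 to stabilise against pixel noise
    k = np.ones((3, 3)) / 9.0
    du = ndimage.convolve(du, k, mode="nearest")
    dv = ndimage.convolve(dv, k, mode="nearest")
    # gradient in (row, col) frame: diagonals u=(1,1)/sqrt2, v=(1,-1)/sqrt2
    g_r = (du + dv) / np.sqrt(2.0)
    g_c = (du - dv) / np.sqrt(2.0)
    mag2 = g_r**2 + g_c**2
    if not mag2.any():
        return ((w.shape[0] - 1) / 2.0, (w.shape[1] - 1) / 2.0)

    rows = np.arange(w.shape[0] - 1) + 0.5
    cols = np.arange(w.shape[1] - 1) + 0.5
    rm, cm = np.meshgrid(rows, cols, indexing="ij")
    # distance weighting: favour gradients near the current centroid estimate
    wsum = mag2.sum()
    rc = (mag2 * rm).sum() / wsum
    cc = (mag2 * cm).sum() / wsum
    dist = np.hypot(rm - rc, cm - cc)
    weight = mag2 / np.maximum(dist, 0.5)

    # minimise sum_i w_i * (perpendicular distance to line i)^2
    norm = np.hypot(g_r, g_c)
    norm[norm == 0] = 1.0
    nr, nc = g_r / norm, g_c / norm
    # line through (rm, cm) with direction (nr, nc); normal (-nc, nr)
    a11 = (weight * nc**2).sum()
    a12 = -(weight * nr * nc).sum()
    a22 = (weight * nr**2).sum()
    b1 = (weight * nc * (nc * rm - nr * cm)).sum()
    b2 = (weight * nr * (nr * cm - nc * rm)).sum()
    det = a11 * a22 - a12 * a12
    if abs(det) < 1e-12 * max(a11 + a22, 1e-30) ** 2:
        return (rc, cc)
    r0 = (a22 * b1 - a12 * b2) / det
    c0 = (a11 * b2 - a12 * b1) / det
    return (float(r0), float(c0))


def _empty_detections() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "frame": pd.Series(dtype=int),
            "x_px": pd.Series(dtype=float),
            "z_px": pd.Series(dtype=float),
            "mass": pd.Series(dtype=float),
            "background": pd.Series(dtype=float),
            "saturated": pd.Series(dtype=bool),
        }
    )


def locate_spots(
    frame: np.ndarray,
    config: TrackingConfig,
    frame_index: int = 0,
    saturation: float | None = None,
) -> pd.DataFrame:
    """Detect bright spots in one frame.

    Returns a DataFrame with columns frame, x_px (row, transverse), z_px
    (column, axial), mass (background-subtracted integrated counts in the
    spot window), background (local median) and a ``saturated`` flag (set
    when any window pixel reaches saturation; flagged, not dropped).
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("frame must be 2D")
    if min(img.shape) < config.spot_diameter_px:
        raise ValueError("frame smaller than the spot diameter")

    background = float(np.median(img))
    smoothed = ndimage.gaussian_filter(img - background, config.smoothing_sigma_px)
    size = config.spot_diameter_px
    peaks = (smoothed == ndimage.maximum_filter(smoothed, size=size)) & (
        smoothed > config.threshold
    )
    rows, cols = np.nonzero(peaks)
    if rows.size == 0:
        return _empty_detections()
    # merge plateau duplicates: greedily keep the brightest candidate of any
    # cluster closer than half a spot diameter
    order = np.argsort(smoothed[rows, cols])[::-1]
    kept: list[tuple[int, int]] = []
    for idx in order:
        r, c = int(rows[idx]), int(cols[idx])
        if all(np.hypot(r - kr, c - kc) >= size / 2.0 for kr, kc in kept):
            kept.append((r, c))

    half = size // 2
    records = []
    for r, c in kept:
        r0, r1 = max(0, r - half), min(img.shape[0], r + half + 1)
        c0, c1 = max(0, c - half), min(img.shape[1], c + half + 1)
        window = img[r0:r1, c0:c1]
        local_bg = float(np.median(np.concatenate([window[0], window[-1]])))
        wr, wc = radial_symmetry_center(window - local_bg)
        # refinement must stay inside the window; fall back to the seed peak
        if not (0 <= wr <= window.shape[0] - 1 and 0 <= wc <= window.shape[1] - 1):
            wr, wc = float(r - r0), float(c - c0)
        mass = float(np.maximum(window - local_bg, 0.0).sum())
        saturated = bool(saturation is not None and (window >= saturation).any())
        records.append((frame_index, r0 + wr, c0 + wc, mass, local_bg, saturated))
    return pd.DataFrame(records, columns=DETECTION_COLUMNS)


def locate_stack(stack: FrameStack, config: TrackingConfig) -> pd.DataFrame:
    """Detect spots in every frame of a stack, in absolute coordinates.

    Column positions are shifted by the per-frame window origin so z_px is
    absolute; x_um / z_um / t columns are added using the stack's pixel pitch.
    """
    parts = []
    for i in range(stack.n_frames):
        det = locate_spots(stack.frames[i], config, frame_index=i, saturation=stack.saturation)
        if len(det):
            det["z_px"] += stack.origin_z_px[i]
            parts.append(det)
    if not parts:
        return _empty_detections().assign(t=[], x_um=[], z_um=[])
    out = pd.concat(parts, ignore_index=True)
    height = stack.frames.shape[1]
    out["t"] = stack.times_s[out["frame"].to_numpy()]
    out["x_um"] = (out["x_px"] - (height - 1) / 2.0) * stack.pixel_pitch_um
    out["z_um"] = out["z_px"] * stack.pixel_pitch_um
    return out


def link_trajectories(detections: pd.DataFrame, config: TrackingConfig) -> pd.DataFrame:
    """Link detections into trajectories by greedy nearest-neighbour matching.

    Detections (sorted by frame) are matched to open tracks within
    ``search_radius_px`` of their last position; gaps up to ``memory_frames``
    are bridged.  Ambiguities are resolved by distance, ties by higher mass.
    Returns the input with a stable integer ``track_id`` column.
    """
    if not len(detections):
        out = detections.copy()
        out["track_id"] = pd.Series(dtype=int)
        return out
    df = detections.sort_values(["frame", "mass"], ascending=[True, False]).reset_index(
        drop=True
    )
    track_ids = np.full(len(df), -1, dtype=int)
    # open tracks: id -> (last_frame, x, z)
    open_tracks: dict[int, tuple[int, float, float]] = {}
    next_id = 0
    for frame, group in df.groupby("frame", sort=True):
        frame = int(frame)
        # candidate pairs (distance, detection row, track id), greedy by distance;
        # groups are pre-sorted by descending mass so ties favour brighter spots
        pairs = []
        for idx in group.index:
            x, z = df.at[idx, "x_px"], df.at[idx, "z_px"]
            for tid, (last_frame, tx, tz) in open_tracks.items():
                if frame - last_frame > config.memory_frames + 1:
                    continue
                d = float(np.hypot(x - tx, z - tz))
                if d <= config.search_radius_px:
                    pairs.append((d, idx, tid))
        pairs.sort(key=lambda p: p[0])
        used_det, used_trk = set(), set()
        for d, idx, tid in pairs:
            if idx in used_det or tid in used_trk:
                continue
            used_det.add(idx)
            used_trk.add(tid)
            track_ids[idx] = tid
            open_tracks[tid] = (frame, float(df.at[idx, "x_px"]), float(df.at[idx, "z_px"]))
        for idx in group.index:
            if idx not in used_det:
                track_ids[idx] = next_id
                open_tracks[next_id] = (
                    frame,
                    float(df.at[idx, "x_px"]),
                    float(df.at[idx, "z_px"]),
                )
                next_id += 1
        # drop stale tracks
        open_tracks = {
            tid: state
            for tid, state in open_tracks.items()
            if frame - state[0] <= config.memory_frames + 1
        }
    df["track_id"] = track_ids
    return df.sort_values(["track_id", "frame"]).reset_index(drop=True)


def normalize_intensity(series) -> np.ndarray | pd.Series:
    """Divide an intensity series by its mean (output mean is exactly 1).

    The convention used throughout the flat-field analysis: measured
    scattered intensities are reported relative to their average.
    """
    values = np.asarray(series, dtype=float)
    if values.size < 2:
        raise ValueError("series must have length >= 2")
    mean = values.mean()
    if mean == 0:
        raise ValueError("cannot normalise a zero-mean series")
    out = values / mean
    if isinstance(series, pd.Series):
        return pd.Series(out, index=series.index, name=series.name)
    return out
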
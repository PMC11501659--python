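"""Mean-squared-displacement analysis and hydrodynamic sizing.

The diffusion coefficient is estimated from the axial (channel-direction)
MSD: MSD(k dt) = < (z_{i+k} - z_i)^2 >, averaged over all overlapping pairs
of the trajectory; a line is fitted through the first two lag times (for long
trajectories with negligible localisation error these carry the greatest
statistical significance) and D = slope / 2 for one-dimensional motion.  The
free intercept diagnoses localisation error.  The hydrodynamic diameter then
follows from the Stokes-Einstein relation, optionally corrected by a
hindered-diffusion factor for the channel confinement.

The MSD is computed on the axial coordinate only: transverse motion is
confined by the channel wall and would bias a multi-dimensional MSD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .beam import LiquidSpec
from .transport import stokes_einstein_d

__all__ = [
    "MSDResult",
    "compute_msd",
    "fit_diffusion",
    "size_particle",
    "d_uncertainty",
]


@dataclass
class MSDResult:
    """MSD curve and, once fitted, the diffusion estimate.

    ``n_pairs[k-1] = N - k`` overlapping displacement pairs enter lag k; the
    shortest lag averages over N - 1 values and is statistically strongest.
    Fit fields are ``None`` until :func:`fit_diffusion` is applied.
    """

    lag_times_s: np.ndarray
    msd_um2: np.ndarray
    n_pairs: np.ndarray
    dt_s: float
    slope_um2_s: float | None = None
    intercept_um2: float | None = None
    diffusion_um2_s: float | None = None
    n_lags_fit: int | None = None

    def to_dict(self) -> dict:
        return {
            "lag_times_s": self.lag_times_s.tolist(),
            "msd_um2": self.msd_um2.tolist(),
            "n_pairs": self.n_pairs.tolist(),
            "dt_s": self.dt_s,
            "slope_um2_s": self.slope_um2_s,
            "intercept_um2": self.intercept_um2,
            "diffusion_um2_s": self.diffusion_um2_s,
            "n_lags_fit": self.n_lags_fit,
        }


def compute_msd(z_um, dt_s: float, max_lag: int = 10) -> MSDResult:
    """Time-averaged 1D MSD over overlapping pairs for lags 1..max_lag.

    ``z_um`` is the axial coordinate sampled at interval ``dt_s``; a
    stationary trajectory gives MSD = 0 at all lags.
    """
    z = np.asarray(z_um, dtype=float)
    if z.ndim != 1:
        raise ValueError("z_um must be 1D")
    n = z.size
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    if max_lag >= n:
        raise ValueError(f"max_lag ({max_lag}) must be < trajectory length ({n})")
    if dt_s <= 0:
        raise ValueError("dt_s must be > 0")
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(max_lag)
    for k in lags:
        diff = z[k:] - z[:-k]
        msd[k - 1] = np.mean(diff * diff)
    return MSDResult(
        lag_times_s=lags * dt_s,
        msd_um2=msd,
        n_pairs=n - lags,
        dt_s=dt_s,
    )


def fit_diffusion(msd: MSDResult, n_lags: int = 2) -> float:
    """Fit D (um^2/s) from the first ``n_lags`` MSD points.

    Ordinary least squares with a free intercept; D = slope / 2 for 1D
    motion.  The fit results are stored on ``msd``.  A non-positive slope
    signals a failed tracking or a stationary particle and raises.
    Using more than four lags is discouraged (their statistical weight drops
    and confinement effects creep in) and triggers a warning.
    """
    if n_lags < 2:
        raise ValueError("n_lags must be >= 2")
    if n_lags > msd.lag_times_s.size:
        raise ValueError("n_lags exceeds the number of computed lags")
    if n_lags > 4:
        warnings.warn(
            "fitting more than 4 lag times typically reduces accuracy",
            UserWarning,
            stacklevel=2,
        )
    t = msd.lag_times_s[:n_lags]
    y = msd.msd_um2[:n_lags]
    slope, intercept = np.polyfit(t, y, 1)
    if slope <= 0:
        raise ValueError(
            f"fitted MSD slope {slope:.3g} um^2/s is not positive; "
            "trajectory does not look diffusive"
        )
    msd.slope_um2_s = float(slope)
    msd.intercept_um2 = float(intercept)
    msd.diffusion_um2_s = float(slope / 2.0)
    msd.n_lags_fit = n_lags
    return msd.diffusion_um2_s


def size_particle(
    diffusion_um2_s: float, liquid: LiquidSpec, hindrance: float = 1.0
) -> float:
    """Hydrodynamic diameter (nm) from a measured diffusion coefficient.

    Confinement slows diffusion by the hindrance factor R >= 1
    (D_measured = D_free / R), so the free-solution coefficient entering the
    Stokes-Einstein inverse is D_measured * R.  With R = 1 this is exactly
    the bare Stokes-Einstein inverse.
    """
    if hindrance < 1.0:
        raise ValueError("hindrance factor must be >= 1")
    return stokes_einstein_d(
        diffusion_um2_s * hindrance, liquid.viscosity_pa_s, liquid.temperature_k
    )


def d_uncertainty(
    z_um,
    dt_s: float,
    liquid: LiquidSpec,
    hindrance: float = 1.0,
    n_blocks: int = 20,
    n_lags: int = 2,
) -> dict:
    """Block standard errors of D and d_h from one trajectory.

    The trajectory is split into ``n_blocks`` non-overlapping contiguous
    segments; D is estimated independently on each and the standard error of
    the full-trajectory estimate is std(D_blocks)/sqrt(n_blocks).  It is
    propagated to the hydrodynamic diameter to first order
    (sigma_d / d = sigma_D / D, since d ~ 1/D).

    Consistent with the information-bound scaling sigma_D ~ 1/sqrt(N): the
    per-block spread shrinks as block length grows.
    """
    z = np.asarray(z_um, dtype=float)
    if z.size < 100:
        raise ValueError("need a trajectory of length >= 100")
    if n_blocks < 5:
        raise ValueError("need at least 5 blocks")
    block_len = z.size // n_blocks
    if block_len < 5 * (n_lags + 1):
        raise ValueError("blocks too short for a stable MSD fit; reduce n_blocks")

    d_blocks = []
    for b in range(n_blocks):
        seg = z[b * block_len : (b + 1) * block_len]
        m = compute_msd(seg, dt_s, max_lag=n_lags)
        d_blocks.append(fit_diffusion(m, n_lags=n_lags))
    d_blocks = np.asarray(d_blocks)

    m_full = compute_msd(z, dt_s, max_lag=n_lags)
    d_full = fit_diffusion(m_full, n_lags=n_lags)
    sigma_d_coeff = float(d_blocks.std(ddof=1) / np.sqrt(n_blocks))
    dh = size_particle(d_full, liquid, hindrance)
    return {
        "D_um2_s": d_full,
        "sigma_D_um2_s": sigma_d_coeff,
        "d_h_nm": dh,
        "sigma_d_h_nm": dh * sigma_d_coeff / d_full,
        "n_blocks": n_blocks,
        "block_length": block_len,
    }
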
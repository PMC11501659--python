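"""Flat-field verification statistics.

The experimental test of flat-field formation: the channel cross-section is
divided transversely into a central bin (CB) and two side bins (SBs); the
scattered intensities measured while the particle resides in each bin are
histogrammed, fitted with Gaussians, and compared.  Under flat-field
illumination both distributions peak at the same intensity (delta_I_max near
zero) with comparable widths; centre-peaked (guided-mode-like) illumination
pushes the CB peak above the SB peak and vice versa for leaky profiles.

Also provides the polydispersity dynamic-range calculator: with scattered
intensity scaling as d^6, a camera spanning noise floor I_min to saturation
I_max can simultaneously resolve diameters over a ratio (I_max/I_min)^(1/6).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import optimize, stats

__all__ = [
    "BinScheme",
    "GaussianFitResult",
    "FlatFieldReport",
    "assign_bins",
    "fit_intensity_histogram",
    "flatfield_metrics",
    "dynamic_range",
]

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class BinScheme:
    """Transverse spatial bins, half-open intervals [lo, hi) in um.

    ``cb`` is the central interval (symmetric about the channel axis),
    ``sb`` the two flanking intervals.  Positions outside every interval are
    unlabelled.
    """

    cb: tuple[float, float]
    sb: tuple[tuple[float, float], tuple[float, float]]

    def __post_init__(self) -> None:
        intervals = [self.cb, *self.sb]
        for lo, hi in intervals:
            if not lo < hi:
                raise ValueError(f"empty interval [{lo}, {hi})")
        ordered = sorted(intervals)
        for (_, hi_a), (lo_b, _) in zip(ordered, ordered[1:]):
            if lo_b < hi_a:
                raise ValueError("bin intervals overlap")

    @classmethod
    def thirds(cls, channel_diameter_um: float) -> "BinScheme":
        """Default scheme: CB = central third of the channel width, SBs = outer thirds."""
        if channel_diameter_um <= 0:
            raise ValueError("channel_diameter_um must be > 0")
        r = channel_diameter_um / 2.0
        third = channel_diameter_um / 3.0
        return cls(
            cb=(-third / 2.0, third / 2.0),
            sb=((-r, -third / 2.0), (third / 2.0, r)),
        )


@dataclass(frozen=True)
class GaussianFitResult:
    """Gaussian fitted to an occurrence-probability histogram."""

    mu: float
    sigma: float
    amplitude: float
    n_samples: int

    @property
    def fwhm(self) -> float:
        return FWHM_PER_SIGMA * self.sigma

    def rescaled(self, factor: float) -> "GaussianFitResult":
        """Fit of the same data with the intensity axis multiplied by ``factor``."""
        return GaussianFitResult(
            mu=self.mu * factor,
            sigma=self.sigma * factor,
            amplitude=self.amplitude,
            n_samples=self.n_samples,
        )


@dataclass(frozen=True)
class FlatFieldReport:
    """Flat-field metrics for one trajectory.

    Peak intensities and FWHMs are on the scale where all intensities are
    renormalised by the CB Gaussian peak (I -> I / I_CB_max); delta_imax_pct
    is positive when the CB is brighter than the SBs (guided-like) and
    negative when the SBs are brighter (leaky-like).
    """

    fit_cb: GaussianFitResult
    fit_sb: GaussianFitResult
    delta_imax_pct: float
    delta_i_pct: float
    skewness: float
    n_cb: int
    n_sb: int

    def to_dict(self) -> dict:
        return {
            "delta_imax_pct": self.delta_imax_pct,
            "delta_i_pct": self.delta_i_pct,
            "skewness": self.skewness,
            "n_cb": self.n_cb,
            "n_sb": self.n_sb,
            "cb": asdict(self.fit_cb) | {"fwhm": self.fit_cb.fwhm},
            "sb": asdict(self.fit_sb) | {"fwhm": self.fit_sb.fwhm},
        }


def assign_bins(x_um, scheme: BinScheme) -> np.ndarray:
    """Label transverse positions: ``"CB"``, ``"SB"`` or ``"none"``.

    Intervals are half-open [lo, hi); a position on a shared boundary belongs
    to the interval it is the lower edge of.
    """
    x = np.asarray(x_um, dtype=float)
    labels = np.full(x.shape, "none", dtype=object)
    for lo, hi in scheme.sb:
        labels[(x >= lo) & (x < hi)] = "SB"
    lo, hi = scheme.cb
    labels[(x >= lo) & (x < hi)] = "CB"
    return labels


def _gauss(x, amplitude, mu, sigma):
    return amplitude * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def fit_intensity_histogram(values, bins="fd") -> GaussianFitResult:
    """Histogram intensities as occurrence probabilities and fit a Gaussian.

    The histogram is normalised so the bar heights sum to 1 (occurrence
    probability per bin); a Gaussian is fitted by nonlinear least squares,
    initialised from the sample mean and standard deviation.  Freedman -
    Diaconis binning by default.

    Raises
    ------
    ValueError
        For fewer than 100 samples, degenerate (constant) data, or a fit that
        fails to converge.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 100:
        raise ValueError(f"need >= 100 intensity values, got {v.size}")
    std = v.std()
    if std == 0 or not np.isfinite(std):
        raise ValueError("degenerate intensity sample (zero spread)")
    counts, edges = np.histogram(v, bins=bins)
    probs = counts / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    span = v.max() - v.min()
    p0 = (probs.max(), v.mean(), std)
    # bounded trust-region fit: keeps the optimiser sane on broad or skewed
    # histograms (mu is constrained to the sample range, so edge-peaked
    # distributions peg the peak at the boundary instead of diverging)
    bounds = (
        [0.0, v.min(), 1e-6 * span],
        [1.0, v.max(), 10.0 * span],
    )
    p0 = (p0[0], float(np.clip(p0[1], v.min(), v.max())), p0[2])
    try:
        popt, _ = optimize.curve_fit(
            _gauss, centers, probs, p0=p0, bounds=bounds, maxfev=10_000
        )
    except RuntimeError as exc:
        raise ValueError(
            f"Gaussian fit did not converge (n={v.size}, mean={v.mean():.4g}, "
            f"std={std:.4g}): {exc}"
        ) from exc
    amplitude, mu, sigma = popt
    sigma = abs(float(sigma))
    if sigma == 0 or not np.isfinite(sigma):
        raise ValueError("Gaussian fit collapsed to zero width")
    return GaussianFitResult(
        mu=float(mu), sigma=sigma, amplitude=float(amplitude), n_samples=int(v.size)
    )


def flatfield_metrics(
    fit_cb: GaussianFitResult, fit_sb: GaussianFitResult, full_series
) -> FlatFieldReport:
    """Combine per-bin fits and the full series into a flat-field report.

    delta_imax = 100 (mu_CB - mu_SB) / mu_CB after renormalising all
    intensities by the CB peak; delta_i = 100 sigma_I / mean of the full
    normalised series; skewness of the full series is reported as a symmetry
    diagnostic (flat fields give symmetric distributions).
    """
    if fit_cb.mu <= 0:
        raise ValueError("CB peak intensity must be > 0")
    series = np.asarray(full_series, dtype=float)
    if series.size < 2:
        raise ValueError("full series must have length >= 2")
    mean = series.mean()
    if mean == 0:
        raise ValueError("full series has zero mean")
    scale = 1.0 / fit_cb.mu
    delta_imax = 100.0 * (fit_cb.mu - fit_sb.mu) / fit_cb.mu
    return FlatFieldReport(
        fit_cb=fit_cb.rescaled(scale),
        fit_sb=fit_sb.rescaled(scale),
        delta_imax_pct=float(delta_imax),
        delta_i_pct=float(100.0 * series.std() / mean),
        skewness=float(stats.skew(series)),
        n_cb=fit_cb.n_samples,
        n_sb=fit_sb.n_samples,
    )


def dynamic_range(noise_floor_counts: float, saturation_counts: float) -> float:
    """Ratio of largest to smallest simultaneously detectable diameters.

    delta_d = (I_max / I_min)^(1/6) under the d^6 scattering law: the smallest
    particle must clear the camera noise floor while the largest must not
    saturate.
    """
    if not 0 < noise_floor_counts < saturation_counts:
        raise ValueError("need 0 < noise_floor_counts < saturation_counts")
    return float((saturation_counts / noise_floor_counts) ** (1.0 / 6.0))
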
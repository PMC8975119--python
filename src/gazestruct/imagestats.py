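"""Structure statistics of grayscale images.

Five per-image properties are computed from pixel luminance:

* ``luminance`` -- mean normalized luminance in [0, 1];
* ``alpha`` -- exponent of the 1/f^alpha power law fitted to the radially
  averaged power spectrum (natural scenes cluster near alpha ~ 2);
* ``deviation`` -- area between the log-power spectrum and its fitted
  power-law line (low deviation ~ scaling invariance);
* ``entropy`` -- Shannon entropy of the 256-level luminance histogram (bits);
* ``skew`` -- third standardized moment of the luminance histogram.

Difference variables quantify how much an inserted target patch perturbs
the variability of a property across 256-px tiles of the stimulus: the
property is computed per tile for the background alone and for the
background carrying the target, the sample variance across tiles is taken
for each, and the background variance is subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image import GrayImage

__all__ = [
    "RadialSpectrum",
    "AlphaFit",
    "PropertySet",
    "DiffVector",
    "radial_power_spectrum",
    "fit_alpha",
    "spectral_deviation",
    "compute_properties",
    "partition_tiles",
    "diff_vector",
]

PROPERTY_NAMES = ("luminance", "alpha", "deviation", "entropy", "skew")

MIN_DIM_SPECTRUM = 64
MIN_FIT_BINS = 8


@dataclass(frozen=True)
class RadialSpectrum:
    """Radially averaged power spectrum.

    ``freq`` is in cycles/image, normalized so that one cycle spans the
    shorter image axis; the DC component is excluded and empty annuli are
    dropped.
    """

    freq: np.ndarray
    power: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.freq)


@dataclass(frozen=True)
class AlphaFit:
    """OLS fit of log10(power) on log10(freq); ``alpha`` is minus the slope."""

    alpha: float
    intercept: float
    fit_lo: float
    fit_hi: float
    log_freq: np.ndarray
    residuals: np.ndarray


@dataclass(frozen=True)
class PropertySet:
    """The five computational properties of one image.

    ``alpha`` and ``deviation`` are NaN when undefined (constant image);
    ``undefined_reason`` then carries the explanation.
    """

    luminance: float
    alpha: float
    deviation: float
    entropy: float
    skew: float
    undefined_reason: str | None = None

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.luminance, self.alpha, self.deviation, self.entropy, self.skew]
        )


@dataclass(frozen=True)
class DiffVector:
    """Tile-variance differences (composed minus background) per property."""

    diff_luminance: float
    diff_alpha: float
    diff_deviation: float
    diff_entropy: float
    diff_skew: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.diff_luminance,
                self.diff_alpha,
                self.diff_deviation,
                self.diff_entropy,
                self.diff_skew,
            ]
        )


def radial_power_spectrum(img: GrayImage, n_bins: int = 64) -> RadialSpectrum:
    """Radially averaged power spectrum of a Hann-windowed image.

    The image is mean-subtracted and windowed (2-D separable Hann) before
    the FFT to suppress edge leakage.  Squared magnitudes are averaged over
    annuli of radial frequency; frequency is expressed in cycles/image of
    the shorter axis so square and non-square images share a scale.
    """
    if min(img.width, img.height) < MIN_DIM_SPECTRUM:
        raise ValueError(f"image must be at least {MIN_DIM_SPECTRUM} px on each side")
    if n_bins < 16:
        raise ValueError("n_bins must be >= 16")
    arr = img.normalized
    h, w = arr.shape
    arr = arr - arr.mean()
    win = np.outer(np.hanning(h), np.hanning(w))
    spec = np.fft.fft2(arr * win)
    power = np.abs(spec) ** 2

    fy = np.fft.fftfreq(h)[:, None]  # cycles per pixel along y
    fx = np.fft.fftfreq(w)[None, :]
    s = min(h, w)
    radius = s * np.sqrt(fy**2 + fx**2)  # cycles per shorter-axis length

    nyquist = s / 2.0
    edges = np.linspace(0.0, nyquist, n_bins + 1)
    mask = radius > 0  # exclude DC
    idx = np.clip(np.digitize(radius[mask], edges) - 1, 0, n_bins - 1)
    p = power[mask]
    r = radius[mask]
    sums = np.bincount(idx, weights=p, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    fsums = np.bincount(idx, weights=r, minlength=n_bins)
    keep = counts > 0
    return RadialSpectrum(freq=fsums[keep] / counts[keep], power=sums[keep] / counts[keep])


def fit_alpha(
    spec: RadialSpectrum, fit_lo: float = 4.0, fit_hi: float | None = None
) -> AlphaFit:
    """Fit the 1/f^alpha power law over [fit_lo, fit_hi] cycles/image.

    ``fit_hi`` defaults to 0.45x the Nyquist frequency implied by the
    spectrum's highest bin.  Ordinary least squares of log10(power) on
    log10(freq); residuals are retained for the deviation measure.
    """
    if fit_hi is None:
        fit_hi = 0.45 * spec.freq[-1]
    sel = (spec.freq >= fit_lo) & (spec.freq <= fit_hi) & (spec.power > 0)
    if sel.sum() < MIN_FIT_BINS:
        raise ValueError(
            f"need >= {MIN_FIT_BINS} bins with positive power in "
            f"[{fit_lo}, {fit_hi}] cycles/image, found {int(sel.sum())}"
        )
    lf = np.log10(spec.freq[sel])
    lp = np.log10(spec.power[sel])
    slope, intercept = np.polyfit(lf, lp, 1)
    resid = lp - (slope * lf + intercept)
    return AlphaFit(
        alpha=-slope,
        intercept=intercept,
        fit_lo=fit_lo,
        fit_hi=fit_hi,
        log_freq=lf,
        residuals=resid,
    )


def spectral_deviation(fit: AlphaFit) -> float:
    """Area between the spectrum and its fitted line.

    Trapezoidal integral of the absolute log10-power residual against
    log10 frequency over the fit range; zero for an exact power law.
    """
    if len(fit.residuals) == 0:
        raise ValueError("fit carries no residuals")
    return float(np.trapezoid(np.abs(fit.residuals), fit.log_freq))


def shannon_entropy(levels: np.ndarray) -> float:
    """Entropy (bits) of the 256-level histogram, with 0*log0 = 0."""
    counts = np.bincount(levels.ravel(), minlength=256)
    p = counts[counts > 0] / levels.size
    return float(abs((p * np.log2(p)).sum()))


def histogram_skew(levels: np.ndarray) -> float:
    """Third standardized moment (population g1); 0 for constant images."""
    x = levels.ravel().astype(np.float64)
    m = x.mean()
    s2 = np.mean((x - m) ** 2)
    if s2 == 0:
        return 0.0
    return float(np.mean((x - m) ** 3) / s2**1.5)


def compute_properties(
    img: GrayImage,
    fit_lo: float = 4.0,
    fit_hi_frac: float = 0.45,
    n_bins: int = 64,
) -> PropertySet:
    """Compute all five properties of one image.

    ``fit_hi_frac`` scales the Nyquist frequency of the shorter axis to give
    the upper end of the power-law fit range.  For a constant image, alpha
    and deviation are undefined (returned as NaN with a reason) rather than
    silently zero.
    """
    levels = img.levels
    luminance = float(levels.mean() / 255.0)
    entropy = shannon_entropy(levels)
    skew = histogram_skew(levels)
    if levels.min() == levels.max():
        return PropertySet(
            luminance=luminance,
            alpha=float("nan"),
            deviation=float("nan"),
            entropy=entropy,
            skew=skew,
            undefined_reason="constant image: power spectrum is identically zero",
        )
    spec = radial_power_spectrum(img, n_bins=n_bins)
    nyquist = min(img.width, img.height) / 2.0  # cycles/image of the shorter axis
    fit = fit_alpha(spec, fit_lo=fit_lo, fit_hi=fit_hi_frac * nyquist)
    return PropertySet(
        luminance=luminance,
        alpha=fit.alpha,
        deviation=spectral_deviation(fit),
        entropy=entropy,
        skew=skew,
    )


def partition_tiles(img: GrayImage, tile: int = 256) -> list[GrayImage]:
    """Disjoint tile x tile squares from the top-left, row-major.

    Partial rows/columns are dropped; for the study geometry (1280x1024,
    tile 256) the tiling is exact (5x4 = 20 tiles).
    """
    if img.width < tile or img.height < tile:
        raise ValueError(f"image {img.width}x{img.height} smaller than tile {tile}")
    out = []
    for r in range(img.height // tile):
        for c in range(img.width // tile):
            out.append(
                GrayImage(img.levels[r * tile : (r + 1) * tile, c * tile : (c + 1) * tile])
            )
    return out


def tile_property_matrix(img: GrayImage, tile: int = 256, **prop_kw) -> np.ndarray:
    """Per-tile property vectors, one row per tile (row-major tile order)."""
    tiles = partition_tiles(img, tile)
    return np.vstack([compute_properties(t, **prop_kw).as_array() for t in tiles])


def diff_from_tile_matrices(pb: np.ndarray, pc: np.ndarray) -> DiffVector:
    """Variance differences from precomputed tile-property matrices."""
    diffs = np.empty(5)
    for j in range(5):
        ok = np.isfinite(pb[:, j]) & np.isfinite(pc[:, j])
        if ok.sum() < 2:
            diffs[j] = float("nan")
            continue
        diffs[j] = np.var(pc[ok, j], ddof=1) - np.var(pb[ok, j], ddof=1)
    return DiffVector(*diffs)


def diff_vector(
    background: GrayImage, composed: GrayImage, tile: int = 256, **prop_kw
) -> DiffVector:
    """Tile-variance difference variables for one composed stimulus.

    For each property, the sample variance (n-1 denominator) across tiles
    of the composed image minus the same variance for the background.
    Tiles where alpha/deviation are undefined in either image are excluded
    pairwise from both variances for those properties.
    """
    if background.levels.shape != composed.levels.shape:
        raise ValueError("background and composed dimensions differ")
    pb = tile_property_matrix(background, tile, **prop_kw)
    pc = tile_property_matrix(composed, tile, **prop_kw)
    return diff_from_tile_matrices(pb, pc)
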
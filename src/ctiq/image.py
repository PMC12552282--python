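"""ROI images and the reference-free noise-isolation filters.

The noise model underlying the whole package: a CT region of interest is a
smooth underlying signal plus stochastic reconstruction noise.  Subtracting a
lowpass (Gaussian) copy from the original removes the anatomy and keeps the
predominantly high-frequency noise; a local standard-deviation filter over the
residual then yields a per-pixel noise map.  Every filter here is mask-aware:
pixels outside the ROI never contribute, and quantities that need a complete
window are left undefined (NaN) rather than silently biased.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .exceptions import EmptyRoiError, RoiTooSmallError

__all__ = [
    "RoiImage",
    "NoiseMap",
    "gaussian_kernel1d",
    "disk_footprint",
    "lowpass",
    "highpass_residual",
    "highpass_attenuation",
    "std_filter",
]


@dataclass
class RoiImage:
    """A 2D intensity grid (HU-like) with a pixel-validity mask.

    Parameters
    ----------
    pixels
        2D array of intensities.  Values outside ``valid_mask`` are ignored by
        every operation and may be arbitrary.
    valid_mask
        Boolean array marking ROI membership.  ``None`` means the full grid.
    pixel_spacing
        Physical length per pixel (isotropic); only edge-sharpness results
        carry this unit.
    """

    pixels: np.ndarray
    valid_mask: np.ndarray | None = None
    pixel_spacing: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"RoiImage expects a 2D grid, got ndim={self.pixels.ndim}")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.pixels.shape, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.pixels.shape:
                raise ValueError("valid_mask shape does not match pixels")
        if not self.valid_mask.any():
            raise EmptyRoiError("ROI mask has no valid pixels")
        if not np.isfinite(self.pixels[self.valid_mask]).all():
            raise ValueError("non-finite intensities inside the ROI")
        if not self.pixel_spacing > 0:
            raise ValueError("pixel_spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class NoiseMap:
    """Per-pixel local standard deviation of a highpass residual.

    ``local_std`` is NaN wherever the full circular window did not fit inside
    the ROI; ``defined_mask`` exposes the complement.
    """

    local_std: np.ndarray
    window_radius: float
    source: RoiImage = field(repr=False)

    @property
    def defined_mask(self) -> np.ndarray:
        return np.isfinite(self.local_std)


def gaussian_kernel1d(sigma: float, truncate: float = 4.0) -> np.ndarray:
    """Discrete, normalized 1D Gaussian kernel truncated at ``truncate`` sigmas."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    radius = max(int(truncate * sigma + 0.5), 1)
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def disk_footprint(radius: float) -> np.ndarray:
    """Boolean disk: offsets whose center distance is <= radius (inclusive)."""
    r = int(np.floor(radius + 1e-9))
    if r < 1:
        raise ValueError("radius must be at least 1 pixel")
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    return (dy * dy + dx * dx) <= radius * radius + 1e-9


def _separable_correlate(arr: np.ndarray, k: np.ndarray) -> np.ndarray:
    out = ndimage.correlate1d(arr, k, axis=0, mode="constant", cval=0.0)
    return ndimage.correlate1d(out, k, axis=1, mode="constant", cval=0.0)


def lowpass(image: RoiImage, lp_sigma: float = 2.0) -> RoiImage:
    """Mask-aware Gaussian smoothing.

    Kernel weights are renormalized over the valid pixels under the window, so
    masked-out neighbours contribute nothing and a constant ROI stays exactly
    constant up to its border (no edge darkening).
    """
    if lp_sigma <= 0:
        raise ValueError("lp_sigma must be positive")
    k = gaussian_kernel1d(lp_sigma)
    m = image.valid_mask.astype(float)
    filled = np.where(image.valid_mask, image.pixels, 0.0)
    num = _separable_correlate(filled, k)
    den = _separable_correlate(m, k)
    out = np.zeros_like(filled)
    inside = image.valid_mask & (den > 0)
    out[inside] = num[inside] / den[inside]
    return RoiImage(out, image.valid_mask.copy(), image.pixel_spacing)


def highpass_residual(
    image: RoiImage, lp_sigma: float = 2.0, *, lowpassed: RoiImage | None = None
) -> RoiImage:
    """Original minus lowpass copy: isolates the noise-dominated frequencies.

    ``lowpassed`` lets callers reuse an already-computed smooth copy.
    """
    lp = lowpassed if lowpassed is not None else lowpass(image, lp_sigma)
    res = np.where(image.valid_mask, image.pixels - lp.pixels, 0.0)
    return RoiImage(res, image.valid_mask.copy(), image.pixel_spacing)


def highpass_attenuation(
    lp_sigma: float = 2.0, noise_corr_sigma: float = 0.0, truncate: float = 4.0
) -> float:
    """STD attenuation factor ``a`` of the highpass step on stationary noise.

    For white noise with STD sigma, the residual ``x - G*x`` has STD
    ``sigma * a`` with ``a = ||delta - g||_2`` computed from the discrete 2D
    kernel ``g``.  For noise pre-correlated with a Gaussian of width
    ``noise_corr_sigma`` (and rescaled back to STD sigma, as the phantom
    generator does), ``a = ||(delta - g) * h||_2 / ||h||_2`` with ``h`` the
    correlation kernel.
    """
    k = gaussian_kernel1d(lp_sigma, truncate)
    g = np.outer(k, k)
    hp = -g.copy()
    c = g.shape[0] // 2
    hp[c, c] += 1.0
    if noise_corr_sigma <= 0:
        return float(np.sqrt((hp**2).sum()))
    hc = gaussian_kernel1d(noise_corr_sigma, truncate)
    h = np.outer(hc, hc)
    conv = signal.fftconvolve(hp, h)
    return float(np.linalg.norm(conv) / np.linalg.norm(h))


def std_filter(residual: RoiImage, window_radius: float = 3) -> NoiseMap:
    """Local sample STD (ddof=1) of the residual over a circular window.

    Defined only at pixels whose complete disk of ``window_radius`` lies inside
    the ROI; everywhere else the map is NaN.
    """
    fp = disk_footprint(window_radius)
    n = int(fp.sum())
    if n < 2:
        raise ValueError("window must contain at least 2 pixels")
    fpi = fp.astype(np.int64)
    cnt = ndimage.correlate(residual.valid_mask.astype(np.int64), fpi, mode="constant", cval=0)
    full = cnt == n
    if not full.any():
        raise RoiTooSmallError("ROI too small for noise estimation")
    fpf = fp.astype(float)
    filled = np.where(residual.valid_mask, residual.pixels, 0.0)
    s1 = ndimage.correlate(filled, fpf, mode="constant", cval=0.0)
    s2 = ndimage.correlate(filled * filled, fpf, mode="constant", cval=0.0)
    var = (s2 - s1 * s1 / n) / (n - 1)
    np.clip(var, 0.0, None, out=var)
    local_std = np.where(full, np.sqrt(var), np.nan)
    return NoiseMap(local_std, float(window_radius), residual)
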
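"""Per-tissue image-quality metrics and the full ROI assessment pipeline.

The pipeline mirrors how objective quality is read off a clinical CT region of
interest without a reference image:

1. isolate noise by subtracting a lowpass copy (``image.highpass_residual``),
2. map it with a local-STD filter (``image.std_filter``),
3. estimate the minimum noise STDmin as the mean of the five lowest
   12-pixel-circle averages of that map (order-statistic estimate, robust to
   anatomy leaking into the highpass),
4. read each tissue's signal intensity SI off its bin-width-20 histogram mode,
5. form SNR = SI / STDmin and, for two-tissue ROIs, CNR = dSI / mean(STDmin),
   plus grey-value entropy and the 10-90% edge-transition width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit
from scipy.special import erf

from .exceptions import (
    BimodalityError,
    EmptyRoiError,
    InsufficientBoundaryError,
    RoiTooSmallError,
    ZeroNoiseError,
)
from .image import NoiseMap, RoiImage, disk_footprint, highpass_residual, lowpass, std_filter

__all__ = [
    "TissueQuality",
    "TwoTissueQuality",
    "std_min",
    "modal_si",
    "grey_entropy",
    "split_two_tissues",
    "snr",
    "cnr",
    "edge_sharpness",
    "assess_roi",
    "EDGE_WIDTH_PER_SIGMA",
]

# 10-90% width of an error-function edge of Gaussian scale sigma:
# 2 * Phi^-1(0.9) = 2 * 1.2815515655...
EDGE_WIDTH_PER_SIGMA = 2.5631031310892007


@dataclass
class TissueQuality:
    """Quality record for a single tissue: SI, STDmin, SNR, entropy."""

    si: float
    std_min: float
    snr: float
    entropy_bits: float
    n_pixels: int


@dataclass
class TwoTissueQuality:
    """Quality record for a two-tissue ROI, ordered so ``delta_si >= 0``."""

    low: TissueQuality
    high: TissueQuality
    delta_si: float
    mean_std_min: float
    cnr: float
    sharpness_width: float
    threshold: float


def _masked_values(image: RoiImage, mask: np.ndarray | None) -> np.ndarray:
    m = image.valid_mask if mask is None else (image.valid_mask & np.asarray(mask, bool))
    vals = image.pixels[m]
    if vals.size == 0:
        raise EmptyRoiError("tissue mask is empty")
    return vals


def _histogram(vals: np.ndarray, bin_width: float):
    """Counts over bins of ``bin_width`` anchored at the minimum value.

    Returns (bin index per value, counts, bin edges).  The anchoring makes all
    downstream quantities exactly invariant under a constant intensity offset.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    vmin = float(vals.min())
    idx = np.floor((vals - vmin) / bin_width).astype(np.int64)
    nbins = int(idx.max()) + 1
    counts = np.bincount(idx, minlength=nbins)
    edges = vmin + bin_width * np.arange(nbins + 1)
    return idx, counts, edges


def _modal_bin(counts: np.ndarray, edges: np.ndarray, overall_mean: float) -> int:
    """Most populated bin; ties go to the bin whose lower edge is nearest the mean."""
    best = counts.max()
    cand = np.flatnonzero(counts == best)
    if cand.size == 1:
        return int(cand[0])
    dist = np.abs(edges[cand] - overall_mean)
    return int(cand[np.argmin(dist)])


def modal_si(image: RoiImage, tissue_mask: np.ndarray | None = None, bin_width: float = 20.0) -> float:
    """Modal signal intensity from the bin-width-20 histogram of a tissue.

    The mode is first located by grouped-data interpolation between the most
    populated bin and its neighbours, ``L + h*(f1-f0)/(2*f1-f0-f2)``, which is
    insensitive to where the bin edges happen to fall relative to the true
    mode; the returned SI is then the mean of the values within half a bin
    width of that location (a self-centering refinement: a window centered on
    the peak trims symmetrically, so the residual bias is second order in the
    interpolation error).  When both neighbouring bins are empty (constant or
    near-constant tissue) the mean of the modal bin is returned directly.
    """
    vals = _masked_values(image, tissue_mask)
    idx, counts, edges = _histogram(vals, bin_width)
    b = _modal_bin(counts, edges, float(vals.mean()))
    f1 = float(counts[b])
    f0 = float(counts[b - 1]) if b > 0 else 0.0
    f2 = float(counts[b + 1]) if b + 1 < counts.size else 0.0
    denom = 2.0 * f1 - f0 - f2
    if (f0 == 0.0 and f2 == 0.0) or denom <= 0.0:
        return float(vals[idx == b].mean())
    mode0 = float(edges[b] + bin_width * (f1 - f0) / denom)
    window = vals[np.abs(vals - mode0) <= bin_width / 2.0]
    return float(window.mean()) if window.size else mode0


def grey_entropy(
    image: RoiImage, tissue_mask: np.ndarray | None = None, bin_width: float = 20.0
) -> float:
    """Shannon entropy (bits) of the normalized bin-width-20 grey-value histogram."""
    vals = _masked_values(image, tissue_mask)
    _, counts, _ = _histogram(vals, bin_width)
    p = counts[counts > 0] / vals.size
    return float(-(p * np.log2(p)).sum())


def split_two_tissues(
    image: RoiImage, bin_width: float = 20.0, min_mode_separation_bins: int = 2
):
    """Histogram-based split of a bimodal ROI into low- and high-SI masks.

    Finds the two most populated bins separated by at least
    ``min_mode_separation_bins`` bin widths; the threshold is the center of the
    least-populated bin between them (the valley), or the midpoint of the two
    mode centers if the valley is tied.  Raises :class:`BimodalityError` when
    no valley strictly below both modes exists.

    Returns ``(mask_low, mask_high, threshold)``.
    """
    vals = _masked_values(image, None)
    overall_mean = float(vals.mean())
    _, counts, edges = _histogram(vals, bin_width)
    if counts.size <= min_mode_separation_bins:
        raise BimodalityError("two-tissue split requires bimodal ROI")
    i1 = _modal_bin(counts, edges, overall_mean)
    far = np.flatnonzero(
        (np.abs(np.arange(counts.size) - i1) >= min_mode_separation_bins) & (counts > 0)
    )
    if far.size == 0:
        raise BimodalityError("two-tissue split requires bimodal ROI")
    far_best = counts[far].max()
    cand = far[counts[far] == far_best]
    if cand.size > 1:
        cand = cand[np.argsort(np.abs(edges[cand] - overall_mean), kind="stable")]
    i2 = int(cand[0])
    lo, hi = sorted((i1, i2))
    between = counts[lo + 1 : hi]
    valley_count = between.min()
    if valley_count >= min(counts[lo], counts[hi]):
        raise BimodalityError("two-tissue split requires bimodal ROI")
    valley_bins = lo + 1 + np.flatnonzero(between == valley_count)
    centers = edges[:-1] + bin_width / 2.0
    if valley_bins.size == 1:
        threshold = float(centers[valley_bins[0]])
    else:
        threshold = float((centers[lo] + centers[hi]) / 2.0)
    mask_low = image.valid_mask & (image.pixels < threshold)
    mask_high = image.valid_mask & (image.pixels >= threshold)
    return mask_low, mask_high, threshold


def std_min(
    noise_map: NoiseMap,
    region_mask: np.ndarray | None = None,
    region_diameter_px: int = 12,
    k_lowest: int = 5,
) -> float:
    """Minimum-noise estimate: mean of the ``k_lowest`` lowest circle averages.

    Candidate circles of ``region_diameter_px`` are placed at every pixel whose
    full circle fits inside the region and the defined part of the noise map;
    each candidate scores the mean local STD over its circle.  Ties are broken
    by (score, row, col) lexicographic order, so the result is deterministic.
    """
    if k_lowest < 1:
        raise ValueError("k_lowest must be at least 1")
    radius = region_diameter_px / 2.0
    fp = disk_footprint(radius)
    m = int(fp.sum())
    defined = noise_map.defined_mask
    if region_mask is not None:
        defined = defined & np.asarray(region_mask, bool)
    cnt = ndimage.correlate(defined.astype(np.int64), fp.astype(np.int64), mode="constant", cval=0)
    ok = cnt == m
    n_cand = int(ok.sum())
    if n_cand < k_lowest:
        raise RoiTooSmallError(
            f"region admits only {n_cand} candidate circles of diameter "
            f"{region_diameter_px}px; need at least {k_lowest}"
        )
    ssum = ndimage.correlate(
        np.nan_to_num(noise_map.local_std), fp.astype(float), mode="constant", cval=0.0
    )
    rows, cols = np.nonzero(ok)
    scores = ssum[rows, cols] / m
    order = np.lexsort((cols, rows, scores))
    return float(scores[order[:k_lowest]].mean())


def snr(si: float, std_min_value: float) -> float:
    """Signal-to-noise ratio SI / STDmin."""
    if std_min_value < 0:
        raise ValueError("std_min must be non-negative")
    if std_min_value == 0:
        raise ZeroNoiseError("zero noise estimate")
    return float(si / std_min_value)


def cnr(si_low: float, si_high: float, std_min_low: float, std_min_high: float) -> float:
    """Contrast-to-noise ratio: (SI_high - SI_low) / mean of both STDmin."""
    mean_std = (std_min_low + std_min_high) / 2.0
    if mean_std < 0:
        raise ValueError("std_min values must be non-negative")
    if mean_std == 0:
        raise ZeroNoiseError("zero noise estimate")
    return float((si_high - si_low) / mean_std)


def _erf_edge(t, lo, delta, t0, sigma):
    return lo + delta * 0.5 * (1.0 + erf((t - t0) / (sigma * np.sqrt(2.0))))


def edge_sharpness(
    image: RoiImage,
    mask_low: np.ndarray,
    mask_high: np.ndarray,
    *,
    smooth_sigma: float = 2.0,
    profile_halflength: float = 8.0,
    sample_step: float = 0.25,
    max_profiles: int = 200,
) -> float:
    """10-90% edge-transition distance across the low/high tissue interface.

    Intensity profiles are sampled along the boundary normal (normals from the
    gradient of a smoothed tissue indicator), aligned at their half-height
    crossing, averaged, and fit with an error-function edge model; the returned
    width is ``2.563 * sigma_fit`` in pixel-spacing units.
    """
    mask_low = np.asarray(mask_low, bool) & image.valid_mask
    mask_high = np.asarray(mask_high, bool) & image.valid_mask
    if not mask_low.any() or not mask_high.any():
        raise InsufficientBoundaryError("insufficient boundary for sharpness")
    st = ndimage.generate_binary_structure(2, 2)
    boundary = (ndimage.binary_dilation(mask_low, st) & mask_high) | (
        ndimage.binary_dilation(mask_high, st) & mask_low
    )
    pts = np.argwhere(boundary)
    if pts.shape[0] < 8:
        raise InsufficientBoundaryError("insufficient boundary for sharpness")
    indicator = ndimage.gaussian_filter(
        mask_high.astype(float) - mask_low.astype(float), smooth_sigma
    )
    gy, gx = np.gradient(indicator)
    if pts.shape[0] > max_profiles:
        pts = pts[np.linspace(0, pts.shape[0] - 1, max_profiles).astype(int)]
    t = np.arange(-profile_halflength, profile_halflength + sample_step / 2, sample_step)
    profiles = []
    plateau = t <= -profile_halflength / 2
    for r, c in pts:
        g = np.array([gy[r, c], gx[r, c]])
        norm = np.hypot(*g)
        if norm < 1e-12:
            continue
        g /= norm
        coords = np.array([r + t * g[0], c + t * g[1]])
        prof = ndimage.map_coordinates(image.pixels, coords, order=1, mode="nearest")
        lo_val = prof[plateau].mean()
        hi_val = prof[plateau[::-1]].mean()
        if not np.isfinite(lo_val) or not np.isfinite(hi_val) or lo_val == hi_val:
            continue
        mid = 0.5 * (lo_val + hi_val)
        sm = ndimage.uniform_filter1d(prof, size=max(int(round(1.0 / sample_step)), 1))
        sign = np.sign(sm - mid)
        crossings = np.flatnonzero(np.diff(sign) != 0)
        if crossings.size == 0:
            continue
        j = crossings[np.argmin(np.abs(t[crossings]))]
        denom = sm[j + 1] - sm[j]
        frac = 0.0 if denom == 0 else (mid - sm[j]) / denom
        t0 = t[j] + frac * sample_step
        profiles.append(np.interp(t + t0, t, prof))
    if len(profiles) < 1:
        raise InsufficientBoundaryError("insufficient boundary for sharpness")
    mean_prof = np.mean(profiles, axis=0)
    lo0 = float(mean_prof[0])
    d0 = float(mean_prof[-1] - mean_prof[0])
    try:
        popt, _ = curve_fit(
            _erf_edge,
            t,
            mean_prof,
            p0=[lo0, d0, 0.0, 1.0],
            bounds=(
                [-np.inf, -np.inf, -profile_halflength, 1e-3],
                [np.inf, np.inf, profile_halflength, profile_halflength],
            ),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological profiles
        raise InsufficientBoundaryError(f"edge model fit failed: {exc}") from exc
    sigma_fit = abs(float(popt[3]))
    return EDGE_WIDTH_PER_SIGMA * sigma_fit * image.pixel_spacing


def _tissue_quality(
    image: RoiImage,
    noise_map: NoiseMap,
    mask: np.ndarray,
    bin_width: float,
    region_diameter_px: int,
    k_lowest: int,
) -> TissueQuality:
    si = modal_si(image, mask, bin_width)
    stdm = std_min(noise_map, mask, region_diameter_px, k_lowest)
    return TissueQuality(
        si=si,
        std_min=stdm,
        snr=snr(si, stdm),
        entropy_bits=grey_entropy(image, mask, bin_width),
        n_pixels=int((image.valid_mask & mask).sum()),
    )


def assess_roi(
    image: RoiImage,
    *,
    lp_sigma: float = 2.0,
    window_radius: float = 3,
    bin_width: float = 20.0,
    region_diameter_px: int = 12,
    k_lowest: int = 5,
) -> TissueQuality | TwoTissueQuality:
    """Run the full objective-quality pipeline on one ROI.

    A bimodal ROI yields a :class:`TwoTissueQuality` (SI, STDmin, SNR and
    entropy per tissue, plus dSI, CNR and edge sharpness); a unimodal ROI
    yields a single :class:`TissueQuality`.  The two-tissue masks are derived
    by thresholding the lowpass copy, where the histogram valley is far better
    resolved; SI, entropy and sharpness are always measured on the original
    image, and STDmin on the noise map of the original's highpass residual.
    """
    lp = lowpass(image, lp_sigma)
    res = highpass_residual(image, lp_sigma, lowpassed=lp)
    nm = std_filter(res, window_radius)
    try:
        mask_low, mask_high, threshold = split_two_tissues(lp, bin_width)
    except BimodalityError:
        return _tissue_quality(image, nm, image.valid_mask, bin_width, region_diameter_px, k_lowest)
    low = _tissue_quality(image, nm, mask_low, bin_width, region_diameter_px, k_lowest)
    high = _tissue_quality(image, nm, mask_high, bin_width, region_diameter_px, k_lowest)
    if low.si > high.si:  # defensive: ordering convention keeps delta_si >= 0
        low, high = high, low
        mask_low, mask_high = mask_high, mask_low
    return TwoTissueQuality(
        low=low,
        high=high,
        delta_si=high.si - low.si,
        mean_std_min=(low.std_min + high.std_min) / 2.0,
        cnr=cnr(low.si, high.si, low.std_min, high.std_min),
        sharpness_width=edge_sharpness(image, mask_low, mask_high),
        threshold=threshold,
    )
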
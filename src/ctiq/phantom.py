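"""Synthetic CT-like ROI phantoms with known ground truth.

Each phantom is one or two flat tissue plateaus (HU-like intensities) with an
optionally blurred boundary, plus additive Gaussian noise of controlled
magnitude and spatial correlation.  The generator records the exact realized
noise STD and the noiseless tissue masks, so every estimator in
:mod:`ctiq.metrics` can be validated by parameter recovery without any patient
data.  Noise is rescaled *after* the correlation filtering, so the ground-truth
magnitude is exact regardless of correlation length.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from itertools import product
from pathlib import Path

import numpy as np
from scipy import ndimage

from .image import RoiImage

__all__ = [
    "EDGE_GEOMETRIES",
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "default_suite_specs",
    "phantom_suite",
    "save_phantom",
    "load_phantom",
]

EDGE_GEOMETRIES = ("vertical-step", "disk")

# Pixels whose noiseless value differs from both plateau levels by more than
# this fraction of dSI form the blurred boundary band, excluded from the masks.
_BOUNDARY_TOL = 0.01


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic ROI phantom.

    ``si_low``/``si_high`` are plateau intensities (HU-like; ``si_high`` absent
    for one-tissue phantoms), ``noise_sigma`` the noise STD, ``noise_corr_sigma``
    the Gaussian correlation length of the noise field (0 = white),
    ``edge_blur_sigma`` the Gaussian blur of the tissue boundary.  ``quantize``
    rounds intensities to integers to mimic HU-valued images.
    """

    si_low: float
    si_high: float | None = None
    shape: tuple[int, int] = (256, 256)
    noise_sigma: float = 0.0
    noise_corr_sigma: float = 0.0
    edge_blur_sigma: float = 0.0
    edge_geometry: str = "vertical-step"
    seed: int = 0
    quantize: bool = False

    def __post_init__(self) -> None:
        rows, cols = self.shape
        if rows <= 0 or cols <= 0:
            raise ValueError("shape must be positive in both dimensions")
        if self.si_high is not None and not self.si_high > self.si_low:
            raise ValueError("si_high must exceed si_low")
        for name in ("noise_sigma", "noise_corr_sigma", "edge_blur_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.edge_geometry not in EDGE_GEOMETRIES:
            raise ValueError(f"edge_geometry must be one of {EDGE_GEOMETRIES}")

    @property
    def two_tissue(self) -> bool:
        return self.si_high is not None


@dataclass
class PhantomTruth:
    """A generated phantom together with its ground truth."""

    spec: PhantomSpec
    image: RoiImage
    tissue_masks: tuple[np.ndarray, ...]
    true_noise_sigma_effective: float


def _template(spec: PhantomSpec) -> np.ndarray:
    rows, cols = spec.shape
    tpl = np.full(spec.shape, float(spec.si_low))
    if spec.two_tissue:
        if spec.edge_geometry == "vertical-step":
            tpl[:, cols // 2 :] = spec.si_high
        else:  # disk
            cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
            yy, xx = np.mgrid[0:rows, 0:cols]
            r = min(rows, cols) / 4.0
            tpl[(yy - cy) ** 2 + (xx - cx) ** 2 <= r * r] = spec.si_high
    return tpl


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Generate one phantom; deterministic for a fixed seed.

    The noiseless template is the plateau image convolved with a Gaussian of
    ``edge_blur_sigma``; the noise field is white Gaussian noise, optionally
    correlated with a Gaussian of ``noise_corr_sigma`` and then rescaled so its
    realized sample STD equals ``noise_sigma`` exactly.
    """
    tpl = _template(spec)
    if spec.edge_blur_sigma > 0:
        tpl = ndimage.gaussian_filter(tpl, spec.edge_blur_sigma, mode="nearest")
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        w = rng.standard_normal(spec.shape)
        if spec.noise_corr_sigma > 0:
            w = ndimage.gaussian_filter(w, spec.noise_corr_sigma)
        w = w - w.mean()
        w *= spec.noise_sigma / w.std(ddof=1)
        realized = float(w.std(ddof=1))
    else:
        w = np.zeros(spec.shape)
        realized = 0.0
    img = tpl + w
    if spec.quantize:
        img = np.rint(img)
    if spec.two_tissue:
        band = _BOUNDARY_TOL * (spec.si_high - spec.si_low)
        masks = (
            np.abs(tpl - spec.si_low) <= band,
            np.abs(tpl - spec.si_high) <= band,
        )
    else:
        masks = (np.ones(spec.shape, dtype=bool),)
    return PhantomTruth(
        spec=spec,
        image=RoiImage(img),
        tissue_masks=masks,
        true_noise_sigma_effective=realized,
    )


def default_suite_specs(base_seed: int = 0) -> list[PhantomSpec]:
    """The 30-phantom fixture grid: sigma x correlation x blur on a 50/150 step.

    sigma in {0, 5, 10, 20, 40} HU, correlation in {0, 1.5} px, blur in
    {0, 1, 2} px; 256x256 vertical-step phantoms with per-spec deterministic
    seeds derived from ``base_seed``.
    """
    specs = []
    for i, (sig, corr, blur) in enumerate(
        product((0.0, 5.0, 10.0, 20.0, 40.0), (0.0, 1.5), (0.0, 1.0, 2.0))
    ):
        specs.append(
            PhantomSpec(
                si_low=50.0,
                si_high=150.0,
                noise_sigma=sig,
                noise_corr_sigma=corr,
                edge_blur_sigma=blur,
                seed=(base_seed * 1009 + 97 * i + 13) % (2**31),
            )
        )
    return specs


def phantom_suite(
    grid: list[PhantomSpec] | None = None, base_seed: int = 0
) -> list[PhantomTruth]:
    """Generate a reproducible phantom collection (default: the 30-spec grid)."""
    if grid is None:
        grid = default_suite_specs(base_seed)
    if len(grid) == 0:
        raise ValueError("phantom grid must be non-empty")
    return [generate_phantom(s) for s in grid]


def save_phantom(truth: PhantomTruth, outdir: str | Path, stem: str) -> Path:
    """Write image and masks as .npy plus a JSON sidecar with spec and truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.save(outdir / f"{stem}.npy", truth.image.pixels)
    for j, m in enumerate(truth.tissue_masks):
        np.save(outdir / f"{stem}.mask{j}.npy", m)
    sidecar = {
        "spec": asdict(truth.spec),
        "true_noise_sigma_effective": truth.true_noise_sigma_effective,
        "n_tissues": len(truth.tissue_masks),
    }
    path = outdir / f"{stem}.json"
    path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def load_phantom(outdir: str | Path, stem: str) -> PhantomTruth:
    """Inverse of :func:`save_phantom`."""
    outdir = Path(outdir)
    meta = json.loads((outdir / f"{stem}.json").read_text())
    spec_dict = dict(meta["spec"])
    spec_dict["shape"] = tuple(spec_dict["shape"])
    spec = PhantomSpec(**spec_dict)
    img = np.load(outdir / f"{stem}.npy")
    masks = tuple(
        np.load(outdir / f"{stem}.mask{j}.npy") for j in range(meta["n_tissues"])
    )
    return PhantomTruth(spec, RoiImage(img), masks, meta["true_noise_sigma_effective"])
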
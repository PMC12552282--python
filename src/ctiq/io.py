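"""Readers and writers: DICOM / portable arrays, ROI specs, provenance sidecars."""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from . import __version__
from .exceptions import InputFormatError
from .image import RoiImage

__all__ = [
    "read_array",
    "read_image",
    "roi_mask_from_spec",
    "read_roi",
    "write_dicom",
    "sha256_of",
    "write_provenance",
]


def read_array(path: str | Path) -> np.ndarray:
    """Read a 2D array from .npy/.npz/.txt/.csv or DICOM (HU-rescaled)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".npy":
        arr = np.load(path)
    elif suffix == ".npz":
        with np.load(path) as z:
            arr = z[z.files[0]]
    elif suffix in (".txt", ".csv"):
        arr = np.loadtxt(path, delimiter="," if suffix == ".csv" else None)
    elif suffix in (".dcm", ".dicom", ".ima"):
        arr = _read_dicom(path)
    else:
        raise InputFormatError(f"unsupported image format: {path.suffix!r}")
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2:
        raise InputFormatError(f"expected a 2D image, got shape {arr.shape}")
    return arr


def _read_dicom(path: Path) -> np.ndarray:
    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(float)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    return arr * slope + intercept


def roi_mask_from_spec(spec: dict, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a JSON ROI spec.

    ``{"circle": {"cx": ..., "cy": ..., "r": ...}}`` with cx = column,
    cy = row and inclusive membership (center distance <= r), or
    ``{"polygon": {"points": [[col, row], ...]}}``.
    """
    if not isinstance(spec, dict) or len(spec) != 1:
        raise InputFormatError(
            "ROI spec must contain exactly one of the keys 'circle' or 'polygon'"
        )
    (kind, body), = spec.items()
    if kind == "circle":
        for key in ("cx", "cy", "r"):
            if key not in body:
                raise InputFormatError(f"circle ROI spec is missing key '{key}'")
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        return (yy - body["cy"]) ** 2 + (xx - body["cx"]) ** 2 <= body["r"] ** 2
    if kind == "polygon":
        if "points" not in body:
            raise InputFormatError("polygon ROI spec is missing key 'points'")
        from skimage.draw import polygon

        pts = np.asarray(body["points"], dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise InputFormatError("polygon 'points' must be >= 3 [col, row] pairs")
        rr, cc = polygon(pts[:, 1], pts[:, 0], shape)
        mask = np.zeros(shape, dtype=bool)
        mask[rr, cc] = True
        return mask
    raise InputFormatError(f"unknown ROI spec key '{kind}'")


def read_roi(path: str | Path, shape: tuple[int, int]) -> np.ndarray:
    """Read an ROI: a boolean .npy mask or a JSON circle/polygon spec."""
    path = Path(path)
    if path.suffix.lower() == ".npy":
        mask = np.load(path)
        if mask.shape != shape:
            raise InputFormatError("ROI mask shape does not match the image")
        return mask.astype(bool)
    if path.suffix.lower() == ".json":
        try:
            spec = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise InputFormatError(f"malformed ROI JSON: {exc}") from exc
        return roi_mask_from_spec(spec, shape)
    raise InputFormatError(f"unsupported ROI format: {path.suffix!r}")


def read_image(image_path, roi_path=None, pixel_spacing: float = 1.0) -> RoiImage:
    """Read an image and optional ROI into a :class:`RoiImage`."""
    arr = read_array(image_path)
    mask = read_roi(roi_path, arr.shape) if roi_path is not None else None
    return RoiImage(arr, mask, pixel_spacing)


def write_dicom(pixels: np.ndarray, path: str | Path) -> Path:
    """Write a float image as 16-bit secondary-capture DICOM with rescale tags."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage

    pixels = np.asarray(pixels, dtype=float)
    vmin, vmax = float(pixels.min()), float(pixels.max())
    slope = (vmax - vmin) / 65535.0 if vmax > vmin else 1.0
    stored = np.round((pixels - vmin) / slope).astype(np.uint16)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = pydicom.uid.generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "OT"
    ds.Rows, ds.Columns = stored.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.RescaleSlope = slope
    ds.RescaleIntercept = vmin
    ds.PixelData = stored.tobytes()
    ds.save_as(str(path), enforce_file_format=True)
    return Path(path)


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_provenance(
    out_path: str | Path,
    subcommand: str,
    params: dict,
    inputs: list[str | Path] | None = None,
    seed: int | None = None,
) -> Path:
    """Write ``<out>.provenance.json`` next to an output artifact.

    Timestamps live only here, so the artifacts themselves stay byte-identical
    across reruns with identical configuration.
    """
    out_path = Path(out_path)
    payload = {
        "tool": "ctiq",
        "version": __version__,
        "subcommand": subcommand,
        "parameters": params,
        "seed": seed,
        "inputs": {str(p): sha256_of(p) for p in (inputs or []) if Path(p).exists()},
        "written_at": datetime.now(timezone.utc).isoformat(),
    }
    sidecar = out_path.with_name(out_path.name + ".provenance.json")
    sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return sidecar
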
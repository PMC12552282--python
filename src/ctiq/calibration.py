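"""Order-statistic calibration of the minimum-noise estimate.

STDmin deliberately under-reads the spatial mean of the local noise STD: it is
the mean of the five *lowest* 12-pixel-circle averages, so on a homogeneous
noise field it sits a calibratable factor ``b`` below ``sigma * a`` (``a`` the
highpass attenuation, see :func:`ctiq.image.highpass_attenuation`).  ``b``
depends on the spatial correlation of the noise (correlated fields fluctuate
more between circles, deepening the minimum) and is measured once on the
default phantom fixture suite, then stored with the package in
``data/calibration.json``.  ``scripts/calibrate.py`` regenerates the file.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np

from .image import highpass_attenuation, highpass_residual, std_filter
from .metrics import std_min
from .phantom import phantom_suite

__all__ = [
    "load_calibration",
    "order_statistic_factor",
    "measure_order_statistic_factors",
]

_DATA = "calibration.json"


def load_calibration(path: str | Path | None = None) -> dict:
    """Load the stored calibration (or a user-supplied JSON)."""
    if path is not None:
        return json.loads(Path(path).read_text())
    ref = resources.files("ctiq").joinpath("data").joinpath(_DATA)
    return json.loads(ref.read_text())


def order_statistic_factor(
    noise_corr_sigma: float = 0.0, calibration: dict | None = None
) -> float:
    """Calibrated ``b = STDmin / (sigma * a)`` for the nearest stored correlation."""
    cal = calibration if calibration is not None else load_calibration()
    table = {float(k): float(v) for k, v in cal["order_statistic_factor"].items()}
    key = min(table, key=lambda c: abs(c - noise_corr_sigma))
    return table[key]


def measure_order_statistic_factors(
    *,
    base_seed: int = 0,
    lp_sigma: float = 2.0,
    window_radius: float = 3,
    region_diameter_px: int = 12,
    k_lowest: int = 5,
) -> dict:
    """Measure ``b`` per correlation level on the default fixture suite.

    For every noisy phantom in the suite, STDmin is evaluated on each true
    tissue mask and divided by ``sigma * a(correlation)``; the per-correlation
    mean of those ratios is the calibration factor.
    """
    ratios: dict[float, list[float]] = {}
    for truth in phantom_suite(base_seed=base_seed):
        spec = truth.spec
        if spec.noise_sigma == 0:
            continue
        a = highpass_attenuation(lp_sigma, spec.noise_corr_sigma)
        res = highpass_residual(truth.image, lp_sigma)
        nm = std_filter(res, window_radius)
        for mask in truth.tissue_masks:
            value = std_min(nm, mask, region_diameter_px, k_lowest)
            ratios.setdefault(spec.noise_corr_sigma, []).append(
                value / (spec.noise_sigma * a)
            )
    return {
        "lp_sigma": lp_sigma,
        "window_radius": window_radius,
        "region_diameter_px": region_diameter_px,
        "k_lowest": k_lowest,
        "base_seed": base_seed,
        "order_statistic_factor": {
            str(corr): float(np.mean(vals)) for corr, vals in sorted(ratios.items())
        },
    }
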
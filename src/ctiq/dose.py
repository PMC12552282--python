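"""Weight-adapted acquisition rule and the CTDIvol -> DLP -> effective-dose chain.

Units follow CT dosimetry convention: CTDIvol in mGy, scan length in cm,
DLP = CTDIvol x length in mGy*cm, effective dose = DLP x k in mSv with the
head/neck conversion factor k = 0.0058 mSv/(mGy*cm).  The weight-adapted tube
voltage rule is 80 kV for <= 70 kg, 100 kV for (70, 80] kg, 120 kV above.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import CtiqError, InputFormatError

__all__ = [
    "KV_LEVELS",
    "DEFAULT_SCAN_LENGTH_CM",
    "DEFAULT_K_FACTOR",
    "DoseRecord",
    "select_kv",
    "dlp",
    "effective_dose",
    "percent_reduction",
    "records_frame",
    "cohort_summary",
    "read_dose_csv",
]

log = logging.getLogger(__name__)

KV_LEVELS = (80, 100, 120)
DEFAULT_SCAN_LENGTH_CM = 25.0
DEFAULT_K_FACTOR = 0.0058  # mSv per mGy*cm, head and neck


def select_kv(weight: float) -> int:
    """Weight-adapted tube voltage in kV (step function of body weight in kg)."""
    if not weight > 0:
        raise CtiqError("patient weight must be positive")
    if weight <= 70:
        return 80
    if weight <= 80:
        return 100
    return 120


def dlp(ctdi_vol: float, scan_length: float = DEFAULT_SCAN_LENGTH_CM) -> float:
    """Dose-length product in mGy*cm."""
    if ctdi_vol < 0 or scan_length < 0:
        raise CtiqError("CTDIvol and scan length must be non-negative")
    return float(ctdi_vol * scan_length)


def effective_dose(dlp_value: float, k_factor: float = DEFAULT_K_FACTOR) -> float:
    """Effective dose in mSv (full precision; summaries round to 2 decimals)."""
    if dlp_value < 0:
        raise CtiqError("DLP must be non-negative")
    if k_factor < 0:
        raise CtiqError("k factor must be non-negative")
    return float(dlp_value * k_factor)


def percent_reduction(reference: float, reduced: float) -> float:
    """Percent dose reduction relative to a reference protocol.

    Negative when the 'reduced' value actually exceeds the reference.
    """
    if not reference > 0:
        raise CtiqError("reference dose must be positive")
    return float(100.0 * (1.0 - reduced / reference))


@dataclass
class DoseRecord:
    """One exam's dose accounting; DLP and effective dose are derived fields."""

    patient_id: str
    weight_kg: float
    tube_voltage: int
    ctdi_vol: float
    scan_length: float = DEFAULT_SCAN_LENGTH_CM
    k_factor: float = DEFAULT_K_FACTOR
    protocol_label: str = "default"
    dlp: float = field(init=False)
    effective_dose: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.weight_kg > 0:
            raise CtiqError("patient weight must be positive")
        if self.tube_voltage not in KV_LEVELS:
            raise CtiqError(f"tube voltage must be one of {KV_LEVELS}")
        self.dlp = dlp(self.ctdi_vol, self.scan_length)
        self.effective_dose = effective_dose(self.dlp, self.k_factor)

    @property
    def expected_kv(self) -> int:
        return select_kv(self.weight_kg)

    @property
    def protocol_deviation(self) -> bool:
        """True when the recorded kV disagrees with the weight-adapted rule."""
        return self.tube_voltage != self.expected_kv


def records_frame(records: list[DoseRecord]) -> pd.DataFrame:
    """Per-record table with the derived chain and the protocol-deviation flag."""
    if not records:
        raise CtiqError("no dose records")
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "protocol_label": [r.protocol_label for r in records],
            "weight_kg": [r.weight_kg for r in records],
            "kv": [r.tube_voltage for r in records],
            "expected_kv": [r.expected_kv for r in records],
            "protocol_deviation": [r.protocol_deviation for r in records],
            "ctdi_vol_mgy": [r.ctdi_vol for r in records],
            "scan_length_cm": [r.scan_length for r in records],
            "dlp_mgycm": [r.dlp for r in records],
            "effective_dose_msv": [r.effective_dose for r in records],
        }
    )


def _mean_sd(x: pd.Series) -> tuple[float, float]:
    sd = 0.0 if len(x) < 2 else float(np.std(x, ddof=1))
    return float(np.mean(x)), sd


def cohort_summary(records: list[DoseRecord]) -> pd.DataFrame:
    """Per-protocol mean +/- SD of CTDIvol, DLP and effective dose.

    Effective-dose columns are rounded to 2 decimals (reporting convention);
    the per-record frame keeps full precision.  ``n_kv_deviations`` counts
    records whose kV disagrees with the weight-adapted rule.
    """
    df = records_frame(records)
    rows = []
    for label, grp in df.groupby("protocol_label", sort=True):
        ctdi_m, ctdi_s = _mean_sd(grp["ctdi_vol_mgy"])
        dlp_m, dlp_s = _mean_sd(grp["dlp_mgycm"])
        ed_m, ed_s = _mean_sd(grp["effective_dose_msv"])
        rows.append(
            {
                "protocol_label": label,
                "n": len(grp),
                "ctdi_vol_mean_mgy": ctdi_m,
                "ctdi_vol_sd_mgy": ctdi_s,
                "dlp_mean_mgycm": dlp_m,
                "dlp_sd_mgycm": dlp_s,
                "effective_dose_mean_msv": round(ed_m, 2),
                "effective_dose_sd_msv": round(ed_s, 2),
                "n_kv_deviations": int(grp["protocol_deviation"].sum()),
            }
        )
    return pd.DataFrame(rows)


def read_dose_csv(path, k_factor: float = DEFAULT_K_FACTOR) -> list[DoseRecord]:
    """Read exam records from CSV.

    Expected columns: patient_id, weight_kg, kv, ctdi_vol_mgy and optionally
    scan_length_cm (missing -> default 25 cm with a logged notice) and
    protocol_label.
    """
    df = pd.read_csv(path)
    required = {"patient_id", "weight_kg", "kv", "ctdi_vol_mgy"}
    missing = required - set(df.columns)
    if missing:
        raise InputFormatError(f"dose CSV is missing columns: {sorted(missing)}")
    if "scan_length_cm" not in df.columns:
        log.info("scan_length_cm missing; using default %.0f cm", DEFAULT_SCAN_LENGTH_CM)
        df["scan_length_cm"] = DEFAULT_SCAN_LENGTH_CM
    else:
        n_na = int(df["scan_length_cm"].isna().sum())
        if n_na:
            log.info("%d records without scan_length_cm; using default %.0f cm",
                     n_na, DEFAULT_SCAN_LENGTH_CM)
            df["scan_length_cm"] = df["scan_length_cm"].fillna(DEFAULT_SCAN_LENGTH_CM)
    if "protocol_label" not in df.columns:
        df["protocol_label"] = "default"
    return [
        DoseRecord(
            patient_id=str(row.patient_id),
            weight_kg=float(row.weight_kg),
            tube_voltage=int(row.kv),
            ctdi_vol=float(row.ctdi_vol_mgy),
            scan_length=float(row.scan_length_cm),
            k_factor=k_factor,
            protocol_label=str(row.protocol_label),
        )
        for row in df.itertuples(index=False)
    ]
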
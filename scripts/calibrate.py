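"""Regenerate the stored order-statistic calibration.

Measures the ratio b = STDmin / (sigma * a) per noise-correlation level on the
default phantom fixture suite and writes it to src/ctiq/data/calibration.json.
Run from the repository root:

    python scripts/calibrate.py
"""

import json
from pathlib import Path

from ctiq.calibration import measure_order_statistic_factors


def main() -> None:
    cal = measure_order_statistic_factors()
    out = Path(__file__).resolve().parents[1] / "src" / "ctiq" / "data" / "calibration.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(cal, indent=2, sort_keys=True) + "\n")
    print(f"wrote {out}")
    print(json.dumps(cal["order_statistic_factor"], indent=2))


if __name__ == "__main__":
    main()
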
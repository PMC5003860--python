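"""Regenerate the packaged synthetic haemoglobin extinction table.

The table emulates the standard HbO/HbR molar extinction compilation used for
haemoglobin spectroscopy: PCHIP interpolation in log-extinction through anchor
values at the spectra's characteristic features (HbO alpha/beta bands at
542/577 nm, HbR band at 556 nm, the ~530 nm isosbestic crossing, and the steep
HbO falloff above 590 nm). It is a synthetic stand-in — anchor values are
rounded literature magnitudes, not a reproduction of any specific file — but
it carries the properties haemoglobin conversion relies on: the 530 nm
isosbestic point and the HbR-dominated red tail.

Run from the repository root:

    python scripts/make_extinction_fixture.py
"""

from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator

# wavelength (nm), xi_HbO, xi_HbR  (decadic, cm^-1 M^-1)
ANCHORS = [
    (440.0, 100000.0, 120000.0),
    (450.0, 62816.0, 70000.0),
    (460.0, 44000.0, 48000.0),
    (470.0, 33000.0, 38000.0),
    (480.0, 26000.0, 32000.0),
    (488.0, 22000.0, 29000.0),
    (500.0, 20800.0, 20800.0),
    (510.0, 24000.0, 22000.0),
    (520.0, 30000.0, 29000.0),
    (530.0, 39956.0, 39036.0),
    (542.0, 53236.0, 46000.0),
    (548.0, 48000.0, 50000.0),
    (556.0, 42000.0, 53412.0),
    (562.0, 36000.0, 51000.0),
    (570.0, 44000.0, 45000.0),
    (577.0, 55540.0, 37000.0),
    (584.0, 33000.0, 33000.0),
    (590.0, 15000.0, 28000.0),
    (600.0, 3200.0, 15000.0),
    (610.0, 1500.0, 9500.0),
    (620.0, 900.0, 6500.0),
    (630.0, 610.0, 5148.8),
    (640.0, 460.0, 4500.0),
    (650.0, 390.0, 3750.0),
    (660.0, 320.0, 3227.0),
    (680.0, 272.0, 2407.0),
    (700.0, 290.0, 1794.0),
    (710.0, 320.0, 1600.0),
]


def main() -> None:
    anchors = np.array(ANCHORS)
    grid = np.arange(450.0, 701.0, 1.0)
    hbo = 10.0 ** PchipInterpolator(anchors[:, 0], np.log10(anchors[:, 1]))(grid)
    hbr = 10.0 ** PchipInterpolator(anchors[:, 0], np.log10(anchors[:, 2]))(grid)
    out = Path(__file__).resolve().parents[1] / "src" / "wfom" / "data" / "hb_extinction_synthetic.csv"
    out.parent.mkdir(parents=True, exist_ok=True)
    with out.open("w") as fh:
        fh.write("# Synthetic HbO/HbR molar extinction table (decadic, cm^-1 M^-1).\n")
        fh.write("# Generated by scripts/make_extinction_fixture.py; see its docstring.\n")
        fh.write("wavelength_nm,xi_hbo,xi_hbr\n")
        for wl, a, b in zip(grid, hbo, hbr):
            fh.write(f"{wl:.0f},{a:.1f},{b:.1f}\n")
    print(f"wrote {out} ({len(grid)} rows)")


if __name__ == "__main__":
    main()
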
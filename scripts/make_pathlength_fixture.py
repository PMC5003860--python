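"""Regenerate the packaged wavelength-dependent pathlength table.

Runs this package's Monte Carlo reflectance model across 450-700 nm with
baseline absorption derived from the standard brain blood assumptions (2 mM
haemoglobin in blood, 3% blood volume, 75% oxygen saturation, via
wfom.spectra.baseline_mua) and a scatter power law anchored at
mu_s = 21 mm^-1 @ 530 nm with b = 1.3, g = 0.85, n_rel = 1.37, NA = 0.2.
The result is frozen as CSV so haemoglobin conversion does not need a Monte
Carlo run; values carry simulation (not measurement) uncertainty.

Run from the repository root:

    python scripts/make_pathlength_fixture.py
"""

from pathlib import Path

import numpy as np

from wfom.montecarlo import DetectionGeometry, OpticalProperties, pathlength_table, scatter_power_law
from wfom.spectra import BloodAssumptions, baseline_mua, load_extinction

N_PHOTONS = 200_000
SEED = 20160360


def main() -> None:
    table = load_extinction()
    blood = BloodAssumptions()
    wavelengths = np.arange(450.0, 701.0, 10.0)
    props = {
        float(wl): OpticalProperties(
            mua=baseline_mua(table, blood, float(wl)),
            mus=float(scatter_power_law(21.0, 530.0, 1.3, wl)),
            g=0.85,
        )
        for wl in wavelengths
    }
    geom = DetectionGeometry()
    result = pathlength_table(props, geom, n_photons=N_PHOTONS, seed=SEED)
    out = Path(__file__).resolve().parents[1] / "src" / "wfom" / "data" / "pathlength_synthetic.csv"
    result.to_csv(
        out,
        header_comment=(
            "Mean differential pathlength X(lambda), mm, of detected diffuse reflectance.\n"
            f"Generated by scripts/make_pathlength_fixture.py: Monte Carlo, {N_PHOTONS} photons\n"
            f"per wavelength, seed {SEED}; mu_a from 2 mM blood Hb / 3% blood volume / 75% SO2,\n"
            "mu_s = 21 mm^-1 (530 nm) * (lambda/530)^-1.3, g = 0.85, n_rel = 1.37, NA = 0.2."
        ),
    )
    print(f"wrote {out}")
    for wl, x in zip(result.wavelength_nm, result.x_mm):
        print(f"  {wl:5.0f} nm  X = {x:.3f} mm")


if __name__ == "__main__":
    main()
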
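"""Haemoglobin extinction spectra, LED-band integration and baseline tissue absorption.

Unit conventions (important — the biggest silent trap in haemoglobin spectroscopy):

* Extinction fixtures are stored **decadic**, in cm^-1 M^-1, as in the standard
  compilations of oxy-/deoxy-haemoglobin molar extinction.
* Every absorption coefficient handled elsewhere in this package is a
  **natural-log** mu_a in mm^-1, because the modified Beer-Lambert law is written
  with a natural exponent, ``I = I0 exp(-mu_a X + G)``.
* The ``ln(10)/10`` conversion (decadic->natural, cm->mm) is applied exactly once,
  in this module — see :func:`natural_extinction_mm` and :func:`baseline_mua`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LN10",
    "MM_PER_CM",
    "ExtinctionTable",
    "LedBand",
    "BloodAssumptions",
    "load_extinction",
    "natural_extinction_mm",
    "band_effective_extinction",
    "baseline_mua",
    "hbo_red_contribution",
]

LN10 = float(np.log(10.0))
MM_PER_CM = 10.0

_DEFAULT_FIXTURE = "hb_extinction_synthetic.csv"


@dataclass(frozen=True)
class ExtinctionTable:
    """Molar extinction spectra of HbO and HbR on a common wavelength grid.

    Attributes
    ----------
    wavelength_nm :
        Strictly increasing wavelength grid (nm), spanning at least 450-700 nm.
    xi_hbo, xi_hbr :
        Decadic molar extinction coefficients (cm^-1 M^-1), strictly positive.
    """

    wavelength_nm: np.ndarray
    xi_hbo: np.ndarray
    xi_hbr: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        hbo = np.asarray(self.xi_hbo, dtype=float)
        hbr = np.asarray(self.xi_hbr, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("wavelength grid must be a 1-d array with >= 2 points")
        if not (wl.shape == hbo.shape == hbr.shape):
            raise ValueError("wavelength, xi_hbo and xi_hbr must share a shape")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(hbo <= 0) or np.any(hbr <= 0):
            raise ValueError("extinction coefficients must be positive")
        if wl[0] > 450.0 or wl[-1] < 700.0:
            raise ValueError(
                f"extinction grid must cover 450-700 nm, got {wl[0]:g}-{wl[-1]:g} nm"
            )
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "xi_hbo", hbo)
        object.__setattr__(self, "xi_hbr", hbr)

    def _check_range(self, wavelength_nm: np.ndarray) -> None:
        wl = np.asarray(wavelength_nm, dtype=float)
        lo, hi = self.wavelength_nm[0], self.wavelength_nm[-1]
        if np.any(wl < lo) or np.any(wl > hi):
            raise ValueError(
                f"wavelength outside extinction grid [{lo:g}, {hi:g}] nm"
            )

    def xi(self, wavelength_nm, chromophore: str):
        """Decadic extinction (cm^-1 M^-1) by linear interpolation on the grid.

        Raises ``ValueError`` for wavelengths outside the tabulated range.
        """
        self._check_range(wavelength_nm)
        col = {"HbO": self.xi_hbo, "HbR": self.xi_hbr}
        try:
            values = col[chromophore]
        except KeyError:
            raise ValueError(f"unknown chromophore {chromophore!r}") from None
        out = np.interp(np.asarray(wavelength_nm, dtype=float), self.wavelength_nm, values)
        return float(out) if np.isscalar(wavelength_nm) else out

    def isosbestic_wavelength(self, near_nm: float = 530.0, window_nm: float = 25.0) -> float:
        """Grid wavelength minimising |xi_HbO - xi_HbR| within a window of `near_nm`."""
        sel = np.abs(self.wavelength_nm - near_nm) <= window_nm
        if not np.any(sel):
            raise ValueError("no grid points within the isosbestic search window")
        gap = np.abs(self.xi_hbo - self.xi_hbr)[sel]
        return float(self.wavelength_nm[sel][np.argmin(gap)])


@dataclass(frozen=True)
class LedBand:
    """Emission band of a filtered LED channel.

    Either a measured spectrum (``wavelength_nm``/``weight`` arrays, normalised to
    unit area internally) or a Gaussian approximation from ``centre_nm``/``fwhm_nm``.
    ``fwhm_nm = 0`` denotes a delta band (pointwise evaluation at the centre).
    """

    name: str
    centre_nm: float | None = None
    fwhm_nm: float | None = None
    wavelength_nm: np.ndarray | None = None
    weight: np.ndarray | None = None

    def __post_init__(self) -> None:
        has_spectrum = self.wavelength_nm is not None and self.weight is not None
        has_gaussian = self.centre_nm is not None
        if has_spectrum == has_gaussian:
            raise ValueError("provide either a measured spectrum or centre_nm (+fwhm_nm)")
        if has_spectrum:
            wl = np.asarray(self.wavelength_nm, dtype=float)
            w = np.asarray(self.weight, dtype=float)
            if np.any(w < 0):
                raise ValueError("band weights must be non-negative")
            if np.trapezoid(w, wl) <= 0:
                raise ValueError("band spectrum must have positive area")
            object.__setattr__(self, "wavelength_nm", wl)
            object.__setattr__(self, "weight", w)
        elif self.fwhm_nm is None:
            object.__setattr__(self, "fwhm_nm", 0.0)

    @property
    def is_delta(self) -> bool:
        return self.wavelength_nm is None and (self.fwhm_nm or 0.0) == 0.0

    @property
    def nominal_nm(self) -> float:
        """Centre wavelength used for labelling and pathlength lookup."""
        if self.centre_nm is not None:
            return float(self.centre_nm)
        wl, w = self.wavelength_nm, self.weight
        return float(np.trapezoid(wl * w, wl) / np.trapezoid(w, wl))

    def weights_on(self, grid_nm: np.ndarray) -> np.ndarray:
        """Band weights sampled on `grid_nm`, normalised to unit trapezoidal area."""
        grid = np.asarray(grid_nm, dtype=float)
        if self.wavelength_nm is not None:
            w = np.interp(grid, self.wavelength_nm, self.weight, left=0.0, right=0.0)
        else:
            sigma = self.fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
            w = np.exp(-0.5 * ((grid - self.centre_nm) / sigma) ** 2)
        area = np.trapezoid(w, grid)
        if area <= 0:
            raise ValueError(f"band {self.name!r} has no support on the extinction grid")
        return w / area


@dataclass(frozen=True)
class BloodAssumptions:
    """Baseline blood content of cortical tissue.

    Defaults are the standard brain-tissue assumptions used for pathlength
    modelling: 2 mM haemoglobin in whole blood, 3% blood volume fraction and
    75% mean oxygen saturation.
    """

    hb_blood_molar: float = 2.0e-3
    blood_volume_fraction: float = 0.03
    oxygen_saturation: float = 0.75

    def __post_init__(self) -> None:
        if self.hb_blood_molar < 0 or self.blood_volume_fraction < 0:
            raise ValueError("blood concentration and volume fraction must be >= 0")
        if not 0.0 <= self.oxygen_saturation <= 1.0:
            raise ValueError("oxygen saturation must lie in [0, 1]")


def load_extinction(source: str | Path = "default") -> ExtinctionTable:
    """Load a packaged (or user) haemoglobin extinction table.

    ``source="default"`` loads the packaged synthetic table emulating the
    standard HbO/HbR compilation. Any other value is treated as a path to a
    3-column CSV with header ``wavelength_nm,xi_hbo,xi_hbr``.
    """
    if source == "default":
        path = importlib.resources.files("wfom").joinpath("data").joinpath(_DEFAULT_FIXTURE)
    else:
        path = Path(source)
    try:
        with importlib.resources.as_file(path) if source == "default" else _open_ctx(path) as p:
            df = pd.read_csv(p, comment="#")
    except FileNotFoundError:
        raise FileNotFoundError(f"extinction fixture not found: {path}") from None
    required = {"wavelength_nm", "xi_hbo", "xi_hbr"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"extinction fixture {path} is missing columns "
            f"{sorted(required - set(df.columns))}"
        )
    return ExtinctionTable(
        wavelength_nm=df["wavelength_nm"].to_numpy(float),
        xi_hbo=df["xi_hbo"].to_numpy(float),
        xi_hbr=df["xi_hbr"].to_numpy(float),
    )


class _open_ctx:
    """Context manager passing a plain path through (mirror of as_file)."""

    def __init__(self, path: Path) -> None:
        self.path = path

    def __enter__(self) -> Path:
        if not self.path.exists():
            raise FileNotFoundError(self.path)
        return self.path

    def __exit__(self, *exc) -> None:
        return None


def natural_extinction_mm(xi_decadic_cm: float | np.ndarray) -> float | np.ndarray:
    """Convert decadic cm^-1 M^-1 extinction to natural-log mm^-1 M^-1."""
    return xi_decadic_cm * LN10 / MM_PER_CM


def band_effective_extinction(
    table: ExtinctionTable, band: LedBand, chromophore: str
) -> float:
    """Spectrum-weighted mean decadic extinction of a chromophore over an LED band.

    The band weights are normalised to unit area on the table grid and the
    weighted extinction is integrated by the trapezoidal rule, mirroring the
    practice of integrating haemoglobin extinction under the measured filtered
    LED spectrum.
    """
    if band.is_delta:
        return table.xi(band.centre_nm, chromophore)
    grid = table.wavelength_nm
    w = band.weights_on(grid)
    xi = {"HbO": table.xi_hbo, "HbR": table.xi_hbr}
    try:
        values = xi[chromophore]
    except KeyError:
        raise ValueError(f"unknown chromophore {chromophore!r}") from None
    return float(np.trapezoid(w * values, grid))


def _effective_xi(table: ExtinctionTable, wavelength_or_band, chromophore: str) -> float:
    if isinstance(wavelength_or_band, LedBand):
        return band_effective_extinction(table, wavelength_or_band, chromophore)
    return table.xi(float(wavelength_or_band), chromophore)


def baseline_mua(
    table: ExtinctionTable,
    blood: BloodAssumptions,
    wavelength_or_band,
) -> float:
    """Baseline tissue absorption coefficient mu_a (natural log, mm^-1).

    mu_a = ln(10) * C_Hb,blood * BVF * [S * xi_HbO + (1-S) * xi_HbR] / 10,
    with xi decadic in cm^-1 M^-1, C in M, and the /10 converting cm^-1 to mm^-1.
    """
    s = blood.oxygen_saturation
    xi_hbo = _effective_xi(table, wavelength_or_band, "HbO")
    xi_hbr = _effective_xi(table, wavelength_or_band, "HbR")
    xi_eff_cm = s * xi_hbo + (1.0 - s) * xi_hbr
    c_tissue = blood.hb_blood_molar * blood.blood_volume_fraction
    return natural_extinction_mm(xi_eff_cm) * c_tissue


def hbo_red_contribution(
    table: ExtinctionTable,
    wavelength_or_band,
    blood: BloodAssumptions | None = None,
) -> dict[str, float]:
    """Fractional HbO share of haemoglobin absorption at a (red) wavelength.

    Two readings of "contribution of HbO absorption" are returned, since they
    differ substantially in the red where HbR extinction dominates:

    * ``equal_concentration`` — xi_HbO / (xi_HbO + xi_HbR), the share if HbO and
      HbR were present at the same concentration;
    * ``saturation_weighted`` — S*xi_HbO / (S*xi_HbO + (1-S)*xi_HbR), the share
      at the baseline oxygen saturation (default 75%).
    """
    blood = blood or BloodAssumptions()
    s = blood.oxygen_saturation
    xi_hbo = _effective_xi(table, wavelength_or_band, "HbO")
    xi_hbr = _effective_xi(table, wavelength_or_band, "HbR")
    return {
        "equal_concentration": xi_hbo / (xi_hbo + xi_hbr),
        "saturation_weighted": s * xi_hbo / (s * xi_hbo + (1.0 - s) * xi_hbr),
    }
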
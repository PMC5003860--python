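"""Modified Beer-Lambert conversion of diffuse-reflectance movies to haemoglobin.

The attenuation model is ``I(r,t,lambda) = I0 * G * exp(-mu_a(r,t,lambda) * X(lambda))``
with X the mean differential pathlength of detected photons. Dividing by a
baseline epoch cancels the unknown illumination distribution and geometric
factor, so ``delta mu_a = -ln(I(t)/I(t0)) / X`` per pixel, and the per-pixel
linear system ``delta mu_a(lambda) = xi_HbO(lambda) dHbO + xi_HbR(lambda) dHbR``
(extinctions in natural-log mm^-1 M^-1 units) is inverted for the concentration
changes.

Invalid pixels (baseline at or below the dark level, non-positive ratios)
propagate as explicit boolean masks rather than NaNs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from wfom.spectra import ExtinctionTable, LedBand, band_effective_extinction, natural_extinction_mm

__all__ = [
    "ImageStack",
    "PathlengthTable",
    "HemoMovie",
    "RatioMovie",
    "extinction_matrix",
    "reflectance_ratio",
    "delta_mua",
    "solve_two_wavelengths",
    "solve_multiwavelength",
    "isosbestic_hbt",
    "pairwise_consistency",
    "PairwiseConsistencyReport",
]

CONDITION_LIMIT = 1e8  # beyond this the inversion only amplifies noise


@dataclass
class ImageStack:
    """A single-channel intensity movie with acquisition metadata.

    ``data`` is (time, height, width) camera counts; ``dark`` is the per-pixel
    dark image D(r) (or a scalar dark level) measured with illumination off.
    """

    data: np.ndarray
    channel: str = ""
    timestamps: np.ndarray | None = None
    dark: np.ndarray | float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("ImageStack.data must be (time, height, width)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ImageStack.data contains non-finite values")
        if self.timestamps is None:
            self.timestamps = np.arange(self.data.shape[0], dtype=float)
        else:
            self.timestamps = np.asarray(self.timestamps, dtype=float)
            if self.timestamps.shape != (self.data.shape[0],):
                raise ValueError("timestamps length must match the frame count")
        if self.dark is not None and np.any(np.asarray(self.dark) < 0):
            raise ValueError("dark level must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]


@dataclass(frozen=True)
class PathlengthTable:
    """Wavelength-dependent mean differential pathlength X (mm)."""

    wavelength_nm: np.ndarray
    x_mm: np.ndarray

    def __post_init__(self) -> None:
        wl = np.atleast_1d(np.asarray(self.wavelength_nm, dtype=float))
        x = np.atleast_1d(np.asarray(self.x_mm, dtype=float))
        if wl.shape != x.shape or wl.ndim != 1:
            raise ValueError("wavelength and pathlength arrays must be 1-d and matching")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(x <= 0):
            raise ValueError("pathlengths must be positive")
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "x_mm", x)

    def x(self, wavelength_nm: float) -> float:
        """Pathlength (mm) at `wavelength_nm`, linear interpolation, no extrapolation."""
        wl = float(wavelength_nm)
        if wl < self.wavelength_nm[0] or wl > self.wavelength_nm[-1]:
            raise ValueError(
                f"{wl:g} nm outside pathlength table range "
                f"[{self.wavelength_nm[0]:g}, {self.wavelength_nm[-1]:g}]"
            )
        return float(np.interp(wl, self.wavelength_nm, self.x_mm))

    @classmethod
    def from_csv(cls, path: str | Path) -> "PathlengthTable":
        df = pd.read_csv(path, comment="#")
        return cls(df["wavelength_nm"].to_numpy(float), df["x_mm"].to_numpy(float))

    def to_csv(self, path: str | Path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            fh.write("wavelength_nm,x_mm\n")
            for wl, x in zip(self.wavelength_nm, self.x_mm):
                fh.write(f"{wl:g},{x:.6g}\n")


@dataclass
class RatioMovie:
    """Intensity ratio I(t)/I(t0) with a validity mask; drr = ratio - 1."""

    ratio: np.ndarray
    valid: np.ndarray
    baseline_window: tuple[int, int]
    channel: str = ""

    @property
    def drr(self) -> np.ndarray:
        """Fractional reflectance change dR/R = I(t)/I(t0) - 1."""
        return self.ratio - 1.0


@dataclass
class HemoMovie:
    """Differential haemoglobin concentration movies (molar).

    ``d_hbt`` is always the elementwise sum of ``d_hbo`` and ``d_hbr``.
    """

    d_hbo: np.ndarray
    d_hbr: np.ndarray
    valid: np.ndarray
    baseline_window: tuple[int, int]
    d_hbt: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.d_hbo = np.asarray(self.d_hbo, dtype=float)
        self.d_hbr = np.asarray(self.d_hbr, dtype=float)
        if self.d_hbo.shape != self.d_hbr.shape:
            raise ValueError("d_hbo and d_hbr shapes must match")
        self.d_hbt = self.d_hbo + self.d_hbr


def _resolve_window(window, n_frames: int) -> tuple[int, int]:
    lo, hi = window
    lo = int(lo)
    hi = int(hi)
    if not (0 <= lo < hi <= n_frames):
        raise ValueError(f"baseline window {window} invalid for {n_frames} frames")
    return lo, hi


def reflectance_ratio(stack: ImageStack, baseline_window: tuple[int, int]) -> RatioMovie:
    """Dark-subtracted intensity ratio relative to a baseline epoch.

    ratio = (I - D)(t) / mean_{t in baseline}(I - D). Pixels whose baseline mean
    does not exceed the dark level are masked invalid (never NaN-propagated).
    A missing dark image is treated as zero.
    """
    lo, hi = _resolve_window(baseline_window, stack.n_frames)
    dark = 0.0 if stack.dark is None else stack.dark
    signal = stack.data - dark
    baseline = signal[lo:hi].mean(axis=0)
    valid = baseline > 0
    safe = np.where(valid, baseline, 1.0)
    ratio = signal / safe
    valid3 = np.broadcast_to(valid, ratio.shape) & (ratio > 0)
    ratio = np.where(valid3, ratio, 1.0)
    return RatioMovie(ratio=ratio, valid=valid3, baseline_window=(lo, hi), channel=stack.channel)


def delta_mua(ratio: RatioMovie, x_mm: float) -> tuple[np.ndarray, np.ndarray]:
    """Absorption change movie: delta mu_a = -ln(I(t)/I(t0)) / X, in mm^-1.

    Returns (dmua, valid); non-positive ratios are masked.
    """
    if x_mm <= 0:
        raise ValueError("pathlength must be positive")
    valid = ratio.valid & (ratio.ratio > 0)
    dmua = np.where(valid, -np.log(np.where(valid, ratio.ratio, 1.0)) / x_mm, 0.0)
    return dmua, valid


def extinction_matrix(
    table: ExtinctionTable, bands: list[LedBand | float]
) -> np.ndarray:
    """(n_bands, 2) matrix of [xi_HbO, xi_HbR] in natural-log mm^-1 M^-1.

    Rows follow the band order; bands may be `LedBand` objects or bare
    wavelengths in nm.
    """
    rows = []
    for band in bands:
        if isinstance(band, LedBand):
            hbo = band_effective_extinction(table, band, "HbO")
            hbr = band_effective_extinction(table, band, "HbR")
        else:
            hbo = table.xi(float(band), "HbO")
            hbr = table.xi(float(band), "HbR")
        rows.append([natural_extinction_mm(hbo), natural_extinction_mm(hbr)])
    return np.asarray(rows, dtype=float)


def _check_conditioning(xi: np.ndarray, label: str) -> None:
    cond = np.linalg.cond(xi)
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        raise np.linalg.LinAlgError(
            f"extinction matrix for {label} is singular or ill-conditioned "
            f"(condition number {cond:.3g} > {CONDITION_LIMIT:g})"
        )


def solve_two_wavelengths(
    dmua_a: np.ndarray,
    dmua_b: np.ndarray,
    xi: np.ndarray,
    valid: np.ndarray | None = None,
    baseline_window: tuple[int, int] = (0, 1),
    label: str = "wavelength pair",
) -> HemoMovie:
    """Per-pixel 2x2 inversion of the two-wavelength absorption system.

    ``xi`` is the 2x2 matrix [[xi_HbO(A), xi_HbR(A)], [xi_HbO(B), xi_HbR(B)]]
    in natural-log mm^-1 M^-1; ``dmua_*`` are mm^-1 movies.
    """
    xi = np.asarray(xi, dtype=float)
    if xi.shape != (2, 2):
        raise ValueError("xi must be a 2x2 matrix")
    _check_conditioning(xi, label)
    dmua_a = np.asarray(dmua_a, dtype=float)
    dmua_b = np.asarray(dmua_b, dtype=float)
    if dmua_a.shape != dmua_b.shape:
        raise ValueError("delta mu_a movies must share a shape")
    inv = np.linalg.inv(xi)
    d_hbo = inv[0, 0] * dmua_a + inv[0, 1] * dmua_b
    d_hbr = inv[1, 0] * dmua_a + inv[1, 1] * dmua_b
    if valid is None:
        valid = np.ones(dmua_a.shape, dtype=bool)
    return HemoMovie(d_hbo=d_hbo, d_hbr=d_hbr, valid=valid, baseline_window=baseline_window)


def solve_multiwavelength(
    dmuas: list[np.ndarray],
    xi: np.ndarray,
    valid: np.ndarray | None = None,
    baseline_window: tuple[int, int] = (0, 1),
) -> tuple[HemoMovie, np.ndarray]:
    """Per-pixel linear least squares over >=2 wavelengths.

    Solves ``xi @ [dHbO, dHbR] = dmua`` for every pixel/time via the
    pseudo-inverse (the design matrix is shared by all pixels) and returns the
    HemoMovie plus the per-pixel residual 2-norm movie.
    """
    xi = np.asarray(xi, dtype=float)
    if xi.ndim != 2 or xi.shape[1] != 2 or xi.shape[0] < 2:
        raise ValueError("xi must be (n_wavelengths >= 2, 2)")
    if len(dmuas) != xi.shape[0]:
        raise ValueError("number of delta mu_a movies must match xi rows")
    if np.linalg.matrix_rank(xi) < 2:
        raise np.linalg.LinAlgError("extinction matrix is rank deficient")
    _check_conditioning(xi, "multiwavelength set")
    stack = np.stack([np.asarray(d, dtype=float) for d in dmuas], axis=0)
    pinv = np.linalg.pinv(xi)
    coeffs = np.tensordot(pinv, stack, axes=(1, 0))  # (2, t, h, w)
    fitted = np.tensordot(xi, coeffs, axes=(1, 0))
    residual = np.sqrt(np.sum((stack - fitted) ** 2, axis=0))
    if valid is None:
        valid = np.ones(stack.shape[1:], dtype=bool)
    hemo = HemoMovie(
        d_hbo=coeffs[0], d_hbr=coeffs[1], valid=valid, baseline_window=baseline_window
    )
    return hemo, residual


ISOSBESTIC_TOLERANCE = 0.05


def isosbestic_hbt(
    ratio: RatioMovie,
    x_iso_mm: float,
    xi_iso_natural_mm: float,
    xi_hbo_natural_mm: float | None = None,
    xi_hbr_natural_mm: float | None = None,
    warn: callable = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Total-haemoglobin change from a single isosbestic channel.

    At an isosbestic wavelength xi_HbO = xi_HbR = xi_iso, so
    ``dHbT = -ln(I(t)/I(t0)) / (X * xi_iso)`` irrespective of the HbO/HbR
    split. Returns (d_hbt, attenuation) where ``attenuation = -ln(ratio)`` is
    the pathlength- and spectrum-free quantity suitable for cross-lab
    comparison.

    If both per-chromophore extinctions are supplied and differ by more than
    5%, a warning is emitted (the channel is then not truly isosbestic).
    """
    import warnings

    if x_iso_mm <= 0 or xi_iso_natural_mm <= 0:
        raise ValueError("pathlength and extinction must be positive")
    if xi_hbo_natural_mm is not None and xi_hbr_natural_mm is not None:
        gap = abs(xi_hbo_natural_mm - xi_hbr_natural_mm) / max(
            xi_hbo_natural_mm, xi_hbr_natural_mm
        )
        if gap > ISOSBESTIC_TOLERANCE:
            warnings.warn(
                f"channel is not isosbestic: HbO/HbR extinctions differ by "
                f"{100 * gap:.1f}% (> {100 * ISOSBESTIC_TOLERANCE:.0f}%)",
                stacklevel=2,
            )
    attenuation = np.where(ratio.valid, -np.log(np.where(ratio.valid, ratio.ratio, 1.0)), 0.0)
    d_hbt = attenuation / (x_iso_mm * xi_iso_natural_mm)
    return d_hbt, attenuation


@dataclass
class PairwiseConsistencyReport:
    """Three pairwise two-wavelength conversions and their mutual agreement."""

    pair_labels: list[tuple[str, str]]
    hemo_by_pair: dict[tuple[str, str], HemoMovie]
    max_discrepancy: float
    discrepancy_by_pair: dict[str, float]
    tolerance: float
    passed: bool


def _rel_rms(a: np.ndarray, b: np.ndarray) -> float:
    scale = np.sqrt(np.mean(a**2) + np.mean(b**2)) / np.sqrt(2.0)
    if scale == 0:
        return 0.0
    return float(np.sqrt(np.mean((a - b) ** 2)) / scale)


def pairwise_consistency(
    dmuas: dict[str, np.ndarray],
    xi_by_channel: dict[str, np.ndarray],
    tolerance: float = 0.05,
    baseline_window: tuple[int, int] = (0, 1),
) -> PairwiseConsistencyReport:
    """Three-wavelength conversion consistency check.

    Converts each of the three channel pairs (A&B, B&C, A&C) to dHbO/dHbR with
    the two-wavelength solver. If the three conversions agree (max relative RMS
    difference across pairs below `tolerance`), the conversion assumptions —
    common pathlength model, shared chromophore mixture across wavelengths —
    are taken to hold.
    """
    names = list(dmuas)
    if len(names) != 3:
        raise ValueError(f"pairwise consistency requires exactly 3 channels, got {len(names)}")
    if len({tuple(np.ravel(xi_by_channel[n])) for n in names}) < 3:
        raise ValueError("channels must have distinct extinction rows (duplicate wavelengths?)")
    pairs = [(names[0], names[1]), (names[1], names[2]), (names[0], names[2])]
    hemo_by_pair: dict[tuple[str, str], HemoMovie] = {}
    for a, b in pairs:
        xi = np.vstack([xi_by_channel[a], xi_by_channel[b]])
        hemo_by_pair[(a, b)] = solve_two_wavelengths(
            dmuas[a], dmuas[b], xi, baseline_window=baseline_window, label=f"{a}&{b}"
        )
    disc: dict[str, float] = {}
    for i in range(len(pairs)):
        for j in range(i + 1, len(pairs)):
            hi, hj = hemo_by_pair[pairs[i]], hemo_by_pair[pairs[j]]
            key = f"{pairs[i][0]}&{pairs[i][1]} vs {pairs[j][0]}&{pairs[j][1]}"
            disc[key] = max(_rel_rms(hi.d_hbo, hj.d_hbo), _rel_rms(hi.d_hbr, hj.d_hbr))
    max_disc = max(disc.values())
    return PairwiseConsistencyReport(
        pair_labels=pairs,
        hemo_by_pair=hemo_by_pair,
        max_discrepancy=max_disc,
        discrepancy_by_pair=disc,
        tolerance=tolerance,
        passed=max_disc <= tolerance,
    )
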
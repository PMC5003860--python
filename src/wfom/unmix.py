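"""Spatio-temporal unmixing of haemodynamic movies into vascular compartments.

Each vascular compartment (artery, arteriole, capillary, venule, vein) carries
a characteristic haemodynamic time course. Seed regions picked on identified
vessels provide per-compartment basis signatures — the ROI-mean dHbO, dHbR and
dHbT traces concatenated in time — and every pixel's concatenated trace is
then decomposed as a non-negative linear sum of those signatures:

    min_P || dc_HbAll(r, .) - sum_comp P_comp(r) * B_comp(.) ||^2,  P >= 0

yielding one non-negative coefficient map per compartment plus a residual map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from wfom.mbll import HemoMovie

__all__ = [
    "CompartmentBasis",
    "CompartmentMaps",
    "build_basis",
    "unmix_nnls",
    "render_merge",
    "DEFAULT_PALETTE",
]

# Block order of the concatenated haemoglobin trace. HbT is linearly dependent
# on the other two but kept by default so coefficients read directly as the
# "concentration" of each full vascular signature; drop_hbt=True removes it.
BLOCK_ORDER = ("hbo", "hbr", "hbt")


@dataclass
class CompartmentBasis:
    """Per-compartment concatenated [HbO | HbR | HbT] time-course signatures."""

    names: list[str]
    basis: np.ndarray            # (n_compartments, n_blocks * n_t)
    seed_rois: dict[str, np.ndarray]
    blocks: tuple[str, ...] = BLOCK_ORDER

    @property
    def n_frames(self) -> int:
        return self.basis.shape[1] // len(self.blocks)

    def normalized(self) -> "CompartmentBasis":
        """Unit-norm rows (coefficients then read as projection amplitudes)."""
        norms = np.linalg.norm(self.basis, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return CompartmentBasis(
            names=list(self.names), basis=self.basis / norms,
            seed_rois=dict(self.seed_rois), blocks=self.blocks,
        )


@dataclass
class CompartmentMaps:
    """Non-negative coefficient map per compartment and per-pixel residual."""

    names: list[str]
    maps: np.ndarray        # (n_compartments, h, w), >= 0
    residual: np.ndarray    # (h, w), fit residual 2-norm

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[self.names.index(name)]


def _roi_mask(roi, shape: tuple[int, int], name: str) -> np.ndarray:
    roi = np.asarray(roi)
    if roi.dtype == bool:
        if roi.shape != shape:
            raise ValueError(f"ROI {name!r} mask shape {roi.shape} != image {shape}")
        mask = roi
    else:
        # (n, 2) array of (row, col) pixel indices, 0-based
        if roi.ndim != 2 or roi.shape[1] != 2:
            raise ValueError(f"ROI {name!r} must be a boolean mask or (n, 2) pixel list")
        mask = np.zeros(shape, dtype=bool)
        rows, cols = roi[:, 0], roi[:, 1]
        if np.any(rows < 0) or np.any(rows >= shape[0]) or np.any(cols < 0) or np.any(cols >= shape[1]):
            raise ValueError(f"ROI {name!r} has pixels outside image bounds {shape}")
        mask[rows, cols] = True
    if not mask.any():
        raise ValueError(f"ROI {name!r} is empty")
    return mask


def _concat_blocks(hemo: HemoMovie, drop_hbt: bool) -> tuple[np.ndarray, tuple[str, ...]]:
    blocks = BLOCK_ORDER[:2] if drop_hbt else BLOCK_ORDER
    data = {"hbo": hemo.d_hbo, "hbr": hemo.d_hbr, "hbt": hemo.d_hbt}
    return np.concatenate([data[b] for b in blocks], axis=0), blocks


def build_basis(
    hemo: HemoMovie, seed_rois: dict[str, np.ndarray], drop_hbt: bool = False
) -> CompartmentBasis:
    """Extract compartment signatures from seed regions of a haemoglobin movie.

    Each ROI (boolean mask or (n, 2) 0-based pixel list) is averaged per frame
    and the dHbO/dHbR/dHbT means are concatenated into one basis row.
    """
    shape = hemo.d_hbo.shape[1:]
    concat, blocks = _concat_blocks(hemo, drop_hbt)
    names, rows, masks = [], [], {}
    for name, roi in seed_rois.items():
        mask = _roi_mask(roi, shape, name)
        rows.append(concat[:, mask].mean(axis=1))
        names.append(name)
        masks[name] = mask
    basis = np.vstack(rows)
    if len(names) > 1:
        rank = np.linalg.matrix_rank(basis)
        if rank < len(names):
            warnings.warn(
                f"basis rows are collinear (rank {rank} < {len(names)}); "
                "coefficient maps will not be unique", stacklevel=2,
            )
    return CompartmentBasis(names=names, basis=basis, seed_rois=masks, blocks=blocks)


def unmix_nnls(
    hemo: HemoMovie, basis: CompartmentBasis, drop_hbt: bool | None = None
) -> CompartmentMaps:
    """Per-pixel non-negative least-squares fit of the compartment basis."""
    if drop_hbt is None:
        drop_hbt = len(basis.blocks) == 2
    concat, blocks = _concat_blocks(hemo, drop_hbt)
    if blocks != basis.blocks:
        raise ValueError(f"block mismatch: movie {blocks} vs basis {basis.blocks}")
    if concat.shape[0] != basis.basis.shape[1]:
        raise ValueError(
            f"time-length mismatch: movie gives {concat.shape[0]} concatenated "
            f"samples, basis has {basis.basis.shape[1]}"
        )
    h, w = concat.shape[1:]
    n_comp = basis.basis.shape[0]
    # solve with unit-norm columns for conditioning (traces are ~1e-6 molar),
    # then rescale: dividing a basis row by its norm multiplies its coefficient
    # by the same factor, so results are mathematically unchanged
    norms = np.linalg.norm(basis.basis, axis=1)
    norms[norms == 0] = 1.0
    a = (basis.basis / norms[:, None]).T  # (n_samples, n_compartments)
    maps = np.zeros((n_comp, h * w))
    residual = np.zeros(h * w)
    flat = concat.reshape(concat.shape[0], -1)
    for p in range(h * w):
        coef, res = nnls(a, flat[:, p], maxiter=50 * n_comp)
        maps[:, p] = coef / norms
        residual[p] = res
    return CompartmentMaps(
        names=list(basis.names),
        maps=maps.reshape(n_comp, h, w),
        residual=residual.reshape(h, w),
    )


DEFAULT_PALETTE = {
    "artery": (1.0, 0.1, 0.1),
    "arteriole": (1.0, 0.6, 0.1),
    "capillary": (0.1, 0.9, 0.1),
    "venule": (0.2, 0.5, 1.0),
    "vein": (0.2, 0.1, 1.0),
}
_FALLBACK_COLOURS = [
    (1.0, 0.1, 0.1), (0.1, 0.9, 0.1), (0.2, 0.1, 1.0),
    (1.0, 0.8, 0.1), (0.8, 0.1, 0.9), (0.1, 0.9, 0.9),
]


def render_merge(
    maps: CompartmentMaps, palette: dict[str, tuple] | None = None
) -> np.ndarray:
    """Colour composite of compartment coefficient maps.

    Each map is normalised by the global coefficient maximum (one shared,
    deterministic scale so relative amplitudes survive) and blended additively
    in its palette colour; output is an (h, w, 3) float image clipped to [0, 1].
    """
    palette = palette or DEFAULT_PALETTE
    colours = []
    fallback = iter(_FALLBACK_COLOURS)
    for name in maps.names:
        colours.append(palette.get(name) or next(fallback))
    if len(maps.names) > len(_FALLBACK_COLOURS):
        raise ValueError("more compartments than available palette colours")
    scale = maps.maps.max()
    if scale <= 0:
        scale = 1.0
    rgb = np.zeros(maps.maps.shape[1:] + (3,))
    for comp, colour in zip(maps.maps, colours):
        rgb += (comp / scale)[:, :, None] * np.asarray(colour)[None, None, :]
    return np.clip(rgb, 0.0, 1.0)
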
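"""Ratiometric fluorescence processing and haemodynamic cross-talk correction.

Detected wide-field fluorescence is attenuated by time-varying haemoglobin
absorption along both the excitation and the emission light paths, so the
dark-subtracted fluorescence ratio factorises as

    F(t)/F(t0) = [c_f(t)/c_f(t0)] * exp(-[dmu_a(ex) X(ex) + dmu_a(em) X(em)])

— the haemodynamic term is *multiplicative* in the ratio, which is why a
brighter fluorophore cannot out-shine the cross-talk. Three corrections are
provided:

1. single-wavelength: divide by a co-acquired reflectance ratio near the
   emission band (assumes equal ex/em absorption changes and that the
   diffuse-reflectance pathlength approximates the ex+em leg sum);
2. Ex-Em: reconstruct dmu_a at the excitation and emission bands from the
   spectroscopically converted haemoglobin movies and undo the exponential
   with estimated leg pathlengths;
3. PCA in log space: blind-source removal of the haemodynamic component from
   ln(F/F0), where the multiplicative contamination becomes an additive
   rank-1 term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import butter, filtfilt

from wfom.mbll import HemoMovie, ImageStack, _resolve_window

__all__ = [
    "FluorRatioMovie",
    "CrosstalkModel",
    "dark_subtract_ratio",
    "correct_single_wavelength",
    "correct_ex_em",
    "correct_pca_log",
    "PcaCorrectionResult",
    "fit_gamma_kernel",
    "GammaFitResult",
    "lowpass_filter",
]


@dataclass
class FluorRatioMovie:
    """Dark-subtracted fluorescence ratio F(t)/F(t0) with validity mask."""

    ratio: np.ndarray
    valid: np.ndarray
    baseline_window: tuple[int, int]
    channel: str = ""

    @property
    def dff(self) -> np.ndarray:
        """Fractional fluorescence change dF/F = ratio - 1."""
        return self.ratio - 1.0


@dataclass
class CrosstalkModel:
    """Ex-Em correction parameters.

    ``x_est_ex_mm`` / ``x_est_em_mm`` are the estimated excitation- and
    emission-leg pathlengths (mm). The defaults (0.56, 0.57 mm) are the values
    found to minimise vessel artefacts in Thy1-GCaMP mouse preparations — they
    are preparation-specific configuration, not constants of the method.
    ``xi_ex`` / ``xi_em`` are (xi_HbO, xi_HbR) natural-log extinction pairs
    (mm^-1 M^-1) at the excitation and emission bands.
    """

    xi_ex: tuple[float, float]
    xi_em: tuple[float, float]
    x_est_ex_mm: float = 0.56
    x_est_em_mm: float = 0.57

    def __post_init__(self) -> None:
        if self.x_est_ex_mm <= 0 or self.x_est_em_mm <= 0:
            raise ValueError("estimated pathlengths must be positive")


def dark_subtract_ratio(
    stack: ImageStack, baseline_window: tuple[int, int]
) -> FluorRatioMovie:
    """Fluorescence ratio after dark subtraction.

    Subtracting the dark signal D(r) before taking the ratio is what lets the
    static gain field S(r) cancel; an ImageStack without a dark image is
    refused — pass an explicit 0 if the camera truly has none.
    """
    if stack.dark is None:
        raise ValueError(
            "dark image/level required for ratiometric fluorescence; "
            "pass dark=0 explicitly if none was acquired"
        )
    lo, hi = _resolve_window(baseline_window, stack.n_frames)
    signal = stack.data - stack.dark
    baseline = signal[lo:hi].mean(axis=0)
    valid = baseline > 0
    safe = np.where(valid, baseline, 1.0)
    ratio = signal / safe
    valid3 = np.broadcast_to(valid, ratio.shape) & (ratio > 0)
    ratio = np.where(valid3, ratio, 1.0)
    return FluorRatioMovie(ratio=ratio, valid=valid3, baseline_window=(lo, hi), channel=stack.channel)


def correct_single_wavelength(fluor: FluorRatioMovie, refl_ratio) -> FluorRatioMovie:
    """Single-wavelength correction: divide fluorescence ratio by reflectance ratio.

    `refl_ratio` is a co-registered, frame-aligned reflectance RatioMovie at a
    band near the fluorophore's emission (e.g. green 530 nm for GCaMP).
    """
    if refl_ratio.ratio.shape != fluor.ratio.shape:
        raise ValueError(
            f"fluorescence {fluor.ratio.shape} and reflectance "
            f"{refl_ratio.ratio.shape} movies are not frame-aligned"
        )
    valid = fluor.valid & refl_ratio.valid & (refl_ratio.ratio > 0)
    corrected = np.where(valid, fluor.ratio / np.where(valid, refl_ratio.ratio, 1.0), 1.0)
    return FluorRatioMovie(
        ratio=corrected, valid=valid, baseline_window=fluor.baseline_window, channel=fluor.channel
    )


def correct_ex_em(
    fluor: FluorRatioMovie, hemo: HemoMovie, model: CrosstalkModel
) -> FluorRatioMovie:
    """Ex-Em correction from spectroscopically converted haemoglobin movies.

    dmu_a at the excitation and emission bands is reconstructed per pixel from
    (dHbO, dHbR) through the extinction pairs of `model`, and the multiplicative
    attenuation is inverted:

        corrected = ratio * exp(dmu_a_ex * X_ex + dmu_a_em * X_em)
    """
    if hemo.d_hbo.shape != fluor.ratio.shape:
        raise ValueError(
            f"haemoglobin movie {hemo.d_hbo.shape} does not match "
            f"fluorescence movie {fluor.ratio.shape}"
        )
    dmua_ex = model.xi_ex[0] * hemo.d_hbo + model.xi_ex[1] * hemo.d_hbr
    dmua_em = model.xi_em[0] * hemo.d_hbo + model.xi_em[1] * hemo.d_hbr
    multiplier = np.exp(dmua_ex * model.x_est_ex_mm + dmua_em * model.x_est_em_mm)
    valid = fluor.valid & hemo.valid
    corrected = np.where(valid, fluor.ratio * multiplier, 1.0)
    return FluorRatioMovie(
        ratio=corrected, valid=valid, baseline_window=fluor.baseline_window, channel=fluor.channel
    )


@dataclass
class PcaCorrectionResult:
    corrected: FluorRatioMovie
    removed_time_course: np.ndarray       # (t,)
    removed_spatial_map: np.ndarray       # (h, w)
    component_index: int
    correlations: np.ndarray              # |corr| of each component with reference
    explained_variance_ratio: np.ndarray


def _reference_trace(reference, n_frames: int) -> np.ndarray:
    if isinstance(reference, HemoMovie):
        trace = reference.d_hbt.reshape(n_frames, -1).mean(axis=1)
    elif hasattr(reference, "ratio"):
        trace = reference.ratio.reshape(n_frames, -1).mean(axis=1)
    else:
        trace = np.asarray(reference, dtype=float)
    if trace.shape != (n_frames,):
        raise ValueError("reference must reduce to a length-n_frames time course")
    return trace


def correct_pca_log(
    fluor: FluorRatioMovie,
    reference=None,
    component_index: int | None = None,
    n_components: int = 5,
    correlation_threshold: float = 0.6,
) -> PcaCorrectionResult:
    """PCA removal of the haemodynamic component from log-fluorescence.

    The decomposition runs on ln(ratio), centred per pixel over time, where the
    multiplicative contamination is an additively separable component. The
    haemodynamic component is chosen by maximum |temporal correlation| with
    `reference` (a HemoMovie, reflectance RatioMovie or bare time course);
    without a reference the caller must name `component_index` explicitly —
    component order is not stable across runs/datasets, so it is never guessed.
    Components whose correlation stays below `correlation_threshold` are left
    untouched (no contamination found).
    """
    from sklearn.decomposition import PCA

    n_t = fluor.ratio.shape[0]
    n_components = min(n_components, n_t - 1, fluor.ratio[0].size)
    if n_components < 1:
        raise ValueError("movie too short for PCA correction")
    log_ratio = np.log(np.where(fluor.valid, fluor.ratio, 1.0))
    flat = log_ratio.reshape(n_t, -1)
    pixel_mean = flat.mean(axis=0, keepdims=True)  # per-pixel temporal centring
    centred = flat - pixel_mean

    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(centred)            # (t, k) temporal components
    loadings = pca.components_                     # (k, n_pixels) spatial maps

    correlations = np.zeros(n_components)
    if reference is not None:
        ref = _reference_trace(reference, n_t)
        if np.std(ref) > 0:
            for k in range(n_components):
                sk = scores[:, k]
                if np.std(sk) > 0:
                    correlations[k] = abs(np.corrcoef(ref, sk)[0, 1])
        idx = int(np.argmax(correlations))
        if correlations[idx] < correlation_threshold:
            idx = -1  # nothing resembles the reference: leave data untouched
    elif component_index is not None:
        idx = int(component_index)
        if not 0 <= idx < n_components:
            raise ValueError(f"component_index {idx} outside 0..{n_components - 1}")
    else:
        evr = ", ".join(
            f"#{k}: {v:.1%}" for k, v in enumerate(pca.explained_variance_ratio_)
        )
        raise ValueError(
            "PCA component selection needs a reference signal or an explicit "
            f"component_index; candidate components by explained variance: {evr}"
        )

    if idx >= 0:
        rank1 = np.outer(scores[:, idx], loadings[idx])
        corrected_log = (centred - rank1) + pixel_mean
        removed_tc = scores[:, idx]
        removed_map = loadings[idx].reshape(fluor.ratio.shape[1:])
    else:
        corrected_log = flat
        removed_tc = np.zeros(n_t)
        removed_map = np.zeros(fluor.ratio.shape[1:])

    corrected = np.exp(corrected_log).reshape(fluor.ratio.shape)
    # centring captures only the zero-mean part of the contamination; its
    # temporal mean survives as a static per-pixel offset, removed by
    # re-referencing the ratio to its own baseline window
    lo, hi = fluor.baseline_window
    base = corrected[lo:hi].mean(axis=0, keepdims=True)
    corrected = corrected / np.where(base > 0, base, 1.0)
    corrected = np.where(fluor.valid, corrected, 1.0)
    return PcaCorrectionResult(
        corrected=FluorRatioMovie(
            ratio=corrected,
            valid=fluor.valid,
            baseline_window=fluor.baseline_window,
            channel=fluor.channel,
        ),
        removed_time_course=removed_tc,
        removed_spatial_map=removed_map,
        component_index=idx,
        correlations=correlations,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


@dataclass
class GammaFitResult:
    shape: float
    scale_s: float
    amplitude: float
    residual_rms: float
    prediction: np.ndarray
    identifiable: bool


def fit_gamma_kernel(
    spike_rate: np.ndarray,
    dff: np.ndarray,
    fs_hz: float,
    initial: tuple[float, float, float] = (2.0, 0.3, 1.0),
) -> GammaFitResult:
    """Fit dff(t) ~= amplitude * (spike_rate (x) gamma_pdf(shape, scale)).

    Models corrected fluorescence as multi-unit activity convolved with a
    gamma kernel capturing the combined calcium/indicator kinetics. Both
    series must share the sampling rate `fs_hz`.
    """
    from scipy.stats import gamma as gamma_dist

    spike_rate = np.asarray(spike_rate, dtype=float)
    dff = np.asarray(dff, dtype=float)
    if spike_rate.shape != dff.shape or spike_rate.ndim != 1:
        raise ValueError("spike rate and dF/F must be 1-d series of equal length")
    if not np.any(spike_rate != 0):
        return GammaFitResult(
            shape=np.nan, scale_s=np.nan, amplitude=0.0,
            residual_rms=float(np.sqrt(np.mean(dff**2))),
            prediction=np.zeros_like(dff), identifiable=False,
        )

    dt = 1.0 / fs_hz
    kern_t = np.arange(0.0, min(10.0, spike_rate.size * dt), dt)

    def predict(params):
        shape, scale, amp = params
        k = gamma_dist.pdf(kern_t, a=shape, scale=scale) * dt
        return amp * np.convolve(spike_rate, k)[: spike_rate.size]

    def resid(params):
        return predict(params) - dff

    result = least_squares(
        resid, x0=np.asarray(initial, dtype=float),
        bounds=([0.2, 1e-3, -np.inf], [50.0, 10.0, np.inf]),
    )
    if not result.success:
        raise RuntimeError(f"gamma-kernel fit did not converge: {result.message}")
    shape, scale, amp = result.x
    pred = predict(result.x)
    return GammaFitResult(
        shape=float(shape), scale_s=float(scale), amplitude=float(amp),
        residual_rms=float(np.sqrt(np.mean((pred - dff) ** 2))),
        prediction=pred, identifiable=True,
    )


def lowpass_filter(movie: np.ndarray, fs_hz: float, cutoff_hz: float = 5.0, order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth low-pass along the time axis (default 5 Hz).

    Standard pre-processing before regression/PCA correction to suppress
    heart-rate and breathing bands.
    """
    nyq = fs_hz / 2.0
    if cutoff_hz >= nyq:
        return movie
    b, a = butter(order, cutoff_hz / nyq)
    return filtfilt(b, a, movie, axis=0)
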
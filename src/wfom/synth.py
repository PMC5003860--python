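"""Synthetic WFOM phantom: forward model with full ground truth.

The phantom emulates the structure of a cortical field of view — sharp surface
vessels (artery/vein, optionally arteriole/venule) over a blurred capillary
"parenchyma" background — with compartment-specific haemodynamic time courses
and a fast stimulus-locked fluorophore (calcium-indicator-like) activity
signal. The forward models are exactly the attenuation models the inverse
operations in :mod:`wfom.mbll` and :mod:`wfom.fluor` assume:

* reflectance:  I = S(r) * I0 * exp(-dmu_a(r,t,lam) * X(lam)) + D + noise
* fluorescence: F = S(r) * sigma * F0 * c_f(r,t) *
                exp(-[dmu_a_ex * x_ex + dmu_a_em * x_em]) + D + noise

with dmu_a from the truth concentration movies through the haemoglobin
extinctions (natural-log mm^-1 M^-1). Shot noise is Poisson on the pre-dark
counts; optional Gaussian read noise. All randomness flows from one seed.

Compartment signatures follow vascular physiology during functional
hyperaemia: arteries dilate (HbT and HbO rise, HbR nearly unchanged), veins
wash out deoxyhaemoglobin (strong HbR decrease, minimal HbT change), and the
capillary bed shows an intermediate, slightly delayed, spatially blurred
response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from wfom.mbll import ImageStack

__all__ = [
    "Phantom",
    "ReflChannelSpec",
    "make_scene",
    "forward_reflectance",
    "forward_fluorescence",
    "gamma_kernel",
]

DEFAULT_DARK_LEVEL = 100.0  # counts; camera dark level can be up to ~100 counts


def gamma_kernel(t: np.ndarray, shape: float, scale: float) -> np.ndarray:
    """Gamma-function kernel (unit area on the given time grid)."""
    from scipy.stats import gamma as gamma_dist

    k = gamma_dist.pdf(t, a=shape, scale=scale)
    area = np.trapezoid(k, t)
    return k / area if area > 0 else k


@dataclass
class ReflChannelSpec:
    """Forward-model parameters of one reflectance channel."""

    name: str
    xi_hbo_nat_mm: float  # natural-log extinction, mm^-1 M^-1
    xi_hbr_nat_mm: float
    x_mm: float           # mean differential pathlength at this band
    i0: float = 1.0e4     # illumination counts at baseline


@dataclass
class Phantom:
    """Synthetic scene: masks, truth dynamics and forward-model parameters."""

    masks: dict[str, np.ndarray]
    compartment_traces: dict[str, dict[str, np.ndarray]]
    d_hbo: np.ndarray          # (t, h, w) truth, molar
    d_hbr: np.ndarray
    truth_cf: np.ndarray       # (t, h, w) fluorophore activity ratio c_f(t)/c_f(t0)
    s_map: np.ndarray          # static gain field S(r)
    dark_level: float
    fs_hz: float
    stim_window_s: tuple[float, float]
    x_ex_mm: float             # effective excitation-leg pathlength
    x_em_mm: float             # effective emission-leg pathlength
    seed: int
    vessel_mask: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        vessels = np.zeros(self.d_hbo.shape[1:], dtype=bool)
        for name, mask in self.masks.items():
            if name not in ("capillary", "parenchyma"):
                vessels |= mask > 0.5
        self.vessel_mask = vessels

    @property
    def d_hbt(self) -> np.ndarray:
        return self.d_hbo + self.d_hbr

    @property
    def n_frames(self) -> int:
        return self.d_hbo.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fs_hz

    @property
    def baseline_window(self) -> tuple[int, int]:
        """All pre-stimulus frames."""
        return (0, max(1, int(self.stim_window_s[0] * self.fs_hz)))


def _hyperaemia(times: np.ndarray, stim: tuple[float, float], fs: float,
                delay_s: float = 0.0) -> np.ndarray:
    """Normalised haemodynamic response: stimulus boxcar (x) gamma kernel."""
    box = ((times >= stim[0] + delay_s) & (times < stim[1] + delay_s)).astype(float)
    kern_t = np.arange(0.0, 8.0, 1.0 / fs)
    kern = gamma_kernel(kern_t, shape=3.0, scale=0.55)
    resp = np.convolve(box, kern)[: times.size] / fs
    peak = resp.max()
    return resp / peak if peak > 0 else resp


def _calcium(times: np.ndarray, stim: tuple[float, float], fs: float,
             sustained: float = 0.15) -> np.ndarray:
    """Fast stimulus-locked fluorophore activity with neural adaptation.

    Rises within ~0.1 s of onset, peaks, then adapts towards a `sustained`
    plateau for the rest of the stimulus and decays after offset — so the
    calcium transient leads the (slower, larger) haemodynamic response and has
    largely adapted by the time hyperaemia peaks.
    """
    resp = np.zeros_like(times)
    on, off = stim
    during = (times >= on) & (times < off)
    dt_on = times[during] - on
    resp[during] = (1.0 - np.exp(-dt_on / 0.1)) * (
        sustained + (1.0 - sustained) * np.exp(-dt_on / 0.8)
    )
    after = times >= off
    level_off = resp[during][-1] if np.any(during) else 0.0
    resp[after] = level_off * np.exp(-(times[after] - off) / 0.4)
    peak = resp.max()
    return resp / peak if peak > 0 else resp


# Per-compartment (dHbO, dHbR) peak amplitudes in molar, and response delays (s).
# Arteries: blood volume rise carried by HbO; veins: HbR washout at near-constant
# volume; capillaries: intermediate and delayed.
_COMPARTMENT_PHYSIOLOGY = {
    "artery": {"hbo": 8.0e-6, "hbr": -0.4e-6, "delay": 0.0},
    "arteriole": {"hbo": 6.0e-6, "hbr": -0.8e-6, "delay": 0.2},
    "capillary": {"hbo": 8.0e-6, "hbr": -2.0e-6, "delay": 0.5},
    "venule": {"hbo": 3.8e-6, "hbr": -3.0e-6, "delay": 0.9},
    "vein": {"hbo": 4.3e-6, "hbr": -4.0e-6, "delay": 1.3},
}


def make_scene(
    seed: int = 0,
    shape: tuple[int, int] = (48, 48),
    n_frames: int = 120,
    fs_hz: float = 10.0,
    stim_window_s: tuple[float, float] = (2.0, 7.0),
    compartments: tuple[str, ...] = ("artery", "capillary", "vein"),
    cf_amplitude: float = 0.10,
    capillary_blur_px: float = 3.0,
    dark_level: float = DEFAULT_DARK_LEVEL,
    x_ex_mm: float = 0.56,
    x_em_mm: float = 0.57,
    gain_inhomogeneity: float = 0.2,
) -> Phantom:
    """Build a deterministic synthetic scene for a given seed.

    The default scene holds an artery and a vein crossing a blurred capillary
    bed, a smooth static gain field S(r) with `gain_inhomogeneity` relative
    spread, a 10% peak fluorophore transient confined to the responding
    region, and the standard 100-count dark level.
    """
    unknown = set(compartments) - set(_COMPARTMENT_PHYSIOLOGY)
    if unknown:
        raise ValueError(f"unknown compartments: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    h, w = shape
    times = np.arange(n_frames) / fs_hz

    masks: dict[str, np.ndarray] = {}
    cols = np.linspace(w // 5, 4 * w // 5, num=max(1, len([c for c in compartments if c != "capillary"])), dtype=int)
    ci = 0
    for name in compartments:
        if name == "capillary":
            blob = np.zeros(shape)
            yy, xx = np.mgrid[0:h, 0:w]
            blob = np.exp(-(((yy - h / 2) / (h / 3)) ** 2 + ((xx - w / 2) / (w / 3)) ** 2))
            blob = gaussian_filter(blob, capillary_blur_px)
            masks[name] = blob / blob.max()
        else:
            m = np.zeros(shape)
            c = cols[ci]
            ci += 1
            m[:, max(0, c - 1): c + 1] = 1.0
            masks[name] = m

    traces: dict[str, dict[str, np.ndarray]] = {}
    d_hbo = np.zeros((n_frames, h, w))
    d_hbr = np.zeros((n_frames, h, w))
    for name in compartments:
        phys = _COMPARTMENT_PHYSIOLOGY[name]
        resp = _hyperaemia(times, stim_window_s, fs_hz, delay_s=phys["delay"])
        hbo = phys["hbo"] * resp
        hbr = phys["hbr"] * resp
        traces[name] = {"hbo": hbo, "hbr": hbr, "hbt": hbo + hbr}
        weight = masks[name]
        d_hbo += hbo[:, None, None] * weight[None, :, :]
        d_hbr += hbr[:, None, None] * weight[None, :, :]

    # fluorophore transient confined to the responding (capillary-bed) region
    ca = _calcium(times, stim_window_s, fs_hz)
    if "capillary" in masks:
        region = masks["capillary"]
    else:
        region = np.ones(shape)
    truth_cf = 1.0 + cf_amplitude * ca[:, None, None] * region[None, :, :]

    s_map = 1.0 + gain_inhomogeneity * gaussian_filter(rng.standard_normal(shape), 6.0) / max(
        1e-9, gaussian_filter(rng.standard_normal(shape), 6.0).std()
    )
    s_map = np.clip(np.abs(s_map), 0.3, None)

    return Phantom(
        masks=masks,
        compartment_traces=traces,
        d_hbo=d_hbo,
        d_hbr=d_hbr,
        truth_cf=truth_cf,
        s_map=s_map,
        dark_level=dark_level,
        fs_hz=fs_hz,
        stim_window_s=stim_window_s,
        x_ex_mm=x_ex_mm,
        x_em_mm=x_em_mm,
        seed=seed,
    )


def _delta_mua(phantom: Phantom, xi_hbo_nat: float, xi_hbr_nat: float) -> np.ndarray:
    """Absorption-change movie (mm^-1) from the truth concentration movies."""
    return xi_hbo_nat * phantom.d_hbo + xi_hbr_nat * phantom.d_hbr


def _add_noise(
    counts: np.ndarray,
    rng: np.random.Generator,
    shot_noise: bool,
    read_noise_std: float,
) -> np.ndarray:
    out = counts
    if shot_noise:
        out = rng.poisson(np.clip(out, 0.0, None)).astype(float)
    if read_noise_std > 0:
        out = out + rng.normal(0.0, read_noise_std, size=out.shape)
    return out


def forward_reflectance(
    phantom: Phantom,
    channels: list[ReflChannelSpec],
    shot_noise: bool = False,
    read_noise_std: float = 0.0,
) -> dict[str, ImageStack]:
    """Render each reflectance channel of the phantom as an ImageStack."""
    rng = np.random.default_rng(np.random.SeedSequence([phantom.seed, 1]))
    stacks: dict[str, ImageStack] = {}
    for ch in channels:
        dmua = _delta_mua(phantom, ch.xi_hbo_nat_mm, ch.xi_hbr_nat_mm)
        clean = phantom.s_map[None, :, :] * ch.i0 * np.exp(-dmua * ch.x_mm)
        counts = _add_noise(clean, rng, shot_noise, read_noise_std) + phantom.dark_level
        stacks[ch.name] = ImageStack(
            data=counts,
            channel=ch.name,
            timestamps=phantom.times_s,
            dark=phantom.dark_level,
        )
    return stacks


def forward_fluorescence(
    phantom: Phantom,
    ex_xi_nat_mm: tuple[float, float],
    em_xi_nat_mm: tuple[float, float],
    f0: float = 1.0e4,
    sigma: float = 1.0,
    shot_noise: bool = False,
    read_noise_std: float = 0.0,
    channel: str = "gcamp",
) -> ImageStack:
    """Render the fluorescence channel with multiplicative haemodynamic cross-talk.

    `ex_xi_nat_mm` / `em_xi_nat_mm` are (xi_HbO, xi_HbR) natural-log extinction
    pairs at the excitation and emission bands. `sigma` is the fluorophore
    conversion efficiency — corrected dF/F outputs must be invariant to it.
    """
    rng = np.random.default_rng(np.random.SeedSequence([phantom.seed, 2]))
    dmua_ex = _delta_mua(phantom, *ex_xi_nat_mm)
    dmua_em = _delta_mua(phantom, *em_xi_nat_mm)
    attenuation = np.exp(-(dmua_ex * phantom.x_ex_mm + dmua_em * phantom.x_em_mm))
    clean = phantom.s_map[None, :, :] * sigma * f0 * phantom.truth_cf * attenuation
    counts = _add_noise(clean, rng, shot_noise, read_noise_std) + phantom.dark_level
    return ImageStack(
        data=counts,
        channel=channel,
        timestamps=phantom.times_s,
        dark=phantom.dark_level,
    )
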
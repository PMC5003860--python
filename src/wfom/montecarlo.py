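"""Monte Carlo photon transport in a homogeneous semi-infinite brain model.

Estimates the two quantities the modified Beer-Lambert conversion needs but
cannot measure: the mean differential pathlength X(lambda) of detected
photons, and the spatial sensitivity dM/dmu_a(x, z) of a camera pixel to
absorption changes at depth z and lateral offset x.

Model and estimator
-------------------
* Semi-infinite homogeneous medium, z positive downward from the surface,
  uniform planar unidirectional illumination. By lateral translation symmetry
  this is simulated by launching every photon straight down at the origin and
  binning path positions relative to the photon's *exit* point — the
  reciprocity trick that turns planar illumination + single-pixel detection
  into point illumination + full-surface detection.
* Henyey-Greenstein scattering with anisotropy g; step lengths sampled from
  the scattering mean free path only.
* Absorption by continuous weight attenuation exp(-mu_a * s) along each
  segment (a pathlength-recording estimator, never terminal absorption
  sampling), so a single photon set supports exact mu_a-perturbation
  re-weighting: R(mu_a + d) = sum_i w_i exp(-d * L_i).
* Detection: the photon exits the top surface with its (refracted) direction
  inside the numerical-aperture acceptance cone. Fresnel reflection at the
  tissue-air boundary (n_rel, default 1.37) is applied at exit by default and
  can be disabled.
* Russian roulette below weight 1e-4 with survival probability 0.1; the
  roulette weight balance is tracked explicitly so energy conservation holds
  to float precision, not just in expectation. Photons reaching the depth
  cutoff (default 10 mm, far beyond visible-light penetration) are terminated
  into a "transmitted" bucket.

The per-segment partial pathlengths of detected photons, binned in (x, z) and
scaled by the photon's final weight, give the sensitivity map; its total obeys
the adjoint identity sum(sensitivity) = <L> * detected_weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from wfom.mbll import PathlengthTable

__all__ = [
    "OpticalProperties",
    "DetectionGeometry",
    "SensitivityResult",
    "FluorescenceResult",
    "scatter_power_law",
    "simulate_reflectance",
    "simulate_fluorescence",
    "pathlength_table",
]

WEIGHT_MIN = 1.0e-4
ROULETTE_SURVIVAL = 0.1


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical properties of the medium at one wavelength."""

    mua: float           # absorption, mm^-1 (natural log)
    mus: float           # scattering, mm^-1
    g: float = 0.85      # Henyey-Greenstein anisotropy
    n_rel: float = 1.37  # tissue refractive index relative to the outside

    def __post_init__(self) -> None:
        if self.mua < 0:
            raise ValueError("mua must be >= 0")
        if self.mus <= 0:
            raise ValueError("mus must be > 0")
        if not -1.0 < self.g < 1.0:
            raise ValueError("anisotropy g must lie in (-1, 1)")
        if self.n_rel < 1.0:
            raise ValueError("n_rel must be >= 1")


@dataclass(frozen=True)
class DetectionGeometry:
    """Illumination/detection geometry and the (x, z) sensitivity grid."""

    na: float = 0.2            # acceptance half-angle sine of the detection lens
    pixel_size_mm: float = 0.02
    x_max_mm: float = 5.0      # lateral half-extent of the sensitivity grid
    z_max_mm: float = 10.0     # depth extent; doubles as the transport cutoff
    bin_mm: float = 0.1        # square (x, z) bin size, half-open [lo, hi)
    fresnel: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.na <= 1.0:
            raise ValueError("numerical aperture must lie in (0, 1]")
        if self.bin_mm <= 0 or self.x_max_mm <= 0 or self.z_max_mm <= 0:
            raise ValueError("grid extents and bin size must be positive")

    @property
    def x_edges(self) -> np.ndarray:
        n = int(round(2 * self.x_max_mm / self.bin_mm))
        return -self.x_max_mm + self.bin_mm * np.arange(n + 1)

    @property
    def z_edges(self) -> np.ndarray:
        n = int(round(self.z_max_mm / self.bin_mm))
        return self.bin_mm * np.arange(n + 1)


@dataclass
class SensitivityResult:
    """Outputs of a reflectance transport run."""

    dpf_pathlength_mm: float        # weight-averaged total pathlength of detected photons
    sensitivity_xz: np.ndarray      # (nx, nz) partial-pathlength map of detected light
    sensitivity_overflow: float     # partial pathlength deposited outside the grid
    x_edges: np.ndarray
    z_edges: np.ndarray
    total_reflectance: float        # detected weight fraction
    detected_weight: float
    escaped_weight: float           # exited the surface outside the NA cone
    transmitted_weight: float       # reached the depth cutoff
    absorbed_weight: float
    roulette_net: float             # net weight created (-) / destroyed (+) by roulette
    detected_pathlengths_mm: np.ndarray
    detected_weights: np.ndarray
    n_photons: int
    seed: int
    props: OpticalProperties
    geom: DetectionGeometry

    @property
    def depth_profile(self) -> np.ndarray:
        """Sensitivity vs depth (sum over lateral bins)."""
        return self.sensitivity_xz.sum(axis=0)

    @property
    def lateral_profile(self) -> np.ndarray:
        """Sensitivity vs lateral offset (sum over depth bins)."""
        return self.sensitivity_xz.sum(axis=1)

    @property
    def weight_balance_error(self) -> float:
        """Relative closure error of the weight budget (should be ~1e-12)."""
        total = (
            self.detected_weight + self.escaped_weight + self.transmitted_weight
            + self.absorbed_weight + self.roulette_net
        )
        return abs(total - self.n_photons) / self.n_photons

    def reweighted_reflectance(self, delta_mua: float) -> float:
        """Detected weight fraction if mu_a were larger by `delta_mua` (mm^-1).

        Exact for this photon set: every detected photon's weight is rescaled
        by exp(-delta_mua * L) using its recorded total pathlength.
        """
        return float(
            np.sum(self.detected_weights * np.exp(-delta_mua * self.detected_pathlengths_mm))
            / self.n_photons
        )

    def mean_depth_mm(self) -> float:
        """Sensitivity-weighted mean probing depth."""
        z_mid = 0.5 * (self.z_edges[:-1] + self.z_edges[1:])
        prof = self.depth_profile
        return float(np.sum(z_mid * prof) / np.sum(prof))


@njit(cache=True)
def _hg_cos(g: float) -> float:
    u = np.random.random()
    if abs(g) < 1e-6:
        return 2.0 * u - 1.0
    frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    return (1.0 + g * g - frac * frac) / (2.0 * g)


@njit(cache=True)
def _rotate(ux: float, uy: float, uz: float, ct: float):
    st = np.sqrt(max(0.0, 1.0 - ct * ct))
    phi = 2.0 * np.pi * np.random.random()
    cp, sp = np.cos(phi), np.sin(phi)
    if abs(uz) > 0.99999:
        nx = st * cp
        ny = st * sp
        nz = ct if uz > 0.0 else -ct
    else:
        den = np.sqrt(1.0 - uz * uz)
        nx = st * (ux * uz * cp - uy * sp) / den + ux * ct
        ny = st * (uy * uz * cp + ux * sp) / den + uy * ct
        nz = -st * cp * den + uz * ct
    norm = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True)
def _fresnel_reflectance(cos_i: float, n_rel: float) -> float:
    # unpolarised reflectance at the tissue->outside boundary
    sin_i = np.sqrt(max(0.0, 1.0 - cos_i * cos_i))
    sin_t = n_rel * sin_i
    if sin_t >= 1.0:
        return 1.0  # total internal reflection
    cos_t = np.sqrt(1.0 - sin_t * sin_t)
    rs = (n_rel * cos_i - cos_t) / (n_rel * cos_i + cos_t)
    rp = (n_rel * cos_t - cos_i) / (n_rel * cos_t + cos_i)
    return 0.5 * (rs * rs + rp * rp)


_MAX_PATH_BUF = 1 << 18


@njit(cache=True)
def _transport_reflectance(
    n_photons: int,
    mua: float,
    mus: float,
    g: float,
    n_rel: float,
    na: float,
    fresnel: int,
    x_min: float,
    bin_mm: float,
    nx: int,
    nz: int,
    z_cut: float,
    seed: int,
):
    np.random.seed(seed)
    sens = np.zeros((nx, nz))
    overflow = 0.0
    det_L = np.zeros(n_photons)
    det_w = np.zeros(n_photons)
    n_det = 0
    w_detected = 0.0
    w_escaped = 0.0
    w_transmitted = 0.0
    w_absorbed = 0.0
    roulette_net = 0.0

    sub_max = 0.5 * bin_mm
    buf_x = np.empty(_MAX_PATH_BUF)
    buf_z = np.empty(_MAX_PATH_BUF)
    buf_l = np.empty(_MAX_PATH_BUF)
    # acceptance: refracted exterior angle within the NA cone
    sin_acc = na / n_rel if fresnel == 1 or n_rel > 1.0 else na
    cos_acc = np.sqrt(max(0.0, 1.0 - sin_acc * sin_acc))

    for _ in range(n_photons):
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = 1.0
        L = 0.0
        nbuf = 0
        buf_over = 0.0  # path length that did not fit the buffer
        alive = True
        detected = False

        while alive:
            s = -np.log(np.random.random()) / mus
            while s > 0.0 and alive:
                # distance to the top surface along current direction
                if uz < 0.0:
                    s_boundary = -z / uz
                else:
                    s_boundary = 1.0e30
                step = s if s < s_boundary else s_boundary
                # deposit the segment in substeps and attenuate
                remaining = step
                while remaining > 0.0:
                    ds = remaining if remaining < sub_max else sub_max
                    mx = x + ux * 0.5 * ds
                    mz = z + uz * 0.5 * ds
                    if nbuf < _MAX_PATH_BUF:
                        buf_x[nbuf] = mx
                        buf_z[nbuf] = mz
                        buf_l[nbuf] = ds
                        nbuf += 1
                    else:
                        buf_over += ds
                    x += ux * ds
                    y += uy * ds
                    z += uz * ds
                    remaining -= ds
                att = np.exp(-mua * step)
                w_absorbed += w * (1.0 - att)
                w *= att
                L += step
                s -= step

                if step == s_boundary and uz < 0.0:
                    # at the surface
                    z = 0.0
                    cos_i = -uz
                    refl = _fresnel_reflectance(cos_i, n_rel) if fresnel == 1 else 0.0
                    if np.random.random() < refl:
                        uz = -uz  # internally reflected, continue the leg
                    else:
                        if cos_i >= cos_acc:
                            detected = True
                            w_detected += w
                        else:
                            w_escaped += w
                        alive = False
                elif z >= z_cut:
                    w_transmitted += w
                    alive = False

            if alive:
                ct = _hg_cos(g)
                ux, uy, uz = _rotate(ux, uy, uz, ct)
                if w < WEIGHT_MIN:
                    if np.random.random() < ROULETTE_SURVIVAL:
                        roulette_net -= w * (1.0 / ROULETTE_SURVIVAL - 1.0)
                        w /= ROULETTE_SURVIVAL
                    else:
                        roulette_net += w
                        alive = False

        if detected:
            det_L[n_det] = L
            det_w[n_det] = w
            n_det += 1
            # bin the recorded path relative to the exit point
            for i in range(nbuf):
                xr = buf_x[i] - x
                ix = int((xr - x_min) / bin_mm)
                iz = int(buf_z[i] / bin_mm)
                if 0 <= ix < nx and 0 <= iz < nz:
                    sens[ix, iz] += w * buf_l[i]
                else:
                    overflow += w * buf_l[i]
            overflow += w * buf_over

    return (
        sens, overflow, det_L[:n_det], det_w[:n_det],
        w_detected, w_escaped, w_transmitted, w_absorbed, roulette_net,
    )


def scatter_power_law(
    mus_ref: float, lambda_ref_nm: float, b: float, lambda_nm
) -> float | np.ndarray:
    """Scattering spectrum mus(lambda) = mus_ref * (lambda/lambda_ref)^(-b).

    For brain tissue the scatter power b is typically between 1.3 and 2.
    """
    if mus_ref <= 0 or lambda_ref_nm <= 0 or np.any(np.asarray(lambda_nm) <= 0):
        raise ValueError("wavelengths and reference scattering must be positive")
    return mus_ref * (np.asarray(lambda_nm, dtype=float) / lambda_ref_nm) ** (-b)


def simulate_reflectance(
    props: OpticalProperties,
    geom: DetectionGeometry = DetectionGeometry(),
    n_photons: int = 100_000,
    seed: int = 0,
) -> SensitivityResult:
    """Run the diffuse-reflectance transport model.

    Reproducible bit-for-bit for a fixed seed. ``n_photons >= 1e4`` is
    recommended when the sensitivity map (not just the pathlength) is used.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    x_edges = geom.x_edges
    z_edges = geom.z_edges
    nx, nz = x_edges.size - 1, z_edges.size - 1
    if nx < 1 or nz < 1:
        raise ValueError("degenerate sensitivity grid")
    (sens, overflow, det_L, det_w, w_det, w_esc, w_trans, w_abs, r_net) = _transport_reflectance(
        int(n_photons), props.mua, props.mus, props.g, props.n_rel,
        geom.na, 1 if geom.fresnel else 0,
        float(x_edges[0]), geom.bin_mm, nx, nz, geom.z_max_mm, int(seed) & 0x7FFFFFFF,
    )
    if not np.all(np.isfinite(sens)):
        raise FloatingPointError("non-finite photon weights in sensitivity map")
    dpf = float(np.sum(det_L * det_w) / np.sum(det_w)) if det_L.size else 0.0
    return SensitivityResult(
        dpf_pathlength_mm=dpf,
        sensitivity_xz=sens,
        sensitivity_overflow=float(overflow),
        x_edges=x_edges,
        z_edges=z_edges,
        total_reflectance=float(w_det / n_photons),
        detected_weight=float(w_det),
        escaped_weight=float(w_esc),
        transmitted_weight=float(w_trans),
        absorbed_weight=float(w_abs),
        roulette_net=float(r_net),
        detected_pathlengths_mm=det_L,
        detected_weights=det_w,
        n_photons=int(n_photons),
        seed=int(seed),
        props=props,
        geom=geom,
    )


@njit(cache=True)
def _transport_fluorescence(
    n_photons: int,
    mua_ex: float, mus_ex: float, g_ex: float,
    mua_em: float, mus_em: float, g_em: float,
    n_rel: float, na: float, fresnel: int,
    f_profile: np.ndarray, bin_mm: float, z_cut: float,
    seed: int,
):
    np.random.seed(seed)
    nzf = f_profile.size
    detected_w = 0.0
    launched_w = 0.0
    sum_ex_leg = 0.0
    sum_em_leg = 0.0
    det_by_depth = np.zeros(nzf)
    sin_acc = na / n_rel
    cos_acc = np.sqrt(max(0.0, 1.0 - sin_acc * sin_acc))

    buf_z = np.empty(_MAX_PATH_BUF)
    buf_q = np.empty(_MAX_PATH_BUF)
    buf_s = np.empty(_MAX_PATH_BUF)

    for _ in range(n_photons):
        # --- excitation leg: record conversion opportunities along the path
        z = 0.0
        ux, uy, uz = 0.0, 0.0, 1.0
        w = 1.0
        L = 0.0
        nbuf = 0
        alive = True
        while alive:
            s = -np.log(np.random.random()) / mus_ex
            while s > 0.0 and alive:
                s_boundary = -z / uz if uz < 0.0 else 1.0e30
                step = s if s < s_boundary else s_boundary
                remaining = step
                while remaining > 0.0:
                    ds = remaining if remaining < 0.5 * bin_mm else 0.5 * bin_mm
                    mz = z + uz * 0.5 * ds
                    iz = int(mz / bin_mm)
                    if 0 <= iz < nzf and nbuf < _MAX_PATH_BUF:
                        q = w * ds * f_profile[iz]
                        if q > 0.0:
                            buf_z[nbuf] = mz
                            buf_q[nbuf] = q
                            buf_s[nbuf] = L + (step - remaining) + 0.5 * ds
                            nbuf += 1
                    z += uz * ds
                    remaining -= ds
                w *= np.exp(-mua_ex * step)
                L += step
                s -= step
                if step == s_boundary and uz < 0.0:
                    z = 0.0
                    cos_i = -uz
                    refl = _fresnel_reflectance(cos_i, n_rel) if fresnel == 1 else 0.0
                    if np.random.random() < refl:
                        uz = -uz
                    else:
                        alive = False  # excitation light lost from the surface
                elif z >= z_cut:
                    alive = False
            if alive:
                ct = _hg_cos(g_ex)
                ux, uy, uz = _rotate(ux, uy, uz, ct)
                if w < WEIGHT_MIN:
                    if np.random.random() < ROULETTE_SURVIVAL:
                        w /= ROULETTE_SURVIVAL
                    else:
                        alive = False

        if nbuf == 0:
            continue
        q_tot = 0.0
        for i in range(nbuf):
            q_tot += buf_q[i]
        launched_w += q_tot
        # sample one conversion point with probability proportional to q
        target = np.random.random() * q_tot
        acc = 0.0
        pick = nbuf - 1
        for i in range(nbuf):
            acc += buf_q[i]
            if acc >= target:
                pick = i
                break
        z0 = buf_z[pick]
        ex_leg = buf_s[pick]
        em_w = q_tot  # importance weight of the emission photon

        # --- emission leg: isotropic launch, transport at emission properties
        ct = 2.0 * np.random.random() - 1.0
        phi = 2.0 * np.pi * np.random.random()
        st = np.sqrt(max(0.0, 1.0 - ct * ct))
        ux, uy, uz = st * np.cos(phi), st * np.sin(phi), ct
        z = z0
        w = em_w
        Lem = 0.0
        alive = True
        while alive:
            s = -np.log(np.random.random()) / mus_em
            while s > 0.0 and alive:
                s_boundary = -z / uz if uz < 0.0 else 1.0e30
                step = s if s < s_boundary else s_boundary
                z += uz * step
                w *= np.exp(-mua_em * step)
                Lem += step
                s -= step
                if step == s_boundary and uz < 0.0:
                    z = 0.0
                    cos_i = -uz
                    refl = _fresnel_reflectance(cos_i, n_rel) if fresnel == 1 else 0.0
                    if np.random.random() < refl:
                        uz = -uz
                    else:
                        if cos_i >= cos_acc:
                            detected_w += w
                            sum_ex_leg += w * ex_leg
                            sum_em_leg += w * Lem
                            iz = int(z0 / bin_mm)
                            if 0 <= iz < nzf:
                                det_by_depth[iz] += w
                        alive = False
                elif z >= z_cut:
                    alive = False
            if alive:
                ct = _hg_cos(g_em)
                ux, uy, uz = _rotate(ux, uy, uz, ct)
                if w < WEIGHT_MIN * em_w:
                    if np.random.random() < ROULETTE_SURVIVAL:
                        w /= ROULETTE_SURVIVAL
                    else:
                        alive = False

    return detected_w, launched_w, sum_ex_leg, sum_em_leg, det_by_depth


@dataclass
class FluorescenceResult:
    """Outputs of an excitation->emission transport run."""

    x_ex_mm: float                 # mean excitation-leg pathlength of detected light
    x_em_mm: float                 # mean emission-leg pathlength of detected light
    detected_fraction: float       # detected emission weight / converted weight
    detected_by_depth: np.ndarray  # detected weight vs fluorophore conversion depth
    z_edges: np.ndarray
    n_photons: int
    seed: int


def simulate_fluorescence(
    props_ex: OpticalProperties,
    props_em: OpticalProperties,
    fluorophore_depth_profile: np.ndarray,
    geom: DetectionGeometry = DetectionGeometry(),
    n_photons: int = 100_000,
    seed: int = 0,
) -> FluorescenceResult:
    """Simulate fluorescence excitation and isotropic re-emission.

    `fluorophore_depth_profile` gives the relative fluorophore density per
    depth bin of the geometry's z grid (normalised internally). Excitation
    photons propagate at `props_ex`; a conversion point is sampled along each
    path in proportion to local excitation fluence times fluorophore density;
    emission photons re-launch isotropically and propagate at `props_em`.
    Returns mean excitation-/emission-leg pathlengths of the detected light
    and the detected weight as a function of fluorophore depth.
    """
    profile = np.asarray(fluorophore_depth_profile, dtype=float)
    nzf = geom.z_edges.size - 1
    if profile.shape != (nzf,):
        raise ValueError(f"depth profile must have {nzf} bins to match the z grid")
    if np.any(profile < 0) or profile.sum() <= 0:
        raise ValueError("depth profile must be non-negative with positive total")
    profile = profile / profile.sum()
    det_w, conv_w, s_ex, s_em, det_depth = _transport_fluorescence(
        int(n_photons),
        props_ex.mua, props_ex.mus, props_ex.g,
        props_em.mua, props_em.mus, props_em.g,
        props_ex.n_rel, geom.na, 1 if geom.fresnel else 0,
        profile, geom.bin_mm, geom.z_max_mm, int(seed) & 0x7FFFFFFF,
    )
    if conv_w <= 0 or det_w <= 0:
        raise RuntimeError("no fluorescence detected; increase n_photons")
    return FluorescenceResult(
        x_ex_mm=float(s_ex / det_w),
        x_em_mm=float(s_em / det_w),
        detected_fraction=float(det_w / conv_w),
        detected_by_depth=det_depth,
        z_edges=geom.z_edges,
        n_photons=int(n_photons),
        seed=int(seed),
    )


def pathlength_table(
    props_by_wavelength: dict[float, OpticalProperties],
    geom: DetectionGeometry = DetectionGeometry(),
    n_photons: int = 100_000,
    seed: int = 0,
) -> PathlengthTable:
    """Mean differential pathlength X(lambda) for a set of wavelengths.

    Runs :func:`simulate_reflectance` per wavelength (each with the same seed,
    so identical properties give identical pathlengths) and returns a table
    consumable by the haemoglobin conversion in :mod:`wfom.mbll`.
    """
    if not props_by_wavelength:
        raise ValueError("at least one wavelength required")
    wavelengths = sorted(props_by_wavelength)
    x_mm = [
        simulate_reflectance(props_by_wavelength[wl], geom, n_photons, seed).dpf_pathlength_mm
        for wl in wavelengths
    ]
    return PathlengthTable(np.asarray(wavelengths), np.asarray(x_mm))
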
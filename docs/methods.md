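# Methods

This note documents the models implemented in `wfom`, the assumptions behind
them, the defaults and why they were chosen, and what the bundled phantom does
and does not emulate.

## Units and the extinction convention

Haemoglobin extinction tables are conventionally published *decadic* in
cm⁻¹·M⁻¹, while the modified Beer–Lambert law (MBLL) is written with a natural
exponent. Mixing the two bases silently is the single most common error in
this analysis, so the package enforces one rule: fixtures are stored decadic
(cm⁻¹·M⁻¹); every absorption coefficient that circulates between modules is
natural-log μₐ in mm⁻¹; and the ln(10)/10 conversion is applied exactly once,
in `wfom.spectra` (`natural_extinction_mm`, `baseline_mua`,
`mbll.extinction_matrix`). Pathlengths are mm, concentrations molar.

## Extinction fixture

`src/wfom/data/hb_extinction_synthetic.csv` is a synthetic stand-in for the
standard HbO/HbR molar extinction compilation, generated
(`scripts/make_extinction_fixture.py`) by monotone (PCHIP) interpolation of
log-extinction through anchor values at the spectra's characteristic
features: the HbO α/β bands at 577/542 nm, the HbR band at 556 nm, the
isosbestic crossing near 530 nm (ξ ≈ 3.9–4.0 × 10⁴ cm⁻¹·M⁻¹) and the
HbR-dominated red tail (630 nm: ξ_HbO ≈ 610, ξ_HbR ≈ 5149 cm⁻¹·M⁻¹). With the
standard brain baseline — 2 mM haemoglobin in whole blood, 3% blood volume,
75% oxygen saturation — it yields tissue μₐ of 0.55 mm⁻¹ at 530 nm,
0.024 mm⁻¹ at 630 nm and 0.33 mm⁻¹ at 488 nm, the values a practitioner would
assume for mouse cortex. It is *not* a measured dataset: band shapes between
anchors are smooth interpolants, adequate for band-integration and unit tests
but not for sub-nanometre spectroscopy.

## Spectroscopic conversion (`wfom.mbll`)

The MBLL attenuation model with the geometry term cancelled by ratioing gives
Δμₐ(t, λ) = −ln[I(t)/I(t₀)]/X(λ). Key choices:

* **Baseline t₀** is the mean over a user-set frame window (the phantom's
  default: all pre-stimulus frames), not a single frame — averaging
  suppresses shot noise in the denominator. No particular window length is
  asserted as canonical; it is a required argument.
* **Invalid pixels** (baseline at/below the dark level, non-positive ratios)
  propagate as explicit boolean masks. They are never NaN, so reductions over
  neighbouring pixels stay finite.
* **Conditioning**: a wavelength pair whose extinction matrix has condition
  number above 1e8 is rejected — beyond that the inversion only amplifies
  noise.
* **No iterative pathlength re-estimation**: recomputing X from inferred
  absorption changes risks divergence and is deliberately not implemented;
  the pairwise consistency check is the supported way to detect pathlength
  model error.
* **Pairwise consistency**: with three wavelengths A, B, C the package
  converts each pair (A&B, B&C, A&C) separately and reports the maximum
  relative RMS disagreement between the three (ΔHbO, ΔHbR) solutions. On a
  consistent forward model the discrepancy is numerically zero; a
  wavelength-dependent pathlength error of tens of percent raises it well
  above the default 5% tolerance.
* The isosbestic estimator also exposes the pathlength- and spectrum-free
  attenuation −ln(I/I₀), the quantity most robust for cross-laboratory
  comparison.

## Monte Carlo photon transport (`wfom.montecarlo`)

Semi-infinite homogeneous medium; z positive downward; uniform planar,
unidirectional illumination. By lateral translation symmetry this equals
launching all photons at one surface point and binning path positions
relative to each photon's *exit* point (reciprocity), which is how the
per-pixel sensitivity map ∂M/∂μₐ(x, z) is accumulated.

* Scattering: Henyey–Greenstein with anisotropy g; step lengths sampled from
  the scattering mean free path only.
* Absorption: continuous weight attenuation exp(−μₐ s) per segment
  (pathlength-recording estimator). This costs nothing and buys two exact
  identities used as tests: the adjoint identity
  Σ_bins sensitivity = ⟨L⟩ × detected weight, and exact μₐ-perturbation
  re-weighting R(μₐ+δ) = Σ wᵢ exp(−δLᵢ) on a single photon set, whose
  logarithmic derivative reproduces the mean pathlength.
* Detection: exit through the top surface with the refracted direction inside
  the NA cone (default NA = 0.2, emulating a low-NA camera lens). Fresnel
  reflection at the tissue–air boundary (n_rel = 1.37) is applied at exit by
  default and is configurable off, since published geometries differ.
* Termination: Russian roulette below weight 1e-4 (survival 0.1) with the
  roulette weight balance tracked explicitly, so the energy budget closes to
  float precision, not merely in expectation; depth cutoff 10 mm (far beyond
  visible penetration), with terminated weight booked as "transmitted".
* Determinism: one integer seed fixes the whole run bit-for-bit.
* Bins are half-open [lo, hi), 0.1 mm square by default, x ∈ [−5, 5] mm,
  z ∈ [0, 10] mm; deposits outside the grid go to an explicit overflow
  accumulator so the adjoint identity still closes.

Fluorescence transport runs an excitation walk, samples one
fluorophore-conversion point per photon along its path in proportion to local
fluence × fluorophore density (no excitation depletion — the dilute-
fluorophore limit), re-emits isotropically and transports at the emission
properties. It reports mean excitation-/emission-leg pathlengths and detected
weight versus fluorophore depth.

### Pathlength fixture

`src/wfom/data/pathlength_synthetic.csv` was generated by this model
(`scripts/make_pathlength_fixture.py`; 2 × 10⁵ photons per wavelength, fixed
seed) with μₐ(λ) from the blood assumptions above and a scatter power law
μ_s = 21 mm⁻¹·(λ/530)^−1.3, g = 0.85. It reproduces the expected *shape* —
short pathlengths (≈1 mm) through the green absorption bands, an order of
magnitude longer in the red — but absolute red-end values depend strongly on
the NA, refractive-index and cutoff conventions, for which published values
vary by factors of ~3. The table is therefore a simulation product with
tolerance, not a calibration standard, and should be regenerated for a
specific instrument geometry.

## Cross-talk corrections (`wfom.fluor`)

All three corrections act on the dark-subtracted fluorescence ratio; dark
subtraction before ratioing is mandatory (the API refuses a missing dark
rather than assuming zero) because only then does the static gain field
cancel.

* **Single-wavelength**: divide by a co-acquired reflectance ratio near the
  emission band. Exact when Δμₐ(λ_ex) ≈ Δμₐ(λ_em) and the diffuse-reflectance
  pathlength ≈ X_ex + X_em; otherwise a bounded approximation.
* **Ex–Em**: reconstruct Δμₐ at the excitation and emission bands per pixel
  from the converted (ΔHbO, ΔHbR) movies and multiply by
  exp(Δμₐ_ex·X_ex + Δμₐ_em·X_em). The default leg pathlengths
  (X_ex = 0.56 mm, X_em = 0.57 mm) are the values found to minimise vessel
  artefacts in Thy1-GCaMP mouse preparations; they are preparation-specific
  configuration. (Published tables sometimes print these with mm⁻¹ units;
  dimensional analysis of the exponent requires mm, and the package treats
  them as mm.)
* **PCA in log space**: the multiplicative contamination is additive in
  ln(F/F₀), so PCA runs on the per-pixel temporally centred log-ratio. The
  haemodynamic component is chosen by maximum |temporal correlation| with a
  reference (a haemoglobin movie, reflectance ratio or bare trace); without a
  reference an explicit component index is required — component order is not
  stable, so the package never guesses. Centring captures only the zero-mean
  part of the contamination; its temporal mean survives as a static per-pixel
  offset, which is removed by re-referencing the corrected ratio to its own
  baseline window (ΔF/F is defined against that baseline in any case).
  Recommended pre-processing (trial averaging, ~5 Hz low-pass via
  `lowpass_filter`) is exposed but optional.

A gamma-kernel model (`fit_gamma_kernel`) fits corrected ΔF/F as
amplitude × (spike rate ⊛ gamma(shape, scale)), the standard validation
against electrophysiology; an all-zero spike train is flagged as
unidentifiable rather than fitted.

## Compartment unmixing (`wfom.unmix`)

Basis rows are ROI-mean ΔHbO/ΔHbR/ΔHbT traces concatenated in time. The HbT
block is linearly dependent on the other two but kept by default so that
coefficients read as "concentration of each full vascular signature"
(`drop_hbt=True` removes it). Rows are not normalised by default for the same
reason; a unit-norm mode exists for display. Internally the per-pixel NNLS is
solved with unit-norm columns and coefficients rescaled afterwards — a pure
conditioning transformation (traces are ~1e-6 molar). Collinear bases warn
rather than error, since overlapping seed ROIs are common in practice.

## The phantom (`wfom.synth`)

The phantom emulates the *structure* the inverse methods rely on: sharp
surface vessels over a spatially blurred capillary background, per-compartment
haemodynamics with the physiological signatures (arteries: HbT/HbO rise with
near-zero HbR change; veins: strong HbR washout at near-constant HbT;
capillaries: intermediate, delayed, blurred), a fast adapting
calcium-indicator transient confined to the responding region, a smooth
static gain field, a 100-count camera dark level, Poisson shot noise on
pre-dark counts (1e4 baseline counts ⇒ 40 dB per-frame SNR) and optional
Gaussian read noise. Defaults: 48×48 pixels (nominal 20 µm pitch), 120 frames
at 10 Hz per channel, stimulus at 2–7 s, 10% peak ΔF/F, hyperaemia peaking
~8 µM ΔHbO in arteries. All randomness flows from one seed and reruns are
bit-exact.

Its attenuation model is exactly the effective-pathlength forward model the
inverse operations assume — deliberately, since the phantom's job is to make
the inversions testable to machine precision. What it therefore does *not*
emulate: 3-D light transport inside the scene (partial-volume and
wavelength-dependent sampling-volume effects), motion, physiological noise
(heart rate, breathing), slow drift, or anatomically realistic vasculature.
Passing the phantom suite shows the algebra and implementation are right, not
that the pathlength model matches a given animal preparation — that is what
the pairwise consistency check and instrument-specific Monte Carlo runs are
for, and why the in-vivo figures of the literature are not claimed to be
reproduced here.

## Problem sizes

Default test problem sizes were chosen to exercise every code path at
desk-scale: 48×48×120 phantoms, 2×10⁴–10⁶ Monte Carlo photons depending on
the identity being checked (pathlength identities need 10⁶; ordering and
conservation properties hold at 10⁴). The acceptance script uses 4×10⁵ green
and 1×10⁵ red photons, where the Monte Carlo summary statistics are stable to
well under a percent.
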
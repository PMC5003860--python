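"""Fluorescence ratiometry and the three haemodynamic cross-talk corrections."""

import numpy as np
import pytest

from conftest import channel_specs, rel_rms
from wfom import fluor, mbll, synth
from wfom.fluor import (
    CrosstalkModel,
    correct_ex_em,
    correct_pca_log,
    correct_single_wavelength,
    dark_subtract_ratio,
    fit_gamma_kernel,
)
from wfom.mbll import ImageStack, extinction_matrix, reflectance_ratio


@pytest.fixture(scope="module")
def bands(ext_table):
    xi_ex = extinction_matrix(ext_table, [488.0])[0]
    xi_em = extinction_matrix(ext_table, [515.0])[0]
    return tuple(xi_ex), tuple(xi_em)


@pytest.fixture(scope="module")
def fluor_stack(phantom, bands):
    return synth.forward_fluorescence(phantom, bands[0], bands[1])


@pytest.fixture(scope="module")
def hemo_truth(phantom):
    return mbll.HemoMovie(
        d_hbo=phantom.d_hbo, d_hbr=phantom.d_hbr,
        valid=np.ones(phantom.d_hbo.shape[1:], bool),
        baseline_window=phantom.baseline_window,
    )


class TestDarkSubtractRatio:
    def test_zero_dark_is_plain_ratio(self):
        data = np.linspace(1.0, 2.0, 4)[:, None, None] * np.ones((4, 2, 2)) * 100
        stack = ImageStack(data=data, dark=0.0)
        ratio = dark_subtract_ratio(stack, (0, 1))
        assert np.allclose(ratio.ratio, data / data[0])

    def test_gain_map_cancels(self, phantom, fluor_stack):
        rng = np.random.default_rng(0)
        gain = rng.uniform(0.5, 2.0, size=fluor_stack.frame_shape)
        rescaled = ImageStack(
            data=(fluor_stack.data - fluor_stack.dark) * gain + fluor_stack.dark,
            dark=fluor_stack.dark,
        )
        r1 = dark_subtract_ratio(fluor_stack, phantom.baseline_window)
        r2 = dark_subtract_ratio(rescaled, phantom.baseline_window)
        assert np.allclose(r1.ratio, r2.ratio, rtol=1e-12)

    def test_missing_dark_refused(self, fluor_stack):
        stack = ImageStack(data=fluor_stack.data, dark=None)
        with pytest.raises(ValueError, match="dark"):
            dark_subtract_ratio(stack, (0, 10))

    def test_skipping_dark_subtraction_biases_dff(self, phantom, bands):
        """With a 100-count dark level and a nonuniform gain, the undark-ed
        ratio is biased relative to truth; subtracting the dark removes it."""
        stack = synth.forward_fluorescence(phantom, bands[0], bands[1])
        bw = phantom.baseline_window
        good = dark_subtract_ratio(stack, bw)
        biased = dark_subtract_ratio(ImageStack(data=stack.data, dark=0.0), bw)
        # compare against the truth contamination-times-activity ratio
        truth = good.ratio  # exact forward ratio (no noise in this stack)
        err_good = rel_rms(good.ratio, truth)
        err_biased = rel_rms(biased.ratio, truth)
        assert err_good < 1e-12
        assert err_biased > 10 * max(err_good, 1e-12)


class TestSingleWavelengthCorrection:
    def test_unit_reflectance_is_identity(self, phantom, fluor_stack):
        bw = phantom.baseline_window
        fl = dark_subtract_ratio(fluor_stack, bw)
        refl = reflectance_ratio(
            ImageStack(data=np.ones_like(fluor_stack.data), dark=0.0), bw
        )
        out = correct_single_wavelength(fl, refl)
        assert np.allclose(out.ratio, fl.ratio)

    def test_exact_on_phantom_matching_assumptions(self, ext_table):
        """Phantom built with equal ex/em attenuation and X_DR = X_ex + X_em."""
        xi = extinction_matrix(ext_table, [515.0])[0]
        ph = synth.make_scene(seed=9, x_ex_mm=0.5, x_em_mm=0.7)
        fl_stack = synth.forward_fluorescence(ph, tuple(xi), tuple(xi))
        spec = synth.ReflChannelSpec("em", xi[0], xi[1], ph.x_ex_mm + ph.x_em_mm)
        refl_stack = synth.forward_reflectance(ph, [spec])["em"]
        bw = ph.baseline_window
        fl = dark_subtract_ratio(fl_stack, bw)
        refl = reflectance_ratio(refl_stack, bw)
        out = correct_single_wavelength(fl, refl)
        assert rel_rms(out.ratio, ph.truth_cf) < 1e-9

    def test_unequal_ex_em_leaves_residual_larger_than_exem(self, phantom, bands, fluor_stack, hemo_truth):
        bw = phantom.baseline_window
        fl = dark_subtract_ratio(fluor_stack, bw)
        xi_em = np.asarray(bands[1])
        spec = synth.ReflChannelSpec("em", xi_em[0], xi_em[1], phantom.x_ex_mm + phantom.x_em_mm)
        refl = reflectance_ratio(synth.forward_reflectance(phantom, [spec])["em"], bw)
        single = correct_single_wavelength(fl, refl)
        model = CrosstalkModel(bands[0], bands[1], phantom.x_ex_mm, phantom.x_em_mm)
        exem = correct_ex_em(fl, hemo_truth, model)
        err_single = rel_rms(single.ratio, phantom.truth_cf)
        err_exem = rel_rms(exem.ratio, phantom.truth_cf)
        assert err_exem < err_single
        assert err_single < 0.05  # still a bounded approximation

    def test_shape_mismatch_raises(self, phantom, fluor_stack):
        bw = phantom.baseline_window
        fl = dark_subtract_ratio(fluor_stack, bw)
        refl = reflectance_ratio(ImageStack(data=np.ones((3, 2, 2)), dark=0.0), (0, 1))
        with pytest.raises(ValueError, match="aligned"):
            correct_single_wavelength(fl, refl)


class TestExEmCorrection:
    def test_zero_hemodynamics_multiplier_is_one(self, phantom, bands, fluor_stack):
        bw = phantom.baseline_window
        fl = dark_subtract_ratio(fluor_stack, bw)
        zeros = np.zeros_like(phantom.d_hbo)
        hemo = mbll.HemoMovie(d_hbo=zeros, d_hbr=zeros,
                              valid=np.ones(zeros.shape[1:], bool), baseline_window=bw)
        model = CrosstalkModel(bands[0], bands[1])
        out = correct_ex_em(fl, hemo, model)
        assert np.allclose(out.ratio, fl.ratio)

    def test_exact_recovery_with_matching_pathlengths(self, phantom, bands, fluor_stack, hemo_truth):
        bw = phantom.baseline_window
        fl = dark_subtract_ratio(fluor_stack, bw)
        model = CrosstalkModel(bands[0], bands[1], phantom.x_ex_mm, phantom.x_em_mm)
        out = correct_ex_em(fl, hemo_truth, model)
        assert rel_rms(out.ratio, phantom.truth_cf) < 1e-12

    def test_uncorrected_dips_corrected_stays_positive(self, phantom, bands, fluor_stack, hemo_truth):
        """The hallmark cross-talk artefact: the uncorrected trace dips below
        baseline as hyperaemia peaks; the corrected trace does not."""
        bw = phantom.baseline_window
        fl = dark_subtract_ratio(fluor_stack, bw)
        model = CrosstalkModel(bands[0], bands[1], phantom.x_ex_mm, phantom.x_em_mm)
        out = correct_ex_em(fl, hemo_truth, model)
        region = phantom.masks["capillary"] > 0.6
        stim = (phantom.times_s >= phantom.stim_window_s[0]) & (
            phantom.times_s < phantom.stim_window_s[1]
        )
        assert fl.dff[stim][:, region].mean(axis=1).min() < -0.005
        assert out.dff[stim][:, region].mean(axis=1).min() > -1e-12

    def test_default_pathlength_estimates(self):
        model = CrosstalkModel((1.0, 1.0), (1.0, 1.0))
        assert model.x_est_ex_mm == 0.56 and model.x_est_em_mm == 0.57

    def test_brightness_invariance(self, phantom, bands, hemo_truth):
        """Doubling fluorophore brightness changes no corrected output."""
        bw = phantom.baseline_window
        model = CrosstalkModel(bands[0], bands[1], phantom.x_ex_mm, phantom.x_em_mm)
        outs = []
        for sigma in (1.0, 2.0):
            stack = synth.forward_fluorescence(phantom, bands[0], bands[1], sigma=sigma)
            fl = dark_subtract_ratio(stack, bw)
            outs.append(correct_ex_em(fl, hemo_truth, model).ratio)
        assert np.allclose(outs[0], outs[1], rtol=1e-12)


@pytest.fixture(scope="module")
def rank1_phantom():
    # single compartment -> log-contamination is exactly rank 1
    return synth.make_scene(seed=13, compartments=("capillary",), cf_amplitude=0.0)


class TestPcaCorrection:
    def test_rank1_contamination_removed(self, rank1_phantom, bands):
        ph = rank1_phantom
        bw = ph.baseline_window
        stack = synth.forward_fluorescence(ph, bands[0], bands[1])
        fl = dark_subtract_ratio(stack, bw)
        ref = ph.d_hbt.reshape(ph.n_frames, -1).mean(axis=1)
        res = correct_pca_log(fl, reference=ref)
        assert res.component_index == 0
        assert np.abs(res.corrected.ratio - 1.0).max() < 1e-9
        assert np.abs(fl.ratio - 1.0).max() > 1e-3

    def test_rank1_with_noise_flat_within_noise_floor(self, rank1_phantom, bands):
        ph = rank1_phantom
        bw = ph.baseline_window
        stack = synth.forward_fluorescence(ph, bands[0], bands[1], shot_noise=True)
        fl = dark_subtract_ratio(stack, bw)
        ref = ph.d_hbt.reshape(ph.n_frames, -1).mean(axis=1)
        res = correct_pca_log(fl, reference=ref)
        noise_floor = 1.0 / np.sqrt(1.0e4)  # shot noise at 1e4 baseline counts
        residual = np.sqrt(np.mean((res.corrected.ratio - 1.0) ** 2))
        assert residual < 3 * noise_floor

    def test_no_contamination_leaves_data_untouched(self, bands):
        ph = synth.make_scene(seed=14, cf_amplitude=0.05)
        ph.d_hbo[:] = 0.0
        ph.d_hbr[:] = 0.0
        bw = ph.baseline_window
        fl = dark_subtract_ratio(synth.forward_fluorescence(ph, bands[0], bands[1]), bw)
        ref = np.sin(np.linspace(0, 20, ph.n_frames))  # unrelated reference
        res = correct_pca_log(fl, reference=ref)
        assert res.component_index == -1
        assert np.allclose(res.corrected.ratio, fl.ratio)

    def test_agrees_with_exem_on_shared_phantom(self, rank1_phantom, bands):
        ph = rank1_phantom
        bw = ph.baseline_window
        fl = dark_subtract_ratio(synth.forward_fluorescence(ph, bands[0], bands[1]), bw)
        hemo = mbll.HemoMovie(d_hbo=ph.d_hbo, d_hbr=ph.d_hbr,
                              valid=np.ones(ph.d_hbo.shape[1:], bool), baseline_window=bw)
        model = CrosstalkModel(bands[0], bands[1], ph.x_ex_mm, ph.x_em_mm)
        exem = correct_ex_em(fl, hemo, model)
        ref = ph.d_hbt.reshape(ph.n_frames, -1).mean(axis=1)
        pca = correct_pca_log(fl, reference=ref)
        assert rel_rms(pca.corrected.ratio, exem.ratio) < 0.01

    def test_ambiguous_selection_refused(self, rank1_phantom, bands):
        ph = rank1_phantom
        fl = dark_subtract_ratio(
            synth.forward_fluorescence(ph, bands[0], bands[1]), ph.baseline_window
        )
        with pytest.raises(ValueError, match="component"):
            correct_pca_log(fl)

    def test_log_space_subtraction_oracle(self, rank1_phantom, bands):
        """exp(ln(ratio) - rank-1 term) reproduces the library output."""
        ph = rank1_phantom
        fl = dark_subtract_ratio(
            synth.forward_fluorescence(ph, bands[0], bands[1]), ph.baseline_window
        )
        ref = ph.d_hbt.reshape(ph.n_frames, -1).mean(axis=1)
        res = correct_pca_log(fl, reference=ref)
        log_ratio = np.log(fl.ratio).reshape(ph.n_frames, -1)
        rank1 = np.outer(res.removed_time_course, res.removed_spatial_map.ravel())
        oracle = np.exp(log_ratio - rank1).reshape(fl.ratio.shape)
        lo, hi = fl.baseline_window
        oracle = oracle / oracle[lo:hi].mean(axis=0, keepdims=True)
        assert np.allclose(res.corrected.ratio, oracle, rtol=1e-12, atol=1e-15)

    def test_brightness_invariance(self, rank1_phantom, bands):
        ph = rank1_phantom
        bw = ph.baseline_window
        ref = ph.d_hbt.reshape(ph.n_frames, -1).mean(axis=1)
        outs = []
        for sigma in (1.0, 3.0):
            fl = dark_subtract_ratio(
                synth.forward_fluorescence(ph, bands[0], bands[1], sigma=sigma), bw
            )
            outs.append(correct_pca_log(fl, reference=ref).corrected.ratio)
        assert np.allclose(outs[0], outs[1], rtol=1e-9)


class TestGammaKernelFit:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(21)
        fs = 20.0
        t = np.arange(0, 30, 1 / fs)
        spikes = (rng.random(t.size) < 0.05).astype(float) * rng.uniform(0.5, 2.0, t.size)
        from scipy.stats import gamma as gamma_dist

        kern = gamma_dist.pdf(np.arange(0, 10, 1 / fs), a=2.0, scale=0.3) / fs
        dff = 0.8 * np.convolve(spikes, kern)[: t.size]
        dff = dff + rng.normal(0, 0.002, t.size)
        fit = fit_gamma_kernel(spikes, dff, fs)
        assert fit.identifiable
        assert fit.shape == pytest.approx(2.0, rel=0.10)
        assert fit.scale_s == pytest.approx(0.3, rel=0.10)
        assert fit.amplitude == pytest.approx(0.8, rel=0.10)

    def test_zero_spike_train_flagged(self):
        fit = fit_gamma_kernel(np.zeros(100), np.zeros(100), 10.0)
        assert not fit.identifiable
        assert np.allclose(fit.prediction, 0.0)

    def test_narrow_kernel_approaches_scaled_spikes(self):
        """In the delta-kernel limit the prediction collapses onto the spikes."""
        fs = 50.0
        spikes = np.zeros(200)
        spikes[[20, 80, 140]] = 1.0
        from scipy.stats import gamma as gamma_dist

        kern = gamma_dist.pdf(np.arange(0, 2, 1 / fs), a=2.0, scale=0.01) / fs
        dff = 0.5 * np.convolve(spikes, kern)[: spikes.size]
        mass = kern.sum()  # discrete kernel area
        # all response mass sits within a few samples of each spike, none elsewhere
        assert dff[20:30].sum() == pytest.approx(0.5 * mass, rel=1e-6)
        assert np.abs(dff[35:70]).max() < 1e-6


def test_lowpass_filter_preserves_slow_signal():
    fs = 30.0
    t = np.arange(0, 10, 1 / fs)
    slow = np.sin(2 * np.pi * 0.5 * t)
    fast = 0.5 * np.sin(2 * np.pi * 10.0 * t)
    movie = (slow + fast)[:, None, None] * np.ones((t.size, 2, 2))
    out = fluor.lowpass_filter(movie, fs, cutoff_hz=5.0)
    assert np.sqrt(np.mean((out[:, 0, 0] - slow) ** 2)) < 0.08
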
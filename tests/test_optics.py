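"""Optical model: focal fields, depletion, scanned PSFs, fingerprints."""

import numpy as np
import pytest

from focusism import (
    DepletionModel,
    DetectorGeometry,
    OpticalConfig,
    VolumeMap,
    axial_energy_curve,
    element_sampled_detection,
    fingerprint_of,
    fingerprint_width,
    focal_intensity,
    scanned_psf_stack,
    survival_factor,
    theoretical_shift_vectors,
)
from focusism.metrics import fwhm_of_profile, image_fwhm
from focusism.optics import _focal_radial_intensity, subvoxel_argmax

pytestmark = pytest.mark.filterwarnings(
    "ignore:lateral grid extent is below 3 Airy units")


# --------------------------------------------------------------------------
# configuration contracts
# --------------------------------------------------------------------------

@pytest.mark.parametrize("kwargs", [
    {"lambda_exc": -1.0},
    {"numerical_aperture": 1.6},  # exceeds refractive index 1.518
    {"grid_shape": (2, 127, 127)},  # even axis: no centre voxel
    {"voxel_size": (0.0, 10.0, 10.0)},
])
def test_optical_config_rejects_invalid(kwargs):
    with pytest.raises(ValueError):
        OpticalConfig(**kwargs)


def test_detector_geometry_basics(config_2d):
    det = DetectorGeometry.from_config(config_2d)
    assert det.airy_unit == pytest.approx(1.22 * 669.0 / 1.4)
    assert det.pitch == pytest.approx(1.4 * det.airy_unit / 5)
    # flat index is a bijection [-2,2]^2 -> [0,24] with centre at 12
    seen = {det.flat_index(n, m) for n in range(-2, 3) for m in range(-2, 3)}
    assert seen == set(range(25))
    assert det.flat_index(0, 0) == 12
    with pytest.raises(ValueError):
        det.flat_index(3, 0)
    with pytest.raises(ValueError):
        DetectorGeometry(airy_unit=583.0, fill_factor=0.0)


def test_volume_map_contracts(config_2d):
    with pytest.raises(ValueError):
        VolumeMap(np.array([[-1.0]]), "excitation")
    with pytest.raises(ValueError):
        VolumeMap(np.array([[2.0]]), "survival")
    with pytest.raises(ValueError):
        VolumeMap(np.ones((2, 2)), "nonsense")


# --------------------------------------------------------------------------
# focal fields
# --------------------------------------------------------------------------

@pytest.mark.parametrize("method", ["debye", "vectorial", "analytic"])
def test_vortex_on_axis_null(config_2d, method):
    vol = focal_intensity(config_2d, "vortex_sted", method=method)
    assert vol.values[tuple(config_2d.center_index)] == 0.0
    assert vol.values.max() == pytest.approx(1.0)


@pytest.mark.parametrize("method", ["debye", "vectorial", "analytic"])
def test_excitation_peaks_on_axis_with_diffraction_fwhm(config_2d, method):
    vol = focal_intensity(config_2d, "gaussian_excitation", method=method)
    assert np.unravel_index(np.argmax(vol.values), vol.values.shape) \
        == config_2d.center_index
    fwhm = image_fwhm(vol.values[0], config_2d.voxel_size[1])
    expected = 0.51 * config_2d.lambda_exc / config_2d.numerical_aperture
    assert abs(fwhm - expected) / expected < 0.15


def test_debye_grid_matches_dense_quadrature(config_2d):
    """The gridded field agrees with a denser, finer radial quadrature."""
    coarse = focal_intensity(config_2d, "gaussian_excitation").values[0]
    r = np.arange(0, 640, 1.0)
    dense = _focal_radial_intensity(config_2d.lambda_exc, 1.4, 1.518, r,
                                    np.array([0.0]), 0, n_theta=768)[0]
    dense /= dense.max()
    mid = config_2d.center_index[1]
    profile = coarse[mid, mid:mid + 60]
    radii = np.arange(60) * 10.0
    assert np.allclose(profile, np.interp(radii, r, dense), atol=2e-3)


def test_detection_first_zero_at_airy_radius():
    """Scalar detection PSF: brute-force radial scan locates the first
    minimum at 0.61 lambda / NA within one voxel."""
    cfg = OpticalConfig(grid_shape=(1, 127, 127))
    vol = focal_intensity(cfg, "detection").values[0]
    mid = cfg.center_index[1]
    profile = vol[mid, mid:]
    d = np.diff(profile)
    first_min = np.flatnonzero((d[:-1] < 0) & (d[1:] >= 0))[0] + 1
    expected = 0.61 * cfg.lambda_det / cfg.numerical_aperture
    assert abs(first_min * 10.0 - expected) <= 10.0


def test_unknown_beam_and_method_rejected(config_2d):
    with pytest.raises(ValueError, match="beam"):
        focal_intensity(config_2d, "bessel")
    with pytest.raises(ValueError, match="method"):
        focal_intensity(config_2d, "detection", method="magic")


def test_small_grid_warns():
    cfg = OpticalConfig(grid_shape=(1, 63, 63))  # 0.63 um < 3 AU
    with pytest.warns(UserWarning, match="Airy"):
        focal_intensity(cfg, "detection", method="analytic")


# --------------------------------------------------------------------------
# depletion
# --------------------------------------------------------------------------

def test_survival_identity_without_depletion(config_2d):
    dough = focal_intensity(config_2d, "vortex_sted", method="analytic")
    eta = survival_factor(DepletionModel(0.0), dough)
    assert np.all(eta.values == 1.0)


def test_survival_closed_form_at_crest():
    """At the doughnut crest (d = 1) the survival equals the closed form
    (1 - e^{-(1+s)T/tau})/(1+s) + e^{-(1+s)T/tau}; frozen from an exact
    high-precision evaluation at s = 300, tau = 3.5 ns, T = 1 ns."""
    model = DepletionModel(300.0, 3.5, 1.0)
    dough = VolumeMap(np.array([[[1.0]]]), "doughnut")
    eta = survival_factor(model, dough).values[0, 0, 0]
    assert eta == pytest.approx(0.0033222591362126246, abs=1e-15)


def test_survival_bounds_and_monotonicity(config_2d):
    dough = focal_intensity(config_2d, "vortex_sted", method="analytic")
    previous = None
    for s in (0.0, 10.0, 30.0, 300.0):
        eta = survival_factor(DepletionModel(s), dough).values
        assert eta.min() >= 0.0 and eta.max() <= 1.0
        assert eta[tuple(config_2d.center_index)] == 1.0  # on-axis null
        if previous is not None:
            assert np.all(eta <= previous + 1e-12)
        previous = eta
    with pytest.raises(ValueError, match="unit maximum"):
        survival_factor(DepletionModel(10.0),
                        VolumeMap(np.array([[[2.0]]]), "doughnut"))


# --------------------------------------------------------------------------
# scanned PSF stack
# --------------------------------------------------------------------------

def test_pinhole_narrowing(stack_confocal):
    """The central-element PSF is no wider than the open-pinhole sum."""
    central = stack_confocal.volumes[12, 0]
    open_psf = stack_confocal.channel_sum()[0]
    assert image_fwhm(central, 10.0) <= image_fwhm(open_psf, 10.0)


def test_sted_psfs_colocated(stack_sted300):
    """At saturation 300 every element's PSF peaks at the scan origin."""
    center = np.array(stack_sted300.config.center_index[1:])
    for c in range(25):
        peak = np.unravel_index(np.argmax(stack_sted300.volumes[c, 0]),
                                stack_sted300.volumes[c, 0].shape)
        assert np.all(np.abs(np.array(peak) - center) <= 1)


def test_channel_sum_equals_full_window(config_2d, detector, stack_confocal):
    """Summing the per-element PSFs reproduces the PSF of the whole-array
    aperture (the indicators tile at fill factor 1)."""
    from focusism.optics import element_indicators

    h_det = focal_intensity(config_2d, "detection", method="analytic").values
    h_exc = focal_intensity(config_2d, "gaussian_excitation",
                            method="analytic").values
    full_window = element_indicators(config_2d, detector).sum(axis=0)
    f_det = np.fft.rfft2(np.fft.ifftshift(h_det[0]))
    f_win = np.fft.rfft2(np.fft.ifftshift(full_window))
    det_map = np.fft.fftshift(np.fft.irfft2(f_det * f_win, s=full_window.shape))
    expected = h_exc[0] * np.clip(det_map, 0, None)
    total = stack_confocal.channel_sum()[0]
    assert np.allclose(total, expected, atol=1e-5 * expected.max())


def test_detector_footprint_must_fit():
    cfg = OpticalConfig(grid_shape=(1, 33, 33))  # 330 nm < array footprint
    det = DetectorGeometry.from_config(cfg)
    with pytest.raises(ValueError, match="footprint"):
        scanned_psf_stack(cfg, det, method="analytic")


# --------------------------------------------------------------------------
# shift vectors
# --------------------------------------------------------------------------

def test_half_displacement_rule_for_matched_gaussians():
    """Zero Stokes shift, point-like elements, no depletion: the PSF peak
    of each element sits at half the element displacement (within 2%)."""
    cfg = OpticalConfig(lambda_det=646.0, grid_shape=(1, 127, 127))
    det = DetectorGeometry(airy_unit=1.22 * 646.0 / 1.4, fill_factor=0.02)
    stack = scanned_psf_stack(cfg, det, DepletionModel(0.0),
                              method="analytic")
    mu = theoretical_shift_vectors(stack, plane=0)
    displacement = det.element_centers() / cfg.voxel_size[1]
    for c in range(25):
        d = np.linalg.norm(displacement[c])
        if d == 0:
            continue
        assert mu.magnitudes()[c] == pytest.approx(d / 2, rel=0.02)


def test_shift_vectors_antisymmetric(stack_confocal):
    mu = theoretical_shift_vectors(stack_confocal, plane=0)
    flipped = mu.shifts.reshape(5, 5, 2)[::-1, ::-1].reshape(25, 2)
    assert np.allclose(mu.shifts, -flipped, atol=0.2)


def test_shift_vectors_vanish_at_high_depletion(stack_sted300):
    mu = theoretical_shift_vectors(stack_sted300, plane=0)
    assert mu.magnitudes().max() < 0.5


def test_shift_vectors_shrink_with_depletion(config_2d, detector,
                                             stack_confocal, stack_sted300):
    mags = [theoretical_shift_vectors(stack_confocal, 0).magnitudes()]
    for s in (10.0, 30.0):
        st = scanned_psf_stack(config_2d, detector, DepletionModel(s),
                               method="analytic")
        mags.append(theoretical_shift_vectors(st, 0).magnitudes())
    mags.append(theoretical_shift_vectors(stack_sted300, 0).magnitudes())
    for a, b in zip(mags, mags[1:]):
        assert np.all(b <= a + 1e-6)


def test_flat_psf_argmax_undefined():
    with pytest.raises(ValueError, match="flat"):
        subvoxel_argmax(np.ones((5, 5)))


# --------------------------------------------------------------------------
# fingerprints
# --------------------------------------------------------------------------

def test_fingerprint_of_single_channel_dataset():
    counts = np.zeros((4, 4, 25), dtype=np.int64)
    counts[..., 12] = 3
    f = fingerprint_of(counts)
    assert f.values[2, 2] == 48
    assert f.total == 48
    assert np.count_nonzero(f.values) == 1


def test_fingerprint_converges_to_detection(config_2d, detector,
                                            stack_sted300):
    """At saturation 300 the fingerprint approaches the element-integrated
    detection PSF (unit-sum normalized L2 discrepancy <= 0.05)."""
    f = fingerprint_of(stack_sted300, plane=0)
    d = element_sampled_detection(config_2d, detector, method="analytic")
    assert np.linalg.norm(f.normalized().ravel()
                          - d.normalized().ravel()) <= 0.05


def test_fingerprint_width_shrinks_with_depletion(stack_confocal,
                                                  stack_sted300):
    w0 = fingerprint_width(fingerprint_of(stack_confocal, plane=0))
    w300 = fingerprint_width(fingerprint_of(stack_sted300, plane=0))
    assert w300 < w0


# --------------------------------------------------------------------------
# axial energy curves
# --------------------------------------------------------------------------

def test_axial_energy_of_uniform_volume():
    curve = axial_energy_curve(np.ones((5, 127, 127)))
    assert np.all(curve == 127 ** 2)
    with pytest.raises(ValueError):
        axial_energy_curve(np.ones((2, 8, 8)))


def test_closed_pinhole_sections_better_axially(stack_3d_confocal):
    """E(z) of the open-pinhole PSF is axially wider than the
    central-element (closed pinhole) PSF."""
    open_curve = axial_energy_curve(stack_3d_confocal.channel_sum())
    central_curve = axial_energy_curve(stack_3d_confocal.volumes[12])
    dz = stack_3d_confocal.config.voxel_size[0]
    assert fwhm_of_profile(open_curve, dz) > fwhm_of_profile(central_curve, dz)
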
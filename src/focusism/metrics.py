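"""Evaluation metrics: bead Gaussian fits, resolution/signal gains, MTF,
radial spectra and axial-fingerprint ratios.

These are the quantities used to compare reconstructions: the FWHM and peak
of isolated fluorescent beads fitted to a 2D Gaussian, the resolution gain
(ratio of mean bead FWHMs) and signal gain (ratio of mean bead peaks)
between two reconstructions of the same field, radially averaged modulation
transfer functions, and the outer-to-centre fingerprint intensity ratio
that tracks defocus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit

from .optics import Fingerprint

__all__ = ["BeadFit", "BeadFitResult", "fit_beads", "gains", "mtf",
           "otf_cutoff", "fwhm_of_profile", "image_fwhm",
           "fingerprint_outer_center_ratio", "radial_power_spectrum",
           "frequency_contrast"]

_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


# --------------------------------------------------------------------------
# bead fitting
# --------------------------------------------------------------------------

@dataclass
class BeadFit:
    center: tuple[float, float]  # (y, x) px
    fwhm: float  # nm
    peak: float  # counts above offset
    success: bool


@dataclass
class BeadFitResult:
    fits: list = field(default_factory=list)

    @property
    def successful(self) -> list:
        return [f for f in self.fits if f.success]

    def _summary(self, attr: str) -> tuple[float, float]:
        vals = np.array([getattr(f, attr) for f in self.successful])
        if len(vals) == 0:
            raise ValueError("no successful bead fits")
        sem = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
        return float(vals.mean()), float(sem)

    @property
    def fwhm_mean_sem(self) -> tuple[float, float]:
        return self._summary("fwhm")

    @property
    def peak_mean_sem(self) -> tuple[float, float]:
        return self._summary("peak")


def _gauss2d(coords, amp, cy, cx, sigma, offset):
    y, x = coords
    return (amp * np.exp(-((y - cy) ** 2 + (x - cx) ** 2)
                         / (2.0 * sigma ** 2)) + offset).ravel()


def fit_beads(image: np.ndarray, pixel_size: float,
              threshold: float | None = None,
              expected_fwhm: float | None = None,
              threshold_factor: float = 5.0) -> BeadFitResult:
    """Detect isolated spots and fit each to a 2D Gaussian plus offset.

    Local maxima above ``threshold`` (default ``threshold_factor`` times
    the image median, or the 90th percentile if the median is zero) are
    fitted inside a window of about seven expected FWHMs.  A fit is flagged
    unsuccessful when the centre leaves the window, the FWHM exceeds the
    window, or the amplitude does not rise above the offset.
    """
    img = np.asarray(image, dtype=float)
    if threshold is None:
        med = np.median(img)
        threshold = threshold_factor * med if med > 0 \
            else float(np.percentile(img, 90))
    if expected_fwhm is None:
        expected_fwhm = 10.0 * pixel_size
    # half-window of ~3.5 expected FWHMs, clamped so small fields keep
    # usable fit regions; windows are clipped at the image borders
    win = max(int(round(3.5 * expected_fwhm / pixel_size)), 4)
    win = min(win, (min(image.shape) - 1) // 4)

    sep = max(3, int(round(1.5 * expected_fwhm / pixel_size)))
    footprint = ndimage.maximum_filter(img, size=2 * sep + 1)
    peaks = np.argwhere((img == footprint) & (img > threshold))
    if len(peaks) == 0:
        raise ValueError("no bead detections above the threshold")

    result = BeadFitResult()
    for py, px in peaks:
        y0, x0 = max(0, py - win), max(0, px - win)
        y1 = min(img.shape[0], py + win + 1)
        x1 = min(img.shape[1], px + win + 1)
        window = img[y0:y1, x0:x1]
        yy, xx = np.mgrid[0:y1 - y0, 0:x1 - x0].astype(float)
        p0 = (window.max() - window.min(), float(py - y0), float(px - x0),
              expected_fwhm / _FWHM / pixel_size, window.min())
        try:
            popt, _ = curve_fit(_gauss2d, (yy, xx), window.ravel(), p0=p0,
                                maxfev=4000)
        except RuntimeError:
            result.fits.append(BeadFit((float(py), float(px)), 0.0, 0.0,
                                       False))
            continue
        amp, cy, cx, sigma, offset = popt
        sigma = abs(sigma)
        fwhm_nm = _FWHM * sigma * pixel_size
        ok = (0 <= cy <= y1 - y0 - 1 and 0 <= cx <= x1 - x0 - 1
              and fwhm_nm <= (2 * win + 1) * pixel_size
              and amp > 0)  # peak must rise above the fitted offset
        result.fits.append(BeadFit((y0 + cy, x0 + cx), fwhm_nm, amp,
                                   bool(ok)))
    return result


def gains(result_open: BeadFitResult,
          result_ism: BeadFitResult) -> dict:
    """Resolution and signal gain of an ISM reconstruction over the
    open-pinhole image of the same field.

    resolution gain = mean FWHM(open) / mean FWHM(ISM);
    signal gain = mean peak(ISM) / mean peak(open).  Standard errors are
    propagated in quadrature on the ratios.
    """
    fw_o, se_fw_o = result_open.fwhm_mean_sem
    fw_i, se_fw_i = result_ism.fwhm_mean_sem
    pk_o, se_pk_o = result_open.peak_mean_sem
    pk_i, se_pk_i = result_ism.peak_mean_sem
    if fw_i == 0 or pk_o == 0:
        raise ValueError("zero denominator in gain computation")
    res_gain = fw_o / fw_i
    sig_gain = pk_i / pk_o
    res_err = res_gain * np.hypot(se_fw_o / fw_o if fw_o else 0.0,
                                  se_fw_i / fw_i)
    sig_err = sig_gain * np.hypot(se_pk_i / pk_i if pk_i else 0.0,
                                  se_pk_o / pk_o)
    return {"resolution_gain": float(res_gain),
            "resolution_gain_err": float(res_err),
            "signal_gain": float(sig_gain),
            "signal_gain_err": float(sig_err)}


# --------------------------------------------------------------------------
# frequency-domain metrics
# --------------------------------------------------------------------------

def _radial_average(spectrum: np.ndarray) -> np.ndarray:
    ny, nx = spectrum.shape
    fy = np.arange(ny) - ny // 2
    fx = np.arange(nx) - nx // 2
    radii = np.round(np.hypot(fy[:, None], fx[None, :])).astype(int)
    n_rings = min(ny, nx) // 2 + 1
    sums = np.bincount(radii.ravel(), weights=spectrum.ravel(),
                       minlength=n_rings)[:n_rings]
    counts = np.bincount(radii.ravel(), minlength=n_rings)[:n_rings]
    return sums / np.maximum(counts, 1)


def mtf(psf: np.ndarray, pixel_size: float = 1.0):
    """Radially averaged modulation transfer function of a centred PSF.

    Returns ``(frequencies, mtf)`` with frequencies in cycles/nm and the
    curve normalized to 1 at zero frequency.
    """
    p = np.asarray(psf, dtype=float)
    spectrum = np.abs(np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(p))))
    curve = _radial_average(spectrum)
    if curve[0] == 0:
        raise ValueError("PSF has zero total mass")
    curve = curve / curve[0]
    n = min(p.shape)
    freqs = np.arange(len(curve)) / (n * pixel_size)
    return freqs, curve


def otf_cutoff(psf: np.ndarray, pixel_size: float,
               threshold: float = 1e-3) -> float:
    """First radial frequency (cycles/nm) where the MTF falls below
    ``threshold``; linearly interpolated between rings."""
    freqs, curve = mtf(psf, pixel_size)
    below = np.flatnonzero(curve < threshold)
    if len(below) == 0:
        return float(freqs[-1])
    i = below[0]
    if i == 0:
        return 0.0
    y0, y1 = curve[i - 1], curve[i]
    t = (y0 - threshold) / (y0 - y1) if y0 != y1 else 0.0
    return float(freqs[i - 1] + t * (freqs[i] - freqs[i - 1]))


def otf_support_edge(psf: np.ndarray, pixel_size: float,
                     fit_band: tuple[float, float] = (1e-3, 5e-2),
                     n_scan: int = 600) -> float:
    """Band-limit (cycles/nm) of a PSF by power-law edge extrapolation.

    A hard threshold crossing underestimates the support of OTFs whose
    edge falls faster than linearly (a point-pinhole confocal OTF
    vanishes as the fourth power of the distance to its cutoff), so the
    cutoff is instead estimated by fitting ``MTF = A (f_c - f)^p`` on the
    shoulder rings where the MTF lies inside ``fit_band`` — well above
    any numerical floor — and scanning ``f_c`` for the best log-domain
    least-squares fit.  The PSF should be windowed (e.g. Blackman) to
    suppress truncation leakage.
    """
    freqs, curve = mtf(psf, pixel_size)
    hi_idx = np.flatnonzero(curve < fit_band[1])
    lo_idx = np.flatnonzero(curve < fit_band[0])
    if len(hi_idx) == 0 or len(lo_idx) == 0 or lo_idx[0] - hi_idx[0] < 4:
        raise ValueError("MTF shoulder is unresolved; use a denser grid")
    fs = freqs[hi_idx[0]:lo_idx[0]]
    ms = np.log(curve[hi_idx[0]:lo_idx[0]])
    best_fc, best_res = fs[-1], np.inf
    for fc in np.linspace(fs[-1] + 1e-9, fs[-1] + 2 * (fs[-1] - fs[0]),
                          n_scan):
        x = np.log(fc - fs)
        design = np.column_stack([x, np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(design, ms, rcond=None)
        res = float(((design @ coef - ms) ** 2).sum())
        if res < best_res:
            best_fc, best_res = fc, res
    return float(best_fc)


def fwhm_of_profile(profile: np.ndarray, spacing: float = 1.0) -> float:
    """FWHM of a single-peaked 1D profile by linear interpolation at the
    half-maximum crossings."""
    p = np.asarray(profile, dtype=float)
    peak = p.max()
    if peak <= 0:
        raise ValueError("profile has no positive peak")
    half = peak / 2.0
    i_max = int(np.argmax(p))

    left = None
    for i in range(i_max - 1, -1, -1):
        if p[i] < half:
            t = (p[i + 1] - half) / (p[i + 1] - p[i])
            left = (i + 1) - t
            break
    right = None
    for i in range(i_max + 1, len(p)):
        if p[i] < half:
            t = (p[i - 1] - half) / (p[i - 1] - p[i])
            right = (i - 1) + t
            break
    if left is None or right is None:
        raise ValueError("profile does not fall below half maximum")
    return float((right - left) * spacing)


def image_fwhm(image: np.ndarray, pixel_size: float = 1.0) -> float:
    """FWHM of a centred, peaked 2D image from its central row/column mean."""
    img = np.asarray(image, dtype=float)
    cy, cx = np.unravel_index(np.argmax(img), img.shape)
    fw_y = fwhm_of_profile(img[:, cx], pixel_size)
    fw_x = fwhm_of_profile(img[cy, :], pixel_size)
    return float((fw_y + fw_x) / 2.0)


# --------------------------------------------------------------------------
# fingerprint and spectral contrast diagnostics
# --------------------------------------------------------------------------

def fingerprint_outer_center_ratio(fingerprints) -> np.ndarray:
    """Outer-frame-to-centre intensity ratio R = sum(outer) / f(0, 0) for a
    sequence of per-plane fingerprints; grows with defocus."""
    ratios = []
    for f in fingerprints:
        vals = f.values if isinstance(f, Fingerprint) else np.asarray(f,
                                                                      dtype=float)
        if vals.shape != (5, 5):
            raise ValueError("fingerprints must be 5x5")
        center = vals[2, 2]
        if center == 0:
            raise ValueError("central fingerprint element is zero")
        outer = vals.sum() - vals[1:4, 1:4].sum()
        ratios.append(outer / center)
    return np.asarray(ratios)


def radial_power_spectrum(image: np.ndarray, pixel_size: float = 1.0):
    """Radially averaged power spectrum; returns (frequencies, power)."""
    img = np.asarray(image, dtype=float)
    spectrum = np.abs(np.fft.fftshift(np.fft.fft2(img - img.mean()))) ** 2
    curve = _radial_average(spectrum)
    n = min(img.shape)
    freqs = np.arange(len(curve)) / (n * pixel_size)
    return freqs, curve


def frequency_contrast(image: np.ndarray, split_fraction: float = 0.25,
                       pixel_size: float = 1.0) -> float:
    """High-to-low frequency energy ratio of the radial power spectrum,
    split at ``split_fraction`` of the Nyquist frequency."""
    freqs, power = radial_power_spectrum(image, pixel_size)
    nyquist = freqs[-1]
    split = split_fraction * nyquist
    low = power[(freqs > 0) & (freqs <= split)].sum()
    high = power[freqs > split].sum()
    if low == 0:
        raise ValueError("no low-frequency energy")
    return float(high / low)
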
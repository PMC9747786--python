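"""Adaptive pixel reassignment (APR).

The 25 scanned images of an ISM dataset are mutually shifted copies of the
same object, displaced by the shift vectors ``mu(x_d)``.  APR estimates the
shift of every scanned image relative to the central element by phase
correlation, translates each image back by its shift, and sums the
registered images into the ISM reconstruction.  Summing the raw images
instead yields the conventional open-pinhole image.

Sign convention: ``ShiftField.shifts[c]`` is the displacement of channel
``c``'s structure relative to the reference (a channel identical to the
reference but rolled by ``(+2, -3)`` has shift ``(+2, -3)``); registration
therefore translates each channel by the negated shift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import fourier_shift
from skimage.registration import phase_cross_correlation

from .dataset import ISMDataset
from .optics import CENTER_CHANNEL, fingerprint_of

__all__ = ["ShiftField", "APRResult", "estimate_shifts", "reassign",
           "sum_channels"]


@dataclass
class ShiftField:
    """25 per-element shift vectors (dy, dx) in scan-pixel units."""

    shifts: np.ndarray
    reference: int = CENTER_CHANNEL
    upsampling: int | None = None
    regularized: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        if self.shifts.shape != (25, 2):
            raise ValueError("shift field must be shaped (25, 2)")
        if not np.all(np.isfinite(self.shifts)):
            raise ValueError("shift vectors must be finite")
        if np.any(np.abs(self.shifts[self.reference]) > 1e-9):
            raise ValueError("reference-element shift must be zero")

    def magnitudes(self) -> np.ndarray:
        return np.linalg.norm(self.shifts, axis=1)

    @classmethod
    def zero(cls) -> "ShiftField":
        return cls(np.zeros((25, 2)))


@dataclass
class APRResult:
    """Registered dataset plus the ISM and open-pinhole reconstructions."""

    registered: ISMDataset
    ism_image: np.ndarray
    open_image: np.ndarray
    shift_field: ShiftField


def sum_channels(dataset: ISMDataset | np.ndarray) -> np.ndarray:
    """Open-pinhole (conventional) image: the sum over the channel axis."""
    counts = np.asarray(getattr(dataset, "counts", dataset))
    return counts.sum(axis=-1, dtype=np.float64)


def _select_plane(dataset: ISMDataset, plane: int | None) -> np.ndarray:
    if not dataset.is_3d:
        return dataset.counts
    if plane is None:  # brightest plane carries the most registration signal
        plane = int(np.argmax(dataset.counts.sum(axis=(1, 2, 3))))
    return dataset.counts[plane]


def estimate_shifts(dataset: ISMDataset, upsampling: int = 20,
                    regularize: bool = False,
                    low_signal_fraction: float = 0.05,
                    plane: int | None = None,
                    normalization: str | None = None) -> ShiftField:
    """Per-element shift vectors by correlation against the central image.

    Each scanned image is compared with the central element's image; the
    correlation peak is refined to ``1/upsampling`` pixel by local Fourier
    upsampling.  ``normalization=None`` (default) uses the plain
    cross-correlation, which is robust for the smooth, band-limited images
    a scanning microscope produces; ``"phase"`` whitens the cross-power
    spectrum by its magnitude instead.  With
    ``regularize``, elements whose fingerprint value falls below
    ``low_signal_fraction`` of the maximum get their shift replaced by a
    least-squares linear (affine in the element indices) model fitted on the
    high-signal elements.  All-zero channels are always replaced this way.
    """
    if upsampling < 1:
        raise ValueError("upsampling must be >= 1")
    counts = _select_plane(dataset, plane).astype(np.float64)
    ref = counts[..., CENTER_CHANNEL]
    if ref.sum() == 0:
        raise ValueError("central-element image is empty")

    finger = fingerprint_of(dataset).values.ravel()
    low = finger < low_signal_fraction * finger.max()

    shifts = np.zeros((25, 2))
    undefined = np.zeros(25, dtype=bool)
    for c in range(25):
        if c == CENTER_CHANNEL:
            continue
        img = counts[..., c]
        if img.sum() == 0:
            undefined[c] = True
            continue
        est, _, _ = phase_cross_correlation(ref, img,
                                            upsample_factor=upsampling,
                                            normalization=normalization)
        # phase_cross_correlation returns the registration shift; the
        # structure displacement is its negative
        shifts[c] = -est

    if undefined.any():
        warnings.warn(f"{int(undefined.sum())} all-zero channel(s); shifts "
                      "replaced by the regularized linear model", stacklevel=2)
    replace = undefined.copy()
    if regularize:
        replace |= low
    replace[CENTER_CHANNEL] = False
    if replace.any():
        nm = np.array([(c // 5 - 2, c % 5 - 2) for c in range(25)], dtype=float)
        design = np.column_stack([nm, np.ones(25)])
        coef, *_ = np.linalg.lstsq(design[~replace], shifts[~replace],
                                   rcond=None)
        shifts[replace] = (design @ coef)[replace]
        shifts -= shifts[CENTER_CHANNEL]

    return ShiftField(shifts, upsampling=upsampling,
                      regularized=bool(regularize),
                      metadata={"low_signal_fraction": low_signal_fraction})


def _shift_image(image: np.ndarray, shift: np.ndarray) -> np.ndarray:
    """Periodic (Fourier) sub-pixel translation; preserves total mass."""
    if np.all(shift == 0):
        return image.astype(np.float64)
    f = fourier_shift(np.fft.rfft2(image), shift, n=image.shape[-1])
    return np.fft.irfft2(f, s=image.shape)


def reassign(dataset: ISMDataset, shifts: ShiftField,
             crop: int | str = 0) -> APRResult:
    """Register the scanned images and sum them into the ISM image.

    Each channel is translated by the negated shift vector with periodic
    Fourier interpolation, which preserves the per-channel photon count
    exactly; the open-pinhole image is the unshifted channel sum.  ``crop``
    removes a border from both reconstructed images to discard
    wrap-contaminated pixels before measuring metrics (``"auto"`` uses
    ``ceil(max |shift|)``); the default keeps everything, so the ISM and
    open images carry identical total mass.  The registered dataset is
    never cropped.
    """
    counts = dataset.counts.astype(np.float64)
    mags = shifts.magnitudes()
    extent = min(dataset.counts.shape[-3:-1])
    if mags.max() > extent / 4:
        warnings.warn("shift magnitude exceeds a quarter of the image extent;"
                      " likely mis-registration", stacklevel=2)

    registered = np.empty_like(counts)
    for c in range(25):
        ch = counts[..., c]
        if dataset.is_3d:  # lateral shifts applied plane by plane
            registered[..., c] = np.stack(
                [_shift_image(ch[z], -shifts.shifts[c])
                 for z in range(ch.shape[0])])
        else:
            registered[..., c] = _shift_image(ch, -shifts.shifts[c])

    reg = ISMDataset(registered, dataset.pixel_size, dataset.z_spacing,
                     dataset.detector,
                     {**dataset.provenance, "apr": True})
    ism = registered.sum(axis=-1)
    open_img = counts.sum(axis=-1)
    if crop == "auto":
        crop = int(np.ceil(mags.max()))
    if crop > 0:
        sl = (Ellipsis, slice(crop, -crop), slice(crop, -crop))
        ism, open_img = ism[sl], open_img[sl]
    return APRResult(reg, ism, open_img, shifts)
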
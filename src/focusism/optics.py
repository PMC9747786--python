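"""Optical model of a STED-ISM microscope with a 5x5 detector array.

This module simulates the focal intensity distributions of the three beams
involved in a STED image-scanning microscope (Gaussian excitation, detection,
and the vortex depletion beam), the fluorescence survival factor produced by
a pulsed depletion beam, and from these the per-element scanned PSFs
``h(x_s | x_d)`` of the detector array.  Derived quantities -- detector
fingerprints, theoretical shift vectors, and axial energy curves -- feed the
reconstruction modules.

Two field models are available:

``debye``
    Scalar Debye (Richards-Wolf-style) focal integrals with a uniform,
    sqrt(cos(theta))-apodized pupil; azimuthal order 0 for the excitation and
    detection beams, order 1 for the 0-2pi helical-phase-ramp vortex beam.
``analytic``
    Fast Gaussian / doughnut stand-ins with a z-dependent width, adequate for
    exercising the downstream algorithms in tests.

Lengths are nanometres throughout; arrays are ordered ``(z, y, x)`` with the
optical axis at the central voxel of an odd-shaped grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import jv

__all__ = [
    "OpticalConfig",
    "DetectorGeometry",
    "DepletionModel",
    "VolumeMap",
    "PSFStack",
    "Fingerprint",
    "focal_intensity",
    "survival_factor",
    "scanned_psf_stack",
    "theoretical_shift_vectors",
    "fingerprint_of",
    "fingerprint_width",
    "element_sampled_detection",
    "axial_energy_curve",
    "subvoxel_argmax",
]

BEAM_TAGS = ("gaussian_excitation", "detection", "vortex_sted")

#: flat channel index of the central detector element (n, m) = (0, 0)
CENTER_CHANNEL = 12


# --------------------------------------------------------------------------
# configuration types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OpticalConfig:
    """Wavelengths, objective and sampling grid of the simulation.

    Defaults follow a far-red STED-ISM system: excitation at 646 nm,
    detection at 669 nm, depletion at 775 nm, a 1.4 NA oil objective and a
    1.27 um cube sampled with 10 nm voxels.
    """

    lambda_exc: float = 646.0
    lambda_det: float = 669.0
    lambda_sted: float = 775.0
    numerical_aperture: float = 1.4
    refractive_index: float = 1.518
    voxel_size: tuple[float, float, float] = (10.0, 10.0, 10.0)  # (dz, dy, dx)
    grid_shape: tuple[int, int, int] = (127, 127, 127)  # (Nz, Ny, Nx)

    def __post_init__(self) -> None:
        for lam in (self.lambda_exc, self.lambda_det, self.lambda_sted):
            if lam <= 0:
                raise ValueError("wavelengths must be positive")
        if not 0 < self.numerical_aperture < self.refractive_index:
            raise ValueError("need 0 < NA < refractive index")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")
        if any(n < 1 or n % 2 == 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be odd in every axis")

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates (nm) of voxel centres along ``axis`` (0=z)."""
        n = self.grid_shape[axis]
        return (np.arange(n) - (n - 1) / 2.0) * self.voxel_size[axis]

    @property
    def z_coords(self) -> np.ndarray:
        return self.axis_coords(0)

    @property
    def center_index(self) -> tuple[int, int, int]:
        return tuple((n - 1) // 2 for n in self.grid_shape)

    def lateral_radius(self) -> np.ndarray:
        """2D map of the radial distance (nm) from the optical axis."""
        y = self.axis_coords(1)
        x = self.axis_coords(2)
        return np.hypot(y[:, None], x[None, :])


@dataclass(frozen=True)
class DetectorGeometry:
    """Square detector array geometry in Airy units.

    The array has ``n_rows x n_cols`` square elements indexed by
    ``(n, m) in [-2, 2]^2`` (row, column); the flat channel index is
    ``c = n_cols * (n + 2) + (m + 2)``.  ``airy_unit`` is the diameter of
    the Airy disc, ``1.22 * lambda_det / NA``, projected into sample space.
    """

    airy_unit: float
    n_rows: int = 5
    n_cols: int = 5
    side_length_au: float = 1.4
    fill_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.airy_unit <= 0:
            raise ValueError("airy_unit must be positive")
        if not 0 < self.fill_factor <= 1:
            raise ValueError("fill_factor must be in (0, 1]")
        if self.n_rows != self.n_cols or self.n_rows % 2 == 0:
            raise ValueError("detector must be a square, odd-sized array")

    @classmethod
    def from_config(cls, config: OpticalConfig, **kwargs) -> "DetectorGeometry":
        au = 1.22 * config.lambda_det / config.numerical_aperture
        return cls(airy_unit=au, **kwargs)

    @property
    def n_elements(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def pitch(self) -> float:
        """Element pitch in sample-space nm."""
        return self.side_length_au * self.airy_unit / self.n_cols

    @property
    def active_side(self) -> float:
        """Side of the light-sensitive square of one element (nm)."""
        return self.pitch * np.sqrt(self.fill_factor)

    def flat_index(self, n: int, m: int) -> int:
        h = self.n_rows // 2
        if not (-h <= n <= h and -h <= m <= h):
            raise ValueError(f"element index ({n}, {m}) out of range")
        return self.n_cols * (n + h) + (m + h)

    def index_pairs(self) -> np.ndarray:
        """All (n, m) pairs in flat-index order, shape (n_elements, 2)."""
        h = self.n_rows // 2
        nn, mm = np.meshgrid(np.arange(-h, h + 1), np.arange(-h, h + 1),
                             indexing="ij")
        return np.stack([nn.ravel(), mm.ravel()], axis=1)

    def element_centers(self) -> np.ndarray:
        """Element centres (y, x) in sample-space nm, flat-index order."""
        return self.index_pairs() * self.pitch


@dataclass(frozen=True)
class DepletionModel:
    """Pulsed stimulated-emission depletion parameters.

    ``saturation_factor`` is the peak depletion rate in units of the
    spontaneous decay rate, referred to the doughnut crest intensity;
    zero reproduces the confocal case.
    """

    saturation_factor: float = 0.0
    fluorescence_lifetime: float = 3.5  # ns
    sted_pulse_duration: float = 1.0  # ns

    def __post_init__(self) -> None:
        if self.saturation_factor < 0:
            raise ValueError("saturation factor must be >= 0")
        if self.fluorescence_lifetime <= 0:
            raise ValueError("fluorescence lifetime must be positive")
        if self.sted_pulse_duration < 0:
            raise ValueError("pulse duration must be >= 0")


@dataclass
class VolumeMap:
    """A non-negative scalar field on the simulation grid with a role tag."""

    values: np.ndarray
    role: str
    config: OpticalConfig | None = None

    ROLES = ("excitation", "detection", "doughnut", "survival",
             "effective_excitation")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.role not in self.ROLES:
            raise ValueError(f"unknown volume role {self.role!r}")
        if np.any(self.values < 0):
            raise ValueError("volume values must be non-negative")
        if self.role == "survival" and np.any(self.values > 1 + 1e-12):
            raise ValueError("survival values must lie in [0, 1]")


@dataclass
class PSFStack:
    """Per-element scanned PSFs ``h_{n,m}(z, y, x)``, shape (25, Nz, Ny, Nx)."""

    volumes: np.ndarray
    detector: DetectorGeometry
    config: OpticalConfig
    depletion: DepletionModel = field(default_factory=DepletionModel)

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes)
        if self.volumes.ndim != 4 or self.volumes.shape[0] != self.detector.n_elements:
            raise ValueError("PSF stack must be shaped (n_elements, Nz, Ny, Nx)")
        if np.any(self.volumes < 0):
            raise ValueError("PSFs must be non-negative")

    @property
    def n_planes(self) -> int:
        return self.volumes.shape[1]

    @property
    def focal_plane(self) -> int:
        return (self.n_planes - 1) // 2

    def plane(self, z: int) -> np.ndarray:
        """The 25 in-plane PSF images at plane ``z``, shape (25, Ny, Nx)."""
        return self.volumes[:, z]

    def channel_sum(self) -> np.ndarray:
        """Open-pinhole PSF: sum over all detector elements."""
        return self.volumes.sum(axis=0)


@dataclass
class Fingerprint:
    """5x5 photon distribution over the detector array."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[-2:] != (5, 5):
            raise ValueError("fingerprint must be 5x5")
        if np.any(self.values < 0):
            raise ValueError("fingerprint must be non-negative")

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def normalized(self) -> np.ndarray:
        tot = self.total
        if tot == 0:
            raise ValueError("cannot normalize an empty fingerprint")
        return self.values / tot


# --------------------------------------------------------------------------
# focal fields
# --------------------------------------------------------------------------

def _focal_radial_intensity(lam: float, na: float, n_ref: float,
                            r: np.ndarray, z: np.ndarray, order: int,
                            vectorial: bool = False,
                            n_theta: int = 192) -> np.ndarray:
    """Debye focal intensity on a (z, r) grid for azimuthal order ``order``.

    Scalar form (default): the Airy-consistent uniform-pupil integral in
    the normalized pupil coordinate s = sin(t)::

        U(r, z) = int_0^{NA/n} J_order(k r s) e^{i k z sqrt(1 - s^2)} s ds

    with k = 2 pi n_ref / lam; the in-focus order-0 pattern is exactly the
    Airy disc (first zero at 0.61 lambda / NA), matching the Airy-unit
    convention of the detector geometry.  Returns |U|^2.

    The vectorial form is the Richards-Wolf focus of a circularly polarized
    beam (co-rotating with the vortex charge), with the aplanatic
    sqrt(cos t) apodization: three integrals with pupil factors
    (1 + cos t), sin t, (1 - cos t) and Bessel orders ``order``,
    ``order + 1``, ``order + 2``; the intensity is
    |I_a|^2 + 2 |I_b|^2 + |I_c|^2.  It keeps the on-axis null of a charge-1
    vortex but fills the off-axis ring minima that the scalar theory
    predicts as exact zeros.
    """
    k = 2.0 * np.pi * n_ref / lam
    if not vectorial:
        smax = na / n_ref
        s = np.linspace(0.0, smax, n_theta)
        w = np.full(n_theta, smax / (n_theta - 1))
        w[0] *= 0.5
        w[-1] *= 0.5
        ct = np.sqrt(1.0 - s ** 2)
        radial = jv(order, k * np.multiply.outer(r, s)) * (s * w)[None, :]
        phase = np.exp(1j * k * np.multiply.outer(z, ct))
        return np.abs(phase @ radial.T) ** 2
    alpha = np.arcsin(na / n_ref)
    theta = np.linspace(0.0, alpha, n_theta)
    st, ct = np.sin(theta), np.cos(theta)
    w = np.full(n_theta, alpha / (n_theta - 1))
    w[0] *= 0.5
    w[-1] *= 0.5
    apod = np.sqrt(ct) * st * w
    phase = np.exp(1j * k * np.multiply.outer(z, ct))  # (Nz, Nt)
    intensity = 0.0
    for d_order, pupil, mult in ((0, 1.0 + ct, 1.0), (1, st, 2.0),
                                 (2, 1.0 - ct, 1.0)):
        radial = jv(order + d_order, k * np.multiply.outer(r, st)) \
            * (apod * pupil)[None, :]
        intensity = intensity + mult * np.abs(phase @ radial.T) ** 2
    return intensity


def _beam_params(config: OpticalConfig, beam: str) -> tuple[float, int]:
    if beam == "gaussian_excitation":
        return config.lambda_exc, 0
    if beam == "detection":
        return config.lambda_det, 0
    if beam == "vortex_sted":
        return config.lambda_sted, 1
    raise ValueError(f"unknown beam tag {beam!r}; expected one of {BEAM_TAGS}")


def _standin_sigma(config: OpticalConfig, lam: float, order: int) -> float:
    if order == 0:
        # lateral std matching the diffraction-limited FWHM 0.51 lambda/NA
        return 0.51 * lam / config.numerical_aperture \
            / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    # doughnut r^2 exp(-r^2/sigma^2) crests at r = sigma; 0.41 lambda/NA
    # matches the crest radius of the vectorially computed vortex ring
    return 0.41 * lam / config.numerical_aperture


def _standin_widths(config: OpticalConfig, lam: float,
                    order: int) -> tuple[float, np.ndarray]:
    """(sigma0, sigma(z)) of the Gaussian-beam stand-in."""
    sigma0 = _standin_sigma(config, lam, order)
    w0 = 2.0 * sigma0
    z_r = np.pi * w0 ** 2 * config.refractive_index / lam
    sigma_z = sigma0 * np.sqrt(1.0 + (config.z_coords / z_r) ** 2)
    return sigma0, sigma_z


def focal_intensity(config: OpticalConfig, beam: str,
                    method: str = "debye", n_theta: int = 192) -> VolumeMap:
    """Normalized focal intensity of one of the three beams.

    Parameters
    ----------
    beam
        One of ``gaussian_excitation``, ``detection``, ``vortex_sted``.
    method
        ``debye`` for the scalar focal integral, ``vectorial`` for the
        circularly polarized Richards-Wolf focus (fills the unphysical
        off-axis zeros of the scalar vortex), ``analytic`` for the
        Gaussian / doughnut stand-in.

    The returned volume is normalized to unit maximum.  The vortex beam is
    identically zero on the optical axis; the other two peak at the central
    voxel of the focal plane.
    """
    lam, order = _beam_params(config, beam)
    ny, nx = config.grid_shape[1], config.grid_shape[2]
    au = 1.22 * config.lambda_det / config.numerical_aperture
    lateral_extent = min(ny * config.voxel_size[1], nx * config.voxel_size[2])
    if lateral_extent < 3.0 * au:
        warnings.warn(
            "lateral grid extent is below 3 Airy units; the first Airy ring "
            "may be truncated", stacklevel=2)

    r_map = config.lateral_radius()
    z = config.z_coords

    if method in ("debye", "vectorial"):
        dr = min(config.voxel_size[1], config.voxel_size[2]) / 4.0
        r = np.arange(0.0, r_map.max() + 2 * dr, dr)
        prof = _focal_radial_intensity(lam, config.numerical_aperture,
                                       config.refractive_index, r, z, order,
                                       vectorial=(method == "vectorial"),
                                       n_theta=n_theta)
        vol = np.empty(config.grid_shape)
        flat_r = r_map.ravel()
        for iz in range(len(z)):
            vol[iz] = np.interp(flat_r, r, prof[iz]).reshape(ny, nx)
    elif method == "analytic":
        sigma0, sigma_z = _standin_widths(config, lam, order)
        r2 = r_map[None, :, :] ** 2
        s2 = (sigma_z ** 2)[:, None, None]
        if order == 0:
            vol = (sigma0 ** 2 / s2) * np.exp(-r2 / (2.0 * s2))
        else:
            # unit crest at r = sigma(z); per-plane energy kept constant
            vol = (sigma0 ** 2 / s2) * (r2 / s2) * np.exp(1.0 - r2 / s2)
    else:
        raise ValueError(f"unknown field method {method!r}")

    if beam == "vortex_sted":
        # enforce the exact on-axis null of the helical phase ramp
        vol[:, r_map == 0] = 0.0
    vol /= vol.max()
    role = {"gaussian_excitation": "excitation", "detection": "detection",
            "vortex_sted": "doughnut"}[beam]
    return VolumeMap(vol, role, config)


# --------------------------------------------------------------------------
# depletion
# --------------------------------------------------------------------------

def survival_factor(model: DepletionModel, doughnut: VolumeMap) -> VolumeMap:
    """Fraction of fluorescence surviving a rectangular depletion pulse.

    With ``d`` the unit-peak doughnut intensity and ``s`` the saturation
    factor, the excited state decays at rate ``k_F (1 + s d)`` during the
    pulse of duration ``T`` and at ``k_F`` afterwards, so the fluorescence
    yield relative to the undepleted case is::

        eta = (1 - exp(-(1 + s d) T / tau_F)) / (1 + s d)
              + exp(-(1 + s d) T / tau_F)

    ``eta`` is 1 wherever the doughnut is dark (in particular on the optical
    axis), lies in [0, 1], and decreases pointwise with the saturation
    factor.
    """
    d = np.asarray(doughnut.values, dtype=float)
    if np.any(d < 0):
        raise ValueError("doughnut intensity must be non-negative")
    if d.max() > 1 + 1e-9:
        raise ValueError("doughnut must be normalized to unit maximum")
    s = model.saturation_factor
    if s == 0:
        return VolumeMap(np.ones_like(d), "survival", doughnut.config)
    rate = 1.0 + s * d
    decay = np.exp(-rate * model.sted_pulse_duration / model.fluorescence_lifetime)
    eta = (1.0 - decay) / rate + decay
    return VolumeMap(np.clip(eta, 0.0, 1.0), "survival", doughnut.config)


# --------------------------------------------------------------------------
# per-element scanned PSFs
# --------------------------------------------------------------------------

def _element_coverage(coords: np.ndarray, center: float, side: float,
                      step: float) -> np.ndarray:
    """Fraction of each voxel (1D) covered by [center - side/2, center + side/2]."""
    lo, hi = center - side / 2.0, center + side / 2.0
    left = coords - step / 2.0
    right = coords + step / 2.0
    return np.clip((np.minimum(right, hi) - np.maximum(left, lo)) / step, 0.0, 1.0)


def element_indicators(config: OpticalConfig,
                       detector: DetectorGeometry) -> np.ndarray:
    """Active-area indicators of all elements mapped to sample space.

    Returns an array (n_elements, Ny, Nx) of voxel coverage fractions; at
    fill factor 1 the indicators tile the full array footprint exactly.
    """
    y = config.axis_coords(1)
    x = config.axis_coords(2)
    dy, dx = config.voxel_size[1], config.voxel_size[2]
    side = detector.active_side
    centers = detector.element_centers()
    half_extent = detector.n_rows / 2.0 * detector.pitch
    if half_extent > min(abs(y[0]), abs(x[0])) + min(dy, dx) / 2.0:
        raise ValueError("detector footprint exceeds the simulation grid")
    out = np.empty((detector.n_elements, len(y), len(x)))
    for c, (cy, cx) in enumerate(centers):
        out[c] = np.outer(_element_coverage(y, cy, side, dy),
                          _element_coverage(x, cx, side, dx))
    return out


def _periodic_conv2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Periodic 2D convolution with the origin at the array centre."""
    fa = np.fft.rfft2(np.fft.ifftshift(a))
    fb = np.fft.rfft2(np.fft.ifftshift(b))
    return np.fft.fftshift(np.fft.irfft2(fa * fb, s=a.shape))


def scanned_psf_stack(config: OpticalConfig, detector: DetectorGeometry,
                      model: DepletionModel | None = None,
                      method: str = "debye",
                      planes: np.ndarray | slice | None = None) -> PSFStack:
    """Simulate the per-element scanned PSFs ``h_{n,m}``.

    Each element's PSF is the product of the effective (depleted) excitation
    volume with the detection PSF convolved with that element's active-area
    indicator::

        h_{n,m}(x, z) = [h_exc(x, z) eta(x, z)] * (h_det(., z) (*) Pi_{n,m})(x)

    ``planes`` restricts the computation to a subset of z planes (the
    returned stack then has that many planes, in the given order).
    """
    if model is None:
        model = DepletionModel()
    h_exc = focal_intensity(config, "gaussian_excitation", method=method).values
    h_det = focal_intensity(config, "detection", method=method).values
    if model.saturation_factor > 0:
        doughnut = focal_intensity(config, "vortex_sted", method=method)
        eta = survival_factor(model, doughnut).values
        h_eff = h_exc * eta
    else:
        h_eff = h_exc

    indicators = element_indicators(config, detector)
    z_idx = np.arange(config.grid_shape[0])
    if planes is not None:
        z_idx = z_idx[planes] if isinstance(planes, slice) else np.atleast_1d(planes)

    nel = detector.n_elements
    ny, nx = config.grid_shape[1], config.grid_shape[2]
    stack = np.empty((nel, len(z_idx), ny, nx), dtype=np.float32)
    f_ind = [np.fft.rfft2(np.fft.ifftshift(indicators[c])) for c in range(nel)]
    for j, iz in enumerate(z_idx):
        f_det = np.fft.rfft2(np.fft.ifftshift(h_det[iz]))
        for c in range(nel):
            det_map = np.fft.fftshift(
                np.fft.irfft2(f_det * f_ind[c], s=(ny, nx)))
            np.clip(det_map, 0.0, None, out=det_map)
            stack[c, j] = h_eff[iz] * det_map
    return PSFStack(stack, detector, config, model)


# --------------------------------------------------------------------------
# derived quantities
# --------------------------------------------------------------------------

def subvoxel_argmax(image: np.ndarray) -> np.ndarray:
    """Sub-voxel argmax of an N-D array by per-axis parabolic interpolation.

    Ties at the integer stage are broken toward the grid centre.  Raises on
    a flat (all-equal) array, whose argmax is undefined.
    """
    img = np.asarray(image, dtype=float)
    if img.max() == img.min():
        raise ValueError("argmax of a flat array is undefined")
    peak = img.max()
    candidates = np.argwhere(img == peak)
    center = (np.array(img.shape) - 1) / 2.0
    best = candidates[np.argmin(((candidates - center) ** 2).sum(axis=1))]
    pos = best.astype(float)
    for ax in range(img.ndim):
        i = best[ax]
        if 0 < i < img.shape[ax] - 1:
            idx = list(best)
            idx[ax] = slice(i - 1, i + 2)
            y0, y1, y2 = img[tuple(idx)]
            denom = y0 - 2.0 * y1 + y2
            if denom < 0:
                pos[ax] = i + 0.5 * (y0 - y2) / denom
    return pos


def theoretical_shift_vectors(stack: PSFStack, plane: int | None = None):
    """Shift vectors from the argmax of each element's in-plane PSF.

    Returns a :class:`focusism.apr.ShiftField` whose entries are the
    displacement (dy, dx), in scan voxels, of each element's PSF peak
    relative to the central element's; the central element is zero by
    construction.
    """
    from .apr import ShiftField  # deferred: apr depends on dataset/optics

    if plane is None:
        plane = stack.focal_plane
    if not 0 <= plane < stack.n_planes:
        raise ValueError("plane index outside the stack")
    images = stack.plane(plane)
    mu = np.array([subvoxel_argmax(np.asarray(im, dtype=float))
                   for im in images])
    mu -= mu[CENTER_CHANNEL]
    return ShiftField(shifts=mu, upsampling=None,
                      metadata={"source": "theoretical", "plane": int(plane)})


def fingerprint_of(source, plane: int | None = None) -> Fingerprint:
    """Detector fingerprint: the sum of all micro-images.

    ``source`` is either a :class:`PSFStack` (summed over the scan
    coordinates of one plane, default the focal plane) or an ISM dataset
    (summed over every scan point and, if 3D, every plane).
    """
    if isinstance(source, PSFStack):
        if plane is None:
            plane = source.focal_plane
        vals = source.plane(plane).reshape(source.detector.n_elements, -1) \
            .sum(axis=1, dtype=float)
        n = source.detector.n_rows
        return Fingerprint(vals.reshape(n, n))
    counts = np.asarray(getattr(source, "counts", source))
    if counts.shape[-1] != 25:
        raise ValueError("expected a trailing channel axis of length 25")
    vals = counts.reshape(-1, 25).sum(axis=0, dtype=float)
    return Fingerprint(vals.reshape(5, 5))


def fingerprint_width(fingerprint: Fingerprint | np.ndarray) -> float:
    """RMS second-moment radius of a fingerprint, in detector-pitch units."""
    f = fingerprint.values if isinstance(fingerprint, Fingerprint) else np.asarray(fingerprint, dtype=float)
    tot = f.sum()
    if tot <= 0:
        raise ValueError("empty fingerprint")
    n = f.shape[0]
    idx = np.arange(n) - (n - 1) / 2.0
    nn, mm = np.meshgrid(idx, idx, indexing="ij")
    return float(np.sqrt(((nn ** 2 + mm ** 2) * f).sum() / tot))


def element_sampled_detection(config: OpticalConfig,
                              detector: DetectorGeometry,
                              method: str = "debye") -> Fingerprint:
    """In-focus detection PSF integrated over each element's active area.

    This is the fingerprint an infinitely small excitation volume would
    produce -- the ideal-STED limit the measured fingerprint converges to.
    """
    h_det = focal_intensity(config, "detection", method=method).values
    focal = h_det[config.center_index[0]]
    indicators = element_indicators(config, detector)
    vals = (indicators * focal[None]).sum(axis=(1, 2))
    n = detector.n_rows
    return Fingerprint(vals.reshape(n, n))


def axial_energy_curve(volume: np.ndarray) -> np.ndarray:
    """Per-plane energy E(z) of a (Nz, Ny, Nx) stack of images."""
    vol = np.asarray(volume)
    if vol.ndim != 3 or vol.shape[0] < 3:
        raise ValueError("need a stack of at least 3 planes")
    return vol.sum(axis=(1, 2), dtype=float)
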
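"""ISM dataset container, HDF5/TIFF I/O, phantoms and the forward model.

An ISM acquisition is a 4D (or 5D, with z planes) array of photon counts
``i(x_s | x_d)`` indexed by scan position and by the flat detector-channel
index ``c = 5 (n + 2) + (m + 2)``.  The same array can be read as a
collection of 5x5 micro-images (one per scan point) or as 25 scanned images
(one per detector element); both views are provided.

The forward model turns a phantom (bead field or 3D filament network) and a
simulated PSF stack into a synthetic acquisition with Poisson noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import tifffile
from scipy import ndimage

from .optics import DetectorGeometry, Fingerprint, PSFStack, fingerprint_of

__all__ = [
    "ISMDataset",
    "Phantom",
    "generate_phantom",
    "simulate_acquisition",
]

N_CHANNELS = 25
HDF5_DATASET = "/ism"


@dataclass
class ISMDataset:
    """Photon counts shaped ``(Ny, Nx, 25)`` or ``(Z, Ny, Nx, 25)``.

    Raw data are non-negative integers; processed data (e.g. after
    registration) may be real-valued.
    """

    counts: np.ndarray
    pixel_size: tuple[float, float] = (10.0, 10.0)  # (dy, dx) nm
    z_spacing: float | None = None
    detector: DetectorGeometry | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim not in (3, 4):
            raise ValueError("counts must be 3D (2D scan) or 4D (z stack)")
        if self.counts.shape[-1] != N_CHANNELS:
            raise ValueError(
                f"expected {N_CHANNELS} channels, found {self.counts.shape[-1]}")
        if np.issubdtype(self.counts.dtype, np.integer) and np.any(self.counts < 0):
            raise ValueError("raw counts must be non-negative")

    # -- basic queries ------------------------------------------------------

    @property
    def is_3d(self) -> bool:
        return self.counts.ndim == 4

    @property
    def scan_shape(self) -> tuple[int, ...]:
        return self.counts.shape[:-1]

    @property
    def total(self) -> float:
        return float(self.counts.sum(dtype=np.float64))

    def fingerprint(self) -> Fingerprint:
        return fingerprint_of(self)

    @classmethod
    def from_psf_stack(cls, stack: PSFStack) -> "ISMDataset":
        """Treat a simulated PSF stack as a (noiseless, real-valued)
        acquisition of a point source: counts[z, y, x, c] = h_c(z, y, x)."""
        counts = np.moveaxis(np.asarray(stack.volumes, dtype=np.float64), 0, -1)
        if counts.shape[0] == 1:
            counts = counts[0]
        return cls(counts,
                   (stack.config.voxel_size[1], stack.config.voxel_size[2]),
                   stack.config.voxel_size[0] if counts.ndim == 4 else None,
                   stack.detector,
                   {"saturation_factor": stack.depletion.saturation_factor,
                    "source": "psf_stack"})

    def plane(self, z: int) -> "ISMDataset":
        """One z plane as a 2D dataset (a view, not a copy)."""
        if not self.is_3d:
            raise ValueError("dataset is not a z stack")
        return ISMDataset(self.counts[z], self.pixel_size, None,
                          self.detector, dict(self.provenance))

    # -- views --------------------------------------------------------------

    def view(self, mode: str, index) -> np.ndarray:
        """A micro-image (5x5, one scan point) or scanned image (Ny x Nx).

        ``index`` is a scan-position tuple for ``micro_image`` and an
        ``(n, m)`` element pair (or flat channel) for ``scanned_image``.
        """
        if mode == "micro_image":
            point = tuple(np.atleast_1d(index))
            if len(point) != self.counts.ndim - 1:
                raise IndexError("scan index rank does not match the dataset")
            for i, n in zip(point, self.scan_shape):
                if not 0 <= i < n:
                    raise IndexError(f"scan index {point} out of range")
            return self.counts[point].reshape(5, 5)
        if mode == "scanned_image":
            if np.isscalar(index):
                c = int(index)
                if not 0 <= c < N_CHANNELS:
                    raise IndexError(f"channel {c} out of range")
            else:
                n, m = index
                det = self.detector or DetectorGeometry(airy_unit=1.0)
                c = det.flat_index(int(n), int(m))
            return self.counts[..., c]
        raise ValueError(f"unknown view mode {mode!r}")

    def micro_images(self) -> np.ndarray:
        """All micro-images, shape ``scan_shape + (5, 5)``."""
        return self.counts.reshape(self.scan_shape + (5, 5))

    # -- I/O ----------------------------------------------------------------

    def to_hdf5(self, path) -> None:
        """Write to a self-describing HDF5 file (dataset ``/ism``)."""
        with h5py.File(path, "w") as f:
            d = f.create_dataset(HDF5_DATASET, data=self.counts)
            d.attrs["pixel_size_nm"] = self.pixel_size
            if self.z_spacing is not None:
                d.attrs["z_spacing_nm"] = self.z_spacing
            for key, val in self.provenance.items():
                if val is not None:
                    d.attrs[f"prov_{key}"] = val
            if self.detector is not None:
                d.attrs["detector_airy_unit_nm"] = self.detector.airy_unit
                d.attrs["detector_side_au"] = self.detector.side_length_au
                d.attrs["detector_fill_factor"] = self.detector.fill_factor

    @classmethod
    def from_hdf5(cls, path) -> "ISMDataset":
        with h5py.File(path, "r") as f:
            if HDF5_DATASET not in f:
                raise ValueError(f"{path}: missing dataset {HDF5_DATASET}")
            d = f[HDF5_DATASET]
            counts = d[()]
            attrs = dict(d.attrs)
        detector = None
        if "detector_airy_unit_nm" in attrs:
            detector = DetectorGeometry(
                airy_unit=float(attrs["detector_airy_unit_nm"]),
                side_length_au=float(attrs.get("detector_side_au", 1.4)),
                fill_factor=float(attrs.get("detector_fill_factor", 1.0)))
        prov = {k[5:]: v for k, v in attrs.items() if k.startswith("prov_")}
        z_spacing = attrs.get("z_spacing_nm")
        return cls(counts, tuple(attrs.get("pixel_size_nm", (10.0, 10.0))),
                   None if z_spacing is None else float(z_spacing),
                   detector, prov)

    def to_tiff(self, path) -> None:
        """Export channel-first TIFF: (25, Ny, Nx) or (25, Z, Ny, Nx)."""
        tifffile.imwrite(path, np.moveaxis(self.counts, -1, 0))

    @classmethod
    def from_tiff(cls, path, pixel_size=(10.0, 10.0)) -> "ISMDataset":
        """Import a channel-first TIFF; the leading axis must have 25 pages
        in flat-index order ``c = 5 (n + 2) + (m + 2)``."""
        arr = tifffile.imread(path)
        if arr.ndim not in (3, 4) or arr.shape[0] != N_CHANNELS:
            found = arr.shape[0] if arr.ndim >= 1 else 0
            raise ValueError(f"expected {N_CHANNELS} channels, found {found}")
        return cls(np.moveaxis(arr, 0, -1), tuple(pixel_size))


# --------------------------------------------------------------------------
# phantoms
# --------------------------------------------------------------------------

@dataclass
class Phantom:
    """Non-negative emitter brightness per voxel, shape (Nz, Ny, Nx)."""

    volume: np.ndarray
    voxel_size: tuple[float, float, float] = (10.0, 10.0, 10.0)
    beads: list | None = None  # [(z, y, x, brightness, diameter_nm)]

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume, dtype=float)
        if self.volume.ndim == 2:
            self.volume = self.volume[None]
        if self.volume.ndim != 3:
            raise ValueError("phantom volume must be 2D or 3D")
        if np.any(self.volume < 0):
            raise ValueError("phantom brightness must be non-negative")

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            d = f.create_dataset("/phantom", data=self.volume)
            d.attrs["voxel_size_nm"] = self.voxel_size

    @classmethod
    def from_hdf5(cls, path) -> "Phantom":
        with h5py.File(path, "r") as f:
            d = f["/phantom"]
            return cls(d[()], tuple(d.attrs["voxel_size_nm"]))


def _render_bead(volume, center, radius_vox, brightness) -> None:
    """Rasterize a sphere: voxels whose centre lies within the radius."""
    shape = volume.shape
    lo = [max(0, int(np.floor(c - r)) - 1) for c, r in zip(center, radius_vox)]
    hi = [min(n, int(np.ceil(c + r)) + 2) for c, r, n in zip(center, radius_vox, shape)]
    zz, yy, xx = np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)],
                             indexing="ij")
    d2 = sum(((g - c) / max(r, 1e-9)) ** 2
             for g, c, r in zip((zz, yy, xx), center, radius_vox))
    mask = d2 <= 1.0
    if not mask.any():  # bead smaller than a voxel: all mass in one voxel
        idx = tuple(int(round(c)) for c in center)
        volume[idx] += brightness
        return
    sub = volume[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    sub[mask] += brightness / mask.sum()


def generate_phantom(kind: str, params: dict | None = None,
                     seed: int | None = None) -> Phantom:
    """Deterministic synthetic phantom.

    ``beads``
        ``n`` spheres of ``diameter_nm`` at uniform positions inside the
        margins, each carrying unit total brightness (scaled by a uniform
        brightness draw in ``brightness_range``).
    ``filaments3d``
        Smooth 3D random-walk tubes: ``n`` filaments of ``n_steps`` steps of
        ``step_nm``, direction persistence ``persistence`` in [0, 1), axial
        excursions confined to ``z_extent_nm`` (0 keeps every filament in
        the focal plane).
    """
    p = dict(params or {})
    rng = np.random.default_rng(seed)
    shape = tuple(p.pop("grid_shape", (1, 127, 127)))
    if len(shape) == 2:
        shape = (1,) + shape
    voxel = tuple(p.pop("voxel_size", (10.0, 10.0, 10.0)))
    volume = np.zeros(shape)

    if kind == "beads":
        n = int(p.pop("n", 50))
        diameter = float(p.pop("diameter_nm", 23.0))
        brange = p.pop("brightness_range", (1.0, 1.0))
        margin_nm = float(p.pop("margin_nm", 2.0 * diameter))
        radius_vox = [diameter / 2.0 / v for v in voxel]
        beads = []
        for _ in range(n):
            frac = rng.uniform(size=3)
            center = []
            for ax, f in enumerate(frac):
                m = margin_nm / voxel[ax]
                lo = min(m, (shape[ax] - 1) / 2.0)
                center.append(lo + f * max(shape[ax] - 1 - 2 * lo, 0.0))
            if shape[0] == 1:
                center[0] = 0.0
            b = rng.uniform(*brange)
            if any(c - r > s - 1 or c + r < 0 for c, r, s in
                   zip(center, radius_vox, shape)):
                raise ValueError("bead extends outside the phantom grid")
            _render_bead(volume, center, radius_vox, b)
            beads.append((center[0] * voxel[0], center[1] * voxel[1],
                          center[2] * voxel[2], b, diameter))
        return Phantom(volume, voxel, beads)

    if kind == "filaments3d":
        n = int(p.pop("n", 10))
        n_steps = int(p.pop("n_steps", 400))
        step_nm = float(p.pop("step_nm", 15.0))
        persistence = float(p.pop("persistence", 0.9))
        z_extent = float(p.pop("z_extent_nm",
                               (shape[0] - 1) * voxel[0]))
        brightness = float(p.pop("brightness", 1.0))
        zc = (shape[0] - 1) / 2.0
        for _ in range(n):
            pos = np.array([zc * voxel[0],
                            rng.uniform(0, (shape[1] - 1) * voxel[1]),
                            rng.uniform(0, (shape[2] - 1) * voxel[2])])
            direction = rng.normal(size=3)
            direction[0] *= 0.3  # filaments run mostly laterally
            direction /= np.linalg.norm(direction)
            for _ in range(n_steps):
                kick = rng.normal(size=3)
                kick /= np.linalg.norm(kick)
                direction = persistence * direction + (1 - persistence) * kick
                direction /= np.linalg.norm(direction)
                pos = pos + step_nm * direction
                # confine axially, reflect laterally
                zlim = z_extent / 2.0
                pos[0] = np.clip(pos[0], zc * voxel[0] - zlim,
                                 zc * voxel[0] + zlim)
                for ax in (1, 2):
                    hi = (shape[ax] - 1) * voxel[ax]
                    if pos[ax] < 0 or pos[ax] > hi:
                        pos[ax] = np.clip(pos[ax], 0, hi)
                        direction[ax] *= -1
                idx = tuple(int(round(pos[ax] / voxel[ax])) for ax in range(3))
                idx = tuple(np.clip(i, 0, s - 1) for i, s in zip(idx, shape))
                volume[idx] += brightness
        if shape[1] >= 3 and shape[2] >= 3:
            volume = ndimage.gaussian_filter(volume, sigma=(0, 0.7, 0.7))
        return Phantom(volume, voxel)

    raise ValueError(f"unknown phantom kind {kind!r}")


# --------------------------------------------------------------------------
# forward model
# --------------------------------------------------------------------------

def _periodic_conv2(kernel: np.ndarray, image: np.ndarray) -> np.ndarray:
    fk = np.fft.rfft2(np.fft.ifftshift(kernel))
    fi = np.fft.rfft2(image)
    return np.fft.irfft2(fk * fi, s=image.shape)


def simulate_acquisition(phantom: Phantom, stack: PSFStack,
                         photon_budget: float = 100.0,
                         dark_rate: float = 0.0,
                         seed: int | None = None,
                         noiseless: bool = False,
                         pad: int = 0) -> ISMDataset:
    """Synthetic ISM acquisition of ``phantom`` through ``stack``.

    The expected counts are the plane-wise periodic convolution of the
    phantom with each element's PSF, summed over planes and scaled so the
    brightest pixel of the channel-summed image equals ``photon_budget``;
    ``dark_rate`` adds a flat per-pixel, per-element expectation.  Counts
    are Poisson draws unless ``noiseless``.

    ``pad`` zero-pads the phantom laterally before the FFT convolution (and
    crops afterwards) to suppress wrap-around from mass near the edges; it
    is recorded in the provenance metadata.
    """
    if photon_budget < 0:
        raise ValueError("photon budget must be non-negative")
    vol = phantom.volume
    if vol.shape[0] != stack.n_planes:
        raise ValueError(
            f"phantom has {vol.shape[0]} planes but the PSF stack has "
            f"{stack.n_planes}")
    ny, nx = stack.volumes.shape[2:]
    if vol.shape[1:] != (ny, nx):
        raise ValueError("phantom and PSF stack lateral grids differ")

    nel = stack.detector.n_elements
    if vol.sum() == 0:
        lam = np.zeros((ny, nx, nel))
    else:
        if pad:
            vol_p = np.pad(vol, ((0, 0), (pad, pad), (pad, pad)))
            psf_p = np.pad(stack.volumes, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        else:
            vol_p, psf_p = vol, stack.volumes
        lam_p = np.zeros((nel,) + vol_p.shape[1:])
        f_planes = [np.fft.rfft2(vol_p[z]) for z in range(vol_p.shape[0])]
        for c in range(nel):
            for z in range(vol_p.shape[0]):
                fk = np.fft.rfft2(np.fft.ifftshift(psf_p[c, z].astype(float)))
                lam_p[c] += np.fft.irfft2(fk * f_planes[z], s=vol_p.shape[1:])
        if pad:
            lam_p = lam_p[:, pad:-pad, pad:-pad]
        np.clip(lam_p, 0.0, None, out=lam_p)
        peak = lam_p.sum(axis=0).max()
        if peak > 0:
            lam_p *= photon_budget / peak
        lam = np.moveaxis(lam_p, 0, -1)
    lam = lam + dark_rate

    if noiseless:
        counts = lam
    else:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(lam).astype(np.int64)

    dy = stack.config.voxel_size[1]
    dx = stack.config.voxel_size[2]
    prov = {"saturation_factor": stack.depletion.saturation_factor,
            "photon_budget": photon_budget, "dark_rate": dark_rate,
            "seed": seed, "noiseless": noiseless, "pad": pad}
    return ISMDataset(counts, (dy, dx), detector=stack.detector,
                      provenance=prov)
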
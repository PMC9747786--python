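"""Focus-ISM: in-focus / out-of-focus classification of micro-images.

After pixel reassignment, every micro-image of an ISM dataset is a scaled
copy of the fingerprint: a narrow spot for in-focus emitters, a broad blob
for out-of-focus (or anti-Stokes) light.  Focus-ISM splits each scan
point's photons into the two components:

``f1``
    The fast estimator.  The background per scan point is the mean count of
    the 16 outer-frame elements, beta = (1/16) sum_{|n|=2 or |m|=2} i_{n,m};
    the in-focus signal is ((1/9) sum_inner i - beta) * 25.  Negative pixels
    can be trimmed to zero.

``f2``
    The model-based estimator.  Each unit-normalized micro-image is fitted
    by bounded least squares to a two-component isotropic Gaussian mixture
    alpha * g(sigma_sig) + beta * g(sigma_bkg) with the photon-flux
    constraint alpha + beta = 1, so signal + background reproduces the
    channel sum exactly and both images are non-negative by construction.

Gaussians are evaluated at the element centres, in detector-pitch units,
and normalized to unit sum over the 25 elements, so a very broad background
component tends to the flat micro-image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .dataset import ISMDataset

__all__ = ["FingerprintModel", "FocusResult", "gaussian_microimage",
           "calibrate_sigma_sig", "f1_classify", "f2_classify",
           "result_images"]

# detector-plane coordinates of the 25 element centres, in pitch units
_N_IDX = np.arange(-2, 3, dtype=float)
_NN, _MM = np.meshgrid(_N_IDX, _N_IDX, indexing="ij")
_R2 = (_NN ** 2 + _MM ** 2).ravel()  # squared radius, flat-index order

_OUTER = ((np.abs(_NN) == 2) | (np.abs(_MM) == 2)).ravel()
_INNER = ~_OUTER


def gaussian_microimage(sigma: float) -> np.ndarray:
    """Centred isotropic Gaussian sampled at the 25 element centres,
    normalized to unit sum; ``sigma`` in detector-pitch units."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    g = np.exp(-_R2 / (2.0 * sigma ** 2))
    return g / g.sum()


@dataclass(frozen=True)
class FingerprintModel:
    """Two-Gaussian micro-image model parameters (pitch units).

    ``sigma_sig`` is the in-focus standard deviation, calibrated from an
    in-focus fingerprint; ``sigma_bkg`` is either fitted freely within
    ``[sigma_bkg_min, sigma_bkg_max]`` (bounded below to avoid degenerate
    fits on low-count micro-images) or held fixed.  Scan points with fewer
    than ``min_counts`` photons are classified through their 3x3 scan
    neighbourhood sum.
    """

    sigma_sig: float
    sigma_bkg_policy: str = "free"
    sigma_bkg_value: float | None = None
    sigma_bkg_min: float | None = None
    sigma_bkg_max: float | None = None
    min_counts: float = 10.0

    def __post_init__(self) -> None:
        if self.sigma_sig <= 0:
            raise ValueError("sigma_sig must be positive")
        if self.sigma_bkg_policy not in ("free", "fixed"):
            raise ValueError("sigma_bkg_policy must be 'free' or 'fixed'")
        if self.sigma_bkg_policy == "fixed" and self.sigma_bkg_value is None:
            raise ValueError("fixed policy requires sigma_bkg_value")
        lo = self.bkg_bounds[0]
        hi = self.bkg_bounds[1]
        if not self.sigma_sig < lo <= hi:
            raise ValueError("need sigma_sig < sigma_bkg_min <= sigma_bkg_max")

    @property
    def bkg_bounds(self) -> tuple[float, float]:
        lo = self.sigma_bkg_min if self.sigma_bkg_min is not None \
            else 1.5 * self.sigma_sig
        hi = self.sigma_bkg_max if self.sigma_bkg_max is not None \
            else 10.0 * self.sigma_sig
        return lo, hi


@dataclass
class FocusResult:
    """Per-scan-point split into in-focus signal and background."""

    signal_image: np.ndarray
    background_image: np.ndarray
    alpha_map: np.ndarray
    beta_map: np.ndarray
    background_per_element: np.ndarray  # (25,) + scan shape
    method: str
    sigma_bkg_map: np.ndarray | None = None
    negatives_trimmed: int = 0
    fallback_pixels: int = 0
    extras: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# calibration
# --------------------------------------------------------------------------

def calibrate_sigma_sig(source, bounds: tuple[float, float] = (0.1, 3.0),
                        n_grid: int = 400) -> float:
    """In-focus standard deviation from a fingerprint (pitch units).

    Least-squares fit of a single centred unit-sum Gaussian to the
    unit-normalized 5x5 fingerprint; ``source`` is a fingerprint object, a
    5x5 array, or an ISM dataset region restricted to in-focus emitters.
    """
    values = getattr(source, "values", None)
    if values is None:
        src = np.asarray(getattr(source, "counts", source), dtype=float)
        values = src.reshape(-1, 25).sum(axis=0) if src.shape[-1] == 25 else src
    f = np.asarray(values, dtype=float).ravel()
    if f.size != 25:
        raise ValueError("calibration source must reduce to a 5x5 fingerprint")
    tot = f.sum()
    if tot <= 0:
        raise ValueError("calibration source has no counts")
    f = f / tot

    sigmas = np.linspace(bounds[0], bounds[1], n_grid)
    sse = np.array([np.sum((gaussian_microimage(s) - f) ** 2) for s in sigmas])
    i = int(np.argmin(sse))
    if i in (0, n_grid - 1):
        warnings.warn(
            "sigma_sig fit hit the bound of its search range; select a "
            "calibration region containing only in-focus emitters",
            stacklevel=2)
        return float(sigmas[i])
    # parabolic refinement on the SSE grid
    y0, y1, y2 = sse[i - 1:i + 2]
    denom = y0 - 2 * y1 + y2
    offset = 0.5 * (y0 - y2) / denom if denom > 0 else 0.0
    return float(sigmas[i] + offset * (sigmas[1] - sigmas[0]))


# --------------------------------------------------------------------------
# f1: outer-frame subtraction
# --------------------------------------------------------------------------

def f1_classify(dataset: ISMDataset, trim_negatives: bool = True,
                estimator: str = "literal") -> FocusResult:
    """Fast background removal by outer-frame averaging.

    ``estimator="literal"`` uses the inner 3x3 mean for the in-focus
    estimate, A = (mean_inner - beta) * 25; ``estimator="total"`` uses the
    flux-consistent alternative A = N - 25 beta.  The per-element
    background is flat, b_{n,m} = beta.
    """
    if estimator not in ("literal", "total"):
        raise ValueError("estimator must be 'literal' or 'total'")
    counts = np.asarray(dataset.counts, dtype=float)
    flat = counts.reshape(-1, 25)
    beta = flat[:, _OUTER].mean(axis=1)
    if estimator == "literal":
        inner_mean = flat[:, _INNER].mean(axis=1)
        signal = (inner_mean - beta) * 25.0
    else:
        signal = flat.sum(axis=1) - 25.0 * beta

    n_negative = int((signal < 0).sum())
    if trim_negatives:
        signal = np.clip(signal, 0.0, None)

    scan_shape = dataset.scan_shape
    total = flat.sum(axis=1)
    background = 25.0 * beta
    b_nm = np.broadcast_to(beta, (25,) + beta.shape).reshape(
        (25,) + scan_shape).copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = np.where(total > 0, signal / total, 0.0)
        beta_frac = np.where(total > 0, background / total, 0.0)
    return FocusResult(
        signal_image=signal.reshape(scan_shape),
        background_image=background.reshape(scan_shape),
        alpha_map=alpha.reshape(scan_shape),
        beta_map=beta_frac.reshape(scan_shape),
        background_per_element=b_nm,
        method="f1",
        negatives_trimmed=n_negative if trim_negatives else 0,
        extras={"negatives_found": n_negative, "estimator": estimator,
                "trimmed": trim_negatives})


# --------------------------------------------------------------------------
# f2: constrained two-Gaussian fit
# --------------------------------------------------------------------------

def _fit_alpha(y: np.ndarray, g_sig: np.ndarray,
               g_bkg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form least-squares alpha in [0, 1] for fixed sigma_bkg.

    The model alpha * g_sig + (1 - alpha) * g_bkg is linear in alpha, so the
    bounded least-squares solution is the clipped projection.  Returns
    (alpha, sse) for data rows ``y`` (each unit-sum).
    """
    d = g_sig - g_bkg
    dd = float(d @ d)
    resid0 = y - g_bkg[None, :]
    num = resid0 @ d
    alpha = np.clip(num / dd, 0.0, 1.0)
    sse = (resid0 ** 2).sum(axis=1) - 2.0 * alpha * num + alpha ** 2 * dd
    return alpha, sse


def f2_classify(dataset_post_apr: ISMDataset, model: FingerprintModel,
                n_sigma_grid: int = 61) -> FocusResult:
    """Two-Gaussian classification of every (post-APR) micro-image.

    Each micro-image with at least ``model.min_counts`` photons is
    unit-normalized and fitted to alpha * g(sigma_sig) + beta * g(sigma_bkg)
    with alpha in [0, 1] and beta = 1 - alpha; with the free policy,
    sigma_bkg is optimized on a dense grid inside its bounds (the model is
    linear in alpha at fixed sigma_bkg, so each grid point has a closed-form
    solution).  Low-count scan points are classified through their 3x3 scan
    neighbourhood sum and keep their own photon total, so
    signal + background equals the channel-summed input exactly everywhere.
    """
    counts = np.asarray(dataset_post_apr.counts, dtype=float)
    scan_shape = dataset_post_apr.scan_shape
    flat = counts.reshape(-1, 25)
    totals = flat.sum(axis=1)

    # 3x3 scan-neighbourhood sums for low-count pixels
    per_channel = counts.reshape(scan_shape + (25,))
    size = (1,) * (len(scan_shape) - 2) + (3, 3, 1)
    neigh = ndimage.uniform_filter(per_channel, size=size, mode="nearest") * 9.0
    neigh_flat = neigh.reshape(-1, 25)

    low = totals < model.min_counts
    fit_data = np.where(low[:, None], neigh_flat, flat)
    fit_totals = fit_data.sum(axis=1)
    ok = fit_totals > 0
    y = np.zeros_like(fit_data)
    y[ok] = fit_data[ok] / fit_totals[ok, None]

    g_sig = gaussian_microimage(model.sigma_sig)
    lo, hi = model.bkg_bounds
    if model.sigma_bkg_policy == "fixed":
        sigma_grid = np.array([model.sigma_bkg_value])
    else:
        sigma_grid = np.linspace(lo, hi, n_sigma_grid)

    best_alpha = np.zeros(len(y))
    best_sse = np.full(len(y), np.inf)
    best_sigma = np.full(len(y), sigma_grid[0])
    for s in sigma_grid:
        alpha, sse = _fit_alpha(y[ok], g_sig, gaussian_microimage(s))
        better = sse < best_sse[ok] - 1e-15
        idx = np.flatnonzero(ok)[better]
        best_alpha[idx] = alpha[better]
        best_sse[idx] = sse[better]
        best_sigma[idx] = s

    alpha = np.where(ok, best_alpha, 0.0)
    beta = np.where(ok, 1.0 - alpha, 0.0)
    # Fourier-interpolated (post-APR) data can carry tiny negative ringing
    # totals; those pixels contribute nothing to either component
    pos_totals = np.maximum(totals, 0.0)
    signal = alpha * pos_totals
    background = beta * pos_totals

    g_bkg_rows = np.stack([gaussian_microimage(s) for s in sigma_grid])
    sigma_pos = np.searchsorted(sigma_grid, best_sigma)
    b_nm_flat = background[:, None] * g_bkg_rows[np.clip(sigma_pos, 0,
                                                         len(sigma_grid) - 1)]
    b_nm = np.moveaxis(b_nm_flat.reshape(scan_shape + (25,)), -1, 0)

    return FocusResult(
        signal_image=signal.reshape(scan_shape),
        background_image=background.reshape(scan_shape),
        alpha_map=alpha.reshape(scan_shape),
        beta_map=beta.reshape(scan_shape),
        background_per_element=b_nm,
        method="f2",
        sigma_bkg_map=best_sigma.reshape(scan_shape),
        fallback_pixels=int(low.sum()),
        extras={"model": model})


def result_images(result: FocusResult):
    """(signal image, background image, diagnostics dict)."""
    diagnostics = {
        "alpha_map": result.alpha_map,
        "beta_map": result.beta_map,
        "sigma_bkg_map": result.sigma_bkg_map,
        "negatives_trimmed": result.negatives_trimmed,
        "fallback_pixels": result.fallback_pixels,
        "method": result.method,
    }
    diagnostics.update(result.extras)
    return result.signal_image, result.background_image, diagnostics
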
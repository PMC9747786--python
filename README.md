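# focusism

Simulation and reconstruction toolkit for **image scanning microscopy
(ISM)** with a small detector array, with optional **stimulated-emission
depletion (STED)**. It targets microscopists and method developers who
work with 5×5 SPAD-array laser-scanning data and want to

- simulate per-element scanned point-spread functions *h*(**x**ₛ∣**x**_d)
  of a STED-ISM microscope at a tunable depletion level,
- reconstruct super-resolved images by **adaptive pixel reassignment
  (APR)** — estimating the per-element shift vectors **μ**(**x**_d) by
  image correlation against the central element and summing the
  registered scanned images,
- remove out-of-focus (and anti-Stokes) background with **focus-ISM**,
  which classifies each post-APR micro-image *i*(**x**_d∣**x**ₛ) into a
  narrow in-focus and a broad out-of-focus component, and
- sharpen the result with **multi-image Richardson–Lucy deconvolution**
  whose Gaussian PSFs are sized parameter-free by **Fourier ring
  correlation (FRC)**.

## The models in brief

**Image formation.** Each detector element (n, m) ∈ [−2, 2]² records a
scanned image whose PSF is

> h_{n,m}(**x**, z) = [h_exc(**x**, z) · η(**x**, z)] · (h_det(·, z) ⊛ Π_{n,m})(**x**),

where Π_{n,m} is the element's active area mapped to sample space and η
is the depletion survival factor.  For a rectangular STED pulse of
duration *T* and saturation factor ς (peak depletion rate over the
spontaneous rate 1/τ_F, referenced to the doughnut crest),

> η = (1 − e^{−(1+ς·d)·T/τ_F}) / (1 + ς·d) + e^{−(1+ς·d)·T/τ_F},

with *d* the unit-crest doughnut intensity.  ς = 0 reproduces the
confocal case.  Focal fields come from scalar Debye integrals (exact
Airy pattern in focus), an optional vectorial Richards–Wolf calculation
(circular polarization; fills the unphysical scalar vortex nulls), or
fast Gaussian/doughnut stand-ins.

**APR.**  Scanned images are mutually displaced by shift vectors
**μ**(**x**_d) — the argmax of the excitation–detection product, equal to
half the element displacement for matched Gaussian PSFs and shrinking to
zero as the STED power grows.  The shifts are estimated blindly by
correlation against the central element, each image is translated back
by −**μ**, and the sum is the ISM image.  Pixel reassignment conserves
photons: Σ ISM = Σ open-pinhole.

**Focus-ISM.**  After APR every micro-image is a scaled copy of the
detector *fingerprint* (the sum of all micro-images).  In-focus light is
narrow on the array, out-of-focus light broad, so each micro-image is
split either by outer-frame subtraction (*f¹*: β = mean of the 16 outer
elements, signal = (mean of the inner 3×3 − β)·25) or by a bounded
least-squares fit to the two-Gaussian mixture (*f²*):

> i(**x**_d∣**x**ₛ) = α·g(**x**_d∣0, σ_sig) + β·g(**x**_d∣0, σ_bkg),  α + β = 1,

with σ_sig calibrated from an in-focus fingerprint.  The α+β=1 flux
constraint makes the f² signal and background images non-negative and
exactly complementary.

**Deconvolution.**  The multi-image Richardson–Lucy update

> o^{k+1} = o^k · Σ_{n,m} w_{n,m} · [h*_{n,m} ⋆ (i_{n,m} / (h_{n,m} ∗ o^k + b_{n,m}))]

uses inverse-fingerprint weights w = f⁻¹ (normalized) and optionally the
focus-ISM background b_{n,m} as prior knowledge.

## Worked example

```python
import numpy as np
from focusism import (OpticalConfig, DetectorGeometry, DepletionModel,
                      scanned_psf_stack, generate_phantom,
                      simulate_acquisition, estimate_shifts, reassign,
                      calibrate_sigma_sig, FingerprintModel, f2_classify)
from focusism.metrics import fit_beads, gains

cfg = OpticalConfig(grid_shape=(1, 127, 127))   # 646/669/775 nm, NA 1.4
det = DetectorGeometry.from_config(cfg)          # 5x5 array, 1.4 AU side
stack = scanned_psf_stack(cfg, det, DepletionModel(saturation_factor=10),
                          method="analytic")

phantom = generate_phantom("beads", {"grid_shape": (1, 127, 127), "n": 6,
                                     "diameter_nm": 23, "margin_nm": 250},
                           seed=3)
data = simulate_acquisition(phantom, stack, photon_budget=2000, seed=1)

shifts = estimate_shifts(data, upsampling=20, regularize=True)
result = reassign(data, shifts)

fo = fit_beads(result.open_image, 10.0, expected_fwhm=150.0)
fi = fit_beads(result.ism_image, 10.0, expected_fwhm=150.0)
g = gains(fo, fi)

sigma_sig = calibrate_sigma_sig(data.fingerprint())
split = f2_classify(result.registered, FingerprintModel(sigma_sig=sigma_sig))
```

Output of this session:

```
max shift vector   : 10.94 px
photon conservation: 1.44e-16
open-pinhole FWHM  : 128 +/- 7 nm
STED-ISM FWHM      : 112 +/- 5 nm
resolution gain    : 1.14 +/- 0.08
signal gain        : 1.06 +/- 0.32
sigma_sig          : 0.82 pitch units
in-focus fraction  : 0.921
```

The shift vectors scale with the residual size of the depleted
excitation spot; reassignment narrows the bead images and raises their
peaks without changing the photon total (conservation at machine
precision); the calibrated in-focus fingerprint width σ_sig then lets f²
classify 92% of this in-focus sample's photons as signal.

The same workflow is available from the shell:

```sh
focusism simulate-psf --sigma 10 --method analytic --out psf.h5
focusism phantom --kind beads --seed 3 --out phantom.h5
focusism acquire --phantom phantom.h5 --psf psf.h5 --budget 2000 --seed 1 --out acq.h5
focusism apr acq.h5 --out apr.h5
focusism focus apr.h5 --method f2 --out split.h5
focusism deconv apr.h5 --iters 5 --background split.h5 --out sharp.tif
```

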
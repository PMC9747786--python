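# Methods

This note records the models implemented in `focusism`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Optical model

The simulation grid is an odd-sized `(Nz, Ny, Nx)` voxel lattice (array
order z, y, x; 0-based indices) whose central voxel is the optical axis
at focus; the physical coordinate of voxel *k* along an axis of size *N*
is `(k − (N−1)/2) · voxel_size`.  Defaults follow a far-red STED system:
λ_exc = 646 nm, λ_det = 669 nm, λ_STED = 775 nm, NA = 1.4 oil
(n = 1.518), 127³ voxels of 10 nm.  The detector is a 5×5 square array
whose side subtends 1.4 Airy units (1 AU = 1.22·λ_det/NA ≈ 583 nm in
sample space), giving an element pitch of ≈163 nm; flat channel index
c = 5(n+2) + (m+2).

Three focal-field models are provided:

- **`debye` (scalar, default).**  The uniform-pupil integral
  `U(r,z) = ∫₀^{NA/n} J_ℓ(k r s) e^{i k z √(1−s²)} s ds` with ℓ = 0 for
  the excitation/detection beams and ℓ = 1 for the 0–2π helical vortex.
  In focus the order-0 intensity is exactly the Airy pattern, so the
  first zero sits at 0.61·λ/NA — consistent with the Airy-unit
  convention used for the detector geometry.  The scalar vortex has
  exact off-axis ring nulls; these are a known artifact of scalar
  theory.
- **`vectorial`.**  The Richards–Wolf focus of a circularly polarized
  beam co-rotating with the vortex charge (√cosθ aplanatic apodization;
  three integrals with pupil factors (1+cosθ), sinθ, (1−cosθ) and
  Bessel orders ℓ, ℓ+1, ℓ+2; intensity |I_a|² + 2|I_b|² + |I_c|²).  It
  keeps the on-axis vortex null but fills the off-axis ring minima,
  which matters whenever a depletion profile multiplies Airy-tailed
  excitation: with the scalar vortex, its nulls coincide with excitation
  rings and let unphysical periphery light survive strong depletion.
- **`analytic`.**  Gaussian stand-ins `exp(−r²/2σ²)` with
  σ = 0.51·λ/NA/2.355 (diffraction-matched FWHM) and a doughnut
  `(r²/σ_d²)·exp(1−r²/σ_d²)` with crest radius σ_d = 0.41·λ_STED/NA,
  matching the crest of the vectorially computed vortex ring (227 nm at
  775 nm, NA 1.4).  Axial behaviour is modelled by a z-dependent width
  σ(z) = σ₀√(1+(z/z_R)²) with the Gaussian-beam Rayleigh range for
  waist w₀ = 2σ₀, and per-plane energy conservation
  (the peak decreases as σ₀²/σ(z)²).  With this crest choice the
  depletion dominates the excitation tail at every radius, so the
  strong-depletion limit is clean; the stand-ins are the recommended
  field model for exercising the classification and reconstruction
  algorithms, while `debye`/`vectorial` serve beam-profile studies.

**Depletion.**  The survival factor for a rectangular depletion pulse of
duration *T* followed by undepleted decay is
η = (1 − e^{−(1+ςd)T/τ_F})/(1+ςd) + e^{−(1+ςd)T/τ_F}, with
τ_F = 3.5 ns, T = 1 ns by default and ς referenced to the doughnut
crest.  η(ς=0) ≡ 1, η = 1 wherever the doughnut is dark (in particular
on axis), and η decreases pointwise in ς.  Note that with T ≪ τ_F a
sizable fraction of the fluorescence is emitted after the pulse
un-depleted only where ςd is small; at ς = 300 the effective excitation
spot retains a ≈28 nm FWHM rather than collapsing to a point, which is
why the measured fingerprint approaches but does not exactly equal the
element-integrated detection PSF (unit-sum L2 discrepancy ≈ 0.04).

**Per-element PSFs.**  Element detection maps are the detection PSF
convolved (FFT, periodic) with the element's active-area indicator,
rasterized with exact fractional voxel coverage; at fill factor 1 the
indicators tile the array footprint exactly, so the channel sum equals
the whole-aperture (open pinhole) PSF.  Sub-voxel PSF peak positions use
per-axis parabolic interpolation of the 3-point neighbourhood, ties
broken toward the grid centre.

## Synthetic data

Phantoms are bead fields (spheres of given diameter rasterized over the
voxels within the radius, unit mass each) or smooth 3D random-walk
filament tubes with persistence, confined to a chosen axial extent.
Acquisitions are plane-wise periodic FFT convolutions of the phantom
with each element's PSF, scaled so the brightest channel-summed pixel
equals the photon budget, plus an optional flat dark rate, then Poisson
sampled with a seeded generator.  An optional zero-padding margin
suppresses wrap-around when phantom mass approaches the edges (recorded
in the provenance metadata; the built-in phantoms keep margins instead).

What the generator emulates: shot noise, detector geometry, depletion
level, axial defocus blur, dark counts.  What it does not: optical
aberrations, misalignment between beams, detector dead time and
afterpulsing, background autofluorescence with structure, sample motion
and photobleaching.  Passing tests therefore demonstrate algorithmic
correctness under the stated image-formation model, not robustness to
instrument non-idealities — with the exception of APR, whose blind shift
estimation is exactly the mechanism that absorbs such non-idealities on
real data.

## Adaptive pixel reassignment

Shifts are estimated per element against the central-element image with
correlation maximization, refined to 1/upsampling pixel (default 20) by
local Fourier upsampling.  The default objective is the plain
cross-correlation; magnitude-whitened ("phase") normalization is
exposed as an option but mis-ranks smooth, band-limited microscopy
images whose whitened spectra are noise-dominated.  Optional
regularization replaces the shifts of low-signal elements (fingerprint
below 5% of its maximum by default) with an affine fit of shift versus
element index over the high-signal elements; all-zero channels are
always replaced this way, with a warning.  Registration uses periodic
Fourier translation, which conserves each channel's photon count to
machine precision; an optional crop (`"auto"` = ceil(max |shift|))
removes wrap-contaminated borders before metrics are computed, and is
off by default so that the ISM and open images carry identical mass.
For 3D stacks, shifts are estimated on the brightest plane and applied
laterally to every plane.  Sign convention: `ShiftField.shifts[c]` is
the structure displacement of channel c relative to the reference;
registration translates by its negative.

## Focus-ISM

*f¹* implements the outer-frame estimator literally: β is the mean of
the 16 |n|=2 ∨ |m|=2 elements and the signal is (inner-3×3 mean − β)·25;
the flux-consistent alternative `signal = N − 25β` is available as
`estimator="total"`.  Negative pixels are counted and, by default,
trimmed to zero.

*f²* fits each unit-sum-normalized micro-image to
α·g(σ_sig) + (1−α)·g(σ_bkg) by bounded least squares.  The Gaussians are
evaluated at the 25 element centres in pitch units and normalized to
unit sum over the array (not analytically), so a very broad background
tends to the flat micro-image — without this the broad component's mass
would leak off the 5×5 support and bias α.  Because the model is linear
in α at fixed σ_bkg, α has a closed-form clipped solution; the free
σ_bkg policy scans a dense grid (default 61 points) over
[1.5σ_sig, 10σ_sig] and keeps the best, which is vectorized over all
scan points and equivalent to a per-pixel bounded optimizer (asserted in
the tests).  Scan points with fewer than `min_counts` photons (default
10) are classified through their 3×3 scan-neighbourhood sum but keep
their own totals, so signal + background reproduces the channel sum
exactly and both images are non-negative; for noiseless data
`min_counts=0` (direct fits everywhere) is appropriate, since the
fallback exists only to stabilize shot-noise-limited fits.  σ_sig is
calibrated by a one-parameter grid-plus-parabolic least-squares fit of a
centred Gaussian to an in-focus fingerprint; hitting the search bound
(e.g. for a degenerate single-element fingerprint) warns and suggests a
better calibration region.  Tiny negative totals that Fourier
interpolation can introduce after APR contribute to neither component.

Applying APR before f² matters even when shift vectors are small: it is
reassignment that makes the micro-images scan-position-independent
copies of the fingerprint.  The perfect-reassignment premise degrades
for isolated sub-resolution emitters under strong depletion, where
scan points in the PSF tail see micro-images displaced toward the
emitter; for spatially extended structures (filaments, cell-scale
samples) the premise is accurate, and the sectioning analyses here use
filament phantoms for that reason.

## Deconvolution and FRC

The multi-image Richardson–Lucy update uses unit-sum Gaussian kernels on
the full image grid (shifted per element for raw data, centred for
post-APR data), inverse-fingerprint weights normalized to unit sum
(zero-fingerprint elements excluded) so the noiseless forward model is a
fixed point, ratio and denominator floors at 10⁻¹², a flat start at the
mean of the channel sum, and a fixed iteration count (default 5) or an
early stop at relative change < 10⁻⁴.  The background variant adds
b_{n,m} (images, per-element constants, or a scalar; may include the
dark rate) to the denominator.  The weighted Poisson negative
log-likelihood is tracked per iteration and is non-increasing on test
problems.

Single-image FRC splits the image by diagonal checkerboard subsampling
([0::2, 0::2] vs [1::2, 1::2]).  The second sub-lattice is offset half a
sub-pixel along both axes; that known displacement is compensated as a
phase ramp before the ring-wise correlation, otherwise the split
geometry alone depresses high-frequency correlation and biases the
estimate fine by ≈√2.  The curve is smoothed by a 3-ring moving average
and the first crossing of the fixed 1/7 threshold is interpolated
linearly; no crossing returns the sub-image Nyquist bound with a
warning.  On fields of 200 nm FWHM spots the estimate is 200–210 nm
across photon budgets from 50 to 5000 counts/peak.

## Evaluation metrics

Bead analysis detects isolated maxima (maximum filter of ≈1.5 expected
FWHMs, threshold a configured multiple of the median) and fits a 2D
Gaussian plus offset in a window of ≈7 expected FWHMs, clipped at the
image borders; fits are rejected when the centre leaves the window, the
FWHM exceeds it, or the amplitude is non-positive.  Resolution gain is
mean-FWHM(open)/mean-FWHM(ISM), signal gain mean-peak(ISM)/mean-
peak(open), with standard errors propagated in quadrature.  MTFs are
radially averaged FFT magnitudes normalized at DC (ring binning incurs
≈2% discretization on steep curves).  OTF band limits use power-law
edge extrapolation: the shoulder rings with MTF in [10⁻³, 5·10⁻²] are
fitted to A·(f_c − f)^p and f_c scanned for the best log-domain fit —
a hard threshold systematically underestimates supports whose edge
falls faster than linearly (the point-pinhole confocal OTF vanishes as
the fourth power of the distance to cutoff).  The bandwidth-doubling
measurement uses a 511² field at 25 nm pixels with a Blackman window;
coarser ring grids (e.g. 255²) leave the window-leakage skirt a few
rings wide relative to the cutoff and bias the ratio low.

## Problem sizes and defaults used in the analyses

Headline analyses run on single-plane 127×127 stacks (10 nm pixels) and
a 3-plane (0, ±500 nm) grid for the sectioning study, with photon
budgets of 500–10⁴ counts at the brightest pixel, 6–8 beads or 6
filaments per field, and 500 Poisson replicates for mixture-weight
recovery; the acceptance script completes in well under a minute on one
CPU.  These sizes were chosen so every quantity is estimated far above
its noise floor while the full suite stays interactive.

## Known limitations

- No aberration or misalignment modelling; the vectorial option covers
  polarization structure only.
- The depletion model is the standard rectangular-pulse survival; it is
  not time-gated, so strong-STED limits retain a finite effective spot.
- f² assumes an isotropic, centred two-Gaussian micro-image model;
  z-dependent σ_bkg and axial localization of emitters are out of scope.
- Deconvolution is 2D per plane with Gaussian PSFs; experimental-PSF and
  axially coupled 3D deconvolution are not provided.
- TIFF interchange uses a channel-first layout with exactly 25 pages;
  instrument-specific file layouts are not parsed.
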
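# Methods

## The measurement model

A membrane sheet is a flat basal plasma-membrane fragment imaged as one 2D
photon-count grid per color channel at a 20 nm pixel pitch, with a boolean
mask marking the analyzable region (sheet minus edges). Protein
nanoclusters appear as diffraction-limited spots: the instrument blurs a
cluster of intrinsic full width at half maximum f with a point-spread
function of width p ≈ 50 nm, so the imaged spot has width √(f² + p²) (for
Gaussian profiles, which we assume throughout). Cluster brightness scales
with the number of labeled molecules; photon shot noise is Poisson.

Coordinates are continuous nm with the origin at the top-left pixel
center, x rightward, y downward; pixel (i, j) covers a 20×20 nm cell
centered on (j·pitch, i·pitch). Distances are nm everywhere; densities
are clusters·μm⁻²; conversions are centralized in `spatial`.

## Synthetic sheets (`temweb.synth`)

The generator is the package's ground-truth instrument. Defaults are the
study conditions of the data it emulates: 20 nm pixels, cluster FWHM
120 ± 25 nm, densities of order 0.5–5 μm⁻², 3.5 molecules per cluster on
average, 50 nm PSF.

* **Placement.** Channel-1 centers are a homogeneous Poisson process of
  the requested density, drawn in a field padded by 3× the mean FWHM and
  cropped, so border intensity is unbiased; ground truth lists only
  in-field centers. Channel 2 is independent Poisson (the
  complete-spatial-randomness null), an exact copy of channel 1
  (co-centered: one protein seen by two antibodies), or displaced from
  each channel-1 center by |N(μ_off, σ_off)| at a uniform angle (offset:
  adjacent-but-distinct domains). An optional hard-core thinning radius
  (`min_separation_nm`) produces resolvability-controlled fields for
  detector benchmarking; it is off by default.
* **Marks.** FWHM is truncated-normal (resampled until positive) or drawn
  from a supplied empirical sample; molecule count is 1 + Poisson(μ − 1),
  so every cluster carries at least one label — a zero-label cluster is
  unobservable and must not appear in ground truth.
* **Rendering.** Each cluster is an isotropic Gaussian with σ = FWHM/2.3548
  whose integrated signal is molecules × photons_per_molecule; the PSF
  convolution is applied analytically (Gaussian ⊛ Gaussian), then a uniform
  background is added and Poisson noise drawn. Defaults
  (500 photons/molecule on background 5) put a mean cluster ~16σ above the
  background noise while leaving single-label clusters near the detection
  limit — deliberately realistic rather than generous.
* **Randomness.** One root seed; per-stage substreams
  (placement ×2, marks ×2, noise) are spawned deterministically, so a
  fixed seed reproduces images and truth bit for bit.

What the generator does **not** emulate: labeling efficiency and antibody
geometry, fluorophore blinking/bleaching, anisotropic or non-Gaussian
PSFs, inhomogeneous cluster densities across a sheet, 3D membrane
topography. Tests passing on synthetic sheets therefore validate the
statistical machinery and the detector's behavior on its stated model,
not robustness to every artifact of real STED data.

## Detection and morphometry (`temweb.detect`)

* **Threshold.** Background median and a MAD-based SD are estimated from
  mask pixels at or below the median (clusters occupy a few percent of
  pixels and cannot inflate a lower-half estimate). Pixels above
  median + k·SD (default k = 3) are segmented into 8-connected components.
* **Minimum blob size = 9 px.** On a ~10⁶-pixel sheet a 3σ threshold
  leaves ~10⁻²·N isolated noise pixels, and 4-pixel noise clumps occur by
  the hundreds; 9 px (a 3×3 block) makes noise components vanishingly rare
  while a real cluster's above-threshold footprint at workable
  signal-to-noise is ≥ ~25 px. 
* **Centers.** Intensity-weighted centroid of background-subtracted pixels
  — at 20 nm pixels this is reliably subpixel (~1–2 nm mean error at high
  SNR); least-squares spot fitting is deliberately out of scope.
* **Merging.** Components whose threshold contours touch are reported as
  one cluster; no watershed splitting. Below ~2–3× FWHM separation,
  neighbors merge — the same resolution limit the microscope imposes.
  Consequently the *detected* same-species NN distribution is depleted at
  short range relative to the Poisson law even for truly random fields;
  the analytic law is validated on ground-truth coordinates, and all
  observed-vs-null comparisons push mocks through the identical detector
  so this bias cancels.
* **FWHM.** Two orthogonal profiles through the peak, background
  subtracted, half-max crossings by linear interpolation, averaged. The
  image is pre-smoothed with a 3×3 boxcar and the kernel variance
  (pitch²·8/12 per axis) removed analytically: measuring on raw pixels
  lets the noise-inflated maximum set the half-max level, biasing widths
  low by up to ~20%; with the correction, accuracy is within ~3% across
  f ∈ [80, 180] nm at realistic photon counts. Profiles that never fall
  below half max inside the mask raise a censored-size error.
* **Masks.** Per-blob region above background + 50% of (peak − background)
  — the FWHM contour, consistent with the sizing rule. Area = pixel count
  × pitch²; circularity = 4π·area/perimeter², clipped to [0, 1], with the
  perimeter measured on the traced 0.5-level contour after a short
  arc-length moving average (raw marching-squares polygons overestimate
  smooth boundaries by ~7%; the smoothed estimate recovers discs and
  ellipses to ~1%).
* **Edge exclusion.** The mask is eroded by a margin (default 500 nm)
  with a square structuring element; the analyzed area is recomputed from
  surviving pixels.

Scale invariance holds by construction: the threshold is
background-relative, so multiplying an image by a positive constant
changes no detection, size or density output.

## Spatial statistics (`temweb.spatial`)

For each reference cluster, the Euclidean distance to the nearest target
cluster (excluding itself for same-species analyses). Edge correction is
minus-sampling: references closer than a border margin (default 500 nm)
to the mask boundary are dropped, while all targets remain candidate
neighbors; on Poisson truth this keeps the mean NN distance within 2% of
the analytic value 1/(2√ρ).

The random null is the 2D Poisson NN law p(r) = 2πρr·exp(−πρr²) with ρ
fixed at the independently measured target density — never a free fit
parameter. Goodness of fit is a one-sample Kolmogorov–Smirnov test
against the closed-form CDF 1 − exp(−πρr²); reporting a statistic and
p-value is a quantitative extension of the visual curve overlay the
analysis descends from, and is labeled as such in outputs. Histograms
default to 20 nm bins (one pixel) over 0–1,000 nm.

Cross-channel association is summarized two ways: the overlap fraction
(% of references within d = 100 nm of a target center — "partly
overlapping" for ~100 nm clusters; under independence its expectation is
100·(1 − exp(−πρd²))), and the per-sheet Pearson correlation of raw pixel
intensities over mask pixels (no Costes-style thresholding).

## Mock-image null (`temweb.nulls`)

The Monte-Carlo null regenerates n = 10 images (the scale used in the
source analyses; configurable) with the observed per-channel densities
and pooled empirical FWHM samples but independent uniform placements,
pushes them through the identical detect → NN path, and pools them.

Two deliberate refinements:

* **Brightness.** Mock clusters render bright
  (photons_per_molecule = 2000) by default: the requested densities are
  *detected* densities, and a dim mock would lose clusters to the
  detector a second time.
* **Density calibration.** Even bright mocks lose a few percent of placed
  clusters to merging. `mock_null_distributions` measures the detected
  mock density and rescales placement densities by observed/detected in
  one fixed-point step, so the null matches the data at the detector
  output.

The comparison reports the excess overlap (observed − pooled null, in
percentage points), a two-sample KS statistic with its asymptotic p-value,
and an ensemble-rank empirical p (resolution 1/(n_mock + 1), so ≥ 1/11 at
n = 10 — the asymptotic p is the one that can certify p < 0.01 at that
ensemble size). Comparisons refuse NN distributions computed from raw
ground-truth coordinates unless explicitly allowed, enforcing the
identical-pipeline contract.

Mocks sample Poisson counts rather than conserving exact per-sheet counts
(the generator's native behavior; fixed counts would narrow the null
slightly).

## Stoichiometry (`temweb.stoich`)

signal = a·mass + b is fit by ordinary least squares to the
recombinant-protein standard curve (≥ 3 distinct masses, positive slope
required); lysate mass inverts the line. Per-molecule mass comes from the
molecular mass via Avogadro's number (1 kDa = 1.6605×10⁻⁹ pg) — the
authoritative route when a printed per-molecule figure disagrees. The
surface fraction is 100·(surface − surface isotype)/(total − total
isotype). Cell surface area is the mean of 4πr² over measured equatorial
radii of swollen spherical cells — mean of squares, not square of the
mean, because membrane area scales with r² cell by cell and the radius
sample is dispersed (Jensen). The chain identity

molecules/cluster × clusters/cell ≡ molecules/cell × fraction

holds to machine precision by construction. Light unit auditing rejects
magnitude-implausible inputs (radii > 100 μm, molecular mass outside
1–1000 kDa) to catch nm/μm and Da/kDa slips; full dimensional typing was
judged not worth the interface cost.

## Numerical and design choices

* Detection threshold offset k = 3 and the 9-px minimum blob size are
  configurable and logged in every pipeline summary.
* KDTree (scipy) for all NN queries; SeedSequence-spawned substreams for
  all randomness; JSON summaries are sorted-key and round-to-fixed-digit,
  so a fixed seed reproduces them byte for byte.
* Problem sizes in the test suite and acceptance script (fields of
  20–50 μm, ensembles of 10 mocks, 500 calibration repeats at n = 200)
  were chosen as the smallest sizes at which the statistical expectations
  are sharp relative to their tolerances.
* Detector benchmarks use hard-core fields at ~3× FWHM separation: at
  exactly 2× FWHM the threshold contours of bright neighbors still touch
  and merge, which is the resolution limit of a non-splitting detector,
  not a defect of it.

## Known limitations

* No watershed or multi-emitter splitting: densities well above ~5 μm⁻²
  or strongly clustered fields undercount.
* The detected same-species NN distribution is not expected to match the
  Poisson law at short range (merging); use ground truth or the mock null
  for distribution-level inference.
* Pearson correlation uses raw mask pixels; background dominates it at
  low cluster density.
* The stoichiometry chain propagates no uncertainties by default; every
  intermediate is reported so bootstrap layers can be added on top.
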
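# Methods

## The measurement being modeled

A single-cell Raman spectrum (SCRS) is a vibrational fingerprint of one
cell: a vector of scattered-light intensities over wavenumber (cm⁻¹),
carrying bands attributable to proteins, nucleic acids, carbohydrates,
lipids and pigments. When cells assimilate a ¹⁵N-labeled nitrogen source,
the heavier isotope lowers the frequency of vibrational modes that involve
nitrogen atoms, moving those bands to lower wavenumber by characteristic
amounts (≈7–39 cm⁻¹ for the bands tracked here) while nitrogen-free modes
stay put. Detecting which bands moved, and by how much, is the core
inference this package implements.

Two organisms are covered, each with a curated reference table of expected
band centers: the dinoflagellate *Durusdinium* sp. (20 bands; a 21st amide
III protein band at 1240 cm⁻¹ is available via `extended=True` because its
¹⁵N shift is part of the documented co-culture labeling signature) and the
bacterium *Ruegeria* sp. (11 bands). Nitrogen-associated rows carry the
documented ¹⁵N target position. Where printed shift magnitudes and rounded
band positions were mutually inconsistent at the 0.1 cm⁻¹ level, the table
encodes the stated shift magnitude relative to the fractional ¹⁴N center
(e.g. the 655.246 cm⁻¹ guanine band carries a ¹⁵N center exactly 7 cm⁻¹
below it).

## Forward model (synthetic ramanomes)

No public single-cell spectra exist for this system, so the simulator is a
first-class component: it generates data with the statistical structure the
analysis assumes, which makes every downstream stage testable against known
ground truth.

A simulated cell is

    I(x) = Σ_b PV(x; center_b + δ, A_b, w_b, η_b) + baseline(x) + ε(x) + spikes

* **Bands**: pseudo-Voigt profiles (unit peak height convention). Defaults
  where no measured values exist: amplitude 1 a.u., FWHM 12 cm⁻¹, η = 0.5 —
  typical of biological Raman bands at this resolution.
* **Labeling**: a nitrogen-sensitive band with labeling fraction
  f ∈ [0, 1] is replaced by a two-component isotopologue mixture — weight
  1 − f at the ¹⁴N center, weight f at the ¹⁵N center, widths preserved,
  total amplitude conserved. Isotopologue populations are discrete, and the
  mixture stresses the fitter the way real partially-labeled cells do.
* **Cell-to-cell variation**: one Gaussian center jitter per physical band
  per cell (σ = 0.5 cm⁻¹ default), applied to both isotopologue positions
  so the isotopic separation itself is exact.
* **Baseline**: a polynomial (degree ≤ 5, coefficients in the normalized
  coordinate) plus an exponential fluorescence term with a 1000 cm⁻¹ decay
  constant, emulating cellular autofluorescence.
* **Noise**: additive Gaussian, default σ = 0.05 (5% of the unit band
  amplitude). Shot noise and detector effects are deliberately not modeled;
  they do not change what the shift-recovery tests probe.
* **Cosmic spikes**: Poisson-count single-pixel positive excursions of
  10–50× the noise σ, off by default, used to exercise spike removal.
* **Grid**: 300–3500 cm⁻¹ at a 1 cm⁻¹ step (the acquisition range; the step
  makes integer shifts exactly representable).
* **Determinism**: the stream for cell *i* is seeded from `(seed, i)`
  (blanks from `(seed, 10⁶ + i)`), so any single cell is reproducible in
  isolation and ramanomes of different sizes share their common prefix.

A default condition uses 20 cells + 4 blank (medium-only) regions per
sample, matching the acquisition protocol the simulator emulates; shift
analyses in the tests use 30 cells per condition.

What the simulator does *not* emulate — resonance-Raman intensity effects,
instrument response, wavenumber-calibration drift, focus variation,
intensity heterogeneity between cells beyond center jitter — limits what
green tests prove about real data: they validate the inference machinery
(preprocessing, fitting, assignment, statistics) under the stated noise
model, not robustness to every instrumental artifact.

## Preprocessing chain

Fixed order: crop → despike → smooth → blank-subtract → baseline-correct →
normalize. Despiking precedes smoothing so spikes are not smeared;
baseline estimation follows blank subtraction so it only absorbs residual
cell autofluorescence. Every stage is purely functional and can be disabled
independently.

* **Despiking**: a pixel is flagged when the modified z-score
  (median/MAD) of the second difference exceeds 8; flagged runs wider than
  4 pixels are ignored (a noiseless band's curvature can exceed any
  MAD-relative threshold, but cosmic spikes are 1–2 pixels), runs are grown
  by one pixel so adjacent spikes cannot anchor each other's interpolation,
  and flagged pixels are linearly interpolated from their neighbours.
* **Smoothing**: Savitzky–Golay, window 11 points, polynomial order 3
  (exact for polynomials up to that order). Requires a uniform axis;
  non-uniform input must be resampled explicitly.
* **Blank subtraction**: the mean of the (identically cropped/despiked/
  smoothed) blanks is subtracted from every cell.
* **Baseline**: asymmetric least squares (Whittaker smoother with
  asymmetric reweighting; λ = 10⁵, p = 0.01, 10 iterations), the community
  standard for fluorescence backgrounds; an iteratively clipped polynomial
  (degree 5) is available for sensitivity checks. The instrument software
  originally used for this step does not document its algorithm, so ALS is
  this package's explicit choice.
* **Normalization**: unit trapezoidal area or unit vector norm; off by
  default because band *positions*, the quantity of interest, are
  scale-invariant.

## Band fitting

For each reference band and cell, one pseudo-Voigt plus a linear local
background is fit by bounded least squares (`scipy.optimize.least_squares`,
trust-region reflective). Initialization: amplitude = max − min in window,
center = intensity argmax in the window, FWHM = 10 cm⁻¹, η = 0.5; center is
constrained to the window, η to [0, 1]. Standard errors come from the
Gauss-Newton covariance; fits that fail to converge are flagged and dropped
downstream, never raised.

Window placement: plain bands get center ± 20 cm⁻¹. Isotope-sensitive bands
get a window centered midway between the ¹⁴N and ¹⁵N positions (half-width
max(20, separation/2 + 10) cm⁻¹) so both isotopologue positions fall in one
window regardless of labeling state; seeding at the window argmax then finds
whichever position is populated. The window geometry was checked against
both reference tables so that no window captures a neighbouring band's
center.

Local background alone is not enough at the ~0.1 cm⁻¹ accuracy this
analysis needs: a neighbouring band's Lorentzian tail leaking into a window
biases the fitted center by up to ~1 cm⁻¹ (enough to corrupt an
integer-rounded shift, as the 1240/1255 cm⁻¹ amide III pair demonstrates).
Any reference position — either isotopologue — within 15 cm⁻¹ of a window
therefore gets its own nuisance pseudo-Voigt component (center bounded ± 4
cm⁻¹ of its expected position), and the target band's component is
reported.

Partially labeled cells contain two sub-bands of the same band; these are
deliberately fit with a *single* profile, so the fitted center moves
continuously from the ¹⁴N to the ¹⁵N position as f grows — matching how a
single position per band per condition is read out in practice. For
separations well beyond the FWHM (the 39 cm⁻¹ proline shift) the profile at
intermediate f is bimodal and the single-profile center follows the
dominant mode rather than interpolating linearly; end states (f = 0, 1) are
unaffected.

## Shift inference

Converged fits are assigned to the nearest reference band within 8 cm⁻¹
(half a typical FWHM — keeps the 1231/1240 and 1157/1130 regions distinct),
measuring distance to whichever isotopologue position is closer so fully
labeled bands map back to their biological band; ties go to the lower
center, and only the closest fit per band per cell is kept.

Per band, the shift is the difference of per-cell median centers
(¹⁴N − ¹⁵N, positive = red shift), tested with a two-sided Mann–Whitney U
test (robust to fit outliers; Welch's t is available). A band is
`red_shifted` when shift ≥ 3 cm⁻¹ and p < α = 0.05, `blue_shifted` for the
mirror case, otherwise `unshifted`. The 3 cm⁻¹ floor sits below the
smallest documented shift (7 cm⁻¹) and above the center noise at default
conditions, separating isotope chemistry from fitting jitter. Raw p-values
drive classification; Benjamini–Hochberg-adjusted values are reported
alongside so the (deliberate) absence of multiplicity correction in the
classification is transparent.

Reported alongside each shift: the rounded integer shift, per-condition
cell counts, and the classification. The `report` CLI command renders the
conventional significance stars (ns, \*, \*\*, \*\*\*, \*\*\*\*).

## Pigment quantification

Closed-form spectrophotometric formulas from methanol-extract absorbances:
Chl a (µg/mL) = 12.9447 × (A665 − A720); total carotenoids =
[1000 × (A470 − A720) − 2.86 × Chl a] / 221, with A720 as the turbidity
reference. Impossible inputs can yield negative concentrations; these are
returned with a warning rather than clamped. Group comparisons use Welch's
unequal-variance t-test — the safer default at n = 3 replicates.

## Numerical and testing choices

* Problem sizes in the test suite are chosen for single-CPU runs: shift
  recovery is verified over 50 replicate seeds per documented shift
  magnitude (7, 11, 12, 14, 15, 20 cm⁻¹) at 30 cells/side on compact
  single-band grids; the false-positive calibration of the classifier runs
  100 replicate unlabeled pairs at 8 cells/side on a 600–1650 cm⁻¹ grid
  (10 bacterial bands) — classifier calibration at f = 0 does not depend on
  these sizes.
* The nucleobase band's injected ¹⁴N/¹⁵N separation is 11.36 cm⁻¹; with
  30-cell medians its rounded recovered shift is 11 for most seeds but can
  round to 12, since the truth sits near the rounding boundary. This is a
  property of the band geometry, not of the estimator.
* Degenerate inputs: empty spectra, all-zero normalization, windows with
  fewer than 10 points, bands with fewer than 3 converged fits per
  condition are all rejected or skipped explicitly with named errors or
  logged reasons.

## Known limitations

* The baseline estimator stands in for an undocumented instrument routine;
  absolute intensities after correction are not calibrated, only positions.
* Assignment assumes fitted peaks arise from reference-table bands;
  unexpected bands are reported as unassigned rather than discovered.
* The labeling model is a two-state mixture; time-resolved or partial
  per-molecule substitution (one of several nitrogens exchanged) would
  produce intermediate positions the tables do not encode.
* Pigment formulas are specific to the methanol-extraction protocol and
  wavelength triple they were derived for.
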
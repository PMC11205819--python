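# ramansip

Single-cell Raman spectroscopy combined with ¹⁵N stable-isotope probing
(¹⁵N-SIP-SCRS) traces nitrogen as it moves from a labeled substrate into the
biomolecules of individual cells: substituting ¹⁵N for ¹⁴N increases the
reduced mass of nitrogen-involving vibrational modes, so the corresponding
Raman bands shift to lower wavenumber (a "red shift" of a few to a few tens
of cm⁻¹). `ramansip` is a tested Python implementation of that analysis for
the coral-symbiosis model system of the dinoflagellate *Durusdinium* sp. and
the coral-associated bacterium *Ruegeria* sp.: it simulates single-cell Raman
spectra with controllable labeling, runs the standard preprocessing chain,
locates band positions by pseudo-Voigt fitting, and quantifies per-band
isotope shifts with statistics. It also includes the spectrophotometric
chlorophyll/carotenoid quantification used alongside such co-culture
experiments.

It is aimed at microbiologists and spectroscopists who want a reproducible,
scriptable version of a workflow usually performed interactively in
instrument software.

## What it computes

**Band model.** Each Raman band is a pseudo-Voigt ("GaussLor") profile with
shared FWHM *w*:

    PV(x; A, x0, w, η) = A · [ η · L(x; x0, w) + (1 − η) · G(x; x0, w) ]

with unit-peak-height Lorentzian L and Gaussian G and mixing fraction
η ∈ [0, 1]. Band positions per cell are obtained by bounded nonlinear least
squares of one pseudo-Voigt plus a local linear background inside a window
around each reference band (neighbouring bands close to the window get a
nuisance component so their tails do not bias the center).

**Isotope labeling.** A nitrogen-sensitive band with labeling fraction *f*
is a two-component isotopologue mixture: weight 1 − *f* at the ¹⁴N center
and weight *f* at the red-shifted ¹⁵N center. The per-band shift statistic
is the difference of the per-cell median fitted centers between an unlabeled
and a labeled ramanome (the collection of single-cell spectra from one
condition), tested with a two-sided Mann–Whitney U test; a band is called
red-shifted when the shift exceeds 3 cm⁻¹ at lower wavenumber and p < 0.05.

**Preprocessing** follows the standard chain: crop (300–3500 cm⁻¹) →
cosmic-spike removal → Savitzky–Golay smoothing → blank subtraction →
asymmetric-least-squares baseline correction → optional normalization.

**Reference tables.** The package ships curated band tables for both
organisms (20 *Durusdinium* bands, 11 *Ruegeria* bands, with the documented
¹⁵N positions attached to the nitrogen-associated bands), plus the table of
41 cultured coral bacterial isolates.

**Pigments.** Chl a (µg/mL) = 12.9447 × (A665 − A720); total carotenoids
(µg/mL) = [1000 × (A470 − A720) − 2.86 × Chl a] / 221.

## Worked example

Simulate paired ¹⁴N/¹⁵N *Ruegeria* ramanomes (30 cells per condition, full
labeling) and run the complete shift analysis:

```sh
ramansip sip --simulate --reference ruegeria --n-cells 30 --seed 42 -o shifts.tsv
ramansip report shifts.tsv
```

prints

```
743.26 C-S stretch                                      shift    -0.22 cm-1 [unshifted] p=0.206 ns
824.35 aromatic ring vibration                          shift    20.64 cm-1 [red_shifted] p=3.02e-11 ****
958.87 C-N stretching                                   shift    39.20 cm-1 [red_shifted] p=3.02e-11 ****
994.42 C-C aromatic and symmetric ring breath           shift    -0.09 cm-1 [unshifted] p=0.501 ns
1157.26 C-C, C=C band stretch                           shift     0.13 cm-1 [unshifted] p=0.912 ns
1231.47 Amide III, C-N stretch, N-H coupling            shift    -0.07 cm-1 [unshifted] p=0.297 ns
1329.66 DNA, Phospholipids, purine                      shift    -0.30 cm-1 [unshifted] p=0.0232 *
1375.36 Thymine, adenine, guanine                       shift    11.01 cm-1 [red_shifted] p=3.02e-11 ****
1460.45 CH2 bending mode, C-H vibrations                shift    12.44 cm-1 [red_shifted] p=3.02e-11 ****
1573.91 Amide II, nucleic acid, Peptidoglycan           shift    -0.25 cm-1 [unshifted] p=0.181 ns
2918.07 C-H vibrations                                  shift     0.38 cm-1 [unshifted] p=0.00275 **
```

Reading the output: the four nitrogen-associated marker bands red-shift —
tyrosine's aromatic ring (824 → ~804 cm⁻¹), proline's C–N stretch
(959 → ~920 cm⁻¹), the nucleotide-base band (1375 → ~1364 cm⁻¹, an 11 cm⁻¹
shift) and the protein CH₂ band (1460 → ~1448 cm⁻¹, 12 cm⁻¹) — while bands
whose modes involve no nitrogen stay put. Note the 1329.66 cm⁻¹ row: its
tiny 0.3 cm⁻¹ displacement is statistically detectable (p ≈ 0.02) but falls
far below the 3 cm⁻¹ minimum-shift threshold, so it is correctly *not*
called a shift.

The pigment formulas are available from the same CLI:

```sh
$ ramansip pigments --a470 0.442 --a665 1.0 --a720 0.0
chl_a_ug_ml     12.9447
carotenoids_ug_ml       1.8325
```

The same workflow is available as a library (`ramansip.simulate_ramanome`,
`ramansip.run_sip_analysis`, …); every simulation takes an explicit seed and
is bitwise reproducible.

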
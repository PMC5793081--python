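# Methods

## The assay

Fucoxanthin and chlorophyll *a* are the two dominant absorbers at 445 nm
in an ethanol extract of *Phaeodactylum tricornutum*; Chl *a* alone
absorbs appreciably at 663 nm.  By the Beer–Lambert law and the
additivity of absorbance,

    A445 = a1·C_fuc + a2·C_chla,        A663 = ε663·C_chla,

with specific extinction coefficients (L·g⁻¹·cm⁻¹) a1 = 156.54
(fucoxanthin, 445 nm), a2 = 66.8 (Chl *a*, 445 nm) and ε663 = 82.04
(Chl *a*, Arnon).  Solving for the fucoxanthin concentration in mg·L⁻¹
gives the extract formula

    C_fuc = (1000/a1)·A445 − (1000·a2/(ε663·a1))·A663
          = 6.39·A445 − 5.20·A663   (full precision)

The published formula prints the A663 coefficient as 5.18; the
intermediate arithmetic behind that value is not recoverable, so the
package ships the printed coefficients (provenance `published`) as
the canonical default and exposes the re-derived ones (provenance
`derived`) as a separate path.  Reproducibility of the published method
takes precedence over our own arithmetic.

For whole cells resuspended in ethanol, non-target pigments (Chl *c*,
diatoxanthin, β-carotene) and cell debris add "background noise" at
both analytical wavelengths.  Empirically this background is linear in
the culture's A750 (a cell-density proxy; pigments do not absorb at
750 nm):

    n1(A750) = 0.14·A750 + 1          (445 nm, R² = 0.9968)
    n2(A750) = 0.233·A750 + 0.217     (663 nm, R² = 0.9962)

Subtracting the background and collecting terms in the three
absorbances yields the closed-form whole-cell rule

    C_fuc = 6.39·A445 − 5.18·A663 + 0.312·A750 − 5.27

where 0.312 = 5.18·0.233 − 6.39·0.14 (exactly 0.31234) and
−5.27 = 5.18·0.217 − 6.39 (exactly −5.26594).  Internal arithmetic is
kept at full precision; rounding to the printed 2–3 decimals is purely
presentational.  The collected and step-by-step forms agree within
0.005 mg·L⁻¹ over absorbances in [0, 2]³ — the residual is coefficient
rounding only.

### Measurement conventions

* **Dilution.** Cultures are diluted with medium (A750) or ethanol
  (A445/A663) so readings land in the instrument's reliable windows.
  `dilution_factor` = total volume ÷ sample volume; measured values are
  multiplied by it to reconstruct undiluted absorbances *before* the
  formula is applied.
* **Validity windows.** Measured A750 outside [0.1, 0.8] or A445/A663
  outside [0.2, 1] sets `below_range`/`above_range` flags; these are
  guidance, not hard failures.
* **Negative estimates** are reported with a `negative_estimate` flag,
  never clamped to zero — clamping would bias validation statistics.
* **Volumes.** Cells from a volume of culture are resuspended in an
  equal volume of ethanol, so concentrations are per litre of original
  culture with no volume correction; a configurable `extract_ratio`
  covers other extraction schemes.
* **Microplates.** 96-well readings (200 µL, ≈0.5 cm path) are divided
  by empirical per-wavelength plate/cuvette scales (defaults 0.504 at
  445 nm, 0.497 at 663 nm, 0.444 at 750 nm).  These are fitted
  through-origin per wavelength rather than taken as a single geometric
  0.5 factor, because the measured scales differ by wavelength.  A
  `pre_corrected` flag skips the division for instruments whose
  software already path-corrects.

### Calibration fits

Beer–Lambert standard curves are ordinary least squares through the
origin (a pure standard at zero concentration has zero absorbance); the
slope in AU per mg·L⁻¹ times 1000 is the coefficient in L·g⁻¹·cm⁻¹.
Background regressions include an intercept (there is a cell-free
offset).  Through-origin fits report the uncentred R² convention
(1 − SSres/Σy²).  Degenerate designs (all concentrations equal, all-zero
cuvette readings, constant A750) raise `SingularFitError` rather than
returning an arbitrary slope.  Literature "1%" (g/100 mL) extinction
coefficients convert to specific coefficients by division by 10.

## Validation statistics

Per-sample percent error is |estimate − reference|/reference × 100, the
reference (HPLC) value as baseline; this convention reproduces the
published cross-species worked values (10.98%, 9.76%, 3.47%) exactly.
Group summaries compute per-replicate errors first, then mean ± sample
SD (n−1).  Method agreement is an OLS regression of estimates on the
reference (R² = squared Pearson correlation) and a two-sided paired
t-test at α = 0.05 with no multiple-testing correction.  Two edge cases
are distinguished deliberately: identical vectors return (t = 0, p = 1)
— perfect agreement is not pathological — while a non-zero constant
shift, whose differences have zero variance, raises a degenerate-test
error because the statistic is undefined.

## The synthetic-data generator

The generator exists so the calibration, quantification and validation
code is testable without laboratory data.  It emulates:

* **Pure-pigment spectra** on a 400–800 nm, 1 nm grid as sums of
  Gaussian bands, scaled so that a 1 g·L⁻¹, 1 cm-path solution reads
  exactly the configured extinction coefficient at each anchor
  wavelength.  Chl *a* has bands near 430 and 663 nm with both anchors
  (66.8 at 445 nm, 82.04 at 663 nm) solved exactly; fucoxanthin a broad
  band at 445 nm (156.54) contributing < 10⁻³% at 663 nm.  Only the
  anchor values are physically constrained; band centres and widths are
  free, plausible choices.
* **The whole-cell background** as the A750-indexed linear models
  themselves, interpolated smoothly (shape-preserving PCHIP) between
  the three anchored wavelengths.  The baseline cannot be monotone in
  wavelength for OD750 ≳ 0.28 — the anchors themselves invert there
  (n2(A750) < A750) — so the interpolant is monotone exactly where the
  anchors are.  Its shape away from 445/663/750 nm is arbitrary and
  unused by the assay.
* **Non-target pigments.** In whole cells, Chl *c*, diatoxanthin and
  β-carotene enter through the background term — that is precisely the
  assay's own model — so their default concentrations are zero and their
  band-library entries (placeholder shapes) only matter if a user adds
  them explicitly, which deliberately injects absorbance the formula
  cannot remove.
* **Noise** as i.i.d. additive Gaussian absorbance error, default
  sd 0.005 AU (a typical replicate spread for a bench
  spectrophotometer), with an explicit integer seed on every stochastic
  operation and no global RNG state.
* **Batch simulation** draws fucoxanthin from U(1, 20) mg·L⁻¹, Chl *a*
  from U(2, 10) mg·L⁻¹ and OD750 from U(0.1, 0.8) — the assay's working
  range.

What the generator does **not** emulate: wavelength-dependent Mie
scattering, pigment photodegradation, extraction-efficiency variation,
solvent effects on band shapes, or instrument stray light.  Passing
tests therefore demonstrate internal consistency of the formulas,
calibration round-trips and statistical machinery — not field accuracy
on real cultures, which the original method established against HPLC.

## Problem sizes and numerical choices

The consistency grid for the whole-cell formula spans fucoxanthin
1–20 mg·L⁻¹ × OD750 0.1–0.8 (10×8 cells, noise-free); the mean relative
error of the shipped (rounded) formula against generator truth is
≈0.14%, dominated by the printed-versus-derived A663 coefficient and
constant rounding.  Background-recovery simulations use n = 100 points
per fit at noise sd 0.005; the type-I-error simulation for the paired
t-test uses 1000 replicates of n = 20.  Parameter-recovery assertions
on noise-free data are at 10⁻⁹ relative tolerance (fits are exact up to
floating point); noisy-fit assertions use ±0.01 on the slope, ~4
standard errors at these sizes.

## Known limitations

* The assay constants are species-specific (*P. tricornutum*); applying
  the shipped formula to other diatoms reproduces the published 3–15%
  cross-species error range, and species-specific background
  recalibration is the intended remedy — supported via
  `fit_background` + `expand_whole_cell_formula`.
* The extract-only pathway (no background correction) is exposed but
  was judged insufficiently accurate on real cultures by the method's
  authors; the package makes no claim either way.
* Only ethanol/80%-acetone coefficients are shipped; no stray-light or
  nonlinear absorbance correction.
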
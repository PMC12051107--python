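# Methods

## Physical model

DNA fragments at equilibrium in a caesium sulphate density gradient band at
the position where the salt density matches their buoyant density. The local
salt concentration is read optically: refractive index (RI) at 20 °C
converts linearly to density. The package ships the experimentally
determined calibration D = 12.46 g/ml · RI − 15.62 g/ml (38 gravimetric
points, R² = 0.9945) as `PAPER_CALIBRATION`; `fit_ri_density_calibration`
refits the line from user-supplied (RI, density) pairs by ordinary least
squares. The printed intercept is negative: bulk DNA at RI 1.3683 must map
to ≈ 1.43 g/ml.

A single homogeneous DNA species forms a Gaussian concentration profile
along the RI axis — mean = buoyant density, height ∝ amount of DNA, sigma
shrinking with fragment size. A gradient containing bulk DNA plus a denser
modified sub-population is a two-Gaussian mixture.

## Gradient handling

Gradients are pumped bottom-to-top: fraction 1 is the densest and RI
decreases with fraction index. RI is measured only for odd-numbered
fractions; `interpolate_ri` fits one regression line of RI against index
and assigns the fitted value to **every** fraction (measured readings are
kept in `measured_refractive_index` for reporting). A zero fitted slope is
rejected because downstream logic requires RI strictly monotone in index.

Raw per-fraction DNA concentrations are blanked spectrophotometer readings
(ng/µl; may be negative) sitting on a slight linear instrumental baseline.
`correct_baseline` fits concentration against RI by OLS over fractions
treated as nucleic-acid-free — by default everything except RI > 1.3780
(RNA-containing bottom) and RI ∈ [1.365, 1.372] (DNA band) — and subtracts
the fitted line from every fraction. RI, not fraction index, is the
regression abscissa because the exclusion windows are defined in RI units.
Refitting the baseline on the corrected profile returns slope and intercept
of exactly zero (an OLS identity), and the operation is idempotent.
Negative corrected values are deliberately retained; clipping would bias
the integrals.

## Mixture fitting

`fit_mixture` minimises the sum of squared residuals between corrected
concentrations and a 1- or 2-component Gaussian mixture using bounded
nonlinear least squares (`scipy.optimize.least_squares`, trf): means within
the data's RI range, σ ∈ [1e-4, 1e-2] RI, amplitudes ≥ 0. Initialisation is
multi-start — moment estimates, and for k = 2 the k = 1 solution plus a
second component seeded at the dense-window centre (1.3705) including a
near-zero-amplitude variant. The last start makes the k = 2 SSE nested
below the k = 1 SSE by construction, which the tests assert. Convergence is
reported honestly via the optimizer status; non-convergence flags, never
raises. Components are returned sorted by ascending mean and the
larger-mean component is exposed as `dense_component`.

The pipeline's k-selection rule (figures in this field typically pick k by
eye) is explicit: accept k = 2 when the SSE improves by more than 20 % over
k = 1 *and* the minor amplitude is at least 5 % of the major one; otherwise
the profile is flagged "no distinct dense DNA distribution" — the expected
outcome for S-phase cells. Both thresholds are configurable
(`PipelineConfig`).

## Dense-DNA quantification

`percent_dense` divides the integrated secondary-gradient signal inside the
extended dense window (RI 1.3700–1.3750, closed bounds) by the integrated
total signal of the primary gradient. Integration is trapezoidal over RI of
the measured corrected points; for the window integral, grid points are
inserted at the exact window bounds by linear interpolation so the result
is the integral of the piecewise-linear interpolant over the window rather
than over whichever samples happen to fall inside — this removes the
half-bin boundary error and lets a 60-fraction profile agree with the
closed-form Gaussian window mass to well under 0.5 %. Data, not fitted
curves, are integrated. Pooling windows (bulk 1.3670–1.3682, dense
1.3695–1.3715, light 1.3630–1.3660, extended dense 1.3700–1.3750) are
constants in `POOLING_WINDOWS`, overridable per call or via config.

## Interval overlap and the shuffle null

Coordinates are 0-based half-open (BED). "Overlap" means ≥ 1 bp shared —
`bedtools intersect -u` semantics, which the test suite verifies both
against a brute-force all-pairs oracle and against bedtools itself.
Duplicate rows count individually. `shuffle_per_chromosome` relocates each
interval uniformly within its own chromosome, preserving lengths, with
rejection sampling for pairwise disjointness (default 10,000 tries per
interval, placement order randomised to reduce packing bias); a chromosome
that cannot be packed raises a `PackingError` naming it. For near-full
chromosomes rejection sampling may wedge even when a valid packing exists —
acceptable for peak-like inputs whose coverage is far below saturation.
`shuffle_null_summary` reports the observed a-in-b count, the null counts
across seeded shuffles, and observed/mean(null) fold change (undefined when
the null mean is zero).

## Nucleoside composition

Reference masses for dC, 5me-dC, 5hm-dC, 5f-dC and 5ca-dC are monoisotopic,
computed from atomic masses and shipped as a package data table. Adduct
offsets are the physically correct cation-minus-electron values
([M+H]⁺ +1.00728 Da, [M+Na]⁺ +22.98922 Da); the instrument software's
"+1 / +23" shifts are nominal shorthand. Peaks are assigned to the nearest
expected adduct m/z within an absolute tolerance of 0.025 Da; exact ties
resolve by reference listing order with a warning, and multiple peaks
hitting one (nucleoside, adduct) slot are summed. Percentages are over the
five dC forms only, so dG/dA/dT or contaminant peaks simply stay
unassigned. At 0.025 Da the five references' adduct windows are ≥ 2 Da
apart and cannot collide. A zero total intensity leaves percentages
undefined (`None`) rather than raising.

## Fragment mass accounting

PCR synthesis with a modified dCTP substitutes **every** cytosine of the
synthesised strand, so mass loading counts all dC (not only CpG context):
top-strand dC = #C, bottom-strand dC = #G of the top strand. Monoisotopic
per-residue deltas vs dC are +CH₂ 14.01565 (5me), +CH₂O 30.01056 (5hm),
+CO 27.99491 (5f), +CO₂ 43.98983 Da (5ca); average-mass variants sit behind
`monoisotopic=False`. Hemi modes model one fully unmodified strand — the
real hemi-amplicons' mid-fragment polarity switch is not modelled
base-by-base. Full loading equals hemi_top + hemi_bottom exactly, for every
sequence. Ambiguity codes (N) are rejected rather than fractionally
counted. `fit_density_shift_model` is a deliberately simple empirical OLS
line from added mass per bp to observed mean RI; no first-principles
density prediction is attempted.

## Synthetic data: what it does and does not emulate

Generators are pure functions of spec + seed (bit-identical reruns).
`simulate_gradient` draws concentrations as mixture + baseline
(slope·RI + intercept; defaults 150 and −202 ng/µl give a gentle 2→5 ng/µl
tilt across the RI 1.3800→1.3600 ramp) + heteroscedastic Gaussian noise
with s.d. = CV·|clean| + floor (defaults 2 % and 0.05 ng/µl), on 60
fractions with RI measured only on odd fractions. `study_gradient_specs`
bundles the five study scenarios at their reported component parameters
(bulk 1.3683/0.00163; light re-run 1.3672/0.0014; biphasic 1.3685/0.0012
plus dense 1.3706/0.0013 at 3:1 amplitudes; late-G1 dense 1.3701/0.0009;
S-phase bulk-only), with peak heights of 10 ng/µl for the major component.

Not emulated: RI measurement error (the plotted RI regressions are visually
exact), non-linear gradient shapes, RNA contamination peaks, fraction
volume variation, and any sequence-composition ↔ density coupling. Passing
parameter-recovery tests therefore demonstrates that the analysis chain is
correct and unbiased under the stated noise model, not that real gradients
meet that model. Interval and MS generators construct their ground truth
exactly (⌊overlap_fraction·n⌋ overlapping intervals; intensities split per
adduct), so round-trip tests are exact identities by design.

## Numerical choices and known limitations

- Optimizer tolerances are tightened (xtol = ftol = gtol = 1e-15,
  ≤ 2000 evaluations per start) so noiseless single-Gaussian recovery is
  exact to ≤ 1e-6 RI.
- Window bounds are closed on both ends throughout.
- For the strongly overlapped biphasic secondary (component means 0.0021 RI
  apart at 3:1 amplitudes), per-replicate estimates of the dense mean carry
  ~3e-4 RI scatter that no estimator can remove: the dense tail protrudes
  past RI 1.372 into the baseline-fit region (a property of the published
  correction windows, reproduced faithfully), and 2 % noise puts the fit
  near its information limit. Medians across 20 replicates recover the
  generating means to ~1e-4. Single-component scenarios recover means to
  ~3e-5 even at 5 % CV.
- Problem sizes used throughout (60-fraction gradients, 20 replicates,
  ≤ 500-interval oracle comparisons on a 1.7 Mb toy genome) were chosen as
  the smallest at which the statistics are stable; everything runs in
  seconds.
- Fitting more than two components, estimating fragment size from sigma,
  peak calling, read alignment and genome-scale overlap percentages (which
  require the study's deposited sequencing data) are out of scope.
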
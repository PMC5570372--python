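# Methods

## The measurement model

A scheduled-MRM assay acquires, for every compound, two
precursor→product transitions: the quantifier (more intense, used for
quantification) and the qualifier (used only to confirm identity via
the quantifier/qualifier area ratio, MRM_qc). One full sweep over all
transitions in both polarities — the duty cycle — takes 0.73 s, which
fixes the chromatographic sampling rate: a 12 s peak (the narrowest in
the panel) is sampled ⌊12/0.73⌋ = 16 times, just above the ≥ 15
points-per-peak requirement for reproducible integration.

Quantification is by isotope dilution: every sample carries a fixed
amount of stable-isotope-labelled internal standard (25 nM-equivalent:
5 µl of a 2 µM stock into a 400 µl lysate), and the measured response
is the analyte/IS quantifier-area ratio. Because analyte and IS share
extraction, injection and ionisation conditions, sample-level
variability cancels in the ratio.

## Calibration and weighting

Calibration fits the area ratio y against the nominal spiked
concentration x by weighted least squares with w = 1/x (equal weights
available). MRM area noise is predominantly proportional, so over a
range spanning three to four decades (0.016–50 nM or 0.01–500 nM) the
absolute residual variance grows with x²; an unweighted fit is then
dominated by the top calibrators and its intercept error, translated to
concentration, is catastrophic at the bottom of the range. The
weighted coefficient of determination is r² = 1 − SSE_w/SST_w with the
weighted mean in SST_w; with equal weights this is exactly the Pearson
r². The fit itself is delegated to `statsmodels` WLS; the test suite
cross-checks it against independently coded normal equations.

Back-calculation inverts the line. Negative raw values (blanks near
zero) are reported as 0 with a `clipped` flag rather than raised;
values outside the fitted range carry an `extrapolated` flag.

Lower limits follow the usual acceptance rules: LLOQ is the lowest
calibrator whose per-level CV and |accuracy − 100| are within 20% and
whose S/N exceeds 10:1; LLOD the lowest level with S/N above 6:1. The
search returns the lowest *passing* level without requiring all lower
levels to fail. When blanks contain endogenous analyte at or above a
candidate level (≈ 0.06–0.10 nM T0 in hepatocyte lysates, ≈ 0.01 nM
T3/T4 in thyrocyte lysates), the corresponding limit is reported as
not-available with the background concentration flagged. Because
calibrators are spiked *on top of* the matrix, the background sits in
the curve's intercept; the blank's endogenous concentration is
therefore estimated as its ratio over the origin (ratio/slope), not by
ordinary back-calculation, which would return ≈ 0 by construction.

The thyrocyte design spans calibrators to 500 nM but fits a default
working range of 0.01–125 nM; levels above the range are excluded from
the regression. Replicate-level points (pooled over days) enter the
fit rather than per-level means; both choices are configurable.

## Validation statistics

Accuracy is 100·(mean measured)/(nominal); precision is the percentage
CV (sample sd over mean). Inter-day statistics pool one mean per day
(n = days); intra-day statistics use the replicates of a single day.
QC levels below an analyte's LLOQ are rendered `<LLOQ>`-style rather
than numerically.

The three-way spiking design quantifies where analyte is lost:
solvent-spiked (no matrix), post-extraction-spiked (matrix, no
extraction losses) and pre-extraction-spiked (matrix and extraction).
We adopt the standard Matuszewski convention — ME = post/solvent,
RE = pre/post, PE = pre/solvent — under which PE = ME·RE/100 holds
exactly on expectation values. Published reports of this assay family
occasionally swap the PE/RE labels in prose; the bundled reference
tables are numerically consistent only with the convention used here
(maximum deviation from the identity ≤ 6 percentage points, attributable
to rounding of replicate means), which is why it was adopted.

## Identity confirmation and mass balance

A metabolite is confirmed when its apex retention time is within a
window (default ±0.1 min; observed deviations in practice are
≤ 0.03 min) *and* its MRM_qc deviates from the neat-standard ratio by
at most ±20% (signed deviation 100·(observed/expected − 1)). An absent
or zero-area qualifier leaves the ratio undefined and can never
confirm. Confirmation is monotone in the tolerance.

Amounts convert as pmol = nM × mL (0.4 mL lysate, 1.5 mL supernatant
by default; supernatant concentrations measured on a 400 µl aliquot
are scaled to the full compartment). Each compound/compartment/time
cell is expressed as a percentage of the incubated amount; per-time
totals sum the *unrounded* percentages over both compartments for all
detected compounds and are rounded last (pmol to integers, percentages
≥ 1% to integers, smaller ones to 1–2 decimals). Not-detected entries
are kept as explicit `nd`, distinct from zero, and contribute nothing
to totals. No recovery correction is applied, so totals typically
close at 66–84%, not 100%.

The bundled thyrocyte time-course dataset contains one internal
inconsistency: the mono-iodothyronine supernatant percentages printed
in its source do not follow from the printed pmol (498/775.9 = 64%,
not 62%). This package reproduces the arithmetic from the pmol
amounts; that row is excluded from exact display checks.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
not the chemistry:

* **Peaks** are pure Gaussians (σ = base width/4, default 12 s base
  width, no tailing), sampled at the duty cycle, with optional additive
  Gaussian baseline noise.
* **Areas** carry two log-normal multiplicative factors, both with
  unit mean: a per-sample factor (`sample_cv`, default 8%) shared by
  every area in a sample, and an independent per-area factor
  (`proportional_cv`, default 6%). IS areas carry only the shared
  factor: at 25 nM the IS sits far above the noise floor, so its
  independent error is negligible next to analytes near the LLOQ.
  Ratio noise therefore equals the proportional CV, and per-level CVs
  grow toward the LLOQ in the way that motivates 1/x weighting.
* **Matrices** apply a suppression factor (ME), a recovery factor (RE)
  and endogenous background: hepatocyte lysate 0.87/0.84 with 0.08 nM
  T0, thyrocyte lysate 0.91/0.84 with 0.01 nM T3 and T4 — the centre
  of the ranges such assays report (ME 70–106%, RE 73–101%).
* **Designs** reproduce the published study layouts: 11 calibrators
  0.016–50 nM with QCs at 0.10/12.5/40 nM for hepatocytes (8 inter-day
  batches), 12 calibrators 0.01–500 nM with QCs at 0.10/1.0/2.5 nM for
  thyrocytes (3 batches).
* **Time courses** are descriptive fraction tables (no rate law — the
  quantity of interest is the fraction accounted per compartment, not
  kinetic constants), with unaccounted loss closing the balance
  exactly in the noise-free generator. The built-in thyronamine
  scenario reproduces cellular uptake rising 238→276→334 pmol of
  812.7 pmol incubated over 5/10/30 min.

Every generator is deterministic under its seed and returns ground
truth alongside the data, so tests assert parameter *recovery*. What
passing tests do **not** show: robustness to peak tailing,
co-elution, retention-time drift between runs, carryover, or
non-log-normal interference — real chromatograms contain all of
these and the generator none.

## Numerical choices and problem sizes

* Integration: trapezoidal above a straight baseline between the
  integration bounds; areas clipped at 0.
* Peak bounds: crossing of baseline + 1·noise sd, capped at ±12 s
  (≈ ±4σ for the default width); apex threshold baseline + 3·noise sd;
  ties between candidate apices go to the one closer to the expected
  retention time, then to the taller.
* Noise estimation: sd of a signal-free window, default the 0.5 min
  before the retention-time window. Zero sd (noise-free synthetic
  data) yields S/N = ∞, which passes any threshold.
* The weighted fit requires ≥ 3 distinct concentrations; all-equal x
  raises a singular-fit error.
* Test and acceptance runs use 1–8 day designs with 3 replicates per
  day over the 17-analyte panel — a few thousand simulated areas per
  run, which keeps the whole suite in the low seconds while every
  statistic still has the replication structure (days × replicates ×
  levels) of the full study.

## Known limitations

* No deconvolution of co-eluting peaks, smoothing, or cross-run
  retention-time alignment; isobaric di-iodothyronine isomers rely on
  chromatographic separation, and overlapping windows should be
  screened with narrower windows rather than trusted silently.
* No quadratic calibration, 1/x² weighting, or carryover correction.
* No stability or dilution-integrity testing.
* Positive-ion MRM parameters in the default registry are placeholders
  (the negative-ion thyroacetic-acid block is real); users must supply
  their instrument's tuned values for real data.
* Kinetic rate constants are out of scope; time-course trends are
  classified descriptively (relative first-to-last change against a
  10% threshold).
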
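# Methods

## Assay model

The package implements the calculation chain of a standardized M86
ELISA inhibition assay for α-Gal antigen. Antigen in a lysed sample
binds and removes M86 antibody before the ELISA step, so the OD450
signal falls as antigen rises. The chain is:

1. **Inhibition rate.** `Y = 100·((a−b)−(c−d))/(a−b)` with `a` the mean
   OD of the 100%-reaction control, `b` the blank, `c` the sample well.
   The formula's fourth symbol `d` is the blank applicable to the sample
   well; the protocol runs a single shared plate blank (lysis buffer
   alone), so `d = b` and the rate reduces to `100·(a−c)/(a−b)`. Raw
   rates outside [0, 100] are *kept* for fitting — clamping would bias
   the calibration — and only flagged at reporting time.
2. **Calibration.** `Y(x) = A·e^(−x/t) + y0` fitted to the Gal-BSA
   standard series by unweighted nonlinear least squares over all
   replicate points (not replicate means). Although such saturation
   curves are colloquially called "hyperbolic", the exponential form
   above is the fitted model. `A` (%, expected < 0) is the negative
   amplitude, `t` (µg/mL) the decay scale, `y0` (%) the plateau.
3. **Inverse prediction.** `x = −t·ln((Y−y0)/A)`, the exact inverse.
   Quantification only inside `[x_min, x_max]` (the smallest/largest
   standard); outside, results carry a censoring flag (`below_ldl`,
   `above_range`) instead of an extrapolated number.
4. **Epitope arithmetic.** Gal-BSA ≈ BSA in mass (66.33 kDa) with ~20
   epitopes per molecule, so epitopes/g = N_A/66330 × 20 ≈ 1.82×10²⁰
   (9.08×10¹⁸ molecules/g at 3 significant figures, with
   N_A = 6.02214×10²³/mol). A sample at concentration `x` µg/mL
   (dilution-corrected) in a `V` mL reaction aliquot carries
   `x·V·10⁻⁶·1.82×10²⁰` epitopes, normalized per mg tissue or per cell
   represented in that aliquot. Counts are floats throughout; they
   exceed 10¹⁴ routinely and integer semantics buy nothing.

### Concentration basis

Standards and samples are expressed on the *pre-mix lysate* basis: the
concentration of the 100 µL lysate aliquot before the 1:1 mix with
antibody solution (which takes M86 from 1:100 to 1:200 final). Keeping
both on the identical basis is what makes the standard curve
transferable to samples; the epitopes-per-reaction figure uses that same
100 µL aliquot. "Wet" vs "freeze-dried" mass is carried as metadata
only (`per_mg_wet` / `per_mg_dry`); no conversion between the two is
attempted.

## Fitting details

* Parameters are optimized as `(A, log t, y0)` (Levenberg–Marquardt),
  so `t > 0` by construction. `A` and `y0` are unconstrained, but a fit
  with `A ≥ 0` — a non-increasing curve — is flagged non-usable and all
  downstream quantification refuses it.
* Initialization: `y0 ← max observed inhibition`; `A ← (mean inhibition
  at the lowest level) − y0`; `t` from a log-linear regression of
  `log(y0 − Y)` on `x` over points with positive residual plateau
  distance (the model gives slope `−1/t`). For monotone saturation data
  this start is inside the convergence basin; for flat (zero-dependence)
  data the optimizer converges to `A ≈ 0` and the usability flag
  catches it.
* At least 4 distinct concentrations are required (3 parameters + 1
  degree of freedom). The reference design uses a 10-level two-fold
  series, 20 → 0.039 µg/mL, 3 parallel wells each; any replicate count
  ≥ 1 is accepted with a warning below 3.
* Numerical limit of the inversion: the curve is resolvable from its
  plateau only while `|A|·e^(−x/t)` is well above float epsilon of
  `y0`; beyond roughly 15 decay scales the round-trip
  `invert(predict(x)) = x` degrades. Real standard ranges sit within a
  handful of decay scales, far from that regime; the property tests
  bound their sampled ranges accordingly.

## Detection limit

The protocol defines the LDL operationally: extend the dilution series
downward until a level is no longer detectable; the LDL is one step
above that level. The protocol does not state a detectability
criterion, so the package adopts an explicit one: a level is *detected*
when its replicate inhibition values are significantly greater than
zero by a one-sided one-sample t-test at α = 0.05 (default). With
fewer than 3 replicates the t-test is hopelessly underpowered; the
fallback rule is mean inhibition > 3 × SD of the negative-reference
inhibition values, which the caller must supply. When every tested
level is detected, the lowest tested concentration is reported with an
`ldl_anchored = False` flag (the true LDL is only bounded above); when
none is, or when the top of the series is undetectable while lower
levels are not, the run is an assay failure.

In the reference conditions the lowest series level, 0.039 µg/mL, is
detectable: at 0.1 mL reaction volume this is 3.9 ng Gal-BSA ≈ 7.1×10¹¹
epitopes per reaction — the method's headline sensitivity. (A
published companion figure of "39 ng" refers to the same 0.039 µg/mL
level via the 1 mL of prepared lysate rather than the 100 µL aliquot;
the per-reaction reading, 3.9 ng ≈ 7.1×10¹¹, is the one this package
reports.)

## QC gates and validation statistics

* **Specificity (negative gate).** ODs of the negative (human-derived)
  reference material vs the 100%-control ODs, Welch two-sample t-test;
  pass when p > α (no inhibition, hence no false positive). With two
  groups a one-way ANOVA is equivalent to the pooled t-test; Welch's
  form is used because group sizes and variances differ (n = 3 vs 9 is
  typical). Degenerate zero-variance groups fall back to exact mean
  equality.
* **Accuracy (positive gate).** The published criterion reads "CV less
  than 15% compared to its defined value"; a CV against a single fixed
  value is not otherwise defined, so it is implemented as relative
  deviation of the measured mean from the certified value < 15%.
* **Repeatability.** CV (= RSD = 100·SD/mean, sample SD, n−1) per
  inter-day and intra-day group plus the pooled total.
* **Homogeneity.** Between-unit RSD < 15% (default threshold).
* **Stability.** Welch t-test *from summary statistics* per storage
  condition against the certified mean/SD/n. A condition is flagged
  unstable only for degradation — p < α **and** mean below the
  certified mean; significantly elevated means are reported but not
  flagged, matching how reference-material stability is adjudicated
  (an apparent content increase is not instability of the analyte). No
  multiplicity correction is applied across conditions; with 16
  conditions at α = 0.05 the family-wise false-flag rate is
  non-trivial, a documented caveat.
* Reported precision: epitope counts to 3 significant figures,
  percentages to 2 decimals, ties away from zero. `summary_stats` can
  additionally form the CV from the mean and SD rounded to a stated
  number of decimals (`report_decimals`), the convention of reports
  whose CV row is computed from the printed summary values; the default
  is full precision.

## Plate simulator

The simulator runs the measurement model forward: a well at lysate
concentration `x` has expected inhibition `Y(x)` from the truth curve
and expected OD `c = b + (a−b)(1 − Y/100)`; realized ODs get
multiplicative Gaussian noise (`OD × (1+ε)`, `ε ~ N(0, cv)`), truncated
at 0 rather than resampled — plate-reader noise scales with signal.
Controls and blanks are drawn with the same noise model around `a` and
`b`. Multi-plate datasets use sub-seeds `seed + plate_index`.

Defaults are the assay's reference conditions: the 10-level two-fold
standard series, 3 parallel wells per group, control OD ≈ 1.16, blank
0.10, truth curve A = −100, y0 = 100 (0% inhibition at zero antigen,
100% plateau — the idealization the inhibition-rate formula implies)
with t = 3 µg/mL placing IC50 ≈ 2.1 µg/mL mid-series, and a 15% read
CV matching the dispersion observed on real 100%-control replicates.

What the simulator does *not* emulate: edge/position effects, drift
across plates, heteroscedastic blank noise, matrix effects, antibody
depletion kinetics, or pipetting serial-dilution error correlation.
Closed-loop tests passing therefore demonstrate correctness of the
calculation chain under the stated noise model, not robustness to every
artifact of real plates.

Simulation-based test sizes: the stochastic recovery property uses 200
plates at 10% OD noise (a mid-curve sample recovers within 15% of truth
in ≥ 90% of plates, ~1 s total); the single-condition tissue round-trip
uses 10 plates. Seeds are fixed in the tests; `numpy.random.default_rng`
makes them platform-stable.

## Known limitations

* Single curve family (exponential saturation); 4PL/5PL alternatives,
  weighting schemes and inverse-prediction confidence intervals are out
  of scope.
* No inter-laboratory reproducibility modelling beyond pooled CV.
* The LDL rule reports a *series-relative* limit; it cannot see below
  the lowest tested concentration (hence the anchored flag).
* Certified constants (20 epitopes/molecule, 66.33 kDa) are treated as
  exact method parameters; their own uncertainty is not propagated.
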
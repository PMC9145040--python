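# Methods

This note documents the models, numerical choices and assumptions behind
cathquant, in the order data flow through the pipeline. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Method model

The assay is described entirely by a transition table plus a configuration
object. Each table row is one MRM channel: analyte, role (parent,
metabolite, internal standard, or qualitative screen), retention time,
precursor/product m/z, quantifier/qualifier kind, cone voltage, collision
energy, dwell time and — for two-transition analytes — the expected
qualifier/quantifier area ratio in (0, 1]. Metabolite qualifier channels
belong to a confirmatory sub-method: they are flagged confirmation-only and
never quantified. Units are fixed package-wide: ng/mL, minutes,
intensity·min.

Tolerances (defaults): RRT ±2.5 %; bias and CV ±20 %; matrix-effect
deviation ≤25 % with CV ≤15 %; S/N ≥ 3 (LOD) and ≥ 10 (LOQ); calibration
R² ≥ 0.990; retention window ±0.15 min. The retention window resolves the
closest-eluting pair in the panel (0.31 min apart) with margin. Ion-ratio
tolerance is a step function of the expected ratio — ±20 % above 0.50,
±25 % in (0.20, 0.50], ±30 % in (0.10, 0.20], ±50 % at or below 0.10 — the
relative windows in common forensic confirmation practice; the bands are
configurable.

LC gradient and source settings are carried as an opaque metadata string;
no computation reads them.

## Synthetic data

The simulator stands in for instrument data and deliberately reproduces
only the statistical structure the validation design assumes:

* **Response.** Quantifier peak area = response factor × concentration.
  Default response factors equal the packaged calibration slopes times a
  nominal internal-standard area of 20 000 intensity·min (at the 500 ng/mL
  spiking level), so a noise-free batch reproduces the published PAR
  slopes exactly. The absolute scale is arbitrary — the assay only ever
  uses area ratios. Screen channels get a flat 1000 area/(ng/mL) factor.
* **Peak shape.** Pure Gaussian, σ = 0.03 min, sampled at 0.01 min over
  ±0.5 min around the expected retention time. Exponentially-modified
  shapes (tailing) are out of scope; area and S/N logic do not depend on
  the shape.
* **Noise.** Mean-one lognormal multiplicative variation per injection
  (within-run CV, default 5 %), a shared mean-one lognormal factor per run
  (between-run CV, default 3 %), and additive Gaussian baseline noise
  (SD 600 intensity units). The lognormal keeps areas positive; the
  defaults match the replicate/run error magnitudes of the validation
  design. With the default scale the weakest responder has S/N ≈ 14 at the
  1 ng/mL LOQ and simulated LODs fall in the 0.05–0.3 ng/mL decade.
* **Matrix effects.** An optional per-sample multiplier applied to analyte
  channels only (never the IS), so post-extraction set-A/set-B comparisons
  measure exactly the injected suppression/enhancement.
* **Carryover.** A configurable fraction of the previous injection's area
  on the same channel is added, deterministically, to the next injection in
  injection order (default 0).
* **Qualifier channels.** Scaled by the analyte's expected ion ratio before
  noise. Metabolite sub-method qualifiers have no published ratio; the
  simulator uses a synthetic 0.5.
* **Randomness.** One master seed; every (sample, analyte, channel) gets a
  child stream derived from stable hashes, so traces are independent of
  insertion order and of which other channels are simulated. Run effects
  draw from their own per-run streams.

What the simulator does **not** emulate: urine matrix chemistry, extraction
recovery, retention drift, tailing/fronting, isotope patterns, detector
saturation, or concentration-dependent ionisation. Passing tests therefore
demonstrate that the *analysis* pipeline is correct under the assumed error
structure, not that the physical assay performs to specification on real
extracts.

## Peak processing

The apex is the raw-intensity maximum inside the retention window (earliest
point wins ties). Peak width σ̂ comes from the full width at half maximum;
integration boundaries are the nearest local minima of a 5-point moving
average, capped at apex ± 4σ̂. A straight baseline between the boundaries
is subtracted and the residual integrated by the trapezoid rule; sampling
at σ/3 or finer keeps a Gaussian's area within 1 % of h·σ·√(2π). Background
noise is the SD of the trace outside the window after subtracting a 9-point
rolling median (removing slow drift while preserving white noise); S/N is
baseline-corrected height over that SD, with +∞ as the zero-noise sentinel.
A peak counts as found only when its height exceeds 3× noise. Non-uniform
or non-increasing time vectors are rejected, not silently repaired.

## Calibration and censoring

Curves are straight lines in (level, PAR), fitted by weighted least squares
(statsmodels WLS) with weights 1/x by default; 1/x² and unweighted are
selectable. R² is reported on the weighted regression (about the weighted
mean) with the unweighted R² kept alongside. At least five distinct levels
are required. Zero/blank samples never enter the fit.

Back-calculation: concentration = DF × (PAR − intercept)/slope. Censoring
precedence is above-diluted-ULOQ > above-ULOQ > below-LOQ; negative
estimates clamp to zero with the below-LOQ flag; a diluted measurement
still above the top calibrator is reported as "> DF × ULOQ". Report
formatting follows the study tables: integers from 100 ng/mL, one decimal
below.

A statistical property worth knowing: with ~7 % PAR noise per point, the
back-calculated 1 ng/mL level of a 1/x-weighted eight-point curve has an
~18 % SD dominated by the intercept estimate, so single-curve LOQ-level
recovery outside ±20 % is a routine tail event, not a defect. The test
suite asserts the median over replicate curves for this reason.

## Validation battery

* **Bias**: 100 × (grand mean − nominal)/nominal over the 5 × 3 QC design.
* **Precision**: one-way ANOVA with runs as groups. Pooled within-run CV =
  √MS_within/grand mean; between-run (intermediate) CV adds the between-run
  variance component max(0, (MS_between − MS_within)/n), truncated at zero,
  and therefore never falls below the within-run CV. A literal mode (SD of
  run means / grand mean) is available for spreadsheet parity.
* **Carryover / interference**: any blank-panel peak whose apparent
  concentration reaches the analyte's LOD fails. Blank areas are converted
  through the slope alone — subtracting the fitted intercept would let a
  slightly negative intercept manufacture apparent concentration from a
  signal-free trace.
* **LOD**: smallest tested concentration whose mean S/N ≥ 3 above the
  largest failing level (default grid 0.05–1 ng/mL); an all-passing series
  returns the lowest tested level. **LOQ** is assigned as the lowest
  calibrator, with a warning if it does not exceed the estimated LOD.
* **Matrix effect**: 100 × mean(B)/mean(A) with the CV of set B; pass when
  the deviation from 100 % is ≤25 % and CV ≤15 %.
* **Stability**: % loss of mean area versus day zero, stable while within
  ±20 %. **Dilution integrity**: bias after DF correction, ±20 %, boundary
  inclusive (as are all pass/fail boundaries).

## Confirmation and screening

Confirmation references are taken from the batch itself — RRT from the
150 ng/mL calibrator, ion ratios as the mean over the QC injections — with
the transition table as fallback, mirroring how spiked samples anchor
acceptance in practice. The confirmation verdict is the conjunction of:
both ions present, RRT within ±2.5 %, ion ratio within its band, and
concentration above the LOQ (censored above-range results qualify).
Degrading any single criterion can only remove a confirmation, never create
one.

The qualitative screen requires found peaks in both product-ion channels
within 0.05 min of each other, and grades by quantifier area: "+" up to
10⁵, "+++" from 10⁶, "++" between. The source tables print grades without
thresholds, so these are package defaults on the simulated-area scale.

## Study pipeline and problem sizes

`run_pipeline` composes one batch: 8 calibrators, 3 carryover blanks after
the top calibrator, a zero control, triplicate QCs at each of 30/400/800
ng/mL, and the 52 case unknowns (three of which carry the reported
positive-sample concentrations; the S49 dihydro-metabolite is set above
5× ULOQ so it stays censored after 1:5 dilution). The batch QC gate
requires every calibration R² ≥ 0.990, every triplicate-mean QC bias within
±20 %, and carryover-free blanks; the CLI exits non-zero when the gate
fails. Above-range unknowns trigger an automatic 1:5 diluted re-injection
(simulated on the fly, or taken from a `<sample>-DF5` entry when the batch
is read from files). These sizes — one analytical run, ~70 injections,
~4 000 simulated traces — keep a full pipeline execution at a few seconds
while exercising every stage; the simulated 5-run × 3-replicate validation
experiment quantifies all 26 analytes against per-run curves.

## Known limitations

* Published per-analyte LODs, slopes and case concentrations derive from a
  real instrument; the package reproduces their *roles* (fixtures drive the
  simulator and summaries) but cannot re-measure them.
* Co-eluting peaks are separated only by the retention window; no
  deconvolution.
* The simulator's matrix-effect and carryover models are first-order
  multiplicative/additive idealisations.
* Only processed-sample stability is modelled; long-term frozen-matrix
  stability is out of scope, as are quadratic calibration and
  standard-addition quantification.
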
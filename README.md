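# cathquant

Targeted LC–MS/MS quantification and method-validation toolkit for a
26-analyte synthetic-cathinone urine panel (16 parent drugs and 10
keto-reduced "dihydro" metabolites, with MDPV-d8 as internal standard),
plus a qualitative methamphetamine/MDMA screen.

It is written for forensic/clinical toxicology data analysts who want the
full quantitative MRM workflow as inspectable, testable code rather than
vendor software: multiple-reaction-monitoring method definition, peak
integration, weighted calibration, the standard validation battery
(SWGTOX/ASB 036-style), forensic identity confirmation and censored
reporting. Because no raw instrument data accompany the published panel,
the package includes a chromatogram simulator that reproduces the study's
batch structure and error model, so every pipeline stage can be exercised
end to end.

## The model

Each analyte is monitored on one or two MRM transitions. Quantification
uses the peak-area ratio against the internal standard,

    PAR = peak area of analyte / peak area of IS,

calibrated over eight non-zero levels (1–1000 ng/mL; metabolites swap the
seventh level from 500 to 750 ng/mL) by weighted least squares with 1/x
weights, accepted when R² ≥ 0.990. Validation computes

* bias (%) = 100 × (grand mean − nominal) / nominal over a 5-run × 3-replicate
  QC design at 30/400/800 ng/mL;
* within-run CV = 100·√MS_within / grand mean and between-run (intermediate)
  CV = 100·√(MS_within + max(0, (MS_between − MS_within)/n)) / grand mean,
  from the one-way ANOVA decomposition (both limited to ±20 %);
* matrix effect ME (%) = 100 × mean(B)/mean(A) from post-extraction-spiked
  (B) versus neat (A) sets, accepted when |ME − 100| ≤ 25 % with CV ≤ 15 %;
* carryover, interference, LOD (S/N ≥ 3), LOQ (lowest calibrator, S/N ≥ 10),
  processed-sample stability (±20 %) and 1:5 dilution integrity (±20 %).

A finding is confirmed only when both product ions give peaks, the relative
retention time (analyte Rt / IS Rt) matches the in-batch reference within
±2.5 %, the qualifier/quantifier area ratio falls inside its tolerance band
(±20 % for ratios > 0.5, widening to ±50 % for ratios ≤ 0.1), and the
concentration exceeds the LOQ. Results outside the calibrated range are
censored: "<LOQ", ">1000", or ">5000" when a 1:5-diluted re-injection still
exceeds the upper limit.

## Worked example

Run the simulated 52-sample case study (calibration, QC gate, carryover
blanks, quantification, confirmation, screening) from the command line:

```
$ cathquant run --seed 7
3/52 samples positive (5.8%): S19, S34, S49
```

or from Python:

```python
from cathquant import run_pipeline

result = run_pipeline(seed=7)
for report in result.reports:
    if report.positive:
        print(report.sample_id,
              [(f.analyte, f.reported) for f in report.findings],
              dict(report.qualitative))
```

which prints

```
S19 [('Dihydro-mephedrone', '183')] {'Methamphetamine': '+'}
S34 [('Dihydro-N-ethylpentylone', '1319'), ('N-ethylpentylone', '55.8')] {'Methamphetamine': '+++'}
S49 [('Dihydro-mephedrone', '>5000'), ('Mephedrone', '1569')] {'MDMA': '+', 'Methamphetamine': '+++'}
```

Three samples carry confirmed synthetic cathinones (5.8 % of the batch);
the concentrations are the simulator's noisy realisations of the spiked
truth (172, 52/1378 and 1537 ng/mL), dihydro-mephedrone in S49 stays above
the quantifiable range even after 1:5 dilution and is censored as
">5000" ng/mL, and every positive also shows classical-stimulant use in the
qualitative screen.

Summaries of the packaged validation tables:

```
$ cathquant validate --fixture table3
grand bias range: -16.9 to 9.5 %
QC 30 ng/mL: max within-run CV 12.9 %
QC 400 ng/mL: max within-run CV 10.2 %
QC 800 ng/mL: max within-run CV 7.8 %
QC 30 ng/mL: max between-run CV 13.4 %
QC 400 ng/mL: max between-run CV 10.4 %
QC 800 ng/mL: max between-run CV 7.9 %
```

## Layout

* `cathquant.method_model` — transition table, tolerances, batch configuration
* `cathquant.fixtures` — packaged CSV transcriptions of the published tables
* `cathquant.synthetic_data` — chromatogram/batch simulator and study designs
* `cathquant.peaks` — peak detection, integration, noise and S/N estimation
* `cathquant.quant` — PAR, weighted calibration, back-calculation, censoring
* `cathquant.validation` — bias/precision (ANOVA), carryover, LOD/LOQ, ME,
  stability, dilution integrity, interference
* `cathquant.confirm` — identity confirmation and the qualitative screen
* `cathquant.cli_report` — pipeline orchestration, reports, CLI

See `docs/methods.md` for the modelling choices, simulator assumptions and
known limitations.
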
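# methindex

Quantitative *MGMT* promoter methylation analysis for glioblastoma:
a bisulfite-Sanger **methylation-index caller** (0–17 scale with
conversion-control QC) and the **nonlinear survival modelling** that goes
with it — Cox proportional-hazards fits under binary / tertile / quintile /
continuous codings of the index, restricted-cubic-spline / B-spline /
P-spline hazard curves, and martingale/Schoenfeld residual diagnostics —
plus a calibrated synthetic-data generator so the whole pipeline is testable
without any external data.

## The problem

*MGMT* encodes a DNA-repair protein that undoes the damage alkylating
chemotherapy inflicts on glioblastoma cells; methylation of the *MGMT*
promoter silences the gene and sensitizes the tumor. Clinically the marker
is usually dichotomized (methylated / unmethylated), discarding how *much*
of the promoter is silenced. A bisulfite Sanger assay of a 191 bp promoter
amplicon scores each of 17 CpG sites as methylated or not — cytosines
surviving bisulfite conversion mark methylation, while 31 non-CpG cytosines
in the same amplicon act as built-in conversion controls that must all read
as thymine before an index is reported. The count of methylated sites is a
0–17 **methylation index**. The statistical question is the functional form
of the index's prognostic effect: is each additional methylated site equally
protective, or is the hazard curve nonlinear, with low-level methylation
*worse* than none and a protective trough at intermediate indices?

## The model

For patient *i* with covariates (age, Karnofsky performance status, IDH1
mutation, extent of resection) and methylation index *x*, the hazard is

    h(t | x, z) = h0(t) · exp( f(x) + z'γ )

where `f` is, depending on the coding: a step function over index groups
(reference: index 0; tertiles 1–6 / 7–12 / 13–17; quintiles 1–3 / 4–6 /
7–9 / 10–13 / 14–17), a linear term, or a spline. Splines are restricted
cubic (natural) with 5 knots by default, or (penalized) cubic B-splines;
the fitted `f(x) − f(0)` is reported as a pointwise log-hazard-ratio curve
with a Wald band. Functional form is cross-checked by LOWESS-smoothed
martingale residuals of a null model, and proportional hazards by scaled
Schoenfeld residuals against Kaplan–Meier-transformed time.

The synthetic cohort generator reproduces the study structure this analysis
was designed for: 240 patients (115 unmethylated, tertile strata of
44/38/43), stratum-specific covariate distributions, survival times drawn
by inverse-CDF sampling under the proportional-hazards model with tertile
hazard ratios 1.62 / 0.48 / 0.62 (overall survival) and 0.85 / 0.27 / 0.46
(progression-free survival), an exponential baseline calibrated so the
unmethylated arm's median OS is 14 months (PFS 8 months), and per-stratum
dropout calibrated to censoring fractions of 40.9 / 15.9 / 21.1 / 7.0%.

## Worked example

Simulate one study-sized cohort and fit the adjusted tertile model:

```sh
methindex simulate-cohort --seed 11 --out cohort.csv
methindex fit --cohort cohort.csv --endpoint os --coding tertile --covariates age,kps,idh1
```

```
     model                 variable           hr        ci         p
OS tertile unmethylated (reference)    Reference Reference Reference
OS tertile                 meth_1-6         2.16 1.40-3.33  0.000478
OS tertile                meth_7-12         0.46 0.29-0.75   0.00152
OS tertile               meth_13-17         0.72 0.48-1.09     0.125
OS tertile                      age         1.02 1.01-1.03   0.00279
OS tertile                      kps         0.98 0.97-1.00    0.0122
OS tertile                     idh1         0.47 0.26-0.88    0.0186
OS tertile                  LR test        44.68      df=6   5.4e-08
OS tertile                Wald test        43.48      df=6   9.4e-08
OS tertile             Logrank test        44.36      df=6   6.3e-08
OS tertile         Concordance (SE) 0.66 (0.022)
```

Read: relative to unmethylated tumors, low-level methylation (1–6 sites)
carries ~2× the mortality hazard in this draw, medium methylation cuts it
by half, and high methylation is protective but less so than medium — the
nonlinear pattern the continuous analysis probes. A spline fit makes the
shape explicit:

```sh
methindex spline --cohort cohort.csv --basis rcs --knots 5
# rcs spline: chi2=33.41 on 4.0 df (p=9.8e-07); lowest hazard at index 9.0
```

At n = 240 these estimates move with the seed; scale the simulation up
(`--scale 100`) and they settle on the configured values. The full pipeline
(template → reads → QC-gated calls → cohort merge → fits → diagnostics)
runs from one JSON config:

```sh
methindex run --config examples/demo_run.json --outdir demo_out
```

## Layout

| path | contents |
| --- | --- |
| `src/methindex/amplicon.py` | template model, site maps, in-silico bisulfite conversion, primer location |
| `src/methindex/caller.py` | pile-up evidence, conversion QC, 0–17 index, categorical codings |
| `src/methindex/synthetic_data.py` | read simulator and calibrated survival-cohort generator |
| `src/methindex/survival.py` | Cox fits, spline bases, residual diagnostics, adjusted curves, tables |
| `src/methindex/_cox.py` | partial-likelihood Newton engine (penalties, ties, score test) |
| `src/methindex/pipeline.py`, `cli.py` | seeded end-to-end orchestration and the `methindex` CLI |
| `docs/methods.md` | methods note: models, calibration, numerical choices, limitations |
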
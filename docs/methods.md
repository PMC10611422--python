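# Methods

This note documents the models and procedures implemented in `methindex`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical choices that matter.

## 1. Amplicon model and in-silico bisulfite conversion

The assay is modelled on the top (sense) strand only. Bisulfite treatment
deaminates unmethylated cytosine to uracil, read as thymine after PCR;
methylated CpG cytosines are protected. A template cytosine is therefore
classified by dinucleotide context in the *pre-conversion* sequence:
followed by G → CpG site (methylatable, scored); otherwise → conversion
control (must read T). A terminal C has no following base and is a control.
Conversion of one molecule, given a binary per-CpG allele, rewrites every
control C to T and every unmethylated CpG C to T; nothing else changes.
Consequences used as test invariants: a fully unmethylated converted
molecule contains no C at all; the number of surviving C equals the number
of methylated alleles; conversion is idempotent on converted material.

The packaged default template is **synthetic**: a 191 bp sequence built to
the assay's printed census — 17 CpG sites and 31 non-CpG control
cytosines — flanked by the published primer pair, with the assayed
promoter's nominal genomic coordinates carried as metadata only. The real
reference sequence is deliberately not fetched, so the package needs no
downloads and the tests are self-contained. One structural point is forced
by the primers themselves: the reverse primer's reverse complement contains
a CG dinucleotide, so any template whose 3' end matches that primer in
converted space necessarily carries one CpG inside the reverse-primer
footprint (a cytosine can survive conversion only at a methylated CpG).
The default template therefore places CpG #17 there and keeps the other 16
CpGs and all 31 controls strictly between the primers. This is harmless in
silico because simulated reads span the whole amplicon. Primer location
against an arbitrary reference treats the reference in fully-converted
space with CpG positions ambiguous (C or T); zero matching spans raises a
not-found error, more than one an ambiguity error.

Coordinates are 0-based half-open internally; the stored genomic
coordinates are 1-based inclusive, as printed.

## 2. Index caller

Chromatogram peak evidence is proxied by per-read base calls piled up at
each CpG and control position after orientation normalization (reverse
reads are reverse-complemented). The per-site statistic is the cytosine
fraction `c = C/(C+T)`; N calls and non-C/T miscalls carry no information
about conversion, so the informative coverage at a site is its C+T count.

Two gates:

1. **Conversion QC.** Every control must have informative coverage ≥ 2 (of
   the up-to-4 reads) and defined `c` strictly below the detection
   threshold. Any failure yields a QC-failed sample with no index — QC
   failure is a value, not an exception, at the sample level.
2. **Index.** A CpG is called methylated when `c ≥ 0.10`. The threshold is
   the approximate sensitivity of Sanger sequencing, the only calibration
   figure the assay states; it is applied symmetrically to control failure
   and CpG detection, and ties at the threshold call methylated (a
   deterministic, documented convention). The index is the count of
   methylated sites; coding boundaries are exact: binary (0 vs 1–17),
   tertiles 1–6 / 7–12 / 13–17, quintiles 1–3 / 4–6 / 7–9 / 10–13 / 14–17
   (note 13 sits in tertile 13–17 but quintile 10–13).

A CpG site whose informative coverage falls below the minimum also fails
the sample: the assay gives no rule for read dropout at scored sites, and
reporting a partial index silently would understate methylation. Both the
threshold and the coverage minimum are configurable (`CallerConfig`).

## 3. Synthetic reads

Each of the four reads (forward/reverse primer × duplicate reactions) is an
independent molecule draw: per CpG, methylated with that site's configured
allele fraction; per control, left unconverted with probability
`conversion_failure_rate`; finally each base is miscalled uniformly with
probability `seq_error_rate`. Defaults are zero noise — the error-free
regime in which the caller must be exact. The generator returns the truth
pattern so recovery can be scored bitwise. What is *not* emulated: peak
height mixtures from subclonal heterogeneity or benign-tissue
contamination, base-quality profiles, primer artefacts, and chromatogram
parsing. Passing tests therefore certify the calling logic, not robustness
to real Sanger noise beyond the modelled substitution/ conversion-failure
channels.

## 4. Synthetic cohorts

The generator emulates a 240-patient newly-diagnosed glioblastoma cohort:

* **Strata.** 115 unmethylated; tertile strata 44 / 38 / 43 (quintile
  strata 24 / 20 / 14 / 31 / 36 when a quintile effect is simulated).
  Within a stratum the index is uniform over the stratum's range — the
  study reports only group sizes, so uniformity is the least-informative
  choice; a sampler hook accepts any discrete distribution.
* **Covariates**, per stratum: age normal (means 58.5/57.4/61.0/60.0,
  SDs 11.5/14.8/11.8/12.2, clipped to 18–90); KPS normal
  (means 82.0/82.1/78.5/81.3), rounded to the nearest 10 and clipped to
  40–100; resection multinomial over biopsy/subtotal/gross-total/unknown
  with the observed per-stratum counts (the explicit `unknown` level is
  kept — about 11% — and stays in the models as its own factor level);
  IDH1 mutation Bernoulli with the observed per-stratum rates; gender
  Bernoulli with the observed two-level split renormalized (59/98 male),
  prognostically passive.
* **Hazards.** `h(t|x,z) = h0(t) exp(f(x) + z'γ)` with an exponential
  baseline by default (Weibull shape exposed). Effect modes: `tertile`
  (log of 1.62 / 0.48 / 0.62 for OS; 0.85 / 0.27 / 0.46 for PFS),
  `quintile`, `binary` (0.79 OS / 0.60 PFS — the OS figure follows the
  tabulated model), `linear` (log 0.96 per unit OS, 0.94 PFS), `null`, and
  `spline-shape` — a piecewise-linear log-HR anchored on the tertile
  values with its trough at index 11 (nodes (0,0), (3.5, log 1.62),
  (11, log 0.40), (15, log 0.62), (17, log 0.62)), used to test whether
  spline fits localize the protective trough in the 9–13 range. Covariate
  effects default to the tabulated adjusted estimates (OS: age 1.02/yr,
  KPS 0.98/pt, IDH1 0.56; PFS adds resection STR 2.08, GTR 1.59 vs
  biopsy). Event times are drawn by inverse-CDF sampling.
* **Baseline calibration.** The baseline scale is solved (root-finding on
  the survival-mixture identity over a large fixed internal draw of
  unmethylated-arm linear predictors, so the calibration is deterministic
  and noise-free) such that the unmethylated arm's *marginal* median is
  14 months (OS) / 8 months (PFS).
* **Censoring.** Exponential dropout plus an administrative cutoff at 132
  months (the observed maximum follow-up). A single shared dropout rate
  cannot reproduce the observed per-stratum censoring fractions
  (40.9 / 15.9 / 21.1 / 7.0% — a 1.62× hazard ratio cannot push censoring
  from 41% to 16%), so one rate per stratum is calibrated by root-finding
  on the closed-form censoring probability. The study prints no PFS
  censoring fractions; the PFS endpoint reuses the OS targets. Censoring
  depends on covariates only through the stratum, which every fitted model
  conditions on, so it is conditionally independent and the Cox fits stay
  consistent.

One seed determines everything; identical config + seed give byte-identical
CSV output. OS and PFS times are drawn independently given covariates —
the generator does not enforce progression-before-death ordering, which
real cohorts would show.

## 5. Survival analysis

Ordinary Cox fits use Efron tie handling (the convention of the R software
family the analysis emulates) through lifelines; a Breslow option runs on
the in-package Newton engine. Reported per term: HR, Wald 95% CI, p;
globally: likelihood-ratio, Wald and score (log-rank) chi-squares on all
model terms, and Harrell's concordance with a delete-one jackknife SE
(computed exactly for n ≤ 3000, omitted above — the O(n²) pair scan is not
worth it on the 100×-scale runs).

**Splines.** The restricted cubic basis is Harrell's truncated-power form
(linear term plus k−2 nonlinear terms, normalized by the squared boundary
span), knots at the conventional quantiles ({.05, .275, .5, .725, .95} for
five knots). On the default cohort 48% of patients sit at index 0, which
collapses those quantiles; the fallback places knots at the same quantiles
of the *distinct* observed values. The number of knots is configurable;
five is the default, giving 4 spline df (the convention that a k-knot RCS
has k−1 parameters). B-spline fits use a cubic basis on the same knots
with the first column dropped (inside a Cox model any constant direction
is unidentified). The P-spline uses a richer equally-spaced cubic basis
(12 functions) with a second-difference penalty; the penalty weight is
chosen on an AIC grid (`λ ∈ 10^[-2, 4]`, AIC = −2·loglik + 2·edf,
edf = tr[(I+λP)⁻¹I]), with sandwich covariance for the band. Every spline
result reports the pointwise log-HR curve on a 0–17 grid referenced to
index 0 (exactly 0 there), a 95% Wald band, a block chi-square, and — for
the RCS — a Wald test of the nonlinear terms.

**Diagnostics.** Martingale residuals (event indicator minus cumulative
hazard; from the Nelson–Aalen estimator for the unadjusted/null case, from
the fitted model otherwise) are smoothed against the index with LOWESS,
default span 0.35 — wide enough to bridge the integer index's tied
x-values, narrow enough to resolve a trough against the rebound at high
indices. Proportionality uses the scaled-Schoenfeld slope test against
Kaplan–Meier-transformed time, one chi-square per term; constant columns
are dropped at fit time with a warning and flagged as undefined in the
test. Adjusted survival curves exponentiate the Breslow baseline at
reference covariate values (means for numeric covariates, modal dummy
pattern for resection).

The Newton engine (Efron/Breslow ties, arbitrary quadratic penalty,
step-halving, convergence on a 1e-9 step norm) is validated against
lifelines coefficient-for-coefficient, and its null score test against the
classical log-rank statistic.

## 6. Problem sizes and test design

Recovery checks run at 100× the study's cohort (n = 24,000), where the
Monte-Carlo SE of a tertile log-HR is ≈ 0.02, so the configured effects are
sharp targets; each assertion uses a 3-SE band around the configured truth.
The trough-localization check fits the RCS on 20 independent 100×-scale
spline-shape replicates and requires the curve minimum in [9, 13] in at
least 19. Baseline calibration is checked on 10,000 uncensored
unmethylated patients (median within ±0.5 months of 14). The Schoenfeld
test's size is checked over 200 null replicates of n = 150 against a
central binomial band for α = 0.05. Exactness of the caller is checked on
1,000 error-free samples (and 1,000 single-control-failure counterparts,
all of which must be rejected), plus exhaustively over all 2⁵ patterns of
a 5-CpG toy template.

## 7. Known limitations

* Per-site percent methylation, subclonal deconvolution and base-quality
  modelling are out of scope; the caller is presence/absence by design.
* The generator's uniform within-stratum index distribution and
  independent OS/PFS draws are simplifications; calibration targets are
  marginal medians and censoring fractions, not joint behaviour.
* Adjusted curves are evaluated at covariate means/modes; other reference
  choices shift the curves (not their ordering).
* The concordance SE is omitted for very large fits (see §5).
* Competing risks, time-varying covariates and frailty are not modelled;
  no multiple-testing correction is applied across codings.
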
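# Methods

## The analysis problem

The Virginia body-weight AIL descends from 29 high-weight (HWS) and 30
low-weight (LWS) selected founders crossed reciprocally and then
intercrossed for eight further generations.  All ~1536 birds carry a
sparse marker backbone (~1 marker/cM in nine previously mapped QTL);
only 40 of the 59 founders carry dense SNP genotypes (6607 markers in
the same regions, 6888 total with the backbone).  The analysis imputes
the dense markers through the pedigree, tests each marker against
56-day body weight (BW56), and isolates statistically independent
signals that are robust to the pedigree structure.

## Statistical models

**Model 1 (single marker).**  `y = μ + β_sex,gen X + β_genotype z + ε`,
with sex (2 levels) and generation (7 levels, F2–F8) as treatment-coded
categorical covariates, reference cell F2 female, and `z` the 0/1/2
reference-allele dosage.  We fit by OLS and test `β_genotype = 0` with
the Wald t-test, computed through Frisch–Waugh–Lovell residualization
(exact, and fast enough to scan ~10⁵ marker fits in seconds).  The
original analysis used a score test from a GWAS toolkit; with ~1348
phenotyped individuals and a quantitative trait the two are
asymptotically equivalent, and the OLS route is exactly reproducible.
Fits are complete-case on (y, z, conditioning markers).

**Forward selection.**  Per region: scan, add the minimum-p marker if
p < 0.05 (ties broken by smallest coordinate), condition and repeat.
The MAF > 0.10 filter (computed among phenotyped individuals) is
applied after the pass completes.  Markers with low imputation call
rates can be excluded from selection (`min_call_rate`, below).

**Model 2 (multi-locus).**  Candidates are recoded by line origin:
+1 when homozygous for the allele that is major among HWS founders,
−1 when homozygous for the LWS-major allele, 0 when heterozygous.
A positive fitted effect therefore means the HWS-major allele increases
weight; negative effects flag transgression or collinearity among
linked markers.  When both lines share a major allele the coding falls
back to HWS-major orientation with a warning.

**Backward elimination and FDR.**  Starting from the full model
(sex + generation + all candidates), marker p-values are tested against
a two-stage adaptive BH criterion at q = 0.20 (stage 1 estimates the
number of true nulls at level q/(1+q); stage 2 re-runs BH at
q·m/m̂₀); the single worst failing marker is dropped and the model
refit, until all survivors pass.  Two details matter:

* The BH thresholds stay anchored at the *original* candidate count
  throughout elimination.  If the multiplicity shrank with the model,
  the final survivor — the minimum p-value among all candidates — would
  only need p ≤ q, and the global-null probability of retaining
  anything would approach 1 − (1−q/1)·…; measured on 500 simulated null
  datasets it was 88%.  With the anchored thresholds the measured
  any-retention rate is ~17%, consistent with FDR control at 20%.
* Perfectly collinear candidate groups are resolved before elimination
  (weakest marginal association dropped first, with a warning).

Plain BH is available via `adaptive=False`.

**Bootstrap RMIP.**  Individuals are resampled with replacement to the
original n (optionally stratified by generation), elimination runs per
resample, and a marker's RMIP is its final-model inclusion fraction
over 1000 resamples (default).  Inclusion in the reported model
requires RMIP strictly greater than 0.46 — a threshold proposed for
AIL-type populations.  Inestimable resamples are redrawn; more than
10% redraws aborts.  The final model is a joint OLS fit of the included
markers, reported with BH-adjusted p-values.

**Contributions.**  Per QTL, `Σ 2aᵢ|pᵢ(HWS) − pᵢ(LWS)|` with signed
aᵢ — the absolute value applies to the frequency differential only,
so transgressive effects subtract.  Per-region values are rounded to
the nearest gram before summing the grand total (matching how the
per-region figures are quoted); the unrounded sum is reported
alongside.  Under pure additivity this is a conservative estimate of a
QTL's share of the founder-line difference (dominance would bias it
downward).  External F2 effect estimates enter only as user-supplied
comparison constants.

## The synthetic-data generator

The generator emulates the study design rather than re-running 40+
generations of selection:

* **Founder divergence** is imposed directly on founder frequencies:
  with probability `f_fixed = 0.2` a marker is fixed for alternative
  alleles (a completed sweep); otherwise each line's frequency is an
  independent Beta(0.8, 0.8) draw, so many markers still segregate
  within lines — both regimes occur at the defaults.
* **Pedigree**: reciprocal HWS×LWS pairings found F1; later generations
  use monogamous random pairing that avoids full sibs, 45 breeding
  pairs (~90 breeders) and ~185 offspring per generation.  The study
  quotes both "~90 birds per generation" and a 1536-bird, 1348-phenotype
  total; those are only mutually consistent if ~90 counts breeders, so
  the defaults follow the totals (simulated: 1539 birds, 1295
  phenotyped).  In unavoidably degenerate configurations (two-bird
  cohorts) sib avoidance relaxes with a warning.
* **Meiosis**: Haldane map function (no interference), sex-averaged,
  3 cM/Mb on the physical map — the chicken genome-wide average is of
  this order; no region-specific map exists for these QTL.
* **Phenotypes**: BW56 = 800 g (F2 female mean) + 150 g for males +
  generation effects (0 for F2–F7, −120 g for F8, emulating the
  younger-dam effect in the final generation) + Σ aᵢ(dosageᵢ − 1) +
  N(0, 80² g²).  Defaults give per-marker standard errors near the
  reported 5–7 g at the study's sample size.  Only F2–F8 receive
  phenotypes.
* **Observation model**: backbone markers observed in everyone; dense
  markers only in a random 40/59 of founders; truth retained separately.

All randomness flows from one master seed through named substreams
(founders, pedigree, meiosis, noise, masking), so runs are bit
reproducible and stages re-runnable in isolation.

What the generator does **not** emulate: genotyping error (outside the
concordance-QC fixture), dominance and epistasis, sex chromosomes,
mutation, LD within founder lines beyond what line frequencies induce,
and selection during the AIL generations.  Passing tests therefore
demonstrate the machinery is correct under an additive, error-free
observation model — not that the real data satisfy those assumptions.

## Imputation algorithm

The published study used pedigree-aware phasing software whose internal
algorithm is not documented; this package substitutes a deterministic
Mendelian/IBD method designed for testability:

1. **Backbone phasing.** Homozygotes self-phase; heterozygous offspring
   resolve when a parent's transmissible allele is forced; founders and
   other parents phase from transmitted gametes by a greedy
   orientation-anchored sweep (alternating directions so orientation
   reaches sites on both sides of the first anchor; per-site majority
   vote across gametes, ties left unresolved); remaining heterozygotes
   fill by copying from the transmitting parent's haplotype inside
   matched IBD runs.  Three global rounds reach a fixed point in
   practice.  Measured on simulated defaults: >99.5% of genotype sites
   resolved with ~99.6% accuracy.
2. **Segment painting.** Each gamete is matched to its parent's
   haplotypes over informative sites (parent heterozygous and phased,
   gamete allele known).  An informative site disagreeing with both
   neighbours is treated as a phase error, painted as a one-site gap;
   runs must end in two agreeing sites before extending to chromosome
   ends; crossovers are localized to the gap between flanking
   informative sites.  Autozygous parent stretches (both haplotypes
   sharing one founder label) paint unambiguously even without
   informative sites.  Labels compose recursively down the pedigree.
3. **Dense imputation.** A dense marker takes the founder label shared
   by its flanking backbone markers; the allele is copied from the
   phased founder panel when that founder is dense-genotyped and its
   phase at the site is not an arbitrary coin flip.  Dosage = sum over
   homologs when both resolve, else missing.  Founder dense
   heterozygotes without informative transmissions are randomized under
   a recorded seed and *flagged*; flagged sites are skipped at
   imputation time by default (`include_uncertain_phase=False`) —
   copying coin flips would trade ~20 points of error for call rate.

Consequences of the conservative design: resolved imputed dosages err
at ~1% against simulated truth, but the dosage call rate among masked
entries is ~20%: a call needs *both* homologs to trace to
dense-genotyped founders (upper bound (40/59)² ≈ 46%) through
confidently phased sites.  The pipeline therefore screens multi-locus
candidates by call rate (`min_call_rate = 0.5` among phenotyped
individuals, reported per candidate): complete-case fitting on the
union of sparsely and disjointly called columns would otherwise
collapse.  With essentially complete imputation, as in the original
data, the filter is inert.

Mendelian violations abort in simulation mode and blank the offending
call in data mode (`mode="mask"`), since real data contain errors.

## Numerical choices

* p-values are floored at the smallest positive double so downstream
  FDR bookkeeping never sees 0.
* Monomorphic or collinear focal markers yield structured "untestable"
  results, not exceptions; rank deficiency among covariates raises.
* Forward-selection ties break toward the smallest genomic coordinate;
  elimination drops exactly one marker per iteration (largest failing
  p), the path-stable choice.
* Line-frequency ties (p = 0.5 exactly) orient to the reference allele.
* Region spans are 1-based inclusive (`size = end − start + 1`);
  marker densities round to the nearest integer per Mb.
* Concordance QC removes a marker on a single discordant non-missing
  call pair; `max_discordant_fraction` relaxes this.

## Problem sizes used in the tests

The suite exercises the full pedigree design (59 founders, 1539 birds,
1295 phenotypes) with two regions of 30 + 150 and 25 + 120 markers —
the statistical behaviour under test (calibration, power, FDR,
imputation accuracy) depends on sample size and marker spacing, not on
the total marker count.  Calibration checks use 250 × 400 null tests,
500 global-null elimination datasets, 20 bootstrap replicates at B = 200
for RMIP and 2500 noise replicates for effect-recovery coverage.

## Known limitations

* The imputation stage is a documented stand-in: it does not attempt
  call-for-call agreement with the original software, and its call rate
  is intentionally sacrificed for accuracy.
* No kinship/GRM mixed model: robustness to structure comes from the
  bootstrap stage, as in the original design.
* Rule-based phasing admits rare block errors (~0.03% of
  haplotype-chromosomes at defaults) where runs of jointly
  unconstrained heterozygotes mimic a crossover.
* The exact adaptive-FDR variant used originally is not recoverable;
  the two-stage adaptive BH with anchored multiplicity is our choice,
  with plain BH as a switch.
* Contribution estimates carry no standard errors, and dominance or
  epistatic contributions are out of scope.
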
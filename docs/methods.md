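# Methods

## Paired fold-change classification

The central statistic is the per-patient log2 fold change of a gene
between a patient's tumor and matched normal sample,
`lfc = x_tumor − x_normal` (log2 intensities), with linear fold change
`FC = 2^lfc`. Patients are classified as **up** (FC > 2), **down**
(FC < 0.5) or **not** deregulated otherwise. Both defining inequalities
are strict, so a fold change exactly at a boundary falls into the middle
class. Fold changes are always computed by subtraction on the log2 scale,
never from linearized intensities, which makes the calls invariant to any
additive offset applied to both members of a pair (background level,
scanner gain, patient effects).

Only patients with exactly one tumor and one normal sample are analyzed;
patients with a single tissue are counted and excluded, and two samples of
the same tissue for one patient are treated as an unrecoverable pairing
ambiguity (hard error) rather than silently averaged. Thresholds (2, 0.5)
are configurable but default-locked, and every output table echoes the
thresholds that produced it.

## Preprocessing

Microarray path (probe-level log2 intensities, assumed background
corrected):

1. **Quantile normalization** — each sample's sorted value vector is
   replaced by the across-sample mean of sorted vectors; ties receive the
   mean of the target quantiles they span, which makes the operation
   idempotent. Quantile normalization assumes most features are unchanged
   between samples; on matrices with only tens of features it visibly
   compresses the fold changes of differential features, so the pipeline
   applies it to file inputs by default but not to simulated cohorts,
   whose generator emits already-normalized intensities (an explicit
   config value overrides either default).
2. **Technical replicate averaging** at the probe level (arithmetic mean
   of log2 values = geometric mean of intensities).
3. **Probe→gene collapse** — mean over the probes targeting a gene;
   unmapped probes are dropped and counted.
4. **Low-intensity filter** — genes whose mean log2 intensity over *all*
   samples is strictly below 5 are removed (a gene at exactly 5 is kept).
   The all-samples mean (rather than a per-group mean) is used because the
   filter feeds the window analysis, which compares the same gene across
   every patient.

RNA-seq count path: median-of-ratios size factors (per-sample median of
count/geometric-mean ratios over genes with nonzero counts everywhere)
followed by `log2(count/size_factor + 1)`. This is a deliberate,
documented approximation to a full variance-stabilizing transform:
downstream deregulation calling uses within-patient fold changes, which
are insensitive to the choice of monotone transform at moderate counts.
Batch handling is an optional per-gene, per-batch mean centering, off by
default; full empirical-Bayes batch correction is out of scope because
deposited inputs are expected to be already batch-corrected.

## Compensation analysis

For two genes A and B the 3×3 cross-tabulation of calls over the shared
paired patients yields the directional fractions
`P(B up | A down)` and `P(B down | A up)`; empty denominators are reported
as undefined, never as zero. The permutation test uses the statistic
`#{A up ∧ B down} + #{A down ∧ B up}`, permutes B's calls across patients,
and reports the one-sided add-one estimate
`p = (1 + #{null ≥ observed}) / (1 + n_perm)` — one-sided because
compensation is a directional hypothesis, and add-one so p is never 0.
The permutation stream is seeded and applied to a canonical patient
ordering, making the p-value reproducible and order-invariant.

## Locus-window co-amplification surrogate

Genomic amplification raises the expression of every gene the amplicon
covers, so coordinated fold-change increases across an anchor gene's
neighbors serve as a surrogate when copy-number data is unavailable.
Internally all coordinates are 0-based half-open, converted at the reader
boundary (BED taken as-is, GFF3 shifted from 1-based closed). The window
is the interval `[anchor.start − flank, anchor.end + flank)` with
flank = 1 Mb by default; membership is by interval *overlap*, so genes
straddling the edge are included. "Downstream" means higher chromosomal
coordinate than the anchor's end, independent of strand. The expressed
mask comes from the intensity filter; unexpressed genes stay listed but
masked. The per-patient call — at least `min_genes` (default 2) expressed
downstream genes with lfc ≥ `lfc_cut` (default 1.0) — is a configurable
screening rule, not a calibrated copy-number caller; both parameters are
echoed in the outputs, and with no expressed downstream gene the flag is
undefined rather than false.

## Survival analysis

Kaplan–Meier estimation, the unweighted log-rank test and univariate Cox
regression are delegated to lifelines; the module fixes the statistical
conventions:

- **Ties**: Efron approximation (tied event times are guaranteed at month
  resolution; Efron is the de facto standard default in survival
  software).
- **KM confidence intervals**: 95%, log-log (complementary log)
  transform, which keeps the band inside [0, 1]; Greenwood variance is
  computed from the event table.
- **Five-year survival** = the KM step value at exactly 60 months; if 60
  months exceeds follow-up the last step is returned with a flag.
- **Cox reference** is the "not deregulated" group, so hazard ratios read
  as up-vs-not and down-vs-not; Wald 95% CIs. Coefficients beyond ±15
  log-hazard units are flagged as monotone-likelihood divergence
  (complete separation) and their CI/p reported as NA.
- Groups smaller than `min_group_size` (default 3) or with zero events
  are summarized descriptively with NA hazard ratios instead of being
  force-fitted.
- Times are used in months as recorded, including zero follow-up times.
- Disease-free survival collapses the four recorded statuses to a binary
  event: recurrence and disease-specific death count as events; other
  death and disease-free end of follow-up are censorings.

The test suite cross-checks this machinery against independent oracles: a
brute-force grid search of the Efron partial likelihood, hand
product-limit computations, a hand log-rank (observed − expected with
hypergeometric variance), and the identity between the two-group log-rank
statistic and the squared Cox score statistic at β = 0. That identity is
exact only without tied event times (the log-rank variance carries the
`(N − d)/(N − 1)` tie correction that the score information does not), so
it is checked on tie-free fixtures; the grid-search comparisons include
ties.

## Synthetic cohort generator

The generator produces data with exactly the statistical structure the
analysis assumes, plus ground truth, and is first-class tested code.

- **Design**: by default 82 paired patients plus 8 tumor-only and 4
  normal-only patients (94 patients; 90 tumor and 86 normal samples),
  ~30% HPV-positive, and 6/82 paired patients without follow-up —
  mirroring the cohort structure the pipeline targets.
- **Classes**: the anchor gene's class is drawn per HPV stratum
  (defaults: HPV+ up/not/down = 0.04/0.44/0.52; HPV− = 0.246/0.632/0.123,
  echoing the anchor fractions such a cohort exhibits). The partner gene
  is *coupled*: with probability κ (default 0.35) a class-deregulated
  patient receives the opposite class for the partner; otherwise the
  partner class is drawn from its own marginal (0.317/0.598/0.085). This
  directional mechanism is the simplest one that reproduces the observed
  reciprocal pattern, and it implies
  `P(B up | A down) = κ + (1 − κ)·P_B(up)` — the closed form the recovery
  tests check.
- **Expression**: normal value = gene baseline (N(8, 1) log2 units,
  floored at 5.5 so expressed genes clear the intensity filter) + patient
  effect (sd 0.5) + residual (sd 0.25). The tumor sample re-uses the
  patient's realized normal value and adds a per-gene delta
  ~ N(class mean, σ) with class means ±1.8 and σ = 0.3, so patient and
  residual effects cancel in paired fold changes by construction — the
  within-class fold-change spread is governed by σ alone, and ±1.8 at
  σ = 0.3 keeps essentially all sampled fold changes on the correct side
  of the 2/0.5 thresholds (≈99.4–99.9% per class after probe noise).
- **Window block**: 10 window genes per side of the anchor on a synthetic
  chr11 layout, 30% of them drawn unexpressed (baseline ≈ 3); anchor-up
  patients are amplified with probability 0.93, adding 1.5 log2 units to
  every downstream window gene's delta. 300 unperturbed background genes
  on another chromosome give quantile normalization a realistic
  complement to work against.
- **Probes**: 2 probes per gene with fixed per-probe affinity offsets
  (sd 0.3) and measurement noise (sd 0.1); 20% of probes are emitted
  twice as technical replicates.
- **Survival**: exponential event times, hazard = per-stratum baseline ×
  exp(group log-HR), with baselines 0.00436/0.0190 per month (≈77% and
  32% five-year survival for HPV+/HPV−) and group log-HRs of 0 by
  default; uniform censoring on (0, 139) months; times rounded to whole
  months so tied event times occur. Disease-free survival uses a 1.4×
  hazard and emits the four-level status coding.
- **Reproducibility**: one seed spawns a sub-stream per model component,
  so identical configs are byte-identical.

What the generator does **not** emulate: spatial/background microarray
artifacts, batch effects, probe-level QC failures, DNA-level copy-number
structure, competing risks, or covariate-dependent censoring. Passing
recovery tests therefore demonstrate the correctness of the estimators
under the model's assumptions, not robustness to real-data pathologies.

## Problem sizes in the checks

The statistical acceptance checks use: 1000 cohorts of n = 82 for
classification accuracy; 500 cohorts of n = 5000 (minimal gene set) for
compensation recovery, compared to the closed form within three
per-cohort Monte-Carlo standard errors; 2000 replicates of 2×200 patients
for log-rank type-I error; 200 cohorts of n = 500 for hazard-ratio
recovery (median within 20% of HR = 3); 1000 amplified patients for
window sensitivity. `scripts/acceptance.py` reports the same quantities
at reduced replicate counts (50–1000) so a full run completes in well
under a minute of compute per experiment.

## Known limitations

- The count path's log2(x+1) is not a variance-stabilizing transform;
  very low counts inflate fold-change noise.
- The co-amplification rule is a screening heuristic; its sensitivity
  figure is specific to the generator's block-effect magnitude.
- Fisher's exact test for clinical associations is exact only for 2×2
  tables; larger tables use a seeded Monte-Carlo estimate.
- No multiple-testing correction is applied anywhere; every table and the
  run manifest say so.
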
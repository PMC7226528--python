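# cyclinpair

Paired tumor/normal deregulation analysis of D-type cyclin expression in
head and neck squamous cell carcinoma (HNSCC), built as a reusable,
tested pipeline for bioinformaticians working with matched tumor–normal
expression cohorts.

## The problem

Cyclin D1 (*CCND1*) is a canonical oncogene in HNSCC, yet its prognostic
value is inconsistent across studies that dichotomize *absolute* tumor
expression. When a matched normal mucosa sample is available for each
patient, a more informative statistic is the **per-patient fold change**

    FC_p = 2^(x_p^tumor − x_p^normal)

where `x` is log2 expression of a gene in patient `p`. Each patient is then
classified into one of three deregulation groups:

- **up**: FC > 2
- **not** (no deregulation): 0.5 ≤ FC ≤ 2
- **down**: FC < 0.5

This package implements that classification and the downstream analyses it
supports:

1. **Deregulation summaries** per gene, overall and stratified by HPV
   status (the major prognostic covariate in HNSCC).
2. **Compensation analysis** between two genes (e.g. *CCND1* and *CCND2*):
   3×3 cross-tabulation of calls, the directional fractions
   P(B up | A down) and P(B down | A up), and a seeded permutation test
   whose statistic counts opposite-direction patients.
3. **Co-amplification surrogate** for the 11q13 locus: per-patient log2
   fold-change profiles of genes within a ±1 Mb window around an anchor
   gene (*CCND1*), with a configurable rule flagging patients whose
   downstream neighbors (*ANO1*, *CTTN*, …) rise together — an
   expression-based stand-in for DNA copy-number data.
4. **Survival analysis** by deregulation group: Kaplan–Meier curves with
   Greenwood variance and log-log 95% CIs, five-year survival (60 months),
   the log-rank test, and univariate Cox proportional-hazards models with
   Efron tie handling, using the "not" group as the reference.
5. **A synthetic cohort generator** that emits paired probe-level
   expression, annotation, clinical follow-up and per-patient ground
   truth, so the whole pipeline is exercisable and testable offline.

Preprocessing stages (quantile normalization, technical-replicate
averaging, probe→gene collapse, mean-intensity filtering for the
microarray path; median-of-ratios size factors + log2 for the RNA-seq
count path) are included behind the same data model.

## Worked example

```python
from cyclinpair import SimulationConfig, simulate_cohort, deregulation_calls, summarize
from cyclinpair.preprocess import average_technical_replicates, collapse_probes_to_genes
from cyclinpair.compensation import cross_tabulate, compensation_fractions

cohort = simulate_cohort(SimulationConfig(seed=1))
probes_avg, probe_ann = average_technical_replicates(cohort.expression, cohort.probes)
genes = collapse_probes_to_genes(probes_avg, probe_ann)

calls = deregulation_calls(genes, cohort.samples, ["CCND1", "CCND2"])
summary = summarize(calls, cohort.samples)
print(summary[summary.gene_symbol == "CCND1"][
    ["gene_symbol", "stratum", "n", "n_up", "n_not", "n_down"]
].to_string(index=False))
```

```
gene_symbol stratum  n  n_up  n_not  n_down
      CCND1     all 82    19     48      15
      CCND1 hpv_neg 59    19     34       6
      CCND1 hpv_pos 23     0     14       9
```

The simulated cohort has 82 paired patients; anchor-gene upregulation is
concentrated in the HPV-negative stratum and downregulation in the
HPV-positive stratum, as configured. Cross-tabulating against the partner
gene quantifies compensation:

```python
ct = cross_tabulate(calls[calls.gene_symbol == "CCND1"],
                    calls[calls.gene_symbol == "CCND2"])
res = compensation_fractions(ct)
print(f"frac(B up | A down) = {res.n_down_a_up_b}/{res.n_down_a} = {res.frac_down_a_up_b:.2f}")
```

```
frac(B up | A down) = 8/15 = 0.53
```

i.e. 8 of the 15 patients who downregulated *CCND1* upregulated *CCND2* —
the compensatory pattern the pipeline is designed to detect (the generator
couples the two genes with probability κ = 0.35 by default).

The same analyses run from the command line against a YAML config:

```
cyclinpair simulate --out cohort/ --seed 1         # write a synthetic cohort
cyclinpair run --config config.yaml --out report/  # full report directory
```

The report directory contains the per-patient call table, gene×stratum
summaries, compensation cross-tabs with permutation p-values, the window
gene/fold-change tables, survival tables (five-year % and hazard ratios
per group), and a `manifest.json` capturing config, seed, versions and
output checksums; identical config + seed reproduce the report
byte-for-byte.

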
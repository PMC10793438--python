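# p16mave

Statistical machinery for a saturation functional assay (deep mutational
scan) of **CDKN2A / p16INK4a** missense variants.

p16INK4a is a 156-residue tumor suppressor: cells expressing a functional
copy are growth-suppressed, so in a pooled competition assay cells carrying a
**functionally deleterious** variant outgrow their neighbours.  Each residue
is assayed as one lentiviral library of 20 variants (19 missense + 1
synonymous) in a CDKN2A-null pancreatic cancer cell line, with variant
representation sequenced at Day 9 after transduction and again at confluency
(Day 16–40).  This package implements everything statistical around that
design, for anyone building or re-analysing a multiplexed assay of variant
effect (MAVE):

- **simulation** of the pooled competition experiment (per-residue library
  composition with the 5% spike-in rule, transduction, exponential growth
  competition, bottleneck and growth-phase noise, two-timepoint sequencing),
  including the all-neutral 20-barcode "CellTag" control in triplicate and a
  paired-FASTQ read emitter;
- **variant counting** from raw paired amplicon reads (overlap merging with
  quality-aware consensus, ungapped anchoring, codon translation);
- the **gamma-GLM null model**: for a tested variant *v* with confluency
  ratio *r*<sub>v,cf</sub> against the synonymous variant, Day-9 ratio
  *r*<sub>v,init</sub> and Day-9 library proportion *p*<sub>v,init</sub>,

  &nbsp;&nbsp;&nbsp;&nbsp;*r*<sub>v,cf</sub> ~ Γ(α, β<sub>v</sub>), with mean
  μ<sub>v</sub> = αβ<sub>v</sub> = *r*<sub>v,init</sub><sup>a</sup> ·
  *p*<sub>v,init</sub><sup>b</sup>

  — a gamma GLM with log link and no intercept, calibrated on 19 × 20 × 3 =
  1,140 neutral-barcode triplets; each variant then gets a one-sided
  upper-tail p-value (a fitness **advantage** is the alternative);
- **classification**: Fisher's method across replicates,
  Benjamini–Hochberg FDR at 0.05, and three-way classes
  (deleterious / indeterminate / neutral) using either the published
  log₂ P cutoffs (≤ −53.2 / ≥ −5.8) or the data-adaptive BH cutoff; plus the
  normalized-fold-change classifier (log₂ NFC, cutoffs ≥ 1.09 / ≤ 0.24 or
  derived from benchmark pathogenic/benign variants) and replicate
  concordance reporting;
- **predictor benchmarking**: binarisation of in-silico predictor scores
  (CADD, PolyPhen-2, SIFT, VEST, AlphaMissense, ESM1b, PrimateAI-3D),
  sensitivity/specificity/PPV/NPV/accuracy, majority-vote ensembles, Pearson
  chi-square and one-sided Fisher exact contingency tests;
- **domain analysis**: ankyrin-repeat assignment (ANK1 11–40, ANK2 44–72,
  ANK3 77–106, ANK4 110–139), two-proportion z-tests with Bonferroni
  correction, and per-residue deleterious fractions with a bootstrap CI.

See `docs/methods.md` for the model, the generative assumptions and their
limitations.

## Worked example

Simulate a full 156-residue screen, calibrate on the CellTag control, and
classify every missense variant (everything is seeded and reproducible):

```sh
p16mave run --seed 7 --out-dir demo
```

```
class_glm
neutral          2427
deleterious       416
indeterminate    121
outputs in demo
```

Of the 2,964 tested missense variants, 416 are called functionally
deleterious at the published log₂ P ≤ −53.2 cutoff, 2,427 functionally
neutral (log₂ P ≥ −5.8) and 121 fall in between.  `demo/results.tsv` holds
one row per variant (per-replicate p-values, combined p-value, log₂ P,
log₂ NFC and both classifications); `demo/null_model.json` records the
calibrated (α, a, b).  Domain-level summaries:

```sh
p16mave enrich --results demo/results.tsv --seed 7 --out demo/enrichment.tsv
```

```
 region   n  n_deleterious  proportion         z        p    p_adj
   ANK1 570             94    0.164912  1.878449 0.060320 0.301599
   ANK2 551             76    0.137931 -0.181240 0.856179 1.000000
   ANK3 570             84    0.147368  0.536700 0.591475 1.000000
   ANK4 570             64    0.112281 -2.146799 0.031809 0.159046
non-ANK 703             98    0.139403 -0.082880 0.933947 1.000000
mean deleterious fraction across residues: 14.0% (95% CI 12.4%-15.7%)
```

Each region's deleterious fraction is tested against its complement
(two-proportion z, Bonferroni × 5).  In this simulation deleterious variants
are placed uniformly at random, so no repeat is significantly enriched — on
real data this table is where ankyrin-repeat enrichment appears.

The same stages are available as library functions
(`simulate_screen`, `build_triplets`, `fit_null`, `glm_classify_table`,
`foldchange_classify`, `confusion_metrics`, `domain_enrichment`, ...) and as
individual subcommands (`simulate`, `count`, `calibrate`, `classify`,
`foldchange`, `evaluate`, `enrich`).

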
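# Methods

## The assay and its statistical question

A saturation functional screen of the 156-residue tumor suppressor p16INK4a
competes, within one lentiviral library per residue, all 20 amino-acid
variants at that residue (19 missense + 1 synonymous) in a CDKN2A-null cell
line.  Functional p16 suppresses proliferation, so cells carrying a
loss-of-function variant expand between the Day-9 harvest and confluency
(Day 16–40).  The statistical question for each variant is whether its
confluency-to-Day-9 enrichment relative to the synonymous variant at its
residue exceeds what neutral variation produces.

## Gamma-GLM null model

For tested variant *v*, the observation is the triplet
(r_cf, r_init, p_init): the count ratio to the reference (synonymous)
variant at confluency, the same ratio at Day 9, and *v*'s Day-9 proportion
within its library.  Under the null,

    r_cf ~ Gamma(shape = alpha, mean = mu_v),
    mu_v = r_init^a * p_init^b,

a gamma GLM with log link, covariates log r_init and log p_init, **no
intercept** (the mean law has none; an intercept remains available as an
option because many GLM implementations add one silently), and one shape
alpha shared across variants.

**Calibration.**  The parameters are fitted on all-neutral control pools: 20
non-functional 9-bp barcodes ("CellTags") of equal initial representation,
assayed in triplicate to a Day-45 confluency endpoint.  Within each
experiment every barcode serves in turn as the reference and the remaining
19 contribute one triplet each: 19 × 20 = 380 triplets per experiment,
1,140 in total.  Exponents (a, b) are estimated by IRLS; for a gamma GLM
with log link the working weights are identically one, so each iteration is
an ordinary least-squares solve on the adjusted response eta + (y − mu)/mu.
The shape is then estimated at the fitted means by maximum likelihood,
solving log(alpha) − psi(alpha) = mean(y/mu − log(y/mu)) − 1 by bracketed
root finding (method-of-moments on Pearson residuals is available as a
documented fallback; the two agree closely on well-specified data).
Convergence tolerance 1e-12 on the coefficients, 200 iterations maximum;
collinear covariates and fewer than 10 triplets are hard errors.

**Testing.**  A variant's p-value is the upper tail of
Gamma(alpha, mu_v/alpha) at the observed r_cf — one-sided, because a fitness
*advantage* is the alternative; depleted (putative gain-of-function)
variants are reported descriptively, not classified.  Tail probabilities are
carried in log space throughout (far tails underflow double precision;
log2 P near −900 is routine for strong variants), with an asymptotic
expansion of the upper incomplete gamma where scipy's `logsf` underflows.
Replicates are combined with Fisher's method (chi-square with 2k df at
−2·sum(log p), in log space), and Benjamini–Hochberg at level 0.05 runs over
the combined p-values of all tested variants.

**Classes.**  Published mode applies the published fixed cutoffs: deleterious at
log2 P ≤ −53.2, neutral at log2 P ≥ −5.8, indeterminate between, with the
printed boundary inclusivities.  Adaptive mode replaces the deleterious
bound with the data-dependent BH raw-p cutoff.  The −5.8 neutral bound is
replicated as a configurable constant; its derivation is not re-derived
here.  BH always runs on combined p-values, also when a single replicate
exists.

## Normalized fold change

FC_v = (confluency proportion)/(Day-9 proportion); NFC_v = FC_v divided by
the synonymous variant's FC at the same residue; log2 NFC is averaged across
replicates.  A variant is deleterious when mean log2 NFC ≥ 1.09 and neutral
when ≤ 0.24 (deleterious variants *enrich*, so the deleterious bound is the
upper one; the bounds equal the minimum benchmark-pathogenic and maximum
benchmark-benign values and can be re-derived from user-supplied benchmark
sets).  The synonymous anchor's own log2 NFC is identically zero.

## Synthetic data generator

The generator produces count tables with the statistical structure the
analysis assumes, so the full pipeline is testable end to end:

1. **Library composition** — symmetric Dirichlet (concentration 10 per
   variant, CV ≈ 30%: a quality-controlled 20-member plasmid pool is nearly
   uniform); any variant drawn at ≤ 1% is spiked to 5% and the vector
   renormalised (repeated in the rare case renormalisation pushes a
   borderline variant back under), mirroring the wet-protocol respiking of
   underrepresented variants.
2. **Transduction** — multinomial assignment of 1e5 cells (MOI ≈ 1).
3. **Growth** — deterministic exponential competition
   a_v(t) = a_v(0)·exp(g_v·t).  Neutral rate 0.35/day (~2-day doubling).
   Deleterious variants get an additive advantage of ln(2)/10 per day:
   their *relative* representation doubles every 10 days, i.e. 1.6–8.6×
   total enrichment across the Day 16–40 confluency window — the magnitude
   the assay's log2 NFC scale exhibits for loss-of-function variants (the
   deleterious NFC threshold is ~2.1×).  Confluency day is drawn uniformly
   from 16–40 per library and replicate and recorded.
4. **Noise** — two count-independent lognormal components on top of the
   sampling steps: a one-shot bottleneck jitter at Day 9 (sd 0.25,
   log scale) for the transduction/selection bottleneck, and growth-phase
   heterogeneity whose log-sd grows as 0.01·sqrt(days of culture) — the
   random-walk signature of stochastic clonal growth.
5. **Sequencing** — multinomial reads at each timepoint (default depth 1e5
   per library and timepoint; the real per-library depth is not pinned by
   the assay design, so this is a configurable choice).
6. **Reads** (optional) — error-free 150-bp read pairs over an amplicon
   window around the target codon, for exercising the merge-and-count stage;
   re-counting emitted reads reproduces the source table exactly.

The CellTag control is simulated identically with 20 barcodes at exactly
equal initial representation, a single shared growth rate, and a fixed
Day-45 endpoint.

### Why the noise model looks the way it does

Two structural facts drive the defaults.  First, with multinomial sampling
as the *only* noise, the implied gamma shape is count-dependent
(alpha ≈ counts/2), so a null calibrated on barcode counts cannot transfer
to assay libraries with different per-variant counts; real pooled screens
are always overdispersed beyond sampling, and the count-independent
components model that.  Second, the bottleneck jitter gives the control
experiments *genuine* Day-9 ratio variation, much larger than sequencing
noise — without it the exponent *a* is unidentifiable from
equal-representation controls (pure errors-in-variables attenuation).
Defaults: bottleneck sd 0.25 (a 7-day antibiotic selection after MOI-1
transduction is a substantial bottleneck), growth noise 0.01·sqrt(day).
Because variance accumulates with culture time and the Day-45 control is the
*longest* culture in the design, the calibrated dispersion is conservative
for every shorter-duration assay library — the property that lets
Benjamini–Hochberg keep the realized false-discovery proportion at or under
its nominal level in simulation (measured ≈ 0.02–0.03 at level 0.05).

### What the generator does not emulate

No sequencing errors beyond the optional uniform substitution setting, no
PCR jackpots or chimeras, no multi-integration (MOI > 1) effects, no
count-dependent extra-Poisson noise, and deleterious effects are a single
shared advantage rather than a spectrum.  Passing tests therefore
demonstrate the statistical machinery under the design's stated assumptions;
they do not certify FDR control on real data whose overdispersion structure
differs (in particular, if real growth noise did *not* accumulate with time,
the control-calibrated null would be tighter than assay reality and the FDR
guarantee would erode).

## Variant counting

Read pairs are merged by scanning ungapped overlaps of mate 1's 3' end
against the reverse-complemented mate 2, accepting the longest overlap with
mismatch fraction ≤ 0.1 and length ≥ 10 (both configurable); disagreements
resolve to the higher-quality base, ties to mate 1; pairs without an
admissible overlap are rejected and tallied, not errors.  Merged reads are
anchored to the reference CDS by best ungapped placement (indels are
rejected by construction: the amplicon has fixed length, and a shifted read
fails the off-target mismatch tolerance, default 0).  The target codon is
translated with the standard genetic code; counts collapse to amino-acid
identity (the assay's unit of analysis), stop codons are tallied separately,
and every discard is accounted for, so counts + stops + discards equals the
number of merged reads.  Residues and CDS positions are 1-based; codon i
spans CDS positions 3i−2..3i.

## Predictor benchmarking

Scores are binarised with direction-aware per-predictor cutoffs (defaults:
CADD phred ≥ 20, SIFT < 0.05, VEST ≥ 0.5, ESM1b < −7.5, PrimateAI-3D ≥ 0.5;
PolyPhen-2 and AlphaMissense by their categorical classes, with "ambiguous"
grouped with tolerated).  These are widely used published conventions — the
assay itself prescribes none — and all are configurable.  Multiple scores
per variant are reduced by mean before the cutoff; variants without a score
are excluded from that predictor's evaluation and tallied as missing.
Confusion metrics take functionally deleterious truth as positive;
indeterminate variants are excluded by default (policies to fold them into
either truth side exist).  Majority-vote ensembles call damaging at
quorum ⌈(k+1)/2⌉ of the k predictors with available calls (4 of 7, 3 of 5).
Contingency tests: Pearson chi-square without continuity correction (1 df)
and a one-sided Fisher exact test (hypergeometric tail for depletion in the
first row, computed via the log-space CDF).

## Domain analysis

Residues map to the four ankyrin repeats (11–40, 44–72, 77–106, 110–139) or
non-ANK.  Each region's deleterious fraction is compared against its
complement with a pooled two-proportion z-test, two-sided, Bonferroni-
corrected by the number of regions tested in the call (5 in the standard
map); comparing region vs complement (rather than vs the overall
proportion) matches the two-sample form of the test.  Per-residue
deleterious fractions are computed over the 19 missense variants; the
protein-wide mean gets a percentile bootstrap 95% CI over residues
(10,000 resamples, seeded) — the bootstrap-over-residues choice is a design
decision, as is the complement comparison.

## Numerical and interface choices

- Zero counts: +0.5 pseudocount on all counts before ratios/proportions
  (configurable, including a strict error-on-zero mode).  Scale
  equivariance (multiplying all counts by a constant changes nothing) holds
  exactly with pseudocounting disabled.
- Determinism: a single master seed expands into per-library substreams
  (numpy `SeedSequence.spawn`); identical configuration + seed gives
  byte-identical outputs, and every run writes a provenance record
  (config echo, seed, version).
- Tables are TSV (UTF-8, header, "." for missing); models and provenance
  are JSON.
- Problem sizes in the shipped tests and the acceptance script: full
  156-residue screens at depth 1e5 and 20–24 simulation replicates for the
  FDR check — large enough for stable means, small enough to run in
  seconds.

## Known limitations

The null model shares one dispersion across variants; count-dependent
overdispersion in real data would violate that and is not modelled.  The
exponent *b* on p_init is weakly identified by equal-representation
controls (its covariate varies only through bottleneck noise); it is kept
because the mean law specifies it, but its fitted value is near zero under
the generator.  Gain-of-function (depleted) variants are deliberately left
unclassified.  The fold-change classifier inherits the benchmark sets'
quality when thresholds are derived from them.
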
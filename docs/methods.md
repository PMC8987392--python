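# Methods

## Pipeline model

The pipeline determines, per patient and per single-nucleotide variant, one
of four genotype statuses — `Homozygous_ref`, `Heterozygous`,
`Homozygous_alt`, `unknown` — by integrating three sequencing data types
(wxs-normal, wxs-tumor, rnaseq-tumor), and then relates the resulting
ordinal genotype to overall survival. Its core assumptions:

- **Germline sharing.** The tumor exome and tumor RNA-seq of a patient carry
  the patient's germline genotype, so either may stand in for the normal
  exome at positions the normal data covered too thinly. Somatic mutations
  and RNA-editing changes violate this assumption; they are not modelled at
  rescue time but removed afterwards by the population-MAF filter
  (variants must be known in a reference population at minor AF ≥ 0.05).
- **Coverage, not quality, drives `unknown`.** A genotype (including the
  implicit hom-ref of a no-call) is trusted only when the position carries
  at least `min_depth` reads at MQ > 30 in that sample. With the default
  thresholds a true alternate allele present at ≥ 10 reads is expected to
  have been sampled at least 3 times, the caller's minimum support.
- **SNVs only.** Indels and structural variants are rejected at parse time
  and never called.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `CallerParams.min_mapq` | 30 | strict: a read at exactly 30 is discarded |
| `CallerParams.min_baseq` | 25 | strict, as above |
| `CallerParams.min_alt_reads` | 3 | minimum reads supporting the alternate |
| `CallerParams.min_vaf` | 0.05 | minimum variant allele fraction, computed on quality-surviving reads |
| `CallerParams.homalt_vaf` | 0.75 | het/hom-alt boundary; the conventional diploid midpoint plus margin (the upstream protocol leaves genotyping to the caller and states no cutoff) |
| `CallerParams.dedup` | true | one read kept per (start position, strand), highest base quality wins |
| `StatusPolicy.min_depth` | 10 | reads (MQ > 30) required to trust a status |
| `maf_threshold` | 0.05 | population minor-AF cutoff |
| `chunk_rows` | 50 000 | rows per chunk when processing combined tables |

Boundary choices that were genuinely open:

- **Depth exactly 10.** "Fewer than ten reads → unknown" and "more than ten
  reads → hom-ref" leave depth = 10 unspecified; we treat depth ≥ 10 as
  sufficient (the complement of "fewer than ten"). Configurable via
  `StatusPolicy`.
- **Duplicate key.** Deduplication collapses reads sharing start position
  *and* strand: collapsing on start alone would merge legitimate
  reverse-strand coverage with forward reads.
- **Which depth governs the ten-read rule.** The coverage-table depth
  (recomputed at union positions, MQ > 30, no base-quality filter, no
  dedup), not the DP the caller reported; the caller's DP is kept in the
  VCFs for provenance. Base quality is applied only at calling; coverage
  deduplication is off by default but available.
- **Alt-allele choice.** Only the single most frequent non-reference base
  per site is considered; ties break deterministically A < C < G < T.
- **AF denominator.** Unknown statuses contribute neither alleles nor
  denominator: AF = (2·#HA + #HT) / (2·(#HR + #HT + #HA)). Variants absent
  from the population AF table are removed by the MAF filter rather than
  imputed at AF 0, since the filter's purpose is to keep only variants known
  to segregate in the population.
- **Rescue scope.** Patients lacking a normal sample start from an
  all-unknown baseline and are genotyped entirely from tumor/rnaseq;
  patients lacking a donor simply keep their unknowns. The potential-SNP
  filter (drop rows that are unknown/hom-ref in every sample) is re-applied
  after filling, and the per-patient fill counts are reported in a rescue
  audit table.
- **Survival model.** Genotype enters the Cox model as a single additive
  ordinal term (0/1/2), not as two indicator contrasts; ties are handled by
  Efron's approximation (the default of the R fitting routine this workflow
  mirrors, via lifelines here); per-variant models use complete cases only,
  since an unknown genotype is a coverage artifact, not informative
  missingness. `Percent_aneuploidy` may be a fraction or a percentage — the
  coefficient rescales accordingly and inference is unchanged.

## Synthetic cohort generator

`gvpipe.synthetic_cohort` emulates the data structure the pipeline assumes:

- **Genotypes**: Hardy-Weinberg draws at per-variant allele frequencies
  (default Uniform(0.05, 0.5), so every variant would pass the MAF filter).
- **Depth**: negative-binomial per (sample, variant). Means 60 / 80 / 30 and
  size parameters 1.0 / 2.0 / 0.7 for wxs-normal / wxs-tumor / rnaseq-tumor.
  Negative-binomial rather than Poisson because exome capture and RNA
  expression produce heavy low-coverage tails; with the defaults ~10–20% of
  wxs-normal cells fall below 10 reads, which is what makes the
  unknown/rescue path do real work. RNA-seq is deliberately the shallowest
  and most dispersed type, which is why tumor-first rescue ordering pays.
- **Alt reads**: Binomial(depth, v) with v = 0.5 (het), 0.98 (hom-alt,
  allowing reference-biased mismapping), 0.005 (hom-ref sequencing error).
- **Reads** (read-level path only): ~5% of reads fail each of the MQ/BQ
  cutoffs; PCR duplicates are injected at rate 0.10 per read.
- **Sample availability**: per data type, `round(p·n)` patients get a
  sample; defaults 5/7, 1.0, 1.0 reproduce a 5 normal / 7 tumor / 7 rnaseq
  test cohort at n = 7.
- **Survival**: event times Exponential(h₀·exp(β·label)) with h₀ = 0.02
  events/month (median ≈ 35 months, a realistic glioma scale), independent
  exponential censoring at 0.01/month, per-allele log-hazard β = 0.7 for
  one designated causal variant; covariates are drawn within their ordinal
  ranges independent of survival.

Two resolutions exist: the read-level path (pileups → caller → VCFs) used
for end-to-end runs, and a count-level fast path that draws (depth, alt)
pairs directly and applies the same count thresholds and status rule, used
for large-cohort statistical checks.

What passing tests on this generator shows — and does not. It validates the
pipeline's logic and statistical behaviour under its own model (HWE,
independent variants, clean binomial VAFs, shared germline across data
types). It says nothing about alignment artifacts, strand bias, RNA
editing, somatic contamination beyond the MAF filter's reach, or population
structure in real cohorts.

## Problem sizes of the verification suite

The test suite and `scripts/acceptance.py` use: exhaustive rule grids
(depth ≤ 30 × three calls; depth ≤ 50 × all alt counts; all genotype-count
triples summing to ≤ 20); a 120 001-row matrix for chunk equivalence
(50 000-row chunks); a deep-coverage cohort of 500 patients × 200 variants
for allele-frequency recovery (bound: 3·√(p(1−p)/2n); concordance between
wxs-normal and merged call sets); 100 replicate cohorts of 500 patients for
Cox effect recovery at β = 0.7 with 95% Wald-CI coverage, plus 100 null
cohorts for log-rank p-value uniformity (Kolmogorov–Smirnov); and the
default 7-patient / 120-variant cohort for the staged end-to-end run. These
sizes keep each property statistically sharp while the whole suite runs in
well under a minute of simulation time.

## Numerical and implementation notes

- Variant ordering is total and deterministic: natural chromosome order
  (chr1…chr22, chrX, chrY, chrM, then others lexicographically), position,
  ref, alt. All outputs are byte-stable for a fixed seed.
- Chunked processing is an equivalence-preserving implementation detail;
  the chunk files carry 4-digit numeric suffixes (`segment_0000.txt`, …) and
  a separate header file, and chunked results are asserted byte-identical to
  unchunked ones.
- The own-implementation Cox score test at β = 0 (`cox_score_test`) exists
  as an independent cross-check of the log-rank statistic (they coincide
  for a binary covariate without ties); the production log-rank and Cox
  fits come from lifelines.
- BED output is proper 0-based half-open BED3 even though the internal
  coverage machinery consumes 1-based positions directly; Annovar input
  uses the 1-based inclusive start = end SNV convention.
- Degenerate inputs raise rather than guess: undefined AF (no genotyped
  patients), zero-variance AF vectors, single-group or event-free survival
  comparisons, constant covariates (named in the error), barcodes in the
  patient map that match no matrix column (named in the error).

## Known limitations

- The built-in caller is a threshold rule on counts; it has no local
  realignment, strand-bias testing or error modelling, and exists so the
  pipeline is exercisable end to end from plain-text pileups. Real cohorts
  should be called upstream with a production caller and ingested as VCF.
- Multi-allelic sites reduce to the single best-supported alternate.
- The rescue step trusts donors blindly at `unknown` positions; its somatic
  /editing contamination is only controlled statistically by the MAF filter.
- Survival scanning refits a full Cox model per variant; at hundreds of
  thousands of variants this is embarrassingly parallel but not optimised.
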
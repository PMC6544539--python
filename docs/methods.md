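# Methods

`brainmosaic` implements a cohort-scale pipeline for detecting somatic
single-nucleotide variants of high allele fraction (>10% of sampled cells)
in exome sequencing of bulk tissue, and for characterizing the detected
variants: mutational spectra, enrichment against genomic backgrounds, and
an early-embryonic mutation-rate estimate. This note describes the models,
the parameters that matter, the synthetic data used for testing, and the
numerical choices made where the design was open.

## Discovery model

The input is a grid of per-sample, per-site read counts (total depth and
alternate-supporting reads), typically extracted from a multi-sample VCF
with `AD`/`DP` fields. Counts and variant records use 1-based VCF
coordinates; interval masks use 0-based half-open BED coordinates, with
the conversion centralized in `filtering.sites_in_intervals`.

A candidate somatic variant in one individual must pass, in order:

1. **SNV restriction.** Only biallelic single-nucleotide substitutions are
   considered.
2. **Region mask.** A site is callable only if it lies outside a blacklist
   of poorly alignable regions, outside copy-number intervals, and has
   depth ≥ 30× in *every* sample. The surviving base count (`callable_bp`)
   is the denominator of the mutation rate.
3. **VAF window.** Observations with variant allele fraction above 50% or
   below 10% are removed. The interval is closed: exactly 10% or 50% is
   retained, since the exclusion is stated for strictly more extreme
   values.
4. **Heterozygosity test.** A germline heterozygote in this data set has a
   mean VAF of 47% (reference-bias pulls it below 50%). The alternate
   count is tested against Binomial(depth, 0.47) with a two-sided exact
   binomial test; candidates survive only when p < 1e-5, i.e. when the
   observation is clearly inconsistent with a germline het. The two-sided
   convention is "twice the smaller exact tail, capped at 1"; the
   minimum-likelihood convention is available via
   `het_binomial_test(..., method="minlike")`. The 47% null is a
   configurable parameter, not re-estimated per cohort by default.
5. **Panel error test** (below), p < 0.001, strict.
6. **Recurrence.** Any (chrom, pos, ref, alt) key observed in more than
   one distinct *individual* is removed everywhere: true early-embryonic
   somatic events are private, whereas recurrent low-VAF signals are
   almost always systematic artifacts or common contamination. Multiple
   samples from the same individual count once.
7. **Population frequency.** Variants with minor allele frequency > 0.5%
   in a population table (ExAC-like) are removed as likely germline;
   variants absent from the table pass (rare by absence).

### Panel error model

Sequencing error at a site is overdispersed across samples: per-site error
rates vary with context, so alternate counts across a panel of unrelated
cohort samples are modelled as beta-binomial rather than binomial. For a
candidate in one sample, a panel of up to 328 other samples (uniformly
sampled, excluding all samples of the case individual, deterministic given
the run seed) provides the null:

* **Mean.** Pooled alternate fraction with a Jeffreys-style pseudocount of
  0.5 alternate / 1 total read added to the pooled counts; this keeps the
  mean strictly inside (0, 1) even for perfectly clean panels.
* **Dispersion.** The intraclass correlation ρ = 1/(α+β+1) is estimated by
  the depth-weighted method of moments (Kleinman estimator) from the
  between-member variability of per-member allele fractions. Panels whose
  empirical variance does not exceed binomial fall back to a binomial null
  with ρ = 0.
* **Test.** One-sided upper tail P(X ≥ alt_count) under the fitted
  beta-binomial; pass iff p < 0.001 (a p of exactly 0.001 fails). The
  published description of this step names only the beta-binomial
  comparison and the threshold; this one-sided tail test against a
  moments-fitted cohort null is this package's deliberate, simpler
  reimplementation of that idea rather than a port of any specific
  likelihood-ratio formulation.

Type-I calibration is verified by simulation: on 1e5 null observations
drawn from the generating error model and tested against independently
fitted panels, the fraction passing p < 0.001 stays below 0.002 (the
excess over the nominal 0.001 is fit-estimation noise).

### Statistical power of the heterozygosity stage

The het-binomial stage is deliberately conservative and dominates the
chain's sensitivity. A true first-division variant (expected VAF 0.25)
must produce a count with two-sided p < 1e-5 against Binomial(depth,
0.47); exact computation gives a pass probability of ~0.15 at 60×, ~0.46
at 100×, and ~0.87 at 150× — ≥90% recovery requires roughly ≥170×. At the
~52× cohort depth emulated here, mostly second-division variants
(VAF 0.125) and the low-VAF sampling tail of first-division variants are
recovered. This is a property of the published operating point, not an
implementation artifact; the test suite asserts the attainable behaviour
(recovery ≥ 80% at ~200× mean depth, monotone in depth) and measures the
low-depth recovery honestly.

## Validation

Amplicon deep-resequencing confirmation: a candidate is confirmed iff case
depth ≥ 500×, case alternate reads ≥ 40, and the matched control (same
tissue type, different individual) shows VAF < 1% (strict). Read-level
base-quality ≥ 30 / mapping-quality ≥ 20 filtering is an input contract on
the deep counts. Cross-platform agreement is summarized as mean |ΔVAF| and
Pearson r over paired exome/amplicon VAFs.

## Spectra and signatures

Substitutions are pyrimidine-collapsed (a purine-reference event is
recorded as its reverse complement), giving 6 classes and, with flanking
bases, 96 trinucleotide channels ordered class-major then 5'/3' flank
(A/C/G/T); channel names (`A[C>T]G`) are written in all outputs so
external matrices can be column-mapped regardless of their native order.
Signature association is Pearson product-moment correlation of the
96-channel spectrum against each column of a signature matrix, with
two-sided p from the t transform at 94 degrees of freedom; Pearson r is
scale-invariant, so counts and frequencies give identical results. No
signature deconvolution (e.g. non-negative least squares attribution) is
performed — correlation only. A CpG variant is a C>T-class event whose 3'
flank is G in pyrimidine orientation.

## Enrichment tests

* **Methylation:** exact binomial test of the number of validated variants
  at bases methylated in the early-embryo inner cell mass against the
  genome-wide methylated fraction 476,286,624 / 3,095,693,981 = 15.4%.
  One-sided (enrichment) by default; sidedness is exposed.
* **Expression:** per-class exact binomial tests of variant-containing
  genes across five brain-expression classes, plus the "expressed in
  brain" aggregate {elevated in brain, expressed in all, mixed}. The
  genome-wide class proportions are an input; the packaged defaults are a
  synthetic stand-in (the published expression atlas snapshot is
  unversioned) and should be replaced for real analyses.
* **Constraint:** per-quartile exact binomial tests (two-sided) of
  missense-constraint quartile membership against uniform 25%.
* **Region bias:** two-sided Fisher exact test on the 2×2 table of
  (variants in cerebellum vs not) × (cohort samples from cerebellum vs
  not). Variant-level and individual-level constructions are both
  plausible; the variant-level default reproduces the published p = 0.18
  on the validated set. A zero-margin table is reported as p = 1 with a
  note.
* **Carrier probability:** each cohort member is a Bernoulli trial with
  unknown probability p of carrying a detectable somatic variant; with a
  uniform prior the posterior is Beta(carriers+1, n−carriers+1), reported
  as mean and central 95% credible interval.

## Mutation-rate chain

rate_per_bp = n_validated / (callable_bp × n_samples); dividing by
`n_cells` = 6 (2 cells after the first cleavage division + 4 after the
second — the cell-division opportunities for a detectable high-VAF
mutation) gives the per-base per-individual early-embryonic rate;
multiplying by 3e9 extrapolates to the genome. On the cohort inputs
(22, 5,906,849, 1461) the chain gives 8,629,906,389 total bases, 2.55e-9,
4.25e-10, and 1.3 mutations per genome. Rates are printed at three
significant figures and expectations at one decimal; full precision is
kept internally. `n_cells` is exposed so alternative lineage models can be
explored; an optional Poisson interval on the count is deliberately not
provided, keeping the estimator a point-estimate chain.

## Synthetic cohort generator

`simulate_cohort` emulates the statistical structure the pipeline assumes,
on a toy contig of contiguous sites:

* **Depth** ~ round(Normal(51.9, 12.9)) truncated at ≥1, decomposed into a
  per-site capture effect (SD 10.9) plus within-site sample noise (SD
  ~6.9) so that depth, and hence callability, is correlated across samples
  at a site as in real capture data; the marginal mean/SD match the
  emulated cohort. With independent per-sample depths, the
  "≥30× in every sample" rule would leave no callable sites at cohort
  scale, which real data contradicts.
* **Germline hets** at density 1e-3 per sample-site (roughly one coding
  het per kilobase), alternate counts ~ Binomial(depth, 0.47).
* **Somatic variants**: `somatic_rate_per_division` (default 3e-4 per bp
  per individual on the toy grid, chosen so a default 400×5000 cohort
  plants a few hundred events with measurable recovery) is apportioned
  across cleavage divisions in proportion to daughter-cell counts (2/6,
  4/6 for two divisions); a division-d event has expected VAF 0.5/2^d
  (0.25, 0.125) under equal lineage contribution, and counts are drawn
  binomially at that VAF. The equal-contribution assumption is exactly
  that — an assumption; real lineage contributions to bulk tissue are
  unequal, which spreads true VAFs.
* **Base error**: beta-binomial with mean 2e-3 and ρ = 0.01 (typical
  post-filter error scale for short-read exomes), drawn at every
  non-variant cell.
* **Masks**: random blacklist intervals covering ~5% of sites plus sparse
  per-sample CNV intervals.
* **Annotations**: i.i.d. random trinucleotide contexts (a stand-in, not a
  real genome), methylation flags at 15.4%, genes of 50 consecutive sites
  with expression classes drawn from the default background and uniform
  constraint quartiles; a sparse population-frequency table covers 2% of
  sites with log-uniform MAFs.

All randomness flows from one master seed through deterministically
spawned child streams; a fixed seed gives bit-identical cohorts.
`simulate_embryonic_lineage` uses the same apportionment convention, so a
rate of 4.25e-10 /bp/individual over a 3 Gb genome yields a mean of ~1.3
mutations across the first two divisions.

What the generator does *not* model — alignment artifacts, strand bias,
mapping error, real trinucleotide composition, unequal lineage
contribution, relatedness — bounds what passing tests show: they verify
the statistical behaviour of the pipeline under its own assumptions, not
performance on real sequencing data.

## The packaged validated-variant table

The 22 amplicon-confirmed variants (gene, position, alleles, consequence,
population frequency, SIFT class, expression class, constraint quartile,
inner-cell-mass methylation flag, exome VAF, and sample metadata) ship as
a TSV fixture verified by checksum. Trinucleotide flanks are not part of
the published record; the `context_synthetic` column carries constructed
flanks consistent with the published per-class CpG counts (8 of 13
C>T-class variants at CpG, the 6 ICM-methylated variants among them) and
is labelled synthetic for that reason. The non-standard gene symbol
`SETP12` is transcribed verbatim.

## Problem sizes and defaults

Default simulated cohorts are 400 samples × 5000 sites (2e6 grid cells),
calibration runs use 1e5 null observations (500 panels × 200 draws), and
oracle comparisons sweep all depths ≤ 200–300; these sizes make the full
test suite and the acceptance script run in minutes on a single core while
keeping Monte-Carlo errors well inside the asserted tolerances.

## Known limitations

* The panel test is a tail test against a moments fit, not a
  likelihood-ratio test; it is slightly conservative for very small
  panels.
* Recurrence filtering removes genuinely recurrent somatic events by
  design, trading sensitivity for specificity exactly as the discovery
  chain intends.
* The expression-class background proportions and the synthetic contexts
  are stand-ins; conclusions drawn from them are interface demonstrations,
  not biology.
* The rate chain propagates no uncertainty from the validated count; it
  reproduces a point-estimate calculation.
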
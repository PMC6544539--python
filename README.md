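# brainmosaic

Detection and characterization of high-allele-fraction somatic variants in
cohort exome data, with an early-embryonic mutation-rate estimator and a
fully synthetic test cohort generator.

Somatic variants acquired in the first cleavage divisions of the embryo
are carried by a large fraction of cells in every tissue — a mutation in
one of the two cells after the first division is expected at variant
allele fraction (VAF) ≈ 0.25 in bulk tissue, one from the second division
at ≈ 0.125. `brainmosaic` is aimed at researchers asking how common such
high-VAF somatic coding variants are in bulk-sequenced tissue cohorts
(the motivating application is postmortem brain exomes) and what their
mutational mechanism looks like.

## What it implements

**Discovery** (`run_discovery`): from a multi-sample counts grid
(VCF with per-sample `AD`/`DP`, or arrays), applies in order — biallelic
SNV restriction; region masking (blacklist ∪ CNV ∪ any-sample depth
< 30×); VAF window 0.10 ≤ VAF ≤ 0.50; a two-sided exact binomial test
against the heterozygous null Binomial(depth, 0.47) at p < 1e-5; a
one-sided beta-binomial tail test against a 328-sample panel error model
at p < 0.001; cohort recurrence removal; and a population-frequency filter
(MAF ≤ 0.5%). Every observation carries a full per-filter audit trail.

**Validation** (`confirm_variant`): amplicon deep-resequencing rules —
case depth ≥ 500×, ≥ 40 supporting reads, control VAF < 1% — plus
cross-platform VAF concordance summaries.

**Spectra** (`build_spectrum`, `signature_correlation`):
pyrimidine-collapsed 6-class and 96-channel trinucleotide spectra, CpG
fractions, and Pearson correlation against signature matrices.

**Enrichment** (`binomial_enrichment`, `expression_enrichment`, ...):
exact binomial tests against methylation / expression / constraint
backgrounds, Fisher exact region-bias test, and the Beta posterior for the
per-person carrier probability.

**Rate** (`estimate_rate`): rate = n_validated / (callable_bp ×
n_samples), divided by the 6 early-embryonic cells in which a detectable
mutation could have arisen, extrapolated to a 3 Gb genome.

**Synthetic cohorts** (`simulate_cohort`): seeded generator with known
ground truth — depth ~ N(51.9, 12.9) with site-correlated capture
efficiency, germline hets at VAF 0.47, somatic variants planted at
division VAFs 0.25/0.125, overdispersed beta-binomial base error, masks,
contexts and annotations. See `docs/methods.md` for the model and its
limits.

A table of 22 amplicon-validated somatic variants ships as a packaged
fixture (`load_table1`) and drives the characterization stages.

## Worked example

```python
>>> import brainmosaic as bm
>>> table = bm.load_table1()
>>> spec = bm.build_spectrum(list(zip(table["ref"], table["alt"])))
>>> spec.n_transitions, spec.n_transversions, int(spec.six_class["C>T"])
(19, 3, 13)
>>> est = bm.estimate_rate(n_validated=22, callable_bp=5_906_849, n_samples=1461)
>>> est.report()["rate_per_bp"], est.report()["rate_per_bp_per_individual"]
(2.55e-09, 4.25e-10)
>>> est.report()["genome_expectation"]
1.3
```

Of the 22 validated variants, 19 (86.4%) are transitions and 13 (59.1%)
are C>T — the footprint of methyl-cytosine deamination — and the rate
chain gives 2.55 × 10⁻⁹ mutations per base across the cohort, 4.25 × 10⁻¹⁰
per base per individual in the first two cleavage divisions, i.e. about
1.3 somatic mutations genome-wide per person from that window.

The `examples/` directory holds one short narrative script per capability
(discovery on a synthetic cohort, panel error model, spectra, enrichment,
rate chain); each prints the numbers it computes and what they mean. A
thin CLI mirrors the stages:

```bash
brainmosaic simulate --n-samples 50 --n-sites 500 --seed 1 --out sim/
brainmosaic discover --counts sim/counts.vcf --blacklist sim/blacklist.bed \
    --popfreq sim/popfreq.tsv --out disc/
brainmosaic rate --n-validated 22 --callable-bp 5906849 --n-samples 1461
```

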
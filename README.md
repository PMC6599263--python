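# mutevo

Longitudinal analysis of mutational and neoantigen evolution in tumor
models (cell lines and serially passaged xenografts), driven entirely by a
seeded synthetic-data generator so every stage is testable offline.

The pipeline covers:

- **variants** — somatic variant model; filter cascade (strand support
  excluding read-terminal positions, allelic frequency >= 10%, exact
  binomial noise test p <= 0.05, dbSNP-style / panel-of-normals sets);
  timepoint and lineage (generation-wise) subtraction into gained/lost
  sets; tumor mutational burden (coding variants per Mb); consequence
  annotation and the non-synonymous : synonymous ratio.
- **signatures** — 96-channel pyrimidine-centric trinucleotide spectra,
  exposure refitting by nonnegative least squares (samples with fewer than
  10 mutations are refused), Euclidean / average-linkage clustering of
  exposure profiles.
- **neoantigens** — cDNA editing, 8–11-mer mutant peptide enumeration
  (missense and frameshift, wild-type-identical peptides excluded), a
  pluggable binding-predictor interface with a deterministic mock, and the
  rank < 0.5 / FPKM > 10 candidate filters.
- **ploidy** — two-step estimator: relative gene copy number from median
  depth ratios (2x gene/overall), circular binary segmentation with a
  permutation test in gene-ordinal space, absolute integer copy number by
  matching smoothed allelic-frequency density modes to the k/N peak grid
  (diploid: one peak at 50%; triploid: peaks at 33% and 66%).
- **evolvability** — doubling time DT = t/n, growth rate GR = ln(2)/DT,
  per-day mutation rate, and the EVOLVING (>= 10 alterations/day) vs
  STABLE call.
- **expression_filter** — significance rule for an externally fitted
  differential-expression table (padj < 0.05 and |log2FC| >= 1 with the
  appropriate group expressed at >= 10 FPKM).
- **synthetic** — seeded generator for every input: toy genome and
  transcriptome, process-specific mutation accrual (MSS / MMR-deficient /
  POLE-mutant / MUTYH-mutant presets with signature-specific contexts and
  homopolymer slippage indels), read counts, depth profiles consistent
  with a copy-number landscape, and expression tables, plus ground truth
  for recovery tests.

## CLI

All stages are subcommands of `mutevo` (see `mutevo --help`):

```sh
mutevo simulate --preset msi --seed 1 --outdir sim/         # inputs + truth
mutevo filter sim/T90.vcf --out T90.filtered.vcf            # cascade, FILTER column
mutevo subtract T90.filtered.vcf T0.filtered.vcf \
    --out-gained gained.vcf --out-lost lost.vcf
mutevo lineage-subtract sim/lineage.json --outdir subtracted/
mutevo tmb gained.vcf --coding-mb 38
mutevo spectrum gained.vcf sim/genome.fa --out spec.tsv
mutevo fit-signatures spec.tsv --out exposures.tsv
mutevo cluster-exposures exposures.tsv --out tree.json
mutevo neoantigens gained.vcf --transcripts sim/transcripts.fa \
    --gene-model sim/gene_model.tsv --expression sim/expression.tsv \
    --alleles HLA-A*02:01 --out candidates.tsv
mutevo ploidy sim/depth_profile.tsv sim/T0.vcf \
    --out-segments segments.tsv --out-summary cn_summary.tsv
mutevo evolvability growth.tsv gained_counts.tsv --out calls.tsv
mutevo de-filter deg_table.tsv --out significant.tsv
mutevo run-all --preset msi --seed 1 --outdir out/          # everything
```

Presets: `mss`, `msi`, `pole`, `mutyh` (T0/T90 in-vitro designs) and `pdx`
(four serially passaged generations F1–F4 with clonal loss allowed).

## File formats

Minimal text dialects only, documented in `mutevo/io.py`: VCF v4.2 with
`AD`/`DP` FORMAT fields and `SAF`/`SAR`/`GENE`/`TX`/`CDSPOS`/`CSQ` INFO
keys; FASTA; TSV tables for gene models, expression, depth profiles,
signature matrices (96 labelled channel rows), exposures, segments and
candidates; lineage descriptions as JSON.
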
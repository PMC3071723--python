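# enrichkit

Toolkit for sex-differential (or any two-library) digital gene expression
analysis on per-contig read counts, built around the exact conditional
two-library enrichment test. It covers the full desk-side workflow of a
two-library EST/454-style study:

- **enrichment** — exact enrichment test (conditional binomial, computed in
  log space so library sizes of 10^6 reads are safe), partition accounting
  (mixed / A-only / B-only contigs), enrichment calling at a p-value cutoff
  (default 0.001), and robust-candidate selection (≥100-fold enrichment
  and/or >100 reads in one library).
- **simulate** — synthetic two-library count tables with known ground truth
  (multinomial allocation so column sums are exact; flat or lognormal
  abundance; planted enriched and library-exclusive contigs), plus power /
  type-I-error curves with Wilson intervals.
- **annotation** — keyword mining over homology-annotation tables
  (default keywords: sex, egg, ovary, sperm, testis, female, male; word or
  substring matching) and annotation-rate-by-length profiling.
- **ceg** — transcriptome-coverage estimation against a 248-gene
  core-eukaryotic-gene reference in four conservation categories.
- **qpcr** — comparative-CT (ΔΔCT) relative quantification with
  reference-gene normalization and two-tailed t-tests between groups.
- **io / pipeline / cli** — TSV/FASTA/YAML/JSON readers and writers, an
  end-to-end pipeline with provenance records, and the `enrich` CLI.

## Test

```sh
python -m pytest tests/
```

The suite includes exact-arithmetic oracles (Fraction-based binomial tails)
for the enrichment statistic, property tests (hypothesis), and
`tests/test_acceptance.py` with the headline accounting / calibration
checks.

## CLI

```sh
# simulate a study-scale count table with 1% truly 100-fold enriched contigs
enrich simulate --n-contigs 45538 --n-reads-a 742771 --n-reads-b 721543 \
    --frac-enriched 0.01 --fold 100 --seed 1 --out-prefix scratch/sim

# exact enrichment test (library sizes default to column sums = reads in contigs)
enrich test --counts scratch/sim.counts.tsv --alpha 0.001 \
    --robust-rule either --out scratch/calls.tsv

# keyword-based candidate prediction from an annotation table
enrich filter --annotations annotations.tsv --mode word --out candidates.tsv

# core-gene coverage from a gene_id / n_hits table
enrich ceg --hits ceg_hits.tsv --out coverage.tsv

# comparative-CT quantification, calibrated on the male group mean
enrich qpcr --ct ct.tsv --calibrator male --out rq.tsv

# full pipeline from a YAML config
enrich run --config pipeline.yaml
```

Count tables are TSV with header `contig_id<TAB>count_a<TAB>count_b`;
annotation tables `contig_id / length_bp / description[ / go_terms]`; CT
tables `sample_id / group / gene / replicate / ct_target / ct_reference`.
Counts must be plain integers (no thousands separators, no decimals).

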
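# regmutnet

Regulatory-network analysis of disease-associated mutations. The package
maps mutations onto a three-layer regulatory network and computes
enrichment and disease-concordance statistics:

- **Interface enrichment** — coding missense mutations are classified by
  the protein interaction interface of their residue (protein-binding,
  DNA-binding, or "double"), and enrichment is measured as an odds ratio
  against the residue composition, with a Z-test on the log odds ratio.
- **Region enrichment** — non-coding mutations are tested for
  length-normalized enrichment in chromatin-state segments (TSS,
  enhancer; ChromHMM/Segway/combined label maps) and in TF binding-motif
  territory within 4-kb search windows.
- **Chromatin pair analysis** — non-coding mutation pairs are classified
  against a chromatin interaction network (same anchor / interacting /
  non-interacting same chromosome / different chromosomes, with
  configurable distance filters), disease concordance per category is
  tested with the upper-tail cumulative binomial, and SQRTVC-normalized
  Hi-C contact counts of same- vs different-disease pairs are compared
  with the Mann-Whitney U test.
- **Motif pipeline** — a log-likelihood-ratio PWM scanner (both
  strands), a motif-pair taxonomy for mutation pairs, and enrichment of
  interacting-TF motif pairs across interacting regions against both an
  analytic baseline and a degree-preserving scrambled-network null.
- **Synthetic data** — seeded generators for every input with planted,
  recoverable effect sizes, so the full pipeline is testable offline.

## CLI

All subcommands log to stderr and write results to `--out` (or stdout):

```sh
# generate a full synthetic fixture set
regmutnet simulate --seed 7 --outdir fixtures/

# interface odds ratios
regmutnet enrich-interfaces --mutations fixtures/mutations.tsv \
    --interfaces fixtures/interfaces.tsv --restrict --out or.tsv

# chromatin-state segment enrichment
regmutnet enrich-regions --mutations m.tsv --segments segments.bed \
    --scheme chromhmm --cls TSS --l-total 3000000000 --out tss.tsv

# chromatin pair concordance (+ optional contact comparison)
regmutnet pairs-chromatin --mutations fixtures/mutations.tsv \
    --anchors fixtures/anchors.bed --interactions fixtures/interactions.tsv \
    --min-bp 20000 --contacts fixtures/contacts.triples \
    --normvec fixtures/contacts.sqrtvc --out pairs.tsv

# PWM scanning and motif-pair concordance
regmutnet scan-motifs --fasta fixtures/regions.fa --pwms fixtures/motifs.meme \
    --threshold 6 --out hits.tsv
regmutnet pairs-motif --mutations m.tsv --hits hits.tsv \
    --tf-network fixtures/tf_network.tsv --scope interacting \
    --anchors fixtures/anchors.bed --interactions fixtures/interactions.tsv

# batch summary / configured pipeline run
regmutnet summary --mutations m.tsv --tf-network net.tsv \
    --anchors a.bed --interactions e.tsv
regmutnet run --config pipeline.yaml --outdir reports/
```

## File formats

All exchange formats are plain text. Mutation tables (TSV with header
`id chrom pos ref alt mclass protein residue diseases`, or a minimal
VCF dialect with `MCLASS`/`PROT`/`RES`/`DIS` INFO keys) carry 1-based
positions; BED files, interval columns and motif-hit tables are 0-based
half-open. Contact matrices are 3-column bp triples plus a one-column
normalization vector. PWMs are read from simple PFM records or MEME
minimal format.

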
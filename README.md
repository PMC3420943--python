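# alleleflow

A tested pipeline linking allelic variation and expression of a small gene
family to a quantitative chemical phenotype across structured populations:

- **synth** — synthetic diploid metapopulation datasets (clone-read FASTAs,
  expression and phenotype tables) with a ground-truth ledger, built on a
  Balding–Nichols-style island model so the expected differentiation has a
  closed form.
- **allelecall** — collapse noisy clone reads into consensus alleles via a
  nucleotide-difference merge rule (single linkage, order invariant), then
  assign allele groups by p-distance UPGMA with column-bootstrap support.
- **annotate** — loss-of-function ORF scanning (premature stops,
  frame-shifting indels, start loss), per-group enrichment by one-sided
  Fisher exact test, three-way allele categorisation
  (functional/nonfunctional/non-expressed per species), and a pairwise
  Nei–Gojobori (1986) dN/dS screen with Jukes–Cantor correction.
- **popgen** — in-silico diploid resampling of expression-inferred
  genotypes, multiallelic Weir–Cockerham theta (unclamped, with replicate
  mean ± SE), and Pearson chi-square on species-by-category tables with an
  optional seeded Monte-Carlo p-value.
- **assoc** — prescribed variable transforms (arcsin√x for proportions,
  ln(x+0.01) for µg amounts, √x for expression), Gaussian linear and
  random-intercept mixed models, and backward stepwise AIC simplification.

## CLI

All stages run from a single YAML configuration (see `tests/test_cli.py`
for a complete example):

```bash
alleleflow run-all -c config.yaml -o outdir/          # full pipeline
alleleflow simulate -c config.yaml -o outdir/synth    # synthetic data only
alleleflow call-alleles -c config.yaml -i clones_L1.fasta -o called/
alleleflow annotate -i called/alleles_L1.fasta -o lof.tsv
alleleflow fst -c config.yaml -e expression_groups.tsv -l L1 -o fst_L1.tsv
alleleflow associate -c config.yaml -e expression_groups.tsv \
    -p phenotype.tsv --compound alkene_9 -o assoc.tsv
```

`run-all` emits per-locus allele FASTAs, newick trees, allele-group /
LoF / enrichment / category / F_ST / association TSVs and a
`run_report.json` capturing version, configuration, seeds and headline
results.  Identical configurations produce byte-identical outputs.

## Conventions

Clone FASTA headers are pipe-separated
(`>cloneID|individual|population|species|locus`); all tables are
tab-separated with header rows; trees are newick; the truth ledger and run
report are JSON.  Every stochastic stage derives its randomness from the
master seed through fixed-offset substreams.
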
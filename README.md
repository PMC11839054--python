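# cladecall

Novelty-aware, clade-level strain profiling of metagenomes.

`cladecall` builds a hierarchical reference database of *clade-specific SNV
barcodes* from a collection of same-species reference genomes (aligned to one
assembly) plus a species phylogeny, then profiles metagenomic samples against
it. For every well-supported clade it jointly estimates:

- **relative abundance** — the ratio of the expected read depth over the
  clade's barcode alleles to the expected depth over all alleles at the same
  positions, and
- **divergence (π)** — the zero-inflation probability of a zero-inflated
  negative-binomial model of barcode-allele counts, i.e. the fraction of
  clade-specific markers *systematically* absent from the sample. π ≈ 0 means
  the sample carries a bona-fide member of the clade; π ≈ 1 means the clade's
  markers are missing beyond what depth and dispersion explain — evidence of
  a related but novel strain.

Because abundances are estimated per clade and are not forced to sum to one,
the unclassified remainder at a given phylogenetic level quantifies novel
diversity in the sample.

## Workflow

### 1. Build a database

Inputs: a per-position nucleotide count table for the reference genomes
(native TSV format, or plain-text `samtools mpileup` output via
`--format pileup-text`) and a rooted Newick/NEXUS tree with bootstrap
support (unrooted trees are midpoint-rooted).

```bash
cladecall makedb --counts refs.counts.tsv --tree refs.nwk --out mydb/
```

The pipeline applies the standard call/genome/position filters (major-allele
frequency ≥ 0.85, per-strand depth ≥ 3, consensus-quality and indel rules;
genome median coverage ≥ 8X and ≤ 10% ambiguous calls; position ≤ 10% N,
median coverage ≥ 5X, copy-number guard), scales branch lengths into
core-genome SNV units when patristic and Hamming distances correlate
(r > 0.75), enumerates candidate clades (≥ 4 genomes, subtending branch
≥ 1000 SNVs, bootstrap > 0.75), and keeps clades with ≥ 10 clade-specific
SNVs. Optional `--outgroups` masks positions callable in > 10% of outgroup
genomes. The database is a directory of four plain-text files (clade table,
barcode table, tree, parameters) that round-trips exactly.

### 2. Classify a metagenome

```bash
cladecall classify --db mydb/ --sample sample.counts.tsv --out profile.tsv \
    -d 0.35 -p 0.5 -h 0.1 --seed 7
```

Default inference is slice-within-Gibbs sampling (10,000 steps, 10%
burn-in); `--mle` selects a penalized maximum-likelihood fast path with a
profile-likelihood pseudo-posterior. A clade is reported detected when at
least 50% of the π posterior lies below 0.35 (`-d`/`-p`), the 95% HPD lower
bound on π is below 0.1 (`-h`), and relative abundance is ≥ 1%. Level sums
above 1 are normalized down to 1. The output TSV carries per-clade detection
flags, abundances, π MAP and HPD bounds, plus a provenance header (version,
resolved parameters, seed); identical inputs and seed reproduce it exactly.

### 3. Simulate and benchmark

The `simulate` module generates genome collections evolved along random
trees (infinite-sites Poisson mutations), count-level metagenome mixtures
(negative-binomial depth noise, per-read errors, strand splits), and drives
three benchmark harnesses:

```bash
cladecall simulate  --out sim/frame --n-genomes 30 --seed 1
cladecall benchmark --mode holdout  --out holdout.tsv  --seed 1 --mle
cladecall benchmark --mode mixtures --out mixtures.tsv --seed 1 --mle \
    --coverages 0.1 0.5 1 2 5 10 20 --replicates 15
cladecall benchmark --mode recovery --out recovery.tsv --seed 1
```

`holdout` masks each well-supported branch, rebuilds the database, and
compares estimated π against the true divergence of a held-out genome;
`mixtures` scores presence precision/recall/F1 and L2 on five-strain
synthetic metagenomes; `recovery` tabulates bias/RMSE of the divergence
estimators over a (π, λ) grid.

## Tests

```bash
python -m pytest -q tests/
```

Unit, property, and oracle tests per module plus `tests/test_acceptance.py`
(hold-out divergence correlation ≥ 0.85 at 10X, mixture precision ≥ 0.95,
recall ≥ 0.90 at ≥ 5X, ZINB recovery grid, prior-value comparison,
arithmetic oracles, determinism). Full suite ≈ 2 minutes.

## Package layout

- `cladecall.counts` — count-table/pileup I/O, base calling, filters
- `cladecall.phylo` — tree scaling, dereplication, clade enumeration,
  barcode discovery, database (de)serialization
- `cladecall.inference` — two-step NB/ZINB model: Gibbs sampler, penalized
  MLE, HPD intervals, detection rules, sample profiles
- `cladecall.simulate` — genome/metagenome simulators and benchmark
  harnesses
- `cladecall.cli` — `makedb` / `classify` / `benchmark` / `simulate`
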
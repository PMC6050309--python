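# repeatscape

Repeat-landscape analysis for assembled genomes and low-coverage shotgun
reads:

- **SSR landscape** — perfect-microsatellite scanning (2–6 bp units, 12 bp
  minimum for 2–4mers, >15 bp for 5–6mers), strand/rotation motif
  canonicalization, loci/Mbp and bp/Mbp density summaries, GC content,
  fold-variation statistics, TE-content summaries, and read subsampling.
- **Seeding analysis** — enrichment tests for TE families adjacent to a
  target SSR motif (default 400 bp flanks) against replicate random genomic
  backgrounds, with one-tailed exact tests on region-level presence/absence,
  plus joint/conditional co-occurrence probabilities.
- **LINE consensus** — reference-free consensus building by iterative
  seed-and-extend mapping and majority rule, with 10×/20× coverage masking.
- **Truncation & divergence** — 3′:5′ normalized read-depth coverage ratio
  (a 5′-truncation index), tiled window / half / third depth profiles, and
  subfamily-filtered per-read pairwise divergence (π) as an age proxy.
- **Comparative phylogenetics** — phylogenetic independent contrasts and
  contrast regressions, censored multi-rate Brownian-motion tests with
  simulation-based p values, BM ancestral state reconstruction,
  Kruskal–Wallis + Dunn/BH tests, normality/homoscedasticity gating, and
  trimmed-median Ne summarization.
- **Synthetic data** — genome/read/tree/trait simulators with full truth
  tables, so every stage is testable end-to-end without external data.

## CLI

All subcommands share `--seed`, `--log-level`, and `--config` (flat
`key = value` lines).

```sh
# generate a synthetic dataset with truth tables
repeatscape --seed 1 simulate --out-prefix sim/demo

# scan for microsatellites and summarize densities
repeatscape ssr-scan --genome sim/demo.genome.fa \
    --out loci.bed --summary landscape.tsv

# test TE-family enrichment adjacent to AATAG loci
repeatscape --seed 1 seeding --genome sim/demo.genome.fa \
    --loci sim/demo.ssr.bed --te sim/demo.te.out \
    --motif AATAG --width 400 --replicates 5 --alpha 0.01 --out seeding.tsv

# build a LINE consensus from reads and a related-species starting reference
repeatscape consensus --reads sim/demo.reads.fa --init ref.fa \
    --k 17 --max-mm 0.2 --out consensus.fa

# truncation and divergence profiles against a consensus
repeatscape truncation --reads sim/demo.reads.fa --consensus cons.fa --out profile.tsv
repeatscape divergence --reads sim/demo.reads.fa --consensus cons.fa --out pi.tsv

# contrast regression of one trait on another over a time-calibrated tree
repeatscape compare --tree tree.nwk --traits traits.tsv \
    --y truncation --x median_ne --log-y --out compare.tsv
```

Formats: FASTA/FASTQ (qualities ignored), RepeatMasker `.out` (modern
fixed-column dialect) or BED6 with the family in the name field, Newick
trees with branch lengths, two-column Ne time-series tables, and TSV trait
tables keyed by species. Coordinates are 0-based half-open internally and
converted only at format boundaries.

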
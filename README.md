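# arichclip

Analysis pipeline for iCLIP crosslink data centered on RNA-binding proteins
that position upstream of A-rich stretches and poly(A) tails. The package
covers:

- **preprocess** — barcode quality filtering (9-nt layout: random barcode at
  positions 1–3/8–9, experimental at 4–7), random-barcode duplicate removal,
  and crosslink-event extraction (one event at the nucleotide upstream of
  each read's 5′ end, strand-aware).
- **sitecalling** — a local negative-binomial peak caller (method-of-moments
  fit over a 500-nt exonic context) followed by the refinement cascade:
  resize to uniform 9-nt windows around weighted centers, sparse-coverage
  filter (≥3 covered nt), iterative merging of overlapping windows at the
  cumulative half-maximum, single-protein-coding-gene and region assignment
  (3′UTR > 5′UTR > CDS > intron), and a per-replicate reproducibility filter
  (≥3 events in every replicate).
- **sob** — signal-over-background binding strength: site window count over
  gene background density (events outside site windows ±5 nt, divided by
  merged exon length with the 3′ UTR truncated 10 nt past the last site or
  at 500 nt), per replicate, averaged; undefined below 10 background events.
- **seqcontext** — positional 4-mer profiles, empirical 4-mer z-scores
  against a resampled 3′ UTR background (1000 windows × 100 repeats),
  the A-rich stretch maximization search (8–30 nt windows in a 55-nt space
  downstream of the site center, scored by A-content, longest continuous
  A-run and weighted A-content), stretch merging, and SOB stratified by LCA.
- **polya_meta** — cumulative A-content and terminal-A curves over unmapped
  reads, and crosslink metaprofiles around annotated polyadenylation sites
  (2001-nt window, 50-nt smoothing, −150..−50 vs −750..−650 enrichment
  factor) and around A-rich stretch starts.
- **synthetic** — a deterministic generator for toy genomes, GTF
  annotations, negative-binomial crosslink tracks with planted 9-nt
  footprints upstream of planted A-rich stretches, and reads with
  untemplated terminal A-runs; every stage is tested against this ground
  truth.

Coordinates are 0-based half-open internally; GTF I/O converts from 1-based
closed, bedGraph I/O is 0-based half-open (one plus- and one minus-strand
file per replicate).

## CLI

```sh
arichclip init-config config.yaml     # write the reference default parameters
arichclip simulate --config config.yaml --seed 1 --outdir out/
arichclip all --config config.yaml    # run on real inputs listed in config
arichclip validate --genome g.fa --annotation a.gtf --bedgraph t.plus.bedgraph
```

`simulate`/`all` run the full cascade and write: `sites.bed` (BED6+ with
gene, region, per-replicate counts, SOB), `sob.tsv`, `stretches.bed`,
`kmer_zscores.tsv`, `kmer_profile.tsv`, `sob_by_lca.tsv`,
`polya_read_curves.tsv`, `polya_metaprofile.tsv`, `stretch_metaprofile.tsv`,
`stretch_heatmap.tsv`, an exclusion log, the echoed config and a
`manifest.json` with a config hash and per-stage record counts. Runs with
identical config and seed are byte-identical. Exit codes: 0 ok, 2 input
error, 3 stage failure.

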
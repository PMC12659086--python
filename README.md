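# plastidflip

Toolkit for chloroplast pangenome analysis on quadripartite genomes
(LSC–IRa–SSC–IRb), built around the flip-flop recombination of the two
inverted repeats (IRs):

- **synthetic data** — generate circular quadripartite genomes (~136 kb by
  default, near-perfect reverse-complement IRs with injected 1–3 bp
  differences), sample populations with region-structured SNP/indel/SV
  variation (indels placeable inside 5–8 bp direct repeats, IRa indels
  mirrorable into IRb), build the two inversion isomers, and simulate
  HiFi-like long reads with hidden truth labels.
- **enrichment** — conserved-window bait sets, k-mer classification of
  reads into chloroplast vs background, cpDNA copy-number estimation, and
  depth profiles on a one-IR reference (the IR shows ~2× the single-copy
  depth).
- **ir_assembly** — IR-centered pseudo-references (IR ± 2 kb flanks),
  flank-orientation classification of reads into IRa/IRb datasets,
  reference-guided majority consensus, IRa-vs-IRb comparison, and
  quadripartite stitching by exact junction overlaps.
- **isomer detection** — stringent counting of junction-spanning reads
  (complete IR plus ≥2 kb single-copy flanks on both sides) per inversion
  isomer, contig classification, and an exact binomial equimolarity test.
- **variant_map** — anchored pairwise alignment (or an external MSA),
  VCF-style left-aligned SNP/indel/SV extraction (≥50 bp ⇒ SV), region and
  genic-context annotation, and the pan unique-sequence curve.
- **popgen_stats** — nucleotide diversity (π = D/L/(N·(N−1)/2)), sliding
  windows (1 kb / 0.5 kb step), Tajima's D, haploid Weir–Cockerham FST,
  LD r² decay, allele-frequency spectra, GC content.
- **repeat_analysis** — direct-repeat census by descending k-mer masking
  (k = 3..30), variant/repeat overlap fractions, and IRa/IRb indel-density
  mirroring.

Everything runs on synthetic data with exact truth tables, so the full
pipeline is testable offline and deterministic under a fixed seed.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the headline end-to-end criteria
(equimolar isomer recovery, IR depth doubling, IRa/IRb dataset-size
identity, pseudo-reference arithmetic, oracle cross-checks, truth
recovery).

## CLI

```sh
plastidflip simulate --seed 1 --outdir sim/            # genome+population+reads
plastidflip enrich --reads sim/reads.fastq --panel sim/reference.fasta --outdir enr/
plastidflip classify-ir --reads sim/reads.fastq --genome sim/reference.fasta --out asg.tsv
plastidflip consensus --reads sim/reads.fastq --genome sim/reference.fasta --out cons.fasta
plastidflip detect-isomers --reads sim/reads.fastq --genome sim/reference.fasta --out iso.json
plastidflip call-variants --samples sim/samples.fasta --reference sim/reference.fasta --out calls.vcf
plastidflip pan-curve --samples sim/samples.fasta --reference sim/reference.fasta --out pan.tsv
plastidflip popgen --msa aln.fasta --outdir pg/
plastidflip repeats --fasta sim/reference.fasta --outdir rep/
plastidflip mirror --vcf calls.vcf --genome sim/reference.fasta --out mirror.tsv
plastidflip run --seed 1 --outdir out/                 # full pipeline + summary.json
```

Configuration is a single YAML document (unknown keys rejected); CLI flags
override file values, and every run writes the resolved config next to its
outputs. BED coordinates are 0-based half-open; VCF positions are 1-based.

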
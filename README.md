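# relign

Localized assembly-based realignment of short-read BAMs for improved indel
representation.

`relign` takes a coordinate-sorted, indexed BAM, a reference FASTA and a
BED of target regions, and writes a realigned BAM. Within each (≤ 2 kb)
region it:

1. builds a De Bruijn graph from the region's reads, filtering k-mers that
   contain low-quality or ambiguous bases and pruning k-mers seen in fewer
   than two distinct reads;
2. traverses every non-cyclic path into contigs longer than the read
   length, retrying with larger k when the graph is cyclic (no smoothing —
   low-frequency branches are kept on purpose);
3. aligns the contigs back to the padded local reference with a glocal
   affine-gap aligner, merging chimeric (split) placements into single
   long-deletion alignments (deletions up to 2000 bp, insertions up to the
   read length), and drops redundant or reference-identical contigs;
4. maps each read gaplessly against the surviving contigs (the *alternate
   reference*) and moves reads that unambiguously align more closely to
   the alternate than to the original reference, projecting the hit back
   to reference coordinates as a new position + CIGAR (indels
   left-aligned). Sequences and qualities are never modified; the original
   alignment of every moved read is preserved in a `YO` tag.

A built-in simulator generates random references, truth variants
(SNV/INS/DEL), error-bearing reads and a deliberately indel-blind baseline
alignment, so the whole pipeline is testable without external data.

## CLI

Realign a BAM:

```sh
relign realign --in reads.bam --out realigned.bam \
    --ref ref.fasta --targets targets.bed \
    [--kmer 25 --min-reads 2 --max-region 2000 --max-del 2000 \
     --decisions decisions.tsv]
```

The run writes `realigned.bam` (+ `.bai`) and a JSON manifest
(`<out>.manifest.json` by default) with region/read counters.

Generate a synthetic dataset (reference FASTA, naive-aligned BAM, truth
TSV and a whole-reference targets BED):

```sh
relign simulate --out-dir sim/ --ref-len 10000 --depth 50 --read-len 100 \
    --variants DEL:4000:2000,SNV:1000,INS:7000:25:0.5 --seed 1
```

Variant spec items are `KIND:POS[:LEN[:VAF]]`; `VAF` 0.5 marks a
heterozygous variant (diploid read sampling), 1.0 homozygous.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes per-module unit tests, hypothesis property tests
(window filtering, region splitting, chimeric merging), independent
oracles (networkx path enumeration, a quadratic affine-gap DP, CIGAR
reconstruction round trips) and end-to-end simulation runs. The full run
takes a few minutes on one CPU.

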
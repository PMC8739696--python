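# longfuse

Fusion gene detection for noisy long-read transcriptome data (ONT / PacBio),
with a built-in simulator and evaluator so the whole method can be exercised
end-to-end on synthetic data with no downloads.

## The problem and the method

Genomic rearrangements in cancer can join two genes into one hybrid
transcript — a fusion gene. Long reads capture fusion transcripts end to end,
but their high error rate (read identities roughly 75–95%) breaks
short-read fusion callers. `longfuse` detects fusions from long reads with a
double-alignment strategy and exon-boundary reasoning:

1. **Transcriptome alignment.** Reads are aligned to a reference
   transcriptome with a noise-tolerant spliced long-read aligner (minimap2,
   `-x map-ont`).
2. **Candidate selection.** A read is a fusion candidate when two of its
   alignment segments hit *different genes*, abut in read coordinates (at
   most 15 bp of overlap and at most a 15 bp gap) and map on the same
   strand.
3. **Genome confirmation.** Candidate reads are re-aligned to the genome
   (`-x splice`); reads that no longer span two genes are dropped.
4. **Breakpoint determination.** The genomic junction of each read is taken
   from alignment end positions, filtered when it is explainable by regular
   transcription (same strand, transcription order, < 10 kbp apart), then
   *anchored to annotated exon boundaries*: rearrangements usually fall in
   introns, so true fusion breakpoints sit at splice sites. A breakpoint is
   snapped when boundaries of both genes lie within 20 bp of the alignment
   ends and the two shifts move the junction consistently (same read-space
   displacement). Remaining breakpoints are clustered by Euclidean genomic
   distance (50 bp), least-supported first.
5. **Classification and reporting.** Breakpoints are ranked
   **HighConfidence** (≥ 2 reads, at exon boundaries), **LowConfidence**
   (≥ 2 reads, inside exon bodies — where cDNA library-preparation chimeras
   characteristically fall), or **PotentialTransSplicing** (1 read, at
   boundaries); single-read non-boundary events are discarded. Read-through
   transcription (< 200 kbp, transcription order) and mitochondrial events
   are filtered by default; in-frame status and known-pair annotation are
   added; reads carrying two or more reported breakpoints are linked into
   multi-gene (≥ 3 gene) fusions.

The package also ships a **simulator** (synthetic multi-chromosome genome
with multi-exon gene models; exon-join fusion transcripts with ≥ 100 bp per
side; full-length reads with per-read identity ~ Normal(mean, 5) and
substitution/insertion/deletion errors 1:1:1; intra-exon chimera artifacts)
and an **evaluator** (truth matching within 1 kbp Euclidean distance,
coverage × identity sensitivity grids, support recovery, callset
comparison).

## Worked example

Simulate three fusions at coverage 10 and 95% identity, call fusions, and
score against the simulation truth:

```bash
longfuse simulate --outdir demo/sim --seed 7 --n-fusions 3 --coverage 10 --identity 95
longfuse call --reads demo/sim/reads.fastq --genome demo/sim/genome.fa \
              --annotation demo/sim/annotation.gtf --outdir demo/call
longfuse evaluate --calls demo/call/fusions.csv --truth demo/sim/truth.tsv \
                  --outdir demo/eval
```

`call` prints per-stage counts — 30 reads in, 27 candidate reads, 3
breakpoints, all HighConfidence:

```json
{"reads_in": 30, "reads_aligned_tx": 30, "candidate_reads": 27,
 "genome_confirmed_reads": 27, "raw_breakpoints_post_intron_filter": 27,
 "breakpoints": 3, "class_HighConfidence": 3, "class_LowConfidence": 0,
 "class_PotentialTransSplicing": 0, "reported_calls": 3}
```

`demo/call/fusions.csv` holds the ranked table (1-based coordinates):

```
sample,fusion_genes,chrom5,base5,strand5,chrom3,base3,strand3,spanning_reads,classification,inframe,known,read_ids
sample,GENE0014:GENE0032,chr3,5418,-,chr5,44059,-,10,HighConfidence,false,false,F0000_r0000;...
```

and `evaluate` reports that all three simulated junctions were recovered,
every one at the exact simulated base, with 90% of the simulated coverage
reported as supporting reads:

```json
{"n_truth": 3, "n_detected": 3, "detected_fraction": 1.0,
 "high_confidence_share": 1.0, "single_breakpoint_share": 1.0,
 "exact_share": 1.0, "support_recovery_by_identity": {"95.0": 0.9}}
```

The same pipeline is available as a library (`longfuse.run_simulate`,
`longfuse.run_call`, `longfuse.run_evaluate`,
`longfuse.benchmark.run_simulation_study`).

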
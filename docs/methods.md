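# Methods

## Model and assumptions

`longfuse` treats a fusion transcript as a concatenation of a 5' gene prefix
and a 3' gene suffix, read out in one direction. Three assumptions drive the
design:

* **Split transcriptome alignment identifies candidates.** A read from a
  fusion aligns to the two partner transcripts over adjacent read intervals.
  Requiring ≤ 15 bp of overlap and ≤ 15 bp of gap between the intervals, and
  equal read-vs-transcript strand, separates genuine two-gene reads from
  coincidental homology hits. The thresholds assume *base-level* alignment
  ends, so the aligner is invoked with `-c`; chain-level (anchor-truncated)
  PAF intervals are tens of bases short and would reject nearly everything.
* **True breakpoints sit at exon boundaries.** Rearrangements mostly fall in
  introns while splicing is preserved, so the RNA junction coincides with an
  annotated exon end (5' side, strand-aware) and exon start (3' side).
  Library-preparation chimeras instead join positions inside exon bodies.
  This asymmetry powers both breakpoint correction (anchoring) and artifact
  separation (the LowConfidence class).
* **Read support plus boundary status orders evidence.** ≥ 2 reads at exon
  boundaries → HighConfidence; ≥ 2 reads off-boundary → LowConfidence
  (chimera-like); 1 read at boundaries → PotentialTransSplicing; 1 read
  off-boundary → discarded.

## Breakpoint coordinates

Internally every junction is a pair of 0-based inter-base cut points
(5' side: cut after the last transcribed base; 3' side: cut before the first
base), the same space as exon `start`/`end` values, so anchoring and truth
matching need no coordinate shimming. CSV output adds 1 to both sides.
Alignment strands are resolved against annotated gene strands by majority
vote, so reverse-complement (antisense) cDNA reads report the same oriented
breakpoint as sense reads.

## Anchoring consistency

A boundary pair (b5, b3) within the 20 bp window is accepted only if the two
shifts land the junction on a single read position:
`|δ5 − δ3 − q_gap| ≤ 10`, where δ is each side's shift expressed as a
read-space displacement and `q_gap` is the signed read-space distance between
the two genome alignment intervals at the junction. The naive form
`|δ5 − δ3| ≤ 10` (the `q_gap = 0` special case) would let a read whose
spliced genome alignment silently dropped a junction-adjacent exon anchor
"consistently" at a wrong boundary pair — in grid simulations this inflated
secondary breakpoints until only ~81% of fusions had a single reported
breakpoint; with the gap-aware form ~100% do. For the same reason the
15 bp overlap/gap abutment requirement is enforced at the genome stage too:
a junction with a > 15 bp hole in read coverage is not located by the
alignment ends and contributes no breakpoint.

## Parameters (defaults)

| parameter | default | meaning |
|---|---|---|
| `max_overlap` / `max_gap` | 15 bp | candidate abutment tolerance (both stages) |
| `intron_filter` | 10 kbp | junction removable as regular transcription |
| `anchor_window` | 20 bp | boundary search window per side |
| `consistency_tol` | 10 bp | allowed read-space disagreement of the two shifts |
| `cluster_radius` | 50 bp | Euclidean √(Δ5′² + Δ3′²) merge radius |
| `readthrough_dist` | 200 kbp | read-through filter span |
| `mito_names` | chrM, MT | chromosomes triggering the mitochondrial filter |
| truth-match radius | 1 kbp | Euclidean distance for evaluation |

Clustering iterates non-anchored breakpoints in ascending read support
(ties: ascending positions), donating each one's reads to the closest
surviving breakpoint within the radius (anchored preferred on distance
ties), recomputing distances after every merge; survivors keep their own
positions, so clusters containing an anchored member report the boundary.

## What the simulator emulates — and what it does not

The generator builds a random multi-chromosome genome with non-overlapping
multi-exon genes (3–8 exons of 80–300 bp, introns 0.2–2 kbp carrying
strand-aware GT..AG dinucleotides so the spliced aligner sees canonical
splice signals, CDS covering all but short terminal UTR stubs). Fusions join
a random exon end of one gene to a random exon start of another with ≥ 100 bp
per side; partners are drawn from different chromosomes, mirroring
genome-wide random pairing where same-chromosome near neighbours are
vanishingly rare. Chimera artifacts join intra-exon positions ≥ 25 bp from
any boundary. Reads are full length; per-read identity is drawn from
Normal(mean, 5) truncated to (50, 100], with errors applied as
substitutions/insertions/deletions in a 1:1:1 ratio; half the reads are
reverse-complemented. All randomness flows from one seed and outputs are
byte-identical across runs.

Departures from real long-read data, and their consequences:

* **No read-length distribution.** Real cDNA/RNA reads are frequently
  truncated and many never span the junction; full-length simulated reads
  therefore *overstate* supporting-read recovery (≈ 93–95% of coverage at
  95% identity in the benchmark grids) and, by making single-read
  detections at coverage 1–2 more common, *understate* the High-Confidence
  share among detected fusions. An optional `truncation` range in
  `SimConfig` exists for experimentation but is off by default.
* **Uniform, unclustered errors.** Real ONT/PacBio errors cluster (e.g. in
  homopolymers), leaving longer clean stretches for minimizer seeding;
  uniform errors at a 25% rate make 75%-identity reads harder to align than
  platform-realistic reads of nominally equal identity, so the
  candidate-stage loss measured at 75% identity (~91–95% of fusion reads)
  is an upper bound relative to real data.
* **No junk/random/adapter reads, no ligation chimeras** — artifact classes
  other than the intra-exon cDNA chimera are out of scope.
* Passing grid tests therefore demonstrate the *method's* behaviour
  (detection, anchoring accuracy, ranking separation) under controlled
  noise, not platform-calibrated absolute sensitivities.

## Numerical and degenerate-input choices

* Deterministic tie-breaks everywhere randomness is not intended: candidate
  chain reduction prefers larger match count, then longer query span, then
  lexicographic transcript id; anchoring prefers the smallest total shift,
  then smaller 5' shift, then lower genomic position; clustering ties by
  position; ranking ties by gene name then position.
* Secondary alignments (`tp:A:S`) are ignored throughout: on a
  transcriptome they are redundant isoform hits that would inflate gene
  pairs. MAPQ is recorded but not filtered on.
* Gene identity is `gene_name` when present, else `gene_id`; a genome
  segment is assigned to the gene whose span its spliced blocks overlap
  most, with the transcriptome-stage gene winning when it overlaps at all.
* Empty inputs produce empty (header-only) tables and exit code 0; a
  missing aligner with no pre-computed PAF is an actionable error.
* The read-through filter runs after classification but before reporting, so
  per-class stage counts are logged on the unfiltered set.
* Single-threaded by design; the determinism guarantee outweighs the
  aligner's thread-level speedup at the problem sizes targeted here.

## Benchmark problem sizes

The acceptance study uses 102 fusions over identities {90, 95}% × coverages
{10, 50, 100} for the sensitivity figure and 500 fusions (20 per cell) over
the full {75, 80, 85, 90, 95}% × {1, 2, 10, 50, 100} grid for the
classification, breakpoint-resolution, support-recovery and read-loss
figures — a scale chosen so the whole study runs in minutes on one CPU while
keeping ≥ 100 fusions behind every reported fraction.

## Known limitations

* Annotation-driven: fusions with intergenic or intronic breakpoints are
  invisible, as are partners absent from the GTF.
* GTF (GENCODE attribute dialect) only; no GFF3.
* Transcriptome-first candidate flow: reads alignable only to the genome are
  never rescued.
* The in-frame annotation is a reconstruction (any transcript pair whose
  coding prefixes agree mod 3); real callers differ in edge handling.
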
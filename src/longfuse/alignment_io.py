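"""PAF alignment parsing, read grouping, and the external aligner contract."""

from __future__ import annotations

import gzip
import logging
import shutil
import subprocess
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from Bio import SeqIO

logger = logging.getLogger(__name__)


class PafError(ValueError):
    pass


@dataclass
class AlignmentSegment:
    """One aligned block of a read (one PAF line).

    Query coordinates are always on the original read strand; ``strand`` gives
    read-vs-target orientation. ``spliced_blocks`` holds target intervals of
    the aligned exonic pieces when the CIGAR contains intron (N) operations.
    """

    read_id: str
    read_len: int
    q_start: int
    q_end: int
    strand: str
    target_id: str
    t_start: int
    t_end: int
    mapq: int = 0
    n_match: int = 0
    is_primary: bool = True
    spliced_blocks: Optional[list[tuple[int, int]]] = None

    def blocks(self) -> list[tuple[int, int]]:
        return self.spliced_blocks or [(self.t_start, self.t_end)]

    @property
    def q_span(self) -> int:
        return self.q_end - self.q_start


@dataclass
class ReadAlignments:
    read_id: str
    segments: list[AlignmentSegment] = field(default_factory=list)


def _blocks_from_cigar(cigar: str, t_start: int) -> Optional[list[tuple[int, int]]]:
    """Walk a PAF cg CIGAR; split target blocks at N (intron) operations."""
    blocks: list[tuple[int, int]] = []
    pos = t_start
    block_start = t_start
    num = ""
    saw_n = False
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in "M=XD":
            pos += n
        elif ch == "N":
            saw_n = True
            if pos > block_start:
                blocks.append((block_start, pos))
            pos += n
            block_start = pos
        elif ch in "I":
            pass
        else:
            raise PafError(f"unsupported CIGAR op {ch!r}")
    if pos > block_start:
        blocks.append((block_start, pos))
    return blocks if saw_n else None


def read_paf(path) -> Iterator[AlignmentSegment]:
    """Parse a PAF file into :class:`AlignmentSegment` records.

    Honours the ``tp:A`` tag (secondary alignments get ``is_primary=False``)
    and reconstructs spliced blocks from a ``cg:Z`` CIGAR when present.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise PafError(f"{path}:{lineno}: PAF line has {len(f)} < 12 columns")
            try:
                seg = AlignmentSegment(
                    read_id=f[0], read_len=int(f[1]),
                    q_start=int(f[2]), q_end=int(f[3]), strand=f[4],
                    target_id=f[5], t_start=int(f[7]), t_end=int(f[8]),
                    n_match=int(f[9]), mapq=int(f[11]))
            except ValueError as exc:
                raise PafError(f"{path}:{lineno}: {exc}") from None
            cigar = None
            for tag in f[12:]:
                if tag.startswith("tp:A:"):
                    seg.is_primary = tag[5] != "S"
                elif tag.startswith("cg:Z:"):
                    cigar = tag[5:]
            if cigar:
                seg.spliced_blocks = _blocks_from_cigar(cigar, seg.t_start)
            yield seg


def write_paf(segments: Iterable[AlignmentSegment], path) -> int:
    """Write minimal 12-column PAF (plus tp tag); used for round-trip tests."""
    n = 0
    with open(path, "w") as fh:
        for s in segments:
            t_len = max(s.t_end, *(e for _, e in s.blocks()))
            fh.write("\t".join(map(str, [
                s.read_id, s.read_len, s.q_start, s.q_end, s.strand,
                s.target_id, t_len, s.t_start, s.t_end, s.n_match,
                max(s.q_span, s.t_end - s.t_start), s.mapq,
                f"tp:A:{'P' if s.is_primary else 'S'}"])) + "\n")
            n += 1
    return n


def group_by_read(segments: Iterable[AlignmentSegment]) -> Iterator[ReadAlignments]:
    """Group segments by read id; within a read, sort by query start."""
    groups: dict[str, list[AlignmentSegment]] = {}
    for s in segments:
        groups.setdefault(s.read_id, []).append(s)
    for read_id, segs in groups.items():
        segs.sort(key=lambda s: (s.q_start, s.q_end, s.target_id, s.t_start))
        yield ReadAlignments(read_id=read_id, segments=segs)


def _open_maybe_gzip(path, mode="rt"):
    with open(path, "rb") as probe:
        magic = probe.read(2)
    return gzip.open(path, mode) if magic == b"\x1f\x8b" else open(path, mode)


def convert_fastq_to_fasta(in_path, out_path) -> int:
    """Convert (optionally gzipped) FASTQ to FASTA; returns the record count."""
    n = 0
    with _open_maybe_gzip(in_path) as fin, open(out_path, "w") as fout:
        for rec in SeqIO.parse(fin, "fastq"):
            fout.write(f">{rec.id}\n{rec.seq}\n")
            n += 1
    return n


def read_fasta_seqs(path) -> dict[str, str]:
    with _open_maybe_gzip(path) as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


# ---------------------------------------------------------------------------
# External aligner contract
# ---------------------------------------------------------------------------

PRESETS = {
    # transcriptome stage: noise-tolerant long-read mapping; -c forces
    # base-level alignment so segment ends are exact, which the tight
    # 15 bp overlap/gap candidate rule depends on
    "transcriptome": ["-x", "map-ont", "-c"],
    # genome stage: spliced alignment; -c emits the CIGAR we need for
    # intron-aware block reconstruction
    "genome": ["-x", "splice", "-c"],
}


class AlignerNotFound(RuntimeError):
    pass


def run_aligner(preset: str, target_fa, query_fa, out_paf,
                binary: str = "minimap2", threads: int = 1,
                extra_args: Optional[list[str]] = None) -> None:
    """Run the external long-read aligner, writing PAF to ``out_paf``.

    The pipeline equally accepts pre-computed PAF, so this wrapper is only
    exercised when an aligner binary is available.
    """
    if shutil.which(binary) is None:
        raise AlignerNotFound(
            f"aligner binary {binary!r} not found on PATH; supply pre-computed "
            f"PAF alignments instead")
    args = [binary, *PRESETS[preset], "-t", str(threads)]
    if extra_args:
        args += extra_args
    args += [str(target_fa), str(query_fa)]
    with open(out_paf, "w") as out:
        res = subprocess.run(args, stdout=out, stderr=subprocess.PIPE, text=True)
    if res.returncode != 0:
        raise RuntimeError(f"aligner failed ({res.returncode}): {res.stderr[-2000:]}")
    logger.info("aligner %s preset=%s -> %s", binary, preset, out_paf)
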
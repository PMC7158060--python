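"""Core data model for the bisulfite RNA-seq pipeline.

All coordinates are 0-based half-open on the plus strand of their contig.
Transcript-strand sequence context (the strand on which bisulfite chemistry
acts) is always derived from the ``strand`` field, never re-guessed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

RNA_CLASSES = ("mRNA", "tRNA", "rRNA", "spikein", "ncRNA")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class TranscriptModel:
    """A transcript: sorted, non-overlapping exons plus an optional CDS.

    ``cds`` is a genomic (start, end) interval that must lie in exonic
    space; its spliced length must be a multiple of 3.
    """

    transcript_id: str
    gene_id: str
    seqname: str
    strand: str
    exons: list[tuple[int, int]]
    cds: Optional[tuple[int, int]] = None
    biotype: str = "mRNA"

    def __post_init__(self) -> None:
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b), (c, d) in zip(self.exons, self.exons[1:]):
            if c < b:
                raise ValueError(f"overlapping exons in {self.transcript_id}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    def genomic_to_spliced(self, pos: int) -> Optional[int]:
        """Spliced-transcript offset (5'->3' on the transcript strand) of a
        genomic position, or None if the position is not exonic."""
        off = 0
        hit = None
        for a, b in self.exons:
            if a <= pos < b:
                hit = off + (pos - a)
                break
            off += b - a
        if hit is None:
            return None
        if self.strand == "-":
            return self.spliced_length - 1 - hit
        return hit

    def spliced_to_genomic(self, off: int) -> int:
        if not 0 <= off < self.spliced_length:
            raise IndexError(off)
        if self.strand == "-":
            off = self.spliced_length - 1 - off
        for a, b in self.exons:
            if off < b - a:
                return a + off
            off -= b - a
        raise AssertionError("unreachable")

    def cds_spliced_interval(self) -> Optional[tuple[int, int]]:
        """CDS as a half-open interval in spliced-transcript coordinates."""
        if self.cds is None:
            return None
        s, e = self.cds
        offs = sorted(
            x
            for x in (self.genomic_to_spliced(s), self.genomic_to_spliced(e - 1))
            if x is not None
        )
        return offs[0], offs[1] + 1

    def spliced_sequence(self, sequences: dict[str, str]) -> str:
        seq = "".join(sequences[self.seqname][a:b] for a, b in self.exons)
        return revcomp(seq) if self.strand == "-" else seq


@dataclass
class ReferenceSet:
    """Sequences + transcript models + RNA-class labels.

    The coordinate frame for everything downstream of read alignment.
    """

    sequences: dict[str, str]
    transcripts: list[TranscriptModel]
    class_of: dict[str, str]
    mature_region_of: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t in self.transcripts:
            if t.seqname not in self.sequences:
                raise ValueError(
                    f"transcript {t.transcript_id} references missing sequence "
                    f"{t.seqname!r}"
                )
            if t.span[1] > len(self.sequences[t.seqname]):
                raise ValueError(f"transcript {t.transcript_id} exceeds sequence bounds")

    def transcripts_of_gene(self, gene_id: str) -> list[TranscriptModel]:
        return [t for t in self.transcripts if t.gene_id == gene_id]

    def genes_on(self, seqname: str) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.transcripts:
            if t.seqname == seqname:
                seen.setdefault(t.gene_id)
        return list(seen)

    def transcript_strand_base(self, seqname: str, pos: int, strand: str) -> str:
        base = self.sequences[seqname][pos].upper()
        return base.translate(COMPLEMENT) if strand == "-" else base


@dataclass
class AlignmentRecord:
    """A mapped read in plus-strand space, with its originating transcript
    strand resolved (YS tag from the simulator / bisulfite aligner)."""

    name: str
    seqname: str
    pos: int  # leftmost, 0-based
    strand: str  # transcript strand, '+' or '-'
    bases: str
    quals: list[int]
    cigar: list[tuple[str, int]]  # ops restricted to M and N
    mapped: bool = True
    unique: bool = True
    mapq: int = 42

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError("bases/quals length mismatch")
        consumed = sum(n for op, n in self.cigar if op == "M")
        if consumed != len(self.bases):
            raise ValueError("CIGAR M length does not match read length")

    @property
    def read_length(self) -> int:
        return len(self.bases)

    def aligned_pairs(self) -> Iterable[tuple[int, int]]:
        """Yield (read_offset, reference_position) for every M base."""
        rpos = self.pos
        qoff = 0
        for op, n in self.cigar:
            if op == "M":
                for i in range(n):
                    yield qoff + i, rpos + i
                qoff += n
                rpos += n
            elif op == "N":
                rpos += n
            else:
                raise ValueError(f"unsupported CIGAR op {op}")

    @property
    def end(self) -> int:
        return self.pos + sum(n for op, n in self.cigar)


@dataclass
class TruthEntry:
    """One planted methylation site: the recovery-testing oracle unit."""

    gene_id: str
    seqname: str
    strand: str
    pos: int  # 0-based plus-strand position of the (transcript-strand) C
    rna_class: str
    stoichiometry: tuple[float, ...]  # one methylation fraction per fraction
    jitter_concentration: float = 200.0


@dataclass
class TruthTable:
    entries: list[TruthEntry]

    def __post_init__(self) -> None:
        keys = [(e.seqname, e.pos) for e in self.entries]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate truth positions")
        for e in self.entries:
            if not all(0.0 <= s <= 1.0 for s in e.stoichiometry):
                raise ValueError("stoichiometry outside [0,1]")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def lookup(self, seqname: str, pos: int) -> Optional[TruthEntry]:
        for e in self.entries:
            if e.seqname == seqname and e.pos == pos:
                return e
        return None
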
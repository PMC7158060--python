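"""Readers and writers for the formats the pipeline touches, plus the
bisulfite reference-conversion utility.

Internal convention: 0-based half-open coordinates everywhere. SAM POS is
converted on ingestion; BED output stays 0-based; site tables additionally
carry a 1-based ``coord1`` column, labelled as such.
"""
from __future__ import annotations

import os
from typing import Iterable, Iterator, Optional

import gffutils
import pysam
from pyfaidx import Fasta

from .models import AlignmentRecord, ReferenceSet, TranscriptModel

_VALID_NT = set("ACGTNacgtn")


# ---------------------------------------------------------------------------
# FASTA / GTF
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _gtf_attrs(**kv: str) -> str:
    return " ".join(f'{k} "{v}";' for k, v in kv.items())


def write_gtf(refset: ReferenceSet, path: str) -> None:
    """Emit gene / transcript / exon / CDS features in a minimal GENCODE-like
    GTF dialect (attributes: gene_id, transcript_id, rna_class)."""
    lines = []
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in refset.transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    for gid, ts in by_gene.items():
        seqname = ts[0].seqname
        strand = ts[0].strand
        gstart = min(t.span[0] for t in ts)
        gend = max(t.span[1] for t in ts)
        cls = refset.class_of.get(gid, "ncRNA")
        attrs = _gtf_attrs(gene_id=gid, rna_class=cls)
        lines.append(
            f"{seqname}\tpolybs\tgene\t{gstart + 1}\t{gend}\t.\t{strand}\t.\t{attrs}"
        )
        for t in ts:
            tattrs = _gtf_attrs(gene_id=gid, transcript_id=t.transcript_id,
                                rna_class=cls, biotype=t.biotype)
            s, e = t.span
            lines.append(
                f"{seqname}\tpolybs\ttranscript\t{s + 1}\t{e}\t.\t{strand}\t.\t{tattrs}"
            )
            for a, b in t.exons:
                lines.append(
                    f"{seqname}\tpolybs\texon\t{a + 1}\t{b}\t.\t{strand}\t.\t{tattrs}"
                )
            if t.cds is not None:
                a, b = t.cds
                lines.append(
                    f"{seqname}\tpolybs\tCDS\t{a + 1}\t{b}\t.\t{strand}\t.\t{tattrs}"
                )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_reference(fasta_path: str, annotation_path: str) -> ReferenceSet:
    """Load FASTA + GTF into a ReferenceSet.

    Round-trip property: ``write_fasta``/``write_gtf`` followed by
    ``load_reference`` is the identity on the data model.
    """
    fa = Fasta(fasta_path, as_raw=True, sequence_always_upper=False,
               build_index=not os.path.exists(fasta_path + ".fai"))
    sequences = {name: str(fa[name][:]) for name in fa.keys()}

    db = gffutils.create_db(
        annotation_path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    transcripts: list[TranscriptModel] = []
    class_of: dict[str, str] = {}
    for g in db.features_of_type("gene"):
        gid = g.attributes["gene_id"][0]
        class_of[gid] = g.attributes.get("rna_class", ["ncRNA"])[0]
    for tr in db.features_of_type("transcript"):
        tid = tr.attributes["transcript_id"][0]
        gid = tr.attributes["gene_id"][0]
        if tr.seqid not in sequences:
            raise ValueError(
                f"transcript {tid} references sequence {tr.seqid!r} absent "
                f"from the FASTA"
            )
        exons = []
        cds: Optional[tuple[int, int]] = None
        for child in db.children(tr, featuretype="exon"):
            exons.append((child.start - 1, child.end))
        cds_parts = [(c.start - 1, c.end) for c in db.children(tr, featuretype="CDS")]
        if cds_parts:
            cds = (min(a for a, _ in cds_parts), max(b for _, b in cds_parts))
        biotype = tr.attributes.get("biotype", [class_of.get(gid, "ncRNA")])[0]
        transcripts.append(
            TranscriptModel(
                transcript_id=tid, gene_id=gid, seqname=tr.seqid,
                strand=tr.strand, exons=exons, cds=cds, biotype=biotype,
            )
        )
    transcripts.sort(key=lambda t: (t.seqname, t.span, t.transcript_id))
    # the annotated span of a tRNA transcript is its mature region; the
    # 100-nt precursor flanks are unannotated contig sequence
    mature = {t.gene_id: t.span for t in transcripts
              if class_of.get(t.gene_id) == "tRNA"}
    return ReferenceSet(sequences=sequences, transcripts=transcripts,
                        class_of=class_of, mature_region_of=mature)


# ---------------------------------------------------------------------------
# Bisulfite reference conversion
# ---------------------------------------------------------------------------

def convert_reference(refset: ReferenceSet) -> tuple[dict[str, str], dict[str, str]]:
    """C->T conversion of the forward strand and G->A conversion of the
    reverse strand, the two indices a bisulfite-aware aligner maps against.

    Idempotent on its own output; lengths and non-C/G characters preserved.
    """
    for name, seq in refset.sequences.items():
        for i, ch in enumerate(seq):
            if ch not in _VALID_NT:
                raise ValueError(
                    f"non-nucleotide character {ch!r} at {name}:{i}"
                )
    c2t = {n: s.replace("C", "T").replace("c", "t")
           for n, s in refset.sequences.items()}
    g2a = {n: s.replace("G", "A").replace("g", "a")
           for n, s in refset.sequences.items()}
    return c2t, g2a


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def _cigar_to_pysam(cigar: list[tuple[str, int]]) -> list[tuple[int, int]]:
    opmap = {"M": 0, "N": 3}
    return [(opmap[op], n) for op, n in cigar]


def _cigar_from_pysam(cigartuples) -> list[tuple[str, int]]:
    opmap = {0: "M", 3: "N", 7: "M", 8: "M"}
    out = []
    for op, n in cigartuples:
        if op not in opmap:
            raise ValueError(f"unsupported CIGAR op code {op}")
        out.append((opmap[op], n))
    return out


def write_sam(records: Iterable[AlignmentRecord], sequences: dict[str, str],
              path: str) -> None:
    """Write records as headered SAM. FLAG encodes the alignment orientation
    (reverse for minus-strand transcripts); the originating transcript strand
    is additionally carried in the YS tag."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": len(s)} for n, s in sequences.items()],
    }
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.name
            a.query_sequence = rec.bases
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in rec.quals)
            )
            a.reference_name = rec.seqname
            a.reference_start = rec.pos
            a.cigartuples = _cigar_to_pysam(rec.cigar)
            a.mapping_quality = rec.mapq
            flag = 0
            if not rec.mapped:
                flag |= 4
            if rec.strand == "-":
                flag |= 16
            a.flag = flag
            a.set_tag("YS", rec.strand, value_type="A")
            if not rec.unique:
                a.set_tag("NH", 2)
            out.write(a)


def read_alignments(sam_path: str, min_mapq: int = 0) -> Iterator[AlignmentRecord]:
    """Stream mapped, unique records at or above ``min_mapq``.

    Transcript strand comes from the YS tag when present; otherwise from the
    FLAG under the stranded-protocol rule (reverse-flag reads originate from
    minus-strand transcripts).
    """
    with pysam.AlignmentFile(sam_path, "r") as fh:
        refs = set(fh.references)
        for a in fh:
            if a.is_unmapped:
                continue
            if a.reference_name not in refs:
                raise ValueError(
                    f"record {a.query_name} references sequence absent from header"
                )
            if a.mapping_quality < min_mapq:
                continue
            if a.has_tag("NH") and a.get_tag("NH") > 1:
                continue
            strand = a.get_tag("YS") if a.has_tag("YS") else (
                "-" if a.is_reverse else "+"
            )
            yield AlignmentRecord(
                name=a.query_name,
                seqname=a.reference_name,
                pos=a.reference_start,
                strand=strand,
                bases=a.query_sequence,
                quals=list(a.query_qualities),
                cigar=_cigar_from_pysam(a.cigartuples),
                mapped=True,
                unique=True,
                mapq=a.mapping_quality,
            )


# ---------------------------------------------------------------------------
# Truth BED
# ---------------------------------------------------------------------------

def write_truth_bed(truth, path: str) -> None:
    """BED6+ (0-based half-open): extra columns are the RNA class and the
    comma-joined per-fraction methylation stoichiometry."""
    with open(path, "w") as fh:
        for e in truth:
            stoich = ",".join(f"{s:.6g}" for s in e.stoichiometry)
            fh.write(
                f"{e.seqname}\t{e.pos}\t{e.pos + 1}\t{e.gene_id}\t0\t{e.strand}"
                f"\t{e.rna_class}\t{stoich}\n"
            )


def read_truth_bed(path: str):
    from .models import TruthEntry, TruthTable

    entries = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            entries.append(
                TruthEntry(
                    gene_id=f[3], seqname=f[0], strand=f[5], pos=int(f[1]),
                    rna_class=f[6],
                    stoichiometry=tuple(float(x) for x in f[7].split(",")),
                )
            )
    return TruthTable(entries)
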
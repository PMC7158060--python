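import numpy as np
import pytest

from polybs.models import AlignmentRecord, ReferenceSet, TranscriptModel
from polybs.simdata import SimConfig, build_reference


@pytest.fixture(scope="session")
def toy_refset() -> ReferenceSet:
    """Two-gene hand-built reference: a plus-strand coding gene with two
    exons and a minus-strand single-exon ncRNA."""
    # chrA: 60 nt; exon1 [5,25), intron [25,35), exon2 [35,55); CDS spans
    # spliced offsets [5, 35) => genomic CDS (10, 50)
    chr_a = "AAAAA" + "CCGTA" * 4 + "TTTTTTTTTT" + "GATCC" * 4 + "AAAAA"
    # chrB: 40 nt, minus-strand gene covering [5, 35)
    chr_b = "GGGGG" + "GATTC" * 6 + "GGGGG"
    t1 = TranscriptModel(
        transcript_id="tA.1", gene_id="geneA", seqname="chrA", strand="+",
        exons=[(5, 25), (35, 55)], cds=(10, 50), biotype="mRNA",
    )
    t2 = TranscriptModel(
        transcript_id="tB.1", gene_id="geneB", seqname="chrB", strand="-",
        exons=[(5, 35)], biotype="ncRNA",
    )
    return ReferenceSet(
        sequences={"chrA": chr_a, "chrB": chr_b},
        transcripts=[t1, t2],
        class_of={"geneA": "mRNA", "geneB": "ncRNA"},
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete synthetic reference with planted truth."""
    cfg = SimConfig(
        n_mrna_genes=10, n_trna_genes=1, n_rrna_genes=1, n_spikeins=1,
        planted_site_count=12, coverage_mean=40.0, seed=11,
    )
    refset, truth = build_reference(cfg, seed=11)
    return cfg, refset, truth


def make_read(seqname, pos, bases, strand="+", quals=None, name="r",
              cigar=None):
    quals = quals if quals is not None else [40] * len(bases)
    cigar = cigar if cigar is not None else [("M", len(bases))]
    return AlignmentRecord(name=name, seqname=seqname, pos=pos, strand=strand,
                           bases=bases, quals=quals, cigar=cigar)


@pytest.fixture
def read_factory():
    return make_read


def brute_force_pileup(records, refset, cfg):
    """Independent per-read, per-position recount of the pileup contract:
    raw coverage from all reads; C/T/other only from reads at or below the
    retained-C threshold, with minBQ exclusion and end masking."""
    from polybs.sitecall import read_nonconversion_count

    out = {}
    for rec in records:
        seq = refset.sequences[rec.seqname]
        ref_c = "C" if rec.strand == "+" else "G"
        base_c, base_t = (("C", "T") if rec.strand == "+" else ("G", "A"))
        ok = (not cfg.enable_read_filter
              or read_nonconversion_count(rec, refset)
              <= cfg.max_nonconverted_per_read)
        pairs = list(rec.aligned_pairs())
        for qoff, rpos in pairs:
            if rpos >= len(seq) or seq[rpos] != ref_c:
                continue
            key = (rec.seqname, rpos, rec.strand)
            col = out.setdefault(key, dict(raw=0, cov=0, c=0, t=0, other=0))
            col["raw"] += 1
            if not ok:
                continue
            col["cov"] += 1
            if rec.quals[qoff] < cfg.min_base_quality:
                continue
            if qoff < cfg.end_mask_nt or qoff >= rec.read_length - cfg.end_mask_nt:
                continue
            b = rec.bases[qoff]
            if b == base_c:
                col["c"] += 1
            elif b == base_t:
                col["t"] += 1
            else:
                col["other"] += 1
    return out


@pytest.fixture
def pileup_oracle():
    return brute_force_pileup
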
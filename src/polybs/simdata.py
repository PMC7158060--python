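"""Synthetic bisulfite RNA-seq generator with planted methylation truth.

Emulates the post-alignment state of a stranded bisulfite RNA-seq
experiment: each emitted read carries the *original unconverted* bases, so
at a transcript-strand cytosine the read shows C (plus strand) / G (minus
strand) when conversion did not occur and T / A when it did. The generator
plants:

* methylated sites on mRNA with fraction-dependent stoichiometry across a
  4-fraction x 3-replicate polysome design, with mild Beta-distributed
  replicate jitter;
* 1-4 clustered high-stoichiometry sites inside the mature region of each
  tRNA-like gene, flanked by 100-nt precursor sequence;
* structure-correlated non-conversion clusters on rRNA-like genes, in which
  several adjacent cytosines co-retain C within the same read;
* fully unmethylated spike-ins, plus a small per-cytosine conversion
  failure everywhere and an optional read-end cytosine bias.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .models import (
    AlignmentRecord,
    ReferenceSet,
    TranscriptModel,
    TruthEntry,
    TruthTable,
    revcomp,
)

_NT = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study-condition knobs for the synthetic experiment.

    Defaults mirror the experimental regime the pipeline targets: ~0.2%
    bisulfite conversion failure, 4 polysome fractions x 3 biological
    replicates, 101-nt reads, and a mix of methylation-vs-translation
    trends dominated by the negative direction.
    """

    n_mrna_genes: int = 20
    n_trna_genes: int = 2
    n_rrna_genes: int = 1
    n_spikeins: int = 2
    gene_length_range: tuple[int, int] = (600, 1200)
    utr_cds_proportions: tuple[float, float, float] = (0.2, 0.5, 0.3)
    conversion_failure_rate: float = 0.002
    planted_site_count: int = 30
    stoich_range: tuple[float, float] = (0.2, 0.6)
    # proportions of planted mRNA sites with negative / neutral / positive
    # methylation trend across fractions (observed mix in polysome data)
    trend_mix: tuple[float, float, float] = (0.6, 0.2, 0.2)
    trend_step: tuple[float, float] = (0.05, 0.09)  # per-fraction-step delta
    structure_cluster_spec: tuple[int, int, float] = (2, 24, 0.35)
    read_length: int = 101
    coverage_mean: float = 50.0
    coverage_by_fraction: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0)
    base_quality_model: tuple[int, int, float] = (37, 20, 0.02)
    end_bias_rate: float = 0.01  # extra non-conversion within 6 nt of read ends
    end_bias_span: int = 6
    replicate_concentration: float = 200.0
    trna_sites_range: tuple[int, int] = (1, 4)
    trna_stoich_range: tuple[float, float] = (0.7, 0.95)
    intron_length: int = 0  # >0 gives each mRNA gene one intron mid-CDS
    spliced_reads: bool = False  # emit N-op reads across introns
    n_fractions: int = 4
    n_replicates: int = 3
    seed: int = 0

    def validate(self) -> None:
        for p in (self.conversion_failure_rate, self.end_bias_rate,
                  self.structure_cluster_spec[2],
                  self.base_quality_model[2]):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0,1]")
        if abs(sum(self.utr_cds_proportions) - 1.0) > 1e-9:
            raise ValueError("utr_cds_proportions must sum to 1")
        if len(self.coverage_by_fraction) != self.n_fractions:
            raise ValueError("coverage_by_fraction length != n_fractions")


@dataclass
class SampleLog:
    """Generator-internal tallies: the exact ground truth every downstream
    recount must reproduce."""

    fraction_index: int
    replicate_index: int
    n_reads: int = 0
    reads_per_gene: dict = field(default_factory=dict)
    # (seqname, pos) -> [retained-C reads, converted reads] among covering reads
    site_tallies: dict = field(default_factory=dict)
    # realised per-site methylation probability after replicate jitter
    replicate_p: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Reference construction
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_NT[rng.integers(0, 4, size=n)])


def _transcript_c_positions(refset: ReferenceSet, t: TranscriptModel,
                            region: Optional[tuple[int, int]] = None) -> list[int]:
    """Plus-strand genomic positions whose transcript-strand base is C."""
    seq = refset.sequences[t.seqname]
    target = "C" if t.strand == "+" else "G"
    out = []
    for a, b in t.exons:
        for p in range(a, b):
            if seq[p] == target:
                if region is None or region[0] <= p < region[1]:
                    out.append(p)
    return out


def build_reference(config: SimConfig, seed: int) -> tuple[ReferenceSet, TruthTable]:
    """Build a toy reference set plus its planted-methylation truth table.

    Deterministic for a fixed (config, seed). Raises if the configuration
    requests more planted sites than there are usable cytosines.
    """
    config.validate()
    rng = np.random.default_rng([seed, 0xB5])
    sequences: dict[str, str] = {}
    transcripts: list[TranscriptModel] = []
    class_of: dict[str, str] = {}
    mature: dict[str, tuple[int, int]] = {}
    pad = 50

    lo, hi = config.gene_length_range

    def gene_len() -> int:
        return int(rng.integers(lo, hi + 1))

    # --- mRNA genes -------------------------------------------------------
    for i in range(config.n_mrna_genes):
        gid = f"mrna{i:04d}"
        L = gene_len()
        u5, cds, u3 = config.utr_cds_proportions
        n5 = max(1, int(round(L * u5)))
        ncds = max(6, int(round(L * cds)) // 3 * 3)
        L = n5 + ncds + max(1, L - n5 - ncds)
        strand = "+" if rng.random() < 0.5 else "-"
        seq = _random_seq(rng, pad) + _random_seq(rng, L) + _random_seq(rng, pad)
        gstart, gend = pad, pad + L
        if config.intron_length > 0:
            ilen = config.intron_length
            # one intron mid-CDS (genomic middle of the gene)
            mid = gstart + L // 2
            seq = seq[:mid] + _random_seq(rng, ilen) + seq[mid:]
            exons = [(gstart, mid), (mid + ilen, gend + ilen)]
            gend = gend + ilen
        else:
            exons = [(gstart, gend)]
        # CDS in transcript (spliced, 5'->3') coordinates [n5, n5+ncds)
        t = TranscriptModel(
            transcript_id=f"{gid}.t1", gene_id=gid, seqname=gid,
            strand=strand, exons=exons, biotype="mRNA",
        )
        cds_g = sorted((t.spliced_to_genomic(n5),
                        t.spliced_to_genomic(n5 + ncds - 1)))
        t.cds = (cds_g[0], cds_g[1] + 1)
        sequences[gid] = seq
        transcripts.append(t)
        class_of[gid] = "mRNA"

    # --- tRNA genes: 100-nt precursor flanks around the mature region -----
    for i in range(config.n_trna_genes):
        gid = f"trna{i:04d}"
        mlen = int(rng.integers(70, 91))
        strand = "+" if rng.random() < 0.5 else "-"
        seq = _random_seq(rng, 100 + mlen + 100)
        sequences[gid] = seq
        transcripts.append(
            TranscriptModel(
                transcript_id=f"{gid}.t1", gene_id=gid, seqname=gid,
                strand=strand, exons=[(100, 100 + mlen)], biotype="tRNA",
            )
        )
        class_of[gid] = "tRNA"
        mature[gid] = (100, 100 + mlen)

    # --- rRNA genes -------------------------------------------------------
    for i in range(config.n_rrna_genes):
        gid = f"rrna{i:04d}"
        L = gene_len()
        seq = _random_seq(rng, pad) + _random_seq(rng, L) + _random_seq(rng, pad)
        sequences[gid] = seq
        transcripts.append(
            TranscriptModel(
                transcript_id=f"{gid}.t1", gene_id=gid, seqname=gid,
                strand="+", exons=[(pad, pad + L)], biotype="rRNA",
            )
        )
        class_of[gid] = "rRNA"

    # --- spike-ins: devoid of modification by construction ----------------
    for i in range(config.n_spikeins):
        gid = f"spike{i:04d}"
        L = gene_len()
        sequences[gid] = _random_seq(rng, L)
        transcripts.append(
            TranscriptModel(
                transcript_id=f"{gid}.t1", gene_id=gid, seqname=gid,
                strand="+", exons=[(0, L)], biotype="spikein",
            )
        )
        class_of[gid] = "spikein"

    refset = ReferenceSet(sequences=sequences, transcripts=transcripts,
                          class_of=class_of, mature_region_of=mature)

    # --- plant mRNA sites -------------------------------------------------
    entries: list[TruthEntry] = []
    mrna_ts = [t for t in transcripts if class_of[t.gene_id] == "mRNA"]
    pool: list[tuple[TranscriptModel, int]] = []
    for t in mrna_ts:
        for p in _transcript_c_positions(refset, t):
            pool.append((t, p))
    if config.planted_site_count > len(pool):
        raise ValueError(
            f"requested {config.planted_site_count} planted sites but only "
            f"{len(pool)} transcript-strand cytosines are available"
        )
    # at most 3 sites per gene so genuine sites alone cannot trip the
    # more-than-three-retained-C read filter
    order = rng.permutation(len(pool))
    per_gene: dict[str, int] = {}
    chosen: list[tuple[TranscriptModel, int]] = []
    for idx in order:
        if len(chosen) >= config.planted_site_count:
            break
        t, p = pool[idx]
        if per_gene.get(t.gene_id, 0) >= 3:
            continue
        chosen.append((t, p))
        per_gene[t.gene_id] = per_gene.get(t.gene_id, 0) + 1
    if len(chosen) < config.planted_site_count:
        raise ValueError("not enough cytosines under the 3-sites-per-gene cap")

    trend_codes = rng.choice(3, size=len(chosen), p=np.asarray(config.trend_mix))
    for (t, p), code in zip(chosen, trend_codes):
        base = rng.uniform(*config.stoich_range)
        step = rng.uniform(*config.trend_step)
        slope = {0: -step, 1: 0.0, 2: step}[int(code)]
        stoich = tuple(
            float(np.clip(base + slope * (k - (config.n_fractions - 1) / 2),
                          0.01, 0.98))
            for k in range(config.n_fractions)
        )
        entries.append(
            TruthEntry(
                gene_id=t.gene_id, seqname=t.seqname, strand=t.strand,
                pos=int(p), rna_class="mRNA", stoichiometry=stoich,
                jitter_concentration=config.replicate_concentration,
            )
        )

    # --- plant clustered tRNA sites in mature regions ---------------------
    for t in transcripts:
        if class_of[t.gene_id] != "tRNA":
            continue
        cpos = _transcript_c_positions(refset, t, region=mature[t.gene_id])
        if not cpos:
            continue
        k = int(rng.integers(config.trna_sites_range[0],
                             config.trna_sites_range[1] + 1))
        k = min(k, len(cpos))
        anchor = int(rng.integers(0, len(cpos)))
        # clustered: k consecutive cytosines starting at the anchor
        picks = cpos[anchor : anchor + k]
        if len(picks) < k:
            picks = cpos[-k:]
        for p in picks:
            s = float(rng.uniform(*config.trna_stoich_range))
            entries.append(
                TruthEntry(
                    gene_id=t.gene_id, seqname=t.seqname, strand=t.strand,
                    pos=int(p), rna_class="tRNA",
                    stoichiometry=tuple([s] * config.n_fractions),
                    jitter_concentration=config.replicate_concentration,
                )
            )

    return refset, TruthTable(entries)


def structure_clusters(refset: ReferenceSet,
                       config: SimConfig) -> list[tuple[str, str, list[int]]]:
    """Deterministic placement of the structure-correlated non-conversion
    clusters on rRNA-like genes: (seqname, strand, C positions) triples.

    Each cluster is the set of transcript-strand cytosines inside a window
    of ``structure_cluster_spec[1]`` nt chosen to contain >= 5 of them, so a
    co-retaining read exceeds the retained-C read-filter threshold.
    """
    n_clusters, width, _ = config.structure_cluster_spec
    out: list[tuple[str, str, list[int]]] = []
    rrna = [t for t in refset.transcripts
            if refset.class_of[t.gene_id] == "rRNA"]
    for t in rrna:
        if len(out) >= n_clusters:
            break
        cpos = _transcript_c_positions(refset, t)
        a, b = t.span
        step = max(1, (b - a) // max(1, n_clusters + 1))
        for w0 in range(a + step // 2, b - width, step):
            members = [p for p in cpos if w0 <= p < w0 + width]
            if len(members) >= 5:
                out.append((t.seqname, t.strand, members[:8]))
                if len(out) >= n_clusters:
                    break
    return out


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _blocks_for_read(exons: list[tuple[int, int]], s: int,
                     rl: int) -> list[tuple[int, int]]:
    """Genomic (start, length) blocks of a read covering the exonic-axis
    interval [s, s+rl), where the axis concatenates exons left-to-right."""
    blocks = []
    off = 0
    need = rl
    for a, b in exons:
        elen = b - a
        if s >= off + elen:
            off += elen
            continue
        start_in = max(s - off, 0)
        take = min(elen - start_in, need)
        blocks.append((a + start_in, take))
        need -= take
        off += elen
        if need == 0:
            break
    return blocks


def simulate_sample(
    refset: ReferenceSet,
    truth: TruthTable,
    fraction_index: int,
    replicate_index: int,
    config: SimConfig,
    seed: int,
) -> tuple[list[AlignmentRecord], SampleLog]:
    """Simulate one (fraction, replicate) library as aligned unconverted
    reads. Deterministic for fixed arguments."""
    config.validate()
    if not 0 <= fraction_index < config.n_fractions:
        raise ValueError(f"fraction index {fraction_index} out of range")
    if not 0 <= replicate_index < config.n_replicates:
        raise ValueError(f"replicate index {replicate_index} out of range")
    rng = np.random.default_rng([seed, 0x5EAD, fraction_index, replicate_index])
    log = SampleLog(fraction_index, replicate_index)

    # realised per-replicate methylation level: Beta around the fraction
    # stoichiometry (concordance regime of replicated bisulfite libraries)
    for e in truth:
        s = e.stoichiometry[fraction_index]
        if 0.0 < s < 1.0 and e.jitter_concentration > 0:
            a = s * e.jitter_concentration
            b = (1.0 - s) * e.jitter_concentration
            p = float(rng.beta(a, b))
        else:
            p = s
        log.replicate_p[(e.seqname, e.pos)] = p
        log.site_tallies[(e.seqname, e.pos)] = [0, 0]

    clusters = structure_clusters(refset, config)
    cluster_by_seq: dict[str, list[list[int]]] = {}
    for seqname, _, members in clusters:
        cluster_by_seq.setdefault(seqname, []).append(members)
    cluster_p = config.structure_cluster_spec[2]

    q_hi, q_lo, p_lo = config.base_quality_model
    fail = config.conversion_failure_rate
    records: list[AlignmentRecord] = []
    genes = sorted({t.gene_id for t in refset.transcripts})
    cov = config.coverage_mean * config.coverage_by_fraction[fraction_index]

    for gid in genes:
        t = refset.transcripts_of_gene(gid)[0]
        cls = refset.class_of[gid]
        seq = refset.sequences[t.seqname]
        if cls == "tRNA":
            # precursor transcription: reads over the full flanked contig
            exons = [(0, len(seq))]
        else:
            exons = t.exons
        axis_len = sum(b - a for a, b in exons)
        rl = min(config.read_length, axis_len)
        n_reads = int(rng.poisson(cov * axis_len / rl))
        log.reads_per_gene[gid] = n_reads
        target = "C" if t.strand == "+" else "G"
        site_pos = {e.pos: e for e in truth if e.seqname == t.seqname}
        gclusters = cluster_by_seq.get(t.seqname, [])

        starts = rng.integers(0, axis_len - rl + 1, size=n_reads)
        for ridx in range(n_reads):
            s = int(starts[ridx])
            blocks = _blocks_for_read(exons, s, rl)
            if len(blocks) > 1 and not config.spliced_reads:
                # unspliced mode: truncate the read at the exon boundary
                blocks = blocks[:1]
            # per-read cluster co-retention decision
            co_retain: set[int] = set()
            for members in gclusters:
                covered = [p for p in members
                           if any(a <= p < a + n for a, n in blocks)]
                if covered and rng.random() < cluster_p:
                    co_retain.update(covered)
            bases: list[str] = []
            qoff = 0
            read_len = sum(n for _, n in blocks)
            for gstart, n in blocks:
                for k in range(n):
                    p = gstart + k
                    ref = seq[p]
                    if ref != target:
                        bases.append(ref)
                        qoff += 1
                        continue
                    near_end = (qoff < config.end_bias_span
                                or qoff >= read_len - config.end_bias_span)
                    if p in site_pos:
                        pm = log.replicate_p[(t.seqname, p)]
                        retained = (rng.random() < pm
                                    or rng.random() < fail)
                        tal = log.site_tallies[(t.seqname, p)]
                        tal[0 if retained else 1] += 1
                    elif p in co_retain:
                        retained = True
                    else:
                        retained = rng.random() < fail
                        if not retained and near_end and config.end_bias_rate:
                            retained = rng.random() < config.end_bias_rate
                    if t.strand == "+":
                        bases.append("C" if retained else "T")
                    else:
                        bases.append("G" if retained else "A")
                    qoff += 1
            quals = np.where(rng.random(read_len) < p_lo, q_lo, q_hi)
            cigar: list[tuple[str, int]] = []
            prev_end = None
            for gstart, n in blocks:
                if prev_end is not None and gstart > prev_end:
                    cigar.append(("N", gstart - prev_end))
                cigar.append(("M", n))
                prev_end = gstart + n
            records.append(
                AlignmentRecord(
                    name=f"{gid}:f{fraction_index}r{replicate_index}:{ridx}",
                    seqname=t.seqname,
                    pos=blocks[0][0],
                    strand=t.strand,
                    bases="".join(bases),
                    quals=[int(q) for q in quals],
                    cigar=cigar,
                )
            )
        log.n_reads += n_reads
    return records, log


def simulate_experiment(
    refset: ReferenceSet,
    truth: TruthTable,
    config: SimConfig,
    seed: int,
) -> dict[tuple[int, int], tuple[list[AlignmentRecord], SampleLog]]:
    """All n_fractions x n_replicates samples, keyed by (fraction, replicate)."""
    return {
        (f, r): simulate_sample(refset, truth, f, r, config, seed)
        for f in range(config.n_fractions)
        for r in range(config.n_replicates)
    }
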
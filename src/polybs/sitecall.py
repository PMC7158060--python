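"""Candidate m5C site calling from bisulfite alignments.

The cascade, in order:

1. read filter — drop reads retaining more than ``max_nonconverted_per_read``
   cytosines (structure-driven conversion failure removes whole reads);
2. quality-aware pileup at transcript-strand cytosines, with base calls
   below ``min_base_quality`` excluded and retained Cs within
   ``end_mask_nt`` of either read end masked;
3. per-position signal-to-noise flag: fraction of covering reads surviving
   the read filter must stay at or above ``signal_to_noise_min``;
4. per-replicate thresholds: coverage, retained-C depth, C+T purity;
5. replicate merging with an average non-conversion floor.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .models import AlignmentRecord, ReferenceSet, TruthTable

log = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    max_nonconverted_per_read: int = 3
    signal_to_noise_min: float = 0.9
    min_base_quality: int = 30
    end_mask_nt: int = 6
    min_coverage: int = 30
    min_c_count: int = 5
    min_ct_fraction: float = 0.8
    min_avg_nonconversion: float = 0.10
    require_all_replicates: bool = True
    # boundary behaviour of the signal-to-noise rule: flag strictly below
    # the threshold by default; inclusive flags the boundary value as well
    sn_boundary_inclusive: bool = False
    # masked read-end calls count to coverage only (no C or T evidence);
    # alternatively score masked calls as converted (added to the T tally)
    mask_as_converted: bool = False
    enable_read_filter: bool = True
    enable_sn_filter: bool = True

    def __post_init__(self) -> None:
        if self.max_nonconverted_per_read < 0 or self.min_coverage < 0:
            raise ValueError("counts must be >= 0")
        for f in (self.signal_to_noise_min, self.min_ct_fraction,
                  self.min_avg_nonconversion):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction {f} outside [0,1]")


@dataclass
class PileupColumn:
    seqname: str
    pos: int
    strand: str
    raw_coverage: int = 0
    filtered_coverage: int = 0
    c_count: int = 0
    t_count: int = 0
    other_count: int = 0
    raw_c: int = 0  # pre-read-filter, unmasked retained-C tally
    raw_t: int = 0

    @property
    def signal_to_noise(self) -> float:
        if self.raw_coverage == 0:
            return 1.0
        return self.filtered_coverage / self.raw_coverage

    def sn_flag(self, cfg: FilterConfig) -> bool:
        if not cfg.enable_sn_filter:
            return False
        sn = self.signal_to_noise
        if cfg.sn_boundary_inclusive:
            return sn <= cfg.signal_to_noise_min
        return sn < cfg.signal_to_noise_min

    @property
    def nonconversion(self) -> float:
        ct = self.c_count + self.t_count
        return self.c_count / ct if ct else 0.0


@dataclass
class SiteCall:
    """A per-replicate call fragment at one locus."""

    seqname: str
    pos: int
    strand: str
    c_count: int
    t_count: int
    coverage: int

    @property
    def nonconversion(self) -> float:
        ct = self.c_count + self.t_count
        return self.c_count / ct if ct else 0.0


@dataclass
class CandidateSite:
    """A replicate-merged candidate site."""

    seqname: str
    pos: int
    strand: str
    per_replicate: list[SiteCall]
    rna_class: str = "other"

    @property
    def avg_nonconversion(self) -> float:
        vals = [r.nonconversion for r in self.per_replicate]
        return float(np.mean(vals)) if vals else 0.0

    @property
    def locus(self) -> tuple[str, int, str]:
        return (self.seqname, self.pos, self.strand)


# ---------------------------------------------------------------------------
# Per-read operations
# ---------------------------------------------------------------------------

def read_nonconversion_count(record: AlignmentRecord,
                             refset: ReferenceSet) -> int:
    """Number of aligned positions where the transcript-strand reference
    base is C and the read retains it, counted over the whole read
    (end-masked positions included; base quality ignored)."""
    seq = refset.sequences[record.seqname]
    if record.strand == "+":
        ref_c, read_c = "C", "C"
    else:
        ref_c, read_c = "G", "G"
    n = 0
    for qoff, rpos in record.aligned_pairs():
        if rpos >= len(seq):
            continue
        if seq[rpos] == ref_c and record.bases[qoff] == read_c:
            n += 1
    return n


def apply_read_filter(
    records: Iterable[AlignmentRecord],
    refset: ReferenceSet,
    cfg: FilterConfig,
) -> tuple[list[AlignmentRecord], list[AlignmentRecord], dict]:
    """Partition reads by the retained-C count threshold."""
    passing, failing = [], []
    for rec in records:
        if (not cfg.enable_read_filter
                or read_nonconversion_count(rec, refset)
                <= cfg.max_nonconverted_per_read):
            passing.append(rec)
        else:
            failing.append(rec)
    stats = {"pass": len(passing), "fail": len(failing),
             "total": len(passing) + len(failing)}
    return passing, failing, stats


# ---------------------------------------------------------------------------
# Pileup
# ---------------------------------------------------------------------------

def build_pileup(
    records: Sequence[AlignmentRecord],
    refset: ReferenceSet,
    cfg: FilterConfig,
    region_of: Optional[dict[str, tuple[int, int]]] = None,
) -> dict[tuple[str, int, str], PileupColumn]:
    """Quality-aware pileup at transcript-strand cytosine positions.

    Raw coverage is tallied from all reads; C/T/other tallies only from
    reads surviving the retained-C filter, after base-quality exclusion and
    end masking. ``raw_c``/``raw_t`` keep the unfiltered, unmasked tallies
    used for bulk conversion summaries. ``region_of`` optionally restricts
    emitted columns per sequence.
    """
    columns: dict[tuple[str, int, str], PileupColumn] = {}
    mismatch = total = 0
    for rec in records:
        seq = refset.sequences[rec.seqname]
        if rec.strand == "+":
            ref_c, base_c, base_t = "C", "C", "T"
        else:
            ref_c, base_c, base_t = "G", "G", "A"
        passes = (not cfg.enable_read_filter
                  or read_nonconversion_count(rec, refset)
                  <= cfg.max_nonconverted_per_read)
        rl = rec.read_length
        for qoff, rpos in rec.aligned_pairs():
            if rpos >= len(seq):
                continue
            if seq[rpos] != ref_c:
                total += 1
                b = rec.bases[qoff]
                if b != seq[rpos] and not (
                    (seq[rpos], b) in {("C", "T"), ("G", "A")}
                ):
                    mismatch += 1
                continue
            if region_of is not None:
                lo, hi = region_of.get(rec.seqname, (0, len(seq)))
                if not lo <= rpos < hi:
                    continue
            key = (rec.seqname, rpos, rec.strand)
            col = columns.get(key)
            if col is None:
                col = columns[key] = PileupColumn(rec.seqname, rpos, rec.strand)
            col.raw_coverage += 1
            b = rec.bases[qoff]
            if b == base_c:
                col.raw_c += 1
            elif b == base_t:
                col.raw_t += 1
            if not passes:
                continue
            col.filtered_coverage += 1
            if rec.quals[qoff] < cfg.min_base_quality:
                continue
            masked = (qoff < cfg.end_mask_nt or qoff >= rl - cfg.end_mask_nt)
            if masked:
                # coverage evidence only: dropping both C and T calls at
                # read ends keeps the non-conversion estimator unbiased;
                # mask_as_converted scores the masked call as converted
                if cfg.mask_as_converted and b in (base_c, base_t):
                    col.t_count += 1
                continue
            if b == base_c:
                col.c_count += 1
            elif b == base_t:
                col.t_count += 1
            else:
                col.other_count += 1
    if total and mismatch / total > 0.05:
        log.warning("reference mismatch rate %.1f%% exceeds sanity bound",
                    100 * mismatch / total)
    return columns


# ---------------------------------------------------------------------------
# Site calling
# ---------------------------------------------------------------------------

def call_replicate_sites(
    columns: dict[tuple[str, int, str], PileupColumn],
    cfg: FilterConfig,
) -> dict[tuple[str, int, str], SiteCall]:
    """Apply the per-replicate coverage / retained-C depth / C+T purity
    thresholds and the signal-to-noise flag to one composite replicate."""
    out: dict[tuple[str, int, str], SiteCall] = {}
    for key, col in columns.items():
        if col.sn_flag(cfg):
            continue
        if col.filtered_coverage < cfg.min_coverage:
            continue
        if col.c_count < cfg.min_c_count:
            continue
        # purity over scored base calls: mask- and quality-dropped calls
        # carry no base identity and do not count against C+T purity
        scored = col.c_count + col.t_count + col.other_count
        if (col.c_count + col.t_count) < cfg.min_ct_fraction * scored:
            continue
        out[key] = SiteCall(col.seqname, col.pos, col.strand,
                            col.c_count, col.t_count, col.filtered_coverage)
    return out


def combine_replicates(
    replicate_calls: Sequence[dict[tuple[str, int, str], SiteCall]],
    cfg: FilterConfig,
    class_of_seq: Optional[dict[str, str]] = None,
) -> list[CandidateSite]:
    """Merge per-replicate calls into candidate sites.

    A site is a candidate iff it passed the per-replicate filters in every
    replicate (when ``require_all_replicates``) and its mean per-replicate
    non-conversion reaches ``min_avg_nonconversion``.
    """
    if len(replicate_calls) < 2:
        raise ValueError("need at least two replicates")
    keys: set[tuple[str, int, str]] = set()
    for calls in replicate_calls:
        keys.update(calls)
    out: list[CandidateSite] = []
    for key in sorted(keys):
        fragments = [calls[key] for calls in replicate_calls if key in calls]
        if cfg.require_all_replicates and len(fragments) < len(replicate_calls):
            continue
        site = CandidateSite(
            seqname=key[0], pos=key[1], strand=key[2],
            per_replicate=fragments,
            rna_class=(class_of_seq or {}).get(key[0], "other"),
        )
        if site.avg_nonconversion >= cfg.min_avg_nonconversion:
            out.append(site)
    return out


def summarize_conversion(
    columns: dict[tuple[str, int, str], PileupColumn],
    class_of_seq: dict[str, str],
) -> dict[str, dict[str, float]]:
    """Per-RNA-class cytosine conversion, pre- and post-read-filter.

    Conversion = sum(T) / sum(C+T) over all reference-C positions; the
    pre-filter variant uses the unfiltered, unmasked tallies.
    """
    agg: dict[str, np.ndarray] = {}
    for col in columns.values():
        cls = class_of_seq.get(col.seqname, "other")
        a = agg.setdefault(cls, np.zeros(4))
        a += (col.raw_c, col.raw_t, col.c_count, col.t_count)
    out = {}
    for cls, (rc, rt, fc, ft) in agg.items():
        out[cls] = {
            "conversion": rt / (rc + rt) if rc + rt else float("nan"),
            "conversion_post_filter": ft / (fc + ft) if fc + ft else float("nan"),
        }
    return out


def call_trna_sites(
    records: Sequence[AlignmentRecord],
    refset: ReferenceSet,
    cfg: FilterConfig,
    replicate_records: Optional[Sequence[Sequence[AlignmentRecord]]] = None,
) -> list[CandidateSite]:
    """tRNA-restricted calling: only 'processed' reads — reads wholly
    contained in a gene's predicted mature region — enter the cascade.

    Pass either one composite replicate via ``records`` plus further
    replicates via ``replicate_records``, or a single list (replicates
    then collapse to that one list, for exploratory use).
    """
    trna_genes = [g for g, c in refset.class_of.items() if c == "tRNA"]
    for g in trna_genes:
        if g not in refset.mature_region_of:
            raise ValueError(f"tRNA gene {g} lacks a mature region")
    region_of = {g: refset.mature_region_of[g] for g in trna_genes}

    def processed(recs: Sequence[AlignmentRecord]) -> list[AlignmentRecord]:
        keep = []
        for r in recs:
            reg = region_of.get(r.seqname)
            if reg is None:
                continue
            if r.pos >= reg[0] and r.end <= reg[1]:
                keep.append(r)
        return keep

    groups = ([records] if replicate_records is None
              else [records, *replicate_records])
    rep_calls = []
    for recs in groups:
        cols = build_pileup(processed(recs), refset, cfg, region_of=region_of)
        rep_calls.append(call_replicate_sites(cols, cfg))
    if len(rep_calls) == 1:
        rep_calls = rep_calls * 2  # degenerate single-replicate use
    return combine_replicates(rep_calls, cfg,
                              class_of_seq=refset.class_of)


def call_candidates(
    replicate_records: Sequence[Sequence[AlignmentRecord]],
    refset: ReferenceSet,
    cfg: FilterConfig,
) -> list[CandidateSite]:
    """Full transcriptome-wide cascade over composite replicates."""
    rep_calls = []
    for recs in replicate_records:
        cols = build_pileup(recs, refset, cfg)
        rep_calls.append(call_replicate_sites(cols, cfg))
    return combine_replicates(rep_calls, cfg, class_of_seq=refset.class_of)


def sample_counts(
    records: Sequence[AlignmentRecord],
    refset: ReferenceSet,
    cfg: FilterConfig,
    loci: Sequence[tuple[str, int, str]],
) -> dict[tuple[str, int, str], tuple[int, int, int]]:
    """Per-sample (c, t, coverage) tallies at given loci, for the
    fraction-wise methylation matrix."""
    columns = build_pileup(records, refset, cfg)
    out = {}
    for key in loci:
        col = columns.get(tuple(key))
        if col is not None and col.filtered_coverage > 0:
            out[tuple(key)] = (col.c_count, col.t_count, col.filtered_coverage)
    return out


def calibration_coverage(
    candidates: Sequence[CandidateSite],
    truth: TruthTable,
    replicate_p: Sequence[dict[tuple[str, int], float]],
    replicate_n: Sequence[dict[tuple[str, int], int]],
    failure_rate: float,
    alpha: float = 0.05,
    classes: Optional[set[str]] = None,
) -> float:
    """Coverage-weighted fraction of recovered truth sites whose realised
    per-replicate methylation level lies inside the exact (Clopper-Pearson)
    binomial CI of the estimate.

    ``replicate_p`` holds the realised methylation probability per site and
    replicate; ``replicate_n`` the per-replicate read depth at the site
    (weights for the composite expectation). The expected non-conversion
    adds the conversion-failure leak: p_eff = p + (1-p) * failure_rate.
    """
    from scipy.stats import binomtest

    hits = []
    bylocus = {(c.seqname, c.pos): c for c in candidates}
    for e in truth:
        if classes is not None and e.rna_class not in classes:
            continue
        cand = bylocus.get((e.seqname, e.pos))
        if cand is None:
            continue
        num = den = 0.0
        for rp, rn in zip(replicate_p, replicate_n):
            p = rp.get((e.seqname, e.pos))
            n = rn.get((e.seqname, e.pos), 0)
            if p is None or n == 0:
                continue
            num += n * (p + (1.0 - p) * failure_rate)
            den += n
        if den == 0:
            continue
        p_truth = num / den
        x = sum(r.c_count for r in cand.per_replicate)
        n = sum(r.c_count + r.t_count for r in cand.per_replicate)
        if n == 0:
            continue
        ci = binomtest(x, n, p_truth).proportion_ci(1 - alpha, method="exact")
        hits.append((float(ci.low <= p_truth <= ci.high), n))
    if not hits:
        return float("nan")
    w = sum(n for _, n in hits)
    return sum(h * n for h, n in hits) / w


def recovery(candidates: Sequence[CandidateSite], truth: TruthTable,
             classes: Optional[set[str]] = None) -> float:
    """Fraction of truth sites present among the candidates."""
    called = {(c.seqname, c.pos) for c in candidates}
    relevant = [e for e in truth
                if classes is None or e.rna_class in classes]
    if not relevant:
        return float("nan")
    hits = sum((e.seqname, e.pos) in called for e in relevant)
    return hits / len(relevant)
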
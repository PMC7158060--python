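"""Annotation of candidate sites to transcript features, plus the
distribution, motif, codon and structure analyses built on it.

Feature labels partition every site into exactly one of: 5UTR, CDS, 3UTR,
intronic, ncRNA_exonic, ncRNA_intronic, intergenic. Sites are assigned to
the longest (spliced length) same-strand transcript of the overlapping
gene, ties broken lexicographically by transcript id.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import Table2x2
from statsmodels.stats.multitest import multipletests

from .fold import fold_window
from .models import ReferenceSet, TranscriptModel, revcomp
from .sitecall import CandidateSite

log = logging.getLogger(__name__)

FEATURES = ("5UTR", "CDS", "3UTR", "intronic", "ncRNA_exonic",
            "ncRNA_intronic", "intergenic")


@dataclass
class SiteAnnotation:
    seqname: str
    pos: int
    strand: str
    transcript_id: Optional[str]
    feature: str
    spliced_offset: Optional[int] = None
    codon_index: Optional[int] = None  # 1-based
    codon_position: Optional[int] = None  # 1, 2 or 3
    codon: Optional[str] = None


@dataclass
class EnrichmentBin:
    label: str
    start: int
    end: int
    observed: int
    null: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    q: float = float("nan")
    corrected: bool = False  # Haldane-Anscombe applied


def _site_key(site) -> tuple[str, int, str]:
    if isinstance(site, CandidateSite):
        return site.locus
    return tuple(site)  # (seqname, pos, strand)


def pick_transcript(refset: ReferenceSet, seqname: str, pos: int,
                    strand: str) -> Optional[TranscriptModel]:
    cands = [
        t for t in refset.transcripts
        if t.seqname == seqname and t.strand == strand
        and t.span[0] <= pos < t.span[1]
    ]
    if not cands:
        return None
    cands.sort(key=lambda t: (-t.spliced_length, t.transcript_id))
    return cands[0]


def annotate_site(site, refset: ReferenceSet) -> SiteAnnotation:
    seqname, pos, strand = _site_key(site)
    t = pick_transcript(refset, seqname, pos, strand)
    if t is None:
        return SiteAnnotation(seqname, pos, strand, None, "intergenic")
    coding = t.cds is not None
    off = t.genomic_to_spliced(pos)
    if off is None:
        feature = "intronic" if coding else "ncRNA_intronic"
        return SiteAnnotation(seqname, pos, strand, t.transcript_id, feature)
    if not coding:
        return SiteAnnotation(seqname, pos, strand, t.transcript_id,
                              "ncRNA_exonic", spliced_offset=off)
    cs, ce = t.cds_spliced_interval()
    if off < cs:
        feature = "5UTR"
    elif off < ce:
        feature = "CDS"
    else:
        feature = "3UTR"
    ann = SiteAnnotation(seqname, pos, strand, t.transcript_id, feature,
                         spliced_offset=off)
    if feature == "CDS":
        rel = off - cs
        ann.codon_index = rel // 3 + 1
        ann.codon_position = rel % 3 + 1
        tx = t.spliced_sequence(refset.sequences)
        ann.codon = tx[cs + (rel // 3) * 3 : cs + (rel // 3) * 3 + 3]
    return ann


def annotate_sites(sites: Sequence, refset: ReferenceSet) -> list[SiteAnnotation]:
    return [annotate_site(s, refset) for s in sites]


# ---------------------------------------------------------------------------
# Metagene profile
# ---------------------------------------------------------------------------

def _region_bounds(t: TranscriptModel) -> dict[str, tuple[int, int]]:
    cs, ce = t.cds_spliced_interval()
    return {"5UTR": (0, cs), "CDS": (cs, ce), "3UTR": (ce, t.spliced_length)}


def _transcript_c_offsets(refset: ReferenceSet, t: TranscriptModel) -> np.ndarray:
    tx = t.spliced_sequence(refset.sequences)
    return np.frombuffer(tx.encode(), dtype=np.uint8) == ord("C")


def metagene_profile(
    sites: Sequence,
    refset: ReferenceSet,
    n_bins: int = 90,
    scaling: str = "median",
):
    """Scaled metagene density of mRNA-exonic sites over a composite
    5UTR/CDS/3UTR axis, with the all-cytosine background of the same
    transcripts. Segment widths are proportional to the median (default)
    or mean region length among represented transcripts.

    Returns (bin_centres, site_density, background_density, widths); both
    densities sum to 1.
    """
    anns = annotate_sites(sites, refset)
    used = [a for a in anns if a.feature in ("5UTR", "CDS", "3UTR")]
    skipped = len(anns) - len(used)
    if skipped:
        log.info("metagene: skipped %d sites without mRNA exonic annotation",
                 skipped)
    if not used:
        raise ValueError("no exonic mRNA sites")
    tids = sorted({a.transcript_id for a in used})
    tmap = {t.transcript_id: t for t in refset.transcripts}
    reg_lengths = {r: [] for r in ("5UTR", "CDS", "3UTR")}
    for tid in tids:
        for r, (a, b) in _region_bounds(tmap[tid]).items():
            reg_lengths[r].append(b - a)
    agg = np.median if scaling == "median" else np.mean
    med = {r: float(agg(v)) if v else 0.0 for r, v in reg_lengths.items()}
    total = sum(med.values())
    widths = {r: med[r] / total for r in med}
    offsets = {"5UTR": 0.0, "CDS": widths["5UTR"],
               "3UTR": widths["5UTR"] + widths["CDS"]}

    def place(t: TranscriptModel, off: int) -> Optional[float]:
        for r, (a, b) in _region_bounds(t).items():
            if a <= off < b and b > a:
                return offsets[r] + (off - a) / (b - a) * widths[r]
        return None

    xs = [place(tmap[a.transcript_id], a.spliced_offset) for a in used]
    xs = np.array([x for x in xs if x is not None])
    bg = []
    for tid in tids:
        t = tmap[tid]
        mask = _transcript_c_offsets(refset, t)
        for off in np.nonzero(mask)[0]:
            x = place(t, int(off))
            if x is not None:
                bg.append(x)
    bg = np.asarray(bg)
    edges = np.linspace(0, 1, n_bins + 1)
    site_d, _ = np.histogram(xs, bins=edges)
    bg_d, _ = np.histogram(bg, bins=edges)
    site_density = site_d / site_d.sum()
    bg_density = bg_d / bg_d.sum() if bg_d.sum() else bg_d.astype(float)
    centres = (edges[:-1] + edges[1:]) / 2
    return centres, site_density, bg_density, widths


# ---------------------------------------------------------------------------
# Binned enrichment
# ---------------------------------------------------------------------------

_ANCHORS = ("region", "start_codon", "stop_codon",
            "transcript_start", "transcript_end")


def _anchor_offset(t: TranscriptModel, anchor: str) -> int:
    if anchor == "transcript_start":
        return 0
    if anchor == "transcript_end":
        return t.spliced_length
    cs, ce = t.cds_spliced_interval()
    return cs if anchor == "start_codon" else ce - 3


def _fisher_bin(obs_in: int, obs_out: int, null_in: int, null_out: int):
    table = np.array([[obs_in, obs_out], [null_in, null_out]], dtype=float)
    corrected = bool((table == 0).any())
    _, p = stats.fisher_exact(table)
    if corrected:
        table = table + 0.5
    t22 = Table2x2(table)
    orr = t22.oddsratio
    lo, hi = t22.oddsratio_confint(0.05)
    return orr, lo, hi, p, corrected


def binned_enrichment(
    sites: Sequence,
    refset: ReferenceSet,
    anchor: str = "start_codon",
    window: tuple[int, int] = (-400, 1000),
    bin_width: int = 100,
    n_null: int = 100,
    seed: int = 0,
) -> list[EnrichmentBin]:
    """Spatial enrichment of sites relative to an anchor, against a null of
    matched-count uniform sampling from unmodified cytosines of the same
    transcript set (``n_null`` resamples aggregated).

    Per bin, a 2x2 (in-bin vs out-of-bin x observed vs null) Fisher test
    gives the odds ratio with 95% CI; q-values are BH across bins.
    """
    if anchor not in _ANCHORS:
        raise ValueError(f"anchor must be one of {_ANCHORS}")
    if anchor != "region" and (window[1] - window[0]) % bin_width:
        raise ValueError("window not divisible by bin_width")
    rng = np.random.default_rng(seed)
    anns = annotate_sites(sites, refset)
    used = [a for a in anns if a.feature in ("5UTR", "CDS", "3UTR")]
    if not used:
        raise ValueError("no exonic mRNA sites")
    tmap = {t.transcript_id: t for t in refset.transcripts}
    tids = sorted({a.transcript_id for a in used})
    site_keys = {(a.seqname, a.pos) for a in used}

    # pool of unmodified C offsets per transcript (for the null)
    pool: list[tuple[str, int]] = []
    for tid in tids:
        t = tmap[tid]
        mask = _transcript_c_offsets(refset, t)
        for off in np.nonzero(mask)[0]:
            g = t.spliced_to_genomic(int(off))
            if (t.seqname, g) not in site_keys:
                pool.append((tid, int(off)))

    if anchor == "region":
        labels = ["5UTR", "CDS", "3UTR"]

        def bin_of_site(a: SiteAnnotation) -> Optional[str]:
            return a.feature

        def bin_of_null(tid: str, off: int) -> Optional[str]:
            for r, (lo, hi) in _region_bounds(tmap[tid]).items():
                if lo <= off < hi:
                    return r
            return None

        obs = {r: 0 for r in labels}
        for a in used:
            obs[a.feature] += 1
        null = {r: 0 for r in labels}
        for _ in range(n_null):
            idx = rng.integers(0, len(pool), size=len(used))
            for i in idx:
                r = bin_of_null(*pool[i])
                if r is not None:
                    null[r] += 1
        n_obs = len(used)
        n_null_total = sum(null.values())
        bins = []
        for r in labels:
            orr, lo_, hi_, p, corr = _fisher_bin(
                obs[r], n_obs - obs[r], null[r], n_null_total - null[r])
            bins.append(EnrichmentBin(r, 0, 0, obs[r], null[r],
                                      orr, lo_, hi_, p, corrected=corr))
    else:
        edges = list(range(window[0], window[1] + 1, bin_width))

        def rel_of(tid: str, off: int) -> int:
            return off - _anchor_offset(tmap[tid], anchor)

        obs_rel = [rel_of(a.transcript_id, a.spliced_offset) for a in used]
        null_rel: list[int] = []
        for _ in range(n_null):
            idx = rng.integers(0, len(pool), size=len(used))
            null_rel.extend(rel_of(*pool[i]) for i in idx)
        obs_hist, _ = np.histogram(obs_rel, bins=edges)
        null_hist, _ = np.histogram(null_rel, bins=edges)
        n_obs, n_nul = len(obs_rel), len(null_rel)
        bins = []
        for k in range(len(edges) - 1):
            o, u = int(obs_hist[k]), int(null_hist[k])
            orr, lo_, hi_, p, corr = _fisher_bin(o, n_obs - o, u, n_nul - u)
            bins.append(EnrichmentBin(
                f"[{edges[k]},{edges[k + 1]})", edges[k], edges[k + 1],
                o, u, orr, lo_, hi_, p, corrected=corr))
    qs = multipletests([b.p for b in bins], method="fdr_bh")[1]
    for b, q in zip(bins, qs):
        b.q = float(q)
    return bins


# ---------------------------------------------------------------------------
# Sequence context
# ---------------------------------------------------------------------------

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}


def _window_seq(refset: ReferenceSet, seqname: str, pos: int, strand: str,
                flank: int) -> Optional[str]:
    seq = refset.sequences[seqname]
    if pos - flank < 0 or pos + flank + 1 > len(seq):
        return None
    w = seq[pos - flank : pos + flank + 1]
    return revcomp(w) if strand == "-" else w


def context_matrix(
    sites: Sequence,
    refset: ReferenceSet,
    flank: int = 10,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Position frequency matrices (rows A/C/G/U, columns -flank..+flank) of
    transcript-strand sequence around sites, and of all cytosines of the
    site-bearing genes as background. Returns (pfm, background, n_used)."""
    keys = [_site_key(s) for s in sites]
    pfm = np.zeros((4, 2 * flank + 1), dtype=float)
    used = 0
    genes: set[str] = set()
    for seqname, pos, strand in keys:
        w = _window_seq(refset, seqname, pos, strand, flank)
        if w is None:
            continue
        used += 1
        genes.update(t.gene_id for t in refset.transcripts
                     if t.seqname == seqname)
        for i, ch in enumerate(w.upper()):
            if ch in _BASE_IDX:
                pfm[_BASE_IDX[ch], i] += 1
    if used < len(keys):
        log.info("context: dropped %d sites within %d nt of sequence ends",
                 len(keys) - used, flank)
    bg = np.zeros_like(pfm)
    for t in refset.transcripts:
        if t.gene_id not in genes:
            continue
        seq = refset.sequences[t.seqname]
        target = "C" if t.strand == "+" else "G"
        for a, b in t.exons:
            for p in range(a, b):
                if seq[p] != target:
                    continue
                w = _window_seq(refset, t.seqname, p, t.strand, flank)
                if w is None:
                    continue
                for i, ch in enumerate(w.upper()):
                    if ch in _BASE_IDX:
                        bg[_BASE_IDX[ch], i] += 1
    return pfm, bg, used


def information_content(pfm: np.ndarray) -> np.ndarray:
    """Per-column information content (bits) of a position frequency matrix."""
    probs = pfm / np.maximum(pfm.sum(axis=0), 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.nansum(np.where(probs > 0, probs * np.log2(probs), 0.0), axis=0)
    return 2.0 - h


# ---------------------------------------------------------------------------
# Codon-position enrichment
# ---------------------------------------------------------------------------

def codon_position_enrichment(sites: Sequence,
                              refset: ReferenceSet) -> pd.DataFrame:
    """Fisher enrichment of each (codon, codon position) among CDS sites
    against codon usage across the represented transcripts."""
    anns = [a for a in annotate_sites(sites, refset) if a.feature == "CDS"]
    if not anns:
        return pd.DataFrame(
            columns=["codon", "position", "sites", "usage", "odds_ratio",
                     "p", "q"])
    tmap = {t.transcript_id: t for t in refset.transcripts}
    usage: dict[str, int] = {}
    for tid in sorted({a.transcript_id for a in anns}):
        t = tmap[tid]
        tx = t.spliced_sequence(refset.sequences)
        cs, ce = t.cds_spliced_interval()
        for k in range(cs, ce - 2, 3):
            cod = tx[k : k + 3]
            usage[cod] = usage.get(cod, 0) + 1
    total_usage = sum(usage.values())
    rows = []
    for position in (1, 2, 3):
        at_pos = [a for a in anns if a.codon_position == position]
        n_pos = len(at_pos)
        for codon in sorted(usage):
            a_ = sum(x.codon == codon for x in at_pos)
            b_ = n_pos - a_
            c_ = usage[codon] - a_
            d_ = total_usage - usage[codon] - b_
            orr, p = stats.fisher_exact([[a_, b_], [max(c_, 0), max(d_, 0)]],
                                        alternative="greater")
            rows.append({"codon": codon, "position": position, "sites": a_,
                         "usage": usage[codon], "odds_ratio": orr, "p": p})
    df = pd.DataFrame(rows)
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df.sort_values("p", ignore_index=True)


# ---------------------------------------------------------------------------
# Pairing profile
# ---------------------------------------------------------------------------

def pairing_profile(
    sites: Sequence,
    refset: ReferenceSet,
    flank: int = 25,
    n_control: int = 1,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-position paired-base fraction for site-centred windows versus
    windows around randomly selected transcribed cytosines.

    Returns (positions -flank..+flank, site fraction, control fraction)."""
    rng = np.random.default_rng(seed)
    keys = [_site_key(s) for s in sites]
    width = 2 * flank + 1

    def profile(wins: list[str]) -> np.ndarray:
        acc = np.zeros(width)
        n = 0
        for w in wins:
            acc += fold_window(w)
            n += 1
        return acc / n if n else acc

    site_wins = [w for k in keys
                 if (w := _window_seq(refset, *k, flank)) is not None]

    pool: list[tuple[str, int, str]] = []
    for t in refset.transcripts:
        seq = refset.sequences[t.seqname]
        target = "C" if t.strand == "+" else "G"
        for a, b in t.exons:
            for p in range(max(a, flank), min(b, len(seq) - flank)):
                if seq[p] == target:
                    pool.append((t.seqname, p, t.strand))
    n_ctrl = min(len(pool), n_control * max(len(site_wins), 1))
    idx = rng.choice(len(pool), size=n_ctrl, replace=False)
    ctrl_wins = [w for i in idx
                 if (w := _window_seq(refset, *pool[i], flank)) is not None]
    positions = np.arange(-flank, flank + 1)
    return positions, profile(site_wins), profile(ctrl_wins)
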
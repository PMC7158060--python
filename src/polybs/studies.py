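"""End-to-end synthetic studies exercising the full pipeline.

Each runner builds a reference with planted truth, simulates the
4-fraction x 3-replicate bisulfite experiment (or the relevant slice of
it), executes the analysis under test and measures the outcome against
the planted truth or an independent oracle. They are the package's own
validation experiments; the problem sizes are chosen so a study finishes
in minutes on one CPU.
"""
from __future__ import annotations

import itertools

import numpy as np

from .fold import MIN_LOOP, can_pair, fold_pairs
from .models import ReferenceSet
from .simdata import SimConfig, build_reference, simulate_sample, structure_clusters
from .sitecall import (
    FilterConfig,
    build_pileup,
    calibration_coverage,
    call_candidates,
    call_replicate_sites,
    combine_replicates,
    recovery,
    sample_counts,
    summarize_conversion,
)


def _sub_seed(seed: int, k: int) -> int:
    return int((seed * 1_000 + k) % (2**31 - 1))


# ---------------------------------------------------------------------------
# Filter-cascade oracle equivalence (toy SAM)
# ---------------------------------------------------------------------------

def _recount_pileup(records, refset: ReferenceSet, cfg: FilterConfig):
    """Independent brute-force per-read, per-position recount of the
    pileup/filter contract, kept deliberately naive."""
    def retained(rec):
        n = 0
        seq = refset.sequences[rec.seqname]
        ref_c = "C" if rec.strand == "+" else "G"
        for qoff, rpos in rec.aligned_pairs():
            if seq[rpos] == ref_c and rec.bases[qoff] == ref_c:
                n += 1
        return n

    out = {}
    for rec in records:
        seq = refset.sequences[rec.seqname]
        ref_c = "C" if rec.strand == "+" else "G"
        base_c, base_t = ("C", "T") if rec.strand == "+" else ("G", "A")
        ok = retained(rec) <= cfg.max_nonconverted_per_read
        for qoff, rpos in rec.aligned_pairs():
            if seq[rpos] != ref_c:
                continue
            key = (rec.seqname, rpos, rec.strand)
            col = out.setdefault(key, dict(raw=0, cov=0, c=0, t=0, other=0))
            col["raw"] += 1
            if not ok:
                continue
            col["cov"] += 1
            if rec.quals[qoff] < cfg.min_base_quality:
                continue
            if (qoff < cfg.end_mask_nt
                    or qoff >= rec.read_length - cfg.end_mask_nt):
                continue
            b = rec.bases[qoff]
            if b == base_c:
                col["c"] += 1
            elif b == base_t:
                col["t"] += 1
            else:
                col["other"] += 1
    return out


def run_filter_oracle_study(seed: int) -> dict:
    """Pileup counts, read-filter partition, S/N flags and site calls on a
    50-read toy sample must match the brute-force recount exactly."""
    cfg = SimConfig(n_mrna_genes=3, n_trna_genes=0, n_rrna_genes=1,
                    n_spikeins=0, planted_site_count=4, coverage_mean=6.0)
    refset, truth = build_reference(cfg, _sub_seed(seed, 1))
    records, _ = simulate_sample(refset, truth, 0, 0, cfg, _sub_seed(seed, 1))
    records = records[:50]
    fcfg = FilterConfig(min_coverage=2, min_c_count=1,
                        min_avg_nonconversion=0.0)
    cols = build_pileup(records, refset, fcfg)
    expected = _recount_pileup(records, refset, fcfg)
    mismatches = 0
    if set(cols) != set(expected):
        mismatches += len(set(cols) ^ set(expected))
    for key, exp in expected.items():
        col = cols.get(key)
        if col is None:
            continue
        got = (col.raw_coverage, col.filtered_coverage, col.c_count,
               col.t_count, col.other_count)
        want = (exp["raw"], exp["cov"], exp["c"], exp["t"], exp["other"])
        mismatches += got != want
        # S/N flag re-derived from the recount
        sn = exp["cov"] / exp["raw"] if exp["raw"] else 1.0
        mismatches += col.sn_flag(fcfg) != (sn < fcfg.signal_to_noise_min)
    calls = call_replicate_sites(cols, fcfg)
    for key, exp in expected.items():
        sn_ok = (exp["cov"] / exp["raw"] if exp["raw"] else 1.0) \
            >= fcfg.signal_to_noise_min
        scored = exp["c"] + exp["t"] + exp["other"]
        should = (sn_ok and exp["cov"] >= fcfg.min_coverage
                  and exp["c"] >= fcfg.min_c_count
                  and exp["c"] + exp["t"] >= fcfg.min_ct_fraction * scored)
        mismatches += (key in calls) != should
    return {"n_reads": len(records), "n_columns": len(expected),
            "mismatches": mismatches}


# ---------------------------------------------------------------------------
# Sensitivity & calibration
# ---------------------------------------------------------------------------

def run_calling_study(seed: int, n_genes: int = 120, n_sites: int = 200,
                      coverage: float = 55.0) -> dict:
    """Full cascade on planted mRNA sites: recovery, calibration against
    the realised per-replicate truth, and residual false positives."""
    cfg = SimConfig(n_mrna_genes=n_genes, planted_site_count=n_sites,
                    coverage_mean=coverage)
    refset, truth = build_reference(cfg, seed)
    fc = FilterConfig()
    reps, rep_p, rep_n = [], [], []
    for r in range(cfg.n_replicates):
        recs, p_acc, n_acc = [], {}, {}
        for f in range(cfg.n_fractions):
            rr, log = simulate_sample(refset, truth, f, r, cfg, seed)
            recs.extend(rr)
            for k, v in log.site_tallies.items():
                n_acc[k] = n_acc.get(k, 0) + sum(v)
                p_acc.setdefault(k, []).append((log.replicate_p[k], sum(v)))
        rep_p.append({k: sum(p * n for p, n in v) / max(sum(n for _, n in v), 1)
                      for k, v in p_acc.items()})
        rep_n.append(n_acc)
        reps.append(recs)
    sites = call_candidates(reps, refset, fc)
    truth_keys = {(e.seqname, e.pos) for e in truth}
    fp = sum((s.seqname, s.pos) not in truth_keys for s in sites)
    return {
        "recovery": recovery(sites, truth, {"mRNA"}),
        "calibration": calibration_coverage(
            sites, truth, rep_p, rep_n, cfg.conversion_failure_rate,
            classes={"mRNA"}),
        "n_sites": sum(e.rna_class == "mRNA" for e in truth),
        "false_positives": fp,
        "candidates": sites,
        "refset": refset,
        "truth": truth,
        "config": cfg,
    }


# ---------------------------------------------------------------------------
# Specificity
# ---------------------------------------------------------------------------

def run_specificity_study(seed: int) -> dict:
    """>= 1e5 unmethylated cytosine observations per composite replicate at
    the default conversion-failure rate: the candidate list must be empty."""
    cfg = SimConfig(n_mrna_genes=10, n_trna_genes=0, n_rrna_genes=0,
                    n_spikeins=2, planted_site_count=0, coverage_mean=50.0,
                    gene_length_range=(800, 1100), n_fractions=1,
                    coverage_by_fraction=(1.0,))
    refset, truth = build_reference(cfg, _sub_seed(seed, 2))
    fc = FilterConfig()
    reps = []
    observations = 0
    for r in range(cfg.n_replicates):
        recs, _ = simulate_sample(refset, truth, 0, r, cfg, _sub_seed(seed, 2))
        reps.append(recs)
    cols = build_pileup(reps[0], refset, fc)
    observations = sum(c.raw_c + c.raw_t for c in cols.values())
    sites = call_candidates(reps, refset, fc)
    return {"false_sites": len(sites), "c_observations": observations}


# ---------------------------------------------------------------------------
# Structure-artefact suppression
# ---------------------------------------------------------------------------

def run_artifact_study(seed: int) -> dict:
    """Co-retained cytosine clusters must be excluded by the read filter +
    S/N rule and re-admitted when both are disabled."""
    cfg = SimConfig(n_mrna_genes=4, n_trna_genes=0, n_rrna_genes=2,
                    n_spikeins=0, planted_site_count=0, coverage_mean=60.0,
                    n_fractions=1, coverage_by_fraction=(1.0,))
    refset, truth = build_reference(cfg, _sub_seed(seed, 3))
    clusters = structure_clusters(refset, cfg)
    cluster_keys = {(s, p) for s, _, members in clusters for p in members}
    reps = []
    for r in range(cfg.n_replicates):
        recs, _ = simulate_sample(refset, truth, 0, r, cfg, _sub_seed(seed, 3))
        reps.append(recs)
    strict = call_candidates(reps, refset, FilterConfig())
    relaxed = call_candidates(
        reps, refset, FilterConfig(enable_read_filter=False,
                                   enable_sn_filter=False))
    return {
        "cluster_positions": len(cluster_keys),
        "called_strict": len(cluster_keys
                             & {(s.seqname, s.pos) for s in strict}),
        "called_relaxed": len(cluster_keys
                              & {(s.seqname, s.pos) for s in relaxed}),
    }


# ---------------------------------------------------------------------------
# Spike-in conversion
# ---------------------------------------------------------------------------

def run_spikein_study(seed: int) -> dict:
    """Measured conversion of unmethylated spike-ins versus the analytic
    binomial expectation at the configured failure rate."""
    cfg = SimConfig(n_mrna_genes=2, n_trna_genes=0, n_rrna_genes=0,
                    n_spikeins=4, planted_site_count=0, coverage_mean=100.0,
                    gene_length_range=(800, 1000), n_fractions=1,
                    coverage_by_fraction=(1.0,))
    refset, truth = build_reference(cfg, _sub_seed(seed, 4))
    records, _ = simulate_sample(refset, truth, 0, 0, cfg, _sub_seed(seed, 4))
    cols = build_pileup(records, refset, FilterConfig())
    table = summarize_conversion(cols, refset.class_of)
    n = sum(c.c_count + c.t_count for c in cols.values()
            if refset.class_of.get(c.seqname) == "spikein")
    expected = 1.0 - cfg.conversion_failure_rate
    bound = 3 * np.sqrt(cfg.conversion_failure_rate * expected / n)
    return {
        "conversion": table["spikein"]["conversion_post_filter"],
        "expected": expected,
        "three_sd_bound": bound,
        "n_observations": n,
    }


# ---------------------------------------------------------------------------
# Differential methylation statistics
# ---------------------------------------------------------------------------

def run_diffmeth_study(seed: int, n_null: int = 2000,
                       n_planted: int = 300) -> dict:
    from .polysome import build_fraction_matrix, pairwise_diffmeth, two_proportion_lrt

    rng = np.random.default_rng(_sub_seed(seed, 5))

    def simulate_matrix(n_sites, p_first, p_rest, cov=50):
        calls = {(f, r): {} for f in range(4) for r in range(3)}
        for i in range(n_sites):
            locus = (f"g{i}", 100, "+")
            for f in range(4):
                p = p_first if f == 0 else p_rest
                for r in range(3):
                    n = int(rng.poisson(cov))
                    c = int(rng.binomial(n, p))
                    calls[(f, r)][locus] = (c, n - c, n)
        return build_fraction_matrix(calls)

    null = pairwise_diffmeth(simulate_matrix(n_null, 0.3, 0.3), (1, 2))
    null_rate = float(np.mean([r.q < 0.05 for r in null]))
    planted = pairwise_diffmeth(simulate_matrix(n_planted, 0.5, 0.1), (1, 2))
    power = float(np.mean([r.significant for r in planted]))

    def ll(m, u, p):
        return (m * np.log(p) if m else 0.0) + (u * np.log(1 - p) if u else 0.0)

    max_dev = 0.0
    for _ in range(200):
        m1, u1, m2, u2 = (int(x) for x in rng.integers(0, 80, 4))
        if m1 + u1 == 0 or m2 + u2 == 0:
            continue
        g, _ = two_proportion_lrt(m1, u1, m2, u2)
        if m1 + m2 == 0 or u1 + u2 == 0:
            oracle = 0.0
        else:
            p0 = (m1 + m2) / (m1 + u1 + m2 + u2)
            oracle = 2 * (ll(m1, u1, m1 / (m1 + u1))
                          + ll(m2, u2, m2 / (m2 + u2))
                          - ll(m1, u1, p0) - ll(m2, u2, p0))
        max_dev = max(max_dev, abs(g - oracle))
    return {"null_rejection_rate": null_rate, "n_null": len(null),
            "power": power, "n_planted": len(planted),
            "max_oracle_deviation": max_dev}


# ---------------------------------------------------------------------------
# Trend recovery
# ---------------------------------------------------------------------------

def run_trend_study(seed: int, n_runs: int = 3) -> dict:
    """Full 4x3 experiments with planted trend trajectories: fuzzy
    clustering + trend assignment versus the generating labels."""
    from .polysome import build_fraction_matrix, cluster_profiles, assign_trend

    agree = total = 0
    membership_ok = True
    for k in range(n_runs):
        run_seed = _sub_seed(seed, 10 + k)
        cfg = SimConfig(n_mrna_genes=60, planted_site_count=100,
                        coverage_mean=50.0)
        refset, truth = build_reference(cfg, run_seed)
        fc = FilterConfig()
        samples = {
            (f, r): simulate_sample(refset, truth, f, r, cfg, run_seed)[0]
            for f in range(4) for r in range(3)
        }
        reps = [sum((samples[(f, r)] for f in range(4)), []) for r in range(3)]
        sites = call_candidates(reps, refset, fc)
        loci = [s.locus for s in sites if s.rna_class == "mRNA"]
        calls = {(f, r): sample_counts(samples[(f, r)], refset, fc, loci)
                 for f in range(4) for r in range(3)}
        mat = build_fraction_matrix(calls).subset("F1234")
        if len(mat.nonconversion) < 9:
            continue
        model = cluster_profiles(mat.nonconversion, c=9, seed=run_seed % 997)
        sums = model.membership.sum(axis=1).to_numpy()
        membership_ok &= bool(np.allclose(sums, 1.0, atol=1e-9))
        _, site_labels = assign_trend(model, mat.nonconversion, matrix=mat)
        truth_trend = {}
        for e in truth:
            s = np.polyfit(np.arange(4), e.stoichiometry, 1)[0]
            truth_trend[(e.seqname, e.pos)] = (
                "negative" if s < -0.01 else
                ("positive" if s > 0.01 else "neutral"))
        for locus, lab in site_labels.items():
            t = truth_trend.get((locus[0], locus[1]))
            if t is None:
                continue
            total += 1
            agree += t == lab
    return {"trend_recovery": agree / total if total else float("nan"),
            "n_sites": total, "membership_rows_sum_to_one": membership_ok}


# ---------------------------------------------------------------------------
# Folding oracle
# ---------------------------------------------------------------------------

def _enumerate_max_pairs(seq: str) -> int:
    seq = seq.upper().replace("T", "U")

    def best(lo, hi):
        if hi - lo <= MIN_LOOP:
            return 0
        b = best(lo + 1, hi)
        for k in range(lo + MIN_LOOP + 1, hi):
            if can_pair(seq[lo], seq[k]):
                b = max(b, 1 + best(lo + 1, k) + best(k + 1, hi))
        return b

    return best(0, len(seq))


def run_fold_oracle_study(seed: int) -> dict:
    """Dynamic-program pair count versus exhaustive enumeration: all
    sequences up to length 5 plus random sequences of length 6-12."""
    rng = np.random.default_rng(_sub_seed(seed, 6))
    agree = total = 0
    for n in range(1, 6):
        for tup in itertools.product("ACGU", repeat=n):
            seq = "".join(tup)
            total += 1
            agree += len(fold_pairs(seq)) == _enumerate_max_pairs(seq)
    for _ in range(300):
        n = int(rng.integers(6, 13))
        seq = "".join(rng.choice(list("ACGU"), n))
        total += 1
        agree += len(fold_pairs(seq)) == _enumerate_max_pairs(seq)
    return {"n_checked": total, "n_agree": agree}


# ---------------------------------------------------------------------------
# Enrichment null calibration
# ---------------------------------------------------------------------------

def run_enrichment_null_study(seed: int, n_runs: int = 200) -> dict:
    """Uniform random site placement: the per-bin Fisher CIs should cover
    an odds ratio of 1 at about the nominal 95% rate."""
    from .siteannot import binned_enrichment

    cfg = SimConfig(n_mrna_genes=12, n_trna_genes=0, n_rrna_genes=0,
                    n_spikeins=0, planted_site_count=0)
    refset, _ = build_reference(cfg, _sub_seed(seed, 7))
    pool = []
    for t in refset.transcripts:
        seq = refset.sequences[t.seqname]
        target = "C" if t.strand == "+" else "G"
        for a, b in t.exons:
            pool.extend((t.seqname, p, t.strand) for p in range(a, b)
                        if seq[p] == target)
    rng = np.random.default_rng(_sub_seed(seed, 8))
    covered = total = 0
    for run in range(n_runs):
        idx = rng.choice(len(pool), size=50, replace=False)
        sites = [pool[i] for i in idx]
        bins = binned_enrichment(sites, refset, anchor="start_codon",
                                 window=(-400, 1000), bin_width=100,
                                 n_null=40, seed=_sub_seed(seed, 100 + run))
        for b in bins:
            if b.observed + b.null == 0:
                continue
            total += 1
            covered += b.ci_low <= 1.0 <= b.ci_high
    return {"ci_coverage": covered / total, "n_intervals": total}
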
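"""Fraction-wise methylation-trend analysis across a polysome profile.

Sites x fractions matrices are built from per-sample calls (4 fractions x
3 replicates), soft-clustered with fuzzy c-means on standardised profiles,
grouped into negative/neutral/positive translation-state trends, and
tested for differential methylation between adjacent fractions with a
binomial logistic-regression (two-proportion likelihood-ratio) test.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.cluster import kmeans_plusplus
from statsmodels.distributions.empirical_distribution import ECDF
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

Locus = tuple[str, int, str]


# ---------------------------------------------------------------------------
# Fraction matrix
# ---------------------------------------------------------------------------

@dataclass
class FractionMatrix:
    """Per-site, per-fraction replicate-averaged methylation summaries.

    ``label`` partitions loci into F1234 (mean coverage >= threshold in all
    fractions, observations in >= 9 of 12 samples), F234 (same for
    fractions 2-4 but failing fraction 1) and excluded (absent here).
    """

    nonconversion: pd.DataFrame  # loci x fractions, mean of replicate proportions
    coverage: pd.DataFrame  # mean coverage
    meth: pd.DataFrame  # mean retained-C count
    unmeth: pd.DataFrame  # mean converted count
    label: pd.Series  # 'F1234' | 'F234'

    def subset(self, label: str) -> "FractionMatrix":
        keep = self.label[self.label == label].index
        return FractionMatrix(
            self.nonconversion.loc[keep], self.coverage.loc[keep],
            self.meth.loc[keep], self.unmeth.loc[keep], self.label.loc[keep],
        )


def build_fraction_matrix(
    sample_calls: dict[tuple[int, int], dict[Locus, tuple[int, int, int]]],
    n_fractions: int = 4,
    n_replicates: int = 3,
    min_mean_coverage: float = 10.0,
    min_samples_with_data: int = 9,
) -> FractionMatrix:
    """Build the sites x fractions matrix from per-sample (c, t, coverage)
    tallies keyed by (fraction_index, replicate_index)."""
    expected = {(f, r) for f in range(n_fractions) for r in range(n_replicates)}
    if set(sample_calls) != expected:
        raise ValueError(
            f"expected {len(expected)} samples "
            f"({n_fractions} fractions x {n_replicates} replicates)"
        )
    loci: set[Locus] = set()
    for calls in sample_calls.values():
        loci.update(calls)
    loci = sorted(loci)
    shape = (len(loci), n_fractions)
    noncon = np.full(shape, np.nan)
    cover = np.zeros(shape)
    meth = np.full(shape, np.nan)
    unmeth = np.full(shape, np.nan)
    n_obs = np.zeros(len(loci), dtype=int)
    for i, locus in enumerate(loci):
        for f in range(n_fractions):
            cs, ts, covs, props = [], [], [], []
            for r in range(n_replicates):
                rec = sample_calls[(f, r)].get(locus)
                if rec is None:
                    continue
                c, t, cov = rec
                cs.append(c)
                ts.append(t)
                covs.append(cov)
                if c + t > 0:
                    props.append(c / (c + t))
                n_obs[i] += 1
            if covs:
                cover[i, f] = float(np.mean(covs))
                meth[i, f] = float(np.mean(cs))
                unmeth[i, f] = float(np.mean(ts))
            if props:
                noncon[i, f] = float(np.mean(props))
    cov_ok = cover >= min_mean_coverage
    labels = {}
    for i, locus in enumerate(loci):
        if n_obs[i] < min_samples_with_data:
            continue
        if cov_ok[i].all():
            labels[locus] = "F1234"
        elif cov_ok[i, 1:].all():
            labels[locus] = "F234"
    keep = [i for i, l in enumerate(loci) if l in labels]
    idx = pd.Index([loci[i] for i in keep], tupleize_cols=False)
    cols = [f"F{f + 1}" for f in range(n_fractions)]

    def df(a: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(a[keep], index=idx, columns=cols)

    return FractionMatrix(
        nonconversion=df(noncon), coverage=df(cover),
        meth=df(meth), unmeth=df(unmeth),
        label=pd.Series({loci[i]: labels[loci[i]] for i in keep}),
    )


# ---------------------------------------------------------------------------
# Fuzzy c-means
# ---------------------------------------------------------------------------

@dataclass
class ClusterModel:
    centroids: np.ndarray  # c x n_fractions, standardised scale
    membership: pd.DataFrame  # sites x c, rows sum to 1
    fuzzifier: float
    objective: float
    dropped: list = field(default_factory=list)  # constant-profile loci

    @property
    def assigned(self) -> pd.Series:
        return pd.Series(
            np.argmax(self.membership.to_numpy(), axis=1),
            index=self.membership.index,
        )


def _standardise(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    ok = sd[:, 0] > 0
    return (x - mu) / np.where(sd > 0, sd, 1.0), ok


def _fcm_memberships(x: np.ndarray, centroids: np.ndarray,
                     m: float) -> np.ndarray:
    d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    d2 = np.maximum(d2, 1e-12)
    w = d2 ** (-1.0 / (m - 1.0))
    return w / w.sum(axis=1, keepdims=True)


def _fcm_objective(x, centroids, u, m) -> float:
    d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return float(((u ** m) * d2).sum())


def cluster_profiles(
    profiles: pd.DataFrame,
    c: int = 9,
    m: float = 2.0,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 300,
    n_restarts: int = 10,
) -> ClusterModel:
    """Fuzzy c-means (Mfuzz-style soft clustering) of per-site fraction
    profiles, standardised per site before clustering.

    k-means++ seeding with ``n_restarts`` restarts, keeping the best
    objective; the objective is non-increasing across iterations and the
    whole procedure is deterministic for a fixed seed.
    """
    if len(profiles) < c:
        raise ValueError(f"need >= {c} profiles, got {len(profiles)}")
    x_all = profiles.to_numpy(dtype=float)
    z, ok = _standardise(x_all)
    dropped = list(profiles.index[~ok])
    if dropped:
        log.info("clustering: dropped %d constant profiles", len(dropped))
    z = z[ok]
    index = profiles.index[ok]
    if c == 1:
        u = np.ones((len(z), 1))
        cen = z.mean(axis=0, keepdims=True)
        return ClusterModel(cen, pd.DataFrame(u, index=index), m,
                            _fcm_objective(z, cen, u, m), dropped)
    rng = np.random.default_rng(seed)
    best: Optional[tuple[float, np.ndarray, np.ndarray]] = None
    for _ in range(n_restarts):
        cen, _ = kmeans_plusplus(
            z, n_clusters=c,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        prev = np.inf
        for _ in range(max_iter):
            u = _fcm_memberships(z, cen, m)
            um = u ** m
            cen = (um.T @ z) / um.sum(axis=0)[:, None]
            j = _fcm_objective(z, cen, u, m)
            if prev - j < tol:
                break
            prev = j
        u = _fcm_memberships(z, cen, m)
        j = _fcm_objective(z, cen, u, m)
        if best is None or j < best[0]:
            best = (j, cen.copy(), u.copy())
    j, cen, u = best
    return ClusterModel(cen, pd.DataFrame(u, index=index), m, j, dropped)


def assign_trend(
    model: ClusterModel,
    profiles: Optional[pd.DataFrame] = None,
    epsilon: float = 0.02,
    matrix: Optional[FractionMatrix] = None,
    z_threshold: float = 1.5,
    z_promote: float = 2.5,
) -> tuple[list[str], pd.Series]:
    """Label each cluster by the least-squares slope of its profile across
    fraction index (an automated surrogate for grouping soft clusters by
    eye): negative below -epsilon, positive above +epsilon, else neutral.
    Sites inherit the label of their highest-membership cluster.

    When the raw (unstandardised) ``profiles`` are given, each cluster's
    trend is read off its membership-weighted mean raw non-conversion
    profile with ``epsilon`` in non-conversion units per fraction step
    (default 2 percentage points). Per-site standardisation is scale-free
    — a flat site is unit-scale noise afterwards — so raw-scale slopes are
    what separates genuine trends from flat profiles; without ``profiles``
    the standardised centroids are used and ``epsilon`` is interpreted on
    that scale.

    When ``matrix`` is given, a per-site evidence check refines the
    inherited labels: a site in a trend-labelled cluster whose own raw
    slope is statistically indistinguishable from zero (|slope| / SE below
    ``z_threshold``, SE from the binomial counting noise of the
    replicate-averaged counts) is reassigned neutral. Flat profiles are
    isotropic after standardisation and a fraction of them lands in
    trend-shaped clusters; their raw profiles carry no evidence of change,
    which this check exploits. Conversely a site inheriting a neutral
    label whose slope evidence is strong (|slope| / SE >= ``z_promote``)
    is promoted to the trend of its own slope sign.
    """
    n_frac = model.centroids.shape[1]
    xs = np.arange(n_frac)
    if profiles is not None:
        raw = profiles.loc[model.membership.index].to_numpy(dtype=float)
        assigned = model.assigned.to_numpy()
        um = model.membership.to_numpy() ** model.fuzzifier
        centroids = np.empty((model.membership.shape[1], n_frac))
        for k in range(centroids.shape[0]):
            members = assigned == k
            if members.any():
                # hard-member mean: soft weights would dilute small
                # clusters with the majority trend
                centroids[k] = raw[members].mean(axis=0)
            else:
                centroids[k] = (um[:, k] @ raw) / um[:, k].sum()
    else:
        centroids = model.centroids
    labels = []
    for cen in centroids:
        slope = np.polyfit(xs, cen, 1)[0]
        if slope < -epsilon:
            labels.append("negative")
        elif slope > epsilon:
            labels.append("positive")
        else:
            labels.append("neutral")
    site_labels = model.assigned.map(lambda i: labels[i])
    if matrix is not None:
        xw = (xs - xs.mean()) / ((xs - xs.mean()) ** 2).sum()
        n_reps = 3  # replicate-averaged counts: variance shrinks by 1/R
        for locus in site_labels.index:
            p = matrix.nonconversion.loc[[locus]].to_numpy(dtype=float)[0]
            n = (matrix.meth.loc[[locus]].to_numpy(dtype=float)[0]
                 + matrix.unmeth.loc[[locus]].to_numpy(dtype=float)[0])
            if np.any(~np.isfinite(p)) or np.any(n <= 0):
                continue
            var = (p * (1 - p)) / (n_reps * n)
            slope = float(xw @ p)
            se = float(np.sqrt((xw ** 2) @ var))
            if se <= 0:
                continue
            z = abs(slope) / se
            if site_labels[locus] != "neutral" and z < z_threshold:
                site_labels[locus] = "neutral"
            elif site_labels[locus] == "neutral" and z >= z_promote:
                site_labels[locus] = "negative" if slope < 0 else "positive"
    return labels, site_labels


# ---------------------------------------------------------------------------
# Differential methylation
# ---------------------------------------------------------------------------

@dataclass
class DiffMethResult:
    locus: Locus
    pair: tuple[int, int]
    diff: float  # percentage points (first minus second fraction)
    statistic: float  # LRT deviance
    p: float
    q: float = float("nan")
    significant: bool = False

    @property
    def direction(self) -> str:
        return "negative" if self.diff > 0 else (
            "positive" if self.diff < 0 else "none")


def two_proportion_lrt(m1: int, u1: int, m2: int, u2: int) -> tuple[float, float]:
    """Binomial logistic-regression LRT for equal methylation proportion in
    two fractions, via the residual deviance of the intercept-only GLM
    (the saturated two-group model fits the two observations exactly)."""
    endog = np.array([[m1, u1], [m2, u2]], dtype=float)
    if endog.sum() == 0 or endog[:, 0].sum() == 0 or endog[:, 1].sum() == 0:
        return 0.0, 1.0
    with warnings.catch_warnings():
        # boundary tables (a zero cell) trip the separation check; the
        # intercept-only deviance used here is still exact
        warnings.simplefilter("ignore")
        res = sm.GLM(endog, np.ones((2, 1)), family=sm.families.Binomial()).fit()
    g = float(res.deviance)
    return g, float(stats.chi2.sf(g, df=1))


def pairwise_diffmeth(
    matrix: FractionMatrix,
    pair: tuple[int, int] = (1, 2),
    alpha: float = 0.05,
    min_diff: float = 10.0,
    relative: bool = False,
    min_coverage: float = 10.0,
) -> list[DiffMethResult]:
    """Per-site differential methylation between two adjacent fractions.

    Replicate-averaged methylated/unmethylated counts are rounded to the
    nearest integer and compared with a two-proportion LRT; q-values are BH
    across tested sites; significance requires q < alpha and a methylation
    difference of at least ``min_diff`` percentage points (or percent of
    the first fraction's level in ``relative`` mode).
    """
    if pair not in {(1, 2), (2, 3), (3, 4)}:
        raise ValueError("pair must be adjacent fractions (1,2), (2,3) or (3,4)")
    fa, fb = f"F{pair[0]}", f"F{pair[1]}"
    results: list[DiffMethResult] = []
    excluded = 0
    for locus in matrix.nonconversion.index:
        cov_a = matrix.coverage.at[locus, fa]
        cov_b = matrix.coverage.at[locus, fb]
        if cov_a < min_coverage or cov_b < min_coverage:
            excluded += 1
            continue
        m1 = int(round(matrix.meth.at[locus, fa]))
        u1 = int(round(matrix.unmeth.at[locus, fa]))
        m2 = int(round(matrix.meth.at[locus, fb]))
        u2 = int(round(matrix.unmeth.at[locus, fb]))
        if m1 + u1 == 0 or m2 + u2 == 0:
            excluded += 1
            continue
        p1, p2 = m1 / (m1 + u1), m2 / (m2 + u2)
        if relative:
            diff = (p1 - p2) / p1 * 100.0 if p1 > 0 else 0.0
        else:
            diff = (p1 - p2) * 100.0
        g, p = two_proportion_lrt(m1, u1, m2, u2)
        results.append(DiffMethResult(locus, pair, diff, g, p))
    if excluded:
        log.info("diffmeth %s: excluded %d sites below coverage", pair, excluded)
    if results:
        qs = multipletests([r.p for r in results], method="fdr_bh")[1]
        for r, q in zip(results, qs):
            r.q = float(q)
            r.significant = bool(q < alpha and abs(r.diff) >= min_diff)
    return results


# ---------------------------------------------------------------------------
# Bulk tests
# ---------------------------------------------------------------------------

def bulk_adjacent_tests(
    matrix: FractionMatrix,
    regions: Optional[dict[Locus, str]] = None,
    welch: bool = False,
) -> pd.DataFrame:
    """Unpaired two-tailed t-tests of non-conversion distributions between
    each pair of adjacent fractions, overall and per mRNA region."""
    groups = {"all": matrix.nonconversion}
    if regions is not None:
        for reg in sorted(set(regions.values())):
            loci = [l for l in matrix.nonconversion.index
                    if regions.get(l) == reg]
            groups[reg] = matrix.nonconversion.loc[loci]
    rows = []
    cols = list(matrix.nonconversion.columns)
    for name, df in groups.items():
        for a, b in zip(cols, cols[1:]):
            xa = df[a].dropna().to_numpy()
            xb = df[b].dropna().to_numpy()
            if len(xa) < 2 or len(xb) < 2:
                log.info("bulk t-test %s %s-%s skipped: too few sites",
                         name, a, b)
                continue
            t, p = stats.ttest_ind(xa, xb, equal_var=not welch)
            rows.append({"region": name, "pair": f"{a}-{b}", "t": t, "p": p,
                         "n_a": len(xa), "n_b": len(xb)})
    return pd.DataFrame(rows)


def region_trend_test(
    site_labels: pd.Series,
    regions: dict[Locus, str],
) -> pd.DataFrame:
    """Exact binomial test of each trend category's mRNA-region composition
    against the region proportions of all sites."""
    loci = [l for l in site_labels.index if l in regions]
    overall = pd.Series([regions[l] for l in loci]).value_counts(normalize=True)
    rows = []
    for trend in sorted(site_labels.unique()):
        members = [l for l in loci if site_labels[l] == trend]
        if not members:
            continue
        counts = pd.Series([regions[l] for l in members]).value_counts()
        for region, p0 in overall.items():
            k = int(counts.get(region, 0))
            res = stats.binomtest(k, len(members), p0)
            rows.append({"trend": trend, "region": region, "count": k,
                         "n": len(members), "expected_prop": float(p0),
                         "p": res.pvalue})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Amplicon grids
# ---------------------------------------------------------------------------

def amplicon_nonconversion(
    sample_records: dict[str, Sequence],
    refset,
    kd_reference: str,
    candidate_positions: Optional[Sequence[Locus]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cytosine non-conversion grid across amplicon samples, plus
    t-tests of each sample against the designated knockdown reference.

    ``sample_records`` maps sample name to a list of per-replicate
    alignment-record lists. Full depth is used: no coverage thresholds, no
    read filter, no end mask.
    """
    from .sitecall import FilterConfig, build_pileup

    if kd_reference not in sample_records:
        raise ValueError(f"knockdown reference {kd_reference!r} not a sample")
    cfg = FilterConfig(enable_read_filter=False, enable_sn_filter=False,
                       end_mask_nt=0, min_base_quality=0)
    per_rep: dict[str, list[dict[Locus, float]]] = {}
    for sample, reps in sample_records.items():
        per_rep[sample] = []
        for recs in reps:
            cols = build_pileup(recs, refset, cfg)
            per_rep[sample].append(
                {k: col.nonconversion for k, col in cols.items()
                 if col.c_count + col.t_count > 0}
            )
    loci = sorted({k for reps in per_rep.values() for d in reps for k in d})
    grid = pd.DataFrame(
        {
            sample: [
                float(np.mean([d[k] for d in reps if k in d]))
                if any(k in d for d in reps) else np.nan
                for k in loci
            ]
            for sample, reps in per_rep.items()
        },
        index=pd.Index(loci, tupleize_cols=False),
    )
    tests = []
    targets = loci if candidate_positions is None else list(candidate_positions)
    kd_reps = per_rep[kd_reference]
    for sample, reps in per_rep.items():
        if sample == kd_reference:
            continue
        if len(reps) < 2 or len(kd_reps) < 2:
            continue  # single-replicate design: grid only
        for k in targets:
            xa = [d[k] for d in reps if k in d]
            xb = [d[k] for d in kd_reps if k in d]
            if len(xa) < 2 or len(xb) < 2:
                continue
            t, p = stats.ttest_ind(xa, xb)
            tests.append({"sample": sample, "locus": k, "t": t, "p": p})
    return grid, pd.DataFrame(tests)


# ---------------------------------------------------------------------------
# Expression association
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    site_values: np.ndarray
    other_values: np.ndarray
    site_ecdf: ECDF
    other_ecdf: ECDF
    statistic: float
    p: float


def expression_association(
    site_genes: set[str],
    table: pd.DataFrame,
    min_reads: int = 60,
) -> AssociationResult:
    """Compare a per-gene measure (translation efficiency or half-life)
    between site-bearing and remaining genes by ECDF + two-sample KS test.

    When raw counts are given (columns ``rna_count``/``rpf_count``), genes
    need more than ``min_reads`` in both and TE = RPF / RNA; a precomputed
    ``measure`` column (already normalised) is accepted as-is.
    """
    df = table.copy()
    if "measure" not in df.columns:
        if not {"rna_count", "rpf_count"} <= set(df.columns):
            raise ValueError("table needs a 'measure' or count columns")
        df = df[(df["rna_count"] > min_reads) & (df["rpf_count"] > min_reads)]
        df["measure"] = df["rpf_count"] / df["rna_count"]
    in_site = df["gene_id"].isin(site_genes)
    xs = df.loc[in_site, "measure"].to_numpy(dtype=float)
    xo = df.loc[~in_site, "measure"].to_numpy(dtype=float)
    if len(xs) == 0 or len(xo) == 0:
        raise ValueError("no overlap between site genes and measure table")
    stat, p = stats.ks_2samp(xs, xo)
    return AssociationResult(xs, xo, ECDF(xs), ECDF(xo), float(stat), float(p))
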
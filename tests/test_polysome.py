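import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from polybs.polysome import (
    ClusterModel,
    _fcm_memberships,
    _fcm_objective,
    assign_trend,
    build_fraction_matrix,
    bulk_adjacent_tests,
    cluster_profiles,
    expression_association,
    pairwise_diffmeth,
    region_trend_test,
    two_proportion_lrt,
)


def make_calls(spec, n_fractions=4, n_replicates=3):
    """spec: locus -> per-fraction (c, t, cov) applied to every replicate,
    or locus -> {(f, r): (c, t, cov)} for full control."""
    calls = {(f, r): {} for f in range(n_fractions) for r in range(n_replicates)}
    for locus, v in spec.items():
        if isinstance(v, dict):
            for (f, r), rec in v.items():
                calls[(f, r)][locus] = rec
        else:
            for f in range(n_fractions):
                for r in range(n_replicates):
                    calls[(f, r)][locus] = v[f]
    return calls


class TestFractionMatrix:
    def test_fully_covered_site_is_f1234(self):
        calls = make_calls({("g", 1, "+"): [(5, 45, 50)] * 4})
        mat = build_fraction_matrix(calls)
        assert mat.label[("g", 1, "+")] == "F1234"
        assert mat.nonconversion.loc[[("g", 1, "+")]].iloc[0].tolist() == \
            pytest.approx([0.1] * 4)

    def test_fraction1_boundary_routes_to_f234(self):
        spec = {("g", 1, "+"): [(1, 8, 9), (5, 45, 50), (5, 45, 50),
                                (5, 45, 50)]}
        mat = build_fraction_matrix(make_calls(spec))
        assert mat.label[("g", 1, "+")] == "F234"

    def test_sparse_site_excluded(self):
        spec = {("g", 1, "+"): {(f, r): (5, 45, 50)
                                for f in range(4) for r in range(2)}}
        mat = build_fraction_matrix(make_calls(spec))  # 8 of 12 samples
        assert ("g", 1, "+") not in mat.label.index

    def test_wrong_sample_count_is_an_error(self):
        with pytest.raises(ValueError, match="samples"):
            build_fraction_matrix({(0, 0): {}})

    def test_partition_matches_brute_force_reapplication(self):
        rng = np.random.default_rng(0)
        spec = {}
        for i in range(60):
            locus = (f"g{i}", 1, "+")
            spec[locus] = {}
            for f in range(4):
                for r in range(3):
                    if rng.random() < 0.12:
                        continue  # missing observation
                    cov = int(rng.integers(2, 40))
                    c = int(rng.binomial(cov, 0.3))
                    spec[locus][(f, r)] = (c, cov - c, cov)
        calls = make_calls(spec)
        mat = build_fraction_matrix(calls)
        for i in range(60):
            locus = (f"g{i}", 1, "+")
            obs = len(spec[locus])
            mean_cov = [
                np.mean([spec[locus][(f, r)][2] for r in range(3)
                         if (f, r) in spec[locus]])
                if any((f, r) in spec[locus] for r in range(3)) else 0.0
                for f in range(4)
            ]
            if obs >= 9 and all(m >= 10 for m in mean_cov):
                expected = "F1234"
            elif obs >= 9 and all(m >= 10 for m in mean_cov[1:]):
                expected = "F234"
            else:
                expected = None
            got = mat.label.get(locus)
            assert got == expected


class TestClustering:
    def _profiles(self, seed=0, n=60):
        rng = np.random.default_rng(seed)
        rows, labels = [], []
        # three distinct profile shapes (down, V, up): separation must
        # survive per-row standardisation, so a flat group would not do
        shapes = {0: np.array([0.6, 0.45, 0.3, 0.15]),
                  1: np.array([0.5, 0.2, 0.2, 0.5]),
                  2: np.array([0.1, 0.25, 0.4, 0.55])}
        for i in range(n):
            k = i % 3
            rows.append(shapes[k] + rng.normal(0, 0.015, 4))
            labels.append(k)
        idx = pd.Index([(f"g{i}", 1, "+") for i in range(n)],
                       tupleize_cols=False)
        return pd.DataFrame(rows, index=idx,
                            columns=["F1", "F2", "F3", "F4"]), labels

    def test_single_cluster_gives_unit_membership(self):
        profiles, _ = self._profiles()
        model = cluster_profiles(profiles, c=1, seed=0)
        assert np.allclose(model.membership.to_numpy(), 1.0)

    def test_membership_rows_sum_to_one(self):
        profiles, _ = self._profiles()
        model = cluster_profiles(profiles, c=5, seed=0)
        sums = model.membership.sum(axis=1).to_numpy()
        assert np.allclose(sums, 1.0, atol=1e-9)
        assert ((model.membership.to_numpy() >= 0)
                & (model.membership.to_numpy() <= 1)).all()

    def test_seed_determinism(self):
        profiles, _ = self._profiles()
        a = cluster_profiles(profiles, c=4, seed=3)
        b = cluster_profiles(profiles, c=4, seed=3)
        assert np.allclose(a.centroids, b.centroids)
        assert np.allclose(a.membership, b.membership)

    def test_well_separated_groups_recovered(self):
        profiles, truth = self._profiles(seed=5, n=90)
        model = cluster_profiles(profiles, c=3, seed=0)
        assert adjusted_rand_score(truth, model.assigned.to_numpy()) >= 0.9

    def test_constant_profiles_dropped(self):
        profiles, _ = self._profiles()
        idx = pd.Index([("flat", 1, "+")], tupleize_cols=False)
        flat = pd.DataFrame([[0.2, 0.2, 0.2, 0.2]], index=idx,
                            columns=profiles.columns)
        both = pd.concat([profiles, flat])
        model = cluster_profiles(both, c=3, seed=0)
        assert model.dropped == [("flat", 1, "+")]
        assert ("flat", 1, "+") not in model.membership.index

    def test_objective_descends_under_update_rule(self):
        profiles, _ = self._profiles()
        x = profiles.to_numpy()
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        rng = np.random.default_rng(0)
        cen = z[rng.choice(len(z), 4, replace=False)]
        prev = math.inf
        for _ in range(20):
            u = _fcm_memberships(z, cen, 2.0)
            um = u ** 2.0
            cen = (um.T @ z) / um.sum(axis=0)[:, None]
            j = _fcm_objective(z, cen, u, 2.0)
            assert j <= prev + 1e-9
            prev = j

    def test_too_few_profiles_is_an_error(self):
        profiles, _ = self._profiles(n=6)
        with pytest.raises(ValueError):
            cluster_profiles(profiles, c=9, seed=0)


class TestAssignTrend:
    def _model(self, centroids):
        idx = pd.Index([(f"g{i}", 1, "+") for i in range(len(centroids))],
                       tupleize_cols=False)
        membership = pd.DataFrame(np.eye(len(centroids)), index=idx)
        return ClusterModel(np.asarray(centroids, dtype=float), membership,
                            2.0, 0.0)

    def test_strictly_decreasing_centroid_is_negative(self):
        model = self._model([[1.0, 0.4, -0.4, -1.0]])
        labels, _ = assign_trend(model)
        assert labels == ["negative"]

    def test_flat_centroid_is_neutral(self):
        model = self._model([[0.01, -0.02, 0.01, 0.0]])
        labels, _ = assign_trend(model)
        assert labels == ["neutral"]

    def test_raw_profile_scale_controls_labels(self):
        # identical standardised shape; only the raw swing differs
        model = self._model([[-1.16, -0.39, 0.39, 1.16],
                             [-1.16, -0.39, 0.39, 1.16]])
        idx = model.membership.index
        raw = pd.DataFrame([[0.10, 0.25, 0.40, 0.55],   # genuine trend
                            [0.299, 0.2995, 0.3005, 0.301]],  # flat
                           index=idx, columns=["F1", "F2", "F3", "F4"])
        labels, site_labels = assign_trend(model, raw)
        assert labels == ["positive", "neutral"]


class TestDiffMeth:
    def test_identical_proportions_not_significant(self):
        calls = make_calls({("g", 1, "+"): [(20, 80, 100)] * 4})
        mat = build_fraction_matrix(calls)
        res = pairwise_diffmeth(mat, (1, 2))
        assert len(res) == 1
        assert res[0].diff == 0.0
        assert res[0].p == pytest.approx(1.0)
        assert not res[0].significant

    def test_forty_point_difference_matches_lrt_oracle(self):
        spec = {("g", 1, "+"): [(50, 50, 100), (10, 90, 100),
                                (10, 90, 100), (10, 90, 100)]}
        mat = build_fraction_matrix(make_calls(spec))
        res = pairwise_diffmeth(mat, (1, 2))[0]
        assert res.diff == pytest.approx(40.0)
        assert res.direction == "negative"

        def ll(m, u, p):
            return (m * math.log(p) if m else 0.0) + \
                (u * math.log(1 - p) if u else 0.0)

        p0 = 60 / 200
        g_oracle = 2 * (ll(50, 50, 0.5) + ll(10, 90, 0.1)
                        - ll(50, 50, p0) - ll(10, 90, p0))
        assert res.statistic == pytest.approx(g_oracle, abs=1e-6)
        assert res.significant

    def test_deviance_matches_oracle_over_random_tables(self):
        rng = np.random.default_rng(2)

        def ll(m, u, p):
            return (m * math.log(p) if m else 0.0) + \
                (u * math.log(1 - p) if u else 0.0)

        for _ in range(100):
            m1, u1, m2, u2 = (int(x) for x in rng.integers(0, 60, 4))
            if m1 + u1 == 0 or m2 + u2 == 0:
                continue
            g, p = two_proportion_lrt(m1, u1, m2, u2)
            if m1 + m2 == 0 or u1 + u2 == 0:
                assert g == 0.0
                continue
            p0 = (m1 + m2) / (m1 + u1 + m2 + u2)
            oracle = 2 * (ll(m1, u1, m1 / (m1 + u1))
                          + ll(m2, u2, m2 / (m2 + u2))
                          - ll(m1, u1, p0) - ll(m2, u2, p0))
            assert g == pytest.approx(oracle, abs=1e-6)

    def test_low_coverage_sites_excluded(self):
        spec = {("g", 1, "+"): [(2, 6, 8)] * 4,
                ("g", 2, "+"): [(5, 45, 50)] * 4}
        mat = build_fraction_matrix(make_calls(spec))
        res = pairwise_diffmeth(mat, (1, 2))
        assert [r.locus for r in res] == [("g", 2, "+")]

    def test_non_adjacent_pair_rejected(self):
        calls = make_calls({("g", 1, "+"): [(5, 45, 50)] * 4})
        mat = build_fraction_matrix(calls)
        with pytest.raises(ValueError):
            pairwise_diffmeth(mat, (1, 3))

    def test_relative_difference_mode(self):
        spec = {("g", 1, "+"): [(40, 60, 100), (32, 68, 100),
                                (32, 68, 100), (32, 68, 100)]}
        mat = build_fraction_matrix(make_calls(spec))
        res = pairwise_diffmeth(mat, (1, 2), relative=True)[0]
        assert res.diff == pytest.approx((0.40 - 0.32) / 0.40 * 100)


class TestBulkTests:
    def _matrix(self, rows):
        idx = pd.Index([(f"g{i}", 1, "+") for i in range(len(rows))],
                       tupleize_cols=False)
        df = pd.DataFrame(rows, index=idx, columns=["F1", "F2", "F3", "F4"])
        from polybs.polysome import FractionMatrix
        return FractionMatrix(df, df * 0 + 50, df * 50, (1 - df) * 50,
                              pd.Series("F1234", index=idx))

    def test_identical_distributions_give_t_zero(self):
        rows = [[0.1, 0.1, 0.3, 0.3], [0.2, 0.2, 0.4, 0.4],
                [0.3, 0.3, 0.5, 0.5]]
        out = bulk_adjacent_tests(self._matrix(rows))
        f12 = out[out["pair"] == "F1-F2"].iloc[0]
        assert f12["t"] == pytest.approx(0.0, abs=1e-12)
        assert f12["p"] == pytest.approx(1.0)

    def test_matches_textbook_student_t(self):
        rng = np.random.default_rng(4)
        rows = rng.uniform(0.1, 0.6, size=(20, 4))
        out = bulk_adjacent_tests(self._matrix(rows))
        a, b = rows[:, 0], rows[:, 1]
        n = len(a)
        sp2 = (((n - 1) * a.var(ddof=1) + (n - 1) * b.var(ddof=1))
               / (2 * n - 2))
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * 2 / n)
        f12 = out[(out["region"] == "all") & (out["pair"] == "F1-F2")].iloc[0]
        assert f12["t"] == pytest.approx(t_hand, abs=1e-10)

    def test_per_region_grouping_and_degenerate_exclusion(self):
        rows = [[0.1, 0.2, 0.3, 0.4]] * 4
        mat = self._matrix(rows)
        regions = {locus: ("CDS" if i < 3 else "5UTR")
                   for i, locus in enumerate(mat.nonconversion.index)}
        out = bulk_adjacent_tests(mat, regions=regions)
        assert "CDS" in set(out["region"])
        assert "5UTR" not in set(out["region"])  # single site: skipped


class TestRegionTrendTest:
    def test_null_composition_not_significant(self):
        loci = [(f"g{i}", 1, "+") for i in range(40)]
        regions = {l: ("CDS" if i % 2 else "3UTR")
                   for i, l in enumerate(loci)}
        labels = pd.Series(["negative" if i < 20 else "positive"
                            for i in range(40)], index=pd.Index(loci, tupleize_cols=False))
        out = region_trend_test(labels, regions)
        assert (out["p"] >= 0.05).all()

    def test_matches_exact_binomial_tail(self):
        from scipy.stats import binom

        loci = [(f"g{i}", 1, "+") for i in range(200)]
        # overall: 50% CDS; category 'negative' (first 100): 80 CDS
        regions = {}
        for i, l in enumerate(loci):
            if i < 100:
                regions[l] = "CDS" if i < 80 else "3UTR"
            else:
                regions[l] = "CDS" if i < 120 else "3UTR"
        labels = pd.Series(["negative"] * 100 + ["positive"] * 100,
                           index=pd.Index(loci, tupleize_cols=False))
        out = region_trend_test(labels, regions)
        row = out[(out["trend"] == "negative") & (out["region"] == "CDS")].iloc[0]
        k, n, p0 = 80, 100, 0.5
        # two-sided exact binomial: sum of outcomes no more likely than k
        pmf = binom.pmf(np.arange(n + 1), n, p0)
        p_exact = pmf[pmf <= pmf[k] * (1 + 1e-12)].sum()
        assert row["p"] == pytest.approx(p_exact, rel=1e-9)


class TestExpressionAssociation:
    def _table(self, rng, n=400):
        rna = rng.integers(100, 5000, size=n)
        te = rng.lognormal(0, 0.5, size=n)
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(n)],
            "rna_count": rna,
            "rpf_count": (rna * te).astype(int),
        })

    def test_boundary_of_read_inclusion_rule(self):
        df = pd.DataFrame({
            "gene_id": ["a", "b", "c", "d"],
            "rna_count": [60, 61, 500, 500],
            "rpf_count": [500, 500, 60, 400],
        })
        # 'a' (rna == 60) and 'c' (rpf == 60) fail "more than 60"
        res = expression_association({"b"}, df)
        assert len(res.site_values) == 1
        assert len(res.other_values) == 1
        with pytest.raises(ValueError):
            expression_association({"a"}, df)  # only excluded genes overlap

    def test_planted_low_te_shift_detected(self):
        rng = np.random.default_rng(6)
        df = self._table(rng)
        te = df["rpf_count"] / df["rna_count"]
        low = set(df.loc[te <= te.quantile(0.1), "gene_id"])
        res = expression_association(low, df)
        assert res.p < 1e-6
        assert res.site_values.mean() < res.other_values.mean()

    def test_null_rejection_rate_near_nominal(self):
        rng = np.random.default_rng(8)
        df = self._table(rng)
        rejections = 0
        reps = 200
        for _ in range(reps):
            genes = set(rng.choice(df["gene_id"], size=60, replace=False))
            rejections += expression_association(genes, df).p < 0.05
        assert rejections / reps <= 0.08

    def test_precomputed_measure_accepted(self):
        df = pd.DataFrame({"gene_id": ["a", "b", "c", "d"],
                           "measure": [1.0, 2.0, 3.0, 4.0]})
        res = expression_association({"a", "b"}, df)
        assert sorted(res.site_values) == [1.0, 2.0]
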
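"""Distances, PERMANOVA, ordination and the correlation screen."""

import math
from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import procrustes
from scipy.spatial.distance import pdist
from scipy.stats import spearmanr

import taxaflow as tf
from taxaflow.multivariate_stats import count_distinct_relabelings


def brute_force_permanova(d: np.ndarray, groups: list[str]):
    """Independent oracle: every distinct relabeling by direct enumeration.

    Enumerates all orderings of the label multiset, dedupes partitions that
    only swap equal-size group labels, and computes pseudo-F from the sum-of-
    squares definition written out longhand.
    """
    n = len(groups)

    def F(labels):
        labs = sorted(set(labels))
        g = len(labs)
        ss_total = sum(
            d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)
        ) / n
        ss_within = 0.0
        for lab in labs:
            idx = [i for i, l in enumerate(labels) if l == lab]
            ss_within += sum(
                d[i, j] ** 2
                for a, i in enumerate(idx)
                for j in idx[a + 1 :]
            ) / len(idx)
        ss_among = ss_total - ss_within
        if ss_within <= 0:
            return math.inf if ss_among > 0 else math.nan
        return (ss_among / (g - 1)) / (ss_within / (n - g))

    sizes = {lab: groups.count(lab) for lab in set(groups)}
    seen = set()
    stats = []
    for perm in set(permutations(groups)):
        # canonical partition key: frozenset of (size, members) blocks
        blocks = {}
        for i, lab in enumerate(perm):
            blocks.setdefault(lab, []).append(i)
        key = frozenset(
            (sizes[lab], frozenset(members)) for lab, members in blocks.items()
        )
        if key in seen:
            continue
        seen.add(key)
        stats.append(F(perm))
    f_obs = F(groups)
    hits = sum(1 for f in stats if f >= f_obs - 1e-12)
    return f_obs, hits / len(stats), len(stats)


class TestDistances:
    def test_bray_curtis_examples(self):
        d = tf.bray_curtis(np.array([[1.0, 2, 3], [1, 2, 3], [2, 1, 3]]))
        assert d.values[0, 1] == pytest.approx(0.0)
        assert d.values[0, 2] == pytest.approx(2 / 12)
        d2 = tf.bray_curtis(np.array([[1.0, 0], [0, 1]]))
        assert d2.values[0, 1] == pytest.approx(1.0)

    def test_bray_curtis_matches_direct_formula(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 10, size=(6, 8))
        d = tf.bray_curtis(x)
        for i in range(6):
            for j in range(6):
                expect = np.abs(x[i] - x[j]).sum() / (x[i] + x[j]).sum()
                assert d.values[i, j] == pytest.approx(expect)

    def test_bray_curtis_rejects_double_zero_pair(self):
        with pytest.raises(ValueError, match="all-zero"):
            tf.bray_curtis(np.array([[0.0, 0], [0, 0], [1, 1]]))

    def test_euclidean_examples(self):
        d = tf.euclidean(np.array([[0.0, 0], [3, 4]]))
        assert d.values[0, 1] == pytest.approx(5.0)

    def test_standardized_euclidean_is_unit_invariant(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(7, 4))
        y = x.copy()
        y[:, 2] *= 1000.0  # rescale one property's units
        a = tf.euclidean(x, standardize=True)
        b = tf.euclidean(y, standardize=True)
        assert np.allclose(a.values, b.values)


class TestPermanova:
    def test_two_groups_of_three_exact_p(self):
        pts = np.array([[1.0], [2.0], [3.0], [11.0], [12.0], [13.0]])
        d = tf.euclidean(pts)
        res = tf.permanova(d, ["a"] * 3 + ["b"] * 3)
        assert res.method == "exact"
        assert res.n_permutations_used == 10  # C(6,3)/2 unordered splits
        assert res.p_perm == pytest.approx(1 / 10)

    @pytest.mark.parametrize(
        "sizes",
        [(2, 2), (2, 3), (3, 3), (2, 2, 2), (2, 2, 3), (2, 3, 3), (4, 4), (2, 2, 4)],
    )
    def test_exact_p_equals_brute_force_oracle(self, sizes):
        rng = np.random.default_rng(sum(sizes) * 13 + len(sizes))
        n = sum(sizes)
        pts = rng.normal(size=(n, 3))
        d = tf.euclidean(pts)
        groups = [f"g{k}" for k, s in enumerate(sizes) for _ in range(s)]
        res = tf.permanova(d, groups, n_perm=99_999)
        f_o, p_o, total_o = brute_force_permanova(d.values, groups)
        assert res.method == "exact"
        assert res.pseudo_F == pytest.approx(f_o, rel=1e-9)
        assert res.n_permutations_used == total_o
        assert res.p_perm == pytest.approx(p_o, rel=1e-12)
        assert total_o == count_distinct_relabelings(list(sizes))

    def test_pseudo_F_matches_independent_implementation(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as skbio_permanova

        rng = np.random.default_rng(17)
        pts = rng.normal(size=(12, 5))
        pts[:6] += 1.5
        d = tf.euclidean(pts)
        groups = ["a"] * 6 + ["b"] * 6
        res = tf.permanova(d, groups, n_perm=999, seed=0)
        sk = skbio_permanova(
            skbio.DistanceMatrix(d.values, ids=list(d.ids)), grouping=groups,
            permutations=0,
        )
        assert res.pseudo_F == pytest.approx(float(sk["test statistic"]), rel=1e-9)

    def test_group_label_names_do_not_matter(self):
        rng = np.random.default_rng(23)
        d = tf.euclidean(rng.normal(size=(9, 2)))
        g1 = ["x"] * 3 + ["y"] * 3 + ["z"] * 3
        g2 = ["z"] * 3 + ["x"] * 3 + ["y"] * 3
        assert tf.permanova(d, g1).pseudo_F == pytest.approx(
            tf.permanova(d, g2).pseudo_F
        )

    def test_identical_points_flagged_degenerate(self):
        d = tf.DistanceMatrix(np.zeros((6, 6)), tuple("abcdef"))
        res = tf.permanova(d, ["a"] * 3 + ["b"] * 3)
        assert res.degenerate and res.p_perm == 1.0

    def test_single_group_rejected(self):
        d = tf.euclidean(np.random.default_rng(0).normal(size=(4, 2)))
        with pytest.raises(ValueError, match="two groups"):
            tf.permanova(d, ["a"] * 4)

    def test_type_one_error_calibrated(self):
        # 7 groups x 3 replicates of i.i.d. features: rejection rate at
        # alpha=0.05 should sit near 0.05 (uniform null p-values)
        rng = np.random.default_rng(2024)
        groups = [f"t{k}" for k in range(7) for _ in range(3)]
        rejections = 0
        n_sims = 200
        for _ in range(n_sims):
            pts = rng.normal(size=(21, 10))
            d = tf.euclidean(pts)
            res = tf.permanova(d, groups, n_perm=999, seed=rng.integers(2**31))
            if res.p_perm < 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_sims <= 0.08


class TestPairwise:
    def test_three_vs_three_triggers_montecarlo(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(21, 4))
        groups = [f"t{k}" for k in range(7) for _ in range(3)]
        out = tf.pairwise_permanova(tf.euclidean(pts), groups, seed=0)
        assert len(out) == 21  # C(7,2) pairs
        assert (out["n_free_permutations"] == 10).all()
        assert out["p_montecarlo"].notna().all()

    def test_identical_groups_not_significant(self):
        pts = np.array([[0.0, 0], [1, 1], [2, 2], [0, 0], [1, 1], [2, 2]])
        out = tf.pairwise_permanova(
            tf.euclidean(pts), ["a"] * 3 + ["b"] * 3, seed=0
        )
        row = out.iloc[0]
        assert row["pseudo_t"] == pytest.approx(0.0, abs=1e-9)
        assert row["p_perm"] == pytest.approx(1.0)

    def test_pair_results_match_permanova_on_submatrix(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(9, 3))
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        d = tf.euclidean(pts)
        out = tf.pairwise_permanova(d, groups, seed=1)
        for _, row in out.iterrows():
            keep = [i for i, g in enumerate(groups) if g in (row.group1, row.group2)]
            sub = d.submatrix([d.ids[i] for i in keep])
            res = tf.permanova(sub, [groups[i] for i in keep], seed=1)
            assert row.pseudo_F == pytest.approx(res.pseudo_F, rel=1e-9)
            assert row.p_perm == pytest.approx(res.p_perm)


class TestPcoa:
    def test_collinear_points_one_axis(self):
        pts = np.array([[0.0], [1.0], [2.0], [5.0]])
        res = tf.pcoa(tf.euclidean(pts))
        assert res.percent_variance[0] == pytest.approx(100.0)

    def test_three_equidistant_points_split_evenly(self):
        d = tf.DistanceMatrix(np.array([[0.0, 1, 1], [1, 0, 1], [1, 1, 0]]),
                              ("a", "b", "c"))
        res = tf.pcoa(d)
        assert res.percent_variance[:2] == pytest.approx([50.0, 50.0])

    def test_round_trip_recovers_configuration(self):
        rng = np.random.default_rng(12)
        pts = rng.normal(size=(15, 2))
        res = tf.pcoa(tf.euclidean(pts))
        _, _, disparity = procrustes(pts, res.coordinates[:, :2])
        rms = math.sqrt(disparity)
        assert rms < 1e-8

    def test_variance_fractions_match_classical_pca(self):
        rng = np.random.default_rng(13)
        pts = rng.normal(size=(10, 4)) @ np.diag([3.0, 2.0, 1.0, 0.5])
        res = tf.pcoa(tf.euclidean(pts))
        cov = np.cov(pts, rowvar=False)
        lam = np.sort(np.linalg.eigvalsh(cov))[::-1]
        pca_frac = 100 * lam / lam.sum()
        assert np.allclose(res.percent_variance[:4], pca_frac, atol=1e-9)

    def test_matches_independent_implementation(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(14)
        d = tf.bray_curtis(rng.uniform(0.1, 5, size=(8, 6)))
        ours = tf.pcoa(d)
        theirs = skbio_pcoa(skbio.DistanceMatrix(d.values, ids=list(d.ids)))
        n_pos = len(ours.percent_variance)
        ours_frac = ours.percent_variance / 100
        theirs_frac = theirs.proportion_explained.to_numpy()[:n_pos]
        # same spectrum, up to skbio's choice of variance denominator
        assert np.allclose(
            ours_frac / ours_frac.sum(), theirs_frac / theirs_frac.sum(), atol=1e-8
        )


class TestNmds:
    def test_embeddable_distances_reach_near_zero_stress(self):
        rng = np.random.default_rng(15)
        pts = rng.normal(size=(12, 2))
        res = tf.nmds(tf.euclidean(pts), k=2, seed=0)
        assert res.stress < 0.01

    def test_stress_sequence_monotone_non_increasing(self):
        rng = np.random.default_rng(16)
        d = tf.bray_curtis(rng.uniform(0.1, 5, size=(10, 6)))
        res = tf.nmds(d, k=2, seed=0)
        hist = res.stress_history
        assert hist and all(b <= a + 1e-12 for a, b in zip(hist, hist[1:]))

    def test_known_layout_recovered_in_rank_order(self):
        rng = np.random.default_rng(17)
        pts = rng.normal(size=(10, 2))
        res = tf.nmds(tf.euclidean(pts), k=2, seed=0)
        rho = spearmanr(pdist(pts), pdist(res.coordinates)).statistic
        assert rho > 0.99


class TestCorrelationScreen:
    def _screen(self, x, y):
        md = tf.SampleMetadata.from_design(["T"], len(x))
        table = tf.UnstratifiedTable(
            pd.DataFrame([x], index=["gene1"], columns=list(md.sample_ids)).astype(
                float
            )
        )
        props = tf.SoilProperties(
            pd.DataFrame(
                {"prop": y}, index=pd.Index(md.sample_ids, name="sample_id")
            ).astype(float)
        )
        return tf.correlation_screen(props, table)

    def test_self_correlation(self):
        out = self._screen([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert out.loc[0, "r"] == pytest.approx(1.0)
        assert out.loc[0, "significant"]

    def test_anti_correlation(self):
        out = self._screen([1, 2, 3, 4, 5], [-1, -2, -3, -4, -5])
        assert out.loc[0, "r"] == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # r = 10 / sqrt(10 * 14.8) = 0.8220 by direct arithmetic
        out = self._screen([1, 2, 3, 4, 5], [2, 1, 4, 3, 6])
        assert out.loc[0, "r"] == pytest.approx(0.8220, abs=5e-5)

    def test_zero_variance_flagged(self):
        out = self._screen([1, 2, 3, 4, 5], [2, 2, 2, 2, 2])
        assert np.isnan(out.loc[0, "r"]) and out.loc[0, "note"] == "undefined"

    def test_pairwise_complete_with_missing(self):
        md = tf.SampleMetadata.from_design(["T"], 6)
        table = tf.UnstratifiedTable(
            pd.DataFrame(
                [[1, 2, 3, 4, 5, 6]], index=["g"], columns=list(md.sample_ids)
            ).astype(float)
        )
        y = pd.DataFrame(
            {"p": [1, 2, 3, 4, 5, np.nan]},
            index=pd.Index(md.sample_ids, name="sample_id"),
        )
        out = tf.correlation_screen(tf.SoilProperties(y), table)
        assert out.loc[0, "n"] == 5
        assert out.loc[0, "r"] == pytest.approx(1.0)
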
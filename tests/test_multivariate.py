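import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_matrix
from oracles import brute_anosim_r, exhaustive_anosim_p, random_dissimilarity
from pmfvar.multivariate import (
    VERY_LARGE,
    DissimilarityMatrix,
    SimperResult,
    anosim,
    anosim_r,
    bray_curtis,
    kruskal_stress,
    nmds,
    pairwise_anosim,
    simper_between,
    simper_within,
    top_contributors,
)


def dis_from_pairs(n, pair_values, samples=None):
    """Build a DissimilarityMatrix from {(i, j): d} upper-triangle values."""
    d = np.zeros((n, n))
    for (i, j), v in pair_values.items():
        d[i, j] = d[j, i] = v
    return DissimilarityMatrix(
        samples=samples or [f"s{i}" for i in range(n)], d=d
    )


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        mat = make_matrix([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        dis = bray_curtis(mat)
        assert dis.d[0, 1] == pytest.approx(0.0)

    def test_disjoint_support_is_100(self):
        mat = make_matrix([[5.0, 0.0], [0.0, 3.0]])
        assert bray_curtis(mat).d[0, 1] == pytest.approx(100.0)

    def test_hand_example(self):
        # x=(4,1,0), y=(1,1,3): 100*(3+0+3)/(5+2+3) = 60
        mat = make_matrix([[4.0, 1.0, 0.0], [1.0, 1.0, 3.0]])
        assert bray_curtis(mat).d[0, 1] == pytest.approx(60.0)

    def test_all_zero_sample_errors(self):
        mat = make_matrix([[1.0, 1.0], [2.0, 0.0]])
        mat.values[0] = 0.0  # bypass constructor check deliberately
        with pytest.raises(ValueError, match="s00"):
            bray_curtis(mat)

    def test_matches_scipy_scaled(self, rng):
        from scipy.spatial.distance import braycurtis

        mat = make_matrix(rng.uniform(0.1, 10, size=(5, 12)))
        dis = bray_curtis(mat)
        for i, j in itertools.combinations(range(5), 2):
            expected = 100 * braycurtis(mat.values[i], mat.values[j])
            assert dis.d[i, j] == pytest.approx(expected)


class TestAnosim:
    def test_perfect_separation_R_is_1(self):
        dis = dis_from_pairs(4, {(0, 1): 1, (2, 3): 2, (0, 2): 3, (0, 3): 4,
                                 (1, 2): 5, (1, 3): 6})
        labels = ["A", "A", "B", "B"]
        assert anosim_r(dis, labels) == pytest.approx(1.0)

    def test_hand_midrank_example(self):
        # within {3,5}, between {1,2,4,6}: R = (3.25 - 4)/3 = -0.25
        dis = dis_from_pairs(4, {(0, 1): 3, (2, 3): 5, (0, 2): 1, (0, 3): 2,
                                 (1, 2): 4, (1, 3): 6})
        labels = ["A", "A", "B", "B"]
        assert anosim_r(dis, labels) == pytest.approx(-0.25)

    def test_sig_percent_convention(self, rng):
        dis = DissimilarityMatrix(
            samples=[f"s{i}" for i in range(8)], d=random_dissimilarity(8, rng)
        )
        labels = ["A"] * 4 + ["B"] * 4
        res = anosim(dis, labels, n_permutations=99, seed=5)
        assert res.sig_percent == pytest.approx(
            100.0 * (res.n_ge_observed + 1) / (res.n_permutations + 1)
        )

    def test_single_sample_group_errors(self, rng):
        dis = DissimilarityMatrix(
            samples=[f"s{i}" for i in range(3)], d=random_dissimilarity(3, rng)
        )
        with pytest.raises(ValueError, match="single sample"):
            anosim(dis, ["A", "A", "B"], n_permutations=9, seed=0)

    def test_degenerate_equal_dissimilarities(self, caplog):
        d = np.full((4, 4), 50.0)
        np.fill_diagonal(d, 0.0)
        dis = DissimilarityMatrix(samples=list("abcd"), d=d)
        with caplog.at_level("WARNING"):
            res = anosim(dis, ["A", "A", "B", "B"], n_permutations=19, seed=0)
        assert res.R == 0.0
        assert "equal" in caplog.text

    def test_seed_reproducibility(self, rng):
        dis = DissimilarityMatrix(
            samples=[f"s{i}" for i in range(8)], d=random_dissimilarity(8, rng)
        )
        labels = ["A"] * 4 + ["B"] * 4
        a = anosim(dis, labels, n_permutations=199, seed=11)
        b = anosim(dis, labels, n_permutations=199, seed=11)
        assert a.n_ge_observed == b.n_ge_observed

    def test_rank_invariance_under_monotone_transform(self, rng):
        for _ in range(10):
            d = random_dissimilarity(7, rng)
            labels = rng.permutation(["A"] * 3 + ["B"] * 2 + ["C"] * 2)
            dis1 = DissimilarityMatrix([f"s{i}" for i in range(7)], d)
            # strictly increasing map into [0, 100]
            d2 = 100 * (np.sqrt(d / 100.0))
            np.fill_diagonal(d2, 0.0)
            dis2 = DissimilarityMatrix([f"s{i}" for i in range(7)], d2)
            assert anosim_r(dis1, labels) == pytest.approx(
                anosim_r(dis2, labels), abs=1e-12
            )

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            d = random_dissimilarity(8, rng)
            labels = list(rng.permutation(["A"] * 3 + ["B"] * 3 + ["C"] * 2))
            dis = DissimilarityMatrix([f"s{i}" for i in range(8)], d)
            assert anosim_r(dis, labels) == pytest.approx(
                brute_anosim_r(d, labels), abs=1e-12
            )

    def test_matches_scikit_bio(self, rng):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        for _ in range(5):
            d = random_dissimilarity(9, rng)
            labels = list(rng.permutation(["A"] * 3 + ["B"] * 3 + ["C"] * 3))
            dm = skbio_distance.DistanceMatrix(d, [f"s{i}" for i in range(9)])
            expected = skbio_distance.anosim(
                dm, grouping=labels, permutations=0
            )["test statistic"]
            dis = DissimilarityMatrix([f"s{i}" for i in range(9)], d)
            assert anosim_r(dis, labels) == pytest.approx(expected, abs=1e-12)

    def test_sampled_p_tracks_exhaustive_p(self, rng):
        d = random_dissimilarity(6, rng)
        labels = ["A", "A", "A", "B", "B", "B"]
        p_exact = exhaustive_anosim_p(d, labels)
        dis = DissimilarityMatrix([f"s{i}" for i in range(6)], d)
        res = anosim(dis, labels, n_permutations=999, seed=21)
        p_sampled = res.sig_percent / 100.0
        se = np.sqrt(p_exact * (1 - p_exact) / 999)
        assert abs(p_sampled - p_exact) < 4 * se + 2 / 999


class TestPairwiseAnosim:
    def test_possible_perms_binomial(self, rng):
        d = random_dissimilarity(4, rng)
        dis = DissimilarityMatrix([f"s{i}" for i in range(4)], d)
        (res,) = pairwise_anosim(dis, ["A", "A", "B", "B"],
                                 n_permutations=9, seed=0)
        assert res.possible_perms == 6  # C(4,2)

    def test_three_groups_three_results(self, rng):
        d = random_dissimilarity(6, rng)
        dis = DissimilarityMatrix([f"s{i}" for i in range(6)], d)
        res = pairwise_anosim(dis, ["A", "A", "B", "B", "C", "C"],
                              n_permutations=9, seed=0)
        assert [r.groups for r in res] == [("A", "B"), ("A", "C"), ("B", "C")]

    def test_identical_clone_groups(self):
        values = np.tile([5.0, 1.0, 2.0], (4, 1))
        mat = make_matrix(values, labels=["A", "A", "B", "B"])
        dis = bray_curtis(mat)
        (res,) = pairwise_anosim(dis, ["A", "A", "B", "B"],
                                 n_permutations=99, seed=1)
        assert res.R == pytest.approx(0.0)
        assert res.sig_percent == pytest.approx(100.0)

    def test_very_large_sentinel(self, rng):
        n = 42
        d = random_dissimilarity(n, rng)
        dis = DissimilarityMatrix([f"s{i}" for i in range(n)], d)
        res = pairwise_anosim(dis, ["A"] * 21 + ["B"] * 21,
                              n_permutations=9, seed=0)
        assert res[0].possible_perms == VERY_LARGE


class TestSimper:
    def test_within_hand_example(self):
        # group of (4,0) and (2,2): similarity 50; contributions 50 and 0
        mat = make_matrix([[4.0, 0.0], [2.0, 2.0]], labels=["A", "A"])
        (res,) = simper_within(mat)
        assert res.average_score == pytest.approx(50.0)
        tbl = res.table.set_index("feature_mz")["contribution"]
        assert tbl[1000.0] == pytest.approx(50.0)
        assert tbl[1010.0] == pytest.approx(0.0)

    def test_within_identical_samples_100(self):
        mat = make_matrix([[3.0, 1.0], [3.0, 1.0]], labels=["A", "A"])
        (res,) = simper_within(mat)
        assert res.average_score == pytest.approx(100.0)

    def test_between_hand_example(self):
        # (4,0) vs (2,2) across groups: dissimilarity 50, 25 per feature
        mat = make_matrix([[4.0, 0.0], [2.0, 2.0]], labels=["A", "B"])
        (res,) = simper_between(mat)
        assert res.average_score == pytest.approx(50.0)
        np.testing.assert_allclose(res.table["contribution"], [25.0, 25.0])

    def test_between_disjoint_support_100(self):
        mat = make_matrix(
            [[4.0, 1.0, 0.0, 0.0], [2.0, 2.0, 0.0, 0.0],
             [0.0, 0.0, 3.0, 1.0], [0.0, 0.0, 1.0, 1.0]],
            labels=["A", "A", "B", "B"],
        )
        (res,) = simper_between(mat)
        assert res.average_score == pytest.approx(100.0)

    def test_contributions_sum_to_group_mean_similarity(self, rng):
        values = rng.uniform(0, 10, size=(9, 15))
        labels = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        mat = make_matrix(values, labels=labels)
        dis = bray_curtis(mat)
        sim = 100.0 - dis.d
        for res in simper_within(mat):
            idx = [i for i, g in enumerate(labels) if g == res.scope]
            pair_sims = [sim[i, j] for i, j in itertools.combinations(idx, 2)]
            assert res.average_score == pytest.approx(
                np.mean(pair_sims), rel=1e-9
            )
            assert res.table["contribution"].sum() == pytest.approx(
                res.average_score, rel=1e-9
            )

    def test_between_sums_to_group_mean_dissimilarity(self, rng):
        values = rng.uniform(0, 10, size=(6, 8))
        labels = ["A"] * 3 + ["B"] * 3
        mat = make_matrix(values, labels=labels)
        dis = bray_curtis(mat)
        (res,) = simper_between(mat)
        cross = [dis.d[i, j] for i in range(3) for j in range(3, 6)]
        assert res.average_score == pytest.approx(np.mean(cross), rel=1e-9)
        assert res.table["contribution"].sum() == pytest.approx(
            res.average_score, rel=1e-9
        )

    def test_cumulative_pct_monotone_ends_at_100(self, rng):
        values = rng.uniform(0, 10, size=(4, 10))
        mat = make_matrix(values, labels=["A", "A", "B", "B"])
        for res in simper_within(mat) + simper_between(mat):
            cum = res.table["cumulative_pct"].to_numpy()
            assert np.all(np.diff(cum) >= -1e-12)
            assert cum[-1] == pytest.approx(100.0)

    def test_singleton_group_skipped_with_warning(self, caplog):
        mat = make_matrix([[1.0, 2.0], [2.0, 1.0], [3.0, 1.0]],
                          labels=["A", "A", "B"])
        with caplog.at_level("WARNING"):
            res = simper_within(mat)
        assert [r.scope for r in res] == ["A"]
        assert "B" in caplog.text

    def test_zero_sd_reports_inf_ratio(self):
        mat = make_matrix([[4.0, 1.0], [4.0, 1.0]], labels=["A", "A"])
        (res,) = simper_within(mat)
        assert np.all(np.isinf(res.table["ratio"]))


def simper_from_contributions(contribs, features=None):
    contribs = np.asarray(contribs, dtype=float)
    if features is None:
        features = 1000.0 + 10 * np.arange(len(contribs))
    order = np.lexsort((features, -contribs))
    c = contribs[order]
    pct = c / c.sum() * 100
    table = pd.DataFrame({
        "feature_mz": np.asarray(features)[order],
        "contribution": c,
        "contribution_pct": pct,
        "cumulative_pct": np.cumsum(pct),
        "ratio": np.ones_like(c),
    })
    return SimperResult(scope="A", kind="similarity",
                        average_score=float(c.sum()), table=table,
                        n_pairs=1)


class TestTopContributors:
    def test_basic_cutoff(self):
        res = simper_from_contributions([50.0, 30.0, 20.0])
        top = top_contributors(res, 70.0)
        assert len(top) == 2
        np.testing.assert_allclose(top["contribution"], [50.0, 30.0])

    def test_cutoff_100_returns_all(self):
        res = simper_from_contributions([50.0, 30.0, 20.0])
        assert len(top_contributors(res, 100.0)) == 3

    def test_tie_broken_by_ascending_mz(self):
        res = simper_from_contributions([40.0, 40.0, 20.0],
                                        features=[1200.0, 1100.0, 1000.0])
        top = top_contributors(res, 50.0)
        assert len(top) == 2
        assert list(top["feature_mz"]) == [1100.0, 1200.0]

    def test_invalid_cutoff(self):
        res = simper_from_contributions([60.0, 40.0])
        with pytest.raises(ValueError):
            top_contributors(res, 0.0)
        with pytest.raises(ValueError):
            top_contributors(res, 101.0)


class TestNmds:
    def test_equilateral_near_zero_stress(self):
        d = np.full((3, 3), 50.0)
        np.fill_diagonal(d, 0.0)
        dis = DissimilarityMatrix(list("abc"), d)
        res = nmds(dis, k=2, n_restarts=8, seed=1)
        assert res.stress < 0.01

    def test_deterministic_given_seed(self, rng):
        dis = DissimilarityMatrix(
            [f"s{i}" for i in range(6)], random_dissimilarity(6, rng)
        )
        a = nmds(dis, k=2, n_restarts=4, seed=9)
        b = nmds(dis, k=2, n_restarts=4, seed=9)
        np.testing.assert_allclose(a.coordinates, b.coordinates)

    def test_stress_invariant_to_doubling(self, rng):
        d = random_dissimilarity(7, rng) / 2.0  # keep doubled version <= 100
        dis1 = DissimilarityMatrix([f"s{i}" for i in range(7)], d)
        dis2 = DissimilarityMatrix([f"s{i}" for i in range(7)], d * 2.0)
        a = nmds(dis1, k=2, n_restarts=4, seed=3)
        b = nmds(dis2, k=2, n_restarts=4, seed=3)
        assert a.stress == pytest.approx(b.stress, abs=1e-8)

    def test_coordinates_centered(self, rng):
        dis = DissimilarityMatrix(
            [f"s{i}" for i in range(6)], random_dissimilarity(6, rng)
        )
        res = nmds(dis, k=2, n_restarts=4, seed=2)
        np.testing.assert_allclose(res.coordinates.mean(axis=0), 0.0,
                                   atol=1e-12)

    def test_kruskal_stress_zero_for_perfect_embedding(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0], [3.0, 1.0]])
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(pts))
        dis = DissimilarityMatrix([f"s{i}" for i in range(4)], d)
        assert kruskal_stress(dis, pts) == pytest.approx(0.0, abs=1e-12)

    def test_non_finite_errors(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError):
            DissimilarityMatrix(list("abc"), d)
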
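"""The community-analysis engine: recoding, dissimilarity, PAVA, NMDS,
MRPP, UPGMA and set overlaps."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from porelist.community import (
    DissimilarityMatrix,
    bonferroni,
    bray_curtis,
    filter_single_habitat_species,
    habitat_matrix,
    mrpp,
    nmds,
    overlap_counts,
    pava_monotone,
    three_class_recode,
    upgma,
)
from porelist.records import band_count


def random_dissimilarity(rng, n):
    X = rng.uniform(size=(n, 4))
    from scipy.spatial.distance import pdist, squareform

    return DissimilarityMatrix([f"s{i}" for i in range(n)],
                               squareform(pdist(X)))


class TestRecode:
    @pytest.mark.parametrize("count,expected", [
        (0, 0), (1, 1), (2, 2), (57, 2),
    ])
    def test_scale(self, count, expected):
        assert three_class_recode(count) == expected

    def test_censored_banded_count_implies_more_than_one(self):
        assert three_class_recode(band_count(150)) == 2

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            three_class_recode(-1)

    def test_habitat_matrix_values_bounded(self, default_sim):
        _, _, records = default_sim
        hm = habitat_matrix(records)
        assert hm.to_numpy().min() >= 0 and hm.to_numpy().max() <= 2


class TestFilterSingleHabitat:
    def test_filtering(self):
        counts = pd.DataFrame(
            {"h1": [3, 1, 0], "h2": [0, 2, 1]}, index=["only1", "both", "only2"])
        filtered, removed = filter_single_habitat_species(counts)
        assert removed == ["only1", "only2"]
        assert list(filtered.index) == ["both"]


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        dm = bray_curtis(np.array([[1, 2, 3], [1, 2, 3]]))
        assert dm.D[0, 1] == pytest.approx(0.0)

    def test_disjoint_rows_one(self):
        dm = bray_curtis(np.array([[1, 0], [0, 5]]))
        assert dm.D[0, 1] == pytest.approx(1.0)

    def test_hand_value(self):
        dm = bray_curtis(np.array([[2, 1, 0], [0, 1, 2]]))
        assert dm.D[0, 1] == pytest.approx(4 / 6)

    def test_all_zero_row_errors_with_name(self):
        with pytest.raises(ValueError, match="empty_sample"):
            bray_curtis(np.array([[1, 1], [0, 0]]), labels=["ok", "empty_sample"])

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis(np.array([[1, -1], [1, 1]]))

    @given(hnp.arrays(float, (4, 5), elements=st.integers(0, 20).map(float)))
    @settings(max_examples=50, deadline=None)
    def test_matches_naive_double_loop(self, X):
        X = X + 0.1  # avoid all-zero rows
        dm = bray_curtis(X)
        for i in range(4):
            for j in range(4):
                naive = np.abs(X[i] - X[j]).sum() / (X[i] + X[j]).sum()
                assert dm.D[i, j] == pytest.approx(naive)


class TestPava:
    def test_monotone_input_unchanged(self):
        y = [1.0, 2.0, 2.0, 5.0]
        assert pava_monotone(y) == pytest.approx(y)

    def test_pooling_average(self):
        assert pava_monotone([3.0, 1.0]) == pytest.approx([2.0, 2.0])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=30)
        once = pava_monotone(y)
        assert pava_monotone(once) == pytest.approx(once)

    def test_weighted_pooling(self):
        # block average with weights 3:1 -> (3*4 + 1*0)/4 = 3
        assert pava_monotone([4.0, 0.0], weights=[3.0, 1.0]) == \
            pytest.approx([3.0, 3.0])

    def test_against_scipy_isotonic(self):
        from scipy.optimize import isotonic_regression

        rng = np.random.default_rng(1)
        for _ in range(20):
            y = rng.normal(size=25)
            w = rng.uniform(0.5, 2.0, size=25)
            ref = isotonic_regression(y, weights=w).x
            assert pava_monotone(y, w) == pytest.approx(ref)

    def test_against_quadratic_program_on_short_inputs(self):
        # brute-force the least-squares monotone fit with SLSQP
        from scipy.optimize import minimize

        rng = np.random.default_rng(2)
        for n in (2, 3, 4, 5, 6):
            y = rng.normal(size=n)
            cons = [{"type": "ineq", "fun": (lambda x, i=i: x[i + 1] - x[i])}
                    for i in range(n - 1)]
            ref = minimize(lambda x: np.sum((x - y) ** 2), y,
                           constraints=cons, method="SLSQP",
                           options={"ftol": 1e-12, "maxiter": 500}).x
            assert pava_monotone(y) == pytest.approx(ref, abs=1e-5)


class TestNmds:
    def test_three_points_embed_exactly(self):
        D = DissimilarityMatrix(
            ["a", "b", "c"],
            np.array([[0, .3, .5], [.3, 0, .4], [.5, .4, 0]]))
        res = nmds(D, k=2, n_starts=5, seed=0)
        assert res.stress <= 1e-6

    def test_euclidean_input_near_zero_stress(self):
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(3)
        pts = rng.uniform(size=(12, 2))
        D = DissimilarityMatrix([str(i) for i in range(12)],
                                squareform(pdist(pts)))
        res = nmds(D, k=2, n_starts=10, seed=0)
        assert res.stress <= 1e-4

    def test_too_few_samples_errors(self):
        D = DissimilarityMatrix(["a", "b"], np.array([[0, 1.], [1., 0]]))
        with pytest.raises(ValueError):
            nmds(D, k=2)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(4)
        D = random_dissimilarity(rng, 10)
        r1 = nmds(D, seed=11, n_starts=4)
        r2 = nmds(D, seed=11, n_starts=4)
        assert np.array_equal(r1.configuration, r2.configuration)
        assert r1.stress == r2.stress

    def test_axis_one_carries_maximal_variance(self):
        rng = np.random.default_rng(5)
        D = random_dissimilarity(rng, 12)
        res = nmds(D, seed=0, n_starts=5)
        var = res.configuration.var(axis=0)
        assert var[0] >= var[1]

    def test_final_stress_not_worse_than_metric_start(self):
        from porelist.community import _metric_start, _stress1, pava_monotone
        from scipy.spatial.distance import pdist

        rng = np.random.default_rng(6)
        D = random_dissimilarity(rng, 10)
        res = nmds(D, seed=0, n_starts=3)
        X0 = _metric_start(D.D, 2)
        d = pdist(X0)
        order = np.argsort(D.condensed(), kind="stable")
        dhat = np.empty_like(d)
        dhat[order] = pava_monotone(d[order])
        assert res.stress <= _stress1(d, dhat) + 1e-12


class TestMrpp:
    def test_singleton_group_errors(self):
        rng = np.random.default_rng(0)
        D = random_dissimilarity(rng, 5)
        with pytest.raises(ValueError):
            mrpp(D, ["a", "a", "a", "a", "b"])

    def test_exact_flag_for_small_designs(self):
        rng = np.random.default_rng(1)
        D = random_dissimilarity(rng, 6)
        res = mrpp(D, ["a"] * 3 + ["b"] * 3)
        assert res.exact and res.B == 20

    def test_montecarlo_within_binomial_error_of_exact(self):
        rng = np.random.default_rng(2)
        D = random_dissimilarity(rng, 10)
        groups = ["a"] * 5 + ["b"] * 5
        exact = mrpp(D, groups, method="exact")
        mc = mrpp(D, groups, method="montecarlo", B=9999, seed=0)
        se = np.sqrt(exact.p_raw * (1 - exact.p_raw) / 9999)
        assert abs(mc.p_raw - exact.p_raw) < 4 * se + 1e-4

    def test_separated_clusters_attain_minimal_p(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.uniform(0, 0.1, (8, 3)),
                       rng.uniform(10, 10.1, (8, 3))])
        dm = bray_curtis(X)
        res = mrpp(dm, ["a"] * 8 + ["b"] * 8, B=199, seed=1,
                   method="montecarlo")
        assert res.p_raw == pytest.approx(1 / 200)
        assert res.A > 0.5

    def test_a_statistic_sign(self):
        # grouped structure gives A > 0; A is bounded by 1
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(5, 0.1, (6, 4)), rng.normal(9, 0.1, (6, 4))])
        dm = bray_curtis(np.abs(X))
        res = mrpp(dm, ["a"] * 6 + ["b"] * 6)
        assert 0 < res.A <= 1


class TestBonferroni:
    @pytest.mark.parametrize("p,m,expected", [
        (0.02, 3, 0.06), (0.5, 3, 1.0), (0.3, 1, 0.3),
    ])
    def test_adjustment(self, p, m, expected):
        assert bonferroni(p, m) == pytest.approx(expected)

    def test_vector_input(self):
        out = bonferroni([0.01, 0.9], 2)
        assert out == pytest.approx([0.02, 1.0])


class TestUpgma:
    def test_zero_distance_pair_merges_first(self):
        D = DissimilarityMatrix(
            ["a", "b", "c"], np.array([[0, 0, .5], [0, 0, .6], [.5, .6, 0]]))
        d = upgma(D)
        assert d.merges[0] == (0, 1, 0.0)

    def test_three_leaf_hand_trace(self):
        D = DissimilarityMatrix(
            ["a", "b", "c"],
            np.array([[0, .2, .6], [.2, 0, .8], [.6, .8, 0]]))
        d = upgma(D)
        assert d.merges[0] == (0, 1, pytest.approx(0.2))
        assert d.merges[1] == (2, 3, pytest.approx(0.7))

    def test_cophenetic_ultrametric_inequality(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(3, 8))
            D = random_dissimilarity(rng, n)
            C = upgma(D).cophenetic_matrix()
            for i, j, k in itertools.combinations(range(n), 3):
                assert C[i, j] <= max(C[i, k], C[j, k]) + 1e-9

    def test_matches_scipy_average_linkage(self):
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(8)
        for _ in range(20):
            D = random_dissimilarity(rng, 9)
            mine = upgma(D).cophenetic_matrix()
            ref = squareform(cophenet(linkage(D.condensed(), method="average")))
            assert mine == pytest.approx(ref)

    def test_ultrametric_input_is_fixed_point(self):
        rng = np.random.default_rng(9)
        D0 = random_dissimilarity(rng, 7)
        ultra = upgma(D0).cophenetic_matrix()
        again = upgma(DissimilarityMatrix(D0.labels, ultra)).cophenetic_matrix()
        assert again == pytest.approx(ultra)

    def test_newick_halving_option(self):
        D = DissimilarityMatrix(
            ["a", "b"], np.array([[0, 0.4], [0.4, 0]]))
        assert upgma(D).to_newick(halve_heights=True) == "(a:0.2,b:0.2);"

    def test_cut_into_clusters(self):
        D = DissimilarityMatrix(
            ["a", "b", "c", "d"],
            np.array([[0, .1, .9, .9], [.1, 0, .9, .9],
                      [.9, .9, 0, .2], [.9, .9, .2, 0]]))
        labels = upgma(D).cut(2)
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]


class TestOverlapCounts:
    def test_set_algebra_example(self):
        rep = overlap_counts({"A": ["s1", "s2"], "B": ["s2"]}, [("A", "B")])
        entry = rep.entries[0]
        assert entry.n_in_all == 1 and entry.n_unique == 1

    def test_singleton_combination(self):
        rep = overlap_counts({"A": ["s1", "s2"], "B": ["s2", "s3"]}, [("A",)])
        assert rep.entries[0].n_in_all == 2
        assert rep.entries[0].n_unique == 1  # s1 is found nowhere else

    def test_unknown_type_errors(self):
        with pytest.raises(ValueError):
            overlap_counts({"A": ["s1"]}, [("A", "Z")])

    def test_against_membership_scan_oracle(self):
        rng = np.random.default_rng(10)
        species = [f"sp{i}" for i in range(40)]
        lists = {t: {s for s in species if rng.random() < 0.3}
                 for t in "ABCD"}
        combos = [("A",), ("A", "B"), ("B", "C", "D")]
        rep = overlap_counts(lists, combos)
        for entry in rep.entries:
            in_all = [s for s in species
                      if all(s in lists[t] for t in entry.combination)]
            unique = [s for s in in_all
                      if not any(s in lists[t] for t in lists
                                 if t not in entry.combination)]
            assert entry.n_in_all == len(in_all)
            assert entry.n_unique == len(unique)
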
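import itertools
import math

import numpy as np
import pandas as pd
import pytest

from hotcomp.comparison import (
    build_consensus,
    count_sharing_sets,
    fisher_overlap,
    hotspot_count_regression,
    hypergeom_right_tail,
    jaccard_distance_matrix,
    mantel_test,
    merge_intervals,
    ubiquitous_hotspots,
)
from hotcomp.io_formats import GenomeLayout, Interval


def iv(start, end, chrom="chr1"):
    return Interval(chrom, start, end)


class TestConsensus:
    def test_two_population_merge(self):
        sharing = build_consensus({"A": [iv(0, 100)], "B": [iv(50, 150)]})
        assert sharing.consensus == [iv(0, 150)]
        assert sharing.matrix.values.all()

    def test_disjoint_hotspots(self):
        sharing = build_consensus(
            {"A": [iv(0, 100)], "B": [iv(200, 300)]}
        )
        assert len(sharing.consensus) == 2
        m = sharing.matrix
        assert m.values.sum() == 2
        assert m.loc["A", "chr1:0-100"]
        assert m.loc["B", "chr1:200-300"]

    def test_chained_overlap_transitive(self):
        sharing = build_consensus(
            {
                "A": [iv(0, 100)],
                "B": [iv(90, 200)],
                "C": [iv(190, 300)],
            }
        )
        assert sharing.consensus == [iv(0, 300)]
        assert sharing.matrix.values.all()

    def test_touching_intervals_not_merged(self):
        merged = merge_intervals([iv(0, 100), iv(100, 200)])
        assert merged == [iv(0, 100), iv(100, 200)]

    def test_idempotent(self):
        sets = {
            "A": [iv(0, 100), iv(500, 700)],
            "B": [iv(50, 150), iv(900, 1000)],
        }
        first = build_consensus(sets)
        again = build_consensus(
            {"A": first.consensus, "B": first.consensus}
        )
        assert again.consensus == first.consensus


class TestSharingCounts:
    def test_all_shared(self):
        m = pd.DataFrame(True, index=["A", "B"], columns=["c1", "c2"])
        from hotcomp.comparison import SharingMatrix

        sm = SharingMatrix([iv(0, 10), iv(20, 30)], m)
        counts = count_sharing_sets(sm)
        assert counts.counts == {frozenset({"A", "B"}): 2}
        assert counts.private_fraction == 0.0

    def test_enumeration_example(self):
        from hotcomp.comparison import SharingMatrix

        m = pd.DataFrame(
            [[True, True, True], [False, False, True]],
            index=["A", "B"],
            columns=["c1", "c2", "c3"],
        )
        sm = SharingMatrix([iv(0, 10), iv(20, 30), iv(40, 50)], m)
        counts = count_sharing_sets(sm)
        assert counts.counts == {
            frozenset({"A"}): 2,
            frozenset({"A", "B"}): 1,
        }
        assert counts.private_fraction == pytest.approx(2 / 3)

    def test_counts_partition(self, rng):
        from hotcomp.comparison import SharingMatrix

        mat = rng.random((5, 40)) < 0.4
        mat[:, 0] = True  # ensure no empty column for partition accounting
        m = pd.DataFrame(
            mat, index=list("ABCDE"),
            columns=[f"c{i}" for i in range(40)],
        )
        cons = [iv(i * 100, i * 100 + 50) for i in range(40)]
        counts = count_sharing_sets(SharingMatrix(cons, m))
        n_nonempty = int((mat.sum(axis=0) > 0).sum())
        assert sum(counts.counts.values()) == n_nonempty


class TestUbiquitous:
    def _random_sharing(self, rng, n_pops=10, n_cols=50):
        from hotcomp.comparison import SharingMatrix

        mat = rng.random((n_pops, n_cols)) < 0.5
        m = pd.DataFrame(
            mat,
            index=[f"p{i}" for i in range(n_pops)],
            columns=[f"c{i}" for i in range(n_cols)],
        )
        cons = [iv(i * 100, i * 100 + 50) for i in range(n_cols)]
        return SharingMatrix(cons, m)

    def test_min_one_returns_all_present(self, rng):
        sm = self._random_sharing(rng)
        got = ubiquitous_hotspots(sm, min_pops=1)
        expected = [
            c for c, n in zip(sm.consensus, sm.presence_counts()) if n >= 1
        ]
        assert got == expected

    def test_more_than_n_pops_empty(self, rng):
        sm = self._random_sharing(rng)
        assert ubiquitous_hotspots(sm, min_pops=11) == []

    def test_column_sum_oracle(self, rng):
        sm = self._random_sharing(rng)
        brute = sm.matrix.values.sum(axis=0)
        for k in (3, 8):
            got = ubiquitous_hotspots(sm, min_pops=k)
            assert len(got) == int((brute >= k).sum())


def _hypergeom_right_tail_oracle(n11, n12, n21, n22):
    """Exhaustive summation of the conditional hypergeometric tail."""
    row1 = n11 + n12
    col1 = n11 + n21
    n = n11 + n12 + n21 + n22
    total = 0.0
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        total_k = (
            math.comb(col1, k)
            * math.comb(n - col1, row1 - k)
            / math.comb(n, row1)
        )
        if k >= n11:
            total += total_k
    return total


class TestFisherOverlap:
    def test_identical_sets(self, layout):
        a = [iv(0, 100), iv(500, 600)]
        res = fisher_overlap(a, a, layout)
        assert res.n11 == 2 and res.n12 == 0 and res.n21 == 0
        assert res.p_right < 1e-6

    def test_hypergeometric_oracle(self):
        p = hypergeom_right_tail(10, 5, 4, 100)
        assert p == pytest.approx(
            _hypergeom_right_tail_oracle(10, 5, 4, 100), rel=1e-10
        )

    @pytest.mark.parametrize(
        "table", [(3, 7, 2, 50), (0, 5, 5, 20), (6, 0, 1, 40)]
    )
    def test_hypergeometric_oracle_more(self, table):
        assert hypergeom_right_tail(*table) == pytest.approx(
            _hypergeom_right_tail_oracle(*table), rel=1e-10
        )

    def test_empty_set_rejected(self, layout):
        with pytest.raises(ValueError, match="non-empty"):
            fisher_overlap([], [iv(0, 10)], layout)

    def test_symmetric_up_to_transposition(self, layout, rng):
        a = [iv(int(s), int(s) + 100) for s in rng.choice(9000, 10) * 100]
        b = [iv(int(s), int(s) + 100) for s in rng.choice(9000, 12) * 100]
        ab = fisher_overlap(a, b, layout)
        ba = fisher_overlap(b, a, layout)
        assert ab.n11 == ba.n11
        assert ab.n12 == ba.n21
        assert ab.n21 == ba.n12
        assert ab.n22 == ba.n22

    def test_null_calibration(self):
        # independent random sets on a large genome rarely reach 0.0011
        layout = GenomeLayout({"chr1": 10_000_000})
        rng = np.random.default_rng(0)
        hits = 0
        reps = 200
        for _ in range(reps):
            a = merge_intervals(
                [iv(int(s), int(s) + 2000)
                 for s in rng.integers(0, 9_990_000, size=30)]
            )
            b = merge_intervals(
                [iv(int(s), int(s) + 2000)
                 for s in rng.integers(0, 9_990_000, size=30)]
            )
            if fisher_overlap(a, b, layout).p_right <= 0.0011:
                hits += 1
        assert hits <= 2  # ~0.11% expected; allow tiny slack at n=200


class TestJaccard:
    def test_formula(self):
        m = pd.DataFrame(
            [[1, 1, 0], [1, 0, 1]], index=["A", "B"], columns=list("xyz")
        ).astype(bool)
        d = jaccard_distance_matrix(m)
        assert d.loc["A", "B"] == pytest.approx(1 - 1 / 3)

    def test_identical_and_disjoint(self):
        m = pd.DataFrame(
            [[1, 1, 0], [1, 1, 0], [0, 0, 1]],
            index=list("ABC"),
            columns=list("xyz"),
        ).astype(bool)
        d = jaccard_distance_matrix(m)
        assert d.loc["A", "B"] == 0.0
        assert d.loc["A", "C"] == 1.0

    def test_empty_rows_warn(self):
        m = pd.DataFrame(
            [[0, 0], [0, 0]], index=["A", "B"], columns=["x", "y"]
        ).astype(bool)
        with pytest.warns(UserWarning, match="empty"):
            d = jaccard_distance_matrix(m)
        assert d.loc["A", "B"] == 0.0

    def test_metric_axioms_brute_force(self, rng):
        mat = rng.random((6, 30)) < 0.5
        mat[:, 0] = True
        m = pd.DataFrame(mat, index=list("ABCDEF"),
                         columns=[f"c{i}" for i in range(30)])
        d = jaccard_distance_matrix(m)
        X = mat
        pops = list("ABCDEF")
        for i, j in itertools.combinations(range(6), 2):
            inter = np.count_nonzero(X[i] & X[j])
            union = np.count_nonzero(X[i] | X[j])
            assert d.loc[pops[i], pops[j]] == pytest.approx(1 - inter / union)
            assert d.loc[pops[i], pops[j]] == d.loc[pops[j], pops[i]]
        for i, j, k in itertools.permutations(range(6), 3):
            assert (
                d.iloc[i, j] <= d.iloc[i, k] + d.iloc[k, j] + 1e-12
            )  # triangle inequality on Boolean rows


def _mantel_oracle_4x4(d1, d2):
    """Full 24-permutation enumeration with naive loops."""
    v1 = [d1[i][j] for i in range(4) for j in range(i)]
    r_obs = np.corrcoef(
        v1, [d2[i][j] for i in range(4) for j in range(i)]
    )[0, 1]
    hits = 0
    for perm in itertools.permutations(range(4)):
        v2 = [d2[perm[i]][perm[j]] for i in range(4) for j in range(i)]
        if np.corrcoef(v1, v2)[0, 1] >= r_obs - 1e-12:
            hits += 1
    return r_obs, hits / 24


class TestMantel:
    def _random_distance(self, rng, n=4):
        x = rng.random((n, 3))
        d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
        return d

    def test_affine_invariance_r_one(self, rng):
        d = self._random_distance(rng, n=5)
        res = mantel_test(d, 2 * d, n_perm=200, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_exhaustive_matches_oracle(self, rng):
        for _ in range(5):
            d1 = self._random_distance(rng)
            d2 = self._random_distance(rng)
            res = mantel_test(d1, d2, n_perm=9999, seed=0)
            r_oracle, p_oracle = _mantel_oracle_4x4(d1, d2)
            assert res.exhaustive
            assert res.r == pytest.approx(r_oracle)
            assert res.p == pytest.approx(p_oracle)

    def test_too_small_rejected(self, rng):
        d = self._random_distance(rng, n=3)
        with pytest.raises(ValueError, match=">= 4"):
            mantel_test(d, d)

    def test_detects_strong_association(self, rng):
        d = self._random_distance(rng, n=8)
        noise = self._random_distance(rng, n=8)
        res = mantel_test(d, d + 0.01 * noise, n_perm=999, seed=1)
        assert res.p < 0.01


class TestCountRegression:
    def test_perfect_fit(self):
        pops = [f"p{i}" for i in range(6)]
        ne = {p: 1000.0 * (i + 1) for i, p in enumerate(pops)}
        counts = {p: 3 * ne[p] for p in pops}
        res = hotspot_count_regression(counts, {"ne": ne})
        assert res["ne"].slope == pytest.approx(3.0)
        assert res["ne"].slope_p < 1e-10

    def test_normal_equations_oracle(self, rng):
        pops = [f"p{i}" for i in range(10)]
        x = {p: float(v) for p, v in zip(pops, rng.normal(size=10))}
        counts = {p: float(v) for p, v in zip(pops, rng.normal(size=10))}
        res = hotspot_count_regression(counts, {"x": x})["x"]
        X = np.column_stack([np.ones(10), [x[p] for p in pops]])
        y = np.array([counts[p] for p in pops])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.slope == pytest.approx(beta[1])
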
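from itertools import combinations, permutations

import numpy as np
import pytest

from lfpconn import tda
from lfpconn.exceptions import ValidationError


# ---------------------------------------------------------------------------
# Independent oracle: Betti numbers of the VR complex at a threshold, from
# simplex counts and the GF(2) rank of the triangle boundary matrix.
# ---------------------------------------------------------------------------

def _gf2_rank(columns):
    rank = 0
    pivots = {}
    for col in columns:
        while col:
            low = col.bit_length() - 1
            if low in pivots:
                col ^= pivots[low]
            else:
                pivots[low] = col
                rank += 1
                break
    return rank


def _betti_at(d, eps):
    """(beta0, beta1) of the VR complex at threshold eps, computed directly."""
    n = d.shape[0]
    edges = [(i, j) for i, j in combinations(range(n), 2) if d[i, j] <= eps]
    eidx = {e: k for k, e in enumerate(edges)}
    # beta0 via union-find
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    beta0 = len({find(i) for i in range(n)})
    # beta1 = |E| - |V| + beta0 - rank(boundary_2)
    cols = []
    for i, j, k in combinations(range(n), 3):
        if max(d[i, j], d[i, k], d[j, k]) <= eps:
            cols.append((1 << eidx[(i, j)]) | (1 << eidx[(i, k)]) | (1 << eidx[(j, k)]))
    beta1 = len(edges) - n + beta0 - _gf2_rank(cols)
    return beta0, beta1


def _betti_from_diagrams(diagrams, eps):
    """Betti numbers implied by the diagrams: features alive at eps."""
    out = []
    for dg in diagrams:
        alive = int(np.sum((dg.pairs[:, 0] <= eps) & (dg.pairs[:, 1] > eps)))
        alive += int(np.sum(dg.essential <= eps))
        out.append(alive)
    return tuple(out)


class TestDissimilarity:
    def test_coherence_map_endpoints(self):
        C = np.array([[1.0, 1.0], [1.0, 1.0]])
        d = tda.dissimilarity_from_connectivity(C, "coherence")
        np.testing.assert_array_equal(d.values, 0.0)
        C0 = np.array([[1.0, 0.0], [0.0, 1.0]])
        d0 = tda.dissimilarity_from_connectivity(C0, "coherence")
        assert d0.values[0, 1] == 1.0

    def test_partial_correlation_magnitude_map(self):
        for rho in (-0.8, 0.8):
            C = np.array([[1.0, rho], [rho, 1.0]])
            d = tda.dissimilarity_from_connectivity(C, "partial_correlation")
            assert d.values[0, 1] == pytest.approx(0.2)

    def test_symmetry_and_zero_diagonal(self, rng):
        C = np.abs(np.corrcoef(rng.standard_normal((5, 100))))
        d = tda.dissimilarity_from_connectivity(C, "coherence").values
        np.testing.assert_array_equal(d, d.T)
        np.testing.assert_array_equal(np.diag(d), 0.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            tda.dissimilarity_from_connectivity(np.array([[1.0, 1.5], [1.5, 1.0]]),
                                                "coherence")

    def test_directed_input_rejected(self):
        bad = np.array([[0.0, 0.2], [0.4, 0.0]])
        with pytest.raises(ValidationError, match="directed"):
            tda.DissimilarityMatrix(values=bad, source="coherence")


class TestVRPersistence:
    def test_equilateral_triple(self):
        d = np.ones((3, 3)) - np.eye(3)
        d0, d1 = tda.vr_persistence(d)
        np.testing.assert_allclose(np.sort(d0.pairs[:, 1]), [1.0, 1.0])
        assert len(d0.essential) == 1
        assert len(d1.pairs) == 0

    def test_unit_square_loop(self):
        s = np.sqrt(2.0)
        d = np.array([[0, 1, s, 1], [1, 0, 1, s], [s, 1, 0, 1], [1, s, 1, 0]])
        d0, d1 = tda.vr_persistence(d)
        np.testing.assert_allclose(d1.pairs, [[1.0, s]])
        np.testing.assert_allclose(np.sort(d0.pairs[:, 1]), [1.0, 1.0, 1.0])

    @pytest.mark.parametrize("n,seed", [(8, 0), (10, 1), (10, 2), (12, 3)])
    def test_matches_betti_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        m = rng.uniform(0.1, 1.0, size=(n, n))
        d = 0.5 * (m + m.T)
        np.fill_diagonal(d, 0.0)
        diagrams = tda.vr_persistence(d)
        vals = np.unique(d[np.triu_indices(n, 1)])
        probes = np.concatenate([vals - 1e-9, vals + 1e-9, [0.0, 2.0]])
        for eps in probes:
            assert _betti_from_diagrams(diagrams, eps) == _betti_at(d, eps)

    def test_stability_under_perturbation(self, rng):
        n = 8
        m = rng.uniform(0.2, 1.0, size=(n, n))
        d = 0.5 * (m + m.T)
        np.fill_diagonal(d, 0.0)
        eps = 1e-3
        noise = rng.uniform(-eps, eps, size=(n, n))
        noise = 0.5 * (noise + noise.T)
        np.fill_diagonal(noise, 0.0)
        d2 = np.clip(d + noise, 0.0, None)
        for dim in (0, 1):
            g1 = tda.vr_persistence(d)[dim]
            g2 = tda.vr_persistence(d2)[dim]
            # bottleneck distance bounded by the sup-norm perturbation
            assert tda.wasserstein_distance(g1, g2) <= eps * (len(g1.pairs)
                                                              + len(g2.pairs) + 1)


class TestWasserstein:
    def test_identical_diagrams_zero(self, rng):
        pairs = np.sort(rng.uniform(size=(4, 2)), axis=1)
        dg = tda.PersistenceDiagram(1, pairs)
        assert tda.wasserstein_distance(dg, dg) == pytest.approx(0.0, abs=1e-12)

    def test_single_point_versus_empty(self):
        d = tda.wasserstein_distance(tda.PersistenceDiagram(1, [[0.0, 1.0]]),
                                     tda.PersistenceDiagram(1, np.empty((0, 2))))
        assert d == pytest.approx(0.5)

    def test_matches_exhaustive_matching(self, rng):
        def brute(a, b):
            na, nb = len(a), len(b)
            pts = list(range(na))
            best = np.inf
            # match each point of a to a point of b or its own diagonal;
            # unmatched b-points go to their diagonals
            for subset_sz in range(min(na, nb) + 1):
                from itertools import combinations as comb
                for asel in comb(range(na), subset_sz):
                    for bsel in permutations(range(nb), subset_sz):
                        cost = 0.0
                        for i, j in zip(asel, bsel):
                            cost += np.abs(a[i] - b[j]).max() ** 2
                        for i in set(range(na)) - set(asel):
                            cost += ((a[i, 1] - a[i, 0]) / 2) ** 2
                        for j in set(range(nb)) - set(bsel):
                            cost += ((b[j, 1] - b[j, 0]) / 2) ** 2
                        best = min(best, cost)
            return np.sqrt(best)

        for _ in range(10):
            na, nb = rng.integers(0, 4, size=2)
            a = np.sort(rng.uniform(size=(na, 2)), axis=1)
            b = np.sort(rng.uniform(size=(nb, 2)), axis=1)
            d1 = tda.wasserstein_distance(tda.PersistenceDiagram(1, a),
                                          tda.PersistenceDiagram(1, b))
            assert d1 == pytest.approx(brute(a, b), abs=1e-10)

    def test_symmetry(self, rng):
        a = np.sort(rng.uniform(size=(3, 2)), axis=1)
        b = np.sort(rng.uniform(size=(5, 2)), axis=1)
        da = tda.PersistenceDiagram(0, a)
        db = tda.PersistenceDiagram(0, b)
        assert tda.wasserstein_distance(da, db) == pytest.approx(
            tda.wasserstein_distance(db, da), abs=1e-12)

    def test_mixed_dimensions_rejected(self):
        with pytest.raises(ValueError):
            tda.wasserstein_distance(tda.PersistenceDiagram(0, [[0, 1]]),
                                     tda.PersistenceDiagram(1, [[0, 1]]))


class TestGroupSummary:
    def test_single_trial_groups_equal_raw_distances(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        out = tda.group_distance_summary(d, ["A", "B"])
        assert out.loc["A", "B"] == 1.0
        assert np.isnan(out.loc["A", "A"])  # single-trial within-group

    def test_toy_two_groups_hand_computed(self):
        d = np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 6.0], [4.0, 6.0, 0.0]])
        out = tda.group_distance_summary(d, ["g", "g", "h"])
        assert out.loc["g", "g"] == pytest.approx(2.0)
        assert out.loc["g", "h"] == pytest.approx(5.0)
        assert np.isnan(out.loc["h", "h"])

    def test_label_length_mismatch(self):
        with pytest.raises(ValueError):
            tda.group_distance_summary(np.zeros((3, 3)), ["a", "b"])
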
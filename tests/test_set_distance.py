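"""Set-level distances: worked values, Hungarian oracle, orderings, dilution."""

import itertools

import numpy as np
import pytest

import taxsim as ts
from taxsim.errors import ConfigurationError, DomainError

A2 = {"A1a1", "A1b"}
B1 = {"A1a2"}


def brute_force_min_matching(cost: np.ndarray) -> float:
    """Exhaustive minimum over all injective assignments of the smaller side."""
    n, m = cost.shape
    if n <= m:
        return min(
            sum(cost[i, p[i]] for i in range(n))
            for p in itertools.permutations(range(m), n)
        )
    return brute_force_min_matching(cost.T)


class TestOverlapFamily:
    def test_worked_values(self, toy5):
        A, B = {"A1a1", "A1a2", "A1b"}, {"A1a2", "A1b", "B1a"}
        assert ts.ss_overlap_family("jaccard", A, B) == pytest.approx(0.5)
        assert ts.ss_overlap_family("dice", A, B) == pytest.approx(1 / 3)
        assert ts.ss_overlap_family("cosine", A, B) == pytest.approx(1 - 2 / 3)
        assert ts.ss_overlap_family("overlap", A, B) == pytest.approx(1 - 2 / 3)

    @pytest.mark.parametrize("m", ["dice", "jaccard", "cosine", "overlap"])
    def test_identity_and_empty(self, m):
        assert ts.ss_overlap_family(m, {"x", "y"}, {"x", "y"}) == 0.0
        with pytest.raises(DomainError):
            ts.ss_overlap_family(m, set(), {"x"})


class TestCSAggregating:
    def test_closest_pair_worked(self, toy5):
        assert ts.ss_closest_pair(toy5, "path", "wu", A2, B1) == \
            pytest.approx((0.2 + 1 / 3 + 0.2) / 3, abs=1e-12)
        assert ts.ss_closest_pair(toy5, "path", "wu", A2, A2) == 0.0
        assert ts.ss_closest_pair(toy5, "path", "wu", {"A1a1"}, {"B1a"}) == \
            pytest.approx(7 / 9, abs=1e-12)

    def test_nonshared_avg_worked(self, toy5):
        assert ts.ss_nonshared_avg(toy5, "path", "wu", A2, B1) == \
            pytest.approx((0.5333333333333333 + 0.26666666666666666) / 3, abs=1e-12)
        assert ts.ss_nonshared_avg(toy5, "path", "wu", A2, A2) == 0.0
        assert ts.ss_nonshared_avg(toy5, "path", "wu", {"A1a1"}, {"B1a"}) == \
            pytest.approx(7 / 9, abs=1e-12)

    def test_allpairs_avg_worked(self, toy5):
        assert ts.ss_allpairs_avg(toy5, "path", "wu", A2, B1) == \
            pytest.approx((0.2 + 1 / 3) / 2, abs=1e-12)
        assert ts.ss_allpairs_avg(toy5, "path", "wu", {"A1a1"}, {"A1a1"}) == 0.0
        # A = B with n > 1: the mean of all n² pairwise distances, not zero
        expected = (0.0 + 0.2 + 0.2 + 0.0) / 4
        assert ts.ss_allpairs_avg(toy5, "path", "wu", {"A1a1", "A1a2"}, {"A1a1", "A1a2"}) == \
            pytest.approx(expected, abs=1e-12)

    def test_bipartite_worked(self, toy5):
        assert ts.ss_bipartite(toy5, "path", "wu", A2, B1) == pytest.approx(0.2, abs=1e-12)
        assert ts.ss_bipartite(toy5, "path", "wu", A2, A2) == 0.0

    def test_root_in_set_rejected(self, toy5):
        with pytest.raises(DomainError, match="virtual root"):
            ts.ss_allpairs_avg(toy5, "path", "wu", {"root"}, {"A1a1"})


class TestHungarian:
    def test_two_by_two(self):
        pairs, total = ts.hungarian_min_matching([[0.1, 0.6], [0.4, 0.2]])
        assert set(pairs) == {(0, 0), (1, 1)}
        assert total == pytest.approx(0.3, abs=1e-12)

    def test_zero_diagonal(self):
        cost = np.full((4, 4), 0.9) - 0.9 * np.eye(4)
        _, total = ts.hungarian_min_matching(cost)
        assert total == 0.0

    def test_single_row(self):
        pairs, total = ts.hungarian_min_matching([[0.5, 0.2, 0.9]])
        assert pairs == [(0, 1)]
        assert total == pytest.approx(0.2)

    def test_non_finite_rejected(self):
        with pytest.raises(DomainError):
            ts.hungarian_min_matching([[np.inf, 1.0]])

    def test_matches_brute_force_up_to_6x6(self, rng):
        """Oracle equivalence over random rectangular matrices."""
        count = 0
        for n in range(1, 7):
            for m in range(1, 7):
                for _ in range(4):
                    cost = rng.random((n, m))
                    _, total = ts.hungarian_min_matching(cost)
                    assert total == pytest.approx(brute_force_min_matching(cost),
                                                  abs=1e-12)
                    count += 1
        assert count >= 100


class TestDispatchAndProperties:
    def test_dispatch_identity(self, toy5):
        got = ts.set_distance(toy5, "path", "wu", "bipartite", A2, B1)
        assert got == ts.ss_bipartite(toy5, "path", "wu", A2, B1)

    def test_overlap_family_ignores_cs(self, toy5):
        A, B = {"A1a1", "A1b"}, {"A1b", "B1a"}
        a = ts.set_distance(toy5, None, None, "jaccard", A, B)
        b = ts.set_distance(toy5, "ontology", "li", "jaccard", A, B)
        assert a == b == pytest.approx(1 - 1 / 3)

    def test_unknown_id(self, toy5):
        with pytest.raises(ConfigurationError):
            ts.set_distance(toy5, "path", "wu", "hausdorff", A2, B1)

    def test_cs_required_for_aggregating(self, toy5):
        with pytest.raises(ConfigurationError):
            ts.set_distance(toy5, None, None, "bipartite", A2, B1)

    @pytest.mark.parametrize("ss", [m.value for m in ts.SSMethod])
    def test_symmetry_on_random_sets(self, ss, small_tax, rng):
        leaves = sorted(n for n in small_tax.nodes if small_tax.is_leaf(n))
        for _ in range(25):
            A = set(rng.choice(leaves, rng.integers(1, 7), replace=False))
            B = set(rng.choice(leaves, rng.integers(1, 7), replace=False))
            d_ab = ts.set_distance(small_tax, "path", "wu", ss, A, B)
            d_ba = ts.set_distance(small_tax, "path", "wu", ss, B, A)
            assert d_ab == pytest.approx(d_ba, abs=1e-12)
            assert -1e-12 <= d_ab <= 1 + 1e-12

    def test_ordering_closest_and_bipartite_vs_allpairs(self, small_tax, rng):
        """Per-element min ≤ mean; matching minimum ≤ permutation average."""
        leaves = sorted(n for n in small_tax.nodes if small_tax.is_leaf(n))
        for _ in range(100):
            size = int(rng.integers(1, 7))
            A = set(rng.choice(leaves, size, replace=False))
            B = set(rng.choice(leaves, size, replace=False))
            ap = ts.ss_allpairs_avg(small_tax, "path", "wu", A, B)
            assert ts.ss_closest_pair(small_tax, "path", "wu", A, B) <= ap + 1e-12
            assert ts.ss_bipartite(small_tax, "path", "wu", A, B) <= ap + 1e-12

    def test_dilution_of_averages(self, small_tax):
        """Shared distant codes drag the all-pairs mean up while the matched core holds."""
        leaves_by_chapter = {}
        for n in small_tax.nodes:
            if small_tax.is_leaf(n):
                leaves_by_chapter.setdefault(n.split(".")[0], []).append(n)
        chapters = sorted(leaves_by_chapter)
        core_a = set(leaves_by_chapter[chapters[0]][:3])
        core_b = set(leaves_by_chapter[chapters[0]][3:6])  # same chapter: close cores
        pool = [leaves_by_chapter[ch][0] for ch in chapters[1:]]  # mutually distant
        base_ap = ts.ss_allpairs_avg(small_tax, "path", "wu", core_a, core_b)
        base_bp = ts.ss_bipartite(small_tax, "path", "wu", core_a, core_b)
        A = core_a | set(pool)
        B = core_b | set(pool)
        diluted_ap = ts.ss_allpairs_avg(small_tax, "path", "wu", A, B)
        diluted_bp = ts.ss_bipartite(small_tax, "path", "wu", A, B)
        assert diluted_ap > base_ap  # average pulled toward the background mean
        assert diluted_bp <= base_bp + 1e-12  # shared pool matches itself at zero cost
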
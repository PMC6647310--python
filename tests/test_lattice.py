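from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pytest

from tbekit import (
    Bicoloration,
    LatticePath,
    caterpillar_expectation,
    caterpillar_moments,
    caterpillar_pmf,
    caterpillar_tree,
    lattice_count,
    manhattan,
    path_from_bicoloration,
    phi_from_path,
    random_bicoloration,
    transfer_index,
)
from tbekit.lattice import (
    bicoloration_from_path,
    lattice_count_bruteforce,
    pmf_bruteforce,
)
from tbekit.simulate import sample_caterpillar_phi


def all_paths(n, p):
    for esteps in combinations(range(n), p):
        es = set(esteps)
        yield LatticePath(tuple("E" if i in es else "N" for i in range(n)))


class TestBijection:
    def test_black_first_is_extreme_path_through_corner(self):
        chi = Bicoloration.from_black_labels(
            [str(i) for i in range(1, 7)], ["1", "2", "3"]
        )
        path = path_from_bicoloration(chi)
        assert path.steps == ("E", "E", "E", "N", "N", "N")
        assert (3, 0) in path.points  # passes through Q
        assert phi_from_path(path) == 0

    def test_direct_scan_small_case(self):
        chi = Bicoloration.from_black_labels(["1", "2", "3", "4"], ["1", "3"])
        path = path_from_bicoloration(chi)
        assert path.steps == ("E", "N", "E", "N")
        assert path.points == ((0, 0), (1, 0), (1, 1), (2, 1), (2, 2))

    def test_invertible_on_all_colorations(self):
        labels = [str(i) for i in range(1, 7)]
        for black in combinations(labels, 3):
            chi = Bicoloration.from_black_labels(labels, black)
            assert bicoloration_from_path(path_from_bicoloration(chi)) == chi

    def test_tip_order_is_numeric_not_lexicographic(self):
        # with n >= 10 the scan must follow 1,2,..,10, not "1","10","2",..
        labels = [str(i) for i in range(1, 11)]
        chi = Bicoloration.from_black_labels(labels, ["9", "10"])
        assert path_from_bicoloration(chi).steps[-2:] == ("E", "E")


class TestPathGeometry:
    def test_manhattan_rectangle_corners(self):
        # distances quoted for the 10-tip, 4-black worked example
        assert manhattan((2, 2), (4, 0)) == 4
        assert manhattan((2, 2), (0, 6)) == 6
        assert manhattan((2, 5), (0, 6)) == 3

    def test_worked_example_path(self):
        # n=10, p=4, black tips {1,3,8,9}: nearest approach is 3 at P7
        path = LatticePath(tuple("ENENNNNEEN"))
        assert (2, 2) in path.points and (2, 5) in path.points
        assert phi_from_path(path) == 3

    def test_cap_at_p_minus_one(self):
        # alternating colours keeps the path near the diagonal; phi <= p-1
        n, p = 20, 10
        path = LatticePath(tuple("EN" * 10))
        assert phi_from_path(path) == p - 1

    def test_agrees_with_tree_transfer_index(self, rng):
        """Path geometry equals the tree computation on random draws."""
        for _ in range(200):
            n = int(rng.choice([8, 16, 50, 128]))
            p = int(rng.integers(2, n // 2 + 1))
            tree = caterpillar_tree(n)
            chi = random_bicoloration(n, p, rng)
            assert phi_from_path(path_from_bicoloration(chi), p) == (
                transfer_index(chi, tree).phi
            )


class TestLatticeCount:
    def test_known_small_counts(self):
        assert lattice_count(4, 2, 2) == 4
        assert lattice_count(6, 2, 2) == 13
        assert lattice_count(4, 2, 3) == comb(4, 2)

    def test_no_constraint_when_lines_outside_rectangle(self):
        for n, p in [(8, 3), (10, 5), (12, 4)]:
            assert lattice_count(n, p, p + 1) == comb(n, p)

    def test_closed_form_equals_enumeration(self):
        for n in range(4, 13):
            for p in range(2, n // 2 + 1):
                for l in range(2, p + 2):
                    assert lattice_count(n, p, l) == lattice_count_bruteforce(n, p, l)

    def test_monotone_in_l(self):
        for n, p in [(12, 5), (20, 10), (30, 7)]:
            vals = [lattice_count(n, p, l) for l in range(2, p + 2)]
            assert vals == sorted(vals)
            assert vals[-1] == comb(n, p)

    def test_wider_k_range_is_harmless(self):
        # out-of-range reflection terms vanish under the binomial convention
        from math import comb as C

        for n, p, l in [(12, 5, 3), (20, 10, 4), (16, 8, 2)]:
            c = n - 2 * p + 2 * l

            def Cn(m):
                return C(n, m) if 0 <= m <= n else 0

            wide = sum(
                Cn(p - k * c) - Cn(p - l - k * c) for k in range(-4 * n, 4 * n)
            )
            assert wide == lattice_count(n, p, l)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            lattice_count(10, 5, 1)
        with pytest.raises(ValueError):
            lattice_count(10, 6, 2)


class TestExactPMF:
    def test_smallest_cases(self):
        assert caterpillar_pmf(4, 2).probs == {0: Fraction(1, 3), 1: Fraction(2, 3)}
        assert caterpillar_pmf(6, 2).probs == {0: Fraction(2, 15), 1: Fraction(13, 15)}

    @pytest.mark.parametrize("n,p", [(8, 3), (10, 4), (12, 6), (14, 7)])
    def test_matches_bicoloration_enumeration(self, n, p):
        exact = caterpillar_pmf(n, p)
        brute = pmf_bruteforce(n, p)
        assert exact.probs == brute.probs

    @pytest.mark.parametrize("n,p", [(8, 4), (11, 5)])
    def test_matches_path_histogram(self, n, p):
        counts = {k: 0 for k in range(p)}
        for path in all_paths(n, p):
            counts[phi_from_path(path, p)] += 1
        exact = caterpillar_pmf(n, p)
        assert exact.probs == {
            k: Fraction(v, comb(n, p)) for k, v in counts.items()
        }

    def test_sums_to_one_exactly(self):
        for n, p in [(10, 4), (40, 17), (64, 32)]:
            assert sum(caterpillar_pmf(n, p).probs.values()) == 1

    def test_large_instance_exact_arithmetic(self):
        d = caterpillar_pmf(1024, 512)
        assert sum(d.probs.values()) == 1
        assert d.L_values[513] == comb(1024, 512)


class TestExpectationAndMoments:
    def test_small_expectations(self):
        assert caterpillar_expectation(4, 2) == Fraction(2, 3)
        assert caterpillar_expectation(6, 2) == Fraction(13, 15)

    def test_telescoping_identity(self):
        """The summed-counts expectation equals sum k * pmf(k), exactly."""
        for n in (8, 16, 33, 64):
            for p in {2, n // 4, n // 2}:
                if p < 2:
                    continue
                assert caterpillar_expectation(n, p) == caterpillar_pmf(n, p).mean()

    def test_expectation_bounded_by_support(self):
        for n, p in [(16, 8), (64, 20)]:
            assert 0 <= caterpillar_expectation(n, p) <= p - 1

    def test_two_point_moments(self):
        m = caterpillar_moments(4, 2)
        assert m.mean_ts == pytest.approx(1 / 3)
        assert m.var_phi == pytest.approx(2 / 9)

    def test_monte_carlo_cross_check(self, rng):
        n, p, draws = 64, 32, 30000
        phi = sample_caterpillar_phi(n, p, draws, rng)
        exact = caterpillar_moments(n, p)
        se = np.sqrt(exact.var_phi / draws)
        assert abs(phi.mean() - exact.mean_phi) < 3 * se
        assert exact.var_phi >= 0
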
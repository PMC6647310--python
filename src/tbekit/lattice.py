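"""Exact distribution of the transfer index on caterpillar trees.

A bicoloration of the oriented caterpillar (tips 1..n along the
internal path, ``p`` black) maps bijectively to a monotone NE lattice
path from (0, 0) to ``(p, n - p)``: scan the tips in order, step east on
black and north on white.  The transfer index is then a geometric
quantity of the path,

    phi = min(M(path, Q), M(path, Q'), p - 1),

with ``M`` the Manhattan distance, ``Q = (p, 0)`` and ``Q' = (0, n-p)``
the off-diagonal corners of the rectangle.  Counting paths that keep a
prescribed Manhattan distance from both corners is a boundary-avoidance
problem solved by the reflection principle: with ``c = n - 2p + 2l``,
the number of paths touching neither ``y = x - l`` nor
``y = x + (n - 2p + l)`` is

    L(n, p, l) = sum_k [ C(n, p - k c) - C(n, p - l - k c) ],

summed over ``k`` from ``floor((p - l - n)/c)`` to ``ceil(p/c)`` (terms
outside the binomial range vanish).  The pmf of phi follows by
differencing consecutive ``L`` values, and the expectation telescopes to
``E[phi] = sum_{l=2..p} L(n, p, l) / C(n, p)``.

All counts use arbitrary-precision integers and all probabilities exact
rationals: the pmf is a difference of astronomically large binomials
(``C(1024, 512) ~ 10**306``) and would be meaningless in floating
point.  Conversion to floats happens only at the moments boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from math import comb, isqrt, sqrt
from typing import NamedTuple, Sequence

from .treeio import Bicoloration

__all__ = [
    "LatticePath",
    "NullPMF",
    "CaterpillarMoments",
    "path_from_bicoloration",
    "bicoloration_from_path",
    "manhattan",
    "phi_from_path",
    "lattice_count",
    "lattice_count_bruteforce",
    "caterpillar_pmf",
    "caterpillar_expectation",
    "caterpillar_moments",
    "pmf_bruteforce",
]


@dataclass(frozen=True)
class LatticePath:
    """Monotone NE path encoded as its step string over {'N', 'E'}."""

    steps: tuple[str, ...]

    def __post_init__(self) -> None:
        if any(s not in ("N", "E") for s in self.steps):
            raise ValueError("steps must be 'N' or 'E'")

    @property
    def n(self) -> int:
        return len(self.steps)

    @property
    def p(self) -> int:
        return sum(1 for s in self.steps if s == "E")

    @property
    def points(self) -> tuple[tuple[int, int], ...]:
        """All n + 1 lattice points, endpoints included."""
        pts = [(0, 0)]
        x = y = 0
        for s in self.steps:
            if s == "E":
                x += 1
            else:
                y += 1
            pts.append((x, y))
        return tuple(pts)


class CaterpillarMoments(NamedTuple):
    mean_phi: float
    var_phi: float
    mean_ts: float
    sd_ts: float


@dataclass(frozen=True)
class NullPMF:
    """Exact null pmf of the transfer index for a uniform bicoloration
    of the caterpillar with ``n`` tips and ``p`` black."""

    n: int
    p: int
    probs: dict[int, Fraction]
    L_values: dict[int, int] = field(default_factory=dict)

    def support(self) -> list[int]:
        return sorted(self.probs)

    def mean(self) -> Fraction:
        return sum((Fraction(k) * v for k, v in self.probs.items()), Fraction(0))

    def variance(self) -> Fraction:
        m = self.mean()
        m2 = sum((Fraction(k * k) * v for k, v in self.probs.items()), Fraction(0))
        return m2 - m * m

    def ts_moments(self) -> CaterpillarMoments:
        """Float moments of phi and of TS = 1 - phi/(p-1)."""
        m, v = self.mean(), self.variance()
        mean_ts = 1 - m / (self.p - 1)
        sd_phi = _frac_sqrt(v)
        return CaterpillarMoments(
            mean_phi=float(m),
            var_phi=float(v),
            mean_ts=float(mean_ts),
            sd_ts=sd_phi / (self.p - 1),
        )


def _frac_sqrt(x: Fraction) -> float:
    """sqrt of a nonnegative rational without overflowing float range."""
    num, den = x.numerator, x.denominator
    if num * den <= 2 ** 52:
        return sqrt(float(x))
    # integer square root keeps precision for huge operands; the exact
    # fraction-to-float division avoids overflow of intermediate ints
    return float(Fraction(isqrt(num * den), den))


# ----------------------------------------------------------------------
# the bicoloration <-> path bijection and the path formula for phi
# ----------------------------------------------------------------------
def path_from_bicoloration(chi: Bicoloration | Sequence[bool]) -> LatticePath:
    """Scan tips in caterpillar order: black -> east, white -> north."""
    if isinstance(chi, Bicoloration):
        colors = chi.colors_in_tip_order()
    else:
        colors = [bool(c) for c in chi]
    return LatticePath(tuple("E" if c else "N" for c in colors))


def bicoloration_from_path(path: LatticePath) -> Bicoloration:
    """Inverse scan: east steps become black tips 1..n in order."""
    n = path.n
    labels = [str(i) for i in range(1, n + 1)]
    black = [labels[i] for i, s in enumerate(path.steps) if s == "E"]
    return Bicoloration.from_black_labels(labels, black)


def manhattan(a: tuple[int, int], b: tuple[int, int]) -> int:
    return abs(a[0] - b[0]) + abs(a[1] - b[1])


def phi_from_path(path: LatticePath, p: int | None = None) -> int:
    """Transfer index of the caterpillar bicoloration encoded by the
    path: nearest Manhattan approach to either corner, capped at
    ``p - 1`` (the cap is realised by any pendant branch at a black
    tip)."""
    if p is None:
        p = path.p
    n = path.n
    q = (p, 0)
    qp = (0, n - p)
    best = p - 1
    for pt in path.points:
        best = min(best, manhattan(pt, q), manhattan(pt, qp))
    return best


# ----------------------------------------------------------------------
# boundary-avoiding path counts (reflection principle closed form)
# ----------------------------------------------------------------------
def _check_np(n: int, p: int) -> None:
    if not 2 <= p <= n // 2:
        raise ValueError(f"need 2 <= p <= n/2, got n={n}, p={p}")


def lattice_count(n: int, p: int, l: int) -> int:
    """Number of NE paths (0,0) -> (p, n-p) touching neither
    ``y = x - l`` nor ``y = x + (n - 2p + l)``."""
    _check_np(n, p)
    if not 2 <= l <= p + 1:
        raise ValueError(f"need 2 <= l <= p + 1, got l={l}")
    c = n - 2 * p + 2 * l

    def C(m: int) -> int:
        return comb(n, m) if 0 <= m <= n else 0

    lo = (p - l - n) // c  # floor
    hi = -((-p) // c)  # ceil
    return sum(C(p - k * c) - C(p - l - k * c) for k in range(lo, hi + 1))


def lattice_count_bruteforce(n: int, p: int, l: int) -> int:
    """Oracle: enumerate all C(n, p) paths and apply the avoidance test
    vertex by vertex (endpoints included)."""
    _check_np(n, p)
    if not 2 <= l <= p + 1:
        raise ValueError(f"need 2 <= l <= p + 1, got l={l}")
    if n > 20:
        raise ValueError("enumeration limited to n <= 20")
    hi_line = n - 2 * p + l
    count = 0
    for esteps in combinations(range(n), p):
        es = set(esteps)
        x = y = 0
        ok = (0 != -l) and (0 != hi_line)  # origin check (y - x)
        if ok:
            for i in range(n):
                if i in es:
                    x += 1
                else:
                    y += 1
                d = y - x
                if d == -l or d == hi_line:
                    ok = False
                    break
        count += ok
    return count


# ----------------------------------------------------------------------
# the exact pmf, expectation and moments
# ----------------------------------------------------------------------
def caterpillar_pmf(n: int, p: int) -> NullPMF:
    """Exact pmf of phi on {0, .., p-1}: ``P(phi = p - l + 1)`` is the
    count of paths first leaving the corner-avoidance regime at level
    ``l``, i.e. ``(L(n,p,l) - L(n,p,l-1)) / C(n, p)`` (the ``l = 2``
    term has no predecessor)."""
    _check_np(n, p)
    total = comb(n, p)
    probs: dict[int, Fraction] = {}
    L_values: dict[int, int] = {}
    L_prev = 0
    for l in range(2, p + 2):
        L_cur = lattice_count(n, p, l)
        L_values[l] = L_cur
        probs[p - l + 1] = Fraction(L_cur - (L_prev if l > 2 else 0), total)
        L_prev = L_cur
    return NullPMF(n=n, p=p, probs=probs, L_values=L_values)


def caterpillar_expectation(n: int, p: int) -> Fraction:
    """Exact ``E[phi]`` via the telescoped sum of avoidance counts."""
    _check_np(n, p)
    total = comb(n, p)
    return Fraction(sum(lattice_count(n, p, l) for l in range(2, p + 1)), total)


def caterpillar_moments(n: int, p: int) -> CaterpillarMoments:
    """Mean/variance of phi and mean/sd of TS under the caterpillar
    null, computed in exact rationals and converted to floats last."""
    return caterpillar_pmf(n, p).ts_moments()


def pmf_bruteforce(n: int, p: int) -> NullPMF:
    """Oracle: exact pmf by enumerating every bicoloration and running
    the tree-based transfer index on the caterpillar."""
    _check_np(n, p)
    total = comb(n, p)
    if total > 10 ** 6:
        raise ValueError("enumeration limited to C(n, p) <= 1e6")
    from .nullmodels import caterpillar_tree
    from .transfer import transfer_index
    from .treeio import Bicoloration

    tree = caterpillar_tree(n)
    labels = [str(i) for i in range(1, n + 1)]
    counts: dict[int, int] = {k: 0 for k in range(p)}
    for black in combinations(labels, p):
        chi = Bicoloration.from_black_labels(labels, black)
        counts[transfer_index(chi, tree).phi] += 1
    probs = {k: Fraction(v, total) for k, v in counts.items()}
    return NullPMF(n=n, p=p, probs=probs)
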
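# Methods

## Statistics computed

For a reference bipartition with light-side size `p` on `n` taxa
(encoded as a bicoloration, black = light side) and a tree `T` on the
same taxa:

- transfer distance to a branch `b`:
  `δ = min(H(v(χ), v(b)), H(v̄(χ), v(b))) = min(W_l + B_h, W_h + B_l)`,
  where `H` is the Hamming distance between 0/1 encodings and
  `B_s`/`W_s` are black/white tip counts on side `s` of `b`;
- transfer index: `φ = min_b δ`, minimised over **every** branch,
  pendant branches included — a pendant branch at a black tip realises
  `δ = p − 1`, which is what caps `φ` at `p − 1`;
- transfer support `TS = 1 − φ/(p − 1)`; TBE = mean TS over bootstrap
  trees (identical to applying the same normalisation to the mean φ).

Rooting is support-neutral: both root-adjacent branches induce the same
bipartition, so rooted inputs are accepted everywhere and never change a
distance.

## Algorithms

**Transfer index** is computed by a single postorder traversal that
accumulates black-tip counts per clade and derives the side counts of
every edge in O(1) each, i.e. O(n) per (bicoloration, tree) pair. A
deliberately naive per-edge Hamming recomputation is kept as a test
oracle, and a vectorised variant evaluates many bicolorations against
one tree for the Monte-Carlo work. Ties among minimising branches
resolve to the first edge in the deterministic postorder enumeration;
the φ value is unaffected.

**Parsimony score** of the binary character uses the Fitch–Hartigan
bottom-up pass (state sets and majority votes) rooted at an arbitrary
internal vertex, followed by a top-down pass that returns one optimal
extension; the score is the number of bichromatic edges and is invariant
to the rooting device (asserted against exhaustive minimisation over all
extensions for small trees). Only strictly binary trees are accepted
here; the transfer index itself works on any topology since it only
needs the edge set. The score lower-bounds the transfer index via
`ps ≤ φ + 1`, which in turn gives the distribution-free bound
`P(φ = p−1) ≥ max(0, 1 − 4p(p−1)/(n−1))` for a uniform bicoloration of
any fixed binary tree (clamped at 0 where vacuous).

**Exact caterpillar null.** With tips 1..n ordered along the caterpillar
path, scanning tips (black → east, white → north) is a bijection onto
monotone NE lattice paths from (0,0) to (p, n−p), and
`φ = min(M(γ, Q), M(γ, Q′), p − 1)` with `Q = (p, 0)`, `Q′ = (0, n−p)`.
Paths whose Manhattan distance to both corners is at least `p − l + 1`
are exactly those avoiding the lines `y = x − l` and `y = x + (n−2p+l)`;
their count follows from the reflection principle,

    L(n, p, l) = Σ_k [ C(n, p − kc) − C(n, p − l − kc) ],  c = n − 2p + 2l,

with `k` from `⌊(p−l−n)/c⌋` to `⌈p/c⌉` and the convention `C(n, m) = 0`
outside `0 ≤ m ≤ n` (a wider `k` range only adds vanishing terms; tested).
"Touching" a line means any path vertex lies on it, endpoints included.
Differencing consecutive `L` values gives the pmf of φ on `{0..p−1}`;
the expectation telescopes to `E[φ] = Σ_{l=2..p} L(n,p,l) / C(n,p)`
(asserted exactly equal to `Σ k·pmf(k)`).

**Significance.** TBE under the null is a mean of `N` TS draws, so the
CLT gives `TBE ≈ Normal(mean_TS, sd_TS/√N)`; the one-sided rejection
threshold at level α is `mean_TS + z_α · sd_TS/√N` and p-values are the
corresponding upper tail. The caterpillar is the null topology: across
the four models its expected TS at `p = ⌊n/2⌋` is the largest in
simulation, so the threshold is believed conservative for other shapes —
this maximality (and the maximality of `p = ⌊n/2⌋` over `p`) is treated
strictly as a simulation-supported heuristic, never assumed in code.

## Numerical design

- All path counts in arbitrary-precision integers and all probabilities
  in exact rationals (`fractions.Fraction`): `C(1024, 512) ≈ 10³⁰⁶` and
  the pmf is a difference of such numbers — catastrophic in floating
  point. Floats appear only at the moments boundary; the standard
  deviation of huge-denominator rationals goes through an integer square
  root to preserve precision and avoid float overflow.
- `z = 3.09` is the fixed quantile for α = 10⁻³ (the conventional
  rounded value); the exact quantile 3.0902… is available via
  `exact_quantile=True` and moves the thresholds by < 0.001.
- Canonical taxon order is the lexicographic order of labels, fixed per
  analysis; all masks refer to it. Bipartition identity is the unordered
  pair {mask, complement} (the numerically smaller mask is stored). The
  caterpillar scan order is the *numeric* tip order 1..n, which differs
  from the lexicographic mask order for n ≥ 10 — conversion is explicit
  and tested.
- Black = light side; for even splits (`p = n/2`) black is the side
  containing the first taxon in canonical order. δ is
  complement-symmetric, so the choice never affects a distance.
- Degenerate inputs: trivial branches (`p < 2`) are rejected wherever
  `TS` would divide by `p − 1 = 0`; multifurcating trees are rejected by
  the generators and the parsimony routine but accepted by the transfer
  index.

## Null models and the synthetic-data generators

All test inputs are generated, not stored. Four null models for
signal-free trees:

- **caterpillar** (fixed): the unique maximally imbalanced labelled
  shape, tips 1..n along the path, cherries {1,2} and {n−1,n};
- **fully balanced** (fixed): rooted complete binary tree, `n = 2^h`;
- **PDA**: uniform over the `(2n−5)!!` unrooted binary labelled
  topologies, by attaching tip `k+1` to one of the `2k−3` edges chosen
  uniformly — exact uniformity, O(n) per tree;
- **Yule–Harding**: repeated uniform splitting of a pendant lineage
  starting from a cherry, then a uniform random tip labelling; kept
  rooted (φ is root-invariant).

Reference bipartitions are uniform `p`-subsets painted black. RNG:
`numpy.random.Generator` (PCG64) with explicit integer seeds; identical
seeds give byte-identical outputs, and every CLI output embeds its full
configuration (seed and RNG algorithm included) in its header.

These generators emulate the *absence* of phylogenetic signal only. They
do not model sequence evolution, reconstruction error, branch lengths,
or the correlation structure of real bootstrap replicates (which are
resampled columns of one alignment, not independent random topologies).
Passing tests therefore validate the mathematics of the statistics and
of the null calibration — not the behaviour of TBE on any real data set.

## Simulation scales

The full no-signal experiment (four models, n up to 1024, every
p ∈ {2..n/2}, 100 bipartitions × 1000 trees per cell) is reproducible
through `tbekit simulate`, but the package's own test defaults are
desk-scale: 100 × 100 draws per (model, n, p) cell and a handful of
representative p values, which keeps the whole suite in tens of seconds
while leaving every Monte-Carlo check at least 3-standard-error sharp.
For the fixed topologies only bicolorations are resampled (the tree is a
constant); for PDA/Yule both trees and bicolorations are redrawn. The
CLT calibration check uses 10⁴ simulated TBEs of 100 replicates each
(10⁶ φ draws), via a vectorised lattice-path sampler.

## Known limitations

- Exact pmfs exist here only for the caterpillar topology; balanced,
  PDA and Yule nulls are handled by simulation (their exact φ
  distribution is an open problem).
- The CLT threshold is an approximation in `N`; for very small replicate
  counts (say N < 30) the normal tail underestimates the discrete upper
  tail and the threshold should be treated as indicative.
- The conservativeness of the caterpillar null for other topologies is
  conjectural (see above); the CLI labels the test accordingly.
- Newick is the only supported tree format (one tree per line for
  bootstrap sets); Nexus/PhyloXML, branch-length-aware metrics and tree
  rearrangements are out of scope.
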
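# tbekit

Tools for the **transfer distance** family of branch-support statistics in
phylogenetics: the transfer index, the transfer support (TS), the transfer
bootstrap expectation (TBE), and — the centrepiece — the **exact null
distribution of the transfer index on caterpillar trees**, from which
significance thresholds for TBE can be computed in the absence of
phylogenetic signal.

## Who this is for

TBE is increasingly used instead of Felsenstein's bootstrap proportions for
large trees, because it degrades gracefully when a handful of unstable taxa
jump around between bootstrap replicates. But a TBE value by itself does not
say whether it could have arisen by chance: random "bootstrap" trees do not
give TBE = 0. `tbekit` is for phylogeneticists and methods developers who
want to (a) compute φ/TS/TBE on Newick trees, (b) know the exact null
distribution of these statistics, and (c) attach a p-value or a rejection
threshold to an observed TBE.

## The statistics

Fix a taxon set of size *n* and a reference branch β whose light side has
*p* taxa (2 ≤ p ≤ ⌊n/2⌋), encoded as a bicoloration χ (black = light side).
For a branch *b* of another tree *T* on the same taxa:

- **transfer distance** δ(χ, b) = min of the Hamming distances between the
  0/1 encodings over the two orientations of *b* — the number of taxa that
  must cross *b* to recreate β. Equivalently δ = min(W_l + B_h, W_h + B_l)
  from the black/white counts on the two sides of *b*.
- **transfer index** φ(χ, T) = min over all branches of *T* of δ; it is 0
  iff β is a branch of *T*, and never exceeds p − 1.
- **transfer support** TS = 1 − φ/(p − 1) ∈ [0, 1].
- **TBE** = mean TS over a set of bootstrap trees.

On a caterpillar tree with tips 1..n ordered along the internal path, a
bicoloration maps bijectively to a monotone NE lattice path from (0, 0) to
(p, n − p) (black tip → east, white tip → north), and

    φ = min( M(path, Q), M(path, Q′), p − 1 ),

where M is the Manhattan distance of the path to the rectangle corners
Q = (p, 0) and Q′ = (0, n − p). Counting paths at a prescribed distance from
both corners is a reflection-principle computation, which yields the exact
pmf and moments of φ — and hence of TS — under a uniform random reference
bipartition. Combining the exact TS moments with the central limit theorem
for the mean of N bootstrap replicates gives a one-sided rejection threshold

    TBE* = mean_TS + z_α · sd_TS / √N .

The caterpillar is used as the null topology because simulations across tree
shapes indicate it maximises the expected null TS at p = ⌊n/2⌋, making the
threshold conservative for other topologies (a heuristic, not a theorem).

## Worked example

```python
import tbekit as tk

ref = tk.parse_newick("(((1,2),(3,4)),((5,6),(7,8)));")
branch = tk.Bicoloration.from_black_labels(ref.taxa, ["1", "2", "3", "4"]).as_bipartition()

# 100 signal-free "bootstrap" trees (Yule–Harding null)
rng = tk.ensure_rng(42)
boots = [tk.yule_tree(8, rng) for _ in range(100)]
print(round(tk.tbe(ref, branch, boots), 4))          # 0.3133

thr = tk.ts_null_threshold(n=8, p=4, replicates=100, alpha=1e-3)
print(round(thr.mean_ts, 4), round(thr.threshold, 4))  # 0.3429 0.4187
print(tk.tbe_pvalue(0.3133, n=8, p=4, replicates=100)) # 0.8855...
```

The reference branch {1,2,3,4} | {5,6,7,8} gets TBE ≈ 0.31 against random
trees — far from 0 on such a tiny tree, but *below* the exact null mean
0.3429, hence entirely consistent with chance (p ≈ 0.89). On large trees the
null mean collapses towards 0, which is what makes TBE interpretable there:

```
$ tbekit threshold --n 128 --n 256 --n 512 --n 1024 --replicates 100 --alpha 1e-3
n     p    ...  mean_ts    sd_ts     threshold  threshold_rounded
128   64   ...  0.132505   0.046697  0.146935   0.147
256   128  ...  0.097742   0.032779  0.107871   0.108
512   256  ...  0.071242   0.023094  0.078378   0.078
1024  512  ...  0.051480   0.016300  0.056517   0.057
```

So on a 128-taxon tree with 100 replicates, any branch with TBE ≤ 0.147
could have been produced with no phylogenetic signal at all (one-sided
p ≥ 10⁻³), while conventional support levels (TBE > 0.7) are unreachable by
chance even on small trees.

Other entry points: `tbekit tbe` (score reference branches against a
bootstrap file), `tbekit exact --n 14 --p 7 --pmf -` (exact pmf of φ as
rational numbers), `tbekit gentree` (caterpillar / balanced / PDA /
Yule–Harding generators), `tbekit simulate` (Monte-Carlo TS curves),
`tbekit parsimony`, `tbekit fixtures`.

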
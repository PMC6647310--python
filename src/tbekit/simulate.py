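"""Monte-Carlo experiments on the null models and fixture generation.

The central experiment mirrors the no-signal protocol: for a grid of
light-side sizes ``p``, draw uniform reference bipartitions and random
null trees, and record the mean and spread of the transfer support over
all (bipartition, tree) pairs.  For the two fixed topologies
(caterpillar, fully balanced) the tree is a constant and only
bicolorations are resampled; for PDA and Yule--Harding both vary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .nullmodels import (
    balanced_tree,
    caterpillar_tree,
    ensure_rng,
    pda_tree,
    yule_tree,
)
from .transfer import transfer_index_batch
from .treeio import PhyloTree, write_newick

__all__ = [
    "MODELS",
    "SimCurve",
    "random_black_matrix",
    "sample_caterpillar_phi",
    "simulate_ts_curve",
    "make_fixtures",
]

MODELS = ("caterpillar", "balanced", "pda", "yule")
FIXED_TOPOLOGY = {"caterpillar", "balanced"}


@dataclass(frozen=True)
class SimCurve:
    """Mean/sd of TS per light-side size under one null model."""

    model: str
    n: int
    seed: int | None
    table: pd.DataFrame  # columns: p, mean_ts, sd_ts, n_bip, n_trees, n_draws


def _make_tree(model: str, n: int, rng) -> PhyloTree:
    if model == "caterpillar":
        return caterpillar_tree(n)
    if model == "balanced":
        h = int(n).bit_length() - 1
        if 2 ** h != n:
            raise ValueError("balanced model requires n = 2**h")
        return balanced_tree(h)
    if model == "pda":
        return pda_tree(n, rng)
    if model == "yule":
        return yule_tree(n, rng)
    raise ValueError(f"unknown model {model!r}; choose from {MODELS}")


def random_black_matrix(n: int, p: int, size: int, rng) -> np.ndarray:
    """``size`` uniform p-subsets as boolean rows over the canonical
    (lexicographic) taxon order of tips labelled 1..n."""
    rng = ensure_rng(rng)
    # draw in tip order, then map to canonical label order
    tip_black = np.zeros((size, n), dtype=bool)
    for i in range(size):
        tip_black[i, rng.choice(n, size=p, replace=False)] = True
    order = np.argsort(np.array([str(i) for i in range(1, n + 1)]))
    canon = np.empty_like(tip_black)
    canon[:, :] = tip_black[:, order]
    return canon


def sample_caterpillar_phi(n: int, p: int, size: int, rng) -> np.ndarray:
    """Vectorised transfer indices of uniform bicolorations on the
    caterpillar, via the lattice-path geometry (nearest Manhattan
    approach to a rectangle corner, capped at ``p - 1``)."""
    rng = ensure_rng(rng)
    out = np.empty(size, dtype=np.int64)
    chunk = max(1, min(size, 2 ** 22 // max(n, 1)))
    done = 0
    while done < size:
        m = min(chunk, size - done)
        # random p-subsets of tip positions via argpartition of uniforms
        u = rng.random((m, n))
        black = np.argpartition(u, p - 1, axis=1)[:, :p]
        steps = np.zeros((m, n), dtype=np.int8)
        np.put_along_axis(steps, black, 1, axis=1)  # 1 = east (black)
        x = np.cumsum(steps, axis=1)
        y = np.cumsum(1 - steps, axis=1)
        d_q = (p - x) + y  # Manhattan to (p, 0)
        d_qp = x + (n - p) - y  # Manhattan to (0, n-p)
        best = np.minimum(d_q, d_qp).min(axis=1)
        best = np.minimum(best, np.minimum(p, n - p))  # origin vertex
        out[done : done + m] = np.minimum(best, p - 1)
        done += m
    return out


def simulate_ts_curve(
    model: str,
    n: int,
    n_bip: int = 100,
    n_trees: int = 100,
    rng=None,
    p_values=None,
) -> SimCurve:
    """Simulated TS curve under a null model.

    For each ``p`` (default: every value from 2 to ``n // 2``), draws
    ``n_bip`` uniform reference bipartitions; for the random models it
    also draws ``n_trees`` trees and evaluates all pairs, while for the
    fixed topologies each bipartition is evaluated once against the
    single tree.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    if n < 8:
        raise ValueError("need n >= 8")
    seed = None
    if not isinstance(rng, np.random.Generator):
        seed = rng
    rng = ensure_rng(rng)
    if p_values is None:
        p_values = range(2, n // 2 + 1)
    fixed = model in FIXED_TOPOLOGY
    fixed_tree = _make_tree(model, n, rng) if fixed else None
    rows = []
    for p in p_values:
        ts_all = []
        if fixed:
            black = random_black_matrix(n, p, n_bip, rng)
            phi = transfer_index_batch(fixed_tree, black)
            ts_all.append(1.0 - phi / (p - 1))
        else:
            black = random_black_matrix(n, p, n_bip, rng)
            for _ in range(n_trees):
                tree = _make_tree(model, n, rng)
                phi = transfer_index_batch(tree, black)
                ts_all.append(1.0 - phi / (p - 1))
        ts = np.concatenate(ts_all)
        rows.append(
            {
                "p": int(p),
                "mean_ts": float(ts.mean()),
                "sd_ts": float(ts.std(ddof=1)) if ts.size > 1 else 0.0,
                "n_bip": n_bip,
                "n_trees": 1 if fixed else n_trees,
                "n_draws": int(ts.size),
            }
        )
    return SimCurve(model=model, n=n, seed=seed, table=pd.DataFrame(rows))


def make_fixtures(out_dir, seed: int) -> dict:
    """Write small Newick fixtures plus a manifest of expected transfer
    indices/supports computed by the per-edge Hamming oracle.

    Returns the manifest (also written as ``manifest.json``).
    """
    from .nullmodels import random_bicoloration
    from .transfer import transfer_index_naive
    from .treeio import write_newick_file

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = ensure_rng(seed)
    manifest: dict = {"seed": seed, "cases": [], "bundles": []}

    # hand-checkable small cases on caterpillars
    for n, black in [(4, ["1", "2"]), (4, ["1", "3"]), (8, ["2", "5", "7"]), (11, ["1", "2", "3", "4", "5"])]:
        tree = caterpillar_tree(n)
        from .treeio import Bicoloration

        chi = Bicoloration.from_black_labels(tree.taxa, black)
        phi = transfer_index_naive(chi, tree)
        fname = f"caterpillar_n{n}_{'_'.join(black)}.nwk"
        write_newick_file(out / fname, [tree])
        manifest["cases"].append(
            {
                "tree": fname,
                "black": black,
                "phi": int(phi),
                "ts": 1.0 - phi / (chi.p - 1),
            }
        )

    # bootstrap bundles under each null model
    for model in MODELS:
        n = 16
        trees = [_make_tree(model, n, rng) for _ in range(20)]
        fname = f"boot_{model}_n{n}.nwk"
        write_newick_file(out / fname, trees)
        chi = random_bicoloration(n, 4, rng)
        phis = [int(transfer_index_naive(chi, t)) for t in trees]
        manifest["bundles"].append(
            {
                "model": model,
                "file": fname,
                "n": n,
                "black": list(chi.black_labels()),
                "phi": phis,
                "mean_ts": float(np.mean([1.0 - f / (chi.p - 1) for f in phis])),
            }
        )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
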
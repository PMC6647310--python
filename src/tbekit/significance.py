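"""Significance thresholds and p-values for TBE under the no-signal
caterpillar null.

TBE is a mean of ``N`` bootstrap transfer supports, so under the null
(random trees carrying no signal for the reference branch) the CLT
approximates its distribution by a normal with the exact caterpillar
TS mean and standard deviation ``sd_TS / sqrt(N)``.  The one-sided
rejection threshold at level ``alpha`` is then

    threshold = mean_TS + z_alpha * sd_TS / sqrt(N).

The caterpillar is used as the null topology because, empirically, it
maximises the expected TS among tree shapes at ``p = n/2`` — making the
test conservative for other topologies; this maximality is a
simulation-supported heuristic, not a theorem, and the module makes no
exactness claim for non-caterpillar shapes.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt
from typing import Sequence

import pandas as pd
from scipy.stats import norm

from .lattice import caterpillar_moments

__all__ = ["ThresholdResult", "ts_null_threshold", "threshold_table", "tbe_pvalue"]

#: the conventional rounded upper 1e-3 normal quantile
Z_1E3 = 3.09


@dataclass(frozen=True)
class ThresholdResult:
    n: int
    p: int
    replicates: int
    alpha: float
    z: float
    mean_ts: float
    sd_ts: float
    threshold: float

    @property
    def threshold_rounded(self) -> float:
        return round(self.threshold, 3)


def _z_quantile(alpha: float, exact_quantile: bool) -> float:
    # 3.09 is the standard rounded value for alpha = 1e-3; the exact
    # quantile 3.0902... is available on request
    if not exact_quantile and abs(alpha - 1e-3) < 1e-12:
        return Z_1E3
    return float(norm.isf(alpha))


def ts_null_threshold(
    n: int,
    p: int,
    replicates: int,
    alpha: float = 1e-3,
    exact_quantile: bool = False,
) -> ThresholdResult:
    """One-sided TBE rejection threshold under the caterpillar null.

    Parameters
    ----------
    n, p:
        taxa count and light-side size of the reference branch,
        ``2 <= p <= n/2``.
    replicates:
        number of bootstrap trees averaged into the TBE.
    alpha:
        one-sided significance level, ``0 < alpha < 0.5``.
    """
    if replicates < 1:
        raise ValueError("need replicates >= 1")
    if not 0 < alpha < 0.5:
        raise ValueError("need 0 < alpha < 0.5")
    mom = caterpillar_moments(n, p)
    z = _z_quantile(alpha, exact_quantile)
    thr = mom.mean_ts + z * mom.sd_ts / sqrt(replicates)
    return ThresholdResult(
        n=n,
        p=p,
        replicates=replicates,
        alpha=alpha,
        z=z,
        mean_ts=mom.mean_ts,
        sd_ts=mom.sd_ts,
        threshold=thr,
    )


def threshold_table(
    ns: Sequence[int],
    replicates: int = 100,
    alpha: float = 1e-3,
    exact_quantile: bool = False,
) -> pd.DataFrame:
    """Threshold per tree size at the hardest reference branch
    ``p = n // 2`` (where the expected null TS is largest)."""
    rows = []
    for n in ns:
        if n < 8:
            raise ValueError("need n >= 8")
        r = ts_null_threshold(n, n // 2, replicates, alpha, exact_quantile)
        rows.append(
            {
                "n": r.n,
                "p": r.p,
                "replicates": r.replicates,
                "alpha": r.alpha,
                "z": r.z,
                "mean_ts": r.mean_ts,
                "sd_ts": r.sd_ts,
                "threshold": r.threshold,
                "threshold_rounded": r.threshold_rounded,
            }
        )
    return pd.DataFrame(rows)


def tbe_pvalue(observed_tbe: float, n: int, p: int, replicates: int) -> float:
    """One-sided p-value of an observed TBE under the caterpillar null:
    upper normal tail at the CLT mean/scale."""
    if not 0 <= observed_tbe <= 1:
        raise ValueError("TBE must lie in [0, 1]")
    mom = caterpillar_moments(n, p)
    scale = mom.sd_ts / sqrt(replicates)
    return float(norm.sf(observed_tbe, loc=mom.mean_ts, scale=scale))
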
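"""Divergence and diversity summaries (d_xy, pi, F_ST), sliding-window
scans, and the 2x2 G-test of gene enrichment.

All quantities are computed from per-block mutation-type counts for
heterospecific pairs of diploids.  For one block of ``ell`` callable sites:

* ``d_xy    = (hetA/2 + hetB/2 + hetAB/2 + fixed) / ell``
* ``pi_A    = (hetA + hetAB) / ell`` (the A individual is heterozygous at
  hetAB sites too -- easy to get wrong from the 4-type tally)
* ``pi_B    = (hetB + hetAB) / ell``

F_ST uses Hudson's ``1 - H_w / H_b`` form on block-aggregated means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

__all__ = [
    "PartitionStats",
    "partition_stats",
    "sliding_window_dxy",
    "gtest_2x2",
]


@dataclass
class PartitionStats:
    d_xy: float
    pi_a: float
    pi_b: float
    f_st: float | None
    n_blocks: int
    partition: str = ""
    site_class: str = ""


def partition_stats(
    block_counts,
    block_length: int,
    partition: str = "",
    site_class: str = "",
) -> PartitionStats:
    """Mean d_xy, within-species pi and Hudson F_ST over blocks (and pairs).

    ``block_counts`` is an (n_blocks, 4) matrix of (hetA, hetB, hetAB,
    fixed) counts, concatenated over heterospecific pairs.  F_ST is
    undefined (None) when d_xy = 0.
    """
    bc = np.asarray(block_counts, dtype=float)
    if bc.ndim != 2 or bc.shape[1] != 4 or len(bc) == 0:
        raise ValueError("block_counts must be a non-empty (n, 4) matrix")
    ha, hb, hab, fx = bc.mean(axis=0)
    ell = float(block_length)
    d_xy = (0.5 * (ha + hb + hab) + fx) / ell
    pi_a = (ha + hab) / ell
    pi_b = (hb + hab) / ell
    f_st = None if d_xy == 0 else 1.0 - 0.5 * (pi_a + pi_b) / d_xy
    return PartitionStats(d_xy, pi_a, pi_b, f_st, len(bc), partition, site_class)


def block_dxy(block_counts, block_length: int) -> np.ndarray:
    """Per-block d_xy values."""
    bc = np.asarray(block_counts, dtype=float)
    return (0.5 * (bc[:, 0] + bc[:, 1] + bc[:, 2]) + bc[:, 3]) / block_length


def sliding_window_dxy(
    block_counts,
    block_length: int,
    window: int = 5000,
    step: int = 500,
    midpoints=None,
    chrom: str = "",
) -> pd.DataFrame:
    """Sliding-window mean d_xy over genome-ordered blocks.

    Windows of ``window`` blocks advance by ``step`` blocks; trailing
    windows with fewer than ``window`` blocks are dropped.  Blocks must all
    belong to one chromosome (windows never span chromosome boundaries).
    """
    if not (window >= step >= 1):
        raise ValueError("need window >= step >= 1")
    d = block_dxy(block_counts, block_length)
    n = len(d)
    if n < window:
        return pd.DataFrame(columns=["chrom", "start_block", "mid", "d_xy"])
    csum = np.concatenate([[0.0], np.cumsum(d)])
    starts = np.arange(0, n - window + 1, step)
    means = (csum[starts + window] - csum[starts]) / window
    if midpoints is not None:
        mids = np.asarray(midpoints, dtype=float)
        mid = (mids[starts] + mids[starts + window - 1]) / 2.0
    else:
        mid = starts + (window - 1) / 2.0
    return pd.DataFrame(
        {"chrom": chrom, "start_block": starts, "mid": mid, "d_xy": means}
    )


def gtest_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Log-likelihood-ratio (G) test of independence for a 2x2 table.

    ``G = 2 * sum O * ln(O / E)`` with expectations from the marginal
    products; p-value from the upper tail of chi-square with 1 df.  No
    continuity or Williams correction is applied.
    """
    obs = np.array([[a, b], [c, d]], dtype=float)
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row <= 0).any() or (col <= 0).any():
        raise ValueError("G-test requires positive marginals")
    exp = np.outer(row, col) / obs.sum()
    mask = obs > 0
    g = 2.0 * float(np.sum(obs[mask] * np.log(obs[mask] / exp[mask])))
    g = max(g, 0.0)
    return g, float(chi2.sf(g, df=1))
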
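"""Exact integer interval-set algebra (0-based, half-open).

Sorted-merge implementations of union, intersection and difference used for
BED-style masks, partition construction and punching per-site missing-data
holes.  All functions take and return lists of ``(start, end)`` tuples with
``end > start``; outputs are sorted and disjoint.
"""

from __future__ import annotations

import numpy as np

__all__ = ["merge", "intersect", "subtract", "total_length", "complement", "validate"]


def validate(iv, chrom_length: int | None = None):
    for s, e in iv:
        if e <= s:
            raise ValueError(f"empty or inverted interval ({s}, {e})")
        if s < 0:
            raise ValueError(f"negative coordinate in ({s}, {e})")
        if chrom_length is not None and e > chrom_length:
            raise ValueError(f"interval ({s}, {e}) beyond chromosome end {chrom_length}")


def merge(iv):
    """Sort and merge overlapping or abutting intervals."""
    if not iv:
        return []
    iv = sorted(iv)
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def intersect(a, b):
    """Set intersection of two interval lists."""
    a, b = merge(a), merge(b)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def subtract(a, b):
    """Set difference a \\ b."""
    a, b = merge(a), merge(b)
    out = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def subtract_positions(a, positions):
    """Remove single positions (1-bp holes) from an interval list."""
    pos = np.unique(np.asarray(list(positions), dtype=np.int64))
    if len(pos) == 0:
        return merge(a)
    return subtract(a, [(int(p), int(p) + 1) for p in pos])


def complement(iv, chrom_length: int):
    return subtract([(0, chrom_length)], iv)


def total_length(iv) -> int:
    return sum(e - s for s, e in merge(iv))
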
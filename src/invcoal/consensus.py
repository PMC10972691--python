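"""Consensus filtering of inversion calls from two SV callers.

Events cluster when both breakpoints agree within a tolerance AND the
reciprocal overlap exceeds a threshold; a cluster is retained as an
alternatively fixed, species-specific inversion when it is supported by
both callers, exceeds the minimum size, reaches the species' carrier
threshold (>= 9 of 12 / >= 6 of 9 samples by default) in exactly one
species, and is called in at most ``rarity_ceiling`` samples of the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SVEvent",
    "SVCluster",
    "ConsensusInversion",
    "merge_calls",
    "fixed_inversion_filter",
]

MIN_SIZE_DEFAULT = 500_000  # >0.5 Mb
CARRIER_THRESHOLDS_DEFAULT = {"A": 9, "B": 6}
COHORT_SIZES_DEFAULT = {"A": 12, "B": 9}


@dataclass(frozen=True)
class SVEvent:
    chrom: str
    start: int
    end: int
    sample: str
    species: str
    caller: str
    svtype: str = "INV"
    genotype: str | None = None

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"end must exceed start ({self.start}, {self.end})")

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class SVCluster:
    chrom: str
    start: float
    end: float
    svtype: str
    events: list = field(default_factory=list)

    @property
    def callers(self) -> set:
        return {e.caller for e in self.events}

    def samples(self, species: str) -> set:
        return {e.sample for e in self.events if e.species == species}

    @property
    def size(self) -> float:
        return self.end - self.start


@dataclass
class ConsensusInversion:
    chrom: str
    start: int
    end: int
    species: str  # carrier of the derived arrangement (or of the calls)
    n_samples: dict
    callers: set

    @property
    def size(self) -> int:
        return self.end - self.start


def events_from_frame(df: pd.DataFrame) -> list:
    return [
        SVEvent(
            str(r.chrom),
            int(r.start),
            int(r.end),
            str(r.sample),
            str(r.species),
            str(r.caller),
            str(getattr(r, "svtype", "INV")),
        )
        for r in df.itertuples(index=False)
    ]


def _reciprocal_overlap(a_start, a_end, b_start, b_end) -> float:
    inter = min(a_end, b_end) - max(a_start, b_start)
    if inter <= 0:
        return 0.0
    return min(inter / (a_end - a_start), inter / (b_end - b_start))


def merge_calls(
    events,
    tolerance: int = 1000,
    min_reciprocal_overlap: float = 0.8,
) -> list:
    """Cluster caller events with agreeing breakpoints.

    Events (from any caller) join a cluster if both breakpoints lie within
    ``tolerance`` bp of the cluster's running mean breakpoints and the
    reciprocal overlap is at least ``min_reciprocal_overlap``.  Events are
    pre-sorted deterministically, so the result is invariant to input
    order.  Mixed SV types never share a cluster.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if not (0 < min_reciprocal_overlap <= 1):
        raise ValueError("min reciprocal overlap must be in (0, 1]")
    evs = sorted(events, key=lambda e: (e.chrom, e.svtype, e.start, e.end, e.sample, e.caller))
    clusters: list[SVCluster] = []
    for e in evs:
        placed = False
        for cl in clusters:
            if cl.chrom != e.chrom or cl.svtype != e.svtype:
                continue
            if (
                abs(e.start - cl.start) <= tolerance
                and abs(e.end - cl.end) <= tolerance
                and _reciprocal_overlap(e.start, e.end, cl.start, cl.end)
                >= min_reciprocal_overlap
            ):
                cl.events.append(e)
                n = len(cl.events)
                cl.start += (e.start - cl.start) / n
                cl.end += (e.end - cl.end) / n
                placed = True
                break
        if not placed:
            clusters.append(SVCluster(e.chrom, float(e.start), float(e.end), e.svtype, [e]))
    return clusters


def fixed_inversion_filter(
    clusters,
    min_size: int = MIN_SIZE_DEFAULT,
    carrier_thresholds: dict | None = None,
    cohort_sizes: dict | None = None,
    rarity_ceiling: int = 1,
    require_both_callers: bool = True,
) -> list:
    """Retain large, species-specific, geographically widespread inversions.

    A cluster passes when: supported by both callers; size > ``min_size``;
    the per-species distinct-sample support reaches the carrier threshold in
    exactly one species; and support in the other species is at most
    ``rarity_ceiling`` (tolerates isolated caller noise while remaining
    effectively alternatively fixed).
    """
    thr = carrier_thresholds or CARRIER_THRESHOLDS_DEFAULT
    cohorts = cohort_sizes or COHORT_SIZES_DEFAULT
    out = []
    for cl in sorted(clusters, key=lambda c: (c.chrom, c.start, c.end)):
        support = {sp: cl.samples(sp) for sp in thr}
        for sp, members in support.items():
            if sp in cohorts and len(members) > cohorts[sp]:
                raise ValueError(
                    f"{len(members)} supporting samples exceed the {sp} cohort size {cohorts[sp]}"
                )
        if require_both_callers and len(cl.callers) < 2:
            continue
        if cl.size <= min_size:
            continue
        carriers = [sp for sp in thr if len(support[sp]) >= thr[sp]]
        if len(carriers) != 1:
            continue
        other = [sp for sp in thr if sp != carriers[0]]
        if any(len(support[sp]) > rarity_ceiling for sp in other):
            continue
        out.append(
            ConsensusInversion(
                chrom=cl.chrom,
                start=int(round(cl.start)),
                end=int(round(cl.end)),
                species=carriers[0],
                n_samples={sp: len(support[sp]) for sp in thr},
                callers=cl.callers,
            )
        )
    return out
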
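"""Sliding-window detection of QTL clusters and single-trait hotspots.

A *cluster* is a chromosome region of roughly one window length (20 cM by
default) holding at least ``min_cluster`` QTL of at least ``min_traits``
distinct trait types. A *hotspot* is the single-trait analogue: the scan is
repeated per trait and a region qualifies with ``min_hotspot`` QTL of that
one trait. Windows are anchored at QTL positions rather than a fixed grid,
which makes the calls deterministic and independent of input order;
overlapping qualifying windows merge into one call, reported as the span
from its first to its last member.

:func:`estimate_false_positive_rate` quantifies how often a cluster-sized
aggregate arises by chance when the same number of QTL is scattered
uniformly over the chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io import QtlRecord

__all__ = [
    "DetectionConfig",
    "ClusterCall",
    "HotspotCall",
    "scan_windows",
    "detect_clusters",
    "detect_hotspots",
    "name_calls",
    "estimate_false_positive_rate",
]


def _chrom_sort_key(code: str) -> int:
    return int(code.lstrip("c"))


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable thresholds of the window scan.

    window
        region size in cM within which co-occurring QTL aggregate (20 by
        default; "approximately 20 cM" in the underlying survey).
    min_cluster / min_hotspot
        minimum member count to declare a call (4: "four or more QTL").
    min_traits
        distinct trait types required for a cluster ("various traits").
    membership
        ``point`` counts a QTL by its point position; ``ci-overlap`` also
        admits QTL whose confidence interval intersects the call interval.
    fpr_reps / seed
        Monte-Carlo settings for the chance-aggregation estimator.
    """

    window: float = 20.0
    min_cluster: int = 4
    min_hotspot: int = 4
    min_traits: int = 2
    membership: str = "point"
    fpr_reps: int = 10_000
    seed: int = 20131111

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.min_cluster < 2 or self.min_hotspot < 2:
            raise ValueError("min_cluster and min_hotspot must be >= 2")
        if self.min_traits < 1:
            raise ValueError("min_traits must be >= 1")
        if self.membership not in ("point", "ci-overlap"):
            raise ValueError(f"unknown membership mode: {self.membership!r}")


@dataclass
class ClusterCall:
    """A multi-trait QTL aggregate on one chromosome."""

    chromosome: str
    start: float
    end: float
    members: list[QtlRecord]
    name: str = ""

    @property
    def n_qtl(self) -> int:
        return len(self.members)

    @property
    def n_traits(self) -> int:
        return len({m.trait for m in self.members})


@dataclass
class HotspotCall:
    """A single-trait QTL aggregate on one chromosome."""

    chromosome: str
    trait: str
    start: float
    end: float
    members: list[QtlRecord]
    name: str = ""

    @property
    def n_qtl(self) -> int:
        return len(self.members)


def scan_windows(
    positions: Sequence[float], window: float, min_count: int
) -> list[tuple[float, float, list[int]]]:
    """Find merged windows of length ``window`` holding >= ``min_count`` points.

    ``positions`` must be sorted ascending. Candidate windows
    ``[x_i, x_i + window]`` are anchored at each position; qualifying
    windows that overlap are merged, and each merged region is reported as
    ``(min member position, max member position, member indices)``. Member
    indices partition across regions.
    """
    n = len(positions)
    if n == 0:
        return []
    x = np.asarray(positions, dtype=float)
    if np.any(np.diff(x) < 0):
        raise ValueError("positions must be sorted ascending")
    # rightmost index whose position fits in the window anchored at i
    right = np.searchsorted(x, x + window, side="right") - 1
    counts = right - np.arange(n) + 1
    anchors = np.flatnonzero(counts >= min_count)
    if anchors.size == 0:
        return []

    regions: list[tuple[float, float, list[int]]] = []
    i = 0
    while i < anchors.size:
        j = i
        # merge anchor windows that overlap: next anchor starts inside the
        # running window span
        while j + 1 < anchors.size and x[anchors[j + 1]] <= x[anchors[j]] + window:
            j += 1
        first = int(anchors[i])
        last = int(right[anchors[j]])
        members = list(range(first, last + 1))
        regions.append((float(x[first]), float(x[last]), members))
        i = j + 1
    return regions


def _sorted_by_position(records: Iterable[QtlRecord]) -> list[QtlRecord]:
    # stable tie-break on name/study keeps calls invariant to input order
    return sorted(records, key=lambda r: (r.position, r.qtl_name, r.study_id))


def _ci_overlap_members(
    records: Iterable[QtlRecord], start: float, end: float
) -> list[QtlRecord]:
    return [r for r in records if r.ci_lo <= end and r.ci_hi >= start]


def detect_clusters(
    records: Sequence[QtlRecord], config: DetectionConfig = DetectionConfig()
) -> list[ClusterCall]:
    """Call multi-trait clusters per chromosome and name them.

    The window scan runs over all trait types jointly; qualifying regions
    with fewer than ``config.min_traits`` distinct traits are dropped.
    Names follow ``c{N}-cluster-{i}`` with ``i`` restarting at 1 per
    chromosome in start order.
    """
    calls: list[ClusterCall] = []
    by_chrom: dict[str, list[QtlRecord]] = {}
    for r in records:
        by_chrom.setdefault(r.chromosome, []).append(r)
    for chrom in sorted(by_chrom, key=_chrom_sort_key):
        recs = _sorted_by_position(by_chrom[chrom])
        positions = [r.position for r in recs]
        for start, end, idx in scan_windows(positions, config.window, config.min_cluster):
            members = [recs[i] for i in idx]
            if config.membership == "ci-overlap":
                members = _ci_overlap_members(recs, start, end)
            call = ClusterCall(chromosome=chrom, start=start, end=end, members=members)
            if call.n_traits >= config.min_traits:
                calls.append(call)
    return name_calls(calls, [])[0]


def detect_hotspots(
    records: Sequence[QtlRecord], config: DetectionConfig = DetectionConfig()
) -> list[HotspotCall]:
    """Call single-trait hotspots: the window scan repeated per trait type."""
    calls: list[HotspotCall] = []
    by_chrom_trait: dict[tuple[str, str], list[QtlRecord]] = {}
    for r in records:
        by_chrom_trait.setdefault((r.chromosome, r.trait), []).append(r)
    for chrom, trait in sorted(
        by_chrom_trait, key=lambda k: (_chrom_sort_key(k[0]), k[1])
    ):
        recs = _sorted_by_position(by_chrom_trait[(chrom, trait)])
        positions = [r.position for r in recs]
        for start, end, idx in scan_windows(positions, config.window, config.min_hotspot):
            members = [recs[i] for i in idx]
            if config.membership == "ci-overlap":
                members = _ci_overlap_members(recs, start, end)
            calls.append(
                HotspotCall(chromosome=chrom, trait=trait, start=start, end=end, members=members)
            )
    return name_calls([], calls)[1]


def name_calls(
    clusters: list[ClusterCall], hotspots: list[HotspotCall]
) -> tuple[list[ClusterCall], list[HotspotCall]]:
    """Assign the published naming convention to calls.

    Clusters: ``c{N}-cluster-{i}``, ``i`` restarting at 1 per chromosome in
    start order. Hotspots: ``c{N}-{Trait}-Hotspot-{j}`` with ``j`` a single
    genome-wide counter per trait, advancing in chromosome then start order.
    """
    clusters = sorted(clusters, key=lambda c: (_chrom_sort_key(c.chromosome), c.start))
    index = 0
    prev_chrom = None
    for call in clusters:
        index = index + 1 if call.chromosome == prev_chrom else 1
        prev_chrom = call.chromosome
        call.name = f"{call.chromosome}-cluster-{index}"

    hotspots = sorted(
        hotspots, key=lambda h: (_chrom_sort_key(h.chromosome), h.start, h.trait)
    )
    per_trait: dict[str, int] = {}
    for call in hotspots:
        j = per_trait.get(call.trait, 0) + 1
        per_trait[call.trait] = j
        call.name = f"{call.chromosome}-{call.trait}-Hotspot-{j}"
    return clusters, hotspots


def estimate_false_positive_rate(
    n_qtl: int,
    chrom_length: float,
    config: DetectionConfig = DetectionConfig(),
) -> float:
    """Chance probability of >= 1 cluster-sized window under a uniform null.

    Scatters ``n_qtl`` positions uniformly on ``[0, chrom_length]`` and
    reports the fraction of ``config.fpr_reps`` replicates in which some
    window of ``config.window`` cM captures at least ``config.min_cluster``
    of them. Deterministic given ``config.seed``.
    """
    if n_qtl < 0:
        raise ValueError("n_qtl must be >= 0")
    if chrom_length <= 0:
        raise ValueError("chrom_length must be positive")
    k = config.min_cluster
    if n_qtl < k:
        return 0.0
    if config.window >= chrom_length:
        return 1.0
    rng = np.random.default_rng(config.seed)
    hits = 0
    reps = config.fpr_reps
    batch = max(1, min(reps, 200_000 // max(n_qtl, 1)))
    done = 0
    while done < reps:
        m = min(batch, reps - done)
        x = np.sort(rng.uniform(0.0, chrom_length, size=(m, n_qtl)), axis=1)
        # window anchored at each point: does it hold k points?
        span = x[:, k - 1:] - x[:, : n_qtl - k + 1]
        hits += int(np.count_nonzero(np.any(span <= config.window, axis=1)))
        done += m
    return hits / reps
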
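"""Synthetic multi-study QTL collections with planted structure.

The generator emulates the statistical shape of a pooled QTL survey in
tetraploid cotton: per-chromosome consensus maps of roughly 80-150 cM,
QTL positions drawn from planted Gaussian clusters plus a uniform
background, heterogeneous confidence-interval widths with a heavy-tailed
(log-normal) spread, trait labels from the 43-code vocabulary and
round-robin study provenance. A configurable fraction of records is
emitted with position and/or CI blanked and flanking markers supplied
instead, so the projection stage is exercised end to end. Ground truth
records which QTL came from which planted region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .detection import ClusterCall, HotspotCall
from .io import CHROMOSOMES, ConsensusMap, MarkerLocus, QtlRecord

__all__ = [
    "PlantedRegion",
    "SyntheticSpec",
    "GroundTruth",
    "RecoveryReport",
    "generate_map",
    "generate_qtl_set",
    "recovery_report",
]


@dataclass(frozen=True)
class PlantedRegion:
    """One planted aggregate: n_per_trait QTL per trait, centered on a chromosome."""

    chromosome: str
    center: float
    sd: float
    traits: tuple[str, ...]
    n_per_trait: int

    @property
    def n_qtl(self) -> int:
        return self.n_per_trait * len(self.traits)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic collection.

    Defaults mirror a pooled cotton survey: 26 chromosomes of 80-150 cM,
    42 contributing studies, log-normal CI widths with median 15 cM
    (sigma 0.5 on the log scale), and a thin uniform background per trait.
    """

    n_chromosomes: int = 26
    length_range: tuple[float, float] = (80.0, 150.0)
    n_studies: int = 42
    planted: tuple[PlantedRegion, ...] = ()
    background_rate: float = 0.2        # QTL per 100 cM per background trait
    background_traits: tuple[str, ...] = ("FS", "FL", "Micro", "FE", "BW")
    ci_width_median: float = 15.0       # cM
    ci_width_sigma: float = 0.5         # log-scale spread
    missing_position_frac: float = 0.0
    missing_ci_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.n_chromosomes > len(CHROMOSOMES):
            raise ValueError("n_chromosomes must be in 1..26")
        if self.length_range[0] <= 0 or self.length_range[1] < self.length_range[0]:
            raise ValueError("bad length_range")
        for frac in (self.missing_position_frac, self.missing_ci_frac):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("missing fractions must be in [0, 1]")

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return CHROMOSOMES[: self.n_chromosomes]


@dataclass
class GroundTruth:
    """Planted regions with their member QTL names and true positions."""

    regions: list[PlantedRegion] = field(default_factory=list)
    members: dict[int, list[str]] = field(default_factory=dict)   # region idx -> qtl names
    true_position: dict[str, float] = field(default_factory=dict)  # qtl name -> cM


def _rng_for(spec: SyntheticSpec, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, salt]))


def generate_map(spec: SyntheticSpec) -> ConsensusMap:
    """Draw a consensus map with markers every 1-5 cM; deterministic per seed."""
    rng = _rng_for(spec, 1)
    cmap = ConsensusMap()
    for ci, chrom in enumerate(spec.chromosomes):
        length = float(rng.uniform(*spec.length_range))
        positions = [0.0]
        while positions[-1] < length:
            positions.append(positions[-1] + float(rng.uniform(1.0, 5.0)))
        positions[-1] = length  # last marker closes the chromosome
        cmap.markers[chrom] = [
            MarkerLocus(name=f"{chrom}M{i + 1}", chromosome=chrom, position=round(p, 4))
            for i, p in enumerate(positions)
        ]
    return cmap


def _nearest_flanks(
    loci: Sequence[MarkerLocus], position: float
) -> tuple[MarkerLocus, MarkerLocus]:
    below = [l for l in loci if l.position <= position]
    above = [l for l in loci if l.position >= position]
    left = below[-1] if below else loci[0]
    right = above[0] if above else loci[-1]
    return left, right


def generate_qtl_set(
    spec: SyntheticSpec, cmap: ConsensusMap
) -> tuple[list[QtlRecord], GroundTruth]:
    """Draw the QTL collection over ``cmap`` and record ground truth.

    Planted QTL positions are Normal(center, sd) truncated to the
    chromosome; background counts per (chromosome, trait) are Poisson with
    mean ``background_rate * length / 100`` and uniform positions. CI are
    centered on the position with log-normal width; records selected for
    blanking lose their position and/or CI and gain the nearest flanking
    markers instead.
    """
    rng = _rng_for(spec, 2)
    truth = GroundTruth(regions=list(spec.planted))
    records: list[QtlRecord] = []
    serial = 0

    def emit(chrom: str, true_pos: float, trait: str, region_idx: int | None) -> None:
        nonlocal serial
        serial += 1
        name = f"q{serial:05d}"
        length = cmap.length(chrom)
        width = float(
            np.exp(np.log(spec.ci_width_median) + spec.ci_width_sigma * rng.normal())
        )
        ci_lo = max(0.0, true_pos - width / 2.0)
        ci_hi = min(length, true_pos + width / 2.0)
        position: float | None = round(true_pos, 4)
        lo: float | None = round(ci_lo, 4)
        hi: float | None = round(ci_hi, 4)
        flank_left = flank_right = None
        blank_pos = rng.random() < spec.missing_position_frac
        blank_ci = rng.random() < spec.missing_ci_frac
        if blank_pos or blank_ci:
            left, right = _nearest_flanks(cmap.markers[chrom], true_pos)
            flank_left, flank_right = left.name, right.name
            if blank_pos:
                position = None
            if blank_ci:
                lo = hi = None
        study = f"study{(serial - 1) % spec.n_studies + 1:02d}"
        records.append(
            QtlRecord(
                map_name="synthetic-consensus",
                qtl_name=name,
                study_id=study,
                chromosome=chrom,
                trait=trait,
                position=position,
                ci_lo=lo,
                ci_hi=hi,
                lod=round(float(rng.uniform(2.5, 12.0)), 2),
                r2=round(float(rng.uniform(0.03, 0.35)), 3),
                method=str(rng.choice(["CIM", "MQM", "ICIM"])),
                flank_left=flank_left,
                flank_right=flank_right,
            )
        )
        truth.true_position[name] = true_pos
        if region_idx is not None:
            truth.members.setdefault(region_idx, []).append(name)

    for idx, region in enumerate(spec.planted):
        length = cmap.length(region.chromosome)
        if not 0.0 <= region.center <= length:
            raise ValueError(
                f"planted center {region.center} outside {region.chromosome} "
                f"(length {length:.1f})"
            )
        for trait in region.traits:
            for _ in range(region.n_per_trait):
                pos = float(
                    np.clip(rng.normal(region.center, region.sd), 0.0, length)
                )
                emit(region.chromosome, pos, trait, idx)

    for chrom in spec.chromosomes:
        length = cmap.length(chrom)
        for trait in spec.background_traits:
            n = int(rng.poisson(spec.background_rate * length / 100.0))
            for _ in range(n):
                emit(chrom, float(rng.uniform(0.0, length)), trait, None)

    return records, truth


@dataclass(frozen=True)
class RecoveryReport:
    """Precision/recall of calls against planted regions."""

    n_regions: int
    n_calls: int
    n_recovered: int
    n_matched_calls: int
    recall: float
    precision: float
    precision_defined: bool


def recovery_report(
    truth: GroundTruth,
    calls: Sequence[ClusterCall | HotspotCall],
    match_cm: float = 10.0,
) -> RecoveryReport:
    """Score calls against planted regions.

    A region is recovered when some call's interval midpoint lies within
    ``match_cm`` of its center on the same chromosome; a call is matched
    when it recovers some region. With no calls, precision is undefined and
    reported as 0 with ``precision_defined=False``.
    """
    recovered = set()
    matched = 0
    for call in calls:
        mid = 0.5 * (call.start + call.end)
        hit = False
        for idx, region in enumerate(truth.regions):
            if region.chromosome == call.chromosome and abs(mid - region.center) <= match_cm:
                recovered.add(idx)
                hit = True
        matched += bool(hit)
    n_regions = len(truth.regions)
    n_calls = len(calls)
    recall = len(recovered) / n_regions if n_regions else 0.0
    return RecoveryReport(
        n_regions=n_regions,
        n_calls=n_calls,
        n_recovered=len(recovered),
        n_matched_calls=matched,
        recall=recall,
        precision=(matched / n_calls) if n_calls else 0.0,
        precision_defined=n_calls > 0,
    )
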
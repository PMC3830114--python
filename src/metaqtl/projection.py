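"""Placement and exclusion of QTL records against a consensus map.

Source studies report QTL heterogeneously: some give a position and a
confidence interval (CI), some only flanking markers. The rules applied
here mirror standard meta-QTL curation practice:

* a missing position is filled with the midpoint of the two flanking
  markers' consensus-map positions;
* a missing CI is substituted by the flanking-marker positions;
* records whose markers are absent from the consensus map, whose position
  falls outside the chromosome span, or whose name maps to several distinct
  positions on one chromosome within one study are excluded.

:func:`ci_to_sigma` converts a CI into the per-observation standard
deviation consumed by the mixture meta-model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from scipy.stats import norm

from .io import ConsensusMap, QtlRecord

__all__ = [
    "ExclusionReason",
    "PlacementError",
    "ProjectionReport",
    "place_qtl",
    "filter_records",
    "ci_to_sigma",
    "SIGMA_FLOOR_CM",
]

log = logging.getLogger(__name__)

#: lower bound on the per-QTL standard deviation, avoids zero-variance
#: mixture components for point (zero-width) confidence intervals
SIGMA_FLOOR_CM = 0.1


class ExclusionReason(str, Enum):
    MARKER_NOT_ON_MAP = "MARKER_NOT_ON_MAP"
    MULTI_LOCATION = "MULTI_LOCATION"
    OUT_OF_RANGE = "OUT_OF_RANGE"
    UNRESOLVABLE = "UNRESOLVABLE"


class PlacementError(ValueError):
    """A record cannot be placed; carries the exclusion reason."""

    def __init__(self, reason: ExclusionReason, message: str):
        super().__init__(message)
        self.reason = reason


@dataclass
class ProjectionReport:
    """Partition of the input into fully resolved and excluded records."""

    kept: list[QtlRecord] = field(default_factory=list)
    excluded: list[tuple[QtlRecord, ExclusionReason]] = field(default_factory=list)

    def to_exclusion_tsv(self) -> str:
        lines = ["qtl_name\tstudy_id\tchromosome\treason"]
        for rec, reason in self.excluded:
            lines.append(f"{rec.qtl_name}\t{rec.study_id}\t{rec.chromosome}\t{reason.value}")
        return "\n".join(lines) + "\n"


def place_qtl(record: QtlRecord, cmap: ConsensusMap) -> QtlRecord:
    """Resolve missing position/CI from flanking markers.

    Records already carrying position and CI are returned unchanged. A
    missing position becomes the midpoint of the flanking markers; a
    missing CI becomes the flanking-marker interval. Raises
    :class:`PlacementError` (MARKER_NOT_ON_MAP or UNRESOLVABLE) when the
    record cannot be completed.
    """
    if not record.needs_projection:
        return record

    flank_pos: tuple[float, float] | None = None
    if record.flank_left and record.flank_right:
        for name in (record.flank_left, record.flank_right):
            if not cmap.has_marker(record.chromosome, name):
                raise PlacementError(
                    ExclusionReason.MARKER_NOT_ON_MAP,
                    f"{record.qtl_name}: flanking marker {name!r} not on "
                    f"{record.chromosome} of the consensus map",
                )
        lo = cmap.marker_position(record.chromosome, record.flank_left)
        hi = cmap.marker_position(record.chromosome, record.flank_right)
        flank_pos = (min(lo, hi), max(lo, hi))

    position = record.position
    if position is None:
        if flank_pos is None:
            raise PlacementError(
                ExclusionReason.UNRESOLVABLE,
                f"{record.qtl_name}: no position and no flanking marker pair",
            )
        position = 0.5 * (flank_pos[0] + flank_pos[1])

    ci_lo, ci_hi = record.ci_lo, record.ci_hi
    if ci_lo is None or ci_hi is None:
        if flank_pos is None:
            raise PlacementError(
                ExclusionReason.UNRESOLVABLE,
                f"{record.qtl_name}: no confidence interval and no flanking marker pair",
            )
        ci_lo, ci_hi = flank_pos
    # a reported point position may sit outside the substituted flanking
    # interval; widen the CI so the record stays internally consistent
    ci_lo = min(ci_lo, position)
    ci_hi = max(ci_hi, position)
    return record.evolve(position=position, ci_lo=ci_lo, ci_hi=ci_hi)


def filter_records(records: Sequence[QtlRecord], cmap: ConsensusMap) -> ProjectionReport:
    """Project all records and partition them into kept and excluded.

    Exclusion rules, applied in order: unplaceable records
    (MARKER_NOT_ON_MAP / UNRESOLVABLE); positions outside [0, chromosome
    length] (OUT_OF_RANGE); QTL names occurring at two or more distinct
    positions on one chromosome within one study (MULTI_LOCATION — all
    copies are dropped). Exclusions are reported and logged, never raised.
    """
    report = ProjectionReport()
    placed: list[QtlRecord] = []
    for record in records:
        try:
            placed.append(place_qtl(record, cmap))
        except PlacementError as exc:
            report.excluded.append((record, exc.reason))
            log.info("excluded %s (%s): %s", record.qtl_name, exc.reason.value, exc)

    # multi-location check: same study + name + chromosome, distinct positions
    position_sets: dict[tuple[str, str, str], set[float]] = {}
    for record in placed:
        key = (record.study_id, record.qtl_name, record.chromosome)
        position_sets.setdefault(key, set()).add(record.position)  # type: ignore[arg-type]

    for record in placed:
        key = (record.study_id, record.qtl_name, record.chromosome)
        if len(position_sets[key]) > 1:
            report.excluded.append((record, ExclusionReason.MULTI_LOCATION))
            log.info(
                "excluded %s (MULTI_LOCATION): %d distinct positions on %s",
                record.qtl_name, len(position_sets[key]), record.chromosome,
            )
            continue
        length = (
            cmap.length(record.chromosome) if record.chromosome in cmap.markers else None
        )
        if length is None or record.position < 0 or record.position > length:
            report.excluded.append((record, ExclusionReason.OUT_OF_RANGE))
            log.info(
                "excluded %s (OUT_OF_RANGE): position %s outside [0, %s] on %s",
                record.qtl_name, record.position, length, record.chromosome,
            )
            continue
        report.kept.append(record)
    return report


def ci_to_sigma(ci_lo: float, ci_hi: float, level: float = 0.95) -> float:
    """Convert a positional confidence interval to a standard deviation (cM).

    Under a normal position estimate, a central ``level`` CI spans
    ``2 * z * sigma`` with ``z`` the (1 + level)/2 standard-normal quantile,
    so ``sigma = (ci_hi - ci_lo) / (2 z)``, floored at
    :data:`SIGMA_FLOOR_CM` to keep degenerate point intervals usable.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    if ci_hi < ci_lo:
        raise ValueError(f"ci_hi {ci_hi} < ci_lo {ci_lo}")
    z = norm.ppf(0.5 * (1.0 + level))
    return max((ci_hi - ci_lo) / (2.0 * z), SIGMA_FLOOR_CM)


def sigmas_for(records: Iterable[QtlRecord], level: float = 0.95) -> list[float]:
    """Per-record standard deviations for projected records."""
    return [ci_to_sigma(r.ci_lo, r.ci_hi, level) for r in records]
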
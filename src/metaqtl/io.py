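"""Readers and writers for consensus-map and QTL description files.

Both formats are plain UTF-8 TSV with one header line; lines starting with
``#`` are comments. A map file lists markers per chromosome with the
distance (cM) from the previous marker, from which cumulative positions are
accumulated. A QTL file lists one mapped QTL per line; numeric fields that a
source study did not report are left empty and stay absent (``None``) in
memory — they are resolved later by projection, never silently zeroed.

The packaged fixtures transcribe the published summary tables of the cotton
meta-QTL study this package reproduces: the 42-study inventory, the
26-chromosome x 43-trait count matrix, the cluster/hotspot catalogue and the
per-chromosome tallies.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, NamedTuple

import pandas as pd

from .vocabulary import DEFAULT_VOCABULARY, TraitVocabulary, UnknownTraitError

__all__ = [
    "CHROMOSOMES",
    "MarkerLocus",
    "ConsensusMap",
    "QtlRecord",
    "StudyRecord",
    "FixtureTables",
    "MapFormatError",
    "QtlFormatError",
    "FixtureError",
    "parse_map_file",
    "write_map_file",
    "parse_qtl_file",
    "write_qtl_file",
    "load_fixture_tables",
]

#: the 26 chromosomes of tetraploid cotton (A subgenome c1-c13, D subgenome c14-c26)
CHROMOSOMES: tuple[str, ...] = tuple(f"c{i}" for i in range(1, 27))

MAP_COLUMNS = ("chromosome", "marker", "distance_from_previous_cM")
QTL_COLUMNS = (
    "map_name", "qtl_name", "study_id", "chromosome", "trait", "lod", "r2",
    "method", "position_cM", "ci_lo_cM", "ci_hi_cM", "flank_left", "flank_right",
)


class MapFormatError(ValueError):
    """Malformed consensus-map file."""


class QtlFormatError(ValueError):
    """Malformed QTL description file."""


class FixtureError(RuntimeError):
    """Packaged fixture missing or corrupted."""


@dataclass(frozen=True)
class MarkerLocus:
    """One marker at a cumulative genetic position on a chromosome."""

    name: str
    chromosome: str
    position: float  # cumulative cM from the chromosome origin


@dataclass
class ConsensusMap:
    """Ordered marker lists per chromosome with cumulative cM positions."""

    markers: dict[str, list[MarkerLocus]] = field(default_factory=dict)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.markers)

    def length(self, chromosome: str) -> float:
        """Span of a chromosome = position of its last marker."""
        loci = self.markers[chromosome]
        return loci[-1].position if loci else 0.0

    def marker_position(self, chromosome: str, name: str) -> float:
        for locus in self.markers.get(chromosome, ()):
            if locus.name == name:
                return locus.position
        raise KeyError(f"marker {name!r} not on chromosome {chromosome}")

    def has_marker(self, chromosome: str, name: str) -> bool:
        return any(l.name == name for l in self.markers.get(chromosome, ()))


@dataclass(frozen=True)
class QtlRecord:
    """One QTL as reported by a source study, possibly incomplete.

    ``position``/``ci_lo``/``ci_hi`` may be ``None`` before projection when
    the study only reported flanking markers. LOD and R^2 are carried
    through verbatim (R^2 exactly as declared, fraction or percent) — they
    do not influence placement.
    """

    map_name: str
    qtl_name: str
    study_id: str
    chromosome: str
    trait: str
    position: float | None = None
    ci_lo: float | None = None
    ci_hi: float | None = None
    lod: float | None = None
    r2: float | None = None
    method: str = ""
    flank_left: str | None = None
    flank_right: str | None = None

    def __post_init__(self) -> None:
        if self.chromosome not in CHROMOSOMES:
            raise ValueError(f"unknown chromosome code: {self.chromosome!r}")
        if self.ci_lo is not None and self.ci_hi is not None and self.ci_lo > self.ci_hi:
            raise ValueError(
                f"{self.qtl_name}: ci_lo {self.ci_lo} > ci_hi {self.ci_hi}"
            )
        if (
            self.position is not None
            and self.ci_lo is not None
            and self.ci_hi is not None
            and not (self.ci_lo <= self.position <= self.ci_hi)
        ):
            raise ValueError(
                f"{self.qtl_name}: position {self.position} outside CI "
                f"[{self.ci_lo}, {self.ci_hi}]"
            )

    @property
    def needs_projection(self) -> bool:
        return self.position is None or self.ci_lo is None or self.ci_hi is None

    def evolve(self, **changes) -> "QtlRecord":
        return replace(self, **changes)


@dataclass(frozen=True)
class StudyRecord:
    """One source QTL-mapping publication."""

    author: str
    journal: str
    year: int
    n_qtl: int
    population: str
    trait_type: str

    def __post_init__(self) -> None:
        if self.n_qtl < 1:
            raise ValueError("n_qtl must be >= 1")


class FixtureTables(NamedTuple):
    studies: list[StudyRecord]
    trait_counts: pd.DataFrame        # 26 chromosomes x 43 traits
    cluster_catalogue: pd.DataFrame   # name, chromosome, start_cM, end_cM, n_qtl
    hotspot_catalogue: pd.DataFrame   # name, chromosome, trait, start_cM, end_cM, n_qtl
    per_chrom_tallies: pd.DataFrame   # chromosome, n_clusters, n_hotspots


# --------------------------------------------------------------------------- TSV plumbing

def _data_lines(text: str) -> Iterable[tuple[int, list[str]]]:
    """Yield (1-based line number, fields) for non-comment, non-blank lines."""
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        yield lineno, line.split("\t")


def _opt_float(value: str, lineno: int, col: str, err: type[ValueError]) -> float | None:
    value = value.strip()
    if value == "":
        return None
    try:
        return float(value)
    except ValueError:
        raise err(f"line {lineno}: column {col!r}: not a number: {value!r}") from None


# --------------------------------------------------------------------------- map files

def parse_map_file(text: str) -> ConsensusMap:
    """Parse a consensus-map TSV into a :class:`ConsensusMap`.

    Marker distances are given relative to the previous marker of the same
    chromosome (first marker: 0); cumulative positions are the running sum.
    Raises :class:`MapFormatError` for negative distances, duplicate marker
    names within a chromosome, or unknown chromosome codes, naming the
    offending line.
    """
    cmap = ConsensusMap()
    cursor: dict[str, float] = {}
    seen: dict[str, set[str]] = {}
    rows = iter(_data_lines(text))
    try:
        _, header = next(rows)
    except StopIteration:
        raise MapFormatError("empty map file") from None
    if [h.strip() for h in header] != list(MAP_COLUMNS):
        raise MapFormatError(f"bad header: expected {MAP_COLUMNS}, got {header}")
    for lineno, fields in rows:
        if len(fields) != 3:
            raise MapFormatError(f"line {lineno}: expected 3 columns, got {len(fields)}")
        chrom, marker, dist_s = (f.strip() for f in fields)
        if chrom not in CHROMOSOMES:
            raise MapFormatError(f"line {lineno}: unknown chromosome code {chrom!r}")
        try:
            dist = float(dist_s)
        except ValueError:
            raise MapFormatError(f"line {lineno}: bad distance {dist_s!r}") from None
        if dist < 0:
            raise MapFormatError(f"line {lineno}: negative marker distance {dist}")
        if marker in seen.setdefault(chrom, set()):
            raise MapFormatError(f"line {lineno}: duplicate marker {marker!r} on {chrom}")
        seen[chrom].add(marker)
        # running sum; the first marker carries distance 0 and anchors the origin
        pos = cursor.get(chrom, 0.0) + dist
        cursor[chrom] = pos
        cmap.markers.setdefault(chrom, []).append(MarkerLocus(marker, chrom, pos))
    return cmap


def write_map_file(cmap: ConsensusMap) -> str:
    """Serialize a map back to the TSV dialect read by :func:`parse_map_file`."""
    lines = ["\t".join(MAP_COLUMNS)]
    for chrom, loci in cmap.markers.items():
        prev = 0.0
        for locus in loci:
            lines.append(f"{chrom}\t{locus.name}\t{_fmt(locus.position - prev)}")
            prev = locus.position
    return "\n".join(lines) + "\n"


def _fmt(x: float) -> str:
    return format(x, ".10g")


# --------------------------------------------------------------------------- QTL files

def parse_qtl_file(
    text: str,
    vocabulary: TraitVocabulary = DEFAULT_VOCABULARY,
    *,
    skip_unknown_traits: bool = False,
) -> list[QtlRecord]:
    """Parse a QTL description TSV into :class:`QtlRecord` objects.

    Empty numeric fields become ``None`` (absent, never zero). Trait labels
    are normalized through the vocabulary's synonym table; an unresolvable
    label raises :class:`QtlFormatError` unless ``skip_unknown_traits``
    downgrades it to a skip.
    """
    records: list[QtlRecord] = []
    rows = iter(_data_lines(text))
    try:
        _, header = next(rows)
    except StopIteration:
        raise QtlFormatError("empty QTL file") from None
    if [h.strip() for h in header] != list(QTL_COLUMNS):
        raise QtlFormatError(f"bad header: expected {QTL_COLUMNS}, got {header}")
    for lineno, fields in rows:
        if len(fields) != len(QTL_COLUMNS):
            raise QtlFormatError(
                f"line {lineno}: expected {len(QTL_COLUMNS)} columns, got {len(fields)}"
            )
        row = dict(zip(QTL_COLUMNS, (f.strip() for f in fields)))
        try:
            trait = vocabulary.resolve(row["trait"])
        except UnknownTraitError as exc:
            if skip_unknown_traits:
                continue
            raise QtlFormatError(f"line {lineno}: {exc}") from None
        try:
            record = QtlRecord(
                map_name=row["map_name"],
                qtl_name=row["qtl_name"],
                study_id=row["study_id"],
                chromosome=row["chromosome"],
                trait=trait,
                lod=_opt_float(row["lod"], lineno, "lod", QtlFormatError),
                r2=_opt_float(row["r2"], lineno, "r2", QtlFormatError),
                method=row["method"],
                position=_opt_float(row["position_cM"], lineno, "position_cM", QtlFormatError),
                ci_lo=_opt_float(row["ci_lo_cM"], lineno, "ci_lo_cM", QtlFormatError),
                ci_hi=_opt_float(row["ci_hi_cM"], lineno, "ci_hi_cM", QtlFormatError),
                flank_left=row["flank_left"] or None,
                flank_right=row["flank_right"] or None,
            )
        except ValueError as exc:
            raise QtlFormatError(f"line {lineno}: {exc}") from None
        records.append(record)
    return records


def write_qtl_file(records: Iterable[QtlRecord]) -> str:
    """Serialize records back to the QTL TSV dialect (round-trips the parser)."""
    def cell(v) -> str:
        if v is None:
            return ""
        if isinstance(v, float):
            return _fmt(v)
        return str(v)

    lines = ["\t".join(QTL_COLUMNS)]
    for r in records:
        lines.append("\t".join(cell(v) for v in (
            r.map_name, r.qtl_name, r.study_id, r.chromosome, r.trait,
            r.lod, r.r2, r.method, r.position, r.ci_lo, r.ci_hi,
            r.flank_left, r.flank_right,
        )))
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------- fixtures

def _read_fixture(name: str, checksums: dict[str, str]) -> str:
    ref = resources.files("metaqtl.data") / name
    try:
        data = ref.read_bytes()
    except FileNotFoundError:
        raise FixtureError(f"missing packaged fixture: {name}") from None
    digest = hashlib.sha256(data).hexdigest()
    if digest != checksums.get(name):
        raise FixtureError(f"fixture {name} corrupted (sha256 mismatch)")
    return data.decode("utf-8")


def load_fixture_tables() -> FixtureTables:
    """Load the packaged transcriptions of the published summary tables.

    Returns the 42-study inventory, the chromosome x trait count matrix,
    the cluster and hotspot catalogues and the per-chromosome tallies.
    Every file is verified against its recorded SHA-256 checksum.
    """
    checksums = json.loads((resources.files("metaqtl.data") / "checksums.json").read_text())

    from io import StringIO

    studies_df = pd.read_csv(StringIO(_read_fixture("studies.tsv", checksums)), sep="\t")
    studies = [
        StudyRecord(
            author=row.author, journal=row.journal, year=int(row.year),
            n_qtl=int(row.n_qtl), population=row.population, trait_type=row.trait_type,
        )
        for row in studies_df.itertuples()
    ]

    trait_counts = pd.read_csv(
        StringIO(_read_fixture("trait_counts.tsv", checksums)), sep="\t", index_col="chromosome"
    )
    clusters = pd.read_csv(StringIO(_read_fixture("clusters.tsv", checksums)), sep="\t")
    hotspots = pd.read_csv(StringIO(_read_fixture("hotspots.tsv", checksums)), sep="\t")
    tallies = pd.read_csv(StringIO(_read_fixture("chromosome_tallies.tsv", checksums)), sep="\t")
    return FixtureTables(studies, trait_counts, clusters, hotspots, tallies)
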
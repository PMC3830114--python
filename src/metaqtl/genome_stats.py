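"""Genome-wide distribution summaries and tests.

Covers the trait-by-chromosome tabulation of projected QTL, chi-square
goodness-of-fit tests of genome uniformity, the A/D-subgenome contrast of
allotetraploid cotton, and the comparison of cluster/hotspot calls between
homoeologous chromosome pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .detection import ClusterCall, HotspotCall
from .io import CHROMOSOMES, QtlRecord
from .vocabulary import DEFAULT_VOCABULARY

__all__ = [
    "TraitChromosomeTable",
    "ChiSquareResult",
    "HomoeologMap",
    "DEFAULT_HOMOEOLOGS",
    "tabulate",
    "uniformity_chisq",
    "subgenome_counts",
    "compare_homoeologs",
]

Call = Union[ClusterCall, HotspotCall]


@dataclass
class TraitChromosomeTable:
    """26-chromosome x 43-trait matrix of QTL counts."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.values.sum())

    def to_tsv(self) -> str:
        out = self.counts.copy()
        out["Total"] = self.row_totals
        out.loc["Total"] = out.sum(axis=0)
        return out.to_csv(sep="\t")

    @classmethod
    def from_counts(cls, counts: pd.DataFrame) -> "TraitChromosomeTable":
        return cls(counts=counts.astype(int))


@dataclass(frozen=True)
class ChiSquareResult:
    """A goodness-of-fit test reported against a critical value at alpha."""

    statistic: float
    df: int
    expected: np.ndarray
    alpha: float
    critical: float
    exceeds: bool

    def to_row(self, label: str) -> str:
        return (
            f"{label}\t{self.statistic:.4g}\t{self.df}\t{self.critical:.4g}"
            f"\t{str(self.exceeds).lower()}"
        )


#: A-subgenome chromosome paired with its D-subgenome homoeologue
_PAIRS = (
    ("c1", "c15"), ("c2", "c14"), ("c3", "c17"), ("c4", "c22"), ("c5", "c19"),
    ("c6", "c25"), ("c7", "c16"), ("c8", "c24"), ("c9", "c23"), ("c10", "c20"),
    ("c11", "c21"), ("c12", "c26"), ("c13", "c18"),
)


@dataclass(frozen=True)
class HomoeologMap:
    """The 13 A-D homoeologous pairs of tetraploid cotton."""

    pairs: tuple[tuple[str, str], ...] = _PAIRS

    @property
    def subgenome(self) -> dict[str, str]:
        sub = {f"c{i}": "A" for i in range(1, 14)}
        sub.update({f"c{i}": "D" for i in range(14, 27)})
        return sub


DEFAULT_HOMOEOLOGS = HomoeologMap()


def tabulate(records: Iterable[QtlRecord]) -> TraitChromosomeTable:
    """Count projected QTL per (chromosome, trait) cell."""
    counts = pd.DataFrame(
        0, index=list(CHROMOSOMES), columns=list(DEFAULT_VOCABULARY.codes), dtype=int
    )
    counts.index.name = "chromosome"
    for r in records:
        counts.loc[r.chromosome, r.trait] += 1
    return TraitChromosomeTable(counts=counts)


def uniformity_chisq(counts: Sequence[int], alpha: float = 0.05) -> ChiSquareResult:
    """Chi-square test of equal expected counts across categories.

    ``statistic = sum (O - E)^2 / E`` with ``E = total / #categories`` and
    ``df = #categories - 1``; the critical value is the chi-square quantile
    at ``1 - alpha``.
    """
    observed = np.asarray(counts, dtype=float)
    if observed.size < 2:
        raise ValueError("at least 2 categories required")
    if np.any(observed < 0):
        raise ValueError("counts must be non-negative")
    total = observed.sum()
    if total == 0:
        raise ValueError("all counts are zero")
    expected = np.full(observed.size, total / observed.size)
    statistic = float(((observed - expected) ** 2 / expected).sum())
    df = observed.size - 1
    critical = float(chi2.ppf(1.0 - alpha, df))
    return ChiSquareResult(
        statistic=statistic, df=df, expected=expected,
        alpha=alpha, critical=critical, exceeds=statistic > critical,
    )


def subgenome_counts(
    table: TraitChromosomeTable,
    homoeologs: HomoeologMap = DEFAULT_HOMOEOLOGS,
    alpha: float = 0.05,
) -> tuple[int, int, ChiSquareResult]:
    """QTL totals on the A (c1-c13) and D (c14-c26) subgenomes with a
    chi-square test against the equal-halves expectation (13 vs 13
    chromosomes, hence df = 1, critical 3.84 at alpha = 0.05)."""
    sub = homoeologs.subgenome
    row = table.row_totals
    nA = int(sum(row[c] for c in row.index if sub[c] == "A"))
    nD = int(sum(row[c] for c in row.index if sub[c] == "D"))
    return nA, nD, uniformity_chisq([nA, nD], alpha=alpha)


@dataclass
class PairComparison:
    """Shared-region report for one homoeologous pair."""

    chrom_a: str
    chrom_d: str
    shared: list[tuple[Call, Call]] = field(default_factory=list)
    n_shared_same_trait_hotspots: int = 0


def _interval_overlap(a: Call, b: Call, slack: float) -> bool:
    return a.start <= b.end + slack and b.start <= a.end + slack


def compare_homoeologs(
    calls: Sequence[Call],
    homoeologs: HomoeologMap = DEFAULT_HOMOEOLOGS,
    overlap_cm: float = 10.0,
) -> list[PairComparison]:
    """Pair calls on homoeologous chromosomes whose intervals coincide.

    Two calls are shared when their cM intervals intersect after allowing
    ``overlap_cm`` of slack on either side — an informal alignment, since
    homoeologues have no common coordinate system. Same-trait hotspot
    sharing is tallied separately.
    """
    by_chrom: dict[str, list[Call]] = {}
    for call in calls:
        by_chrom.setdefault(call.chromosome, []).append(call)
    report: list[PairComparison] = []
    for a, d in homoeologs.pairs:
        cmp = PairComparison(chrom_a=a, chrom_d=d)
        for ca in by_chrom.get(a, ()):
            for cd in by_chrom.get(d, ()):
                if _interval_overlap(ca, cd, overlap_cm):
                    cmp.shared.append((ca, cd))
                    if (
                        isinstance(ca, HotspotCall)
                        and isinstance(cd, HotspotCall)
                        and ca.trait == cd.trait
                    ):
                        cmp.n_shared_same_trait_hotspots += 1
        report.append(cmp)
    return report
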
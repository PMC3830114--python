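"""End-to-end orchestration: project -> detect -> meta-model -> stats.

One configured run reads a consensus map and a QTL file, applies the
projection rules, calls clusters and hotspots, fits the per-chromosome
mixture meta-model, computes the genome-distribution summaries and writes
every result as TSV plus one YAML manifest. Identical configuration and
inputs yield byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .detection import DetectionConfig, detect_clusters, detect_hotspots
from .genome_stats import (
    DEFAULT_HOMOEOLOGS,
    compare_homoeologs,
    subgenome_counts,
    tabulate,
    uniformity_chisq,
)
from .io import parse_map_file, parse_qtl_file
from .meta_model import MetaModelConfig, metaqtl_intervals, select_model
from .projection import filter_records, sigmas_for

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "render_summary"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    map_path: Path
    qtl_path: Path
    out_dir: Path
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    meta: MetaModelConfig = field(default_factory=MetaModelConfig)
    alpha: float = 0.05
    ci_level: float = 0.95

    def echo(self) -> dict:
        return {
            "map_path": str(self.map_path),
            "qtl_path": str(self.qtl_path),
            "out_dir": str(self.out_dir),
            "detection": vars(self.detection).copy(),
            "meta": vars(self.meta).copy(),
            "alpha": self.alpha,
            "ci_level": self.ci_level,
        }


@dataclass
class RunManifest:
    config: dict
    input_checksums: dict[str, str]
    seeds: dict[str, int]
    version: str
    counts: dict[str, int]

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "config": self.config,
                "input_checksums": self.input_checksums,
                "seeds": self.seeds,
                "version": self.version,
                "counts": self.counts,
            },
            sort_keys=True,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _chrom_key(code: str) -> int:
    return int(code.lstrip("c"))


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run every stage and write the report files under ``config.out_dir``.

    Outputs: ``exclusions.tsv``, ``clusters.tsv``, ``hotspots.tsv``,
    ``metaqtl.tsv``, ``trait_counts.tsv``, ``chisq.tsv``,
    ``homoeologs.tsv``, ``summary.txt`` and ``manifest.yaml``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    map_text = Path(config.map_path).read_text(encoding="utf-8")
    qtl_text = Path(config.qtl_path).read_text(encoding="utf-8")
    cmap = parse_map_file(map_text)
    records = parse_qtl_file(qtl_text)
    log.info("parsed %d markers, %d QTL records",
             sum(len(v) for v in cmap.markers.values()), len(records))

    report = filter_records(records, cmap)
    log.info("projection kept %d, excluded %d", len(report.kept), len(report.excluded))
    (out / "exclusions.tsv").write_text(report.to_exclusion_tsv(), encoding="utf-8")

    clusters = detect_clusters(report.kept, config.detection)
    hotspots = detect_hotspots(report.kept, config.detection)
    log.info("detected %d clusters, %d hotspots", len(clusters), len(hotspots))

    def call_rows(calls, with_trait):
        lines = [
            "name\tchromosome\t" + ("trait\t" if with_trait else "")
            + "start_cM\tend_cM\tn_qtl\t" + ("" if with_trait else "n_traits\t") + "members"
        ]
        for c in calls:
            member_ids = ";".join(m.qtl_name for m in c.members)
            mid = [c.name, c.chromosome]
            if with_trait:
                mid.append(c.trait)
            mid += [f"{c.start:g}", f"{c.end:g}", str(c.n_qtl)]
            if not with_trait:
                mid.append(str(c.n_traits))
            mid.append(member_ids)
            lines.append("\t".join(mid))
        return "\n".join(lines) + "\n"

    (out / "clusters.tsv").write_text(call_rows(clusters, False), encoding="utf-8")
    (out / "hotspots.tsv").write_text(call_rows(hotspots, True), encoding="utf-8")

    # per-chromosome mixture meta-model
    meta_lines = ["chromosome\tK\tcomponent\tmu_cM\tci_lo\tci_hi\tweight\tn_qtl"]
    fits = {}
    by_chrom: dict[str, list] = {}
    for r in report.kept:
        by_chrom.setdefault(r.chromosome, []).append(r)
    for chrom in sorted(by_chrom, key=_chrom_key):
        recs = sorted(by_chrom[chrom], key=lambda r: (r.position, r.qtl_name))
        positions = [r.position for r in recs]
        sigmas = sigmas_for(recs, config.ci_level)
        fit, _table = select_model(positions, sigmas, config.meta)
        fits[chrom] = fit
        if not fit.converged:
            log.warning("EM hit max_iter on %s (K=%d)", chrom, fit.K)
        for k, (mu, lo, hi) in enumerate(
            metaqtl_intervals(fit, cmap.length(chrom)), start=1
        ):
            meta_lines.append(
                f"{chrom}\t{fit.K}\t{k}\t{mu:.4f}\t{lo:.4f}\t{hi:.4f}"
                f"\t{fit.pi[k - 1]:.6f}\t{len(recs)}"
            )
    (out / "metaqtl.tsv").write_text("\n".join(meta_lines) + "\n", encoding="utf-8")

    # genome distribution
    table = tabulate(report.kept)
    (out / "trait_counts.tsv").write_text(table.to_tsv(), encoding="utf-8")
    chisq_lines = ["test\tstatistic\tdf\tcritical\texceeds"]
    if table.grand_total > 0:
        chrom_test = uniformity_chisq(table.row_totals.tolist(), alpha=config.alpha)
        nA, nD, sub_test = subgenome_counts(table, alpha=config.alpha)
        chisq_lines.append(chrom_test.to_row("per_chromosome_uniformity"))
        chisq_lines.append(sub_test.to_row(f"subgenome_A{nA}_vs_D{nD}"))
    (out / "chisq.tsv").write_text("\n".join(chisq_lines) + "\n", encoding="utf-8")

    pair_report = compare_homoeologs(list(clusters) + list(hotspots), DEFAULT_HOMOEOLOGS)
    pair_lines = ["chrom_A\tchrom_D\tn_shared\tn_shared_same_trait_hotspots\tshared_calls"]
    for cmp in pair_report:
        shared = ";".join(f"{a.name}|{b.name}" for a, b in cmp.shared)
        pair_lines.append(
            f"{cmp.chrom_a}\t{cmp.chrom_d}\t{len(cmp.shared)}"
            f"\t{cmp.n_shared_same_trait_hotspots}\t{shared}"
        )
    (out / "homoeologs.tsv").write_text("\n".join(pair_lines) + "\n", encoding="utf-8")

    manifest = RunManifest(
        config=config.echo(),
        input_checksums={
            "map": _sha256(Path(config.map_path)),
            "qtl": _sha256(Path(config.qtl_path)),
        },
        seeds={"detection": config.detection.seed, "meta": config.meta.seed},
        version=__version__,
        counts={
            "parsed": len(records),
            "kept": len(report.kept),
            "excluded": len(report.excluded),
            "clusters": len(clusters),
            "hotspots": len(hotspots),
        },
    )
    (out / "summary.txt").write_text(
        render_summary(manifest, clusters, hotspots, fits, table), encoding="utf-8"
    )
    (out / "manifest.yaml").write_text(manifest.to_yaml(), encoding="utf-8")
    return manifest


def render_summary(manifest, clusters, hotspots, fits, table) -> str:
    """Human-readable per-chromosome report of calls, selected K and totals."""
    lines = [
        "meta-QTL analysis summary",
        "=========================",
        f"records parsed: {manifest.counts['parsed']}  "
        f"kept: {manifest.counts['kept']}  excluded: {manifest.counts['excluded']}",
        "",
    ]
    chroms = sorted(
        {c.chromosome for c in clusters}
        | {h.chromosome for h in hotspots}
        | set(fits),
        key=_chrom_key,
    )
    if not clusters:
        lines.append("no clusters detected")
    if not hotspots:
        lines.append("no hotspots detected")
    for chrom in chroms:
        lines.append(f"{chrom}:")
        if chrom in fits:
            fit = fits[chrom]
            mus = ", ".join(f"{m:.1f}" for m in fit.mu)
            lines.append(f"  meta-model: K={fit.K} (means {mus} cM)")
        for c in (x for x in clusters if x.chromosome == chrom):
            lines.append(
                f"  {c.name}: {c.start:g}-{c.end:g} cM, {c.n_qtl} QTL, {c.n_traits} traits"
            )
        for h in (x for x in hotspots if x.chromosome == chrom):
            lines.append(f"  {h.name}: {h.start:g}-{h.end:g} cM, {h.n_qtl} {h.trait} QTL")
    lines.append("")
    lines.append(f"total QTL tabulated: {table.grand_total}")
    return "\n".join(lines) + "\n"
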
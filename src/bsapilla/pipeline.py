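"""End-to-end orchestration: simulate -> screen -> index -> intervals ->
annotate -> co-localize -> expression filter -> report.

One population run consumes either a synthetic genome specification or a
set of real input files (two parent VCFs, two bulk VCFs, GFF3), and
produces marker tables, delta-index tracks, candidate intervals, interval
gene sets, plots and a machine-readable manifest.  Two population runs
are then combined: candidate gene sets are intersected per marker class,
unioned across classes, and filtered by expression pattern.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from . import simdata
from .bsa_index import (
    IndexTrack,
    call_intervals,
    compute_index,
    intervals_to_bed,
    intervals_to_json,
    plot_tracks,
    summarize_chromosomes,
    window_track,
)
from .colocal import GeneSet, genes_in_intervals, intersect_populations, load_gff3, union_marker_classes
from .expression import pattern_census, read_fpkm, select_candidates, census_to_json
from .variant_io import load_vcf, screen_homozygous_differential

log = logging.getLogger("bsapilla")

MARKER_CLASSES = ("SNP", "InDel")


@dataclass
class RunConfig:
    """Parameters of one population run (synthetic or file-based)."""

    outdir: str = "bsapilla_run"
    seed: int = 1
    # synthetic-genome parameters (ignored when VCF paths are given)
    n_chromosomes: int = 9
    chrom_length_bp: int = 40_000_000
    cm_per_mb: float = 3.0
    markers_per_chromosome: int = 2000
    causal_chrom: str | None = "chr5"
    causal_pos: int = 20_000_000
    dominant: bool = True
    indel_fraction: float = 0.15
    n_f2: int = 300
    bulk_size: int = 30
    coverage: float = 50.0
    error_rate: float = 0.002
    # real inputs (all four VCFs required together)
    parent1_vcf: str | None = None
    parent2_vcf: str | None = None
    bulk_papilla_vcf: str | None = None
    bulk_nonpapilla_vcf: str | None = None
    gff3: str | None = None
    fpkm: str | None = None
    # analysis parameters
    min_depth: int = 8
    window_size: int = 1_000_000
    step: int = 100_000
    threshold: float = 0.5
    min_markers: int = 5
    high_cut: float = 1.0
    off_cut: float = 0.1
    make_plots: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError("threshold must be in (0, 1]")
        vcfs = [self.parent1_vcf, self.parent2_vcf,
                self.bulk_papilla_vcf, self.bulk_nonpapilla_vcf]
        if any(vcfs) and not all(vcfs):
            raise ValueError("all four VCF paths must be given together")

    @property
    def simulate(self) -> bool:
        return self.parent1_vcf is None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "seed" not in data:
            raise ValueError("config must declare a seed")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def genome_spec(self) -> simdata.GenomeSpec:
        chroms = [
            simdata.ChromosomeSpec(f"chr{i}", self.chrom_length_bp, self.cm_per_mb)
            for i in range(1, self.n_chromosomes + 1)
        ]
        causal = (
            (self.causal_chrom, self.causal_pos) if self.causal_chrom else None
        )
        return simdata.GenomeSpec(
            chromosomes=chroms,
            markers_per_chromosome=self.markers_per_chromosome,
            causal_locus=causal,
            dominant=self.dominant,
            indel_fraction=self.indel_fraction,
        )


@dataclass
class PopulationResult:
    """Artifacts of one population run, keyed by marker class."""

    config: RunConfig
    outdir: Path
    filter_report: "object"
    tracks: dict[str, IndexTrack]
    intervals: dict[str, list]
    gene_sets: dict[str, GeneSet]
    summaries: dict[str, "object"]
    manifest: dict


def simulate_population_files(cfg: RunConfig, outdir: Path) -> dict[str, Path]:
    """Run the simulator and write the VCF/GFF3/FPKM fixture set."""
    spec = cfg.genome_spec()
    mm = simdata.build_marker_map(spec, cfg.seed)
    pop = simdata.simulate_f2_population(mm, cfg.n_f2, cfg.seed, dominant=spec.dominant)
    bulks = simdata.make_bulks(pop, cfg.bulk_size, cfg.seed)
    reads = (
        simdata.sequence_bulk(bulks[0], cfg.coverage, cfg.error_rate, cfg.seed),
        simdata.sequence_bulk(bulks[1], cfg.coverage, cfg.error_rate, cfg.seed + 1),
    )
    paths = simdata.write_fixture_set(
        outdir / "fixtures", spec, pop, bulks, reads, seed=cfg.seed,
        high_cut=cfg.high_cut, off_cut=cfg.off_cut,
    )
    log.info("simulated %d F2 (%s papilla / %s non-papilla), %d markers",
             len(pop), *pop.phenotype_counts, len(mm))
    return paths


def run_single_population(cfg: RunConfig) -> PopulationResult:
    """Screen -> index -> windows -> intervals -> annotate for one population."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if cfg.simulate:
        paths = simulate_population_files(cfg, outdir)
        p1_path, p2_path = paths["parent1_vcf"], paths["parent2_vcf"]
        bp_path, bn_path = paths["bulk_papilla_vcf"], paths["bulk_nonpapilla_vcf"]
        gff3 = paths["gff3"]
        chrom_lengths = {
            c.name: c.length_bp for c in cfg.genome_spec().chromosomes
        }
    else:
        p1_path, p2_path = cfg.parent1_vcf, cfg.parent2_vcf
        bp_path, bn_path = cfg.bulk_papilla_vcf, cfg.bulk_nonpapilla_vcf
        gff3 = cfg.gff3
        chrom_lengths = None

    p1, m1 = load_vcf(p1_path)
    p2, m2 = load_vcf(p2_path)
    bp, _ = load_vcf(bp_path)
    bn, _ = load_vcf(bn_path)
    table, report = screen_homozygous_differential(
        p1, p2, bp, bn, min_depth=cfg.min_depth, n_multiallelic=m1 + m2
    )
    table.to_tsv(outdir / "marker_table.tsv")
    report.to_json(outdir / "filter_report.json")
    log.info("screen: retained %d / %d sites", report.retained, report.input)

    annotation = load_gff3(gff3) if gff3 else None
    tracks, intervals, gene_sets, summaries = {}, {}, {}, {}
    artifacts = {
        "marker_table": "marker_table.tsv",
        "filter_report": "filter_report.json",
    }
    for klass in MARKER_CLASSES:
        track = compute_index(table, marker_class=klass)
        wt = window_track(track, cfg.window_size, cfg.step, chrom_lengths)
        ivs = call_intervals(wt, cfg.threshold, cfg.min_markers)
        summary = summarize_chromosomes(track, cfg.threshold)
        tag = klass.lower()
        track.to_tsv(outdir / f"index_track.{tag}.tsv")
        wt.to_tsv(outdir / f"window_track.{tag}.tsv")
        intervals_to_bed(ivs, outdir / f"intervals.{tag}.bed")
        intervals_to_json(ivs, outdir / f"intervals.{tag}.json")
        artifacts.update({
            f"index_track_{tag}": f"index_track.{tag}.tsv",
            f"window_track_{tag}": f"window_track.{tag}.tsv",
            f"intervals_{tag}_bed": f"intervals.{tag}.bed",
            f"intervals_{tag}_json": f"intervals.{tag}.json",
        })
        if cfg.make_plots:
            plot_tracks(track, wt, ivs, outdir / f"delta_index.{tag}.png",
                        cfg.threshold)
            artifacts[f"plot_{tag}"] = f"delta_index.{tag}.png"
        tracks[klass], intervals[klass], summaries[klass] = track, ivs, summary
        if annotation is not None:
            gs = genes_in_intervals(ivs, annotation, label=f"{outdir.name}:{klass}")
            gs.write(outdir / f"genes.{tag}.txt")
            artifacts[f"genes_{tag}"] = f"genes.{tag}.txt"
            gene_sets[klass] = gs
        log.info("%s: %d markers, %d interval(s), peak on %s",
                 klass, len(track), len(ivs), summary.argmax_chrom)

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": asdict(cfg),
        "artifacts": artifacts,
        "chromosome_summaries": {
            k: asdict(s) for k, s in summaries.items()
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return PopulationResult(cfg, outdir, report, tracks, intervals,
                            gene_sets, summaries, manifest)


def run_colocalization(
    pop1: PopulationResult,
    pop2: PopulationResult,
    fpkm_path: str | Path,
    outdir: str | Path,
) -> dict:
    """Combine two population runs into the final candidate report.

    Per marker class the two populations' interval gene sets are
    intersected; the SNP-common and InDel-common sets are unioned; the
    union is censused by expression pattern and filtered to the
    first-two-stages candidates.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for klass in MARKER_CLASSES:
        if klass not in pop1.gene_sets or klass not in pop2.gene_sets:
            raise ValueError(
                f"both populations must carry {klass} gene sets "
                "(was a GFF3 provided to each run?)"
            )
    common = {
        klass: intersect_populations(pop1.gene_sets[klass], pop2.gene_sets[klass])
        for klass in MARKER_CLASSES
    }
    union = union_marker_classes(common["SNP"], common["InDel"])
    em = read_fpkm(fpkm_path)
    cfg = pop1.config
    census = pattern_census(union, em, cfg.high_cut, cfg.off_cut)
    candidates = select_candidates(union, em, cfg.high_cut, cfg.off_cut)

    common["SNP"].write(outdir / "common_genes.snp.txt")
    common["InDel"].write(outdir / "common_genes.indel.txt")
    union.write(outdir / "common_genes.union.txt")
    candidates.write(outdir / "candidate_genes.txt")
    census_to_json(census, outdir / "pattern_census.json")
    report = {
        "snp_common": len(common["SNP"]),
        "indel_common": len(common["InDel"]),
        "union": len(union),
        "pattern_census": census,
        "n_candidates": len(candidates),
        "candidates": candidates.sorted_ids(),
    }
    with open(outdir / "colocalization_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info(
        "co-localization: %d SNP-common, %d InDel-common, %d union, %d candidates",
        report["snp_common"], report["indel_common"], report["union"],
        report["n_candidates"],
    )
    return report
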
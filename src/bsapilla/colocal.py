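"""Candidate-interval gene annotation and two-population co-localization.

A candidate interval is annotated with every gene model it overlaps by at
least one base pair (coordinates 1-based inclusive, strand ignored).
Gene sets from two independent mapping populations are intersected per
marker class, and the SNP-common and InDel-common sets are unioned into
the final co-localized candidate list.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd

from .bsa_index import CandidateInterval

__all__ = [
    "GeneModel",
    "GeneSet",
    "load_gff3",
    "genes_in_intervals",
    "intersect_populations",
    "union_marker_classes",
]


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


@dataclass
class GeneSet:
    """A labelled set of gene ids with per-gene provenance.

    ``label`` records population x marker class (e.g. "pop1:SNP");
    ``provenance`` maps each gene id to the evidence strings (intervals,
    source sets) that produced it.
    """

    label: str
    genes: frozenset[str]
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    def sorted_ids(self) -> list[str]:
        return sorted(self.genes)

    def write(self, path: str | Path) -> None:
        """One gene id per line plus a sibling provenance JSON."""
        path = Path(path)
        path.write_text("".join(g + "\n" for g in self.sorted_ids()))
        with open(path.with_suffix(path.suffix + ".provenance.json"), "w") as fh:
            json.dump(
                {"label": self.label, "provenance": self.provenance},
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")


def load_gff3(path: str | Path, feature_type: str = "gene") -> list[GeneModel]:
    """Load gene models from GFF3; identity from the ID/Name attribute.

    Duplicate gene ids are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="error",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for feat in db.features_of_type(feature_type):
        gid = feat.attributes.get("ID", feat.attributes.get("Name", [feat.id]))[0]
        if gid in seen:
            raise ValueError(f"duplicate gene id {gid!r} in {path}")
        seen.add(gid)
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand or ".",
            )
        )
    return genes


def genes_in_intervals(
    intervals: list[CandidateInterval],
    annotation: list[GeneModel],
    label: str = "candidate",
    variant_positions: pd.DataFrame | None = None,
) -> GeneSet:
    """Genes overlapping any candidate interval by >= 1 bp.

    Overlap is inclusive-coordinate: gene [100, 200] overlaps interval
    [150, 300] but not [201, 300].  With ``variant_positions`` (a frame
    with chrom/pos of above-threshold variants) a gene must additionally
    contain at least one such variant.  Result is deduplicated and
    provenance records which interval(s) hit each gene.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in annotation:
        by_chrom.setdefault(g.chrom, []).append(g)
    hits: dict[str, list[str]] = {}
    coord: dict[str, tuple[str, int]] = {}
    for iv in intervals:
        if iv.chrom not in by_chrom:
            warnings.warn(
                f"interval chromosome {iv.chrom!r} absent from annotation; skipped"
            )
            continue
        tag = f"{label}:{iv.chrom}:{iv.start}-{iv.end}"
        for g in by_chrom[iv.chrom]:
            if g.start <= iv.end and iv.start <= g.end:
                hits.setdefault(g.gene_id, []).append(tag)
                coord[g.gene_id] = (g.chrom, g.start)
    if variant_positions is not None:
        keep = set()
        for g in annotation:
            if g.gene_id not in hits:
                continue
            vp = variant_positions
            inside = (
                (vp["chrom"] == g.chrom)
                & (vp["pos"] >= g.start)
                & (vp["pos"] <= g.end)
            )
            if inside.any():
                keep.add(g.gene_id)
        hits = {g: t for g, t in hits.items() if g in keep}
    return GeneSet(label=label, genes=frozenset(hits), provenance=hits)


def intersect_populations(a: GeneSet, b: GeneSet) -> GeneSet:
    """Genes found by both mapping populations (strict set intersection)."""
    common = a.genes & b.genes
    prov = {
        g: sorted(set(a.provenance.get(g, [a.label]) + b.provenance.get(g, [b.label])))
        for g in common
    }
    return GeneSet(label=f"({a.label})&({b.label})", genes=frozenset(common), provenance=prov)


def union_marker_classes(snp_common: GeneSet, indel_common: GeneSet) -> GeneSet:
    """Deduplicated union of the SNP-common and InDel-common gene sets."""
    union = snp_common.genes | indel_common.genes
    prov: dict[str, list[str]] = {}
    for src in (snp_common, indel_common):
        for g in src.genes:
            prov.setdefault(g, [])
            prov[g] = sorted(set(prov[g] + src.provenance.get(g, [src.label])))
    return GeneSet(
        label=f"({snp_common.label})|({indel_common.label})",
        genes=frozenset(union),
        provenance=prov,
    )
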
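"""Synthetic F2 bulked-segregant data generator.

Simulates the data-generating process that delta-index mapping assumes:
two fully inbred parents fixed for alternate alleles at every marker, an
F2 population segregating for a single dominant locus, phenotype-extreme
bulks, and read-depth-sampled allele counts per bulk.

Model summary
-------------
* Genetic map: linear bp -> Morgan interpolation at a constant cM/Mb per
  chromosome (default 3 cM/Mb).
* Gametes: first-order Markov chain along ordered markers with Haldane's
  map function r = (1 - exp(-2d)) / 2, no interference.
* Phenotype: papilla iff the individual carries >= 1 copy of the P1
  (papilla-parent) allele at the causal locus under the dominant model;
  papilla iff homozygous P1 under the recessive model.  With no causal
  locus the phenotype is an independent Bernoulli draw at the dominant
  3:1 rate (the null model for type-I-error checks).
* Sequencing: per marker, depth ~ Poisson(lambda); each read reports the
  wrong allele with probability e, so the non-P1 read count is
  Binomial(depth, f(1-e) + (1-f)e) where f is the bulk's true non-P1
  allele frequency.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ChromosomeSpec",
    "GenomeSpec",
    "MarkerMap",
    "F2Individual",
    "F2Population",
    "BulkReads",
    "build_marker_map",
    "simulate_f2_population",
    "make_bulks",
    "sequence_bulk",
    "marker_table_from_sim",
    "make_pattern_fpkm",
    "write_fixture_set",
]

PATTERN_ORDER = (
    "not_expressed_all",
    "high_all",
    "high_last_two",
    "low_first_three",
    "high_first_two",
    "high_second_only",
)

#: pattern partition reported for the 72 co-localized genes in the study
#: this generator emulates (33 silent, 26 high at all stages, 6 high at the
#: last two, 2 low over the first three, 4 high at the first two, 1 high at
#: the second stage only)
REFERENCE_PATTERN_COUNTS = {
    "not_expressed_all": 33,
    "high_all": 26,
    "high_last_two": 6,
    "low_first_three": 2,
    "high_first_two": 4,
    "high_second_only": 1,
}


@dataclass(frozen=True)
class ChromosomeSpec:
    """One simulated chromosome: physical length and map density."""

    name: str
    length_bp: int
    cm_per_mb: float = 3.0

    @property
    def genetic_length_morgans(self) -> float:
        return self.length_bp / 1e6 * self.cm_per_mb / 100.0


@dataclass
class GenomeSpec:
    """Layout of the simulated genome and trait architecture.

    ``causal_locus`` is ``(chromosome_name, position_bp)`` or ``None`` for
    a null genome with no trait locus.  ``dominant`` selects whether the
    papilla allele (carried by parent P1) is dominant or recessive.
    """

    chromosomes: list[ChromosomeSpec]
    markers_per_chromosome: int = 2000
    causal_locus: tuple[str, int] | None = ("chr5", 20_000_000)
    dominant: bool = True
    indel_fraction: float = 0.15

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for c in self.chromosomes:
            if c.length_bp <= 0 or c.genetic_length_morgans <= 0:
                raise ValueError(f"non-positive length for {c.name}")
        if self.causal_locus is not None:
            chrom, pos = self.causal_locus
            by_name = {c.name: c for c in self.chromosomes}
            if chrom not in by_name:
                raise ValueError(f"causal chromosome {chrom!r} not declared")
            if not 1 <= pos <= by_name[chrom].length_bp:
                raise ValueError("causal position outside chromosome")
        if not 0.0 <= self.indel_fraction <= 1.0:
            raise ValueError("indel_fraction must be in [0, 1]")
        if self.markers_per_chromosome < 1:
            raise ValueError("need at least one marker per chromosome")

    @classmethod
    def default(cls, **overrides) -> "GenomeSpec":
        """Nine 40-Mb chromosomes, causal locus mid-chromosome-5."""
        chroms = [ChromosomeSpec(f"chr{i}", 40_000_000) for i in range(1, 10)]
        kwargs = dict(chromosomes=chroms)
        kwargs.update(overrides)
        return cls(**kwargs)

    @classmethod
    def null(cls, **overrides) -> "GenomeSpec":
        """Default layout with no causal locus (type-I-error control)."""
        overrides.setdefault("causal_locus", None)
        return cls.default(**overrides)


@dataclass
class MarkerMap:
    """Ordered marker positions with genetic coordinates and classes.

    ``sites`` columns: chrom, pos (1-based), morgans, marker_class
    (SNP|InDel), ref, alt, p1_is_ref (bool).  ``causal_index`` is the row
    index of the marker carrying the causal locus, or ``None``.
    """

    sites: pd.DataFrame
    chrom_lengths: dict[str, int]
    causal_index: int | None

    def __len__(self) -> int:
        return len(self.sites)

    def chrom_slice(self, chrom: str) -> slice:
        idx = np.flatnonzero((self.sites["chrom"] == chrom).to_numpy())
        return slice(int(idx[0]), int(idx[-1]) + 1)


def _draw_positions(rng: np.random.Generator, length: int, m: int) -> np.ndarray:
    """m distinct sorted 1-based positions on [1, length]."""
    pos: np.ndarray = np.unique(rng.integers(1, length + 1, size=m))
    while len(pos) < m:
        extra = rng.integers(1, length + 1, size=m - len(pos))
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(pos[:m])


_SNP_BASES = np.array(list("ACGT"))


def build_marker_map(spec: GenomeSpec, seed: int) -> MarkerMap:
    """Draw a random marker map consistent with ``spec``.

    Positions are uniform (distinct, sorted) per chromosome.  If a causal
    locus is declared, the nearest marker on its chromosome is moved onto
    the causal position so the locus sits exactly on a marker; a stated
    causal position therefore always has a marker attached.  Marker class
    and parental REF/ALT orientation are drawn per site.
    """
    rng = np.random.default_rng(seed)
    frames = []
    causal_index: int | None = None
    offset = 0
    for c in spec.chromosomes:
        pos = _draw_positions(rng, c.length_bp, spec.markers_per_chromosome)
        if spec.causal_locus is not None and spec.causal_locus[0] == c.name:
            cpos = spec.causal_locus[1]
            j = int(np.argmin(np.abs(pos - cpos)))
            if pos[j] != cpos and cpos not in pos:
                pos[j] = cpos
                pos = np.sort(pos)
                j = int(np.searchsorted(pos, cpos))
            causal_index = offset + j
        m = len(pos)
        is_indel = rng.random(m) < spec.indel_fraction
        ref_base = _SNP_BASES[rng.integers(0, 4, size=m)]
        alt_base = _SNP_BASES[(rng.integers(0, 4, size=m) + rng.integers(1, 4, size=m)) % 4]
        # guarantee alt != ref for SNPs
        same = ref_base == alt_base
        alt_base[same] = _SNP_BASES[(np.flatnonzero(same) + 1) % 4]
        alt_base = np.where(alt_base == ref_base, np.where(ref_base == "A", "C", "A"), alt_base)
        ref = np.where(is_indel, np.char.add(ref_base.astype("U2"), "T"), ref_base).astype("U2")
        alt = np.where(is_indel, ref_base, alt_base).astype("U2")
        # half the indels are insertions instead of deletions
        ins = is_indel & (rng.random(m) < 0.5)
        ref[ins], alt[ins] = alt[ins].copy(), ref[ins].copy()
        frames.append(
            pd.DataFrame(
                {
                    "chrom": c.name,
                    "pos": pos,
                    "morgans": pos / 1e6 * c.cm_per_mb / 100.0,
                    "marker_class": np.where(is_indel, "InDel", "SNP"),
                    "ref": ref,
                    "alt": alt,
                    "p1_is_ref": rng.random(m) >= 0.3,
                }
            )
        )
        offset += m
    sites = pd.concat(frames, ignore_index=True)
    if spec.causal_locus is not None and causal_index is None:
        raise AssertionError("causal locus not attached to any marker")
    return MarkerMap(
        sites=sites,
        chrom_lengths={c.name: c.length_bp for c in spec.chromosomes},
        causal_index=causal_index,
    )


@dataclass(frozen=True)
class F2Individual:
    """One F2 plant: per-marker genotype and papilla phenotype.

    ``genotype`` counts P2 alleles per marker (0 = P1/P1, 1 = P1/P2,
    2 = P2/P2); ``phenotype`` is ``"papilla"`` or ``"non-papilla"``.
    """

    genotype: np.ndarray
    phenotype: str


@dataclass
class F2Population(Sequence):
    """F2 cohort stored column-major for speed; iterates as individuals."""

    marker_map: MarkerMap
    genotypes: np.ndarray  # (n, m) int8, count of P2 alleles
    papilla: np.ndarray  # (n,) bool

    def __len__(self) -> int:
        return self.genotypes.shape[0]

    def __getitem__(self, i) -> F2Individual:
        if isinstance(i, slice):
            return F2Population(self.marker_map, self.genotypes[i], self.papilla[i])
        return F2Individual(
            genotype=self.genotypes[i],
            phenotype="papilla" if self.papilla[i] else "non-papilla",
        )

    def __iter__(self) -> Iterator[F2Individual]:
        for i in range(len(self)):
            yield self[i]

    def subset(self, idx: np.ndarray) -> "F2Population":
        return F2Population(self.marker_map, self.genotypes[idx], self.papilla[idx])

    @property
    def phenotype_counts(self) -> tuple[int, int]:
        """(papilla, non-papilla) counts."""
        n_pap = int(self.papilla.sum())
        return n_pap, len(self) - n_pap


def _simulate_gametes(
    rng: np.random.Generator, marker_map: MarkerMap, n_gametes: int
) -> np.ndarray:
    """F1 gametes (n_gametes, m) of 0/1 alleles, Haldane recombination."""
    m = len(marker_map)
    out = np.empty((n_gametes, m), dtype=np.int8)
    morgans = marker_map.sites["morgans"].to_numpy()
    for chrom in marker_map.chrom_lengths:
        sl = marker_map.chrom_slice(chrom)
        d = np.diff(morgans[sl])
        r = 0.5 * (1.0 - np.exp(-2.0 * d))
        u = rng.random((n_gametes, sl.stop - sl.start))
        cross = np.zeros_like(u, dtype=np.int8)
        cross[:, 0] = u[:, 0] < 0.5  # random founder strand
        cross[:, 1:] = u[:, 1:] < r
        out[:, sl] = np.cumsum(cross, axis=1, dtype=np.int32) & 1
    return out


def simulate_f2_population(
    spec: GenomeSpec | MarkerMap, n: int, seed: int, dominant: bool | None = None
) -> F2Population:
    """Simulate ``n`` F2 individuals by uniting two independent F1 gametes.

    Accepts either a :class:`GenomeSpec` (a marker map is drawn from the
    same seed stream first) or a pre-built :class:`MarkerMap`, with
    ``dominant`` overriding the inheritance model (default: the spec's
    flag, or dominant for a bare map).

    Under the dominant model the expected phenotype ratio is 3:1
    papilla : non-papilla and each marker segregates 1:2:1.
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    if isinstance(spec, GenomeSpec):
        marker_map = build_marker_map(spec, seed)
        if dominant is None:
            dominant = spec.dominant
        has_locus = spec.causal_locus is not None
    else:
        marker_map = spec
        if dominant is None:
            dominant = True
        has_locus = marker_map.causal_index is not None
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF2]))
    gametes = _simulate_gametes(rng, marker_map, 2 * n)
    genotypes = (gametes[:n] + gametes[n:]).astype(np.int8)
    if has_locus:
        g_causal = genotypes[:, marker_map.causal_index]
        papilla = (g_causal <= 1) if dominant else (g_causal == 0)
    else:
        papilla = rng.random(n) < 0.75  # null genome: independent 3:1 draw
    return F2Population(marker_map, genotypes, papilla)


def make_bulks(
    pop: F2Population, bulk_size: int = 30, seed: int = 0
) -> tuple[F2Population, F2Population]:
    """Sample the papilla and non-papilla bulks without replacement.

    Returns ``(papilla_bulk, non_papilla_bulk)``, each of exactly
    ``bulk_size`` individuals drawn uniformly within the phenotype class.
    """
    if bulk_size < 1:
        raise ValueError("bulk_size must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB]))
    pap_idx = np.flatnonzero(pop.papilla)
    non_idx = np.flatnonzero(~pop.papilla)
    for name, idx in (("papilla", pap_idx), ("non-papilla", non_idx)):
        if len(idx) < bulk_size:
            raise ValueError(
                f"only {len(idx)} {name} individuals available; "
                f"cannot form a bulk of {bulk_size}"
            )
    pap_pick = np.sort(rng.choice(pap_idx, size=bulk_size, replace=False))
    non_pick = np.sort(rng.choice(non_idx, size=bulk_size, replace=False))
    return pop.subset(pap_pick), pop.subset(non_pick)


@dataclass
class BulkReads:
    """Read-sampled allele counts for one bulk.

    ``counts`` columns: depth, p1_count, nonp1_count, aligned row-for-row
    with the marker map.  ``coverage`` is the Poisson mean depth and
    ``error_rate`` the per-read allele flip probability.
    """

    marker_map: MarkerMap
    counts: pd.DataFrame
    coverage: float
    error_rate: float

    def __post_init__(self) -> None:
        c = self.counts
        if not ((c["p1_count"] + c["nonp1_count"]) == c["depth"]).all():
            raise ValueError("allele counts must sum to depth")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error rate must be in [0, 0.5)")


def sequence_bulk(
    bulk: F2Population, coverage: float, error_rate: float = 0.0, seed: int = 0
) -> BulkReads:
    """Draw Poisson depths and binomial allele counts for a bulk.

    The bulk's true non-P1 allele frequency f at a marker is the mean P2
    dosage over its 2 * bulk_size allele copies; each of the
    Poisson(coverage) reads reports non-P1 with probability
    f(1-e) + (1-f)e.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error rate must be in [0, 0.5)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EC]))
    f = bulk.genotypes.mean(axis=0) / 2.0
    p = f * (1.0 - error_rate) + (1.0 - f) * error_rate
    depth = rng.poisson(coverage, size=len(bulk.marker_map))
    nonp1 = rng.binomial(depth, p)
    counts = pd.DataFrame(
        {"depth": depth, "p1_count": depth - nonp1, "nonp1_count": nonp1}
    )
    return BulkReads(bulk.marker_map, counts, coverage, error_rate)


def marker_table_from_sim(
    reads_papilla: BulkReads, reads_nonpapilla: BulkReads
):
    """Assemble the screened marker table directly from simulated reads.

    Byte-for-byte equivalent to writing the VCF fixture set and running
    the reader + homozygous-differential screen with min_depth=0, but
    without file I/O; used for replicate studies.
    """
    from .variant_io import MarkerTable  # local import to avoid a cycle

    mm = reads_papilla.marker_map
    sites = mm.sites
    p1_ref = sites["p1_is_ref"].to_numpy()
    df = pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "pos": sites["pos"],
            "ref": sites["ref"],
            "alt": sites["alt"],
            "marker_class": sites["marker_class"],
            "p1_gt": np.where(p1_ref, "0/0", "1/1"),
            "p2_gt": np.where(p1_ref, "1/1", "0/0"),
            "papilla_p1": reads_papilla.counts["p1_count"],
            "papilla_nonp1": reads_papilla.counts["nonp1_count"],
            "nonpapilla_p1": reads_nonpapilla.counts["p1_count"],
            "nonpapilla_nonp1": reads_nonpapilla.counts["nonp1_count"],
        }
    )
    return MarkerTable(df)


# ---------------------------------------------------------------------------
# fixture writers


def _vcf_header(chrom_lengths: dict[str, int], sample: str) -> str:
    lines = ["##fileformat=VCFv4.2", "##source=bsapilla-simdata"]
    for name, length in chrom_lengths.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,'
        'Description="Allelic depths for the ref and alt alleles">'
    )
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample
    )
    return "\n".join(lines) + "\n"


def _write_parent_vcf(
    path: Path, mm: MarkerMap, parent: int, sample: str, depth: int = 30
) -> None:
    """Parent VCFs: homozygous at every site, opposite alleles."""
    sites = mm.sites
    p1_ref = sites["p1_is_ref"].to_numpy()
    hom_ref = p1_ref if parent == 1 else ~p1_ref
    gt = np.where(hom_ref, "0/0", "1/1")
    ad = np.where(hom_ref, f"{depth},0", f"0,{depth}")
    with open(path, "w") as fh:
        fh.write(_vcf_header(mm.chrom_lengths, sample))
        for chrom, pos, ref, alt, g, a in zip(
            sites["chrom"], sites["pos"], sites["ref"], sites["alt"], gt, ad
        ):
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:AD\t{g}:{a}\n")


def _write_bulk_vcf(path: Path, reads: BulkReads, sample: str) -> None:
    """Bulk VCFs carry pooled AD in REF,ALT orientation and no GT call."""
    mm = reads.marker_map
    sites = mm.sites
    p1_ref = sites["p1_is_ref"].to_numpy()
    p1 = reads.counts["p1_count"].to_numpy()
    nonp1 = reads.counts["nonp1_count"].to_numpy()
    ref_ad = np.where(p1_ref, p1, nonp1)
    alt_ad = np.where(p1_ref, nonp1, p1)
    with open(path, "w") as fh:
        fh.write(_vcf_header(mm.chrom_lengths, sample))
        for chrom, pos, ref, alt, ra, aa in zip(
            sites["chrom"], sites["pos"], sites["ref"], sites["alt"], ref_ad, alt_ad
        ):
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:AD\t./.:{ra},{aa}\n"
            )


def _tile_genes(
    mm: MarkerMap, gene_length: int, gene_spacing: int
) -> pd.DataFrame:
    rows = []
    for chrom, length in mm.chrom_lengths.items():
        k = 0
        start = 1
        while start + gene_length - 1 <= length:
            k += 1
            rows.append(
                {
                    "gene_id": f"{chrom}g{k:04d}",
                    "chrom": chrom,
                    "start": start,
                    "end": start + gene_length - 1,
                    "strand": "+" if k % 2 else "-",
                }
            )
            start += gene_spacing
    return pd.DataFrame(rows)


def _pattern_fpkm_row(
    pattern: str, rng: np.random.Generator, high_cut: float, off_cut: float
) -> np.ndarray:
    """Draw a 4-stage FPKM vector realizing one expression pattern."""
    high = lambda: high_cut * rng.uniform(2.0, 50.0)
    low = lambda: rng.uniform(off_cut * 1.5, high_cut * 0.8)
    off = lambda: rng.uniform(0.0, off_cut * 0.5)
    draw = {
        "not_expressed_all": (off, off, off, off),
        "high_all": (high, high, high, high),
        "high_last_two": (off, low, high, high),
        "low_first_three": (low, low, low, high),
        "high_first_two": (high, high, off, off),
        "high_second_only": (low, high, low, off),
    }[pattern]
    return np.array([f() for f in draw])


def make_pattern_fpkm(
    gene_ids: Sequence[str],
    patterns: Sequence[str],
    seed: int = 0,
    high_cut: float = 1.0,
    off_cut: float = 0.1,
    replicates: int = 1,
) -> pd.DataFrame:
    """FPKM matrix with one planted pattern per gene.

    With ``replicates > 1`` emits S1r1..S4r{k} columns whose per-stage mean
    equals the planted value (replicate noise is multiplicative around it).
    """
    if len(gene_ids) != len(patterns):
        raise ValueError("gene_ids and patterns must align")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF9]))
    base = np.vstack(
        [_pattern_fpkm_row(p, rng, high_cut, off_cut) for p in patterns]
    )
    if replicates == 1:
        return pd.DataFrame(
            base, index=pd.Index(gene_ids, name="gene_id"),
            columns=["S1", "S2", "S3", "S4"],
        )
    cols, data = [], []
    for s in range(4):
        w = rng.uniform(0.85, 1.15, size=(len(gene_ids), replicates))
        w *= replicates / w.sum(axis=1, keepdims=True)  # mean preserved
        for r in range(replicates):
            cols.append(f"S{s + 1}r{r + 1}")
            data.append(base[:, s] * w[:, r])
    return pd.DataFrame(
        np.column_stack(data), index=pd.Index(gene_ids, name="gene_id"), columns=cols
    )


def write_fixture_set(
    outdir: str | Path,
    spec: GenomeSpec,
    pop: F2Population,
    bulks: tuple[F2Population, F2Population],
    reads: tuple[BulkReads, BulkReads],
    seed: int = 0,
    gene_length: int = 20_000,
    gene_spacing: int = 100_000,
    n_planted_candidates: int = 2,
    high_cut: float = 1.0,
    off_cut: float = 0.1,
) -> dict[str, Path]:
    """Write the complete file fixture: 4 VCFs, GFF3, FPKM matrix, truth.

    Genes are tiled uniformly over every chromosome; the
    ``n_planted_candidates`` genes nearest the causal locus are planted
    with the high-first-two-stages expression pattern (the trait-candidate
    signature), the rest cycle through the remaining patterns.  The truth
    JSON records the planted causal position and candidate gene ids.
    Deterministic: a fixed seed yields byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mm = pop.marker_map
    paths = {
        "parent1_vcf": outdir / "parent1.vcf",
        "parent2_vcf": outdir / "parent2.vcf",
        "bulk_papilla_vcf": outdir / "bulk_papilla.vcf",
        "bulk_nonpapilla_vcf": outdir / "bulk_nonpapilla.vcf",
        "gff3": outdir / "genes.gff3",
        "fpkm": outdir / "fpkm.tsv",
        "truth": outdir / "truth.json",
    }
    _write_parent_vcf(paths["parent1_vcf"], mm, 1, "P1")
    _write_parent_vcf(paths["parent2_vcf"], mm, 2, "P2")
    _write_bulk_vcf(paths["bulk_papilla_vcf"], reads[0], "BULK_PAP")
    _write_bulk_vcf(paths["bulk_nonpapilla_vcf"], reads[1], "BULK_NON")

    genes = _tile_genes(mm, gene_length, gene_spacing)
    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        for name, length in mm.chrom_lengths.items():
            fh.write(f"##sequence-region {name} 1 {length}\n")
        for row in genes.itertuples(index=False):
            fh.write(
                f"{row.chrom}\tbsapilla\tgene\t{row.start}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID={row.gene_id};Name={row.gene_id}\n"
            )

    # plant expression patterns: candidates at the causal locus, the other
    # patterns cycled over the remaining genes
    patterns = np.array(
        [PATTERN_ORDER[i % len(PATTERN_ORDER)] for i in range(len(genes))],
        dtype=object,
    )
    planted: list[str] = []
    if spec.causal_locus is not None and n_planted_candidates > 0:
        chrom, cpos = spec.causal_locus
        on_chrom = genes.index[genes["chrom"] == chrom]
        mid = (genes.loc[on_chrom, "start"] + genes.loc[on_chrom, "end"]) / 2
        nearest = on_chrom[np.argsort(np.abs(mid - cpos))][:n_planted_candidates]
        others = ~genes.index.isin(nearest)
        patterns[(patterns == "high_first_two") & others] = "high_all"
        patterns[(patterns == "high_second_only") & others] = "high_all"
        patterns[nearest] = "high_first_two"
        planted = sorted(genes.loc[nearest, "gene_id"])
    fpkm = make_pattern_fpkm(
        genes["gene_id"].tolist(), patterns.tolist(), seed=seed,
        high_cut=high_cut, off_cut=off_cut, replicates=3,
    )
    fpkm.to_csv(paths["fpkm"], sep="\t", float_format="%.6g")

    truth = {
        "causal_locus": list(spec.causal_locus) if spec.causal_locus else None,
        "dominant": spec.dominant,
        "n_markers": len(mm),
        "planted_candidates": planted,
        "phenotype_counts": dict(
            zip(("papilla", "non_papilla"), pop.phenotype_counts)
        ),
        "seed": seed,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
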
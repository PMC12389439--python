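"""VCF ingestion and the homozygous-differential marker screen.

Bulked-segregant mapping only uses sites where the two inbred parents are
homozygous for different alleles; this module reads parent and bulk VCFs
(GT + AD FORMAT fields), applies that screen, and orients each bulk's
allele depths relative to the P1 (papilla-reference) parent, whichever of
REF/ALT that parent carries at the site.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

__all__ = ["MarkerTable", "FilterReport", "load_vcf", "screen_homozygous_differential"]

MARKER_TABLE_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "marker_class",
    "p1_gt",
    "p2_gt",
    "papilla_p1",
    "papilla_nonp1",
    "nonpapilla_p1",
    "nonpapilla_nonp1",
]


@dataclass
class MarkerTable:
    """Screened markers with parent genotypes and P1-oriented bulk depths.

    ``sites`` columns (in order): chrom, pos (1-based), ref, alt,
    marker_class (SNP|InDel), p1_gt, p2_gt, then per bulk the P1-allele
    and non-P1-allele read depths (papilla_p1, papilla_nonp1,
    nonpapilla_p1, nonpapilla_nonp1).  Rows are sorted by (chrom, pos).
    """

    sites: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MARKER_TABLE_COLUMNS if c not in self.sites.columns]
        if missing:
            raise ValueError(f"marker table missing columns: {missing}")
        self.sites = (
            self.sites[MARKER_TABLE_COLUMNS]
            .sort_values(["chrom", "pos"], kind="mergesort")
            .reset_index(drop=True)
        )
        depths = self.sites[
            ["papilla_p1", "papilla_nonp1", "nonpapilla_p1", "nonpapilla_nonp1"]
        ].to_numpy()
        if (depths < 0).any():
            raise ValueError("negative allele depths")

    def __len__(self) -> int:
        return len(self.sites)

    def subset(self, marker_class: str) -> "MarkerTable":
        if marker_class not in ("SNP", "InDel"):
            raise ValueError("marker_class must be 'SNP' or 'InDel'")
        return MarkerTable(
            self.sites[self.sites["marker_class"] == marker_class].reset_index(
                drop=True
            )
        )

    def to_tsv(self, path: str | Path) -> None:
        self.sites.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MarkerTable":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class FilterReport:
    """Site accounting for the homozygous-differential screen."""

    input: int = 0
    dropped_multiallelic: int = 0
    dropped_heterozygous_parent: int = 0
    dropped_nondifferential: int = 0
    dropped_missing: int = 0
    dropped_low_depth: int = 0
    retained: int = 0

    def __post_init__(self) -> None:
        total = (
            self.dropped_multiallelic
            + self.dropped_heterozygous_parent
            + self.dropped_nondifferential
            + self.dropped_missing
            + self.dropped_low_depth
            + self.retained
        )
        if self.input != total:
            raise ValueError(
                f"filter report does not balance: input={self.input}, parts={total}"
            )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")


def load_vcf(
    path: str | Path, sample: str | None = None, multiallelic: str = "drop"
) -> tuple[pd.DataFrame, int]:
    """Read one single-sample VCF into per-site records.

    Returns ``(records, n_multiallelic_dropped)``.  Records columns:
    chrom, pos, ref, alt, gt ("0/0", "0/1", "1/1" or "./."), ad_ref,
    ad_alt (-1 when AD is absent).  ``multiallelic`` is "drop" (default)
    or "split" (one record per ALT allele; AD taken per allele).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if multiallelic not in ("drop", "split"):
        raise ValueError("multiallelic policy must be 'drop' or 'split'")
    vcf = VCF(str(path))
    if sample is None:
        if len(vcf.samples) != 1:
            raise ValueError(
                f"{path} has {len(vcf.samples)} samples; pass sample= explicitly"
            )
        sidx = 0
        sample = vcf.samples[0]
    else:
        if sample not in vcf.samples:
            raise ValueError(f"sample {sample!r} not in {path} ({vcf.samples})")
        sidx = vcf.samples.index(sample)

    rows = []
    n_multi = 0
    for v in vcf:
        alts = v.ALT
        if len(alts) == 0:
            continue
        symbolic = any(a.startswith("<") or "[" in a or "]" in a for a in alts)
        if len(alts) > 1 or symbolic:
            if multiallelic == "drop" or symbolic:
                n_multi += 1
                continue
        g = v.genotypes[sidx]
        a, b = g[0], g[1] if len(g) > 2 else -1
        ad = v.format("AD")
        ad_row = ad[sidx] if ad is not None else None
        for alt_i, alt in enumerate(alts, start=1):
            if a < 0 or b < 0:
                gt = "./."
            else:
                # restrict to ref / this alt when splitting
                aa = 0 if a == 0 else (1 if a == alt_i else -1)
                bb = 0 if b == 0 else (1 if b == alt_i else -1)
                gt = "./." if aa < 0 or bb < 0 else f"{min(aa, bb)}/{max(aa, bb)}"
            if ad_row is None:
                ad_ref, ad_alt = -1, -1
            else:
                ad_ref = int(ad_row[0]) if ad_row[0] >= 0 else -1
                ad_alt = int(ad_row[alt_i]) if len(ad_row) > alt_i and ad_row[alt_i] >= 0 else -1
            rows.append((v.CHROM, v.POS, v.REF, alt, gt, ad_ref, ad_alt))
    records = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "gt", "ad_ref", "ad_alt"]
    )
    return records, n_multi


def _classify(ref: pd.Series, alt: pd.Series) -> np.ndarray:
    snp = (ref.str.len() == 1) & (alt.str.len() == 1)
    return np.where(snp, "SNP", "InDel")


def screen_homozygous_differential(
    parent1: pd.DataFrame,
    parent2: pd.DataFrame,
    bulk_papilla: pd.DataFrame,
    bulk_nonpapilla: pd.DataFrame,
    min_depth: int = 8,
    n_multiallelic: int = 0,
) -> tuple[MarkerTable, FilterReport]:
    """Retain sites where both parents are homozygous for different alleles.

    Sites are keyed by (chrom, pos, ref, alt).  A site is dropped and
    counted as heterozygous-parent when either parent's genotype is
    heterozygous; as missing when a parental genotype or a bulk AD record
    is absent; as low-depth when either bulk's total depth at the site is
    below ``min_depth``.  Bulk depths are re-oriented so "P1 allele" is
    whichever allele parent1 is homozygous for.  ``n_multiallelic``
    carries the loader's drop count into the report.
    """
    key = ["chrom", "pos", "ref", "alt"]
    p = parent1.merge(
        parent2, on=key, how="outer", suffixes=("_p1", "_p2"), sort=True
    )
    n_input = len(p) + n_multiallelic

    gt1 = p["gt_p1"].fillna("./.")
    gt2 = p["gt_p2"].fillna("./.")
    missing_parent = (gt1 == "./.") | (gt2 == "./.")
    het = (~missing_parent) & ((gt1 == "0/1") | (gt2 == "0/1"))
    hom_diff = (~missing_parent) & (~het) & (gt1 != gt2)
    same_hom = (~missing_parent) & (~het) & (gt1 == gt2)

    kept = p[hom_diff].copy()
    bp = bulk_papilla.rename(
        columns={"ad_ref": "pap_ref", "ad_alt": "pap_alt"}
    )[key + ["pap_ref", "pap_alt"]]
    bn = bulk_nonpapilla.rename(
        columns={"ad_ref": "non_ref", "ad_alt": "non_alt"}
    )[key + ["non_ref", "non_alt"]]
    kept = kept.merge(bp, on=key, how="left").merge(bn, on=key, how="left")
    ad_cols = ["pap_ref", "pap_alt", "non_ref", "non_alt"]
    missing_bulk = kept[ad_cols].isna().any(axis=1) | (kept[ad_cols] < 0).any(axis=1)
    n_missing = int(missing_parent.sum()) + int(missing_bulk.sum())
    kept = kept[~missing_bulk.to_numpy()].copy()
    kept[ad_cols] = kept[ad_cols].astype(np.int64)

    low = (
        (kept["pap_ref"] + kept["pap_alt"] < min_depth)
        | (kept["non_ref"] + kept["non_alt"] < min_depth)
    )
    n_low = int(low.sum())
    kept = kept[~low.to_numpy()].copy()

    p1_is_ref = (kept["gt_p1"] == "0/0").to_numpy()
    table = pd.DataFrame(
        {
            "chrom": kept["chrom"],
            "pos": kept["pos"],
            "ref": kept["ref"],
            "alt": kept["alt"],
            "marker_class": _classify(kept["ref"], kept["alt"]),
            "p1_gt": kept["gt_p1"],
            "p2_gt": kept["gt_p2"],
            "papilla_p1": np.where(p1_is_ref, kept["pap_ref"], kept["pap_alt"]),
            "papilla_nonp1": np.where(p1_is_ref, kept["pap_alt"], kept["pap_ref"]),
            "nonpapilla_p1": np.where(p1_is_ref, kept["non_ref"], kept["non_alt"]),
            "nonpapilla_nonp1": np.where(p1_is_ref, kept["non_alt"], kept["non_ref"]),
        }
    )
    report = FilterReport(
        input=n_input,
        dropped_multiallelic=n_multiallelic,
        dropped_heterozygous_parent=int(het.sum()),
        dropped_nondifferential=int(same_hom.sum()),
        dropped_missing=n_missing,
        dropped_low_depth=n_low,
        retained=len(table),
    )
    return MarkerTable(table), report
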
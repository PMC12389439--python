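"""Stage-pattern classification of husk expression and candidate filtering.

Expression is an FPKM matrix over four developmental stages: S1 panicle
branch at differentiation, S2 panicle branch at heading, S3 husk at
pollination, S4 husk at filling.  Because papilla cells are fully formed
by the pollination stage, genes driving their differentiation should be
highly expressed during the first two stages; the candidate filter keeps
exactly those patterns.

A stage is "high" at FPKM >= high_cut (default 1), "off" below off_cut
(default 0.1), and "low" in between.  Pattern labels, applied in
precedence order so they are mutually exclusive and exhaustive:

1. not_expressed_all  — all four stages off
2. high_all           — all four stages high
3. high_first_two     — S1 and S2 high, S3 and S4 not high
4. high_second_only   — S2 high, S1/S3/S4 not high
5. high_last_two      — S3 and S4 high, S1 and S2 not high
6. low_first_three    — S1..S3 not high (not all off), S4 high
7. other              — anything else
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .colocal import GeneSet

__all__ = [
    "PATTERN_LABELS",
    "ExpressionMatrix",
    "read_fpkm",
    "classify_pattern",
    "pattern_census",
    "select_candidates",
]

PATTERN_LABELS = (
    "not_expressed_all",
    "high_all",
    "high_last_two",
    "low_first_three",
    "high_first_two",
    "high_second_only",
    "other",
)

CANDIDATE_LABELS = frozenset({"high_first_two", "high_second_only"})

STAGES = ("S1", "S2", "S3", "S4")

_REP_COL = re.compile(r"^(S[1-4])(?:[._ ]?r?e?p?(\d+))?$", re.IGNORECASE)


@dataclass
class ExpressionMatrix:
    """Gene x stage FPKM values (replicates already averaged)."""

    fpkm: pd.DataFrame  # index gene_id, columns S1..S4

    def __post_init__(self) -> None:
        missing = [s for s in STAGES if s not in self.fpkm.columns]
        if missing:
            raise ValueError(f"expression matrix missing stages: {missing}")
        self.fpkm = self.fpkm[list(STAGES)].astype(float)
        if (self.fpkm.to_numpy() < 0).any():
            raise ValueError("negative FPKM values")

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.fpkm.index

    def vector(self, gene_id: str) -> np.ndarray:
        return self.fpkm.loc[gene_id].to_numpy()


def read_fpkm(path: str | Path) -> ExpressionMatrix:
    """Read a tab-delimited FPKM table.

    First column is the gene id; remaining columns are S1..S4 or
    per-replicate variants (S1r1..S4r3, S1_1, "S2 rep2", ...).  Replicate
    columns are averaged per stage.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    stage_of: dict[str, str] = {}
    for col in df.columns:
        m = _REP_COL.match(str(col).strip())
        if m:
            stage_of[col] = m.group(1).upper()
    unknown = [c for c in df.columns if c not in stage_of]
    if unknown:
        raise ValueError(f"unrecognized FPKM columns: {unknown}")
    mean = df.T.groupby([stage_of[c] for c in df.columns]).mean().T
    return ExpressionMatrix(mean)


def _stage_states(
    fpkm: np.ndarray, high_cut: float, off_cut: float
) -> np.ndarray:
    """Per-stage state codes: 2 = high, 1 = low, 0 = off."""
    return np.where(fpkm >= high_cut, 2, np.where(fpkm < off_cut, 0, 1))


def classify_pattern(
    fpkm, high_cut: float = 1.0, off_cut: float = 0.1
) -> str:
    """Label one 4-stage FPKM vector (see module docstring for the rules)."""
    if not off_cut < high_cut:
        raise ValueError("off_cut must be below high_cut")
    v = np.asarray(fpkm, dtype=float)
    if v.shape != (4,):
        raise ValueError("expected a 4-stage FPKM vector")
    if (v < 0).any():
        raise ValueError("negative FPKM")
    s = _stage_states(v, high_cut, off_cut)
    high = s == 2
    if (s == 0).all():
        return "not_expressed_all"
    if high.all():
        return "high_all"
    if high[0] and high[1] and not high[2] and not high[3]:
        return "high_first_two"
    if high[1] and not high[0] and not high[2] and not high[3]:
        return "high_second_only"
    if high[2] and high[3] and not high[0] and not high[1]:
        return "high_last_two"
    if not high[0] and not high[1] and not high[2] and high[3]:
        return "low_first_three"
    return "other"


def _labels_for(
    genes: GeneSet, em: ExpressionMatrix, high_cut: float, off_cut: float
) -> dict[str, str]:
    labels = {}
    absent = []
    for g in genes.sorted_ids():
        if g in em:
            labels[g] = classify_pattern(em.vector(g), high_cut, off_cut)
        else:
            absent.append(g)
            labels[g] = "not_expressed_all"
    if absent:
        warnings.warn(
            f"{len(absent)} gene(s) absent from the expression matrix; "
            "treated as not expressed"
        )
    return labels


def pattern_census(
    genes: GeneSet,
    em: ExpressionMatrix,
    high_cut: float = 1.0,
    off_cut: float = 0.1,
) -> dict[str, int]:
    """Count genes per pattern label; counts partition the gene set."""
    labels = _labels_for(genes, em, high_cut, off_cut)
    census = {lab: 0 for lab in PATTERN_LABELS}
    for lab in labels.values():
        census[lab] += 1
    return census


def select_candidates(
    genes: GeneSet,
    em: ExpressionMatrix,
    high_cut: float = 1.0,
    off_cut: float = 0.1,
) -> GeneSet:
    """Keep genes highly expressed in the first two stages.

    Retains patterns high_first_two and high_second_only — both signatures
    where expression peaks before the papillae are fully formed at the
    pollination stage and S3/S4 are not high.
    """
    labels = _labels_for(genes, em, high_cut, off_cut)
    kept = {g for g, lab in labels.items() if lab in CANDIDATE_LABELS}
    prov = {
        g: sorted(set(genes.provenance.get(g, [genes.label]) + [f"pattern:{labels[g]}"]))
        for g in kept
    }
    return GeneSet(
        label=f"{genes.label}:expression-filtered",
        genes=frozenset(kept),
        provenance=prov,
    )


def census_to_json(census: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(census, fh, indent=2, sort_keys=True)
        fh.write("\n")
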
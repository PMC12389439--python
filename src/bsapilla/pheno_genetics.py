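"""Mendelian segregation tests and seed-phenotype utility statistics.

For a monogenic dominant trait an F2 population segregates 3:1
dominant : recessive.  Observed counts are tested with an uncorrected
chi-square goodness-of-fit statistic on one degree of freedom (no Yates
continuity correction — the convention under which a 128:36 split against
3:1 gives chi2 = 0.813, p = 0.367).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd
from scipy import stats

__all__ = [
    "SegregationCount",
    "UptakeRecord",
    "chisq_goodness_of_fit",
    "format_ratio",
    "water_uptake",
    "germination_fraction",
    "segregation_table",
]


def chisq_goodness_of_fit(
    observed: tuple[int, int], ratio: tuple[float, float] = (3, 1)
) -> tuple[float, float]:
    """Chi-square goodness of fit of (dominant, recessive) counts to a ratio.

    Expected counts are total * (a, b) / (a + b); the statistic is
    sum((obs - exp)^2 / exp) with no continuity correction, and the
    p-value the upper tail of chi-square with one degree of freedom.
    """
    n_dom, n_rec = observed
    if n_dom < 0 or n_rec < 0:
        raise ValueError("counts must be non-negative")
    total = n_dom + n_rec
    if total == 0:
        raise ValueError("total count must be positive")
    a, b = ratio
    if a <= 0 or b <= 0:
        raise ValueError("expected ratio parts must be positive")
    expected = (total * a / (a + b), total * b / (a + b))
    chi2, p = stats.chisquare(f_obs=list(observed), f_exp=list(expected))
    return float(chi2), float(p)


def format_ratio(n_dom: int, n_rec: int) -> str:
    """Observed segregation ratio rendered as "x.x:1" (one decimal)."""
    if n_rec == 0:
        return "all-dominant"
    return f"{n_dom / n_rec:.1f}:1"


@dataclass
class SegregationCount:
    """One population's segregation record and its chi-square test."""

    population: str
    papilla: int
    non_papilla: int
    expected_ratio: tuple[float, float] = (3, 1)
    chi2: float = None  # type: ignore[assignment]
    p_value: float = None  # type: ignore[assignment]
    observed_ratio: str = ""

    def __post_init__(self) -> None:
        self.chi2, self.p_value = chisq_goodness_of_fit(
            (self.papilla, self.non_papilla), self.expected_ratio
        )
        self.observed_ratio = format_ratio(self.papilla, self.non_papilla)

    @property
    def total(self) -> int:
        return self.papilla + self.non_papilla


def segregation_table(counts: list[SegregationCount]) -> pd.DataFrame:
    """Mirror the standard F2 segregation report (chi2 and p to 3 decimals)."""
    return pd.DataFrame(
        {
            "population": [c.population for c in counts],
            "total": [c.total for c in counts],
            "papilla": [c.papilla for c in counts],
            "non_papilla": [c.non_papilla for c in counts],
            "observed_ratio": [c.observed_ratio for c in counts],
            "expected_ratio": [
                f"{c.expected_ratio[0]:g}:{c.expected_ratio[1]:g}" for c in counts
            ],
            "chi2": [round(c.chi2, 3) for c in counts],
            "p": [round(c.p_value, 3) for c in counts],
        }
    )


def segregation_json(counts: list[SegregationCount], path: str | Path) -> None:
    """Full-precision JSON record of the segregation tests."""
    with open(path, "w") as fh:
        json.dump([asdict(c) for c in counts], fh, indent=2, default=list)
        fh.write("\n")


def water_uptake(wet_weight: float, dry_weight: float) -> float:
    """Percent weight increase Wr = (Wa - Wb) / Wb * 100.

    ``wet_weight`` (Wa) is the seed mass after water contact, ``dry_weight``
    (Wb) the initial dry mass, both in grams.
    """
    if dry_weight <= 0:
        raise ValueError("dry weight must be positive")
    if wet_weight < dry_weight:
        raise ValueError("wet weight below dry weight")
    return (wet_weight - dry_weight) / dry_weight * 100.0


def germination_fraction(germinated: int, total: int) -> float:
    """Fraction of seeds germinated."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= germinated <= total:
        raise ValueError("germinated count outside [0, total]")
    return germinated / total


@dataclass
class UptakeRecord:
    """One water-uptake / germination observation."""

    dry_weight: float
    wet_weight: float
    germinated: int = 0
    total_seeds: int = 0
    uptake_percent: float = None  # type: ignore[assignment]
    germination: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.uptake_percent = water_uptake(self.wet_weight, self.dry_weight)
        self.germination = (
            germination_fraction(self.germinated, self.total_seeds)
            if self.total_seeds
            else float("nan")
        )
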
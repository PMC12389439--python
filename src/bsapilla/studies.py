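"""Replicate simulation studies: calibration and operating characteristics.

These routines re-run the simulate -> index -> interval chain over many
seeded replicates to measure the method's behaviour under the study
conditions (tail bulks of 30, ~50x bulk coverage, dominant monogenic
trait): the expected delta index at and away from the causal locus, the
locus recovery rate of interval calling, and the false-call rate on a
null genome with no trait locus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import simdata
from .bsa_index import call_intervals, compute_index, summarize_chromosomes, window_track

__all__ = [
    "delta_expectation_study",
    "locus_recovery_study",
    "null_control_study",
    "segregation_calibration_study",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) >> 1]  # keep below 2**31


def delta_expectation_study(
    n_replicates: int = 200,
    seed: int = 0,
    n_f2: int = 240,
    bulk_size: int = 30,
    coverage: float = 50.0,
    error_rate: float = 0.002,
) -> dict[str, float]:
    """Mean empirical delta index at the causal and an unlinked marker.

    Uses a two-chromosome genome with the causal locus mid-chromosome-1;
    the unlinked marker is mid-chromosome-2.  For the dominant model the
    exact expectations are 2/3 and 0.
    """
    spec = simdata.GenomeSpec(
        chromosomes=[
            simdata.ChromosomeSpec("chr1", 40_000_000),
            simdata.ChromosomeSpec("chr2", 40_000_000),
        ],
        markers_per_chromosome=11,
        causal_locus=("chr1", 20_000_000),
    )
    causal_deltas, unlinked_deltas = [], []
    for s in _child_seeds(seed, n_replicates):
        mm = simdata.build_marker_map(spec, s)
        pop = simdata.simulate_f2_population(mm, n_f2, s)
        pap, non = simdata.make_bulks(pop, bulk_size, s)
        r_pap = simdata.sequence_bulk(pap, coverage, error_rate, s)
        r_non = simdata.sequence_bulk(non, coverage, error_rate, s + 1)
        table = simdata.marker_table_from_sim(r_pap, r_non)
        track = compute_index(table)
        m = track.markers.set_index(["chrom", "pos"])
        causal_pos = int(mm.sites.loc[mm.causal_index, "pos"])
        if ("chr1", causal_pos) in m.index:
            causal_deltas.append(float(m.loc[("chr1", causal_pos), "delta"]))
        chr2 = m.loc["chr2"]
        # marker nearest mid-chromosome-2: unlinked to the causal locus
        j = (chr2.index.to_numpy() - 20_000_000).__abs__().argmin()
        unlinked_deltas.append(float(chr2.iloc[j]["delta"]))
    return {
        "mean_delta_causal": float(np.mean(causal_deltas)),
        "mean_delta_unlinked": float(np.mean(unlinked_deltas)),
        "n_replicates": n_replicates,
    }


def locus_recovery_study(
    n_runs: int = 50,
    seed: int = 0,
    n_f2: int = 300,
    bulk_size: int = 30,
    coverage: float = 50.0,
    error_rate: float = 0.002,
    window_size: int = 1_000_000,
    step: int = 100_000,
    threshold: float = 0.5,
    min_markers: int = 5,
) -> dict[str, float]:
    """Fraction of seeded default-scale runs that recover the planted locus.

    Per run (9 chromosomes x 40 Mb, 2000 markers each, causal locus on
    chromosome 5): whether a called SNP candidate interval contains the
    causal position, and whether the chromosome summary puts both the
    above-threshold marker count maximum and the global |delta| argmax on
    chromosome 5.
    """
    spec = simdata.GenomeSpec.default()
    causal_chrom, causal_pos = spec.causal_locus
    recovered = summary_chr5 = 0
    causal_deltas = []
    for s in _child_seeds(seed, n_runs):
        mm = simdata.build_marker_map(spec, s)
        pop = simdata.simulate_f2_population(mm, n_f2, s)
        pap, non = simdata.make_bulks(pop, bulk_size, s)
        r_pap = simdata.sequence_bulk(pap, coverage, error_rate, s)
        r_non = simdata.sequence_bulk(non, coverage, error_rate, s + 1)
        table = simdata.marker_table_from_sim(r_pap, r_non)
        snp_track = compute_index(table, marker_class="SNP")
        wt = window_track(snp_track, window_size, step, mm.chrom_lengths)
        intervals = call_intervals(wt, threshold, min_markers)
        if any(
            iv.chrom == causal_chrom and iv.start <= causal_pos <= iv.end
            for iv in intervals
        ):
            recovered += 1
        full_track = compute_index(table)
        summary = summarize_chromosomes(full_track, threshold)
        count_max = max(summary.counts, key=summary.counts.get)
        if count_max == causal_chrom and summary.argmax_chrom == causal_chrom:
            summary_chr5 += 1
        m = full_track.markers
        at_causal = m[(m["chrom"] == causal_chrom) & (m["pos"] == causal_pos)]
        if len(at_causal):
            causal_deltas.append(float(at_causal["delta"].iloc[0]))
    return {
        "recovery_rate": recovered / n_runs,
        "causal_chromosome_summary_rate": summary_chr5 / n_runs,
        "mean_delta_at_causal": float(np.mean(causal_deltas)),
        "n_runs": n_runs,
    }


def null_control_study(
    n_runs: int = 50,
    seed: int = 0,
    n_f2: int = 300,
    bulk_size: int = 30,
    coverage: float = 50.0,
    error_rate: float = 0.002,
    window_size: int = 1_000_000,
    step: int = 100_000,
    threshold: float = 0.5,
    min_markers: int = 5,
) -> dict[str, float]:
    """Type-I control on a null genome with no causal locus.

    Returns the overall fraction of markers with |delta| >= threshold and
    the number of runs in which any candidate interval with >=
    ``min_markers`` supporting markers was called.
    """
    spec = simdata.GenomeSpec.null()
    n_exceed = n_markers = runs_with_interval = 0
    for s in _child_seeds(seed, n_runs):
        mm = simdata.build_marker_map(spec, s)
        pop = simdata.simulate_f2_population(mm, n_f2, s)
        pap, non = simdata.make_bulks(pop, bulk_size, s)
        r_pap = simdata.sequence_bulk(pap, coverage, error_rate, s)
        r_non = simdata.sequence_bulk(non, coverage, error_rate, s + 1)
        table = simdata.marker_table_from_sim(r_pap, r_non)
        track = compute_index(table)
        n_exceed += int((track.markers["delta"].abs() >= threshold).sum())
        n_markers += len(track)
        wt = window_track(track, window_size, step, mm.chrom_lengths)
        if call_intervals(wt, threshold, min_markers):
            runs_with_interval += 1
    return {
        "marker_exceed_fraction": n_exceed / n_markers,
        "runs_with_interval": runs_with_interval,
        "clean_runs": n_runs - runs_with_interval,
        "n_runs": n_runs,
    }


def segregation_calibration_study(
    n_replicates: int = 200,
    seed: int = 0,
    n_f2: int = 300,
    alpha: float = 0.01,
) -> dict[str, float]:
    """Fraction of simulated F2 cohorts whose phenotype counts pass 3:1."""
    from .pheno_genetics import chisq_goodness_of_fit

    spec = simdata.GenomeSpec(
        chromosomes=[simdata.ChromosomeSpec("chr1", 1_000_000)],
        markers_per_chromosome=3,
        causal_locus=("chr1", 500_000),
    )
    passed = 0
    for s in _child_seeds(seed, n_replicates):
        pop = simdata.simulate_f2_population(spec, n_f2, s)
        _, p = chisq_goodness_of_fit(pop.phenotype_counts, (3, 1))
        if p > alpha:
            passed += 1
    return {"pass_fraction": passed / n_replicates, "n_replicates": n_replicates}
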
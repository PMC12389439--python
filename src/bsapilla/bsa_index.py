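"""Delta-index computation, window aggregation and interval calling.

The per-bulk index at a marker is the fraction of that bulk's reads
carrying the non-P1 allele: 0 when the bulk matches the P1 (reference)
parent, 1 when it is completely mismatched.  The delta index is the
non-papilla bulk's index minus the papilla bulk's index; markers linked
to the causal locus show a large |delta| (2/3 in expectation at the locus
itself for a dominant monogenic trait with tail bulks), unlinked markers
fluctuate around 0.  Sliding-window means of delta are thresholded at
|mean| >= 0.5 and merged into candidate intervals.

Coordinates are 1-based inclusive throughout; BED exports convert to
0-based half-open.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .variant_io import MarkerTable

__all__ = [
    "IndexTrack",
    "WindowTrack",
    "CandidateInterval",
    "ChromosomeSummary",
    "compute_index",
    "window_track",
    "call_intervals",
    "summarize_chromosomes",
    "permutation_band",
    "plot_tracks",
]


@dataclass
class IndexTrack:
    """Per-marker index values for both bulks and their difference.

    ``markers`` columns: chrom, pos, marker_class, index_papilla,
    index_nonpapilla, delta; sorted by (chrom, pos).
    ``n_zero_depth_excluded`` counts markers dropped because a bulk had
    zero coverage (index undefined there).
    """

    markers: pd.DataFrame
    n_zero_depth_excluded: int = 0

    def __len__(self) -> int:
        return len(self.markers)

    def to_tsv(self, path: str | Path) -> None:
        self.markers.to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class Window:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    n_markers: int
    mean_delta: float  # nan when empty


@dataclass
class WindowTrack:
    """Sliding-window means of delta over each chromosome.

    ``windows`` columns: chrom, start, end, n_markers, mean_delta (NaN for
    empty windows).  Keeps a reference to the source track so interval
    calling can locate peak markers.
    """

    windows: pd.DataFrame
    window_size: int
    step: int
    track: IndexTrack

    def to_tsv(self, path: str | Path) -> None:
        self.windows.to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class CandidateInterval:
    """A merged run of threshold-passing windows."""

    chrom: str
    start: int  # 1-based inclusive
    end: int
    peak_abs_delta: float
    peak_pos: int
    n_markers: int
    marker_class: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("interval start > end")


@dataclass
class ChromosomeSummary:
    """Per-chromosome counts of |delta| >= threshold and the global peak."""

    threshold: float
    counts: dict[str, int]
    argmax_chrom: str | None
    argmax_pos: int | None
    argmax_delta: float | None


def compute_index(table: MarkerTable, marker_class: str | None = None) -> IndexTrack:
    """Per-bulk non-P1 read fraction and the delta track.

    ``marker_class`` restricts to "SNP" or "InDel"; markers with zero
    depth in either bulk are excluded and counted.
    """
    df = table.sites
    if marker_class is not None:
        df = df[df["marker_class"] == marker_class]
    dp_pap = (df["papilla_p1"] + df["papilla_nonp1"]).to_numpy(dtype=float)
    dp_non = (df["nonpapilla_p1"] + df["nonpapilla_nonp1"]).to_numpy(dtype=float)
    covered = (dp_pap > 0) & (dp_non > 0)
    df = df[covered]
    idx_pap = df["papilla_nonp1"].to_numpy(float) / dp_pap[covered]
    idx_non = df["nonpapilla_nonp1"].to_numpy(float) / dp_non[covered]
    markers = pd.DataFrame(
        {
            "chrom": df["chrom"].to_numpy(),
            "pos": df["pos"].to_numpy(),
            "marker_class": df["marker_class"].to_numpy(),
            "index_papilla": idx_pap,
            "index_nonpapilla": idx_non,
            "delta": idx_non - idx_pap,
        }
    ).sort_values(["chrom", "pos"], kind="mergesort", ignore_index=True)
    return IndexTrack(markers, n_zero_depth_excluded=int((~covered).sum()))


def window_track(
    track: IndexTrack,
    window_size: int = 1_000_000,
    step: int = 100_000,
    chrom_lengths: dict[str, int] | None = None,
) -> WindowTrack:
    """Sliding-window arithmetic means of delta.

    Windows start at 1, 1+step, ... and span ``window_size`` bp.  Tiling
    extends to the chromosome length when given, else to the last marker.
    Empty windows carry NaN means and are never thresholded downstream.
    """
    if step <= 0 or window_size <= 0:
        raise ValueError("window size and step must be positive")
    if window_size < step:
        raise ValueError("window size must be >= step")
    rows = []
    for chrom, sub in track.markers.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        delta = sub["delta"].to_numpy()
        csum = np.concatenate([[0.0], np.cumsum(delta)])
        length = (
            chrom_lengths[chrom]
            if chrom_lengths is not None
            else int(pos[-1]) if len(pos) else window_size
        )
        starts = np.arange(1, max(length - window_size + 1, 1) + 1, step)
        if len(starts) == 0 or starts[-1] + window_size - 1 < length:
            starts = np.append(starts, starts[-1] + step if len(starts) else 1)
        ends = starts + window_size - 1
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="right")
        n = hi - lo
        with np.errstate(invalid="ignore"):
            means = np.where(n > 0, (csum[hi] - csum[lo]) / np.maximum(n, 1), np.nan)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "n_markers": n,
                    "mean_delta": means,
                }
            )
        )
    windows = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["chrom", "start", "end", "n_markers", "mean_delta"])
    )
    return WindowTrack(windows, window_size, step, track)


def call_intervals(
    wt: WindowTrack, threshold: float = 0.5, min_markers: int = 5
) -> list[CandidateInterval]:
    """Merge threshold-passing windows into candidate intervals.

    A window qualifies when it holds >= ``min_markers`` markers and
    |mean delta| >= ``threshold`` (boundary included).  Qualifying windows
    on the same chromosome are merged while they overlap or touch; the
    peak is the constituent marker with the largest |delta|.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    w = wt.windows
    ok = w[
        (w["n_markers"] >= min_markers)
        & w["mean_delta"].notna()
        & (w["mean_delta"].abs() >= threshold)
    ]
    intervals: list[CandidateInterval] = []
    markers = wt.track.markers
    for chrom, sub in ok.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        cur_start = cur_end = None
        spans = []
        for s, e in zip(sub["start"], sub["end"]):
            if cur_start is None:
                cur_start, cur_end = s, e
            elif s <= cur_end + 1:
                cur_end = max(cur_end, e)
            else:
                spans.append((cur_start, cur_end))
                cur_start, cur_end = s, e
        if cur_start is not None:
            spans.append((cur_start, cur_end))
        msub = markers[markers["chrom"] == chrom]
        klass = msub["marker_class"].unique()
        marker_class = klass[0] if len(klass) == 1 else "mixed"
        for s, e in spans:
            inside = msub[(msub["pos"] >= s) & (msub["pos"] <= e)]
            j = inside["delta"].abs().idxmax()
            intervals.append(
                CandidateInterval(
                    chrom=chrom,
                    start=int(s),
                    end=int(e),
                    peak_abs_delta=float(abs(inside.loc[j, "delta"])),
                    peak_pos=int(inside.loc[j, "pos"]),
                    n_markers=int(len(inside)),
                    marker_class=marker_class,
                )
            )
    return intervals


def summarize_chromosomes(
    track: IndexTrack, threshold: float = 0.5
) -> ChromosomeSummary:
    """Count markers with |delta| >= threshold per chromosome; find the peak."""
    m = track.markers
    counts = {
        chrom: int((sub["delta"].abs() >= threshold).sum())
        for chrom, sub in m.groupby("chrom", sort=True)
    }
    if len(m) == 0:
        return ChromosomeSummary(threshold, counts, None, None, None)
    j = m["delta"].abs().idxmax()
    if abs(float(m.loc[j, "delta"])) == 0.0:
        # a flat all-zero track has no meaningful peak
        return ChromosomeSummary(threshold, counts, None, None, None)
    return ChromosomeSummary(
        threshold,
        counts,
        str(m.loc[j, "chrom"]),
        int(m.loc[j, "pos"]),
        float(m.loc[j, "delta"]),
    )


def permutation_band(
    track: IndexTrack,
    window_size: int = 1_000_000,
    step: int = 100_000,
    n_permutations: int = 200,
    quantile: float = 0.995,
    seed: int = 0,
) -> float:
    """Optional empirical null band for window means (off by default).

    Randomly flips the sign of each marker's delta (exchangeable under no
    linkage), recomputes window means, and returns the requested quantile
    of |mean| over all permutations and non-empty windows.
    """
    rng = np.random.default_rng(seed)
    maxima = []
    base = track.markers
    for _ in range(n_permutations):
        flipped = base.copy()
        flipped["delta"] = base["delta"].to_numpy() * rng.choice(
            [-1.0, 1.0], size=len(base)
        )
        wt = window_track(IndexTrack(flipped), window_size, step)
        vals = wt.windows["mean_delta"].abs().dropna()
        if len(vals):
            maxima.extend(vals.to_numpy())
    return float(np.quantile(maxima, quantile)) if maxima else float("nan")


def intervals_to_bed(intervals: list[CandidateInterval], path: str | Path) -> None:
    """Write intervals as BED (0-based half-open) with the peak as score."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t"
                f"{iv.marker_class}_interval\t{iv.peak_abs_delta:.4f}\t.\n"
            )


def intervals_to_json(intervals: list[CandidateInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([asdict(iv) for iv in intervals], fh, indent=2)
        fh.write("\n")


def plot_tracks(
    track: IndexTrack,
    wt: WindowTrack | None = None,
    intervals: list[CandidateInterval] | None = None,
    outpath: str | Path = "delta_index.png",
    threshold: float = 0.5,
) -> Path:
    """One panel per chromosome: marker deltas, window means, threshold lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = sorted(track.markers["chrom"].unique())
    n = max(len(chroms), 1)
    fig, axes = plt.subplots(n, 1, figsize=(10, 1.6 * n + 1), sharey=True, squeeze=False)
    for ax, chrom in zip(axes.ravel(), chroms):
        sub = track.markers[track.markers["chrom"] == chrom]
        ax.scatter(sub["pos"] / 1e6, sub["delta"], s=2, alpha=0.4, color="grey")
        if wt is not None:
            wsub = wt.windows[wt.windows["chrom"] == chrom]
            mid = (wsub["start"] + wsub["end"]) / 2e6
            ax.plot(mid, wsub["mean_delta"], color="tab:blue", lw=1.2)
        for y in (threshold, -threshold):
            ax.axhline(y, color="tab:red", ls="--", lw=0.8)
        for iv in intervals or []:
            if iv.chrom == chrom:
                ax.axvspan(iv.start / 1e6, iv.end / 1e6, color="tab:orange", alpha=0.3)
        ax.set_ylabel(chrom, rotation=0, ha="right", va="center")
        ax.set_ylim(-1.05, 1.05)
    if chroms:
        axes.ravel()[len(chroms) - 1].set_xlabel("position (Mb)")
    for ax in axes.ravel()[len(chroms):]:
        ax.axis("off")
    fig.suptitle("delta index along chromosomes")
    fig.tight_layout()
    outpath = Path(outpath)
    fig.savefig(outpath, dpi=120)
    plt.close(fig)
    return outpath
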
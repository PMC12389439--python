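"""Index computation, windowing, interval calling and summaries."""

import numpy as np
import pandas as pd
import pytest

from bsapilla.bsa_index import (
    IndexTrack,
    call_intervals,
    compute_index,
    intervals_to_bed,
    permutation_band,
    plot_tracks,
    summarize_chromosomes,
    window_track,
)
from bsapilla.variant_io import MarkerTable
from conftest import f2_expected_delta


def make_table(rows):
    """rows: (chrom, pos, papilla_p1, papilla_nonp1, nonpap_p1, nonpap_nonp1)"""
    return MarkerTable(
        pd.DataFrame(
            [
                {
                    "chrom": c,
                    "pos": p,
                    "ref": "A",
                    "alt": "C",
                    "marker_class": "SNP",
                    "p1_gt": "0/0",
                    "p2_gt": "1/1",
                    "papilla_p1": pp,
                    "papilla_nonp1": pn,
                    "nonpapilla_p1": np_,
                    "nonpapilla_nonp1": nn,
                }
                for c, p, pp, pn, np_, nn in rows
            ]
        )
    )


def track_from_deltas(deltas, positions=None, chrom="chr1"):
    """IndexTrack with papilla index 0 and non-papilla index = delta."""
    positions = positions or [(i + 1) * 1000 for i in range(len(deltas))]
    return IndexTrack(
        pd.DataFrame(
            {
                "chrom": chrom,
                "pos": positions,
                "marker_class": "SNP",
                "index_papilla": 0.0,
                "index_nonpapilla": deltas,
                "delta": deltas,
            }
        )
    )


class TestComputeIndex:
    def test_fully_matched_bulk_index_zero(self):
        t = make_table([("chr1", 100, 10, 0, 10, 0)])
        track = compute_index(t)
        assert track.markers.loc[0, "index_papilla"] == 0.0

    def test_fully_mismatched_bulk_index_one(self):
        t = make_table([("chr1", 100, 0, 12, 0, 12)])
        track = compute_index(t)
        assert track.markers.loc[0, "index_papilla"] == 1.0
        assert track.markers.loc[0, "delta"] == 0.0

    def test_dominant_expectation_delta_two_thirds(self):
        # papilla bulk index 1/3, non-papilla index 1 -> delta 2/3;
        # matches the exact enumeration oracle for the dominant model
        t = make_table([("chr1", 100, 20, 10, 0, 30)])
        track = compute_index(t)
        assert track.markers.loc[0, "delta"] == pytest.approx(f2_expected_delta())

    def test_zero_depth_markers_excluded_and_counted(self):
        t = make_table(
            [("chr1", 100, 0, 0, 5, 5), ("chr1", 200, 5, 5, 5, 5)]
        )
        track = compute_index(t)
        assert len(track) == 1
        assert track.n_zero_depth_excluded == 1

    def test_index_bounds_on_random_tables(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(500):
            d = rng.integers(0, 60, size=4)
            rows.append(("chr1", 1000 + i, d[0], d[1], d[2], d[3]))
        track = compute_index(make_table(rows))
        m = track.markers
        assert ((m["index_papilla"] >= 0) & (m["index_papilla"] <= 1)).all()
        assert ((m["index_nonpapilla"] >= 0) & (m["index_nonpapilla"] <= 1)).all()
        assert ((m["delta"] >= -1) & (m["delta"] <= 1)).all()
        assert np.allclose(m["delta"], m["index_nonpapilla"] - m["index_papilla"])


class TestWindowTrack:
    def test_mean_of_single_marker(self):
        track = track_from_deltas([0.8], positions=[500])
        wt = window_track(track, 1000, 1000)
        w = wt.windows[wt.windows["n_markers"] > 0]
        assert w["mean_delta"].tolist() == [0.8]

    def test_mean_of_two_markers(self):
        track = track_from_deltas([0.4, 0.8], positions=[100, 200])
        wt = window_track(track, 1000, 1000)
        w = wt.windows[wt.windows["n_markers"] > 0].iloc[0]
        assert w["mean_delta"] == pytest.approx(0.6)
        assert w["n_markers"] == 2

    def test_all_zero_deltas_give_zero_means(self):
        track = track_from_deltas([0.0] * 10)
        wt = window_track(track, 2000, 1000)
        nz = wt.windows[wt.windows["n_markers"] > 0]
        assert (nz["mean_delta"] == 0.0).all()

    def test_empty_windows_flagged_not_averaged(self):
        track = track_from_deltas([0.5], positions=[100])
        wt = window_track(track, 1000, 1000, chrom_lengths={"chr1": 5000})
        empty = wt.windows[wt.windows["n_markers"] == 0]
        assert len(empty) >= 1
        assert empty["mean_delta"].isna().all()

    def test_invalid_geometry_rejected(self):
        track = track_from_deltas([0.5])
        with pytest.raises(ValueError):
            window_track(track, 0, 0)
        with pytest.raises(ValueError):
            window_track(track, 100, 200)  # step larger than window


def brute_force_intervals(wt, threshold, min_markers):
    """Oracle: enumerate qualifying windows, merge by transitive overlap."""
    w = wt.windows
    ok = w[
        (w["n_markers"] >= min_markers)
        & w["mean_delta"].notna()
        & (w["mean_delta"].abs() >= threshold)
    ]
    spans = []
    for chrom in sorted(ok["chrom"].unique()):
        sub = ok[ok["chrom"] == chrom]
        remaining = [(int(s), int(e)) for s, e in zip(sub["start"], sub["end"])]
        while remaining:
            cur = remaining.pop(0)
            changed = True
            while changed:
                changed = False
                for other in list(remaining):
                    if other[0] <= cur[1] + 1 and cur[0] <= other[1] + 1:
                        cur = (min(cur[0], other[0]), max(cur[1], other[1]))
                        remaining.remove(other)
                        changed = True
            spans.append((chrom, cur[0], cur[1]))
    return sorted(spans)


class TestCallIntervals:
    def test_no_window_above_threshold_gives_empty_list(self):
        track = track_from_deltas([0.1, 0.2, -0.3])
        wt = window_track(track, 1000, 1000)
        assert call_intervals(wt, 0.5, min_markers=1) == []

    def test_boundary_value_is_included(self):
        track = track_from_deltas([0.5], positions=[100])
        wt = window_track(track, 1000, 1000)
        ivs = call_intervals(wt, 0.5, min_markers=1)
        assert len(ivs) == 1

    def test_two_runs_split_by_gap(self):
        positions = [100, 200, 5100, 5200]
        track = track_from_deltas([0.8, 0.8, 0.7, 0.7], positions=positions)
        wt = window_track(track, 1000, 1000, chrom_lengths={"chr1": 6000})
        ivs = call_intervals(wt, 0.5, min_markers=1)
        assert len(ivs) == 2
        assert ivs[0].end < ivs[1].start

    def test_negative_deltas_called_by_absolute_value(self):
        track = track_from_deltas([-0.9, -0.8])
        wt = window_track(track, 5000, 5000)
        ivs = call_intervals(wt, 0.5, min_markers=2)
        assert len(ivs) == 1
        assert ivs[0].peak_abs_delta == pytest.approx(0.9)

    def test_min_marker_windows_never_called(self):
        track = track_from_deltas([0.9], positions=[100])
        wt = window_track(track, 1000, 1000)
        assert call_intervals(wt, 0.5, min_markers=5) == []

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for trial in range(40):
            n = int(rng.integers(1, 51))
            chroms = rng.choice(["chr1", "chr2"], size=n)
            rows = []
            for c in ("chr1", "chr2"):
                pos = np.sort(
                    rng.choice(np.arange(100, 20_000), size=(chroms == c).sum(),
                               replace=False)
                )
                for p in pos:
                    rows.append((c, int(p), float(rng.uniform(-1, 1))))
            track = IndexTrack(
                pd.DataFrame(
                    [
                        {
                            "chrom": c, "pos": p, "marker_class": "SNP",
                            "index_papilla": 0.0, "index_nonpapilla": d, "delta": d,
                        }
                        for c, p, d in rows
                    ]
                )
            )
            W = int(rng.choice([1000, 2000, 5000]))
            S = int(rng.choice([500, 1000]))
            if S > W:
                W, S = S, W
            wt = window_track(track, W, S, chrom_lengths={"chr1": 20000, "chr2": 20000})
            mk = int(rng.integers(1, 4))
            got = sorted(
                (iv.chrom, iv.start, iv.end)
                for iv in call_intervals(wt, 0.5, min_markers=mk)
            )
            assert got == brute_force_intervals(wt, 0.5, mk), f"trial {trial}"

    def test_peak_marker_inside_interval(self):
        track = track_from_deltas([0.6, 0.9, 0.7], positions=[100, 200, 300])
        wt = window_track(track, 1000, 1000)
        (iv,) = call_intervals(wt, 0.5, min_markers=1)
        assert iv.peak_pos == 200
        assert iv.peak_abs_delta == pytest.approx(0.9)
        assert iv.n_markers == 3


class TestSummaries:
    def test_single_high_marker(self):
        track = track_from_deltas([0.6], positions=[100], chrom="chr2")
        s = summarize_chromosomes(track, 0.5)
        assert s.counts == {"chr2": 1}
        assert s.argmax_chrom == "chr2"
        assert s.argmax_delta == pytest.approx(0.6)

    def test_all_zero_track_has_no_argmax(self):
        track = track_from_deltas([0.0, 0.0])
        s = summarize_chromosomes(track, 0.5)
        assert s.counts == {"chr1": 0}
        assert s.argmax_chrom is None

    def test_label_swap_negates_delta_and_preserves_intervals(self):
        rng = np.random.default_rng(3)
        rows = [
            ("chr1", 1000 + i * 100, int(d[0]), int(d[1]), int(d[2]), int(d[3]))
            for i, d in enumerate(rng.integers(1, 40, size=(60, 4)))
        ]
        t = make_table(rows)
        fwd = compute_index(t)
        swapped = make_table(
            [(c, p, np_, nn, pp, pn) for c, p, pp, pn, np_, nn in rows]
        )
        rev = compute_index(swapped)
        assert np.allclose(rev.markers["delta"], -fwd.markers["delta"])
        for thr in (0.3, 0.5):
            wf = window_track(fwd, 2000, 1000)
            wr = window_track(rev, 2000, 1000)
            a = [(i.chrom, i.start, i.end) for i in call_intervals(wf, thr, 1)]
            b = [(i.chrom, i.start, i.end) for i in call_intervals(wr, thr, 1)]
            assert a == b


class TestOutputs:
    def test_bed_export_is_zero_based_half_open(self, tmp_path):
        track = track_from_deltas([0.8], positions=[100])
        wt = window_track(track, 1000, 1000)
        ivs = call_intervals(wt, 0.5, min_markers=1)
        bed = tmp_path / "iv.bed"
        intervals_to_bed(ivs, bed)
        chrom, start, end = bed.read_text().split("\t")[:3]
        assert int(start) == ivs[0].start - 1
        assert int(end) == ivs[0].end

    def test_plot_smoke_and_determinism(self, tmp_path):
        track = track_from_deltas([0.1, 0.8, -0.2])
        wt = window_track(track, 1000, 1000)
        out1 = plot_tracks(track, wt, call_intervals(wt, 0.5, 1), tmp_path / "a.png")
        out2 = plot_tracks(track, wt, call_intervals(wt, 0.5, 1), tmp_path / "b.png")
        assert out1.exists()
        assert out1.read_bytes() == out2.read_bytes()

    def test_plot_renders_empty_track(self, tmp_path):
        track = IndexTrack(
            pd.DataFrame(
                columns=[
                    "chrom", "pos", "marker_class",
                    "index_papilla", "index_nonpapilla", "delta",
                ]
            )
        )
        out = plot_tracks(track, None, None, tmp_path / "empty.png")
        assert out.exists()

    def test_permutation_band_below_half_for_null_noise(self):
        rng = np.random.default_rng(9)
        track = track_from_deltas(rng.normal(0, 0.1, size=200).tolist())
        band = permutation_band(track, 5000, 5000, n_permutations=20, seed=4)
        assert 0 < band < 0.5
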
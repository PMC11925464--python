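"""Oscillogram cycles, arrests, packet segmentation, transit velocimetry."""

import collections

import numpy as np
import pytest

from valveflow import angiography as ang
from valveflow import pulsatility as pul
from valveflow import videogen as vg
from valveflow.io import ROISpec, VideoStack

from conftest import perivalve_roi


def sinusoid_trace(n_periods=10, fs=100.0, f=2.0, amp=50.0, gap=None):
    t = np.arange(0.0, n_periods / f, 1.0 / fs)
    v = amp * 0.5 * (1.0 - np.cos(2 * np.pi * f * t))
    if gap is not None:
        v[(t >= gap[0]) & (t <= gap[1])] = 0.0
    return ang.IntensityTrace(t, v)


class TestDetectCycles:
    def test_sinusoid_peak_count(self):
        feats = pul.detect_cycles(sinusoid_trace(10))
        assert feats.n_cycles == 10
        assert not feats.arrest_intervals
        assert feats.closure_ok_per_cycle.all()

    def test_flat_trace_warns_whole_span_arrest(self):
        trace = ang.IntensityTrace(np.arange(5.0), np.full(5, 3.0))
        with pytest.warns(UserWarning):
            feats = pul.detect_cycles(trace)
        assert feats.n_cycles == 0
        assert feats.arrest_intervals == [(0.0, 4.0)]

    def test_silent_gap_yields_one_arrest(self):
        # gap-scan oracle over the known peak grid: peaks at (k+0.5)/f;
        # a 3-period silence removes peaks inside it
        trace = sinusoid_trace(20, gap=(4.0, 5.5))
        feats = pul.detect_cycles(trace)
        assert len(feats.arrest_intervals) == 1
        a, b = feats.arrest_intervals[0]
        assert a == pytest.approx(4.25, abs=0.06)  # last peak 3.75 + period
        assert b == pytest.approx(5.75, abs=0.06)  # first peak after gap

    def test_baseline_is_quantile(self):
        trace = sinusoid_trace(10)
        feats = pul.detect_cycles(trace, baseline_quantile=0.5)
        assert feats.baseline == pytest.approx(np.quantile(trace.values, 0.5))

    def test_no_closure_when_trace_stays_high(self):
        t = np.arange(0.0, 5.0, 0.01)
        v = 100.0 + 30.0 * np.sin(2 * np.pi * 2.0 * t)  # never near baseline
        feats = pul.detect_cycles(ang.IntensityTrace(t, v),
                                  closure_fraction=0.1)
        # baseline is the 10% quantile of the sinusoid itself, so the trace
        # does return there; verify with an offset floor instead
        v2 = np.concatenate([np.zeros(100), v])
        t2 = np.arange(v2.size) * 0.01
        feats2 = pul.detect_cycles(ang.IntensityTrace(t2, v2),
                                   closure_fraction=0.1)
        assert not feats2.closure_ok_per_cycle.all()


class TestSegmentPacket:
    def test_uniform_disk(self):
        frame = np.zeros((40, 40))
        rr, cc = np.mgrid[0:40, 0:40]
        disk = (rr - 20) ** 2 + (cc - 20) ** 2 <= 100
        frame[disk] = 200.0
        seg = pul.segment_packet(frame, (20, 20), tolerance=10)
        assert seg.pixels.shape[0] == disk.sum()
        assert seg.mean_intensity == 200.0

    def test_zero_tolerance_exact_value_region(self):
        rng = np.random.default_rng(0)
        frame = rng.integers(0, 5, size=(20, 20)).astype(float)
        frame[5:8, 5:8] = 99.0
        seg = pul.segment_packet(frame, (6, 6), tolerance=0)
        assert {tuple(p) for p in seg.pixels} == {
            (r, c) for r in range(5, 8) for c in range(5, 8)}

    def test_matches_bfs_flood_fill_oracle(self):
        rng = np.random.default_rng(1)
        frame = rng.uniform(0, 255, size=(24, 24))
        seed, tol = (12, 12), 60.0

        def bfs(img, start, tolerance):
            base = img[start]
            seen = {start}
            queue = collections.deque([start])
            while queue:
                r, c = queue.popleft()
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if dr == dc == 0:
                            continue
                        p = (r + dr, c + dc)
                        if (0 <= p[0] < img.shape[0]
                                and 0 <= p[1] < img.shape[1]
                                and p not in seen
                                and abs(img[p] - base) <= tolerance):
                            seen.add(p)
                            queue.append(p)
            return seen

        seg = pul.segment_packet(frame, seed, tol)
        assert {tuple(p) for p in seg.pixels} == bfs(frame, seed, tol)

    def test_isolated_seed_single_pixel_warns(self):
        frame = np.full((10, 10), 7.0)
        frame[0, 0] = 200.0
        with pytest.warns(UserWarning, match="seed"):
            seg = pul.segment_packet(frame, (0, 0), tolerance=1)
        assert seg.pixels.shape[0] == 1

    def test_area_scaled_by_pixel_size(self):
        frame = np.zeros((10, 10))
        frame[2:4, 2:4] = 100.0
        seg = pul.segment_packet(frame, (2, 2), tolerance=5, pixel_size=5.0)
        assert seg.area == pytest.approx(4 * 25.0)


class TestPacketSeries:
    def test_five_identical_packets(self):
        frames = np.zeros((5, 20, 20), np.uint8)
        for k in range(5):
            frames[k, 8:12, 8:12] = 120
        stack = VideoStack(frames, 0.01, 1.0)
        seeds = [(k, 10, 10) for k in range(5)]
        segs, summary = pul.packet_intensity_series(stack, seeds, tolerance=10)
        assert len(segs) == 5
        assert summary == pytest.approx(120.0)

    def test_narrow_valve_reduces_packet_intensity(self):
        summaries = {}
        for frac in (1.0, 0.5):
            p = vg.SceneParams(duration=4.0, valve_opening_fraction=frac,
                               noise_sd=2.0, seed=21)
            stack, truth = vg.generate_heart_video(p)
            seeds = []
            for packet in truth.packet_centroids[:5]:
                mid = packet[len(packet) // 2]
                seeds.append((int(mid[0]), int(round(mid[1])),
                              int(round(mid[2]))))
            _, summary = pul.packet_intensity_series(stack, seeds,
                                                     tolerance=40)
            summaries[frac] = summary
        assert summaries[0.5] < summaries[1.0]

    def test_arrested_video_empty_series(self):
        stack = VideoStack(np.zeros((5, 10, 10), np.uint8), 0.01, 1.0)
        with pytest.warns(UserWarning):
            segs, summary = pul.packet_intensity_series(
                stack, [(2, 5, 5)], tolerance=5)
        assert np.isnan(summary)


class TestEstimateVelocity:
    def test_delayed_copy_gives_distance_over_delay(self):
        trace = sinusoid_trace(8, fs=100.0, f=2.0)
        shifted = np.concatenate([np.zeros(10), trace.values[:-10]])  # 0.1 s
        delayed = ang.IntensityTrace(trace.times, shifted)
        est = pul.estimate_velocity(trace, delayed, distance=0.5, n_cycles=3)
        assert est.velocity == pytest.approx(5.0)
        assert np.allclose(est.transit_times, 0.1)

    def test_one_frame_delay(self):
        trace = sinusoid_trace(8, fs=100.0, f=2.0)
        delayed = ang.IntensityTrace(trace.times, np.roll(trace.values, 1))
        est = pul.estimate_velocity(trace, delayed, distance=0.05, n_cycles=3)
        assert est.velocity == pytest.approx(5.0)

    def test_reverse_flow_rejected(self):
        trace = sinusoid_trace(8)
        advanced = np.concatenate([trace.values[10:], np.zeros(10)])
        early = ang.IntensityTrace(trace.times, advanced)
        with pytest.raises(ValueError, match="direction"):
            pul.estimate_velocity(trace, early, distance=0.5, n_cycles=3)

    def test_recovers_generator_velocity_within_5pct(self):
        p = vg.SceneParams(duration=6.0, packet_velocity=5.2, beat_rate=1.0,
                           noise_sd=5.0, image_size=(48, 512), seed=11)
        stack, _ = vg.generate_heart_video(p)
        sub = ang.subtract_background(stack)
        c0, c1 = 100, 420
        tp = ang.extract_trace(sub, ROISpec("post", p.tube_axis_row - 7,
                                            c0 - 7, 15, 15))
        ta = ang.extract_trace(sub, ROISpec("ant", p.tube_axis_row - 7,
                                            c1 - 7, 15, 15))
        dist_mm = (c1 - c0) * p.pixel_size / 1000.0
        est = pul.estimate_velocity(tp, ta, dist_mm, n_cycles=3)
        assert est.velocity == pytest.approx(5.2, rel=0.05)

    def test_too_few_matches_lists_orphans(self):
        trace = sinusoid_trace(3)
        flat = ang.IntensityTrace(trace.times, np.zeros_like(trace.values))
        with pytest.raises(ValueError):
            pul.estimate_velocity(trace, flat, distance=0.5, n_cycles=3)


def test_cycle_count_matches_generator_beats(short_heart_scene):
    params, stack, truth = short_heart_scene
    trace = ang.extract_trace(ang.subtract_background(stack),
                              perivalve_roi(params))
    feats = pul.detect_cycles(trace)
    assert abs(feats.n_cycles - len(truth.beat_times)) <= 1
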
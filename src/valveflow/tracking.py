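"""Spot detection, track linking and track metrics.

Serves two assays: injected fluorescent microparticles streaming through
the heart tube (with speed gating to the valve region delimited by the
cardiomyocyte reporter signal), and crawling-larva centroid tracks with the
standard endurance metrics (total distance, displacement, confinement
ratio, mean and peak speed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.ndimage import gaussian_laplace
from skimage.feature import peak_local_max

from .io import ROISpec

__all__ = [
    "Track",
    "TrackMetrics",
    "RegionGate",
    "detect_spots",
    "link_tracks",
    "compute_track_metrics",
    "gate_speeds_by_region",
]


@dataclass
class Track:
    """Time-stamped 2-D point sequence: columns (t_s, row, col)."""

    points: np.ndarray
    id: int = 0

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        t = self.points[:, 0]
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError(f"track {self.id}: times must be strictly increasing")

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def coords(self) -> np.ndarray:
        return self.points[:, 1:3]


@dataclass
class TrackMetrics:
    total_distance: float  # µm
    displacement: float  # µm
    confinement_ratio: float
    mean_speed: float  # µm/s
    peak_speed: float  # µm/s


@dataclass
class RegionGate:
    """Valve region used for speed gating: a mask or an ROISpec."""

    region: Union[np.ndarray, ROISpec]

    def contains(self, row: float, col: float) -> bool:
        if isinstance(self.region, ROISpec):
            return (self.region.row0 <= row < self.region.row0 + self.region.height
                    and self.region.col0 <= col < self.region.col0 + self.region.width)
        mask = np.asarray(self.region)
        r, c = int(round(row)), int(round(col))
        if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]):
            return False
        return bool(mask[r, c])

    def __post_init__(self):
        if isinstance(self.region, np.ndarray) and not self.region.any():
            raise ValueError("gating region is empty")


def detect_spots(
    frame: np.ndarray,
    spot_sigma: float = 1.5,
    threshold: float = 20.0,
) -> np.ndarray:
    """Detect bright Gaussian spots in one frame, sub-pixel refined.

    Laplacian-of-Gaussian response maxima above ``threshold`` (on the
    scale-normalised negated LoG, so the response at a matched spot roughly
    equals half its amplitude) are refined per axis by a quadratic fit to
    the response.  Returns an ``(n, 2)`` float array of (row, col).
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("detect_spots expects a single-channel frame")
    resp = -gaussian_laplace(frame, spot_sigma) * spot_sigma ** 2
    peaks = peak_local_max(resp, min_distance=max(int(spot_sigma), 1),
                           threshold_abs=threshold, exclude_border=False)
    out = []
    for (r, c) in peaks:
        rr, cc = float(r), float(c)
        if 0 < r < resp.shape[0] - 1:
            y0, y1, y2 = resp[r - 1, c], resp[r, c], resp[r + 1, c]
            den = y0 - 2 * y1 + y2
            if den != 0:
                rr += np.clip(0.5 * (y0 - y2) / den, -0.5, 0.5)
        if 0 < c < resp.shape[1] - 1:
            y0, y1, y2 = resp[r, c - 1], resp[r, c], resp[r, c + 1]
            den = y0 - 2 * y1 + y2
            if den != 0:
                cc += np.clip(0.5 * (y0 - y2) / den, -0.5, 0.5)
        out.append((rr, cc))
    return np.asarray(out, dtype=float).reshape(-1, 2)


def link_tracks(
    detections: Sequence[np.ndarray],
    max_disp: float,
    max_gap: int = 0,
    frame_interval: float = 1.0,
) -> List[Track]:
    """Link per-frame detections into tracks.

    Frame-to-frame greedy mutual-nearest-neighbour assignment; links longer
    than ``max_disp`` pixels per frame step are forbidden (scaled by the
    number of skipped frames when bridging gaps of up to ``max_gap``
    frames).  Unmatched detections seed new tracks.
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be > 0")
    active: List[dict] = []  # {"points": [(k, r, c)...], "last": k}
    finished: List[dict] = []
    for k, dets in enumerate(detections):
        dets = np.asarray(dets, dtype=float).reshape(-1, 2)
        # retire tracks whose gap can no longer be bridged
        still = []
        for tr in active:
            if k - tr["last"] > max_gap + 1:
                finished.append(tr)
            else:
                still.append(tr)
        active = still
        claimed = set()
        if active and len(dets):
            last_pts = np.asarray([tr["points"][-1][1:] for tr in active])
            # allow proportionally larger steps across bridged gaps
            steps = np.asarray([k - tr["last"] for tr in active], dtype=float)
            d = np.linalg.norm(last_pts[:, None, :] - dets[None, :, :], axis=-1)
            pairs = [
                (d[i, j] / steps[i], last_pts[i, 0], last_pts[i, 1], i, j)
                for i in range(len(active))
                for j in range(len(dets))
                if d[i, j] <= max_disp * steps[i]
            ]
            pairs.sort()
            used_i = set()
            for (_, _, _, i, j) in pairs:
                if i in used_i or j in claimed:
                    continue
                used_i.add(i)
                claimed.add(j)
                active[i]["points"].append((k, dets[j, 0], dets[j, 1]))
                active[i]["last"] = k
        for j in range(len(dets)):
            if j not in claimed:
                active.append({"points": [(k, dets[j, 0], dets[j, 1])],
                               "last": k})
    finished.extend(active)
    finished.sort(key=lambda tr: (tr["points"][0][0], tr["points"][0][1],
                                  tr["points"][0][2]))
    tracks = []
    for tid, tr in enumerate(finished):
        pts = np.asarray(tr["points"], dtype=float)
        pts[:, 0] *= frame_interval
        tracks.append(Track(pts, id=tid))
    return tracks


def compute_track_metrics(track: Track, pixel_size: float) -> TrackMetrics:
    """Standard track metrics in µm / µm/s.

    confinement_ratio = displacement / total_distance ∈ [0, 1]; equal to 1
    only for collinear monotone motion.  A zero-length path (stationary
    object) has ratio 1 by convention.
    """
    if len(track) < 2:
        raise ValueError("track metrics need at least 2 points")
    t = track.times
    if np.any(np.diff(t) == 0):
        raise ValueError("duplicate timestamps in track")
    xy = track.coords * pixel_size
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    total = float(steps.sum())
    disp = float(np.linalg.norm(xy[-1] - xy[0]))
    ratio = disp / total if total > 0 else 1.0
    speeds = steps / np.diff(t)
    return TrackMetrics(
        total_distance=total,
        displacement=disp,
        confinement_ratio=min(ratio, 1.0),
        mean_speed=total / float(t[-1] - t[0]),
        peak_speed=float(speeds.max()),
    )


def gate_speeds_by_region(
    tracks: Sequence[Track],
    region: RegionGate,
    pixel_size: float,
) -> Tuple[dict, int]:
    """Per-track peak step speed inside the valve region.

    A step counts as inside when its midpoint lies in the region.  Returns
    ``(peaks, n_excluded)`` where ``peaks`` maps track id -> max in-region
    step speed (µm/s) and ``n_excluded`` counts tracks that never enter the
    region.
    """
    peaks = {}
    excluded = 0
    for tr in tracks:
        if len(tr) < 2:
            excluded += 1
            continue
        t = tr.times
        xy = tr.coords
        mid = 0.5 * (xy[:-1] + xy[1:])
        inside = np.asarray([region.contains(r, c) for (r, c) in mid])
        if not inside.any():
            excluded += 1
            continue
        steps = np.linalg.norm(np.diff(xy, axis=0), axis=1) * pixel_size
        speeds = steps / np.diff(t)
        peaks[tr.id] = float(speeds[inside].max())
    return peaks, excluded
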
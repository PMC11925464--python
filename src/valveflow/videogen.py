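"""Synthetic assay videos with known ground truth.

Every quantitative readout in this package was designed against live
recordings that cannot be redistributed, so each assay has a generator here
that renders the same scene geometry with all true parameters recorded:

* :func:`generate_heart_video` — dorsal view of the prepupal heart tube after
  posterior dye injection.  Hemolymph is not transported as a continuous
  current but as one discrete dye packet per heartbeat; packets are emitted at
  the intracardiac valve, advected anteriorly (increasing column index) and
  deposited in an anterior accumulation zone, while the valve occluder opens
  and closes with a raised-cosine waveform.
* :func:`generate_particle_video` — two-channel fluorescence scene of
  injected microparticles streaming past the valve constriction, with speeds
  obeying kinematic continuity (speed × local gap width = const).
* :func:`generate_crawl_sequence` — binary silhouette of a crawling larva
  (a capsule, optionally bent) following a waypoint path.
* :func:`generate_fiber_texture` — oriented sinusoidal stripe texture for
  the Fourier directionality analysis.

Conventions (shared with the whole package): 0-based ``(row, col)`` pixel
coordinates, posterior → anterior along increasing column, 8-bit intensities,
frame ``k`` at time ``k / frame_rate``.  All randomness flows from
``SceneParams.seed``; identical parameters give bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .io import VideoStack

__all__ = [
    "SceneParams",
    "GroundTruth",
    "generate_heart_video",
    "generate_valve_label_video",
    "generate_particle_video",
    "generate_crawl_sequence",
    "generate_fiber_texture",
]


@dataclass
class SceneParams:
    """Scene description for the synthetic heart-tube assays.

    Parameters
    ----------
    frame_rate : float
        Acquisition rate in frames/s.  Dye angiography runs at ~100 fps,
        particle velocimetry at 200 fps.
    duration : float
        Recording length in seconds (dye angiography: 30 s).
    image_size : (int, int)
        Frame size ``(rows, cols)`` in pixels.
    pixel_size : float
        µm per pixel.  Calibration is always explicit: the assays' optics
        are not standardised, so there is no meaningful default to inherit.
    tube_axis_row : int
        Pixel row of the heart-tube centreline.
    tube_width : float
        Luminal width of the tube in µm.
    beat_rate : float
        Heartbeats per second.
    packet_velocity : float
        Anterior advection speed of dye packets / upstream particle speed,
        mm/s (healthy larvae: ~5.2 mm/s).
    valve_opening_fraction : float
        Peak luminal opening as a fraction of ``tube_width``; 1 emulates
        wildtype valves, < 1 emulates malformed valves.  Dye-packet amplitude
        scales with this fraction (a narrower opening lets less hemolymph
        through per beat).
    valve_rest_gap_fraction : float
        Residual gap fraction when the valve is "closed".  0 is the normal
        sealed diastolic state; > 0 emulates valves unable to seal the lumen.
    valve_position_col : int
        Pixel column of the valve.
    arrest_intervals : list of (float, float)
        Cardiac-arrest windows in seconds; no beats occur inside them.
    noise_sd : float
        Additive Gaussian pixel noise, 8-bit intensity units.
    background_drift_per_s : float
        Linear whole-frame intensity drift (intensity/s) emulating the
        continuous darkening of the cuticle during a recording.
    seed : int
        Seed for all stochastic rendering.
    packet_sigma_px : float
        Gaussian radius of a rendered dye packet, pixels.
    """

    frame_rate: float = 100.0
    duration: float = 30.0
    image_size: Tuple[int, int] = (48, 384)
    pixel_size: float = 5.0
    tube_axis_row: int = 24
    tube_width: float = 100.0
    beat_rate: float = 2.0
    packet_velocity: float = 5.2
    valve_opening_fraction: float = 1.0
    valve_rest_gap_fraction: float = 0.0
    valve_position_col: int = 60
    arrest_intervals: List[Tuple[float, float]] = field(default_factory=list)
    noise_sd: float = 5.0
    background_drift_per_s: float = 0.5
    seed: int = 0
    packet_sigma_px: float = 3.0

    def __post_init__(self):
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if not 0.0 <= self.valve_opening_fraction <= 1.0:
            raise ValueError("valve_opening_fraction must be in [0, 1]")
        if not 0.0 <= self.valve_rest_gap_fraction <= self.valve_opening_fraction:
            raise ValueError(
                "valve_rest_gap_fraction must be in [0, valve_opening_fraction]"
            )
        if self.packet_velocity < 0:
            raise ValueError("packet_velocity must be >= 0")
        if self.beat_rate <= 0:
            raise ValueError("beat_rate must be > 0")
        for (a, b) in self.arrest_intervals:
            if not (0.0 <= a < b <= self.duration):
                raise ValueError(
                    f"arrest interval ({a}, {b}) outside [0, {self.duration}]"
                )

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))

    @property
    def frame_interval(self) -> float:
        return 1.0 / self.frame_rate

    @property
    def tube_halfwidth_px(self) -> float:
        return 0.5 * self.tube_width / self.pixel_size

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def in_arrest(self, t: float) -> bool:
        return any(a <= t <= b for (a, b) in self.arrest_intervals)


@dataclass
class GroundTruth:
    """True scene parameters paired with a generated video.

    ``packet_centroids`` holds one ``(n_i, 3)`` array per dye packet with
    columns ``(frame, row, col)``; ``particle_tracks`` holds one
    ``(n_i, 4)`` array per particle with columns ``(frame, row, col,
    speed_um_per_s)``; ``larva_shape_series`` is ``(T, 6)`` with columns
    ``(centroid_row, centroid_col, area_um2, major_um, minor_um,
    orientation_rad)``.
    """

    beat_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    arrest_intervals: list = field(default_factory=list)
    valve_gap: np.ndarray = field(default_factory=lambda: np.empty(0))
    packet_centroids: list = field(default_factory=list)
    particle_tracks: list = field(default_factory=list)
    larva_shape_series: Optional[np.ndarray] = None

    def to_jsonable(self) -> dict:
        return {
            "beat_times": np.asarray(self.beat_times).tolist(),
            "arrest_intervals": [list(map(float, ab)) for ab in self.arrest_intervals],
            "valve_gap": np.asarray(self.valve_gap).tolist(),
            "packet_centroids": [np.asarray(p).tolist() for p in self.packet_centroids],
            "particle_tracks": [np.asarray(p).tolist() for p in self.particle_tracks],
            "larva_shape_series": (
                None
                if self.larva_shape_series is None
                else np.asarray(self.larva_shape_series).tolist()
            ),
        }


# ---------------------------------------------------------------------------
# shared rendering helpers

#: peak rendered amplitude of one dye packet at full valve opening (8-bit).
PACKET_AMPLITUDE = 150.0
#: per-pixel intensity a single full-opening packet adds to the anterior
#: accumulation zone.  60 beats x 3.0 stays below 8-bit saturation on top of
#: the rendered background, keeping the accumulation readout linear in the
#: number and amplitude of arriving packets.
ACCUMULATION_INCREMENT = 3.0
BACKGROUND_LEVEL = 20.0
VALVE_LOBE_INTENSITY = 80.0


def _beat_times(params: SceneParams) -> np.ndarray:
    """Beats at k / beat_rate, k >= 0, skipping arrest intervals."""
    t = np.arange(0.0, params.duration, 1.0 / params.beat_rate)
    keep = [tb for tb in t if not params.in_arrest(tb)]
    return np.asarray(keep)


def _valve_gap_um(params: SceneParams, times: np.ndarray) -> np.ndarray:
    """Raised-cosine luminal gap, closed to rest level during arrests."""
    rest = params.valve_rest_gap_fraction
    swing = params.valve_opening_fraction - rest
    phase = 0.5 * (1.0 - np.cos(2.0 * np.pi * params.beat_rate * times))
    frac = rest + swing * phase
    for (a, b) in params.arrest_intervals:
        frac[(times >= a) & (times <= b)] = rest
    return frac * params.tube_width


def _add_gaussian_blob(frame: np.ndarray, row: float, col: float,
                       amplitude: float, sigma: float):
    """Add a 2-D Gaussian into ``frame`` in-place, windowed to ±4σ."""
    h, w = frame.shape
    r0 = max(int(np.floor(row - 4 * sigma)), 0)
    r1 = min(int(np.ceil(row + 4 * sigma)) + 1, h)
    c0 = max(int(np.floor(col - 4 * sigma)), 0)
    c1 = min(int(np.ceil(col + 4 * sigma)) + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    rr = np.arange(r0, r1)[:, None] - row
    cc = np.arange(c0, c1)[None, :] - col
    frame[r0:r1, c0:c1] += amplitude * np.exp(-(rr ** 2 + cc ** 2) / (2 * sigma ** 2))


def _render_valve_lobes(frame: np.ndarray, params: SceneParams, gap_um: float,
                        intensity: float = VALVE_LOBE_INTENSITY):
    """Two opposing occluder lobes separated by the current luminal gap.

    The gap is rounded to a whole number of empty pixel rows, so a fully
    closed valve renders as touching (8-connected) lobes and the rendered
    gap is exactly ``round(gap_um / pixel_size)`` rows.
    """
    half_w = 3  # valve half-width along the tube, px
    lobe_body = 4  # rows each lobe extends beyond the lumen (cell body)
    c0 = max(params.valve_position_col - half_w, 0)
    c1 = min(params.valve_position_col + half_w + 1, frame.shape[1])
    hw = params.tube_halfwidth_px
    n_gap = int(round(gap_um / params.pixel_size))
    r_top0 = int(round(params.tube_axis_row - hw)) - lobe_body
    r_top1 = params.tube_axis_row - (n_gap + 1) // 2
    r_bot0 = r_top1 + n_gap
    r_bot1 = int(round(params.tube_axis_row + hw)) + 1 + lobe_body
    if r_top1 > r_top0:
        frame[max(r_top0, 0):max(r_top1, 0), c0:c1] = intensity
    if r_bot1 > r_bot0:
        frame[max(r_bot0, 0):max(r_bot1, 0), c0:c1] = intensity


def _finalize_frame(frame: np.ndarray, rng, noise_sd: float) -> np.ndarray:
    if noise_sd > 0:
        frame = frame + rng.normal(0.0, noise_sd, size=frame.shape)
    return np.clip(np.floor(frame + 0.5), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# dye angiography scene


def generate_heart_video(params: SceneParams) -> Tuple[VideoStack, GroundTruth]:
    """Render a dye-angiography recording of the heart tube.

    One dye packet is emitted at the valve per heartbeat (none during
    arrests), advected anteriorly at ``packet_velocity`` and, on reaching the
    anterior margin, deposited into a static accumulation zone whose
    intensity therefore grows with every arriving packet — the readout the
    dye-accumulation analysis quantifies.  Packet amplitude scales with
    ``valve_opening_fraction``: a malformed, narrow-opening valve passes
    less dye per beat.

    Returns the 8-bit single-channel stack and the paired ground truth
    (beat times, per-frame valve gap, per-packet centroid trajectories).
    """
    n_frames = params.n_frames
    h, w = params.image_size
    times = params.times()
    rng = np.random.default_rng(params.seed)

    beat_times = _beat_times(params)
    gap_um = _valve_gap_um(params, times)

    v_px_per_s = params.packet_velocity * 1000.0 / params.pixel_size
    emit_col = float(params.valve_position_col)
    # packets freeze (accumulate) once they reach the anterior margin
    accumulate_col = w - 1 - int(np.ceil(4 * params.packet_sigma_px))
    acc_c0 = max(accumulate_col - 10, 0)

    amp = PACKET_AMPLITUDE * params.valve_opening_fraction
    acc_inc = ACCUMULATION_INCREMENT * params.valve_opening_fraction

    hw_px = params.tube_halfwidth_px
    tube_r0 = max(int(round(params.tube_axis_row - hw_px)), 0)
    tube_r1 = min(int(round(params.tube_axis_row + hw_px)) + 1, h)

    frames = np.empty((n_frames, h, w), dtype=np.uint8)
    centroids: List[List[Tuple[int, float, float]]] = [[] for _ in beat_times]
    n_arrived = np.zeros(n_frames)

    # per-packet column at each frame (vectorised over packets per frame)
    for k in range(n_frames):
        t = times[k]
        frame = np.full((h, w), BACKGROUND_LEVEL, dtype=np.float64)
        frame[tube_r0:tube_r1, :] += 10.0  # tube lumen slightly brighter
        _render_valve_lobes(frame, params, gap_um[k])

        arrived = 0
        for b, tb in enumerate(beat_times):
            if t < tb:
                continue
            col = emit_col + v_px_per_s * (t - tb)
            if col >= accumulate_col:
                arrived += 1
                continue
            _add_gaussian_blob(frame, params.tube_axis_row, col, amp,
                               params.packet_sigma_px)
            centroids[b].append((k, float(params.tube_axis_row), col))
        n_arrived[k] = arrived
        # anterior accumulation zone: uniform deposit per arrived packet
        frame[tube_r0:tube_r1, acc_c0:w] += acc_inc * arrived
        # cuticle darkening: global linear drift over the whole scene
        frame += params.background_drift_per_s * t
        frames[k] = _finalize_frame(frame, rng, params.noise_sd)

    truth = GroundTruth(
        beat_times=beat_times,
        arrest_intervals=list(params.arrest_intervals),
        valve_gap=gap_um,
        packet_centroids=[np.asarray(c).reshape(-1, 3) for c in centroids],
    )
    stack = VideoStack(frames, params.frame_interval, params.pixel_size,
                       ("brightfield",))
    return stack, truth


def generate_valve_label_video(params: SceneParams) -> Tuple[VideoStack, GroundTruth]:
    """Render the valve-label channel of a semi-intact preparation.

    The two labelled valve cells appear as bright opposing lobes on a dark
    background; their separation follows the same raised-cosine gap waveform
    as :func:`generate_heart_video` (recorded per frame in the ground
    truth).  This is the input the valve-kinematics analysis consumes.
    """
    n_frames = params.n_frames
    h, w = params.image_size
    times = params.times()
    rng = np.random.default_rng(params.seed)
    gap_um = _valve_gap_um(params, times)
    frames = np.empty((n_frames, h, w), dtype=np.uint8)
    for k in range(n_frames):
        frame = np.zeros((h, w), dtype=np.float64)
        _render_valve_lobes(frame, params, gap_um[k], intensity=200.0)
        frames[k] = _finalize_frame(frame, rng, params.noise_sd)
    truth = GroundTruth(
        beat_times=_beat_times(params),
        arrest_intervals=list(params.arrest_intervals),
        valve_gap=gap_um,
    )
    stack = VideoStack(frames, params.frame_interval, params.pixel_size,
                       ("valve_label",))
    return stack, truth


# ---------------------------------------------------------------------------
# particle velocimetry scene


def _local_gap_profile(params: SceneParams, cols: np.ndarray,
                       sigma_px: float = 8.0) -> np.ndarray:
    """Luminal width (µm) along the tube: narrowed near the valve.

    A Gaussian bump centred on the valve narrows the lumen from
    ``tube_width`` (far field) down to ``valve_opening_fraction *
    tube_width`` at the valve column.
    """
    bump = np.exp(-((cols - params.valve_position_col) ** 2) / (2 * sigma_px ** 2))
    return params.tube_width * (1.0 - (1.0 - params.valve_opening_fraction) * bump)


def particle_capacity(params: SceneParams, spot_sigma_px: float = 1.5) -> int:
    """Collision-free particle capacity: distinct rows spaced >= 4 spot σ."""
    inner = 2 * (params.tube_halfwidth_px - 2.0)
    spacing = max(int(np.ceil(4 * spot_sigma_px)), 1)
    return max(int(inner) // spacing, 0)


def generate_particle_video(
    params: SceneParams,
    n_particles: int,
    spot_sigma_px: float = 1.5,
    position_noise_px: float = 0.0,
) -> Tuple[VideoStack, GroundTruth]:
    """Render injected fluorescent microparticles streaming past the valve.

    Channel 0 carries the particles as Gaussian spots; channel 1 carries a
    static label of the valve region (the reporter-signal stand-in used to
    delimit the region for speed gating).  Particle speed follows kinematic
    continuity through the constriction: ``speed(col) x local_gap(col)`` is
    constant along the tube, so speed peaks at the valve where the lumen is
    narrowest.  True per-point speeds (µm/s) are recorded in the ground
    truth; ``position_noise_px`` adds positional jitter to the *rendered*
    spots only, leaving the recorded truth exact.
    """
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    cap = particle_capacity(params, spot_sigma_px)
    if n_particles > cap:
        raise ValueError(
            f"n_particles={n_particles} exceeds the collision-free capacity "
            f"of {cap} for this tube geometry (rows spaced 4 spot sigma)"
        )
    n_frames = params.n_frames
    h, w = params.image_size
    rng = np.random.default_rng(params.seed)
    dt = params.frame_interval

    v0_um = params.packet_velocity * 1000.0  # upstream speed, µm/s

    def speed_um(col):
        gap = _local_gap_profile(params, np.asarray(col, dtype=float))
        return v0_um * params.tube_width / gap

    # non-crossing: one lane (row) per particle, evenly spaced in the lumen
    hw_px = params.tube_halfwidth_px
    lane_lo = params.tube_axis_row - hw_px + 2.0
    lane_hi = params.tube_axis_row + hw_px - 2.0
    rows = np.linspace(lane_lo, lane_hi, n_particles + 2)[1:-1]
    rows = rows + rng.uniform(-0.3, 0.3, size=n_particles)
    cols = rng.uniform(2.0, w * 0.5, size=n_particles)

    margin = 4 * spot_sigma_px
    tracks: List[List[Tuple[int, float, float, float]]] = [
        [] for _ in range(n_particles)
    ]
    track_of = list(range(n_particles))  # current track id per lane

    frames = np.empty((n_frames, 2, h, w), dtype=np.uint8)

    # valve-region label: columns where the lumen is meaningfully narrowed
    tube_r0 = max(int(round(params.tube_axis_row - hw_px)), 0)
    tube_r1 = min(int(round(params.tube_axis_row + hw_px)) + 1, h)
    gap_cols = _local_gap_profile(params, np.arange(w, dtype=float))
    if params.valve_opening_fraction < 1.0:
        narrowed = gap_cols <= params.tube_width * (
            1.0 - 0.5 * (1.0 - params.valve_opening_fraction)
        )
    else:
        narrowed = np.abs(np.arange(w) - params.valve_position_col) <= 9
    label = np.zeros((h, w), dtype=np.uint8)
    label[tube_r0:tube_r1, narrowed] = 255

    n_substeps = 4  # Euler substeps per frame for the advection integral
    for k in range(n_frames):
        ch0 = np.full((h, w), 10.0)
        for i in range(n_particles):
            c = cols[i]
            v = float(speed_um(c))
            tracks[track_of[i]].append((k, float(rows[i]), float(c), v))
            jr = rng.normal(0.0, position_noise_px) if position_noise_px else 0.0
            jc = rng.normal(0.0, position_noise_px) if position_noise_px else 0.0
            _add_gaussian_blob(ch0, rows[i] + jr, c + jc, 200.0, spot_sigma_px)
            # advect to next frame
            cc = c
            for _ in range(n_substeps):
                cc += float(speed_um(cc)) / params.pixel_size * dt / n_substeps
            if cc > w - 1 - margin:  # left the field: respawn as a new track
                cc = margin + rng.uniform(0.0, 2.0)
                tracks.append([])
                track_of[i] = len(tracks) - 1
            cols[i] = cc
        frames[k, 0] = _finalize_frame(ch0, rng, params.noise_sd)
        frames[k, 1] = label

    truth = GroundTruth(
        beat_times=np.empty(0),
        arrest_intervals=[],
        valve_gap=np.full(n_frames, params.valve_opening_fraction * params.tube_width),
        particle_tracks=[np.asarray(tr).reshape(-1, 4) for tr in tracks if tr],
    )
    stack = VideoStack(frames, dt, params.pixel_size, ("particles", "valve_label"))
    return stack, truth


# ---------------------------------------------------------------------------
# larval crawling scene


def _capsule_mask(shape, center_row, center_col, heading, bend,
                  length_px, width_px):
    """Rasterise a capsule (two joined segments + circular caps), centred.

    The spine is two straight segments of length ``length_px/2`` meeting at
    the bend point with exterior angle ``bend``; the silhouette is every
    pixel within ``width_px/2`` of the spine.  The capsule is translated so
    its *pixel centroid* (not its bend point) sits at the requested centre,
    which keeps the recorded centroid truth accurate to rasterisation error.
    """
    half = length_px / 2.0
    r = width_px / 2.0

    def segments(origin_r, origin_c):
        # spine in image coords; heading/bend measured on (x=col, y=-row)
        d0 = np.array([-np.sin(heading), np.cos(heading)])  # (drow, dcol)
        a0 = np.array([origin_r, origin_c])
        a1 = a0 + d0 * half  # front half along heading
        phi = heading + bend
        d1 = np.array([-np.sin(phi), np.cos(phi)])
        a2 = a0 - d1 * half  # rear half
        return (a0, a1), (a0, a2)

    def render(origin_r, origin_c):
        (p0, p1), (q0, q1) = segments(origin_r, origin_c)
        rr, cc = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
        pts = np.stack([rr, cc], axis=-1)

        def dist_seg(a, b):
            ab = b - a
            denom = float(ab @ ab)
            if denom == 0:
                return np.linalg.norm(pts - a, axis=-1)
            tproj = np.clip(((pts - a) @ ab) / denom, 0.0, 1.0)
            proj = a + tproj[..., None] * ab
            return np.linalg.norm(pts - proj, axis=-1)

        d = np.minimum(dist_seg(p0, p1), dist_seg(q0, q1))
        return d <= r

    mask = render(center_row, center_col)
    if not mask.any():
        raise ValueError("capsule silhouette fell entirely outside the frame")
    # recentre on the pixel centroid and render once more
    rr, cc = np.nonzero(mask)
    off_r, off_c = rr.mean() - center_row, cc.mean() - center_col
    return render(center_row - off_r, center_col - off_c)


def _mask_shape_moments(mask: np.ndarray, pixel_size: float):
    """(centroid_row, centroid_col, area_um2, major_um, minor_um, theta)."""
    rr, cc = np.nonzero(mask)
    n = rr.size
    r0, c0 = rr.mean(), cc.mean()
    mu_rr = ((rr - r0) ** 2).mean()
    mu_cc = ((cc - c0) ** 2).mean()
    mu_rc = ((rr - r0) * (cc - c0)).mean()
    common = np.sqrt((mu_rr - mu_cc) ** 2 + 4 * mu_rc ** 2)
    l1 = 0.5 * (mu_rr + mu_cc + common)
    l2 = 0.5 * (mu_rr + mu_cc - common)
    major = 4.0 * np.sqrt(max(l1, 0.0)) * pixel_size
    minor = 4.0 * np.sqrt(max(l2, 0.0)) * pixel_size
    theta = 0.5 * np.arctan2(2 * mu_rc, mu_cc - mu_rr)  # vs +col axis, y down
    return (r0, c0, n * pixel_size ** 2, major, minor, theta)


def generate_crawl_sequence(
    params: SceneParams,
    path_spec: Sequence[Tuple[float, float]],
    bend_schedule: Optional[np.ndarray] = None,
    length_um: float = 3000.0,
    width_um: float = 600.0,
) -> Tuple[VideoStack, GroundTruth]:
    """Render a crawling-larva silhouette following a waypoint path.

    ``path_spec`` lists centroid waypoints as ``(row, col)`` pixels, linearly
    interpolated over the recording; ``bend_schedule`` gives a per-frame
    body-bend angle in radians (0 = straight, elongated larva; larger bends
    give a rounder outline).  The heading follows the local path tangent.
    Frames are binary masks (255/0).  A silhouette touching the frame border
    raises — mirroring the discard rule for larvae reaching the dish edge.
    """
    waypoints = np.asarray(path_spec, dtype=float)
    if waypoints.ndim != 2 or waypoints.shape[0] < 1 or waypoints.shape[1] != 2:
        raise ValueError("path_spec must be a list of (row, col) waypoints")
    h, w = params.image_size
    if (waypoints[:, 0].min() < 0 or waypoints[:, 0].max() >= h
            or waypoints[:, 1].min() < 0 or waypoints[:, 1].max() >= w):
        raise ValueError("waypoints must lie inside image bounds")
    n_frames = params.n_frames
    if bend_schedule is None:
        bend_schedule = np.zeros(n_frames)
    bend_schedule = np.asarray(bend_schedule, dtype=float)
    if bend_schedule.size != n_frames:
        raise ValueError(
            f"bend_schedule has {bend_schedule.size} entries, need {n_frames}"
        )

    # piecewise-linear path sampled at frame times (arc-length uniform in t)
    if waypoints.shape[0] == 1:
        path = np.repeat(waypoints, n_frames, axis=0)
    else:
        s = np.linspace(0.0, 1.0, waypoints.shape[0])
        tt = np.linspace(0.0, 1.0, n_frames)
        path = np.column_stack([
            np.interp(tt, s, waypoints[:, 0]),
            np.interp(tt, s, waypoints[:, 1]),
        ])

    length_px = length_um / params.pixel_size
    width_px = width_um / params.pixel_size

    frames = np.zeros((n_frames, h, w), dtype=np.uint8)
    shape_series = np.zeros((n_frames, 6))
    for k in range(n_frames):
        nxt = min(k + 1, n_frames - 1)
        prv = max(k - 1, 0)
        d = path[nxt] - path[prv]
        heading = np.arctan2(-d[0], d[1]) if np.any(d) else 0.0
        mask = _capsule_mask((h, w), path[k, 0], path[k, 1], heading,
                             bend_schedule[k], length_px, width_px)
        rr, cc = np.nonzero(mask)
        if rr.min() == 0 or rr.max() == h - 1 or cc.min() == 0 or cc.max() == w - 1:
            raise ValueError(
                f"larva silhouette reached the frame border at frame {k}; "
                "discard this sequence (animal left the arena)"
            )
        frames[k][mask] = 255
        shape_series[k] = _mask_shape_moments(mask, params.pixel_size)

    truth = GroundTruth(larva_shape_series=shape_series)
    stack = VideoStack(frames, params.frame_interval, params.pixel_size,
                       ("silhouette",))
    return stack, truth


# ---------------------------------------------------------------------------
# fiber texture


def generate_fiber_texture(
    theta: float,
    coherence: float,
    size: int = 256,
    seed: int = 0,
    wavelength_px: float = 8.0,
) -> Tuple[np.ndarray, float]:
    """Oriented stripe texture for directionality analysis.

    Returns a float image in [0, 255]: sinusoidal stripes whose crests run
    along orientation ``theta`` (radians, measured from the +col axis,
    counter-clockwise with row pointing down the negative y direction),
    mixed with white noise in proportion ``coherence`` (1 = pure stripes,
    0 = pure isotropic noise).  The true orientation is returned alongside.
    """
    if not 0.0 <= coherence <= 1.0:
        raise ValueError("coherence must be in [0, 1]")
    if size < 8:
        raise ValueError("size must be >= 8 px")
    rng = np.random.default_rng(seed)
    rows = np.arange(size)[:, None].astype(float)
    cols = np.arange(size)[None, :].astype(float)
    # coordinate perpendicular to the fiber axis, on (x=col, y=-row)
    s = cols * (-np.sin(theta)) + (-rows) * np.cos(theta)
    stripes = 0.5 + 0.5 * np.sin(2.0 * np.pi * s / wavelength_px)
    noise = rng.uniform(0.0, 1.0, size=(size, size))
    img = coherence * stripes + (1.0 - coherence) * noise
    return img * 255.0, theta
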
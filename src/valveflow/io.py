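"""Image-stack and configuration I/O.

Every recording enters the pipeline as a :class:`VideoStack`: a
``(frame, row, col)`` or ``(frame, channel, row, col)`` array with the frame
interval (s) and pixel size (µm/px) attached.  Calibration is always an
explicit input — no magnification defaults are assumed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = [
    "VideoStack",
    "ROISpec",
    "read_video",
    "write_video",
    "to_grayscale_8bit",
    "load_roi_config",
]

#: ITU-R 601 luminance weights for RGB -> grayscale conversion.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass
class VideoStack:
    """Time-ordered image frames with acquisition metadata.

    Parameters
    ----------
    frames : ndarray
        ``(T, H, W)`` single-channel or ``(T, C, H, W)`` multi-channel.
    frame_interval : float
        Seconds between consecutive frames (> 0).
    pixel_size : float
        µm per pixel (> 0); isotropic.
    channel_names : tuple of str, optional
        One label per channel for multi-channel stacks.
    """

    frames: np.ndarray
    frame_interval: float
    pixel_size: float
    channel_names: tuple = ()

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim not in (3, 4):
            raise ValueError(
                f"frames must be (T,H,W) or (T,C,H,W), got shape {self.frames.shape}"
            )
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if np.issubdtype(self.frames.dtype, np.floating) and not np.all(
            np.isfinite(self.frames)
        ):
            raise ValueError("frame intensities must be finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_channels(self) -> int:
        return self.frames.shape[1] if self.frames.ndim == 4 else 1

    @property
    def shape(self):
        return self.frames.shape

    @property
    def frame_shape(self):
        return self.frames.shape[-2:]

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps in seconds (frame 0 at t = 0)."""
        return np.arange(self.n_frames) * self.frame_interval

    def channel(self, key) -> "VideoStack":
        """Extract one channel as a single-channel stack.

        ``key`` is an integer index or a name from ``channel_names``.
        """
        if self.frames.ndim == 3:
            if key in (0, *(self.channel_names or ())):
                return self
            raise ValueError(f"single-channel stack has no channel {key!r}")
        if isinstance(key, str):
            if key not in self.channel_names:
                raise ValueError(
                    f"unknown channel {key!r}; have {self.channel_names}"
                )
            key = self.channel_names.index(key)
        name = (
            (self.channel_names[key],)
            if self.channel_names and key < len(self.channel_names)
            else ()
        )
        return replace(self, frames=self.frames[:, key], channel_names=name)


@dataclass
class ROISpec:
    """Half-open rectangular region of interest, 0-based (row, col) corner."""

    name: str
    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self):
        if self.height < 1 or self.width < 1:
            raise ValueError(f"ROI {self.name!r}: height and width must be >= 1")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError(f"ROI {self.name!r}: corner must be non-negative")

    @property
    def area_px(self) -> int:
        return self.height * self.width

    def slices(self):
        return (
            slice(self.row0, self.row0 + self.height),
            slice(self.col0, self.col0 + self.width),
        )

    def validate_against(self, frame_shape):
        h, w = frame_shape
        if self.row0 + self.height > h or self.col0 + self.width > w:
            raise ValueError(
                f"ROI {self.name!r} ({self.row0},{self.col0},"
                f"{self.height}x{self.width}) exceeds frame bounds {h}x{w}"
            )

    def overlaps(self, other: "ROISpec") -> bool:
        return (
            self.row0 < other.row0 + other.height
            and other.row0 < self.row0 + self.height
            and self.col0 < other.col0 + other.width
            and other.col0 < self.col0 + self.width
        )


_VIDEO_SUFFIXES = {".avi", ".mp4", ".mov", ".mkv"}


def read_video(path, frame_interval: float, pixel_size: float,
               channel_names=()) -> VideoStack:
    """Read a multi-page TIFF or a common video container into a VideoStack.

    RGB video containers are converted to single-channel luminance
    (ITU-R 601 weights).  Multi-channel TIFFs keep their channel axis.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in _VIDEO_SUFFIXES:
        import imageio.v3 as iio

        frames = np.asarray(iio.imread(path))
        if frames.ndim == 4 and frames.shape[-1] in (3, 4):
            frames = frames[..., :3] @ LUMA_WEIGHTS
            frames = np.round(frames).astype(np.uint8)
    else:
        try:
            frames = tifffile.imread(path)
        except Exception as exc:  # noqa: BLE001 - re-raise as format error
            raise ValueError(f"cannot read {path} as TIFF: {exc}") from exc
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim not in (3, 4):
        raise ValueError(f"unsupported stack shape {frames.shape} in {path}")
    return VideoStack(frames, frame_interval, pixel_size, tuple(channel_names))


def write_video(stack: VideoStack, path, interleave_channels: bool = True):
    """Write a VideoStack as a multi-page TIFF.

    Multi-channel stacks are written interleaved ``(T, C, H, W)`` by default;
    with ``interleave_channels=False`` one file per channel is written with a
    ``.<channel>`` suffix.
    """
    path = Path(path)
    if stack.frames.ndim == 4 and not interleave_channels:
        for c in range(stack.n_channels):
            name = (
                stack.channel_names[c]
                if c < len(stack.channel_names)
                else f"ch{c}"
            )
            out = path.with_name(f"{path.stem}.{name}{path.suffix}")
            tifffile.imwrite(out, stack.frames[:, c], photometric="minisblack")
        return
    tifffile.imwrite(path, stack.frames, photometric="minisblack")


def to_grayscale_8bit(stack: VideoStack) -> VideoStack:
    """Linearly rescale the global min–max range to [0, 255] uint8.

    The rescale is global over the whole stack (per-frame scaling would
    distort slow accumulation trends).  Rounding is half-up.  A constant
    stack has no range to scale and maps to all zeros with a warning.
    """
    frames = stack.frames.astype(np.float64)
    lo, hi = float(frames.min()), float(frames.max())
    if hi == lo:
        warnings.warn("constant-intensity stack: degenerate range, output is all zeros")
        out = np.zeros_like(frames, dtype=np.uint8)
    else:
        scaled = (frames - lo) * (255.0 / (hi - lo))
        out = np.floor(scaled + 0.5).clip(0, 255).astype(np.uint8)
    return replace(stack, frames=out)


def load_roi_config(path, frame_shape=None):
    """Load ROIs and calibration from a YAML config.

    Expected layout::

        pixel_size_um: 5.0
        frame_interval_s: 0.01
        rois:
          - {name: anterior, row0: 10, col0: 300, height: 15, width: 15}

    Returns ``(rois, calibration)`` where calibration is a dict with
    ``pixel_size_um`` / ``frame_interval_s`` keys (values may be None when
    absent).  When ``frame_shape`` is given each ROI is bounds-checked;
    overlapping ROIs are accepted with a warning.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    rois = []
    for entry in cfg.get("rois") or []:
        try:
            roi = ROISpec(
                name=str(entry["name"]),
                row0=int(entry["row0"]),
                col0=int(entry["col0"]),
                height=int(entry["height"]),
                width=int(entry["width"]),
            )
        except KeyError as exc:
            raise ValueError(
                f"ROI entry {entry!r} is missing required key {exc}"
            ) from exc
        if frame_shape is not None:
            roi.validate_against(frame_shape)
        rois.append(roi)
    for i, a in enumerate(rois):
        for b in rois[i + 1:]:
            if a.overlaps(b):
                warnings.warn(f"ROIs {a.name!r} and {b.name!r} overlap")
    calibration = {
        "pixel_size_um": cfg.get("pixel_size_um"),
        "frame_interval_s": cfg.get("frame_interval_s"),
    }
    return rois, calibration
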
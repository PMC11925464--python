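"""Still-image morphometrics.

Myofiber orientation by the Fourier-components method (2-D power spectrum
binned into a 2°-resolution orientation histogram over [-90°, 90°)), fiber
density as the thresholded coverage fraction of an ROI, heart-lumen area
from a traced polygon, and moment-based shape descriptors of binary masks —
including the roundness used for crawling-larva body shape,

    roundness = 4 · area / (π · major_axis²),

the inverse aspect ratio of the moments-fitted ellipse (1 = circle,
→ 0 = elongated).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .io import ROISpec

__all__ = [
    "OrientationHistogram",
    "ShapeDescriptors",
    "directionality_histogram",
    "fiber_density",
    "polygon_area",
    "fit_shape_descriptors",
]


@dataclass
class OrientationHistogram:
    """Power-weighted orientation histogram over [-90°, 90°)."""

    bin_centers: np.ndarray  # degrees
    amplitudes: np.ndarray  # normalised, sum to 1
    dominant_angle: float  # degrees, centre of the max bin
    dispersion: float  # axial circular std, degrees


@dataclass
class ShapeDescriptors:
    area: float  # µm²
    major_axis: float  # µm
    minor_axis: float  # µm
    orientation: float  # radians
    roundness: float


def directionality_histogram(image: np.ndarray, n_bins: int = 90
                             ) -> OrientationHistogram:
    """Fourier-components orientation histogram of an image texture.

    Each non-DC sample of the 2-D power spectrum is assigned to the
    orientation bin of its frequency vector: image structure oriented at θ
    concentrates spectral power along θ + 90°, so orientation = spectral
    angle + 90°, folded into [-90°, 90°).  Default 90 bins give the
    conventional 2° resolution.  Dispersion is the axial (180°-periodic)
    circular standard deviation of the distribution.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("directionality expects a single-channel image")
    if min(image.shape) < 64:
        raise ValueError("image side must be >= 64 px")
    flat = np.ptp(image) == 0
    if flat:
        warnings.warn("constant image: orientation histogram is flat")

    power = np.abs(np.fft.fft2(image - image.mean())) ** 2
    fr = np.fft.fftfreq(image.shape[0])[:, None]  # row frequency
    fc = np.fft.fftfreq(image.shape[1])[None, :]  # col frequency
    # spectral angle on (x=col, y=-row); orientation folds with period 180°
    ang = np.degrees(np.arctan2(-fr, fc)) + 90.0
    ang = ((ang + 90.0) % 180.0) - 90.0
    dc = (fr == 0) & (fc == 0)

    edges = np.linspace(-90.0, 90.0, n_bins + 1)
    which = np.clip(np.digitize(ang[~dc], edges) - 1, 0, n_bins - 1)
    hist = np.bincount(which, weights=power[~dc], minlength=n_bins)
    total = hist.sum()
    if total == 0 or flat:
        hist = np.full(n_bins, 1.0 / n_bins)
    else:
        hist = hist / total
    centers = 0.5 * (edges[:-1] + edges[1:])
    dominant = float(centers[int(np.argmax(hist))])
    # axial circular statistics: double the angles
    z = np.sum(hist * np.exp(2j * np.radians(centers) * 2.0))
    r = min(abs(z), 1.0)
    dispersion = (
        float("inf") if r == 0
        else float(np.degrees(np.sqrt(-2.0 * np.log(r))) / 2.0)
    )
    return OrientationHistogram(centers, hist, dominant, dispersion)


def fiber_density(
    image: np.ndarray,
    roi: ROISpec,
    threshold_method: str = "otsu",
    threshold_value: float = None,
) -> float:
    """Fraction of ROI pixels covered by fibers (above threshold).

    ``threshold_method`` is ``"otsu"`` (default) or ``"fixed"`` with
    ``threshold_value``.
    """
    image = np.asarray(image, dtype=float)
    roi.validate_against(image.shape)
    rs, cs = roi.slices()
    patch = image[rs, cs]
    if threshold_method == "fixed":
        if threshold_value is None:
            raise ValueError("fixed threshold needs threshold_value")
        thr = float(threshold_value)
    elif threshold_method == "otsu":
        if np.ptp(patch) == 0:
            raise ValueError(
                f"ROI {roi.name!r} is constant: Otsu threshold undefined"
            )
        thr = float(threshold_otsu(patch))
    else:
        raise ValueError(f"unknown threshold_method {threshold_method!r}")
    return float((patch > thr).mean())


def polygon_area(vertices: Sequence[Tuple[float, float]],
                 pixel_size: float = 1.0) -> float:
    """Shoelace area of a simple polygon, in µm² via ``pixel_size``."""
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
        raise ValueError("need >= 3 (row, col) vertices")
    from shapely.geometry import Polygon

    poly = Polygon(verts)
    if not poly.is_valid:
        raise ValueError("polygon is self-intersecting or degenerate")
    r, c = verts[:, 0], verts[:, 1]
    area_px = 0.5 * abs(np.sum(r * np.roll(c, -1) - np.roll(r, -1) * c))
    if area_px == 0:
        raise ValueError("polygon vertices are collinear")
    return float(area_px) * pixel_size ** 2


def fit_shape_descriptors(mask: np.ndarray, pixel_size: float = 1.0
                          ) -> ShapeDescriptors:
    """Moments-fitted ellipse descriptors of a single-component binary mask.

    The ellipse has the same second-order central moments as the mask (the
    standard "fit ellipse" of shape-descriptor tools); roundness is
    4·area/(π·major²).
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    lab, n = cc_label(mask, connectivity=2, return_num=True)
    if n != 1:
        raise ValueError(f"mask has {n} connected components, need exactly 1")
    props = regionprops(lab)[0]
    area = props.area * pixel_size ** 2
    major = props.axis_major_length * pixel_size
    minor = props.axis_minor_length * pixel_size
    if major == 0:
        raise ValueError("degenerate mask: zero major axis")
    roundness = 4.0 * area / (np.pi * major ** 2)
    return ShapeDescriptors(
        area=float(area),
        major_axis=float(major),
        minor_axis=float(minor),
        orientation=float(props.orientation),
        roundness=float(roundness),
    )
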
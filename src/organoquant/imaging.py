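"""Lipid-droplet and immunofluorescence quantification.

The droplet pipeline mirrors a common confocal workflow for punctate
neutral-lipid stains (LipidTOX): a constant intensity threshold per channel,
an area filter on connected components, circle detection with a circular
Hough accumulator, and a marker-seeded watershed to split touching droplets.
Per-cell normalisation uses the DAPI nucleus count of the same field.

Intensity (Filipin) quantification is a whole-field mean, and immunomarker
burden is the thresholded marker area divided by the thresholded DAPI area
of the same image.  All coordinates are 0-based (row, col), origin top-left.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import erosion as _gray_erosion
from skimage.segmentation import watershed

__all__ = [
    "ChannelImage",
    "CircleDetection",
    "DropletQuant",
    "ImagingConfig",
    "binarize",
    "area_filter",
    "find_circles",
    "watershed_split",
    "count_nuclei",
    "detect_droplets",
    "mean_intensity",
    "area_fraction",
    "field_average",
]

#: Recognised channel labels.  GENERIC is accepted for ad-hoc images.
CHANNELS = ("DAPI", "FILIPIN", "LIPIDTOX", "MARKER", "GENERIC")


@dataclass(frozen=True)
class ChannelImage:
    """One fluorescence channel: a 2-D grid of finite nonnegative intensities.

    Parameters
    ----------
    pixels:
        2-D float array, arbitrary intensity units.
    channel:
        Label, one of :data:`CHANNELS`.
    """

    pixels: np.ndarray
    channel: str = "GENERIC"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a nonempty 2-D array")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixel intensities must be finite")
        if px.min() < 0:
            raise ValueError("pixel intensities must be nonnegative")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel label {self.channel!r}; expected one of {CHANNELS}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class CircleDetection:
    """A detected circle: subpixel center, radius, and accumulator support in [0, 1]."""

    center: tuple[float, float]
    radius_px: float
    score: float


@dataclass
class DropletQuant:
    """Droplet detections and per-cell summaries for one field.

    ``droplets`` has one row per labeled droplet with columns
    ``droplet_id, center_row, center_col, radius_px, area_px2,
    equiv_diameter_px, mean_intensity``.  ``mean_area_px2`` and
    ``mean_equiv_diameter_px`` are NaN when no droplet was detected
    (an undefined mean, not zero).
    """

    droplets: pd.DataFrame
    n_cells: int
    count_per_cell: float
    mean_area_px2: float
    mean_equiv_diameter_px: float
    labels: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def n_droplets(self) -> int:
        return len(self.droplets)


@dataclass
class ImagingConfig:
    """Tunable constants of the droplet pipeline.

    The thresholds are constant per channel, in the same arbitrary units as
    the images; defaults match the synthetic-field generator defaults
    (background 100, droplet amplitude 600, nucleus amplitude 400) and must
    be re-tuned for real acquisitions.
    """

    thresholds: Mapping[str, float] = field(
        default_factory=lambda: {
            "DAPI": 250.0,
            "LIPIDTOX": 350.0,
            "FILIPIN": 350.0,
            "MARKER": 250.0,
        }
    )
    min_area_px2: float = 9.0
    max_area_px2: float = 2500.0
    r_min: float = 2.0
    r_max: float = 10.0
    sensitivity: float = 0.85
    connectivity: int = 8
    fields_per_coverslip: int = 3
    nucleus_min_area_px2: float = 40.0
    nucleus_max_area_px2: float = math.inf
    nucleus_min_peak_distance: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.r_min <= self.r_max):
            raise ValueError("require 0 < r_min <= r_max")
        if self.min_area_px2 > self.max_area_px2:
            raise ValueError("require min_area_px2 <= max_area_px2")
        if not (0 < self.sensitivity <= 1):
            raise ValueError("sensitivity must be in (0, 1]")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    def threshold_for(self, channel: str) -> float:
        try:
            return float(self.thresholds[channel])
        except KeyError:
            raise KeyError(f"no constant threshold configured for channel {channel!r}") from None


def _cc_connectivity(connectivity: int) -> int:
    # skimage counts connectivity in orthogonal steps: 1 -> 4-connected, 2 -> 8-connected
    return 2 if connectivity == 8 else 1


def binarize(image: ChannelImage, threshold: float) -> np.ndarray:
    """Constant-threshold binarization: foreground where pixel >= threshold."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return image.pixels >= threshold


def area_filter(
    mask: np.ndarray,
    min_area_px2: float,
    max_area_px2: float = math.inf,
    connectivity: int = 8,
) -> np.ndarray:
    """Remove connected components whose pixel area lies outside [min, max]."""
    if min_area_px2 > max_area_px2:
        raise ValueError("require min_area_px2 <= max_area_px2")
    mask = np.asarray(mask, dtype=bool)
    labels, n = cc_label(mask, connectivity=_cc_connectivity(connectivity), return_num=True)
    if n == 0:
        return mask.copy()
    areas = np.bincount(labels.ravel())[1:]  # skip background
    keep = (areas >= min_area_px2) & (areas <= max_area_px2)
    keep_lut = np.concatenate([[False], keep])
    return keep_lut[labels]


def _circle_offsets(radius: int) -> np.ndarray:
    """Unique integer (dr, dc) offsets approximating the circle of given radius."""
    n = max(16, int(math.ceil(4 * math.pi * radius)))
    theta = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    dr = np.rint(radius * np.sin(theta)).astype(int)
    dc = np.rint(radius * np.cos(theta)).astype(int)
    return np.unique(np.stack([dr, dc], axis=1), axis=0)


def find_circles(
    mask: np.ndarray,
    r_min: float,
    r_max: float,
    sensitivity: float = 0.85,
    min_center_distance: float | None = None,
) -> list[CircleDetection]:
    """Circular Hough transform on the boundary pixels of a binary mask.

    For each integer radius r in [r_min, r_max] every boundary pixel votes
    for candidate centers on the circle of radius r around it.  Accumulator
    support is normalised by the discrete perimeter length; candidates with
    support >= ``1 - sensitivity`` survive and are reduced by greedy
    non-maximum suppression with minimum center separation ``r_min``
    (overridable).  Centers and radii are refined to subpixel precision by a
    score-weighted centroid over the 3x3 accumulator neighbourhood and the
    adjacent radius planes.  Detections are returned sorted by descending
    score.
    """
    if r_min <= 0:
        raise ValueError("r_min must be positive")
    if r_min > r_max:
        raise ValueError("require r_min <= r_max")
    if not (0 < sensitivity <= 1):
        raise ValueError("sensitivity must be in (0, 1]")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []

    boundary = mask & ~_gray_erosion(mask, footprint=np.ones((3, 3), dtype=bool))
    br, bc = np.nonzero(boundary)
    if br.size == 0:  # degenerate: mask touches nothing after erosion
        br, bc = np.nonzero(mask)

    radii = np.arange(int(math.ceil(r_min)), int(math.floor(r_max)) + 1)
    if radii.size == 0:
        radii = np.array([int(round(r_min))])
    h, w = mask.shape
    score_threshold = 1.0 - sensitivity

    acc = np.zeros((radii.size, h, w), dtype=np.float32)
    for i, r in enumerate(radii):
        offs = _circle_offsets(int(r))
        rows = br[:, None] + offs[None, :, 0]
        cols = bc[:, None] + offs[None, :, 1]
        inside = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
        np.add.at(acc[i], (rows[inside], cols[inside]), 1.0)
        acc[i] /= len(offs)

    cand = np.nonzero(acc >= score_threshold)
    if cand[0].size == 0:
        return []
    scores = acc[cand]
    order = np.argsort(scores)[::-1]
    ri, rr, cc = (a[order] for a in cand)
    scores = scores[order]

    sep = float(min_center_distance) if min_center_distance is not None else float(r_min)
    kept_idx: list[int] = []
    kept_pts: list[tuple[float, float]] = []
    for k in range(scores.size):
        p = (float(rr[k]), float(cc[k]))
        if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= sep * sep for q in kept_pts):
            kept_idx.append(k)
            kept_pts.append(p)

    detections: list[CircleDetection] = []
    for k in kept_idx:
        i, r0, c0 = int(ri[k]), int(rr[k]), int(cc[k])
        # subpixel center: weighted centroid of the 3x3 accumulator patch
        r_lo, r_hi = max(0, r0 - 1), min(h, r0 + 2)
        c_lo, c_hi = max(0, c0 - 1), min(w, c0 + 2)
        patch = acc[i, r_lo:r_hi, c_lo:c_hi]
        gr, gc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
        wsum = patch.sum()
        center = (float((gr * patch).sum() / wsum), float((gc * patch).sum() / wsum))
        # subpixel radius: score-weighted mean over adjacent radius planes
        i_lo, i_hi = max(0, i - 1), min(radii.size, i + 2)
        rw = acc[i_lo:i_hi, r0, c0].astype(float)
        radius = float(np.sum(radii[i_lo:i_hi] * rw) / rw.sum())
        detections.append(
            CircleDetection(center=center, radius_px=radius, score=float(min(1.0, scores[k])))
        )
    detections.sort(key=lambda d: -d.score)
    return detections


def watershed_split(mask: np.ndarray, circles: Sequence[CircleDetection]) -> np.ndarray:
    """Split the mask into one region per circle center by marker-seeded watershed.

    The watershed runs on the negative Euclidean distance transform of the
    mask, restricted to foreground.  Circle centers falling on background
    are dropped with a warning.  Returns an integer label image; labels
    1..k follow the order of the retained circles.
    """
    mask = np.asarray(mask, dtype=bool)
    markers = np.zeros(mask.shape, dtype=np.int32)
    next_label = 1
    for det in circles:
        r = int(round(det.center[0]))
        c = int(round(det.center[1]))
        if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]) or not mask[r, c]:
            warnings.warn(
                f"circle center ({det.center[0]:.1f}, {det.center[1]:.1f}) lies outside "
                "the mask foreground; dropped",
                stacklevel=2,
            )
            continue
        if markers[r, c] == 0:
            markers[r, c] = next_label
            next_label += 1
    if next_label == 1:
        return markers
    distance = ndi.distance_transform_edt(mask)
    return watershed(-distance, markers=markers, mask=mask)


def count_nuclei(dapi: ChannelImage, config: ImagingConfig) -> int:
    """Count nuclei in the DAPI channel.

    Threshold, area-filter, then split touching nuclei with a watershed
    seeded at the local maxima of the distance transform.
    """
    if dapi.channel not in ("DAPI", "GENERIC"):
        raise ValueError(f"count_nuclei expects a DAPI channel, got {dapi.channel!r}")
    mask = binarize(dapi, config.threshold_for("DAPI"))
    mask = area_filter(
        mask, config.nucleus_min_area_px2, config.nucleus_max_area_px2, config.connectivity
    )
    if not mask.any():
        return 0
    distance = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(
        distance,
        min_distance=config.nucleus_min_peak_distance,
        labels=cc_label(mask, connectivity=_cc_connectivity(config.connectivity)),
        exclude_border=False,
    )
    if len(peaks) == 0:
        return 0
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-distance, markers=markers, mask=mask)
    return int(len(np.unique(labels)) - (1 if (labels == 0).any() else 0))


def _suppress_contained(circles: Sequence[CircleDetection]) -> list[CircleDetection]:
    """Greedy selection of circular features: drop any candidate overlapping a kept one.

    Candidates are visited in descending score order; one is dropped when its
    circle intersects an already kept circle (center distance below the sum of
    radii).  This removes the low-score rim artifacts a Hough accumulator
    produces around each strong disk.  Droplets that physically overlap are
    reported as one feature and separated afterwards by the watershed only if
    both centers survive.
    """
    kept: list[CircleDetection] = []
    for det in sorted(circles, key=lambda d: -d.score):
        overlaps = any(
            (det.center[0] - k.center[0]) ** 2 + (det.center[1] - k.center[1]) ** 2
            < (k.radius_px + det.radius_px) ** 2
            for k in kept
        )
        if not overlaps:
            kept.append(det)
    return kept


def detect_droplets(
    droplet_channel: ChannelImage,
    dapi: ChannelImage,
    config: ImagingConfig,
) -> DropletQuant:
    """Full droplet pipeline: binarize, area-filter, find circles, watershed-split.

    Droplet count and sizes come from the watershed-labeled regions of the
    selected circular features; the per-cell denominator is the DAPI nucleus
    count of the same field.
    """
    if droplet_channel.shape != dapi.shape:
        raise ValueError(
            f"channel shapes differ: droplet {droplet_channel.shape} vs DAPI {dapi.shape}"
        )
    mask = binarize(droplet_channel, config.threshold_for(droplet_channel.channel))
    mask = area_filter(mask, config.min_area_px2, config.max_area_px2, config.connectivity)
    circles = find_circles(mask, config.r_min, config.r_max, config.sensitivity)
    circles = _suppress_contained(circles)
    # pre-drop centers on background (and rounded-pixel duplicates) so that
    # watershed label i+1 corresponds to circles[i]
    seen_px: set[tuple[int, int]] = set()
    retained: list[CircleDetection] = []
    for det in circles:
        r, c = int(round(det.center[0])), int(round(det.center[1]))
        if 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] and mask[r, c] and (r, c) not in seen_px:
            seen_px.add((r, c))
            retained.append(det)
    circles = retained
    labels = watershed_split(mask, circles)

    rows = []
    props = regionprops(labels, intensity_image=droplet_channel.pixels)
    # watershed labels follow circle insertion order; recover the radius per label
    radius_by_label = {i + 1: c.radius_px for i, c in enumerate(circles)}
    for p in props:
        rows.append(
            {
                "droplet_id": int(p.label),
                "center_row": float(p.centroid[0]),
                "center_col": float(p.centroid[1]),
                "radius_px": float(radius_by_label.get(p.label, np.nan)),
                "area_px2": float(p.area),
                "equiv_diameter_px": float(p.equivalent_diameter_area),
                "mean_intensity": float(p.intensity_mean),
            }
        )
    droplets = pd.DataFrame(
        rows,
        columns=[
            "droplet_id",
            "center_row",
            "center_col",
            "radius_px",
            "area_px2",
            "equiv_diameter_px",
            "mean_intensity",
        ],
    )
    n_cells = count_nuclei(dapi, config)
    n = len(droplets)
    count_per_cell = n / n_cells if n_cells > 0 else math.nan
    mean_area = float(droplets["area_px2"].mean()) if n else math.nan
    mean_diam = float(droplets["equiv_diameter_px"].mean()) if n else math.nan
    return DropletQuant(
        droplets=droplets,
        n_cells=n_cells,
        count_per_cell=count_per_cell,
        mean_area_px2=mean_area,
        mean_equiv_diameter_px=mean_diam,
        labels=labels,
    )


def mean_intensity(image: ChannelImage) -> float:
    """Arithmetic mean intensity over the whole field."""
    return float(image.pixels.mean())


def area_fraction(
    marker: ChannelImage, dapi: ChannelImage, t_marker: float, t_dapi: float
) -> float:
    """Thresholded marker-positive area over thresholded DAPI-positive area."""
    if marker.shape != dapi.shape:
        raise ValueError(f"channel shapes differ: {marker.shape} vs {dapi.shape}")
    marker_area = int(binarize(marker, t_marker).sum())
    dapi_area = int(binarize(dapi, t_dapi).sum())
    if dapi_area == 0:
        raise ZeroDivisionError("DAPI-positive area is zero; area fraction undefined")
    return marker_area / dapi_area


def field_average(values: Sequence[float]) -> float:
    """Average per-field measurements into one per-coverslip value.

    The coverslip is the replicate unit handed to group statistics.
    """
    if len(values) == 0:
        raise ValueError("field_average requires at least one value")
    return float(np.mean(values))
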
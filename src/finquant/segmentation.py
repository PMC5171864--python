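"""Raster segmentation: plane splitting, colour thresholding, regenerate
tracing, distal-tip polygons and ray-width measurement.

All operations work on (row, col) 0-based pixel coordinates and treat
pixels lying exactly on the amputation-plane line as distal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon
from skimage.measure import label

from .exceptions import (
    EmptyPolygonError,
    EmptyRegenerateError,
    InvalidAnnotationError,
    MissingRayError,
)
from .records import AmputationPlane, MineralMask, RegionMask, ThresholdSpec

#: Connected mineral components smaller than this are discarded as speckle.
MIN_COMPONENT_PX = 20

#: Components whose along-plane projection intervals are closer than this
#: (px) belong to the same ray (joints split one ray into several segments).
RAY_MERGE_TOL_PX = 2.0


def split_by_plane(
    raster_shape: tuple[int, int], plane: AmputationPlane
) -> tuple[RegionMask, RegionMask]:
    """Partition a raster into distal and proximal half-planes.

    Every pixel is assigned by the sign of its centre's distance to the
    infinite line through the plane endpoints; pixels exactly on the line
    are distal.  Returns ``(distal, proximal)``.
    """
    h, w = int(raster_shape[0]), int(raster_shape[1])
    if h <= 0 or w <= 0:
        raise InvalidAnnotationError("raster shape must be positive")
    rows, cols = np.ogrid[0:h, 0:w]
    d = plane.signed_distance(rows, cols)
    distal = d >= 0
    return RegionMask(distal), RegionMask(~distal)


def apply_rgb_threshold(
    fluorescence: np.ndarray,
    spec: ThresholdSpec,
    restrict_to: Optional[RegionMask] = None,
) -> MineralMask:
    """Select pixels whose R, G and B all fall inside the threshold bands.

    The test is conjunctive across channels; an optional region mask
    restricts the selection (e.g. to the regenerate, yielding RMA).
    """
    img = np.asarray(fluorescence)
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    m = (
        (r >= spec.red_min)
        & (r <= spec.red_max)
        & (g >= spec.green_min)
        & (g <= spec.green_max)
        & (b >= spec.blue_min)
        & (b <= spec.blue_max)
    )
    if restrict_to is not None:
        if restrict_to.mask.shape != m.shape:
            raise InvalidAnnotationError("restrict_to mask shape mismatch")
        m &= restrict_to.mask
    return MineralMask(m, threshold_used=spec)


@dataclass(frozen=True)
class AutotunedThreshold:
    """Result of automatic red-minimum tuning."""

    spec: ThresholdSpec
    no_signal: bool = False  #: set when no distal pixel reaches the search floor


def autotune_red_min(
    fluorescence: np.ndarray,
    distal: RegionMask,
    search: tuple[int, int] = (20, 60),
    base: Optional[ThresholdSpec] = None,
) -> AutotunedThreshold:
    """Choose the red-channel minimum by Otsu's split inside the distal region.

    The published protocol fixes green/blue to 0-30 and red up to 255 but
    leaves the red minimum to be adjusted "methodically and consistently";
    here it is Otsu's threshold on the distal red-channel histogram,
    clamped to the search range (default 20-60).  Deterministic for a
    fixed image; a manual ``ThresholdSpec`` always takes precedence
    upstream.
    """
    lo, hi = int(search[0]), int(search[1])
    if lo > hi:
        raise ValueError("search range is empty")
    base = base or ThresholdSpec(red_min=lo)
    red = np.asarray(fluorescence)[..., 0][distal.mask]
    if red.size == 0 or int(red.max(initial=0)) < lo:
        # No candidate signal: RMA will be 0 under any in-range threshold.
        return AutotunedThreshold(
            ThresholdSpec(
                red_min=hi,
                red_max=base.red_max,
                green_min=base.green_min,
                green_max=base.green_max,
                blue_min=base.blue_min,
                blue_max=base.blue_max,
            ),
            no_signal=True,
        )
    red_min = int(np.clip(_otsu_midpoint(red) + 1, lo, hi))
    return AutotunedThreshold(
        ThresholdSpec(
            red_min=red_min,
            red_max=base.red_max,
            green_min=base.green_min,
            green_max=base.green_max,
            blue_min=base.blue_min,
            blue_max=base.blue_max,
        )
    )


def _otsu_midpoint(values: np.ndarray) -> int:
    """Otsu threshold of 8-bit values, taken at the midpoint of the
    between-class-variance plateau (a two-spike histogram thresholds at
    the spikes' midpoint rather than at the lower spike)."""
    counts = np.bincount(values.ravel(), minlength=256).astype(float)
    total = counts.sum()
    w0 = np.cumsum(counts)  # weight of class <= t
    mu = np.cumsum(counts * np.arange(256))
    mu_t = mu[-1]
    w1 = total - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        between = (mu * total - mu_t * w0) ** 2 / (w0 * w1)
    between[~np.isfinite(between)] = -1.0
    best = np.flatnonzero(between == between.max())
    return int(round((best[0] + best[-1]) / 2))


def rasterize_outline(
    outline: Sequence[tuple[float, float]], shape: tuple[int, int]
) -> RegionMask:
    """Rasterize a manually traced polygon outline ((row, col) vertices)."""
    verts = np.asarray(outline, float)
    if verts.ndim != 2 or verts.shape[0] < 3:
        raise InvalidAnnotationError("manual outline needs >= 3 vertices")
    rr, cc = draw_polygon(verts[:, 0], verts[:, 1], shape=shape)
    m = np.zeros(shape, bool)
    m[rr, cc] = True
    return RegionMask(m)


def segment_regenerate(
    brightfield: np.ndarray,
    distal: RegionMask,
    manual_outline: Optional[Sequence[tuple[float, float]]] = None,
    luminance_factor: float = 0.9,
) -> RegionMask:
    """Trace the regenerate (REG) in the distal half-plane.

    Default rule: tissue pixels have luminance below ``luminance_factor``
    times the modal background luminance (estimated from the image border
    frame, where a well-framed micrograph shows only background); the
    regenerate is the largest connected tissue component distal to the
    plane, with holes filled.  A manually traced outline takes precedence
    when given (the published workflow traces REG by hand).
    """
    from .intensity import rgb_to_luma

    if manual_outline is not None:
        return rasterize_outline(manual_outline, distal.mask.shape)
    luma = rgb_to_luma(brightfield)
    if luma.shape != distal.mask.shape:
        raise InvalidAnnotationError("brightfield shape mismatch with distal mask")
    border = min(8, max(1, min(luma.shape) // 8))
    frame = np.concatenate([
        luma[:border].ravel(), luma[-border:].ravel(),
        luma[:, :border].ravel(), luma[:, -border:].ravel(),
    ])
    modal_background = int(np.bincount(frame, minlength=256).argmax())
    tissue = (luma < luminance_factor * modal_background) & distal.mask
    if not tissue.any():
        raise EmptyRegenerateError("no tissue found distal to the amputation plane")
    lab, n = label(tissue, connectivity=2, return_num=True)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    m = lab == int(sizes.argmax())
    m = ndimage.binary_fill_holes(m)
    return RegionMask(m)


def _ray_groups(mask: np.ndarray, plane: AmputationPlane) -> list[np.ndarray]:
    """Group mineral components into rays.

    8-connected components below ``MIN_COMPONENT_PX`` are speckle and
    dropped.  Components whose projection intervals onto the plane axis
    overlap (within ``RAY_MERGE_TOL_PX``) belong to one joint-segmented
    ray.  Returns one boolean mask per ray, ordered along the plane axis.
    """
    lab, n = label(mask, connectivity=2, return_num=True)
    comps = []
    for i in range(1, n + 1):
        rows, cols = np.nonzero(lab == i)
        if rows.size < MIN_COMPONENT_PX:
            continue
        proj = plane.along_axis(rows, cols)
        comps.append((float(proj.min()), float(proj.max()), rows, cols))
    comps.sort(key=lambda c: c[0])
    groups: list[list[tuple]] = []
    cur_end = None
    for comp in comps:
        if cur_end is not None and comp[0] <= cur_end + RAY_MERGE_TOL_PX:
            groups[-1].append(comp)
            cur_end = max(cur_end, comp[1])
        else:
            groups.append([comp])
            cur_end = comp[1]
    out = []
    for grp in groups:
        m = np.zeros(mask.shape, bool)
        for _, _, rows, cols in grp:
            m[rows, cols] = True
        out.append(m)
    return out


def distal_tip_polygon(
    mineral: MineralMask, plane: AmputationPlane
) -> list[tuple[float, float]]:
    """Polygon joining the most distal mineral tip of each ray (EMA).

    Per ray, the tip is the pixel with maximal signed distance from the
    plane (ties broken toward the dorsal end of the plane axis).  The
    polygon runs p_dorsal -> tips ordered along the plane axis ->
    p_ventral and closes along the plane segment.
    """
    rays = _ray_groups(mineral.mask, plane)
    tips = []
    for m in rays:
        rows, cols = np.nonzero(m)
        dist = plane.signed_distance(rows, cols)
        keep = dist >= 0
        if not keep.any():
            continue
        rows, cols, dist = rows[keep], cols[keep], dist[keep]
        proj = plane.along_axis(rows, cols)
        best = np.lexsort((proj, -dist))[0]
        tips.append((float(proj[best]), float(rows[best]), float(cols[best])))
    if not tips:
        raise EmptyPolygonError("no mineral components distal to the plane")
    tips.sort(key=lambda t: t[0])
    poly = [tuple(map(float, plane.p_dorsal))]
    poly += [(r, c) for _, r, c in tips]
    poly.append(tuple(map(float, plane.p_ventral)))
    return poly


def shoelace_area(polygon: Sequence[tuple[float, float]]) -> float:
    """Area (px^2) of a simple polygon given as (row, col) vertices."""
    pts = np.asarray(polygon, float)
    r, c = pts[:, 0], pts[:, 1]
    return 0.5 * abs(float(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1))))


def ray_widths_at_first_joint(
    mineral_proximal: MineralMask,
    plane: AmputationPlane,
    joint_min_gap_px: int = 2,
    manual_widths_px: Optional[Sequence[float]] = None,
) -> list[float]:
    """Width of each mineralized ray at its first intersegment joint
    proximal to the amputation plane (the RAY measurements).

    Moving proximally from the plane along each ray's axis, the first run
    of >= ``joint_min_gap_px`` mineral-free steps is the joint; the width
    is the ray's extent along the plane axis at the distal border of that
    joint.  Rays without a visible joint are skipped with a warning;
    manual width annotations take precedence.
    """
    if manual_widths_px is not None:
        widths = [float(w) for w in manual_widths_px]
        if not widths:
            raise MissingRayError("manual ray-width list is empty")
        return widths
    widths = []
    for m in _ray_groups(mineral_proximal.mask, plane):
        rows, cols = np.nonzero(m)
        depth = -plane.signed_distance(rows, cols)  # >0 proximal
        keep = depth > 0
        if not keep.any():
            continue
        rows, cols, depth = rows[keep], cols[keep], depth[keep]
        bins = np.floor(depth).astype(int)
        proj = plane.along_axis(rows, cols)
        n_bins = bins.max() + 1
        occupied = np.zeros(n_bins + 1, bool)
        occupied[bins] = True
        first = int(np.argmax(occupied))  # first occupied bin
        width = None
        gap_run = 0
        for b in range(first, n_bins):
            if occupied[b]:
                gap_run = 0
                continue
            gap_run += 1
            if gap_run >= joint_min_gap_px and occupied[b + 1 :].any():
                border = b - gap_run  # last mineral bin before the joint
                sel = bins == border
                width = float(proj[sel].max() - proj[sel].min()) + 1.0
                break
        if width is None:
            warnings.warn(
                "ray without a visible intersegment joint skipped", stacklevel=2
            )
            continue
        widths.append(width)
    if not widths:
        raise MissingRayError("no ray yielded a measurable first-joint width")
    return widths
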
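"""Core data records: annotated image pairs, amputation-plane geometry,
colour-threshold specifications and binary masks.

Coordinate convention: raster origin at the top-left corner, coordinates
are ``(row, col)``, 0-based.  Areas are measured in px^2 and converted to
mm^2 through ``mm_per_px**2``; lengths through ``mm_per_px``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import InvalidAnnotationError

#: Unit vectors (row, col) pointing toward each admissible distal side.
_SIDE_VECTORS = {
    "left": np.array([0.0, -1.0]),
    "right": np.array([0.0, 1.0]),
    "up": np.array([-1.0, 0.0]),
    "down": np.array([1.0, 0.0]),
}


@dataclass(frozen=True)
class AmputationPlane:
    """Straight two-point annotation of the amputation plane.

    Parameters
    ----------
    p_dorsal, p_ventral : (row, col)
        Endpoints of the plane in pixel coordinates.
    distal_side : {'left', 'right', 'up', 'down'}
        Which side of the infinite line through the endpoints holds the
        regenerate.  Must not be parallel to the plane direction.
    """

    p_dorsal: tuple[float, float]
    p_ventral: tuple[float, float]
    distal_side: str = "up"

    def __post_init__(self) -> None:
        if tuple(self.p_dorsal) == tuple(self.p_ventral):
            raise InvalidAnnotationError("amputation plane endpoints coincide")
        if self.distal_side not in _SIDE_VECTORS:
            raise InvalidAnnotationError(
                f"distal_side must be one of {sorted(_SIDE_VECTORS)}, "
                f"got {self.distal_side!r}"
            )
        if abs(np.dot(self.distal_normal, _SIDE_VECTORS[self.distal_side])) < 1e-12:
            raise InvalidAnnotationError(
                "distal_side is parallel to the amputation plane"
            )

    @property
    def direction(self) -> np.ndarray:
        """Unit vector along the plane, from p_dorsal toward p_ventral."""
        v = np.asarray(self.p_ventral, float) - np.asarray(self.p_dorsal, float)
        return v / np.linalg.norm(v)

    @property
    def distal_normal(self) -> np.ndarray:
        """Unit normal to the plane pointing toward the distal side."""
        d = self.direction
        n = np.array([-d[1], d[0]])
        side = _SIDE_VECTORS[self.distal_side]
        if np.dot(n, side) < 0:
            n = -n
        return n

    def signed_distance(self, rows, cols) -> np.ndarray:
        """Signed distance from pixel centres to the plane line.

        Positive values lie on the distal side.  ``rows``/``cols`` may be
        scalars or broadcastable arrays.
        """
        n = self.distal_normal
        r0, c0 = self.p_dorsal
        return (np.asarray(rows, float) - r0) * n[0] + (
            np.asarray(cols, float) - c0
        ) * n[1]

    def along_axis(self, rows, cols) -> np.ndarray:
        """Projection of pixel centres onto the plane axis (px, from p_dorsal)."""
        d = self.direction
        r0, c0 = self.p_dorsal
        return (np.asarray(rows, float) - r0) * d[0] + (
            np.asarray(cols, float) - c0
        ) * d[1]

    @property
    def width_px(self) -> float:
        """Euclidean distance between the endpoints (the stump width STU, px)."""
        return float(
            np.linalg.norm(
                np.asarray(self.p_ventral, float) - np.asarray(self.p_dorsal, float)
            )
        )


@dataclass(frozen=True)
class ThresholdSpec:
    """RGB colour-threshold bands selecting alizarin-red-positive pixels.

    Defaults follow the published protocol: green and blue bands 0-30,
    red up to 255 with a per-dataset minimum expected within 20-60.
    """

    red_min: int = 40
    red_max: int = 255
    green_min: int = 0
    green_max: int = 30
    blue_min: int = 0
    blue_max: int = 30

    def __post_init__(self) -> None:
        for lo, hi, name in (
            (self.red_min, self.red_max, "red"),
            (self.green_min, self.green_max, "green"),
            (self.blue_min, self.blue_max, "blue"),
        ):
            if not (0 <= lo <= hi <= 255):
                raise ValueError(f"{name} band [{lo}, {hi}] is not valid for 8-bit")


@dataclass
class RegionMask:
    """Binary raster region (e.g. the traced regenerate behind REG)."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, bool)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass
class MineralMask(RegionMask):
    """Binary raster of alizarin-red-positive pixels plus the threshold used."""

    threshold_used: ThresholdSpec = field(default_factory=ThresholdSpec)


@dataclass
class FinRecord:
    """One specimen at one time point: image pair, annotation, metadata.

    ``brightfield``/``fluorescence`` are 8-bit RGB arrays of identical
    shape.  ``mm_per_px`` converts pixels to millimetres.  Optional manual
    annotations (regenerate outline polygon, per-ray widths) take
    precedence over automatic segmentation when present.
    """

    specimen_id: str
    time_hpa: float
    brightfield: np.ndarray
    fluorescence: np.ndarray
    plane: AmputationPlane
    mm_per_px: float
    wei_mg: Optional[float] = None
    len_mm: Optional[float] = None
    group_label: str = "control"
    exposure_ms: Optional[float] = None
    manual_outline: Optional[Sequence[tuple[float, float]]] = None
    manual_ray_widths_px: Optional[Sequence[float]] = None

    def __post_init__(self) -> None:
        self.brightfield = as_rgb8(self.brightfield)
        self.fluorescence = as_rgb8(self.fluorescence)
        if self.brightfield.shape != self.fluorescence.shape:
            raise InvalidAnnotationError(
                "bright-field and fluorescence rasters differ in shape"
            )
        if self.mm_per_px <= 0:
            raise InvalidAnnotationError("mm_per_px must be positive")
        if self.time_hpa < 0:
            raise InvalidAnnotationError("time_hpa must be non-negative")


def as_rgb8(image: np.ndarray) -> np.ndarray:
    """Coerce an image to 8-bit RGB.

    RGBA alpha is dropped; 16-bit inputs are linearly rescaled to 8-bit
    (the published thresholds are 8-bit values) with a warning; grayscale
    is replicated across channels.
    """
    import warnings

    img = np.asarray(image)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.ndim != 3 or img.shape[-1] not in (3, 4):
        raise InvalidAnnotationError(f"expected an RGB(A) raster, got shape {img.shape}")
    if img.shape[-1] == 4:
        img = img[..., :3]
    if img.dtype == np.uint16:
        warnings.warn(
            "16-bit image rescaled to 8-bit; colour thresholds assume 8-bit values",
            stacklevel=2,
        )
        img = (img.astype(np.float64) / 257.0).round().astype(np.uint8)
    elif img.dtype != np.uint8:
        img = np.clip(np.asarray(img, np.float64).round(), 0, 255).astype(np.uint8)
    return img


def mm_per_px_from_calibrator(n_pixels: float, span_mm: float) -> float:
    """Spatial calibration from a ruled calibrator image.

    Parameters
    ----------
    n_pixels : float
        Pixel count measured across a ruled span of the calibrator target.
    span_mm : float
        Physical length of that span in millimetres.
    """
    if n_pixels <= 0 or span_mm <= 0:
        raise InvalidAnnotationError("calibrator span and pixel count must be positive")
    return span_mm / n_pixels
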